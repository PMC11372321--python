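attribute,group,recall,specificity,accuracy,auc,difference,optimal_threshold
sex,a,57.14,96.8,96.63,92.65,2.82,
sex,b,59.26,96.1,95.79,92.34,2.82,
marital,a,64.71,96.74,96.58,95.75,11.12,
marital,b,54.17,96.16,95.84,90.33,11.12,
working,a,77.78,96.0,95.9,97.72,25.25,
working,b,53.13,96.6,96.32,90.74,25.25,
race,a,65.52,95.9,95.71,95.72,67.63,
race,b,0.0,98.01,97.52,76.74,67.63,
income,a,60.0,94.14,93.99,93.36,5.4,
income,b,58.06,97.6,97.32,92.54,5.4,
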