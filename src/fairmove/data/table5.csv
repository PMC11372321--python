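attribute,group,recall,specificity,accuracy,auc,difference,optimal_threshold
sex,a,50.0,97.67,97.47,92.94,2.02,
sex,b,51.85,97.84,97.46,96.1,2.02,
marital,a,58.82,97.74,97.54,95.06,13.02,
marital,b,45.83,97.77,97.38,94.83,13.02,
working,a,66.67,97.84,97.66,96.61,19.91,
working,b,46.88,97.72,97.4,94.43,19.91,
race,a,58.62,97.46,97.21,95.31,60.16,
race,b,0.0,99.0,98.51,84.33,60.16,
income,a,50.0,96.54,96.33,94.54,3.42,
income,b,51.61,98.35,98.02,95.48,3.42,
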