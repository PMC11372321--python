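attribute,group,recall,specificity,accuracy,auc,difference,optimal_threshold
sex,a,7.14,99.6,99.17,82.42,22.74,
sex,b,29.63,99.35,98.83,87.3,22.74,
marital,a,23.53,99.25,98.8,82.83,3.07,
marital,b,20.83,99.62,99.12,87.61,3.07,
working,a,11.11,99.77,99.47,92.97,14.4,
working,b,25.0,99.26,98.65,81.93,14.4,
race,a,27.59,99.55,99.07,99.07,28.08,
race,b,0.0,99.06,98.6,98.6,28.08,
income,a,0.0,98.7,97.72,84.9,29.93,
income,b,29.03,99.6,99.21,85.22,29.93,
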