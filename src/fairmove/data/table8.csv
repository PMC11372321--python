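attribute,group,recall,specificity,accuracy,auc,difference,optimal_threshold
sex,a,78.5,95.81,95.73,,4.35,22.7
sex,b,81.48,94.37,94.27,,4.35,22.7
marital,a,100.0,65.43,65.64,,1.53,0.6
marital,b,100.0,66.96,67.17,,1.53,0.6
working,a,77.78,96.75,96.68,,1.26,35.4
working,b,78.13,95.84,95.7,,1.26,35.4
race,a,96.55,90.11,90.15,,4.95,5.9
race,b,100.0,88.61,88.66,,4.95,5.9
income,a,80.0,94.48,94.34,,15.18,45.6
income,b,67.74,97.4,97.24,,15.18,45.6
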