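attribute,group,recall,specificity,accuracy,auc,difference,optimal_threshold
sex,a,50.0,97.88,97.68,,1.85,66.6
sex,b,51.85,97.88,97.49,,1.85,66.6
marital,a,88.24,88.36,88.36,,0.79,18.6
marital,b,87.5,88.31,88.3,,0.79,18.6
working,a,77.78,93.33,93.24,,9.92,33.8
working,b,68.75,94.22,94.06,,9.92,33.8
race,a,89.66,88.27,88.28,,25.92,19.9
race,b,66.67,91.2,91.07,,25.92,19.9
income,a,50.0,97.0,96.79,,3.19,68.0
income,b,51.61,98.58,98.25,,3.19,68.0
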