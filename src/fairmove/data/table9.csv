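attribute,group,recall,specificity,accuracy,auc,difference,optimal_threshold
sex,a,50.0,97.85,97.65,,1.88,52.1
sex,b,51.85,97.88,97.49,,1.88,52.1
marital,a,100.0,50.26,50.51,,0.07,5.8
marital,b,100.0,50.33,50.69,,0.07,5.8
working,a,88.89,89.27,89.27,,5.12,12.5
working,b,87.5,85.54,85.56,,5.12,12.5
race,a,100.0,73.39,73.56,,0.03,8.1
race,b,100.0,73.42,73.55,,0.03,8.1
income,a,50.0,96.96,96.74,,3.07,52.6
income,b,51.61,98.42,98.09,,3.07,52.6
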