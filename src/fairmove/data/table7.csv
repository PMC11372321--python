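attribute,group,recall,specificity,accuracy,auc,difference,optimal_threshold
sex,a,85.71,58.99,59.12,,1.08,18.4
sex,b,85.19,58.43,58.63,,1.08,18.4
marital,a,76.47,87.13,87.07,,3.69,24.1
marital,b,75.0,89.35,89.25,,3.69,24.1
working,a,66.67,95.01,94.91,,15.22,24.5
working,b,71.88,85.0,84.9,,15.22,24.5
race,a,89.66,58.64,58.85,,26.6,18.4
race,b,66.67,62.25,62.27,,26.6,18.4
income,a,90.0,44.83,45.28,,8.89,17.3
income,b,87.1,50.82,51.02,,8.89,17.3
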