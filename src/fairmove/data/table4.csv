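attribute,group,recall,specificity,accuracy,auc,difference,optimal_threshold
sex,a,57.14,97.69,97.5,97.49,21.31,
sex,b,77.78,97.02,96.87,95.83,21.31,
marital,a,76.47,96.98,96.85,97.81,10.4,
marital,b,66.67,97.58,97.39,95.71,10.4,
working,a,77.78,97.73,97.67,97.69,9.71,
working,b,68.75,97.05,96.82,95.82,9.71,
race,a,79.31,97.07,96.95,97.66,46.57,
race,b,33.33,97.66,97.36,94.33,46.57,
income,a,80.0,94.68,94.54,97.43,15.38,
income,b,67.74,97.8,97.63,96.42,15.38,
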