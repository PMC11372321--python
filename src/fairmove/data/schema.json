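{
 "p01": {
  "kind": "clinical",
  "name": "oxycodone_use",
  "prevalence": 0.0653,
  "coefficient": 2.4
 },
 "p02": {
  "kind": "clinical",
  "name": "oxymorphone_use",
  "prevalence": 0.0029,
  "coefficient": 2.7
 },
 "p03": {
  "kind": "clinical",
  "name": "hydrocodone_use",
  "prevalence": 0.1063,
  "coefficient": 2.1
 },
 "p04": {
  "kind": "clinical",
  "name": "hydromorphone_use",
  "prevalence": 0.004,
  "coefficient": 2.55
 },
 "p05": {
  "kind": "clinical",
  "name": "fentanyl_use",
  "prevalence": 0.004,
  "coefficient": 3.0
 },
 "p06": {
  "kind": "clinical",
  "name": "morphine_use",
  "prevalence": 0.01,
  "coefficient": 2.4
 },
 "p07": {
  "kind": "clinical",
  "name": "codeine_use",
  "prevalence": 0.0612,
  "coefficient": 1.5
 },
 "p08": {
  "kind": "clinical",
  "name": "methadone_use",
  "prevalence": 0.005,
  "coefficient": 3.3
 },
 "p09": {
  "kind": "clinical",
  "name": "tramadol_use",
  "prevalence": 0.03,
  "coefficient": 1.8
 },
 "p10": {
  "kind": "clinical",
  "name": "buprenorphine_use",
  "prevalence": 0.008,
  "coefficient": 3.6
 },
 "p11": {
  "kind": "clinical",
  "name": "heroin_use",
  "prevalence": 0.006,
  "coefficient": 3.9
 },
 "p12": {
  "kind": "clinical",
  "name": "drug_treatment_history",
  "prevalence": 0.0487,
  "coefficient": 2.7
 },
 "p13": {
  "kind": "clinical",
  "name": "diabetes",
  "prevalence": 0.0562,
  "coefficient": 0.3
 },
 "p14": {
  "kind": "clinical",
  "name": "chronic_bronchitis",
  "prevalence": 0.03,
  "coefficient": 0.45
 },
 "p15": {
  "kind": "clinical",
  "name": "cirrhosis",
  "prevalence": 0.003,
  "coefficient": 0.6
 },
 "p16": {
  "kind": "clinical",
  "name": "hepatitis_b",
  "prevalence": 0.004,
  "coefficient": 0.45
 },
 "p17": {
  "kind": "clinical",
  "name": "hepatitis_c",
  "prevalence": 0.006,
  "coefficient": 0.75
 },
 "p18": {
  "kind": "clinical",
  "name": "kidney_disease",
  "prevalence": 0.01,
  "coefficient": 0.3
 },
 "p19": {
  "kind": "clinical",
  "name": "asthma",
  "prevalence": 0.1196,
  "coefficient": 0.3
 },
 "p20": {
  "kind": "clinical",
  "name": "aids",
  "prevalence": 0.002,
  "coefficient": 0.45
 },
 "p21": {
  "kind": "clinical",
  "name": "cancer",
  "prevalence": 0.02,
  "coefficient": 0.15
 },
 "p22": {
  "kind": "clinical",
  "name": "depression",
  "prevalence": 0.2882,
  "coefficient": 1.05
 },
 "p23": {
  "kind": "clinical",
  "name": "anxiety",
  "prevalence": 0.15,
  "coefficient": 0.75
 },
 "p24": {
  "kind": "clinical",
  "name": "cigarette_use",
  "prevalence": 0.25,
  "coefficient": 0.75
 },
 "p25": {
  "kind": "clinical",
  "name": "alcohol_use",
  "prevalence": 0.5,
  "coefficient": 0.3
 },
 "p26": {
  "kind": "clinical",
  "name": "marijuana_use",
  "prevalence": 0.18,
  "coefficient": 0.9
 },
 "p27": {
  "kind": "clinical",
  "name": "cocaine_use",
  "prevalence": 0.02,
  "coefficient": 1.2
 },
 "p28": {
  "kind": "clinical",
  "name": "sedative_misuse",
  "prevalence": 0.01,
  "coefficient": 1.35
 },
 "p29": {
  "kind": "clinical",
  "name": "stimulant_misuse",
  "prevalence": 0.015,
  "coefficient": 1.2
 },
 "p30": {
  "kind": "onehot",
  "name": "sex_male",
  "attribute": "sex",
  "level": "male",
  "coefficient": 0.0
 },
 "p31": {
  "kind": "onehot",
  "name": "sex_female",
  "attribute": "sex",
  "level": "female",
  "coefficient": 0.0
 },
 "p32": {
  "kind": "onehot",
  "name": "marital_married",
  "attribute": "marital",
  "level": "married",
  "coefficient": 0.0
 },
 "p33": {
  "kind": "onehot",
  "name": "marital_widowed",
  "attribute": "marital",
  "level": "widowed",
  "coefficient": 0.0
 },
 "p34": {
  "kind": "onehot",
  "name": "marital_divorced",
  "attribute": "marital",
  "level": "divorced",
  "coefficient": 0.0
 },
 "p35": {
  "kind": "onehot",
  "name": "marital_never",
  "attribute": "marital",
  "level": "never",
  "coefficient": 0.0
 },
 "p36": {
  "kind": "onehot",
  "name": "marital_unknown",
  "attribute": "marital",
  "level": "unknown",
  "coefficient": 0.0
 },
 "p37": {
  "kind": "onehot",
  "name": "working_full",
  "attribute": "working",
  "level": "full",
  "coefficient": 0.0
 },
 "p38": {
  "kind": "onehot",
  "name": "working_part",
  "attribute": "working",
  "level": "part",
  "coefficient": 0.0
 },
 "p39": {
  "kind": "onehot",
  "name": "working_unknown",
  "attribute": "working",
  "level": "unknown",
  "coefficient": 0.0
 },
 "p40": {
  "kind": "onehot",
  "name": "race_white",
  "attribute": "race",
  "level": "white",
  "coefficient": 0.0
 },
 "p41": {
  "kind": "onehot",
  "name": "race_black",
  "attribute": "race",
  "level": "black",
  "coefficient": 0.0
 },
 "p42": {
  "kind": "onehot",
  "name": "race_other",
  "attribute": "race",
  "level": "other",
  "coefficient": 0.0
 },
 "p43": {
  "kind": "onehot",
  "name": "income_low",
  "attribute": "income",
  "level": "low",
  "coefficient": 0.0
 },
 "p44": {
  "kind": "onehot",
  "name": "income_other",
  "attribute": "income",
  "level": "other",
  "coefficient": 0.0
 }
}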