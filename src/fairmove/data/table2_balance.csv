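covariate,level,status,smd,variance_ratio
race,white,before,0.1526,0.8896
race,white,after,0.0188,0.9869
race,black,before,-0.0351,0.9065
race,black,after,-0.0385,0.8979
race,other,before,-0.1453,0.8317
race,other,after,0.006,1.0141
income,low,before,0.4106,1.7267
income,low,after,-0.0178,0.9913
sex,male,before,0.1049,1.0108
sex,male,after,0.0069,1.0045
marital,married,before,-0.34,0.7332
marital,married,after,0.0094,1.018
marital,widowed,before,-0.0866,0.4867
marital,widowed,after,-0.0019,0.9863
marital,divorced,before,0.3862,2.3224
marital,divorced,after,0.0324,1.0534
marital,never,before,0.1467,1.0195
marital,never,after,-0.0077,1.0053
working,full,before,-0.3279,0.7921
working,full,after,0.0391,1.052
working,part,before,-0.0608,0.8793
working,part,after,0.0069,1.0212
bmi,,before,-0.0464,1.2435
bmi,,after,0.0169,1.0244
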