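model,tp,fn,fp,tn
nn_sgd,9,32,35,6503
nn_adam,29,12,175,6363
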