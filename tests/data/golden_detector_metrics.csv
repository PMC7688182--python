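partner,n_children,accuracy,precision,recall,f1
adult,3,98.0729,100.0,36.6577,84.6034
peer,3,99.4965,100.0,91.915,95.7569
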