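cohort,n,n_ge1,n_ge3
patients,52,42,36
healthy,10,0,0
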