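group,pr,no_pr
CTC-HER2+,5,1
CTC-HER2-,0,5
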