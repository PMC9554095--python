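ctc_status,HER2-neg,HER2-low,HER2-pos
CTC-HER2-,14,5,9
CTC-HER2+,0,4,10
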