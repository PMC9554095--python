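variable,group,responders,nonresponders
count,lt3,5,1
count,ge3,6,10
her2,CTC-HER2-,0,6
her2,CTC-HER2+,6,4
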