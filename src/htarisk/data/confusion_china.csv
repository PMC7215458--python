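actual,II,III,IV,V
II,399,2,0,7
III,93,9,0,2
IV,19,1,0,12
V,4,1,0,20
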