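metal,background_value,toxic_response
As,9.1,10
Cd,0.1,30
Cr,55.3,2
Cu,22.9,5
Ni,29.9,5
Pb,14.7,5
Zn,63.5,1
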