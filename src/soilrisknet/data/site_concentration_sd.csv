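site,As,Cd,Cr,Cu,Ni,Pb,Zn
TD0,2.42,0.08,20.04,184.21,7.63,221.91,18.91
TD1,4.32,0.66,176.75,157.59,55.13,360.65,36.37
TD2,3.44,0.34,169.15,36.15,44.53,292.03,23.84
TD3,3.96,0.25,174.71,36.37,67.16,349.17,16.73
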