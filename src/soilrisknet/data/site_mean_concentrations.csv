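site,As,Cd,Cr,Cu,Ni,Pb,Zn
TD0,6.94,0.17,47.24,338.00,34.17,756.76,33.43
TD1,12.28,1.25,381.91,323.28,79.51,1227.24,77.17
TD2,7.15,0.54,371.90,122.10,77.89,983.42,89.23
TD3,10.52,0.76,339.05,157.91,101.79,1098.53,64.67
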