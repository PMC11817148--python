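element,vdw_radius,vdw_epsilon
H,1.20,0.0157
C,1.70,0.0903
N,1.55,0.0860
O,1.52,0.2100
S,1.80,0.2500
P,1.80,0.2000
F,1.47,0.0610
Cl,1.75,0.2650
Br,1.85,0.3200
I,1.98,0.4000
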