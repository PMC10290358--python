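element,control_epiderm,control_cross_section,water_epiderm,water_cross_section
C,57.14,54.43,40.75,56.44
N,0.99,0.67,0.94,1.18
O,26.39,37.32,45.98,37.47
Na,0.13,0.09,0.11,0.10
Mg,0.09,0.05,0.07,0.00
Al,0.12,0.05,0.16,0.06
Si,13.77,2.83,10.74,1.96
P,0.02,0.00,0.09,0.15
Hg,0.00,0.26,0.26,0.00
S,0.00,0.04,0.00,0.17
Cl,0.09,0.55,0.05,0.24
K,0.15,0.77,0.09,0.55
Ca,0.08,0.51,0.00,0.54
Ti,0.10,0.00,0.00,0.00
V,0.10,0.00,0.00,0.00
Pb,0.10,0.49,0.12,0.00
Fe,0.41,0.80,0.19,0.63
Cr,0.00,0.71,0.24,0.51
Cu,0.34,0.42,0.19,0.00
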