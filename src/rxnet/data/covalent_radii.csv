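symbol,atomic_number,covalent_radius,electronegativity,mass
H,1,0.31,2.20,1.008
He,2,0.28,0.00,4.003
Li,3,1.28,0.98,6.94
Be,4,0.96,1.57,9.012
B,5,0.84,2.04,10.81
C,6,0.76,2.55,12.011
N,7,0.71,3.04,14.007
O,8,0.66,3.44,15.999
F,9,0.57,3.98,18.998
Ne,10,0.58,0.00,20.180
Na,11,1.66,0.93,22.990
Mg,12,1.41,1.31,24.305
Al,13,1.21,1.61,26.982
Si,14,1.11,1.90,28.085
P,15,1.07,2.19,30.974
S,16,1.05,2.58,32.06
Cl,17,1.02,3.16,35.45
Ar,18,1.06,0.00,39.948
K,19,2.03,0.82,39.098
Ca,20,1.76,1.00,40.078
Fe,26,1.32,1.83,55.845
Ni,28,1.24,1.91,58.693
Cu,29,1.32,1.90,63.546
Zn,30,1.22,1.65,65.38
Br,35,1.20,2.96,79.904
I,53,1.39,2.66,126.904
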