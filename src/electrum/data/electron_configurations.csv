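symbol,atomic_number,1s,2s,2p,3s,3p,4s,3d,4p,5s,4d,5p,6s,4f,5d,6p
H,1,1,0,0,0,0,0,0,0,0,0,0,0,0,0,0
He,2,2,0,0,0,0,0,0,0,0,0,0,0,0,0,0
Li,3,2,1,0,0,0,0,0,0,0,0,0,0,0,0,0
Be,4,2,2,0,0,0,0,0,0,0,0,0,0,0,0,0
B,5,2,2,1,0,0,0,0,0,0,0,0,0,0,0,0
C,6,2,2,2,0,0,0,0,0,0,0,0,0,0,0,0
N,7,2,2,3,0,0,0,0,0,0,0,0,0,0,0,0
O,8,2,2,4,0,0,0,0,0,0,0,0,0,0,0,0
F,9,2,2,5,0,0,0,0,0,0,0,0,0,0,0,0
Ne,10,2,2,6,0,0,0,0,0,0,0,0,0,0,0,0
Na,11,2,2,6,1,0,0,0,0,0,0,0,0,0,0,0
Mg,12,2,2,6,2,0,0,0,0,0,0,0,0,0,0,0
Al,13,2,2,6,2,1,0,0,0,0,0,0,0,0,0,0
Si,14,2,2,6,2,2,0,0,0,0,0,0,0,0,0,0
P,15,2,2,6,2,3,0,0,0,0,0,0,0,0,0,0
S,16,2,2,6,2,4,0,0,0,0,0,0,0,0,0,0
Cl,17,2,2,6,2,5,0,0,0,0,0,0,0,0,0,0
Ar,18,2,2,6,2,6,0,0,0,0,0,0,0,0,0,0
K,19,2,2,6,2,6,1,0,0,0,0,0,0,0,0,0
Ca,20,2,2,6,2,6,2,0,0,0,0,0,0,0,0,0
Sc,21,2,2,6,2,6,2,1,0,0,0,0,0,0,0,0
Ti,22,2,2,6,2,6,2,2,0,0,0,0,0,0,0,0
V,23,2,2,6,2,6,2,3,0,0,0,0,0,0,0,0
Cr,24,2,2,6,2,6,1,5,0,0,0,0,0,0,0,0
Mn,25,2,2,6,2,6,2,5,0,0,0,0,0,0,0,0
Fe,26,2,2,6,2,6,2,6,0,0,0,0,0,0,0,0
Co,27,2,2,6,2,6,2,7,0,0,0,0,0,0,0,0
Ni,28,2,2,6,2,6,2,8,0,0,0,0,0,0,0,0
Cu,29,2,2,6,2,6,1,10,0,0,0,0,0,0,0,0
Zn,30,2,2,6,2,6,2,10,0,0,0,0,0,0,0,0
Ga,31,2,2,6,2,6,2,10,1,0,0,0,0,0,0,0
Ge,32,2,2,6,2,6,2,10,2,0,0,0,0,0,0,0
As,33,2,2,6,2,6,2,10,3,0,0,0,0,0,0,0
Se,34,2,2,6,2,6,2,10,4,0,0,0,0,0,0,0
Br,35,2,2,6,2,6,2,10,5,0,0,0,0,0,0,0
Kr,36,2,2,6,2,6,2,10,6,0,0,0,0,0,0,0
Rb,37,2,2,6,2,6,2,10,6,1,0,0,0,0,0,0
Sr,38,2,2,6,2,6,2,10,6,2,0,0,0,0,0,0
Y,39,2,2,6,2,6,2,10,6,2,1,0,0,0,0,0
Zr,40,2,2,6,2,6,2,10,6,2,2,0,0,0,0,0
Nb,41,2,2,6,2,6,2,10,6,1,4,0,0,0,0,0
Mo,42,2,2,6,2,6,2,10,6,1,5,0,0,0,0,0
Tc,43,2,2,6,2,6,2,10,6,2,5,0,0,0,0,0
Ru,44,2,2,6,2,6,2,10,6,1,7,0,0,0,0,0
Rh,45,2,2,6,2,6,2,10,6,1,8,0,0,0,0,0
Pd,46,2,2,6,2,6,2,10,6,0,10,0,0,0,0,0
Ag,47,2,2,6,2,6,2,10,6,1,10,0,0,0,0,0
Cd,48,2,2,6,2,6,2,10,6,2,10,0,0,0,0,0
In,49,2,2,6,2,6,2,10,6,2,10,1,0,0,0,0
Sn,50,2,2,6,2,6,2,10,6,2,10,2,0,0,0,0
Sb,51,2,2,6,2,6,2,10,6,2,10,3,0,0,0,0
Te,52,2,2,6,2,6,2,10,6,2,10,4,0,0,0,0
I,53,2,2,6,2,6,2,10,6,2,10,5,0,0,0,0
Xe,54,2,2,6,2,6,2,10,6,2,10,6,0,0,0,0
Cs,55,2,2,6,2,6,2,10,6,2,10,6,1,0,0,0
Ba,56,2,2,6,2,6,2,10,6,2,10,6,2,0,0,0
La,57,2,2,6,2,6,2,10,6,2,10,6,2,0,1,0
Ce,58,2,2,6,2,6,2,10,6,2,10,6,2,1,1,0
Pr,59,2,2,6,2,6,2,10,6,2,10,6,2,3,0,0
Nd,60,2,2,6,2,6,2,10,6,2,10,6,2,4,0,0
Pm,61,2,2,6,2,6,2,10,6,2,10,6,2,5,0,0
Sm,62,2,2,6,2,6,2,10,6,2,10,6,2,6,0,0
Eu,63,2,2,6,2,6,2,10,6,2,10,6,2,7,0,0
Gd,64,2,2,6,2,6,2,10,6,2,10,6,2,7,1,0
Tb,65,2,2,6,2,6,2,10,6,2,10,6,2,9,0,0
Dy,66,2,2,6,2,6,2,10,6,2,10,6,2,10,0,0
Ho,67,2,2,6,2,6,2,10,6,2,10,6,2,11,0,0
Er,68,2,2,6,2,6,2,10,6,2,10,6,2,12,0,0
Tm,69,2,2,6,2,6,2,10,6,2,10,6,2,13,0,0
Yb,70,2,2,6,2,6,2,10,6,2,10,6,2,14,0,0
Lu,71,2,2,6,2,6,2,10,6,2,10,6,2,14,1,0
Hf,72,2,2,6,2,6,2,10,6,2,10,6,2,14,2,0
Ta,73,2,2,6,2,6,2,10,6,2,10,6,2,14,3,0
W,74,2,2,6,2,6,2,10,6,2,10,6,2,14,4,0
Re,75,2,2,6,2,6,2,10,6,2,10,6,2,14,5,0
Os,76,2,2,6,2,6,2,10,6,2,10,6,2,14,6,0
Ir,77,2,2,6,2,6,2,10,6,2,10,6,2,14,7,0
Pt,78,2,2,6,2,6,2,10,6,2,10,6,1,14,9,0
Au,79,2,2,6,2,6,2,10,6,2,10,6,1,14,10,0
Hg,80,2,2,6,2,6,2,10,6,2,10,6,2,14,10,0
Tl,81,2,2,6,2,6,2,10,6,2,10,6,2,14,10,1
Pb,82,2,2,6,2,6,2,10,6,2,10,6,2,14,10,2
Bi,83,2,2,6,2,6,2,10,6,2,10,6,2,14,10,3
Po,84,2,2,6,2,6,2,10,6,2,10,6,2,14,10,4
At,85,2,2,6,2,6,2,10,6,2,10,6,2,14,10,5
Rn,86,2,2,6,2,6,2,10,6,2,10,6,2,14,10,6
Pa,91,2,2,6,2,6,2,10,6,2,10,6,2,14,10,6
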