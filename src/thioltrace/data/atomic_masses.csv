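element,monoisotopic_mass
H,1.00782503
C,12.0
N,14.00307401
O,15.99491462
F,18.99840316
Na,22.98976928
Si,27.97692653
P,30.97376200
S,31.97207117
Cl,34.96885268
K,38.96370649
Se,79.91652180
Br,78.91833760
I,126.90447190
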