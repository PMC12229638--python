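analyte,formula,precursor_mz,product_mz
CA,C2H7NS,449.2172,406.1769
Cys,C3H7NO2S,493.2072,406.1746
Hcy,C4H9NO2S,507.2202,406.1770
GSH,C10H17N3O6S,679.2752,406.1769
Nac,C5H9NO3S,535.2181,406.1751
Cys-Gly,C5H10N2O3S,550.2288,406.1758
gGlu-Cys,C8H14N2O5S,622.2416,406.1743
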