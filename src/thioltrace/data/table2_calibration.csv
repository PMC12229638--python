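analyte,range_min_pmol,range_max_pmol,slope,intercept,r_squared,lod_fmol,loq_fmol
CA,0.024,250,0.00007,-0.0001,0.9995,8,12
Cys,0.024,500,0.0022,0.00004,0.9999,7.5,12
Hcy,0.024,500,0.00008,0.0003,0.9997,9,12
GSH,0.024,125,0.0005,0.0004,0.9995,8,12
Nac,0.024,500,0.0007,0.0013,0.9999,0.8,1.2
Cys-Gly,0.024,250,0.0019,-0.0031,0.9999,7.5,12
gGlu-Cys,0.024,125,0.0001,0.0001,0.9997,8,12
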