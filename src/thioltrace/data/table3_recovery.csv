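analyte,matrix,spike_pmol,measured_mean_pmol,measured_sd_pmol,inter_day_cv,intra_day_cv,recovery_pct
CA,serum,0,0.05,,3.37,3.48,
CA,serum,1.95,1.85,0.03,4.42,2.15,92.12
CA,serum,3.91,3.52,0.12,2.13,4.17,88.8
CA,serum,15.63,13.41,0.15,3.86,3.23,85.57
CA,CSF,0,0.03,,2.62,1.63,
CA,CSF,1.95,1.93,0.073,3.61,2.52,97.5
CA,CSF,3.91,3.64,0.10,3.6,1.65,92.49
CA,CSF,15.63,14.00,0.019,3.61,4.6,89.44
Cys,serum,0,244.62,,3.92,2.34,
Cys,serum,1.95,246.37,0.60,3.08,2.7,89.69
Cys,serum,3.91,248.01,5.13,4.24,3.39,86.8
Cys,serum,15.63,257.86,4.65,2.6,1.55,84.77
Cys,CSF,0,1.68,,3.08,3.68,
Cys,CSF,1.95,3.59,0.039,4.66,4.13,97.85
Cys,CSF,3.91,5.34,0.31,5.27,4.74,93.73
Cys,CSF,15.63,15.65,0.52,4.09,2.91,89.37
Hcy,serum,0,10.56,,3.27,3.08,
Hcy,serum,1.95,12.39,0.56,3.18,1.46,93.78
Hcy,serum,3.91,14.04,0.31,2.94,3.59,89.14
Hcy,serum,15.63,24.22,0.19,3.63,2.81,87.44
Hcy,CSF,0,0.1,,4.3,2.12,
Hcy,CSF,1.95,1.86,0.03,5.45,3.69,89.95
Hcy,CSF,3.91,3.40,0.08,4.11,5.07,84.48
Hcy,CSF,15.63,12.82,0.17,2.49,3.87,81.4
GSH,serum,0,1.63,,2.45,2.16,
GSH,serum,1.95,3.35,0.094,5.58,2.83,88.28
GSH,serum,3.91,4.94,0.34,4.17,4.21,84.66
GSH,serum,15.63,14.44,0.58,1.59,3.46,82
GSH,CSF,0,0.34,,3.13,4.59,
GSH,CSF,1.95,2.16,0.11,4.53,4.05,93.14
GSH,CSF,3.91,3.85,0.31,2.17,4.22,89.79
GSH,CSF,15.63,12.87,0.086,2.32,4.58,80.17
Nac,serum,0,0.96,,2.99,1.99,
Nac,serum,1.95,2.79,0.07,4.69,0.99,94.06
Nac,serum,3.91,4.57,0.01,3.95,3.38,92.53
Nac,serum,15.63,14.07,0.30,4.99,4.23,83.65
Nac,CSF,0,0.08,,3.44,2.87,
Nac,CSF,1.95,1.86,0.045,2.56,4.31,91.18
Nac,CSF,3.91,3.39,0.10,4.1,3.73,84.84
Nac,CSF,15.63,13.00,0.32,3.37,3.71,82.98
Cys-Gly,serum,0,40.17,,5.84,1.84,
Cys-Gly,serum,1.95,42.05,0.48,5.2,1.86,96.05
Cys-Gly,serum,3.91,43.82,0.72,3.85,3.95,93.37
Cys-Gly,serum,15.63,53.52,0.82,4.07,3.8,85.41
Cys-Gly,CSF,0,7.46,,3.59,2.48,
Cys-Gly,CSF,1.95,9.40,0.57,3.21,2.74,99.42
Cys-Gly,CSF,3.91,11.25,0.50,3.86,2.97,97.31
Cys-Gly,CSF,15.63,22.60,1.26,3.28,2.18,96.91
gGlu-Cys,serum,0,5.56,,4.02,2.22,
gGlu-Cys,serum,1.95,7.39,0.27,1.53,2.27,92.96
gGlu-Cys,serum,3.91,9.09,0.22,5.16,5.54,90.23
gGlu-Cys,serum,15.63,18.41,0.51,3.67,2.82,82.24
gGlu-Cys,CSF,0,0.22,,2.08,1.58,
gGlu-Cys,CSF,1.95,1.98,0.49,4.73,3.67,90.31
gGlu-Cys,CSF,3.91,3.67,0.33,2.8,5.53,88.26
gGlu-Cys,CSF,15.63,13.03,0.23,5.49,3.73,82.02
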