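# Reported serum / CSF group-mean ratios for the seven targeted thiols.
# "fold" is the magnitude of the ratio; "higher_in" gives its direction
# (which cohort had the larger mean).  Case/control ratios used by the
# cohort generator are fold when higher_in == PCNSL and 1/fold otherwise.
serum:
  CA:       {fold: 1.04,  higher_in: HV}
  Cys:      {fold: 1.089, higher_in: PCNSL}
  Hcy:      {fold: 1.36,  higher_in: PCNSL}
  GSH:      {fold: 1.25,  higher_in: PCNSL}
  Nac:      {fold: 1.25,  higher_in: PCNSL}
  Cys-Gly:  {fold: 1.18,  higher_in: HV}
  gGlu-Cys: {fold: 1.89,  higher_in: PCNSL}
csf:
  CA:       {fold: 1.14,  higher_in: HV}
  Cys:      {fold: 1.36,  higher_in: PCNSL}
  Hcy:      {fold: 1.17,  higher_in: PCNSL}
  GSH:      {fold: 1.58,  higher_in: HV}
  Nac:      {fold: 1.40,  higher_in: HV}
  Cys-Gly:  {fold: 1.02,  higher_in: PCNSL}
  gGlu-Cys: {fold: 1.09,  higher_in: PCNSL}
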