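# File formats

All CSV files are UTF-8, comma-separated, header required. Retention times
are minutes everywhere (mzML scan times in seconds are converted on read).
Greek γ in analyte names is stored as the ASCII alias `gGlu-Cys`.

## MS2 spectra

- **MGF** (read/write): `TITLE` = spectrum id, `PEPMASS` = precursor m/z,
  `RTINSECONDS`, peak lines `m/z intensity` at 6 decimals.
- **mzML** (read only): MS1 spectra skipped; MS2 spectra without a selected
  ion m/z skipped with a logged count; 64/32-bit float peak arrays, zlib or
  uncompressed.

## Compound library (`table4_library.csv` schema)

| column | meaning |
|--------|---------|
| index | unique integer record id |
| rt_min | retention time, minutes |
| charge | ion charge (1) |
| mz | observed adducted m/z |
| formula | plain Hill notation (no underscores) |
| adducts | `;`-separated adduct names (`M+H;M+Na`) |
| mass_error_ppm | printed mass error (carried, not recomputed) |
| description | compound name |
| in_serum / in_csf | 0/1 matrix flags |

## Quantification inputs

- `calibration.csv`: analyte, amount_pmol, analyte_area, is_area, day, replicate
- `precision.csv`: analyte, level_pmol, day, measured_pmol
- `recovery.csv`: analyte, matrix, spike_pmol, measured_mean_pmol,
  measured_sd_pmol, inter_day_cv, intra_day_cv, recovery_pct
  (spike 0 rows carry the endogenous level; their recovery is empty)

## Cohort tables (`cohort.csv`)

`sample_id, group, matrix`, then one numeric column per feature. Exactly two
group labels are required.

## Outputs

- `annotations.csv`: index, rt_min, charge, mz, formula, adduct, ppm_error,
  description, n_spectra, in_serum, in_csf, spectrum_ids, native_mass_da
- `compare.csv`: feature, fold_change, t_stat, p_value, stars (+ optional
  q_value_bh)
- `plsda_scores.csv`: sample_id, group, t1..tk
- `splot.csv`: feature, p1, pcorr1
- `volcano.csv`: feature, log2_fc, p_value, neg_log10_p, significant, t_stat
- `report.json` (quant) and `eval.json` (classify): nested JSON as produced
  by `validation_report` and `EvalReport.to_dict`.

## Configuration (YAML)

All keys optional; flags override file values.

```yaml
seed: 0
probe:
  cation_formula: C25H28BrNP
  leaving_group: HBr
  diagnostic_fragment_formula: C25H29NPS
  # diagnostic_fragment_mz: 406.1753   # explicit value wins over formula
screen:
  reporter_tol_ppm: 10
  annot_tol_ppm: 5
  rt_tol_min: 0.5
  min_rel_intensity: 0.05
quant_weighting: none     # or "1/x"
stats_variant: student    # or "welch"
n_components: 3
classify:
  model: rf
  n_trials: 200
  n_train: 14
  n_test: 6
  rf_trees: 500
instrument: {}            # carried as inert provenance metadata
```
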