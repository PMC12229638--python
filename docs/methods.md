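# Methods

## Mass model

All masses are monoisotopic, summed from a packaged table of NIST/CODATA
most-abundant-isotope masses (8 decimals, `data/atomic_masses.csv`); nothing
is fetched from external services, so results are bit-reproducible. Ion m/z
is always electron-mass corrected (0.00054858 Da per positive charge): the
probe cation C25H28BrNP computes to 452.1137 only with the correction, which
matches its reported accurate mass (452.1135) within 1 ppm, while the
uncorrected value does not.

The tag conjugation is strictly additive: `derivative = probe cation +
analyte − HBr`, charge +1. Composition subtraction that would drive any
element negative is an error; analytes without sulfur produce a warning but
are still computed (the reagent also reacts with amines under forcing
conditions). The shared diagnostic product ion is modeled as the
sulfur-retaining tag fragment C25H29NPS⁺ = 406.1753; its composition is
configurable on `ProbeSpec` because instruments report it only at nominal
precision (406.17). Bookkeeping closes exactly: derivative − fragment =
analyte − H2S for every targeted thiol.

ppm convention: `1e6 × (observed − theoretical) / theoretical`, signed,
theoretical in the denominator. Note this is only approximately antisymmetric
under swapping the arguments (the denominator changes); the definition above
is the one used everywhere. Display m/z are rounded to 4 decimals; full
precision is kept internally.

Three of the seven monitored precursor values (Hcy 507.2202, GSH 679.2752,
γ-Glu-Cys 622.2416) deviate 5–13 ppm from any m/z the conjugation model can
produce for their compositions, while the other four agree to <1 ppm. These
are carried as measured instrument settings in the transitions fixture and
are deliberately not "corrected" to theory.

## Screening

A spectrum is a labeled-thiol candidate when it contains a peak within a ppm
tolerance of the reporter at a minimum relative intensity. Defaults: reporter
match 10 ppm, library annotation 5 ppm, retention-time gate 0.5 min, minimum
reporter intensity 5% of the base peak, deduplication windows 0.2 min / 10
ppm. The source data name no tolerances; these are loose against 4-decimal
rounding of printed m/z and tight against random decoys, and all are
overridable from the CLI and config file.

Native thiol mass is the inverse of the additive model:
`M = precursor + m(e⁻) − m(tag cation) + m(HBr)`; precursors lighter than
the tag are a domain error. Annotation matches the hit precursor against the
library's adducted m/z (the packaged library lists observed adducted values);
a `native` mode matching the inferred neutral mass against formula masses is
available for libraries of probe-conjugate [M]⁺ records, since printed
libraries of labeled metabolites are often ambiguous about which of the two
they list. Rows declaring several adducts are expanded one candidate per
adduct; only charge 1 is supported. The best candidate minimises
(|ppm|, |ΔRT|, record index).

Printed compound tables list positional isomers that are analytically
indistinguishable — identical retention time and identical reported m/z
(the packaged 97-entry library contains several such groups). A per-hit
"single best record" annotation cannot distinguish them, and collapsing them
would under-report the library's own row count. The implementation therefore
records, alongside the best match, the full set of library entries
indistinguishable from it (same printed m/z and retention time), and the
final report emits one row per such entry — exactly how published annotation
tables list isomeric candidates.

Deduplication clusters annotations as connected components of a proximity
graph (both RT and m/z windows satisfied) with an identity constraint: two
annotations matched to *different* records are never merged, while
unannotated hits merge freely with neighbours. On record-free input this
reduces to plain proximity components. The cluster representative is the
annotation with the highest reporter relative intensity (annotated
representatives preferred); output is sorted by retention time, which makes
`screen_run` invariant to input order.

With jitter below half the annotation tolerance the generate→screen round
trip is exact: 97 library entries plus any number of reporter-free decoys
yield exactly 97 annotated rows and zero decoy rows. At mass error
comparable to the tolerance (e.g. 3 ppm jitter vs 5 ppm tolerance) a few
percent of precursors fall outside tolerance and one near-duplicate library
pair (two entries 1.1 ppm apart) can cross-annotate, so counts may fluctuate
by ±1–2; this is a property of the library, not of the seed.

## Quantification and validation

Calibration is ordinary least squares of the analyte/IS area ratio on amount
(pmol); `1/x` weighting is available for wide ranges (it stabilises relative
error at the low end) but the default is unweighted, matching the simple
printed line equations. R² is 1 − SS_res/SS_tot on the unweighted scale.
Inverse prediction never clips: out-of-range amounts are flagged "below" /
"above".

LOD and LOQ implement the S/N 3:1 and 10:1 definitions as 3σ/slope and
10σ/slope with σ supplied by the caller (blank-ratio SD); chromatographic
noise estimation from raw profiles is out of scope. The formula forces
LOQ/LOD = 10/3; published per-analyte LOD/LOQ values that do not satisfy
that ratio are experimental observations and are carried in the fixture
untouched. Units are pmol throughout, with fmol (×1000) only for LOD/LOQ
display.

CV uses the sample (n−1) standard deviation. Recovery is
`(spiked − unspiked)/spike × 100`, invariant under common rescaling of the
three inputs. The summary "mean recovery" is the arithmetic mean of
per-level recoveries, which reproduces the reference summaries exactly from
their printed per-level values (e.g. CA serum (92.12 + 88.8 + 85.57)/3 =
88.83%).

## Cohort statistics

The default two-sample test is Student's pooled-variance t, two-sided, with
Welch by flag; stars follow the usual p < 0.05/0.01/0.001 mapping and the
reported p-value is floored at 1e-300. Fold change is the ratio of group
arithmetic means, case/control; values below 1 mean controls ran higher. No
multiple-testing correction is applied by default (raw p-values are what the
reporting convention uses); Benjamini–Hochberg q-values are available and
clearly labeled.

PLS-DA uses NIPALS on autoscaled X (unit variance; constant features dropped
with a warning) with the two groups coded ±1, 3 components by default, max
500 iterations, tolerance 1e-10. Initialisation from y makes the fit
deterministic, deflation follows each component, and the sign of each
component is fixed by making its largest-magnitude weight positive. Scores
are mutually orthogonal to numerical precision; for a single y column NIPALS
is algebraically the dominant-eigenvector solution of X'yy'X, which is the
independent oracle used in the tests. S-plot coordinates are, per feature,
the covariance (p1, modeled magnitude) and correlation (pcorr1, reliability)
of the autoscaled feature with the first score vector.

Heatmap ordering z-scores each feature (sample SD), then applies average
linkage on Euclidean distances (a standard metabolomics default; the source
material is silent); scipy's deterministic leaf ordering breaks ties by
index. The volcano stage runs the same t-test per protein. Protein abundance
matrices are treated as log2-scale (the proteomics convention), so log2 fold
change is the difference of group means; for strictly positive concentration
tables a `linear` mode takes log2 of the mean ratio.

## Classifier evaluation

With 10 + 10 samples a single split is dominated by split noise, so accuracy
is summarised over repeated stratified splits: default 200 trials, 14
training / 6 test samples, proportional per-class allocation. Feature
standardisation is fit on the training fold only (no leakage). Models:
random forest (500 trees, √p features per split) and L2 logistic regression
(unit regularisation strength); accuracy is the headline metric, with
per-trial confusion counts retained for audit. All child-model seeds derive
from a single `random_state`, so identical (data, params, seed) give
bit-identical reports. Feature importance is Gini importance (forest) or
|coefficient on standardised features| (logistic), normalised to sum to 1.

The published split description for the source cohort is internally
inconsistent (80% of 20, "fourteen… six", and a 20-sample hold-out are all
mentioned); the implementation makes the split sizes configuration with
14/6 defaults, matching the 200-trial protocol sentence. Under label
permutation the chance level is assessed over the permutation distribution:
a single permutation of 20 labels retains chance label–feature correlation
and can score well away from 50% on its own.

## Synthetic data

The generators are pure functions of (parameters, seed) and emulate exactly
what the downstream arithmetic consumes:

- **MS2 runs** — per library record, spectra with precursor
  `m/z × (1 + ε)`, ε ~ N(0, 3 ppm), retention time jittered with SD 0.05
  min, the jittered reporter at 80% of the strongest of 5–20 uniform filler
  peaks, plus reporter-free decoys whose peaks are rejection-sampled out of
  3× the screening tolerance (a guaranteed zero false-positive floor).
- **Calibration series** — triplicates per level on the seven packaged line
  equations (each restricted to its printed 0.024–500/250/125 pmol range),
  with relative Gaussian ratio noise.
- **Cohorts** — log-normal concentrations (positive, right-skewed): control
  geometric mean 5 pmol, natural-scale CV 15% where not configured, case
  geometric mean = control × fold change, n = 30 per group. The packaged
  `fig7_foldchanges.yaml` carries the seven reported serum and CSF ratios
  with their directions. The ratio of arithmetic means is then exactly the
  configured fold, so the estimator is unbiased.
- **Protein tables** — 340 features, standard-normal (log-scale) background,
  12 planted features shifted 3 SD in the case group with alternating sign,
  n = 10 per group; planted positions are returned for truth-aware tests.

What the generators do **not** emulate: chromatographic peak shapes,
isotope envelopes, ion suppression/matrix effects, correlated analyte
biology, instrument drift, heteroscedastic area noise, or missingness.
Passing tests therefore demonstrate the correctness of the arithmetic and
the behaviour of the statistical machinery under its stated model — not
assay performance on real serum or CSF.

## Problem sizes and numerical choices

The test suite uses the study-scale sizes where they are cheap (10,000 null
t-simulations at n = 30/group; 100-seed fold-change recovery; 200-trial
classifier runs with 500 trees) and small matrices (6×3, 5-feature) where an
oracle is compared elementwise. Brute-force oracles (linear peak scans,
exhaustive candidate search, naive UPGMA, eigen-PLS1) are implemented inside
the tests, independent of the library paths they check. Ties are broken
deterministically everywhere (lowest index); p-value floor 1e-300; NIPALS
tolerance 1e-10; calibration requires ≥3 distinct amounts.

## Known limitations

- Only singly charged species are handled; multiply charged adducts are out
  of scope, as are isotope-pattern simulation and average masses.
- LOD/LOQ require an externally estimated noise SD.
- mzML support is read-only and limited to centroided MS2 with standard
  CV terms (64/32-bit float arrays, zlib or no compression); runs are
  written as MGF.
- The screening stage assumes the library's printed m/z are directly
  comparable with precursors (observed-adduct mode); native-mass mode is
  provided but neither interpretation is asserted as the source table's
  intent.
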