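"""Seeded generators for every input the toolkit consumes.

These emulate, at the level the downstream arithmetic sees, (i) an IDA MS2
run over probe-labeled thiols — each library compound yields spectra whose
precursor carries ppm-scale mass error and whose peak list contains the
jittered tag reporter plus random filler peaks, with reporter-free decoy
spectra mixed in; (ii) calibration series around known linear equations;
(iii) two-group cohorts with log-normal per-analyte concentrations at
configured fold changes; and (iv) protein tables with a handful of planted
group effects on a standard-normal background.

Every generator is a pure function of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .chemmass import ProbeSpec, default_probe
from .diffstats import CohortTable
from .screening import CompoundRecord, Ms2Spectrum

__all__ = [
    "SynthConfig",
    "gen_ms2_run",
    "gen_cohort",
    "gen_calibration_series",
    "gen_protein_table",
    "load_fold_changes",
    "case_control_ratios",
]


@dataclass
class SynthConfig:
    """Default study conditions for the generators."""

    seed: int = 0
    mz_jitter_ppm: float = 3.0  # SD of relative mass error
    rt_jitter_min: float = 0.05  # SD of retention-time error, minutes
    reporter_rel_intensity: float = 0.8  # reporter height vs max filler
    n_decoys: int = 0
    n_replicates: int = 1
    filler_peaks: tuple[int, int] = (5, 20)
    mz_range: tuple[float, float] = (50.0, 1000.0)
    # cohort defaults: n per group and concentration CV on the natural scale
    n_per_group: int = 30
    cohort_cv: float = 0.15
    # protein-table defaults
    n_proteins: int = 340
    n_planted: int = 12
    effect_sd: float = 3.0


def load_fold_changes(matrix: str = "serum") -> dict[str, dict]:
    """Packaged per-analyte fold changes and directions for serum or csf."""
    text = resources.files("thioltrace.data").joinpath("fig7_foldchanges.yaml").read_text()
    data = yaml.safe_load(text)
    key = matrix.lower()
    if key not in data:
        raise KeyError(f"unknown matrix {matrix!r}; have {sorted(data)}")
    return data[key]


def case_control_ratios(matrix: str = "serum") -> dict[str, float]:
    """Case/control mean ratios implied by the packaged fold-change file."""
    out = {}
    for analyte, spec in load_fold_changes(matrix).items():
        fold, higher = float(spec["fold"]), spec["higher_in"]
        out[analyte] = fold if higher == "PCNSL" else 1.0 / fold
    return out


def _reporter_mz(probe: ProbeSpec) -> float:
    return probe.reporter_mz


def gen_ms2_run(
    library: Sequence[CompoundRecord],
    probe: ProbeSpec | None = None,
    cfg: SynthConfig | None = None,
) -> list[Ms2Spectrum]:
    """Simulate an MS2 run over a compound library.

    Per record, ``cfg.n_replicates`` spectra are produced with precursor
    m/z = record m/z x (1 + jitter) and retention time = record RT + jitter,
    each containing the (jittered) tag reporter at
    ``reporter_rel_intensity`` of the strongest filler peak, plus 5-20 random
    filler peaks.  ``cfg.n_decoys`` extra spectra are guaranteed to contain no
    peak within 3x a 10 ppm screening tolerance of the reporter.
    """
    if not library:
        raise ValueError("library must be non-empty")
    probe = probe or default_probe()
    cfg = cfg or SynthConfig()
    rng = np.random.default_rng(cfg.seed)
    reporter = _reporter_mz(probe)
    guard = reporter * 3 * 10e-6  # keep decoy/filler peaks out of 3x tolerance
    spectra: list[Ms2Spectrum] = []

    def filler(n: int) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = cfg.mz_range
        mzs = np.empty(n)
        for i in range(n):
            m = rng.uniform(lo, hi)
            while abs(m - reporter) < guard:  # rejection-sample off the reporter
                m = rng.uniform(lo, hi)
            mzs[i] = m
        return mzs, rng.uniform(10.0, 1000.0, size=n)

    for rec in library:
        for rep in range(cfg.n_replicates):
            n_fill = int(rng.integers(cfg.filler_peaks[0], cfg.filler_peaks[1] + 1))
            fmz, fint = filler(n_fill)
            rep_mz = reporter * (1 + rng.normal(0, cfg.mz_jitter_ppm) * 1e-6)
            rep_int = cfg.reporter_rel_intensity * fint.max()
            prec = rec.mz * (1 + rng.normal(0, cfg.mz_jitter_ppm) * 1e-6)
            rt = (rec.retention_time or 0.0) + rng.normal(0, cfg.rt_jitter_min)
            spectra.append(
                Ms2Spectrum(
                    spectrum_id=f"cmpd{rec.index}_rep{rep}",
                    precursor_mz=prec,
                    retention_time=rt,
                    mz=np.append(fmz, rep_mz),
                    intensity=np.append(fint, rep_int),
                )
            )
    for d in range(cfg.n_decoys):
        n_fill = int(rng.integers(cfg.filler_peaks[0], cfg.filler_peaks[1] + 1))
        fmz, fint = filler(n_fill)
        spectra.append(
            Ms2Spectrum(
                spectrum_id=f"decoy{d}",
                precursor_mz=rng.uniform(100.0, 900.0),
                retention_time=rng.uniform(0.0, 10.0),
                mz=fmz,
                intensity=fint,
            )
        )
    return spectra


def gen_cohort(
    analytes: Mapping[str, tuple[float, float, float]] | None = None,
    n_per_group: int = 30,
    seed: int = 0,
    matrix: str = "serum",
    case: str = "PCNSL",
    control: str = "HV",
) -> CohortTable:
    """Two-group log-normal concentration cohort.

    ``analytes`` maps name -> (control geometric mean pmol, case/control fold
    change, CV fraction on the natural scale).  When omitted, the packaged
    fold changes for ``matrix`` are used with geometric mean 5 pmol and
    CV 0.15.  CV = 0 gives exactly constant groups.
    """
    if analytes is None:
        analytes = {
            name: (5.0, ratio, 0.15) for name, ratio in case_control_ratios(matrix).items()
        }
    rng = np.random.default_rng(seed)
    cols = {}
    for name, (gm, fold, cv) in analytes.items():
        if fold <= 0:
            raise ValueError(f"{name}: fold change must be positive")
        if cv < 0:
            raise ValueError(f"{name}: CV must be >= 0")
        sigma = np.sqrt(np.log1p(cv**2))
        ctrl = gm * np.exp(rng.normal(0, sigma, n_per_group)) if cv > 0 else np.full(n_per_group, gm)
        case_vals = (
            gm * fold * np.exp(rng.normal(0, sigma, n_per_group))
            if cv > 0
            else np.full(n_per_group, gm * fold)
        )
        cols[name] = np.concatenate([case_vals, ctrl])
    ids = [f"{case}_{i + 1}" for i in range(n_per_group)] + [
        f"{control}_{i + 1}" for i in range(n_per_group)
    ]
    values = pd.DataFrame(cols, index=ids)
    group = pd.Series([case] * n_per_group + [control] * n_per_group, index=ids)
    return CohortTable(values=values, group=group, matrix_type=matrix)


def gen_calibration_series(
    equations: Mapping[str, tuple[float, float]] | None = None,
    levels: Sequence[float] = (0.024, 0.1, 1.0, 10.0, 50.0, 150.0, 500.0),
    reps: int = 3,
    noise_rel: float = 0.0,
    seed: int = 0,
    is_area: float = 1e6,
) -> pd.DataFrame:
    """Calibration points around known lines ratio = slope*amount + intercept.

    Gaussian noise with SD ``noise_rel x |ratio|`` is added per injection;
    triplicate injections per level by default.  When ``equations`` is omitted
    the packaged table of seven printed calibration equations is used (each
    restricted to its printed range).  Returns the long-format
    ``calibration.csv`` schema: analyte, amount_pmol, analyte_area, is_area,
    day, replicate.
    """
    if len(levels) < 3:
        raise ValueError("need >= 3 calibration levels")
    if equations is None:
        equations, ranges = {}, {}
        text = resources.files("thioltrace.data").joinpath("table2_calibration.csv").read_text()
        tbl = pd.read_csv(pd.io.common.StringIO(text))
        for r in tbl.itertuples():
            equations[r.analyte] = (float(r.slope), float(r.intercept))
            ranges[r.analyte] = (float(r.range_min_pmol), float(r.range_max_pmol))
    else:
        ranges = {a: (min(levels), max(levels)) for a in equations}
    rng = np.random.default_rng(seed)
    rows = []
    for analyte, (slope, intercept) in equations.items():
        lo, hi = ranges[analyte]
        use_levels = [lv for lv in levels if lo <= lv <= hi]
        if len(use_levels) < 3:
            use_levels = list(np.geomspace(lo, hi, 7))
        for amount in use_levels:
            for rep in range(reps):
                ratio = slope * amount + intercept
                if noise_rel > 0:
                    ratio += rng.normal(0, noise_rel * abs(ratio))
                rows.append(
                    {
                        "analyte": analyte,
                        "amount_pmol": amount,
                        "analyte_area": ratio * is_area,
                        "is_area": is_area,
                        "day": 1,
                        "replicate": rep + 1,
                    }
                )
    return pd.DataFrame(rows)


def gen_protein_table(
    n_features: int = 340,
    n_planted: int = 12,
    effect_sd: float = 3.0,
    n_per_group: int = 10,
    seed: int = 0,
    case: str = "PCNSL",
    control: str = "HV",
) -> tuple[CohortTable, list[str]]:
    """Protein-abundance cohort: N(0,1) background with planted group shifts.

    The first ``n_planted`` proteins (by a seeded draw of positions) are
    shifted by ``effect_sd`` standard deviations in the case group, with
    alternating sign so both up- and down-regulation occur.  Returns the
    cohort and the list of planted feature ids for truth-aware tests.
    """
    if n_planted > n_features:
        raise ValueError("n_planted cannot exceed n_features")
    rng = np.random.default_rng(seed)
    names = [f"protein_{i + 1}" for i in range(n_features)]
    X = rng.normal(0, 1, size=(2 * n_per_group, n_features))
    planted_pos = rng.choice(n_features, size=n_planted, replace=False)
    for k, j in enumerate(planted_pos):
        sign = 1.0 if k % 2 == 0 else -1.0
        X[:n_per_group, j] += sign * effect_sd
    ids = [f"{case}_{i + 1}" for i in range(n_per_group)] + [
        f"{control}_{i + 1}" for i in range(n_per_group)
    ]
    values = pd.DataFrame(X, index=ids, columns=names)
    group = pd.Series([case] * n_per_group + [control] * n_per_group, index=ids)
    table = CohortTable(values=values, group=group, matrix_type="serum")
    return table, [names[j] for j in sorted(planted_pos)]
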