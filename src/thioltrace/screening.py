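"""Diagnostic-fragment screening of MS2 runs for probe-labeled thiols.

Every Br-OTPP-labeled thiol yields the same tag-side product ion near m/z
406.17, so labeled thiols are recognised in MS2 data by (i) finding that
reporter peak within a ppm tolerance, (ii) inverting the additive derivative
mass model to recover the native thiol mass, and (iii) matching precursors
against a compound library (one row per metabolite, retention time, adducted
m/z, formula, description).

Libraries transcribed from printed tables can contain entries that are
analytically indistinguishable (identical printed m/z and retention time —
positional isomers).  Annotation keeps the whole indistinguishable set so the
final report can list isomeric candidates as separate rows, the way such
tables are conventionally published.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .chemmass import (
    ELECTRON_MASS,
    Formula,
    ProbeSpec,
    default_adducts,
    default_probe,
    ppm_error,
)

__all__ = [
    "Ms2Spectrum",
    "DiagnosticHit",
    "CompoundRecord",
    "Annotation",
    "ScreenConfig",
    "find_diagnostic",
    "infer_native_mass",
    "annotate",
    "deduplicate",
    "screen_run",
]


@dataclass
class Ms2Spectrum:
    """One product-ion spectrum: precursor, retention time, peak list."""

    spectrum_id: str
    precursor_mz: float
    retention_time: float  # minutes
    mz: np.ndarray = field(default_factory=lambda: np.empty(0))
    intensity: np.ndarray = field(default_factory=lambda: np.empty(0))
    precursor_charge: int = 1

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays differ in length")
        if np.any(self.intensity < 0):
            raise ValueError("negative peak intensity")
        if self.precursor_mz <= 0:
            raise ValueError("precursor m/z must be positive")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    @property
    def peaks(self) -> list[tuple[float, float]]:
        return list(zip(self.mz.tolist(), self.intensity.tolist()))


@dataclass(frozen=True)
class DiagnosticHit:
    """A spectrum whose peak list contains the tag reporter ion."""

    spectrum_id: str
    matched_peak_mz: float
    ppm_to_reporter: float
    relative_intensity: float  # fraction of the base peak, (0, 1]
    precursor_mz: float
    retention_time: float


@dataclass(frozen=True)
class CompoundRecord:
    """One library entry (printed-table transcription)."""

    index: int
    retention_time: float | None
    charge: int
    mz: float
    formula: Formula | None
    adducts: tuple[str, ...]
    description: str = ""
    in_serum: bool = False
    in_csf: bool = False

    def __post_init__(self):
        if self.mz <= 0:
            raise ValueError(f"record {self.index}: m/z must be positive")
        if not self.adducts:
            raise ValueError(f"record {self.index}: at least one adduct required")


@dataclass(frozen=True)
class Annotation:
    """A diagnostic hit resolved against the library (or left unmatched)."""

    hit: DiagnosticHit
    record: CompoundRecord | None = None
    matched_adduct: str | None = None
    ppm: float | None = None
    native_thiol_mass: float | None = None
    #: library entries indistinguishable from ``record`` (same printed m/z
    #: and retention time); includes ``record`` itself when matched
    co_records: tuple[CompoundRecord, ...] = ()
    #: filled by deduplicate(): cluster size and supporting spectrum ids
    n_spectra: int = 1
    support_ids: tuple[str, ...] = ()


def find_diagnostic(
    s: Ms2Spectrum,
    reporter_mz: float,
    tol_ppm: float = 10.0,
    min_rel_intensity: float = 0.05,
) -> DiagnosticHit | None:
    """Locate the reporter ion in a spectrum.

    Returns the most intense peak within ``tol_ppm`` of ``reporter_mz``
    provided it reaches ``min_rel_intensity`` of the base peak; ``None`` if no
    qualifying peak exists (an empty peak list is not an error).
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    if not 0 <= min_rel_intensity < 1:
        raise ValueError("min_rel_intensity must be in [0, 1)")
    if s.mz.size == 0:
        return None
    tol = reporter_mz * tol_ppm * 1e-6
    in_window = np.abs(s.mz - reporter_mz) <= tol
    if not in_window.any():
        return None
    base = s.intensity.max()
    idx = np.flatnonzero(in_window)
    best = idx[np.argmax(s.intensity[idx])]
    if base <= 0 or s.intensity[best] < min_rel_intensity * base:
        return None
    return DiagnosticHit(
        spectrum_id=s.spectrum_id,
        matched_peak_mz=float(s.mz[best]),
        ppm_to_reporter=ppm_error(float(s.mz[best]), reporter_mz).ppm,
        relative_intensity=float(s.intensity[best] / base),
        precursor_mz=s.precursor_mz,
        retention_time=s.retention_time,
    )


def infer_native_mass(precursor_mz: float, probe: ProbeSpec | None = None) -> float:
    """Neutral thiol mass implied by a singly charged derivative precursor.

    Inverts the additive model: M = m/z + e - mass(tag cation) + mass(HBr).
    """
    probe = probe or default_probe()
    mass = (
        precursor_mz
        + ELECTRON_MASS
        - probe.cation_formula.mass
        + probe.leaving_group.mass
    )
    if mass <= 0:
        raise ValueError(
            f"precursor {precursor_mz} is lighter than the tag; no native mass"
        )
    return mass


def _expand_candidates(library, mode, probe):
    """(record, adduct, target m/z or mass) triples, one per declared adduct."""
    out = []
    for rec in library:
        if mode == "native":
            if rec.formula is None:
                continue
            out.append((rec, "[M]+", rec.formula.mass))
        else:
            for ad in rec.adducts:
                out.append((rec, ad, rec.mz))
    return out


def annotate(
    hits: Iterable[DiagnosticHit],
    library: Sequence[CompoundRecord],
    mz_tol_ppm: float = 5.0,
    rt_tol: float = 0.5,
    mode: str = "observed",
    probe: ProbeSpec | None = None,
) -> list[Annotation]:
    """Match each hit to the best library record.

    In ``observed`` mode the hit precursor is compared with the library's
    adducted m/z; in ``native`` mode the inferred native thiol mass is compared
    with the record's formula mass (for probe-conjugate [M]+ libraries).
    Candidates must lie within ``mz_tol_ppm`` and, when the record carries a
    retention time, within ``rt_tol`` minutes.  The winner minimises
    (|ppm|, |dRT|, record index); unmatched hits are kept with no record.
    """
    if not library:
        raise ValueError("library must be non-empty")
    if mode not in ("observed", "native"):
        raise ValueError(f"unknown annotation mode {mode!r}")
    probe = probe or default_probe()
    candidates = _expand_candidates(library, mode, probe)
    tag_mass = probe.cation_formula.mass - probe.leaving_group.mass

    out = []
    for hit in hits:
        native = None
        if hit.precursor_mz + ELECTRON_MASS > tag_mass:
            native = infer_native_mass(hit.precursor_mz, probe)
        query = native if mode == "native" else hit.precursor_mz
        scored = []
        for rec, ad, target in candidates:
            if mode == "native" and query is None:
                continue
            ppm = 1e6 * (query - target) / target
            if abs(ppm) > mz_tol_ppm:
                continue
            drt = (
                abs(hit.retention_time - rec.retention_time)
                if rec.retention_time is not None
                else 0.0
            )
            if rec.retention_time is not None and drt > rt_tol:
                continue
            scored.append((abs(ppm), drt, rec.index, rec, ad, ppm))
        if not scored:
            out.append(Annotation(hit=hit, native_thiol_mass=native))
            continue
        scored.sort(key=lambda t: t[:3])
        _, _, _, best, best_ad, best_ppm = scored[0]
        co = tuple(
            sorted(
                {
                    rec.index: rec
                    for _, _, _, rec, _, _ in scored
                    if rec.mz == best.mz and rec.retention_time == best.retention_time
                }.values(),
                key=lambda r: r.index,
            )
        )
        out.append(
            Annotation(
                hit=hit,
                record=best,
                matched_adduct=best_ad,
                ppm=best_ppm,
                native_thiol_mass=native,
                co_records=co,
            )
        )
    return out


def _proximate(a: Annotation, b: Annotation, rt_window: float, mz_window_ppm: float):
    drt = abs(a.hit.retention_time - b.hit.retention_time)
    m1, m2 = a.hit.precursor_mz, b.hit.precursor_mz
    dppm = 2e6 * abs(m1 - m2) / (m1 + m2)
    return drt <= rt_window and dppm <= mz_window_ppm


def deduplicate(
    annos: Sequence[Annotation],
    rt_window: float = 0.2,
    mz_window_ppm: float = 10.0,
) -> list[Annotation]:
    """Collapse replicate observations of the same metabolite.

    Annotations are clustered as the connected components of a proximity
    graph: two annotations are linked when they fall inside both the retention
    time and the m/z window and are compatible in identity (same matched
    record, or at least one of the two is unannotated).  Each cluster is
    represented by its highest reporter relative intensity (annotated
    representatives preferred); output is sorted by retention time.
    """
    if rt_window <= 0 or mz_window_ppm <= 0:
        raise ValueError("windows must be positive")
    n = len(annos)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    def key(a: Annotation):
        return a.record.index if a.record is not None else None

    for i in range(n):
        for j in range(i + 1, n):
            ki, kj = key(annos[i]), key(annos[j])
            if ki is not None and kj is not None and ki != kj:
                continue
            if _proximate(annos[i], annos[j], rt_window, mz_window_ppm):
                union(i, j)

    clusters: dict[int, list[Annotation]] = {}
    for i, a in enumerate(annos):
        clusters.setdefault(find(i), []).append(a)

    reps = []
    for members in clusters.values():
        matched = [a for a in members if a.record is not None]
        pool = matched or members
        rep = max(pool, key=lambda a: a.hit.relative_intensity)
        rep = replace(
            rep,
            n_spectra=len(members),
            support_ids=tuple(sorted(a.hit.spectrum_id for a in members)),
        )
        reps.append(rep)
    reps.sort(key=lambda a: (a.hit.retention_time, a.hit.precursor_mz))
    return reps


@dataclass
class ScreenConfig:
    """Tolerances and probe definition for a screening run."""

    probe: ProbeSpec = field(default_factory=default_probe)
    reporter_mz: float | None = None  # default: probe's diagnostic fragment
    reporter_tol_ppm: float = 10.0
    min_rel_intensity: float = 0.05
    annot_tol_ppm: float = 5.0
    rt_tol_min: float = 0.5
    dedup_rt_min: float = 0.2
    dedup_mz_ppm: float = 10.0
    mode: str = "observed"

    def resolved_reporter(self) -> float:
        return self.reporter_mz if self.reporter_mz is not None else self.probe.reporter_mz


_REPORT_COLUMNS = [
    "index", "rt_min", "charge", "mz", "formula", "adduct", "ppm_error",
    "description", "n_spectra", "in_serum", "in_csf", "spectrum_ids",
    "native_mass_da",
]


def screen_run(
    spectra: Iterable[Ms2Spectrum],
    library: Sequence[CompoundRecord],
    config: ScreenConfig | None = None,
) -> pd.DataFrame:
    """Full screen: reporter detection -> native mass -> annotation -> dedup.

    Returns one table row per library entry supported by a deduplicated
    feature (indistinguishable isomeric entries each get a row) plus one row
    per unannotated feature; deterministic and invariant to input order.
    """
    config = config or ScreenConfig()
    reporter = config.resolved_reporter()
    spectra = sorted(spectra, key=lambda s: (s.retention_time, s.precursor_mz, s.spectrum_id))
    hits = []
    for s in spectra:
        h = find_diagnostic(s, reporter, config.reporter_tol_ppm, config.min_rel_intensity)
        if h is not None:
            hits.append(h)
    if not hits:
        return pd.DataFrame(columns=_REPORT_COLUMNS)
    annos = annotate(
        hits, library, config.annot_tol_ppm, config.rt_tol_min, config.mode, config.probe
    )
    reps = deduplicate(annos, config.dedup_rt_min, config.dedup_mz_ppm)

    rows = []
    for rep in reps:
        base = {
            "n_spectra": rep.n_spectra,
            "spectrum_ids": ";".join(rep.support_ids) or rep.hit.spectrum_id,
            "native_mass_da": rep.native_thiol_mass,
        }
        if rep.record is None:
            rows.append(
                {
                    **base,
                    "index": pd.NA,
                    "rt_min": rep.hit.retention_time,
                    "charge": 1,
                    "mz": rep.hit.precursor_mz,
                    "formula": "",
                    "adduct": "",
                    "ppm_error": pd.NA,
                    "description": "",
                    "in_serum": pd.NA,
                    "in_csf": pd.NA,
                }
            )
            continue
        for rec in rep.co_records or (rep.record,):
            rows.append(
                {
                    **base,
                    "index": rec.index,
                    "rt_min": rec.retention_time,
                    "charge": rec.charge,
                    "mz": rec.mz,
                    "formula": rec.formula.hill() if rec.formula else "",
                    "adduct": rep.matched_adduct,
                    "ppm_error": rep.ppm,
                    "description": rec.description,
                    "in_serum": int(rec.in_serum),
                    "in_csf": int(rec.in_csf),
                }
            )
    df = pd.DataFrame(rows, columns=_REPORT_COLUMNS)
    return df.sort_values(
        ["rt_min", "mz", "index"], na_position="last", kind="stable"
    ).reset_index(drop=True)
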