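"""Targeted quantification and method-validation arithmetic.

Quantification uses internal-standard ratio calibration: the response is the
analyte/IS peak-area ratio, fit linearly against the injected amount (pmol).
Validation metrics follow standard bioanalytical definitions: LOD and LOQ at
signal-to-noise 3:1 and 10:1 (3 sigma/slope and 10 sigma/slope, with sigma the
blank-ratio SD supplied by the caller), precision as the sample coefficient of
variation, and spike recovery as (spiked - unspiked) / spike x 100.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "CalibrationPoint",
    "CalibrationCurve",
    "CalibrationModel",
    "PrecisionResult",
    "RecoveryResult",
    "fit_calibration",
    "apply_calibration",
    "lod_loq",
    "precision_cv",
    "recovery",
    "mean_recovery",
    "validation_report",
]


@dataclass(frozen=True)
class CalibrationPoint:
    """One calibration injection: amount (pmol) and the two peak areas."""

    amount: float
    analyte_area: float
    is_area: float

    def __post_init__(self):
        if self.is_area <= 0:
            raise ValueError("internal-standard area must be positive")
        if self.amount < 0:
            raise ValueError("amount must be non-negative")

    @property
    def ratio(self) -> float:
        return self.analyte_area / self.is_area


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted line ratio = slope * amount + intercept, with validation extras."""

    analyte: str
    slope: float
    intercept: float
    r_squared: float
    range: tuple[float, float]
    lod_fmol: float | None = None
    loq_fmol: float | None = None


class CalibrationModel(RegressorMixin, BaseEstimator):
    """Linear IS-ratio calibration as an sklearn estimator.

    Parameters
    ----------
    weighting : {"none", "1/x"}
        Ordinary least squares (default) or 1/amount-weighted least squares;
        weighting stabilises the relative error at the low end of wide
        calibration ranges.
    analyte : str, optional
        Carried through to reports.
    """

    def __init__(self, weighting: str = "none", analyte: str | None = None):
        self.weighting = weighting
        self.analyte = analyte

    def fit(self, X, y):
        """Fit on amounts ``X`` (pmol, shape (n,) or (n, 1)) and ratios ``y``."""
        amounts = np.asarray(X, dtype=float).reshape(-1)
        ratios = np.asarray(y, dtype=float).reshape(-1)
        if amounts.shape != ratios.shape:
            raise ValueError("X and y must have the same length")
        if np.unique(amounts).size < 3:
            raise ValueError(
                f"calibration needs >= 3 distinct amounts, got {np.unique(amounts).size}"
            )
        if self.weighting not in ("none", "1/x"):
            raise ValueError(f"unknown weighting {self.weighting!r}")
        design = sm.add_constant(amounts)
        if self.weighting == "1/x":
            w = np.where(amounts > 0, 1.0 / np.where(amounts > 0, amounts, 1.0), 0.0)
            if not np.any(w > 0):
                raise ValueError("1/x weighting requires positive amounts")
            res = sm.WLS(ratios, design, weights=w).fit()
        else:
            res = sm.OLS(ratios, design).fit()
        self.intercept_ = float(res.params[0])
        self.slope_ = float(res.params[1])
        # R^2 on the unweighted scale: 1 - SS_res / SS_tot
        pred = self.intercept_ + self.slope_ * amounts
        ss_res = float(np.sum((ratios - pred) ** 2))
        ss_tot = float(np.sum((ratios - ratios.mean()) ** 2))
        self.r_squared_ = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        self.range_ = (float(amounts.min()), float(amounts.max()))
        self.n_points_ = amounts.size
        return self

    def predict(self, X):
        """Predicted ratio for amounts ``X``."""
        check_is_fitted(self, "slope_")
        amounts = np.asarray(X, dtype=float).reshape(-1)
        return self.intercept_ + self.slope_ * amounts

    def quantify(self, ratio, with_flags: bool = False):
        """Inverse prediction: amount = (ratio - intercept) / slope.

        Out-of-range results are flagged, never clipped.  With
        ``with_flags=True`` returns ``(amounts, flags)`` where flags are
        "below", "above" or "" per element.
        """
        check_is_fitted(self, "slope_")
        if self.slope_ == 0:
            raise ZeroDivisionError("calibration slope is zero; cannot invert")
        r = np.asarray(ratio, dtype=float)
        amounts = (r - self.intercept_) / self.slope_
        if not with_flags:
            return amounts
        lo, hi = self.range_
        flags = np.where(amounts < lo, "below", np.where(amounts > hi, "above", ""))
        return amounts, flags

    def to_curve(self, noise_sd: float | None = None) -> CalibrationCurve:
        check_is_fitted(self, "slope_")
        lod = loq = None
        if noise_sd is not None:
            lod, loq = lod_loq(self.slope_, noise_sd)
        return CalibrationCurve(
            analyte=self.analyte or "",
            slope=self.slope_,
            intercept=self.intercept_,
            r_squared=self.r_squared_,
            range=self.range_,
            lod_fmol=lod,
            loq_fmol=loq,
        )


def fit_calibration(
    points: Sequence[CalibrationPoint],
    weighting: str = "none",
    analyte: str | None = None,
    noise_sd: float | None = None,
) -> CalibrationCurve:
    """Fit a calibration series (>= 3 distinct amounts) to a line."""
    amounts = [p.amount for p in points]
    ratios = [p.ratio for p in points]
    model = CalibrationModel(weighting=weighting, analyte=analyte).fit(amounts, ratios)
    return model.to_curve(noise_sd)


def apply_calibration(curve: CalibrationCurve, ratio):
    """Amount (pmol) implied by a measured ratio; out-of-range flagged.

    Returns ``(amount, flag)`` for a scalar ratio, or arrays for array input.
    """
    if curve.slope == 0:
        raise ZeroDivisionError("calibration slope is zero; cannot invert")
    r = np.asarray(ratio, dtype=float)
    amount = (r - curve.intercept) / curve.slope
    lo, hi = curve.range
    flag = np.where(amount < lo, "below", np.where(amount > hi, "above", ""))
    if np.isscalar(ratio) or r.ndim == 0:
        return float(amount), str(flag)
    return amount, flag


def lod_loq(slope: float, noise_sd: float) -> tuple[float, float]:
    """LOD and LOQ (fmol) at S/N 3:1 and 10:1: 3 sigma/slope and 10 sigma/slope.

    ``slope`` is in ratio/pmol and ``noise_sd`` in ratio units; results are
    converted pmol -> fmol (x1000).  LOQ/LOD is 10/3 by construction.
    """
    if slope <= 0 or noise_sd <= 0:
        raise ValueError("slope and noise_sd must both be positive")
    lod_pmol = 3.0 * noise_sd / slope
    loq_pmol = 10.0 * noise_sd / slope
    return lod_pmol * 1000.0, loq_pmol * 1000.0


@dataclass(frozen=True)
class PrecisionResult:
    analyte: str
    level: float
    cv: float  # percent
    grouping: str  # "intra" or "inter"
    n: int


def precision_cv(
    replicates: Sequence[float],
    grouping: str = "intra",
    analyte: str = "",
    level: float = float("nan"),
) -> PrecisionResult:
    """Coefficient of variation (%) with the sample (n-1) standard deviation."""
    x = np.asarray(replicates, dtype=float)
    if x.size < 2:
        raise ValueError("precision needs >= 2 replicates")
    mean = x.mean()
    if mean == 0:
        raise ValueError("mean of replicates is zero; CV undefined")
    cv = float(x.std(ddof=1) / mean * 100.0)
    return PrecisionResult(analyte=analyte, level=level, cv=cv, grouping=grouping, n=x.size)


@dataclass(frozen=True)
class RecoveryResult:
    analyte: str
    matrix: str
    spike: float
    unspiked_mean: float
    spiked_mean: float

    @property
    def recovery(self) -> float:
        return (self.spiked_mean - self.unspiked_mean) / self.spike * 100.0


def recovery(unspiked_mean: float, spiked_mean: float, spike: float) -> float:
    """Spike recovery in percent: (spiked - unspiked) / spike x 100."""
    if spike <= 0:
        raise ValueError(f"spike must be positive, got {spike}")
    return (spiked_mean - unspiked_mean) / spike * 100.0


def mean_recovery(per_level: Sequence[float]) -> float:
    """Arithmetic mean of per-level recoveries (the reported summary)."""
    vals = np.asarray(per_level, dtype=float)
    if vals.size == 0:
        raise ValueError("no recovery levels")
    return float(vals.mean())


def validation_report(
    calibration: pd.DataFrame | None = None,
    precision: pd.DataFrame | None = None,
    recovery_table: pd.DataFrame | None = None,
    weighting: str = "none",
) -> dict:
    """Assemble per-analyte validation results from long-format tables.

    calibration : columns analyte, amount_pmol, analyte_area, is_area
    precision   : columns analyte, level_pmol, day, measured_pmol
    recovery_table : columns analyte, matrix, spike_pmol, recovery_pct
        (spike 0 rows, which have no recovery, are ignored for the mean)

    Missing analytes in any table yield ``None`` cells, never an error.
    """
    analytes: list[str] = []
    for df in (calibration, precision, recovery_table):
        if df is not None:
            for a in df["analyte"].unique():
                if a not in analytes:
                    analytes.append(a)

    report: dict = {}
    for analyte in analytes:
        entry: dict = {"calibration": None, "precision": None, "recovery": None}
        if calibration is not None:
            sub = calibration[calibration["analyte"] == analyte]
            if len(sub):
                curve = fit_calibration(
                    [
                        CalibrationPoint(r.amount_pmol, r.analyte_area, r.is_area)
                        for r in sub.itertuples()
                    ],
                    weighting=weighting,
                    analyte=analyte,
                )
                entry["calibration"] = {
                    "slope": curve.slope,
                    "intercept": curve.intercept,
                    "r_squared": curve.r_squared,
                    "range_pmol": list(curve.range),
                }
        if precision is not None:
            sub = precision[precision["analyte"] == analyte]
            if len(sub):
                levels = {}
                for level, grp in sub.groupby("level_pmol"):
                    intra = [
                        precision_cv(day_grp["measured_pmol"], "intra", analyte, level).cv
                        for _, day_grp in grp.groupby("day")
                        if len(day_grp) >= 2
                    ]
                    day_means = grp.groupby("day")["measured_pmol"].mean()
                    inter = (
                        precision_cv(day_means, "inter", analyte, level).cv
                        if len(day_means) >= 2
                        else None
                    )
                    levels[float(level)] = {
                        "intra_day_cv": float(np.mean(intra)) if intra else None,
                        "inter_day_cv": inter,
                        "n": int(len(grp)),
                    }
                entry["precision"] = levels
        if recovery_table is not None:
            sub = recovery_table[
                (recovery_table["analyte"] == analyte)
                & (recovery_table["spike_pmol"] > 0)
                & recovery_table["recovery_pct"].notna()
            ]
            if len(sub):
                per_matrix = {}
                for matrix, grp in sub.groupby("matrix"):
                    per_level = dict(zip(grp["spike_pmol"], grp["recovery_pct"]))
                    per_matrix[matrix] = {
                        "per_level_pct": {float(k): float(v) for k, v in per_level.items()},
                        "mean_pct": mean_recovery(list(per_level.values())),
                    }
                entry["recovery"] = per_matrix
        report[analyte] = entry
    return report
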