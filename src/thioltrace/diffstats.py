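"""Cohort-level differential statistics for targeted metabolite panels.

Two-group cohorts (cases vs healthy volunteers) are compared per feature by
fold change of group means and a two-sided Student's t-test (pooled variance;
Welch available), with the conventional significance stars.  Multivariate
separation uses PLS-DA fit by NIPALS on autoscaled data with a +/-1 group
code, read out as 3-D score plots, an S-plot (per-feature covariance vs
correlation with the first score) and an average-linkage heatmap ordering of
z-scored features.  The same t-test drives the protein volcano stage
(log2 fold change vs -log10 p).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CohortTable",
    "GroupCompareResult",
    "PLSDA",
    "SplotPoint",
    "fold_change",
    "two_sample_t",
    "compare_groups",
    "significance_stars",
    "plsda_fit",
    "splot",
    "heatmap_cluster",
    "volcano",
]

_P_FLOOR = 1e-300  # reported lower bound for vanishing p-values


@dataclass
class CohortTable:
    """Samples x features concentration (or abundance) matrix with labels."""

    values: pd.DataFrame  # index = sample ids, columns = feature ids
    group: pd.Series  # per-sample label, aligned with values.index
    matrix_type: str = ""  # e.g. "serum" or "CSF"

    def __post_init__(self):
        self.group = pd.Series(self.group, index=self.values.index)
        if self.values.columns.duplicated().any():
            raise ValueError("feature ids must be unique")
        counts = self.group.value_counts()
        if len(counts) != 2:
            raise ValueError(f"expected exactly two groups, got {list(counts.index)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    def split(self, case: str, control: str) -> tuple[pd.DataFrame, pd.DataFrame]:
        return (
            self.values.loc[self.group == case],
            self.values.loc[self.group == control],
        )

    # -- cohort.csv round trip -------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        df = self.values.copy()
        df.insert(0, "matrix", self.matrix_type)
        df.insert(0, "group", self.group)
        df.insert(0, "sample_id", self.values.index)
        return df.reset_index(drop=True)

    @staticmethod
    def from_frame(df: pd.DataFrame) -> "CohortTable":
        required = {"sample_id", "group"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"cohort table missing columns: {sorted(missing)}")
        meta = [c for c in ("sample_id", "group", "matrix") if c in df.columns]
        values = df.drop(columns=meta).astype(float)
        values.index = df["sample_id"].astype(str)
        matrix = str(df["matrix"].iloc[0]) if "matrix" in df.columns and len(df) else ""
        group = pd.Series(df["group"].to_numpy(), index=values.index, name="group")
        return CohortTable(values=values, group=group, matrix_type=matrix)


def fold_change(
    table: CohortTable, feature: str, case: str = "PCNSL", control: str = "HV"
) -> float:
    """Ratio of group means, case / control.

    A value of 1.89 means the case mean is 1.89 times the control mean; ratios
    below 1 mean the control group ran higher.
    """
    case_vals, ctrl_vals = table.split(case, control)
    mc, m0 = case_vals[feature].mean(), ctrl_vals[feature].mean()
    if m0 == 0:
        raise ZeroDivisionError(f"control mean of {feature!r} is zero; ratio undefined")
    return float(mc / m0)


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class GroupCompareResult:
    feature: str
    fold_change: float
    t_stat: float
    p_value: float
    stars: str


def two_sample_t(
    table: CohortTable,
    feature: str,
    variant: str = "student",
    case: str = "PCNSL",
    control: str = "HV",
) -> GroupCompareResult:
    """Two-sided two-sample t-test on one feature.

    ``student`` pools the variances; ``welch`` does not.  Degenerate input
    (both groups constant) gives t = 0, p = 1 for equal means and a floored
    p-value for unequal means.
    """
    if variant not in ("student", "welch"):
        raise ValueError(f"unknown variant {variant!r}")
    x, y = table.split(case, control)
    x, y = x[feature].to_numpy(float), y[feature].to_numpy(float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need >= 2 samples per group")
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        if x.mean() == y.mean():
            t, p = 0.0, 1.0
        else:
            t, p = np.inf * np.sign(x.mean() - y.mean()), _P_FLOOR
    else:
        t, p = stats.ttest_ind(x, y, equal_var=(variant == "student"))
        p = max(float(p), _P_FLOOR)
    fc = float(x.mean() / y.mean()) if y.mean() != 0 else np.nan
    return GroupCompareResult(
        feature=feature,
        fold_change=fc,
        t_stat=float(t),
        p_value=float(p),
        stars=significance_stars(float(p)),
    )


def compare_groups(
    table: CohortTable,
    variant: str = "student",
    case: str = "PCNSL",
    control: str = "HV",
    fdr: bool = False,
) -> pd.DataFrame:
    """Per-feature fold change + t-test table; optional Benjamini-Hochberg.

    No multiplicity correction is applied by default (raw p-values are
    reported); ``fdr=True`` appends a clearly labeled ``q_value_bh`` column.
    """
    rows = [two_sample_t(table, f, variant, case, control) for f in table.feature_ids]
    df = pd.DataFrame(
        {
            "feature": [r.feature for r in rows],
            "fold_change": [r.fold_change for r in rows],
            "t_stat": [r.t_stat for r in rows],
            "p_value": [r.p_value for r in rows],
            "stars": [r.stars for r in rows],
        }
    )
    if fdr:
        df["q_value_bh"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df


class PLSDA(ClassifierMixin, TransformerMixin, BaseEstimator):
    """Partial least squares discriminant analysis via NIPALS.

    X is autoscaled (centered, unit variance; constant features dropped with a
    warning) and y is coded +/-1 from the two group labels.  Components are
    extracted by NIPALS with deflation of X after each component;
    initialisation from y makes the fit deterministic.  The sign of each
    component is fixed by making its largest-magnitude weight positive.

    Attributes (after fit): ``x_scores_`` (T), ``x_weights_`` (W),
    ``x_loadings_`` (P), ``y_loadings_`` (q), ``x_mean_``, ``x_std_``,
    ``classes_``, ``coef_``.
    """

    def __init__(self, n_components: int = 3, max_iter: int = 500, tol: float = 1e-10):
        self.n_components = n_components
        self.max_iter = max_iter
        self.tol = tol

    def _autoscale(self, X):
        return (X - self.x_mean_) / self.x_std_

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError("PLS-DA requires exactly two classes")
        self.classes_ = classes
        ycode = np.where(y == classes[1], 1.0, -1.0)
        n, p = X.shape
        if self.n_components > min(n - 1, p):
            raise ValueError(
                f"n_components={self.n_components} exceeds min(n-1, p)={min(n - 1, p)}"
            )
        sd = X.std(axis=0, ddof=1)
        keep = sd > 0
        if not keep.all():
            warnings.warn(
                f"dropping {int((~keep).sum())} constant feature(s) from autoscaling",
                stacklevel=2,
            )
        self.kept_features_ = keep
        self.x_mean_ = X.mean(axis=0)[keep]
        self.x_std_ = sd[keep]
        Xa = (X[:, keep] - self.x_mean_) / self.x_std_
        yc = ycode - ycode.mean()

        k = self.n_components
        T = np.zeros((n, k))
        W = np.zeros((keep.sum(), k))
        P = np.zeros((keep.sum(), k))
        q = np.zeros(k)
        Xd, yd = Xa.copy(), yc.copy()
        for h in range(k):
            u = yd.copy()
            w = np.zeros(Xd.shape[1])
            for _ in range(self.max_iter):
                w_new = Xd.T @ u / (u @ u)
                norm = np.linalg.norm(w_new)
                if norm == 0:
                    raise ValueError("degenerate component: zero weight vector")
                w_new /= norm
                t = Xd @ w_new
                qh = yd @ t / (t @ t)
                u_new = yd * qh  # single y column: u is proportional to y
                if np.linalg.norm(w_new - w) < self.tol:
                    w = w_new
                    break
                w, u = w_new, u_new
            # sign convention: largest |weight| positive
            j = int(np.argmax(np.abs(w)))
            sgn = 1.0 if w[j] >= 0 else -1.0
            w *= sgn
            t = Xd @ w
            ph = Xd.T @ t / (t @ t)
            qh = yd @ t / (t @ t)
            Xd = Xd - np.outer(t, ph)
            yd = yd - t * qh
            T[:, h], W[:, h], P[:, h], q[h] = t, w, ph, qh
        self.x_scores_ = T
        self.x_weights_ = W
        self.x_loadings_ = P
        self.y_loadings_ = q
        self._y_mean = ycode.mean()
        # regression vector b = W (P'W)^-1 q  (autoscaled X -> y code)
        self.coef_ = W @ np.linalg.solve(P.T @ W, q)
        return self

    def transform(self, X):
        check_is_fitted(self, "x_scores_")
        X = np.asarray(X, dtype=float)[:, self.kept_features_]
        Xa = self._autoscale(X)
        # scores of new data: successive projection with deflation weights
        R = self.x_weights_ @ np.linalg.inv(self.x_loadings_.T @ self.x_weights_)
        return Xa @ R

    def decision_function(self, X):
        check_is_fitted(self, "x_scores_")
        X = np.asarray(X, dtype=float)[:, self.kept_features_]
        return self._autoscale(X) @ self.coef_ + self._y_mean

    def predict(self, X):
        d = self.decision_function(X)
        return np.where(d >= 0, self.classes_[1], self.classes_[0])


def plsda_fit(
    table: CohortTable, n_components: int = 3, max_iter: int = 500, tol: float = 1e-10
) -> PLSDA:
    """Fit PLS-DA on a cohort table (labels from ``table.group``)."""
    model = PLSDA(n_components=n_components, max_iter=max_iter, tol=tol)
    return model.fit(table.values.to_numpy(float), table.group.to_numpy())


@dataclass(frozen=True)
class SplotPoint:
    feature: str
    p1: float  # covariance with t1: modeled magnitude
    pcorr1: float  # correlation with t1: reliability, in [-1, 1]


def splot(model: PLSDA, table: CohortTable) -> list[SplotPoint]:
    """S-plot coordinates: cov and corr of each autoscaled feature with t1.

    Zero-variance features have undefined correlation and are emitted with
    ``pcorr1 = nan``.
    """
    check_is_fitted(model, "x_scores_")
    t1 = model.x_scores_[:, 0]
    X = table.values.to_numpy(float)
    features = table.feature_ids
    out = []
    kept = model.kept_features_
    Xa = np.full_like(X, np.nan, dtype=float)
    Xa[:, kept] = (X[:, kept] - model.x_mean_) / model.x_std_
    for j, name in enumerate(features):
        if not kept[j]:
            out.append(SplotPoint(feature=name, p1=0.0, pcorr1=float("nan")))
            continue
        xj = Xa[:, j]
        p1 = float(np.cov(xj, t1, ddof=1)[0, 1])
        denom = xj.std(ddof=1) * t1.std(ddof=1)
        pcorr = float(p1 / denom) if denom > 0 else float("nan")
        out.append(SplotPoint(feature=name, p1=p1, pcorr1=pcorr))
    return out


def heatmap_cluster(
    table: CohortTable, method: str = "average", metric: str = "euclidean"
):
    """Z-score per feature, then agglomerative ordering of features and samples.

    Returns ``(z, feature_order, sample_order, feature_linkage)`` where ``z``
    is the per-feature z-scored DataFrame (mean 0, SD 1 with the sample SD).
    Leaf orders come from scipy's deterministic traversal (ties by index).
    """
    X = table.values
    if X.shape[0] < 2:
        raise ValueError("z-scores need >= 2 samples")
    if X.shape[1] < 2:
        raise ValueError("clustering needs >= 2 features")
    z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    zf = z.T.to_numpy(float)  # features x samples
    feat_link = linkage(zf, method=method, metric=metric)
    samp_link = linkage(z.to_numpy(float), method=method, metric=metric)
    return z, leaves_list(feat_link).tolist(), leaves_list(samp_link).tolist(), feat_link


def volcano(
    protein_table: CohortTable,
    alpha: float = 0.05,
    variant: str = "student",
    case: str = "PCNSL",
    control: str = "HV",
    data_scale: str = "log2",
) -> pd.DataFrame:
    """Per-protein log2 fold change, -log10 p and a significance flag.

    Proteomics abundance matrices are conventionally already log-scale, so
    the default ``data_scale="log2"`` computes the log2 fold change as the
    difference of group means; ``data_scale="linear"`` takes
    log2(mean ratio) for strictly positive concentration tables.
    Down-regulated proteins carry negative log2 fold changes; the flag is the
    raw-p threshold (no multiplicity correction, matching the reporting
    convention this stage mirrors).
    """
    if data_scale not in ("log2", "linear"):
        raise ValueError(f"unknown data_scale {data_scale!r}")
    df = compare_groups(protein_table, variant=variant, case=case, control=control)
    if data_scale == "linear":
        with np.errstate(divide="ignore", invalid="ignore"):
            df["log2_fc"] = np.log2(df["fold_change"])
    else:
        case_vals, ctrl_vals = protein_table.split(case, control)
        diff = case_vals.mean(axis=0) - ctrl_vals.mean(axis=0)
        df["log2_fc"] = diff.loc[df["feature"]].to_numpy()
    df["neg_log10_p"] = -np.log10(df["p_value"])
    df["significant"] = df["p_value"] < alpha
    return df[["feature", "log2_fc", "p_value", "neg_log10_p", "significant", "t_stat"]]
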