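"""Repeated stratified train/test evaluation for small biomarker cohorts.

With tens of samples, a single train/test split is dominated by split noise,
so model quality is summarised over many random stratified splits: per trial,
a split is drawn, features are standardised on the training fold only (no
leakage), the model is fit, and test accuracy recorded.  Random forest and
L2-penalised logistic regression are the two supported models; feature
importance is Gini importance (forest) or |standardised coefficient|
(logistic), normalised to sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

from .diffstats import CohortTable

__all__ = ["EvalConfig", "EvalReport", "RepeatedStratifiedEvaluator",
           "repeated_eval", "feature_importance"]

_MAX_SEED = 2**31 - 1


@dataclass
class EvalConfig:
    """Evaluation protocol: model choice, split sizes, trial count, seed."""

    model: str = "rf"  # "rf" or "lr"
    n_trials: int = 200
    n_train: int = 14
    n_test: int = 6
    stratified: bool = True
    seed: int | None = None
    rf_trees: int = 500
    lr_penalty: float = 1.0  # inverse of sklearn's C


@dataclass
class EvalReport:
    model: str
    per_trial_accuracy: list[float]
    mean_accuracy: float  # percent
    sd_accuracy: float  # percent
    feature_importance: "pd.Series"  # sorted descending, sums to 1
    confusion_counts: list[tuple[int, int, int, int]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "mean_accuracy_pct": self.mean_accuracy,
            "sd_accuracy_pct": self.sd_accuracy,
            "n_trials": len(self.per_trial_accuracy),
            "per_trial_accuracy": self.per_trial_accuracy,
            "feature_importance": self.feature_importance.to_dict(),
        }


class RepeatedStratifiedEvaluator(BaseEstimator):
    """sklearn-style wrapper around the repeated-split protocol.

    Parameters mirror :class:`EvalConfig`; ``fit(X, y)`` runs all trials and
    exposes ``per_trial_accuracy_``, ``mean_accuracy_`` (percent),
    ``sd_accuracy_``, ``feature_importance_`` and ``confusion_counts_``.
    Identical (data, params, random_state) give identical reports.
    """

    def __init__(
        self,
        model: str = "rf",
        n_trials: int = 200,
        n_train: int = 14,
        n_test: int = 6,
        stratified: bool = True,
        rf_trees: int = 500,
        lr_penalty: float = 1.0,
        random_state: int | None = None,
    ):
        self.model = model
        self.n_trials = n_trials
        self.n_train = n_train
        self.n_test = n_test
        self.stratified = stratified
        self.rf_trees = rf_trees
        self.lr_penalty = lr_penalty
        self.random_state = random_state

    def _make_model(self, seed: int):
        if self.model == "rf":
            return RandomForestClassifier(
                n_estimators=self.rf_trees,
                max_features="sqrt",
                random_state=seed,
                n_jobs=1,
            )
        if self.model == "lr":
            # default penalty is ridge (L2); strength = 1 / C
            return LogisticRegression(
                C=1.0 / self.lr_penalty, max_iter=5000, random_state=seed
            )
        raise ValueError(f"unknown model {self.model!r}")

    def _split(self, y, rng):
        """One stratified (or plain) train/test index pair."""
        n = len(y)
        if self.stratified:
            train_idx: list[int] = []
            rest: list[int] = []
            classes, counts = np.unique(y, return_counts=True)
            # proportional allocation of the training budget across classes
            alloc = {
                c: int(round(self.n_train * cnt / n)) for c, cnt in zip(classes, counts)
            }
            drift = self.n_train - sum(alloc.values())
            alloc[classes[0]] += drift
            for c in classes:
                idx = np.flatnonzero(y == c)
                rng.shuffle(idx)
                take = alloc[c]
                train_idx.extend(idx[:take])
                rest.extend(idx[take:])
            rest = np.array(rest)
            rng.shuffle(rest)
            test_idx = rest[: self.n_test]
        else:
            idx = rng.permutation(n)
            train_idx = idx[: self.n_train]
            test_idx = idx[self.n_train : self.n_train + self.n_test]
        return np.asarray(train_idx), np.asarray(test_idx)

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if not np.all(np.isfinite(X)):
            raise ValueError("features must be finite")
        n = len(y)
        classes, counts = np.unique(y, return_counts=True)
        if classes.size != 2:
            raise ValueError("exactly two classes required")
        if self.n_train + self.n_test > n:
            raise ValueError(
                f"n_train + n_test = {self.n_train + self.n_test} exceeds n = {n}"
            )
        if self.stratified:
            alloc = [int(round(self.n_train * c / n)) for c in counts]
            if min(alloc) < 1:
                raise ValueError("requested split sizes leave a class out of training")
        rng = np.random.default_rng(self.random_state)
        accs, confusions = [], []
        for _ in range(self.n_trials):
            tr, te = self._split(y, rng)
            if np.unique(y[tr]).size < 2:
                raise ValueError("a class is absent from a training split")
            scaler = StandardScaler().fit(X[tr])
            model = self._make_model(int(rng.integers(_MAX_SEED)))
            model.fit(scaler.transform(X[tr]), y[tr])
            pred = model.predict(scaler.transform(X[te]))
            accs.append(float(np.mean(pred == y[te])))
            pos = classes[1]
            tp = int(np.sum((pred == pos) & (y[te] == pos)))
            tn = int(np.sum((pred != pos) & (y[te] != pos)))
            fp = int(np.sum((pred == pos) & (y[te] != pos)))
            fn = int(np.sum((pred != pos) & (y[te] == pos)))
            confusions.append((tp, tn, fp, fn))
        self.per_trial_accuracy_ = accs
        self.mean_accuracy_ = float(np.mean(accs) * 100.0)
        self.sd_accuracy_ = float(np.std(accs, ddof=1) * 100.0) if len(accs) > 1 else 0.0
        self.confusion_counts_ = confusions
        self.feature_importance_ = self._importance(X, y, rng)
        return self

    def _importance(self, X, y, rng) -> np.ndarray:
        """Normalised importances from a fit on the full standardised data."""
        scaler = StandardScaler().fit(X)
        Xs = scaler.transform(X)
        model = self._make_model(int(rng.integers(_MAX_SEED)))
        model.fit(Xs, y)
        if self.model == "rf":
            imp = model.feature_importances_.astype(float)
        else:
            imp = np.abs(model.coef_).ravel().astype(float)
        total = imp.sum()
        return imp / total if total > 0 else imp

    def report(self, feature_names: Sequence[str] | None = None) -> EvalReport:
        check_is_fitted(self, "per_trial_accuracy_")
        imp = self.feature_importance_
        names = (
            list(feature_names)
            if feature_names is not None
            else [f"feature_{i}" for i in range(len(imp))]
        )
        series = pd.Series(imp, index=names).sort_values(ascending=False)
        return EvalReport(
            model=self.model,
            per_trial_accuracy=self.per_trial_accuracy_,
            mean_accuracy=self.mean_accuracy_,
            sd_accuracy=self.sd_accuracy_,
            feature_importance=series,
            confusion_counts=self.confusion_counts_,
        )


def repeated_eval(table: CohortTable, config: EvalConfig | None = None) -> EvalReport:
    """Run the repeated stratified evaluation on a cohort table."""
    config = config or EvalConfig()
    ev = RepeatedStratifiedEvaluator(
        model=config.model,
        n_trials=config.n_trials,
        n_train=config.n_train,
        n_test=config.n_test,
        stratified=config.stratified,
        rf_trees=config.rf_trees,
        lr_penalty=config.lr_penalty,
        random_state=config.seed,
    ).fit(table.values.to_numpy(float), table.group.to_numpy())
    return ev.report(table.feature_ids)


def feature_importance(table: CohortTable, config: EvalConfig | None = None) -> pd.Series:
    """Ranked, normalised feature importances on the full cohort."""
    return repeated_eval(table, config).feature_importance
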