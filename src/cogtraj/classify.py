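"""Validation of the trajectory clusters by supervised classification.

The four clusters are merged into high- vs low-performing classes; for each
modality a ridge-penalized logistic regression on the first available visit's
features produces an ROC curve and AUC (in-sample by default, cross-validated
by flag). A univariate scan fits one single-score model per cognitive test
and ranks the scores by direction-corrected AUC.

AUC is computed two ways — the Mann-Whitney rank statistic and the
trapezoidal area under the stored ROC curve — which must agree to 1e-12.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sst
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

__all__ = [
    "MERGE_MAP",
    "BinaryLabeling",
    "ROCResult",
    "merge_high_low",
    "first_visit_features",
    "fit_logistic",
    "roc_auc",
    "modality_auc_comparison",
    "univariate_auc_scan",
]

MERGE_MAP = {
    "high": ("high_upper", "high_lower"),
    "low": ("low_stable", "low_declining"),
}


@dataclass(frozen=True)
class BinaryLabeling:
    labels: pd.Series  # participant_id -> "high" | "low"
    provenance: dict

    @property
    def class_sizes(self) -> dict:
        return self.labels.value_counts().to_dict()

    def y(self, participant_ids) -> np.ndarray:
        """1 = low-performing (the positive, at-risk class)."""
        vals = self.labels.reindex(participant_ids)
        if vals.isna().any():
            raise ValueError("some participants have no class label")
        return (vals == "low").to_numpy(dtype=int)


@dataclass
class ROCResult:
    modality: str
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    n_used: int
    notes: list = field(default_factory=list)


def merge_high_low(
    cluster_labels: pd.Series,
    archetype_map: dict[int, str],
    merge_map: dict = MERGE_MAP,
) -> BinaryLabeling:
    """Merge archetype-named clusters into high/low classes."""
    reverse = {a: cls for cls, archs in merge_map.items() for a in archs}
    arch = cluster_labels.map(archetype_map)
    unknown = set(arch.dropna().unique()) - set(reverse)
    if unknown or arch.isna().any():
        raise ValueError(f"unknown archetype names: {sorted(unknown)}")
    merged = arch.map(reverse).rename("class")
    return BinaryLabeling(labels=merged, provenance={
        "merge_map": {k: tuple(v) for k, v in merge_map.items()},
        "archetype_map": dict(archetype_map),
    })


def first_visit_features(table: pd.DataFrame, modality: str = "") -> pd.DataFrame:
    """Wide matrix of each participant's earliest visit with any data.

    Features missing at that visit are mean-imputed (count logged);
    participants without any observation are excluded.
    """
    obs = table.dropna(subset=["value"])
    if obs.empty:
        raise ValueError(f"no participants with data for modality {modality!r}")
    first = obs.groupby("participant_id")["visit_index"].min().rename("first_visit")
    sel = obs.merge(first, on="participant_id")
    sel = sel[sel["visit_index"] == sel["first_visit"]]
    wide = sel.pivot_table(index="participant_id", columns="variable", values="value",
                           aggfunc="first")
    n_missing = int(wide.isna().sum().sum())
    if n_missing:
        logger.info("first_visit_features[%s]: mean-imputing %d missing entries",
                    modality, n_missing)
        wide = wide.fillna(wide.mean())
    return wide


def fit_logistic(
    X: np.ndarray, y: np.ndarray, standardize: bool = True, l2: float = 1e-4
):
    """Ridge-penalized logistic regression (deterministic lbfgs fit).

    Zero-variance columns are dropped before standardization (their
    coefficients are reported as exactly 0). Returns (model, scaler) where
    ``model.predict_proba`` works on the standardized, guarded matrix and
    ``scaler`` is a callable applying the same transform.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present to fit a classifier")
    if X.shape[0] <= 2:
        raise ValueError("need more than two samples")
    keep = np.ones(X.shape[1], dtype=bool)
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    if standardize:
        keep = sd > 0
        if not keep.all():
            logger.info("fit_logistic: dropping %d zero-variance features",
                        int((~keep).sum()))

    def scaler(A: np.ndarray) -> np.ndarray:
        A = np.asarray(A, dtype=float)
        if not standardize:
            return A[:, keep]
        return (A[:, keep] - mean[keep]) / sd[keep]

    clf = LogisticRegression(C=1.0 / max(l2, 1e-12), solver="lbfgs", max_iter=2000)
    clf.fit(scaler(X), y)
    if not hasattr(clf, "n_iter_") or clf.n_iter_[0] >= clf.max_iter:
        logger.warning("fit_logistic: lbfgs hit the iteration cap")
    coef = np.zeros(X.shape[1])
    coef[keep] = clf.coef_[0]
    clf.full_coef_ = coef
    return clf, scaler


def auc_rank(scores: np.ndarray, y: np.ndarray) -> float:
    """AUC as the Mann-Whitney rank statistic with half credit for ties."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=int)
    n1, n0 = int(y.sum()), int((1 - y).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = sst.rankdata(scores)  # midranks
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def roc_auc(scores, y, modality: str = "") -> ROCResult:
    """ROC curve plus AUC; the rank statistic and the trapezoidal area under
    the stored curve agree to numerical precision."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=int)
    auc = auc_rank(scores, y)
    fpr, tpr, thresholds = roc_curve(y, scores, drop_intermediate=False)
    trap = float(np.trapezoid(tpr, fpr))
    if abs(trap - auc) > 1e-10:
        raise AssertionError(f"rank AUC {auc} and trapezoidal AUC {trap} disagree")
    return ROCResult(modality=modality, thresholds=thresholds, tpr=tpr, fpr=fpr,
                     auc=auc, n_used=int(y.size))


def _model_scores(X: np.ndarray, y: np.ndarray, cv: int | None, seed: int,
                  l2: float = 1e-4) -> np.ndarray:
    if cv is None:
        clf, scaler = fit_logistic(X, y, l2=l2)
        return clf.predict_proba(scaler(X))[:, 1]
    scores = np.empty(len(y))
    splitter = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)
    for train, test in splitter.split(X, y):
        clf, scaler = fit_logistic(X[train], y[train], l2=l2)
        scores[test] = clf.predict_proba(scaler(X[test]))[:, 1]
    return scores


def modality_auc_comparison(
    modality_tables: dict[str, pd.DataFrame],
    labeling: BinaryLabeling,
    cv: int | None = None,
    seed: int = 0,
) -> list[ROCResult]:
    """One multivariate logistic model per modality on first-visit features;
    results sorted by AUC, highest first. ``cv=K`` switches from in-sample to
    K-fold cross-validated scores."""
    results = []
    for modality, table in modality_tables.items():
        wide = first_visit_features(table, modality)
        wide = wide.loc[wide.index.intersection(labeling.labels.index)]
        y = labeling.y(wide.index)
        scores = _model_scores(wide.to_numpy(), y, cv=cv, seed=seed)
        res = roc_auc(scores, y, modality=modality)
        if cv is not None:
            res.notes.append(f"{cv}-fold cross-validated scores")
        results.append(res)
    return sorted(results, key=lambda r: r.auc, reverse=True)


def univariate_auc_scan(
    cognitive: pd.DataFrame,
    labeling: BinaryLabeling,
    cv: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Single-feature logistic model per cognitive score, AUC direction-
    corrected to >= 0.5, ranked descending."""
    wide = first_visit_features(cognitive, "cognitive")
    wide = wide.loc[wide.index.intersection(labeling.labels.index)]
    y = labeling.y(wide.index)
    rows = []
    for var in wide.columns:
        x = wide[[var]].to_numpy()
        scores = _model_scores(x, y, cv=cv, seed=seed)
        auc = auc_rank(scores, y)
        rows.append({"score": var, "auc": max(auc, 1.0 - auc),
                     "direction_flipped": auc < 0.5})
    return (pd.DataFrame(rows)
            .sort_values("auc", ascending=False, kind="stable")
            .reset_index(drop=True))
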