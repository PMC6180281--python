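"""Leave-one-subject-out cross-validation and performance metrics.

All sessions of one subject form one test fold, so feature standardization,
penalty selection, and fitting never see that subject.  Test metrics are
computed on session-level predictions pooled across folds; the more severe
group of the contrast is the positive class.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .montage import GROUP_SEVERITY
from .reglearn import (
    PenalizedLRModel,
    fit_penalized_lr,
    predict_proba,
    select_lambda_nested,
)

logger = logging.getLogger(__name__)

META_COLUMNS = ("subject_id", "session_id", "group")

__all__ = [
    "Metrics",
    "FoldResult",
    "CVResult",
    "loso_folds",
    "confusion_metrics",
    "roc_auc",
    "run_loso",
    "metrics_row",
]


@dataclass
class Metrics:
    tp: int
    tn: int
    fp: int
    fn: int
    sensitivity: float
    specificity: float
    accuracy: float
    auc: float = np.nan

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class FoldResult:
    test_subject: str
    test_index: np.ndarray
    proba: np.ndarray
    y_true: np.ndarray
    selected_features: list[str]
    lam: float
    train_accuracy: float
    model: PenalizedLRModel


@dataclass
class CVResult:
    folds: list[FoldResult]
    feature_names: list[str]
    contrast: tuple[str, str]
    positive: str
    pooled_proba: np.ndarray = field(default_factory=lambda: np.empty(0))
    pooled_y: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def mean_train_accuracy(self) -> float:
        return float(np.mean([f.train_accuracy for f in self.folds]))


def loso_folds(groups: np.ndarray | list[str]) -> list[tuple[np.ndarray, np.ndarray]]:
    """One (train_rows, test_rows) pair per subject, ordered by subject id."""
    groups = np.asarray(groups)
    subjects = sorted(set(groups.tolist()))
    if len(subjects) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")
    idx = np.arange(groups.size)
    folds = []
    for s in subjects:
        test = idx[groups == s]
        folds.append((idx[groups != s], test))
    return folds


def confusion_metrics(y_true, y_pred, positive) -> Metrics:
    """Counts and proportions with the stated positive (more severe) class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty input")
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    t = y_true == positive
    p = y_pred == positive
    tp = int(np.sum(t & p))
    tn = int(np.sum(~t & ~p))
    fp = int(np.sum(~t & p))
    fn = int(np.sum(t & ~p))
    sens = tp / (tp + fn) if (tp + fn) else np.nan
    spec = tn / (tn + fp) if (tn + fp) else np.nan
    acc = (tp + tn) / y_true.size
    return Metrics(tp=tp, tn=tn, fp=fp, fn=fn, sensitivity=sens, specificity=spec, accuracy=acc)


def roc_auc(y_true, scores) -> float:
    """Rank-based (Mann-Whitney) AUC; ties contribute 1/2; NaN if one class
    is absent."""
    y_true = np.asarray(y_true, dtype=float)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(y_true.sum())
    n_neg = y_true.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    from scipy.stats import rankdata

    ranks = rankdata(scores)
    auc = (ranks[y_true == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    return float(auc)


def _order_contrast(contrast: tuple[str, str]) -> tuple[str, str]:
    """Return (negative, positive) with positive = more severe group."""
    a, b = contrast
    if GROUP_SEVERITY[a] == GROUP_SEVERITY[b]:
        raise ValueError(f"contrast groups {contrast} have equal severity")
    return (a, b) if GROUP_SEVERITY[a] < GROUP_SEVERITY[b] else (b, a)


def _split_features(features: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    missing = [c for c in META_COLUMNS if c not in features.columns]
    if missing:
        raise ValueError(f"feature table lacks metadata columns {missing}")
    names = [c for c in features.columns if c not in META_COLUMNS]
    return features, names


def run_loso(features: pd.DataFrame, config: AnalysisConfig) -> tuple[CVResult, Metrics]:
    """Full leave-one-subject-out evaluation of one pairwise contrast."""
    features, names = _split_features(features)
    negative, positive = _order_contrast(config.contrast)
    sub = features[features["group"].isin([negative, positive])].reset_index(drop=True)
    if sub.empty:
        raise ValueError(f"no rows for contrast {config.contrast}")
    X_all = sub[names].to_numpy(dtype=float)
    bad = np.isnan(X_all).any(axis=1)
    if bad.any():
        warnings.warn(
            f"dropping {int(bad.sum())} rows with missing feature values",
            RuntimeWarning,
            stacklevel=2,
        )
        sub = sub.loc[~bad].reset_index(drop=True)
        X_all = X_all[~bad]
    subjects = sub["subject_id"].to_numpy()
    if len(set(subjects.tolist())) < 2:
        raise ValueError("need at least 2 subjects for leave-one-subject-out")
    y_all = (sub["group"] == positive).to_numpy(dtype=float)

    cc = config.classify
    folds_out: list[FoldResult] = []
    pooled_proba = np.full(len(sub), np.nan)
    for fold_i, (train, test) in enumerate(loso_folds(subjects)):
        Xtr, ytr = X_all[train], y_all[train]
        mu = Xtr.mean(axis=0)
        sd = Xtr.std(axis=0)
        sd[sd == 0] = 1.0  # constant training column carries no information
        Ztr = (Xtr - mu) / sd
        Zte = (X_all[test] - mu) / sd
        if cc.method == "lr":
            lam = 0.0
            model = fit_penalized_lr(Ztr, ytr, 0.0, 1.0, max_iter=200)
        else:
            alpha = cc.effective_alpha
            lam = select_lambda_nested(
                Ztr,
                ytr,
                subjects[train],
                alpha,
                inner_folds=cc.inner_folds,
                grid_size=cc.lambda_grid_size,
                seed=config.seed + fold_i,
            )
            model = fit_penalized_lr(Ztr, ytr, lam, alpha, tol=1e-6)
        train_acc = float(np.mean((predict_proba(model, Ztr) >= 0.5) == ytr.astype(bool)))
        proba = predict_proba(model, Zte)
        pooled_proba[test] = proba
        selected = (
            [names[j] for j in model.active_set] if cc.method != "lr" else list(names)
        )
        folds_out.append(
            FoldResult(
                test_subject=str(subjects[test][0]),
                test_index=test,
                proba=proba,
                y_true=y_all[test],
                selected_features=selected,
                lam=lam,
                train_accuracy=train_acc,
                model=model,
            )
        )
        logger.debug("fold %s: lambda=%.4g train_acc=%.3f", subjects[test][0], lam, train_acc)

    cv = CVResult(
        folds=folds_out,
        feature_names=names,
        contrast=(negative, positive),
        positive=positive,
        pooled_proba=pooled_proba,
        pooled_y=y_all,
    )
    pred_labels = np.where(pooled_proba >= 0.5, positive, negative)
    true_labels = np.where(y_all == 1.0, positive, negative)
    metrics = confusion_metrics(true_labels, pred_labels, positive)
    metrics.auc = roc_auc(y_all, pooled_proba)
    return cv, metrics


def metrics_row(
    method: str, contrast: tuple[str, str], metrics: Metrics, train_accuracy: float
) -> dict:
    """One summary-table row with percentage-scaled proportions."""
    return {
        "method": method,
        "contrast": f"{contrast[0]} vs {contrast[1]}",
        "sensitivity_pct": 100.0 * metrics.sensitivity,
        "specificity_pct": 100.0 * metrics.specificity,
        "test_accuracy_pct": 100.0 * metrics.accuracy,
        "train_accuracy_pct": 100.0 * train_accuracy,
        "auc": metrics.auc,
    }
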