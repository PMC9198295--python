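"""ROC analysis: AUC by rank statistics, bootstrap CIs, confusion counts.

AUC is computed by the Mann–Whitney pair-counting identity — the fraction
of (positive, negative) pairs where the positive scores higher, ties
counting one half — which equals the trapezoidal area under the empirical
ROC curve.  Confidence intervals come from a stratified percentile
bootstrap (resampling within each class, so no resample loses a class).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "ROCResult",
    "auc_mann_whitney",
    "roc_points",
    "bootstrap_ci",
    "confusion_at_threshold",
    "roc_analysis",
]


def _as_binary(labels) -> np.ndarray:
    y = np.asarray(labels)
    if y.dtype.kind in "UOS":
        y = (y == "treatment").astype(int)
    y = y.astype(int)
    if not set(np.unique(y)) <= {0, 1}:
        raise ValueError("labels must be 0/1 or control/treatment")
    return y


@dataclass
class ROCResult:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int


def auc_mann_whitney(probs, labels) -> float:
    """AUC as the normalized Mann–Whitney U statistic (midrank ties)."""
    p = np.asarray(probs, dtype=float)
    y = _as_binary(labels)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = rankdata(p)  # midranks handle ties as half-wins
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_points(probs, labels) -> tuple[np.ndarray, np.ndarray]:
    """Empirical ROC curve from (0,0) to (1,1), thresholds descending."""
    p = np.asarray(probs, dtype=float)
    y = _as_binary(labels)
    order = np.argsort(-p, kind="stable")
    p, y = p[order], y[order]
    # group tied scores: step once per distinct threshold
    distinct = np.r_[np.diff(p) != 0, True]
    tps = np.cumsum(y)[distinct]
    fps = np.cumsum(1 - y)[distinct]
    tpr = np.r_[0.0, tps / max(y.sum(), 1)]
    fpr = np.r_[0.0, fps / max((1 - y).sum(), 1)]
    return fpr, tpr


def bootstrap_ci(
    probs, labels, n_boot: int = 2000, seed: int = 0
) -> tuple[float, float]:
    """Stratified percentile bootstrap 95% CI of the AUC."""
    p = np.asarray(probs, dtype=float)
    y = _as_binary(labels)
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is small; CI will be coarse")
    pos, neg = np.flatnonzero(y == 1), np.flatnonzero(y == 0)
    if len(pos) < 2 or len(neg) < 2:
        warnings.warn("fewer than 2 samples in a class; CI reported as [0, 1]")
        return 0.0, 1.0
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        ip = rng.choice(pos, size=len(pos), replace=True)
        ineg = rng.choice(neg, size=len(neg), replace=True)
        idx = np.r_[ip, ineg]
        aucs[b] = auc_mann_whitney(p[idx], y[idx])
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return float(lo), float(hi)


def confusion_at_threshold(probs, labels, thr: float = 0.5) -> dict[str, int]:
    """TP/FP/TN/FN counts; probability >= thr predicts treatment."""
    p = np.asarray(probs, dtype=float)
    y = _as_binary(labels)
    pred = (p >= thr).astype(int)
    return {
        "TP": int(((pred == 1) & (y == 1)).sum()),
        "FP": int(((pred == 1) & (y == 0)).sum()),
        "TN": int(((pred == 0) & (y == 0)).sum()),
        "FN": int(((pred == 0) & (y == 1)).sum()),
    }


def roc_analysis(probs, labels, n_boot: int = 2000, seed: int = 0) -> ROCResult:
    """Full ROC summary: curve, AUC and bootstrap CI."""
    fpr, tpr = roc_points(probs, labels)
    auc = auc_mann_whitney(probs, labels)
    lo, hi = bootstrap_ci(probs, labels, n_boot=n_boot, seed=seed)
    lo, hi = min(lo, auc), max(hi, auc)  # point estimate always inside
    return ROCResult(fpr=fpr, tpr=tpr, auc=auc, ci_low=lo, ci_high=hi, n_boot=n_boot, seed=seed)
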