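"""Differential expression by empirical-Bayes moderated t-statistics.

For each gene the two-sample pooled residual variance s_g^2 on
d_g = n1 + n2 - 2 degrees of freedom is shrunk toward a prior (d0, s0^2)
estimated from all genes by moment matching on log s_g^2 (digamma/trigamma
matching of the scaled-F model).  The posterior variance

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

replaces s_g^2 in the t denominator and the reference distribution becomes
Student t with d0 + d_g degrees of freedom (normal when d0 is infinite).
This stabilizes inference at the very small arm sizes typical of tissue
microarray cohorts.  log2 fold change is mean(treatment) - mean(control),
so "up" means higher in tumors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .cohort import CohortLabels

__all__ = [
    "DEThresholds",
    "moderated_t_table",
    "filter_degs",
    "top_k_by_direction",
    "fit_variance_prior",
]


@dataclass
class DEThresholds:
    """DEG filter: |logFC| >= logfc_cut and (FDR if use_fdr else p) < p_cut."""

    logfc_cut: float = 2.0
    p_cut: float = 0.05
    use_fdr: bool = True

    def __post_init__(self) -> None:
        if self.logfc_cut <= 0:
            raise ValueError("logfc_cut must be positive")
        if not (0 < self.p_cut < 1):
            raise ValueError("p_cut must be in (0,1)")


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (monotone, convex)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) / y < 1e-10:
            break
    return float(y)


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Estimate (d0, s0^2) of the scaled inverse-chi-square variance prior.

    Moment matching on z = log s^2: under the model z - log(s0^2) is a
    log-F variate whose mean and variance involve digamma/trigamma of
    df/2 and d0/2.  Returns d0 = inf (complete shrinkage) when the excess
    variance of z is non-positive or the inversion degenerates.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return np.inf, float(np.mean(s2)) if s2.size else 1.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    n = e.size
    evar = np.mean((e - e.mean()) ** 2) * n / (n - 1) - special.polygamma(1, df / 2.0)
    if evar <= 0:
        return np.inf, float(np.exp(e.mean()))
    d0 = 2.0 * _trigamma_inverse(float(evar))
    if not np.isfinite(d0) or d0 <= 0:
        return np.inf, float(np.exp(e.mean()))
    s0_2 = float(np.exp(e.mean() + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_2


def moderated_t_table(
    x: pd.DataFrame,
    labels: CohortLabels,
    thresholds: DEThresholds | None = None,
    d0_override: float | None = None,
) -> pd.DataFrame:
    """Per-gene moderated t-test of treatment vs control.

    Parameters
    ----------
    x
        Genes x samples log2 expression matrix.
    labels
        Cohort labels; both groups need >= 2 samples.
    thresholds
        Used only to annotate the ``direction`` column (up/down/none).
    d0_override
        Force the prior degrees of freedom: ``0`` reproduces the ordinary
        pooled-variance t-test, ``inf`` applies complete shrinkage to the
        pooled prior variance.

    Returns a DataFrame indexed by gene with columns ``logFC``, ``t``,
    ``p``, ``fdr``, ``direction``.
    """
    labels.validate_against(x)
    thresholds = thresholds or DEThresholds()
    ctl = x[labels.control_samples].values
    trt = x[labels.treatment_samples].values
    n1, n2 = ctl.shape[1], trt.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError(f"need >=2 samples per group, got control={n1}, treatment={n2}")

    logfc = trt.mean(axis=1) - ctl.mean(axis=1)
    df_resid = n1 + n2 - 2
    ss = ((ctl - ctl.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (trt - trt.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = ss / df_resid

    if d0_override is not None:
        d0 = float(d0_override)
        _, s0_2 = fit_variance_prior(s2, df_resid)
        if d0 == 0:
            s0_2 = 0.0  # unused; keeps posterior equal to s2
    else:
        d0, s0_2 = fit_variance_prior(s2, df_resid)

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_2 + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = logfc / se
    t = np.where((logfc == 0) & (se == 0), 0.0, t)

    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(np.isnan(p), 1.0, np.clip(p, 0.0, 1.0))
    fdr = multipletests(p, method="fdr_bh")[1]

    out = pd.DataFrame({"logFC": logfc, "t": t, "p": p, "fdr": fdr}, index=x.index)
    crit = out["fdr"] if thresholds.use_fdr else out["p"]
    direction = np.where(
        (out["logFC"] >= thresholds.logfc_cut) & (crit < thresholds.p_cut),
        "up",
        np.where(
            (out["logFC"] <= -thresholds.logfc_cut) & (crit < thresholds.p_cut),
            "down",
            "none",
        ),
    )
    out["direction"] = direction
    return out


def filter_degs(det: pd.DataFrame, thr: DEThresholds | None = None) -> list[tuple[str, str]]:
    """Genes passing the DEG thresholds as (gene, direction) pairs.

    Ordered by |t| descending, ties broken lexicographically by gene id.
    """
    thr = thr or DEThresholds()
    crit = det["fdr"] if thr.use_fdr else det["p"]
    mask = (det["logFC"].abs() >= thr.logfc_cut) & (crit < thr.p_cut)
    hits = det.loc[mask].copy()
    hits["_abst"] = hits["t"].abs()
    hits = hits.sort_index().sort_values("_abst", ascending=False, kind="stable")
    return [
        (gene, "up" if row.logFC > 0 else "down")
        for gene, row in hits.iterrows()
    ]


def top_k_by_direction(det: pd.DataFrame, k: int) -> list[str]:
    """The k most significant up genes and k most significant down genes.

    Significance is p ascending (ties by gene id); meant for heatmap
    export.  Directions with fewer than k passing genes return what is
    available with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    out: list[str] = []
    for direction in ("up", "down"):
        sub = det.loc[det["direction"] == direction].sort_index().sort_values(
            "p", kind="stable"
        )
        if len(sub) < k:
            warnings.warn(
                f"only {len(sub)} {direction} genes available for top-{k} selection"
            )
        out.extend(sub.index[:k])
    return out
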