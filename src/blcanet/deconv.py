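"""Reference-based immune-cell deconvolution of bulk expression.

Each bulk profile b is modeled as a non-negative combination of cell-type
reference profiles (the columns of a signature matrix S): fractions solve

    min_f || S f - b ||_2   subject to  f >= 0,

by non-negative least squares, then are normalized to sum to one.  Per
sample a permutation p-value measures whether the fit beats chance: the
statistic is the Pearson correlation between the fitted profile S f and b,
and the null redraws it after randomly permuting the gene labels of b.
Samples with p below a threshold (default 0.05) are retained for the
downstream summaries: a Spearman correlation matrix between cell-type
fractions and two-sided Wilcoxon rank-sum contrasts of each cell type
between treatment and control (exact enumeration for combined n <= 10,
normal approximation with tie correction above).

This is a transparent stand-in for kitchen-sink deconvolution suites: no
support-vector regression, no built-in signature — any non-negative
marker-genes x cell-types TSV works.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cohort import CohortLabels

__all__ = [
    "DeconvResult",
    "read_signature",
    "deconvolve",
    "permutation_p",
    "run_deconvolution",
    "fraction_correlations",
    "group_contrast",
    "rank_sum_test",
]


def read_signature(path) -> pd.DataFrame:
    """Signature TSV: first column gene symbols, header of cell types."""
    sig = pd.read_csv(path, sep="\t", index_col=0)
    validate_signature(sig)
    return sig


def validate_signature(sig: pd.DataFrame) -> None:
    if (sig.values < 0).any():
        raise ValueError("signature matrix contains negative entries")
    if sig.columns.duplicated().any():
        raise ValueError("duplicate cell-type names in signature")
    if np.linalg.matrix_rank(sig.values) < sig.shape[1]:
        raise ValueError("signature matrix is column-rank deficient")


def _nnls_fractions(S: np.ndarray, b: np.ndarray) -> np.ndarray:
    f, _ = optimize.nnls(S, b)
    total = f.sum()
    if total <= 0:
        raise ValueError("all-zero solution; bulk profile cannot be decomposed")
    return f / total


def _match_genes(bulk: pd.DataFrame, sig: pd.DataFrame) -> pd.Index:
    shared = bulk.index.intersection(sig.index)
    if len(shared) < sig.shape[1]:
        raise ValueError(
            f"only {len(shared)} genes shared between bulk and signature; "
            f"need at least {sig.shape[1]} (one per cell type)"
        )
    return shared


def deconvolve(
    bulk: pd.DataFrame, sig: pd.DataFrame, log2_scale: bool = False
) -> pd.DataFrame:
    """Estimate cell-type fractions per bulk sample.

    Genes are matched by symbol intersection; set ``log2_scale`` when the
    bulk matrix holds log2 values (they are linearized as 2^x first, since
    mixing is linear in expression space).  Returns samples x cell types;
    rows are non-negative and sum to one.
    """
    validate_signature(sig)
    shared = _match_genes(bulk, sig)
    B = bulk.loc[shared].values.astype(float)
    if log2_scale:
        B = np.power(2.0, B)
    S = sig.loc[shared].values.astype(float)
    out = np.empty((bulk.shape[1], sig.shape[1]))
    for j in range(B.shape[1]):
        if not B[:, j].any():
            raise ValueError(f"bulk column {bulk.columns[j]!r} is all zero")
        out[j] = _nnls_fractions(S, B[:, j])
    return pd.DataFrame(out, index=bulk.columns, columns=sig.columns)


def permutation_p(
    b: pd.Series | np.ndarray,
    sig: pd.DataFrame,
    n_perm: int = 100,
    seed: int = 0,
) -> float:
    """Permutation p-value for the goodness of a single sample's fit.

    Observed statistic: Pearson r between S f and b.  Null: the same
    statistic after permuting the gene labels of b.  p = (1 + #{null >=
    observed}) / (n_perm + 1), so the smallest attainable value is
    1/(n_perm+1).
    """
    if n_perm < 10:
        raise ValueError("n_perm must be >= 10")
    if isinstance(b, pd.Series):
        shared = sig.index.intersection(b.index)
        if len(shared) < sig.shape[1]:
            raise ValueError("too few shared genes for deconvolution")
        bv = b.loc[shared].values.astype(float)
        S = sig.loc[shared].values.astype(float)
    else:
        bv = np.asarray(b, dtype=float)
        S = sig.values.astype(float)

    def fit_corr(vec: np.ndarray) -> float:
        f, _ = optimize.nnls(S, vec)
        fitted = S @ f
        if fitted.std() == 0 or vec.std() == 0:
            return -1.0
        return float(np.corrcoef(fitted, vec)[0, 1])

    observed = fit_corr(bv)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if fit_corr(rng.permutation(bv)) >= observed:
            hits += 1
    return (1 + hits) / (n_perm + 1)


@dataclass
class DeconvResult:
    """Fractions plus per-sample fit p-values and the retention mask."""

    fractions: pd.DataFrame  # samples x cell types
    p_perm: pd.Series
    retained: pd.Series  # bool per sample
    p_threshold: float = 0.05


def run_deconvolution(
    bulk: pd.DataFrame,
    sig: pd.DataFrame,
    n_perm: int = 100,
    seed: int = 0,
    p_threshold: float = 0.05,
    log2_scale: bool = False,
) -> DeconvResult:
    """Deconvolve every sample and attach permutation p-values."""
    fractions = deconvolve(bulk, sig, log2_scale=log2_scale)
    shared = _match_genes(bulk, sig)
    B = bulk.loc[shared]
    if log2_scale:
        B = np.power(2.0, B)
    rng = np.random.default_rng(seed)
    pvals = {}
    for sample in bulk.columns:
        pvals[sample] = permutation_p(
            B[sample].values, sig.loc[shared], n_perm=n_perm,
            seed=int(rng.integers(2**31)),
        )
    p_perm = pd.Series(pvals).reindex(fractions.index)
    return DeconvResult(
        fractions=fractions,
        p_perm=p_perm,
        retained=p_perm < p_threshold,
        p_threshold=p_threshold,
    )


def fraction_correlations(result: DeconvResult) -> pd.DataFrame:
    """Spearman rho between cell-type fractions over retained samples.

    Cell types with constant fractions get missing entries for their
    pairs; the diagonal is fixed at 1.
    """
    kept = result.fractions.loc[result.retained]
    if len(kept) < 3:
        raise ValueError(f"need >=3 retained samples, have {len(kept)}")
    ranks = kept.rank(axis=0, method="average")
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(ranks.values, rowvar=False)
    corr = pd.DataFrame(corr, index=kept.columns, columns=kept.columns)
    np.fill_diagonal(corr.values, 1.0)
    return corr


def rank_sum_test(a, b) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact null by enumerating all C(n, n_a) group assignments of the
    pooled midranks when the combined n is at most 10; normal
    approximation with tie correction otherwise.  The two-sided p is twice
    the smaller tail, capped at 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    n = n1 + n2
    if n <= 10:
        pooled = np.r_[a, b]
        ranks = stats.rankdata(pooled)
        observed = ranks[:n1].sum()
        total = comb(n, n1)
        le = ge = 0
        eps = 1e-9
        for idx in combinations(range(n), n1):
            w = ranks[list(idx)].sum()
            if w <= observed + eps:
                le += 1
            if w >= observed - eps:
                ge += 1
        return min(1.0, 2.0 * min(le, ge) / total)
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.pvalue)


def group_contrast(result: DeconvResult, labels: CohortLabels) -> pd.DataFrame:
    """Per-cell-type Wilcoxon contrast of retained treatment vs control.

    Returns a DataFrame with columns ``p``, ``direction`` (sign of the
    treatment-minus-control median difference) and per-group sample
    counts; cell types are skipped with a warning when a group has fewer
    than 2 retained samples.
    """
    kept = result.fractions.loc[result.retained]
    groups = labels.groups.reindex(kept.index)
    trt = kept.loc[groups == "treatment"]
    ctl = kept.loc[groups == "control"]
    if len(trt) < 2 or len(ctl) < 2:
        raise ValueError(
            f"need >=2 retained samples per group, have treatment={len(trt)}, "
            f"control={len(ctl)}"
        )
    rows = []
    for ct in kept.columns:
        diff = float(trt[ct].median() - ctl[ct].median())
        p = rank_sum_test(trt[ct].values, ctl[ct].values)
        direction = "up" if diff > 0 else ("down" if diff < 0 else "none")
        rows.append((ct, p, direction, len(trt), len(ctl)))
    return pd.DataFrame(
        rows, columns=["cell_type", "p", "direction", "n_treatment", "n_control"]
    ).set_index("cell_type")
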