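"""Median binarization of feature-gene expression.

Each feature gene is reduced to a per-sample 0/1 score against the gene's
median over all samples of the cohort (both groups pooled): an up-regulated
gene scores 1 when expression is strictly above its median, a
down-regulated gene scores 1 when strictly below.  Values exactly at the
median score 0 in either direction.  These score vectors are the input
schema of the downstream classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import FeatureGeneSet

__all__ = ["ScoreMatrix", "cohort_medians", "score_samples"]


@dataclass
class ScoreMatrix:
    """Samples x feature genes binary scores plus the medians that made
    them (re-applying the stored medians reproduces the matrix)."""

    scores: pd.DataFrame  # samples x genes, values in {0,1}
    medians: pd.Series  # gene -> cohort median used
    cohort: str = "train"

    def __post_init__(self) -> None:
        vals = self.scores.values
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("score entries must be exactly 0 or 1")
        if list(self.scores.columns) != list(self.medians.index):
            raise ValueError("score columns and median index disagree")

    @property
    def feature_genes(self) -> list[str]:
        return list(self.scores.columns)


def cohort_medians(x: pd.DataFrame, genes: FeatureGeneSet | list[str]) -> pd.Series:
    """Per-gene median over all samples of the cohort (groups pooled).

    Even sample counts use the midpoint of the two central order
    statistics (the usual linear-interpolation median).
    """
    names = genes.genes if isinstance(genes, FeatureGeneSet) else list(genes)
    missing = [g for g in names if g not in x.index]
    if missing:
        raise KeyError(f"feature genes absent from the matrix: {missing}")
    return x.loc[names].median(axis=1)


def score_samples(
    x: pd.DataFrame,
    genes: FeatureGeneSet,
    medians: pd.Series | None = None,
    cohort: str = "train",
) -> ScoreMatrix:
    """Binary score matrix for *x* given feature genes and their medians.

    When *medians* is omitted they are computed from *x* itself (the
    within-cohort reading); pass the training medians explicitly for
    deployment-style scoring of new samples.
    """
    if medians is None:
        medians = cohort_medians(x, genes)
    medians = medians.reindex(genes.genes)
    if medians.isna().any():
        raise KeyError(
            f"medians missing for: {list(medians.index[medians.isna()])}"
        )
    if (~genes.direction.isin(["up", "down"])).any():
        bad = list(genes.direction.index[~genes.direction.isin(["up", "down"])])
        raise ValueError(f"feature genes without an up/down direction: {bad}")

    expr = x.loc[genes.genes].T  # samples x genes
    up = genes.direction.reindex(genes.genes) == "up"
    cols = {
        g: (expr[g] > medians[g]) if up[g] else (expr[g] < medians[g])
        for g in genes.genes
    }
    scores = pd.DataFrame(cols, index=expr.index).astype(int)
    return ScoreMatrix(scores=scores, medians=medians, cohort=cohort)
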