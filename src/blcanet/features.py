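"""Random-forest screening of candidate genes.

A bagged ensemble of CART trees (Gini criterion, ``mtry`` random candidate
features per split) is grown on bootstrap resamples of the cohort.  The
out-of-bag (OOB) misclassification rate is tracked as a function of the
number of trees; the forest is truncated at the first minimum of that
curve, and per-gene importance is the mean over the retained trees of the
total Gini impurity decrease attributable to splits on the gene, weighted
by node sample counts.  That count-weighted scale matches the
MeanDecreaseGini reported by the classic R randomForest implementation
(scores routinely exceed 1), which is the scale on which an importance
cutoff of 0.30 is meaningful.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .cohort import CohortLabels

__all__ = [
    "ForestConfig",
    "RandomForest",
    "FeatureGeneSet",
    "train_forest",
    "select_n_trees",
    "importance_scores",
    "select_feature_genes",
]


@dataclass
class ForestConfig:
    max_trees: int = 500
    mtry: int | None = None  # default floor(sqrt(p)) at fit time
    min_leaf: int = 1
    importance_cut: float = 0.30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_trees < 1:
            raise ValueError("max_trees must be >= 1")
        if self.mtry is not None and self.mtry < 1:
            raise ValueError("mtry must be >= 1")
        if self.min_leaf < 1:
            raise ValueError("min_leaf must be >= 1")


@dataclass
class RandomForest:
    """Trained ensemble with everything needed for OOB curves and
    count-scale importances."""

    trees: list[DecisionTreeClassifier]
    oob_masks: list[np.ndarray]  # per tree: bool mask of out-of-bag samples
    feature_names: list[str]
    n_samples: int
    config: ForestConfig

    def __len__(self) -> int:
        return len(self.trees)


@dataclass
class FeatureGeneSet:
    """Genes passing the importance cutoff, sorted by importance descending."""

    genes: list[str]
    importance: pd.Series  # selected genes only
    direction: pd.Series  # up/down per selected gene
    n_trees_selected: int
    oob_curve: np.ndarray
    importances_full: pd.Series = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if (self.importance < 0).any():
            raise ValueError("importances must be non-negative")
        missing = [g for g in self.genes if g not in self.direction.index]
        if missing:
            raise ValueError(f"feature genes without a DE direction: {missing}")


def train_forest(
    x: pd.DataFrame,
    labels: CohortLabels,
    cfg: ForestConfig | None = None,
) -> tuple[RandomForest, np.ndarray]:
    """Grow the bagged CART ensemble and its OOB error curve.

    *x* is genes x samples restricted to the candidate (DEG) genes;
    ``oob_curve[k-1]`` is the OOB misclassification rate of the first k
    trees (majority vote over trees for which a sample was out of bag;
    samples not yet out of bag for any tree are excluded from the rate).
    """
    cfg = cfg or ForestConfig()
    labels.validate_against(x)
    samples = labels.sample_ids
    X = x[samples].T.values  # samples x genes
    y = labels.binary().loc[samples].values
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    n, p = X.shape
    if p < 2:
        raise ValueError("need >=2 candidate genes")
    mtry = cfg.mtry or max(1, int(np.sqrt(p)))
    if mtry > p:
        raise ValueError(f"mtry={mtry} exceeds number of candidate genes p={p}")

    rng = np.random.default_rng(cfg.seed)
    trees: list[DecisionTreeClassifier] = []
    oob_masks: list[np.ndarray] = []
    votes = np.zeros((n, 2))
    curve = np.empty(cfg.max_trees)
    for k in range(cfg.max_trees):
        idx = rng.integers(0, n, size=n)
        oob = np.ones(n, dtype=bool)
        oob[idx] = False
        tree = DecisionTreeClassifier(
            criterion="gini",
            max_features=mtry,
            min_samples_leaf=cfg.min_leaf,
            random_state=int(rng.integers(2**31)),
        )
        tree.fit(X[idx], y[idx])
        trees.append(tree)
        oob_masks.append(oob)
        if oob.any():
            pred = tree.predict(X[oob]).astype(int)
            votes[np.flatnonzero(oob), pred] += 1
        covered = votes.sum(axis=1) > 0
        if covered.any():
            majority = (votes[covered, 1] > votes[covered, 0]).astype(int)
            curve[k] = float(np.mean(majority != y[covered]))
        else:
            curve[k] = 1.0
    forest = RandomForest(trees, oob_masks, list(x.index), n, cfg)
    return forest, curve


def select_n_trees(oob_curve: np.ndarray) -> int:
    """Smallest tree count attaining the minimum OOB error."""
    curve = np.asarray(oob_curve, dtype=float)
    if curve.size == 0:
        raise ValueError("empty OOB curve")
    return int(np.argmin(curve)) + 1


def importance_scores(
    forest: RandomForest,
    n_trees: int | None = None,
    directions: pd.Series | None = None,
    importance_cut: float | None = None,
) -> FeatureGeneSet:
    """Count-weighted mean decrease in Gini over the first *n_trees* trees.

    Each tree contributes, per gene, the sum over its splits on that gene
    of ``n_node*Gini(node) - n_left*Gini(left) - n_right*Gini(right)``
    (sample counts, not fractions); the gene score is the average over
    trees.  Genes above ``importance_cut`` form the feature set, each
    carrying its DE direction from *directions*.
    """
    cut = forest.config.importance_cut if importance_cut is None else importance_cut
    n_trees = len(forest) if n_trees is None else n_trees
    if not (1 <= n_trees <= len(forest)):
        raise ValueError(f"n_trees must be in [1, {len(forest)}]")
    total = np.zeros(len(forest.feature_names))
    for tree in forest.trees[:n_trees]:
        # sklearn's unnormalized importances are count-weighted decreases
        # divided by the root sample count; multiply back to the R scale.
        total += tree.tree_.compute_feature_importances(normalize=False) * forest.n_samples
    imp_full = pd.Series(total / n_trees, index=forest.feature_names)

    selected = imp_full[imp_full > cut].sort_values(ascending=False, kind="stable")
    if selected.empty:
        warnings.warn(
            f"no gene exceeds importance cutoff {cut} "
            f"(max observed {imp_full.max():.3f})"
        )
    if directions is None:
        directions = pd.Series("none", index=forest.feature_names, dtype=object)
    return FeatureGeneSet(
        genes=list(selected.index),
        importance=selected,
        direction=directions.reindex(selected.index),
        n_trees_selected=n_trees,
        oob_curve=np.array([]),
        importances_full=imp_full,
    )


def select_feature_genes(
    x: pd.DataFrame,
    labels: CohortLabels,
    degs: list[tuple[str, str]],
    cfg: ForestConfig | None = None,
) -> FeatureGeneSet:
    """End-to-end screening: train, truncate at the OOB minimum, score.

    *degs* are (gene, direction) pairs from the DE stage; only those genes
    enter the forest.
    """
    cfg = cfg or ForestConfig()
    genes = [g for g, _ in degs]
    directions = pd.Series({g: d for g, d in degs}, dtype=object)
    forest, curve = train_forest(x.loc[genes], labels, cfg)
    n_trees = select_n_trees(curve)
    fgs = importance_scores(forest, n_trees, directions)
    fgs.oob_curve = curve
    return fgs
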