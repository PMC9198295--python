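"""Synthetic inputs for every pipeline stage, with ground truth attached.

Three generators:

* ``generate_expression`` — log2-intensity microarray-like matrices for a
  two-group cohort with a planted subset of differentially expressed genes
  (Gaussian noise per gene, per-gene variance heterogeneity).
* ``generate_mixtures`` — a non-negative signature matrix and bulk profiles
  that are noisy convex combinations of its columns, with the true cell
  fractions returned alongside.
* ``generate_gmt`` — a gene-set collection with one set deliberately
  enriched for a supplied gene list.

Defaults mirror small two-arm tissue cohorts: 6 control vs 10 treatment
samples, baseline log2 intensity around 8, per-gene standard deviations in
0.3–1.0, and planted effects of 3 log2 units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import CONTROL, TREATMENT, CohortLabels
from .enrichment import GeneSetCollection

__all__ = [
    "SyntheticExpressionSpec",
    "SyntheticMixtureSpec",
    "generate_expression",
    "generate_mixtures",
    "generate_gmt",
]


@dataclass
class SyntheticExpressionSpec:
    """Parameters of the two-group expression generator.

    ``de_logfc_magnitude`` is the planted |log2 fold change|; up-regulated
    genes gain it in the treatment arm, down-regulated genes lose it.
    """

    n_genes: int = 1000
    n_control: int = 6
    n_treatment: int = 10
    n_de_up: int = 25
    n_de_down: int = 25
    de_logfc_magnitude: float = 3.0
    baseline_mean: float = 8.0
    baseline_mean_sd: float = 2.0
    gene_sd_range: tuple[float, float] = (0.3, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        counts = dict(
            n_genes=self.n_genes,
            n_control=self.n_control,
            n_treatment=self.n_treatment,
            n_de_up=self.n_de_up,
            n_de_down=self.n_de_down,
        )
        for name, v in counts.items():
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")
        if self.n_de_up + self.n_de_down > self.n_genes:
            raise ValueError(
                f"n_de_up + n_de_down = {self.n_de_up + self.n_de_down} "
                f"exceeds n_genes = {self.n_genes}"
            )
        lo, hi = self.gene_sd_range
        if not (0 < lo <= hi):
            raise ValueError(f"gene_sd_range must satisfy 0 < lo <= hi, got {self.gene_sd_range}")


def generate_expression(
    spec: SyntheticExpressionSpec,
) -> tuple[pd.DataFrame, CohortLabels, pd.Series]:
    """Draw a genes x samples log2 matrix with planted DE genes.

    Per gene g: baseline mu_g ~ Normal(baseline_mean, baseline_mean_sd^2),
    sd sigma_g ~ Uniform(gene_sd_range); control samples ~ Normal(mu_g,
    sigma_g^2); treatment samples get mu_g +/- de_logfc_magnitude for the
    planted genes.  The first ``n_de_up`` genes are planted up, the next
    ``n_de_down`` down, so planted identities are stable across cohorts
    generated from specs sharing those counts.

    Returns the matrix, cohort labels and a ground-truth direction Series
    (values ``up``/``down``/``none``) indexed by gene.
    """
    rng = np.random.default_rng(spec.seed)
    genes = [f"G{i:05d}" for i in range(spec.n_genes)]
    samples = [f"ctl_{i + 1:02d}" for i in range(spec.n_control)] + [
        f"trt_{i + 1:02d}" for i in range(spec.n_treatment)
    ]

    mu = rng.normal(spec.baseline_mean, spec.baseline_mean_sd, size=spec.n_genes)
    sd = rng.uniform(*spec.gene_sd_range, size=spec.n_genes)

    truth = pd.Series("none", index=genes, name="direction", dtype=object)
    delta = np.zeros(spec.n_genes)
    delta[: spec.n_de_up] = spec.de_logfc_magnitude
    delta[spec.n_de_up : spec.n_de_up + spec.n_de_down] = -spec.de_logfc_magnitude
    truth.iloc[: spec.n_de_up] = "up"
    truth.iloc[spec.n_de_up : spec.n_de_up + spec.n_de_down] = "down"

    n_samples = spec.n_control + spec.n_treatment
    values = rng.normal(size=(spec.n_genes, n_samples)) * sd[:, None] + mu[:, None]
    values[:, spec.n_control :] += delta[:, None]

    matrix = pd.DataFrame(values, index=genes, columns=samples)
    groups = pd.Series(
        [CONTROL] * spec.n_control + [TREATMENT] * spec.n_treatment, index=samples
    )
    labels = CohortLabels(groups, role="train")
    return matrix, labels, truth


@dataclass
class SyntheticMixtureSpec:
    """Parameters of the signature/bulk mixture generator."""

    n_marker_genes: int = 200
    n_cell_types: int = 5
    n_mixtures: int = 20
    dirichlet_alpha: float = 1.0
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_marker_genes", "n_cell_types", "n_mixtures"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.dirichlet_alpha <= 0:
            raise ValueError("dirichlet_alpha must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def generate_mixtures(
    spec: SyntheticMixtureSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw a signature matrix S, true fractions F and bulk = S.F + noise.

    The signature has lognormal marker expression with each cell type given
    an exclusive block of high-expressed markers, which keeps the columns
    well separated; full column rank is verified and the draw repeated (up
    to 10 times) otherwise.

    Returns ``(signature genes x types, bulk genes x mixtures, fractions
    mixtures x types)``; fractions are Dirichlet(alpha) and sum to one.
    """
    rng = np.random.default_rng(spec.seed)
    genes = [f"M{i:04d}" for i in range(spec.n_marker_genes)]
    types = [f"cell_type_{i + 1}" for i in range(spec.n_cell_types)]

    for _attempt in range(10):
        sig = rng.lognormal(mean=1.0, sigma=0.6, size=(spec.n_marker_genes, spec.n_cell_types))
        # exclusive high-expression marker block per cell type
        block = max(1, spec.n_marker_genes // (2 * spec.n_cell_types))
        for j in range(spec.n_cell_types):
            rows = slice(j * block, min((j + 1) * block, spec.n_marker_genes))
            sig[rows, j] += rng.lognormal(mean=2.5, sigma=0.4, size=(rows.stop - rows.start))
        if (
            spec.n_marker_genes < spec.n_cell_types
            or np.linalg.matrix_rank(sig) == spec.n_cell_types
        ):
            break
    else:
        raise RuntimeError("failed to draw a full-column-rank signature in 10 attempts")

    fractions = rng.dirichlet(
        np.full(spec.n_cell_types, spec.dirichlet_alpha), size=spec.n_mixtures
    )
    bulk = sig @ fractions.T
    if spec.noise_sd > 0:
        bulk = bulk + rng.normal(0.0, spec.noise_sd, size=bulk.shape)

    mixtures = [f"mix_{i + 1:03d}" for i in range(spec.n_mixtures)]
    return (
        pd.DataFrame(sig, index=genes, columns=types),
        pd.DataFrame(bulk, index=genes, columns=mixtures),
        pd.DataFrame(fractions, index=mixtures, columns=types),
    )


def generate_gmt(
    n_sets: int,
    universe_size: int,
    planted_list: list[str],
    planted_set_overlap: int,
    seed: int = 0,
    set_size: int = 40,
    planted_set_name: str = "planted_set",
    universe: list[str] | None = None,
) -> GeneSetCollection:
    """Gene-set collection with one set enriched for *planted_list*.

    The universe is the planted list plus filler symbols up to
    ``universe_size`` (or an explicit *universe* containing the planted
    list).  One set holds exactly ``planted_set_overlap`` genes from the
    planted list (the rest of its members drawn from outside the list);
    the remaining ``n_sets - 1`` sets are uniform draws from the whole
    universe.
    """
    if planted_set_overlap > len(planted_list):
        raise ValueError(
            f"planted_set_overlap ({planted_set_overlap}) exceeds planted list "
            f"size ({len(planted_list)})"
        )
    rng = np.random.default_rng(seed)
    if universe is None:
        if universe_size < len(planted_list):
            raise ValueError("universe_size smaller than the planted list")
        filler = [f"U{i:05d}" for i in range(universe_size - len(planted_list))]
        universe = list(planted_list) + filler
    else:
        universe = list(universe)
        if not set(planted_list) <= set(universe):
            raise ValueError("explicit universe must contain the planted list")
        universe_size = len(universe)

    sets: dict[str, list[str]] = {}
    desc: dict[str, str] = {}
    in_list = rng.choice(planted_list, size=planted_set_overlap, replace=False).tolist()
    outside = [g for g in universe if g not in set(planted_list)]
    n_fill = min(max(set_size - planted_set_overlap, 0), len(outside))
    members = in_list + rng.choice(outside, size=n_fill, replace=False).tolist()
    sets[planted_set_name] = members
    desc[planted_set_name] = "synthetic set enriched for the planted gene list"
    for i in range(n_sets - 1):
        name = f"random_set_{i + 1:03d}"
        sets[name] = rng.choice(universe, size=min(set_size, universe_size), replace=False).tolist()
        desc[name] = "synthetic uniform draw from the universe"
    return GeneSetCollection(sets, universe, desc)
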