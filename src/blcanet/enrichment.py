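"""Over-representation analysis (ORA) of a gene list against GMT gene sets.

The test is the one-sided hypergeometric tail: given a universe of N
scorable genes, a set of K members and a query list of n genes with k of
them in the set, p = P(X >= k) for X ~ Hypergeometric(N, K, n).  Records
carry the enrichment factor k / (n*K/N) — observed overlap over its
expectation under random draws — and Benjamini–Hochberg adjusted p-values.
The default reporting filters keep terms with p < 0.01, overlap >= 3 and
enrichment factor > 1.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "ora_test",
    "apply_metascape_filters",
]


@dataclass
class GeneSetCollection:
    """Named gene sets plus the universe of scorable genes.

    ``sets`` maps set name to an ordered list of member symbols;
    ``descriptions`` keeps the GMT description column for round-tripping.
    """

    sets: dict[str, list[str]]
    universe: list[str]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        empty = [name for name, members in self.sets.items() if not members]
        if empty:
            raise ValueError(f"empty gene sets not allowed: {empty}")

    def harmonized(self) -> "GeneSetCollection":
        """Restrict every set to the universe; drop sets that become empty."""
        uni = set(self.universe)
        sets, desc = {}, {}
        for name, members in self.sets.items():
            kept = [g for g in members if g in uni]
            if kept:
                sets[name] = kept
                desc[name] = self.descriptions.get(name, "")
        return GeneSetCollection(sets, list(self.universe), desc)


def read_gmt(path) -> GeneSetCollection:
    """Read a tab-delimited GMT file (name, description, members...)."""
    sets: dict[str, list[str]] = {}
    desc: dict[str, str] = {}
    universe: dict[str, None] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line (need >=3 fields): {line[:80]!r}")
            name, description, members = fields[0], fields[1], fields[2:]
            members = [m for m in members if m]
            sets[name] = members
            desc[name] = description
            for m in members:
                universe[m] = None
    return GeneSetCollection(sets, list(universe), desc)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            description = collection.descriptions.get(name, "")
            fh.write("\t".join([name, description, *members]) + "\n")


def ora_test(gene_list: list[str], collection: GeneSetCollection) -> pd.DataFrame:
    """Hypergeometric over-representation test of *gene_list* per set.

    Returns a DataFrame indexed by set name with columns ``k`` (overlap),
    ``n`` (list size after harmonization), ``K`` (set size), ``N``
    (universe size), ``p``, ``fdr``, ``enrichment_factor`` and ``passes``
    (the default reporting filters), sorted by p ascending.
    """
    universe = set(collection.universe)
    query = [g for g in dict.fromkeys(gene_list) if g in universe]
    dropped = len(set(gene_list)) - len(query)
    if dropped:
        warnings.warn(f"{dropped} query genes outside the universe were dropped")
    if not query:
        raise ValueError("gene list empty after harmonization with the universe")

    harm = collection.harmonized()
    n, N = len(query), len(universe)
    qset = set(query)
    rows = []
    for name, members in harm.sets.items():
        K = len(set(members))
        k = len(qset & set(members))
        # survival function at k-1 gives P(X >= k); exact at k=0 (p=1)
        p = float(hypergeom.sf(k - 1, N, K, n))
        expected = n * K / N
        ef = k / expected if expected > 0 else 0.0
        rows.append((name, k, n, K, N, min(p, 1.0), ef))
    if not rows:
        raise ValueError("no gene sets overlap the universe")
    out = pd.DataFrame(rows, columns=["set", "k", "n", "K", "N", "p", "enrichment_factor"])
    out["fdr"] = multipletests(out["p"].values, method="fdr_bh")[1]
    out = out.set_index("set").sort_values(["p", "k"], ascending=[True, False])
    out["passes"] = (out["p"] < 0.01) & (out["k"] >= 3) & (out["enrichment_factor"] > 1.5)
    return out[["k", "n", "K", "N", "p", "fdr", "enrichment_factor", "passes"]]


def apply_metascape_filters(
    records: pd.DataFrame,
    p_cut: float = 0.01,
    min_count: int = 3,
    ef_cut: float = 1.5,
) -> pd.DataFrame:
    """Keep records with p < p_cut, overlap >= min_count and enrichment
    factor > ef_cut (p and EF strict, count inclusive)."""
    mask = (
        (records["p"] < p_cut)
        & (records["k"] >= min_count)
        & (records["enrichment_factor"] > ef_cut)
    )
    return records.loc[mask]
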