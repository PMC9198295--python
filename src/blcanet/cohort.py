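"""Sample-group bookkeeping shared by every pipeline stage.

A cohort is a set of samples split into a ``control`` arm (normal tissue)
and a ``treatment`` arm (tumor tissue), optionally annotated with the
accession each sample came from and whether the cohort plays the ``train``
or ``test`` role.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

CONTROL = "control"
TREATMENT = "treatment"
GROUPS = (CONTROL, TREATMENT)


@dataclass
class CohortLabels:
    """Mapping of sample id to study group.

    Parameters
    ----------
    groups
        Series indexed by sample id with values ``"control"`` or
        ``"treatment"``.
    role
        ``"train"`` or ``"test"``.
    accession
        Optional series indexed by sample id giving the source accession.
    """

    groups: pd.Series
    role: str = "train"
    accession: pd.Series | None = field(default=None)

    def __post_init__(self) -> None:
        self.groups = pd.Series(self.groups, dtype=object)
        if self.groups.index.duplicated().any():
            raise ValueError("duplicate sample ids in cohort labels")
        bad = set(self.groups.unique()) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.groups.index)

    def samples(self, group: str) -> list[str]:
        if group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {group!r}")
        return list(self.groups.index[self.groups == group])

    @property
    def control_samples(self) -> list[str]:
        return self.samples(CONTROL)

    @property
    def treatment_samples(self) -> list[str]:
        return self.samples(TREATMENT)

    def binary(self) -> pd.Series:
        """0/1 encoding: control=0, treatment=1 (treatment is positive)."""
        return (self.groups == TREATMENT).astype(int)

    def validate_against(self, matrix: pd.DataFrame) -> None:
        """Check every labeled sample is a column of *matrix* and both arms
        are non-empty."""
        missing = [s for s in self.sample_ids if s not in matrix.columns]
        if missing:
            raise ValueError(f"labeled samples absent from matrix: {missing}")
        for g in GROUPS:
            if not self.samples(g):
                raise ValueError(f"cohort has no {g} samples")

    def subset(self, sample_ids: list[str]) -> "CohortLabels":
        acc = self.accession.loc[sample_ids] if self.accession is not None else None
        return CohortLabels(self.groups.loc[sample_ids], role=self.role, accession=acc)

    def concat(self, other: "CohortLabels", role: str | None = None) -> "CohortLabels":
        groups = pd.concat([self.groups, other.groups])
        acc = None
        if self.accession is not None and other.accession is not None:
            acc = pd.concat([self.accession, other.accession])
        return CohortLabels(groups, role=role or self.role, accession=acc)


def write_labels(labels: CohortLabels, path) -> None:
    """Two-column TSV: sample_id, group (plus accession when known)."""
    df = pd.DataFrame({"sample_id": labels.sample_ids, "group": labels.groups.values})
    if labels.accession is not None:
        df["accession"] = labels.accession.loc[labels.sample_ids].values
    df.to_csv(path, sep="\t", index=False)


def read_labels(path, role: str = "train") -> CohortLabels:
    df = pd.read_csv(path, sep="\t", dtype=str)
    groups = pd.Series(df["group"].values, index=df["sample_id"].values)
    acc = None
    if "accession" in df.columns:
        acc = pd.Series(df["accession"].values, index=df["sample_id"].values)
    return CohortLabels(groups, role=role, accession=acc)
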