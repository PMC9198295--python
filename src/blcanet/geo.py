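"""GEO series-matrix ingestion: parse, label, collapse probes, merge cohorts.

A series-matrix file interleaves ``!``-prefixed metadata lines with one
probes x samples data table delimited by ``!series_matrix_table_begin`` /
``!series_matrix_table_end``.  Sample ids in the table header are quoted;
missing cells are empty or the literal ``null``.  Files may be gzipped.

Free-text sample metadata (characteristics, source, title) is matched
against configurable substring rules to assign tumor (treatment) vs normal
(control) groups.  Probe-level tables are collapsed to gene symbols using a
two-column annotation (probe_id, symbol), keeping the probe with the
highest mean expression per symbol, and cohorts from different platforms
are merged on the symbol intersection after per-dataset quantile
normalization.
"""

from __future__ import annotations

import gzip
import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CONTROL, TREATMENT, CohortLabels

__all__ = [
    "SeriesMatrix",
    "LabelRule",
    "parse_series_matrix",
    "assign_labels",
    "collapse_probes",
    "merge_cohorts",
    "quantile_normalize",
    "read_matrix",
    "write_matrix",
    "read_annotation",
]

MISSING_MARKERS = {"", "null", "NULL", "NA", "NaN"}


@dataclass
class SeriesMatrix:
    """Parsed series-matrix file: metadata plus the probe-level table."""

    accession: str
    platform: str
    sample_ids: list[str]
    sample_metadata: dict[str, list[str]]  # metadata key -> one value per sample
    probe_table: pd.DataFrame  # probes x samples, NaN where missing

    def __post_init__(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids in series matrix")
        if self.probe_table.shape[1] != len(self.sample_ids):
            raise ValueError(
                f"table has {self.probe_table.shape[1]} columns but "
                f"{len(self.sample_ids)} sample ids"
            )


def _open_text(path):
    data = open(path, "rb").read()
    if data[:2] == b"\x1f\x8b":
        data = gzip.decompress(data)
    return io.StringIO(data.decode("utf-8", errors="replace"))


def _unquote(tok: str) -> str:
    tok = tok.strip()
    if len(tok) >= 2 and tok[0] == '"' and tok[-1] == '"':
        tok = tok[1:-1]
    return tok


def parse_series_matrix(path) -> SeriesMatrix:
    """Parse a GEO series-matrix TXT (optionally gzipped)."""
    fh = _open_text(path)
    meta: dict[str, list[list[str]]] = {}
    accession = platform = ""
    table_lines: list[str] = []
    in_table = False
    begin_seen = end_seen = False
    for lineno, raw in enumerate(fh, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if line.startswith("!series_matrix_table_begin"):
            in_table, begin_seen = True, True
            continue
        if line.startswith("!series_matrix_table_end"):
            in_table, end_seen = False, True
            continue
        if in_table:
            if line.strip():
                table_lines.append(line)
            continue
        if not line.startswith("!"):
            continue
        key, _, rest = line[1:].partition("\t")
        values = [_unquote(v) for v in rest.split("\t")] if rest else []
        meta.setdefault(key, []).append(values)
        if key == "Series_geo_accession" and values:
            accession = values[0]
        if key == "Series_platform_id" and values and not platform:
            platform = values[0]

    if not begin_seen:
        raise ValueError(f"{path}: no !series_matrix_table_begin line found")
    if not end_seen:
        raise ValueError(f"{path}: no !series_matrix_table_end line found")
    if not table_lines:
        raise ValueError(f"{path}: empty data table")

    header = [_unquote(t) for t in table_lines[0].split("\t")]
    sample_ids = header[1:]
    probes, rows = [], []
    for line in table_lines[1:]:
        toks = line.split("\t")
        probe = _unquote(toks[0])
        vals = []
        for sample, tok in zip(sample_ids, toks[1:]):
            tok = _unquote(tok)
            if tok in MISSING_MARKERS:
                vals.append(np.nan)
                continue
            try:
                vals.append(float(tok))
            except ValueError as exc:
                raise ValueError(
                    f"{path}: non-numeric value {tok!r} at probe {probe!r}, "
                    f"sample {sample!r}"
                ) from exc
        if len(vals) < len(sample_ids):
            vals.extend([np.nan] * (len(sample_ids) - len(vals)))
        probes.append(probe)
        rows.append(vals)

    table = pd.DataFrame(rows, index=probes, columns=sample_ids, dtype=float)

    # per-sample metadata: keys whose value lists are sample-aligned
    sample_meta: dict[str, list[str]] = {}
    for key, occurrences in meta.items():
        if not key.startswith("Sample_"):
            continue
        for i, values in enumerate(occurrences):
            if len(values) == len(sample_ids):
                name = key if len(occurrences) == 1 else f"{key}.{i}"
                sample_meta[name] = values

    return SeriesMatrix(
        accession=accession or "unknown",
        platform=platform or "unknown",
        sample_ids=sample_ids,
        sample_metadata=sample_meta,
        probe_table=table,
    )


@dataclass
class LabelRule:
    """Case-insensitive substring rules mapping metadata text to groups.

    A sample whose concatenated metadata contains any ``treatment_patterns``
    substring is a tumor (treatment) sample; ``control_patterns`` mark
    normal tissue.  When both sides match — common in GEO, where normal
    tissue is described as "para-tumor" — the side whose longest matched
    pattern is more specific (longer) wins; an exact specificity tie is a
    genuine conflict and raises.
    """

    treatment_patterns: tuple[str, ...] = ("tumor", "tumour", "cancer", "carcinoma", "blca")
    control_patterns: tuple[str, ...] = ("normal", "para-tumor", "paratumor", "adjacent", "healthy")


def assign_labels(sm: SeriesMatrix, rule: LabelRule | None = None, role: str = "train") -> CohortLabels:
    """Assign control/treatment groups from free-text sample metadata."""
    rule = rule or LabelRule()
    groups: dict[str, str] = {}
    unmatched: list[str] = []
    seen_values: list[str] = []
    for i, sample in enumerate(sm.sample_ids):
        text = " | ".join(values[i] for values in sm.sample_metadata.values()).lower()
        seen_values.append(text)
        trt_len = max((len(p) for p in rule.treatment_patterns if p.lower() in text), default=0)
        ctl_len = max((len(p) for p in rule.control_patterns if p.lower() in text), default=0)
        if trt_len and trt_len == ctl_len:
            raise ValueError(
                f"sample {sample} matches both treatment and control patterns "
                f"with equal specificity: {text!r}"
            )
        if trt_len > ctl_len:
            groups[sample] = TREATMENT
        elif ctl_len > trt_len:
            groups[sample] = CONTROL
        else:
            unmatched.append(sample)
    if unmatched:
        warnings.warn(f"{len(unmatched)} samples matched no pattern and were excluded: {unmatched}")
    for g, name in ((TREATMENT, "treatment"), (CONTROL, "control")):
        if g not in groups.values():
            raise ValueError(
                f"no sample matched the {name} patterns; metadata seen: {seen_values}"
            )
    series = pd.Series(groups, dtype=object)
    acc = pd.Series(sm.accession, index=series.index)
    return CohortLabels(series, role=role, accession=acc)


def read_annotation(path) -> pd.Series:
    """Two-column TSV (probe_id, symbol) -> Series probe -> symbol."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    df = df.dropna()
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values)


def collapse_probes(
    sm: SeriesMatrix,
    annotation: pd.Series,
    log2_threshold: float = 50.0,
) -> pd.DataFrame:
    """Collapse the probe table to unique gene symbols.

    Probes without a symbol are dropped; when several probes map to one
    symbol the probe with the highest mean expression wins.  If the matrix
    maximum exceeds ``log2_threshold`` the values are taken to be on the
    linear scale and log2(x+1) transformed.
    """
    table = sm.probe_table.dropna(axis=0, how="any")
    annotation = annotation.dropna()
    shared = table.index.intersection(annotation.index)
    if len(shared) == 0:
        raise ValueError("annotation covers none of the probes in the table")
    table = table.loc[shared]
    symbols = annotation.loc[shared]

    means = table.mean(axis=1)
    # highest-mean probe per symbol; ties broken by probe id for determinism
    order = pd.DataFrame({"symbol": symbols.values, "mean": means.values, "probe": shared})
    order = order.sort_values(["symbol", "mean", "probe"], ascending=[True, False, True])
    best = order.drop_duplicates("symbol", keep="first")
    out = table.loc[best["probe"].values]
    out.index = best["symbol"].values

    if float(np.nanmax(out.values)) > log2_threshold:
        out = np.log2(out + 1.0)
    return out.sort_index()


def quantile_normalize(x: pd.DataFrame) -> pd.DataFrame:
    """Map every sample to the mean order-statistic profile (rank ties
    averaged)."""
    sorted_vals = np.sort(x.values, axis=0)
    mean_profile = sorted_vals.mean(axis=1)
    out = np.empty_like(x.values, dtype=float)
    for j in range(x.shape[1]):
        ranks = pd.Series(x.values[:, j]).rank(method="average").values  # 1-based
        out[:, j] = np.interp(ranks, np.arange(1, x.shape[0] + 1), mean_profile)
    return pd.DataFrame(out, index=x.index, columns=x.columns)


def merge_cohorts(
    a: pd.DataFrame,
    b: pd.DataFrame,
    normalize: bool = True,
) -> pd.DataFrame:
    """Join two gene-level log2 matrices on their gene intersection.

    Each dataset is quantile normalized on the shared genes before the
    join (configurable off); no explicit batch correction is applied.
    """
    shared = a.index.intersection(b.index)
    if len(shared) == 0:
        raise ValueError("gene intersection of the two matrices is empty")
    left, right = a.loc[shared], b.loc[shared]
    if normalize:
        left, right = quantile_normalize(left), quantile_normalize(right)
    clash = right.columns.intersection(left.columns)
    if len(clash) > 0:
        warnings.warn(f"sample ids shared across cohorts were suffixed: {list(clash)}")
        right = right.rename(columns={c: f"{c}_b" for c in clash})
    return pd.concat([left, right], axis=1)


def write_matrix(x: pd.DataFrame, path) -> None:
    """Genes-in-rows TSV with a header row of sample ids."""
    x.to_csv(path, sep="\t", index_label="gene")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
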