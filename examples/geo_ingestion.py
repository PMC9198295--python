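"""Parsing, labeling and merging GEO-style series-matrix cohorts.

Writes two miniature series-matrix files (the flat format GEO serves for
expression arrays), parses them, assigns tumor/normal groups from the
free-text sample metadata, collapses probes to gene symbols, and merges
the cohorts on their gene intersection with per-dataset quantile
normalization.
"""

import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

import blcanet as b
from blcanet.geo import read_annotation


def write_series(path: Path, accession: str, groups: list[str], probes: dict) -> None:
    q = lambda v: f'"{v}"'
    sample_ids = [f"GSM{accession[3:]}{i:02d}" for i in range(1, len(groups) + 1)]
    lines = [
        f"!Series_geo_accession\t{q(accession)}",
        f"!Series_platform_id\t{q('GPL570')}",
        "!Sample_geo_accession\t" + "\t".join(q(s) for s in sample_ids),
        "!Sample_source_name_ch1\t" + "\t".join(q(g) for g in groups),
        "!series_matrix_table_begin",
        '"ID_REF"\t' + "\t".join(q(s) for s in sample_ids),
        *("\t".join([q(p), *map(str, vals)]) for p, vals in probes.items()),
        "!series_matrix_table_end",
    ]
    path.write_text("\n".join(lines) + "\n")


rng = np.random.default_rng(0)
tmp = Path(tempfile.mkdtemp())
probes = lambda n: {f"p{i}": rng.normal(8, 1, n).round(3).tolist() for i in range(6)}
write_series(tmp / "a.txt", "GSE90001",
             ["bladder tumor"] * 2 + ["normal para-tumor tissue"] * 2, probes(4))
write_series(tmp / "b.txt", "GSE90002",
             ["bladder carcinoma"] * 3 + ["normal bladder"] * 2, probes(5))
annotation = pd.Series({f"p{i}": f"GENE{i % 4}" for i in range(6)})

merged_cohorts = []
all_labels = None
for name in ("a.txt", "b.txt"):
    sm = b.parse_series_matrix(tmp / name)
    labels = b.assign_labels(sm)
    genes = b.collapse_probes(sm, annotation)
    print(f"{sm.accession}: {sm.probe_table.shape[0]} probes x "
          f"{sm.probe_table.shape[1]} samples -> {genes.shape[0]} genes; "
          f"{len(labels.treatment_samples)} tumor / {len(labels.control_samples)} normal")
    merged_cohorts.append(genes)
    all_labels = labels if all_labels is None else all_labels.concat(labels)

train = b.merge_cohorts(*merged_cohorts)
print(f"merged train matrix: {train.shape[0]} genes x {train.shape[1]} samples")
# Probes sharing a symbol collapse to the probe with the highest mean
# expression; quantile normalization before the join aligns the two
# platforms' intensity distributions without explicit batch correction.
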