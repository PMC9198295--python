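import numpy as np
import pandas as pd
import pytest

from blcanet import CohortLabels, SyntheticExpressionSpec, generate_expression


def make_series_matrix_text(
    accession: str,
    sample_groups: list[str],
    probe_values: dict[str, list[float | None]],
    platform: str = "GPL570",
) -> str:
    """Build a minimal GEO series-matrix file as text.

    ``sample_groups`` holds free-text source descriptions (one per sample,
    e.g. "bladder tumor"); ``probe_values`` maps probe id to one value per
    sample, with None rendered as the literal ``null``.
    """
    n = len(sample_groups)
    sample_ids = [f"GSM{accession[3:]}{i:02d}" for i in range(1, n + 1)]
    q = lambda v: f'"{v}"'
    lines = [
        f"!Series_title\t{q('synthetic fixture series')}",
        f"!Series_geo_accession\t{q(accession)}",
        f"!Series_platform_id\t{q(platform)}",
        "!Sample_geo_accession\t" + "\t".join(q(s) for s in sample_ids),
        "!Sample_source_name_ch1\t" + "\t".join(q(g) for g in sample_groups),
        "!Sample_characteristics_ch1\t" + "\t".join(q(f"tissue: {g}") for g in sample_groups),
        "!series_matrix_table_begin",
        '"ID_REF"\t' + "\t".join(q(s) for s in sample_ids),
    ]
    for probe, vals in probe_values.items():
        cells = ["null" if v is None else repr(float(v)) for v in vals]
        lines.append("\t".join([q(probe), *cells]))
    lines.append("!series_matrix_table_end")
    return "\n".join(lines) + "\n"


@pytest.fixture
def tiny_series_file(tmp_path):
    """3 probes x 2 samples fixture file."""
    text = make_series_matrix_text(
        "GSE00001",
        ["bladder tumor", "normal bladder"],
        {"p1": [1.0, 2.0], "p2": [3.0, 4.0], "p3": [5.0, 6.0]},
    )
    path = tmp_path / "series.txt"
    path.write_text(text)
    return path


@pytest.fixture
def planted_cohort():
    """1000-gene, 6+10 cohort with 25 up / 25 down planted genes."""
    spec = SyntheticExpressionSpec(
        n_genes=1000, n_control=6, n_treatment=10, n_de_up=25, n_de_down=25, seed=7
    )
    return generate_expression(spec)


@pytest.fixture
def two_group_labels():
    def _make(n_control: int, n_treatment: int, role: str = "train") -> CohortLabels:
        samples = [f"c{i}" for i in range(n_control)] + [f"t{i}" for i in range(n_treatment)]
        groups = pd.Series(
            ["control"] * n_control + ["treatment"] * n_treatment, index=samples
        )
        return CohortLabels(groups, role=role)

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
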