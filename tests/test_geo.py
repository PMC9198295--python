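import numpy as np
import pandas as pd
import pytest

from blcanet import (
    assign_labels,
    collapse_probes,
    merge_cohorts,
    parse_series_matrix,
    quantile_normalize,
)
from blcanet.geo import LabelRule, SeriesMatrix, read_matrix, write_matrix

from conftest import make_series_matrix_text


def _write(tmp_path, text, name="series.txt"):
    path = tmp_path / name
    path.write_text(text)
    return path


class TestParser:
    def test_minimal_fixture_shape_and_values(self, tiny_series_file):
        sm = parse_series_matrix(tiny_series_file)
        assert sm.probe_table.shape == (3, 2)
        assert sm.accession == "GSE00001"
        np.testing.assert_allclose(
            sm.probe_table.values, [[1, 2], [3, 4], [5, 6]]
        )

    def test_missing_cell_becomes_nan(self, tmp_path):
        text = make_series_matrix_text(
            "GSE00002", ["tumor", "normal"], {"p1": [1.0, None], "p2": [2.0, 3.0]}
        )
        sm = parse_series_matrix(_write(tmp_path, text))
        assert int(sm.probe_table.isna().sum().sum()) == 1

    def test_absent_table_delimiters_error(self, tmp_path):
        text = make_series_matrix_text("GSE00003", ["tumor"], {"p1": [1.0]})
        broken = text.replace("!series_matrix_table_begin\n", "")
        with pytest.raises(ValueError, match="table_begin"):
            parse_series_matrix(_write(tmp_path, broken))
        broken = text.replace("!series_matrix_table_end\n", "")
        with pytest.raises(ValueError, match="table_end"):
            parse_series_matrix(_write(tmp_path, broken))

    def test_non_numeric_cell_names_probe_and_sample(self, tmp_path):
        text = make_series_matrix_text("GSE00004", ["tumor", "normal"], {"p1": [1.0, 2.0]})
        broken = text.replace("2.0", "oops")
        with pytest.raises(ValueError, match="p1"):
            parse_series_matrix(_write(tmp_path, broken))

    def test_round_trip_of_written_fixture(self, tmp_path):
        values = {"pA": [1.25, -2.5, 3.0], "pB": [0.0, 7.75, 8.5]}
        text = make_series_matrix_text("GSE00005", ["tumor", "normal", "tumor"], values)
        sm = parse_series_matrix(_write(tmp_path, text))
        np.testing.assert_array_equal(sm.probe_table.values, pd.DataFrame(values).T.values)

    def test_gzip_input_supported(self, tmp_path):
        import gzip

        text = make_series_matrix_text("GSE00006", ["tumor", "normal"], {"p1": [1.0, 2.0]})
        path = tmp_path / "series.txt.gz"
        path.write_bytes(gzip.compress(text.encode()))
        sm = parse_series_matrix(path)
        assert sm.probe_table.shape == (1, 2)


class TestLabels:
    def test_default_rule_maps_cancer_and_normal(self, tmp_path):
        text = make_series_matrix_text(
            "GSE00007", ["bladder cancer", "normal bladder"], {"p1": [1.0, 2.0]}
        )
        labels = assign_labels(parse_series_matrix(_write(tmp_path, text)))
        assert list(labels.groups.values) == ["treatment", "control"]

    def test_ambiguous_metadata_raises(self, tmp_path):
        # "cancer" and "normal" match with equal specificity: unresolvable
        text = make_series_matrix_text(
            "GSE00008", ["cancer or normal, unclear", "tumor"], {"p1": [1.0, 2.0]}
        )
        with pytest.raises(ValueError, match="both"):
            assign_labels(parse_series_matrix(_write(tmp_path, text)))

    def test_para_tumor_specificity_resolves_to_control(self, tmp_path):
        text = make_series_matrix_text(
            "GSE00011", ["bladder tumor", "normal para-tumor tissue"], {"p1": [1.0, 2.0]}
        )
        labels = assign_labels(parse_series_matrix(_write(tmp_path, text)))
        assert list(labels.groups.values) == ["treatment", "control"]

    def test_missing_group_raises_with_values_seen(self, tmp_path):
        text = make_series_matrix_text("GSE00009", ["tumor", "tumor"], {"p1": [1.0, 2.0]})
        with pytest.raises(ValueError, match="control"):
            assign_labels(parse_series_matrix(_write(tmp_path, text)))

    def test_unmatched_samples_excluded_with_warning(self, tmp_path):
        text = make_series_matrix_text(
            "GSE00010", ["tumor", "normal", "mystery tissue"], {"p1": [1.0, 2.0, 3.0]}
        )
        with pytest.warns(UserWarning, match="excluded"):
            labels = assign_labels(parse_series_matrix(_write(tmp_path, text)))
        assert len(labels.sample_ids) == 2


class TestCollapseProbes:
    def _sm(self, table: pd.DataFrame) -> SeriesMatrix:
        return SeriesMatrix(
            accession="GSEx", platform="GPLx",
            sample_ids=list(table.columns),
            sample_metadata={}, probe_table=table,
        )

    def test_max_mean_probe_wins(self):
        table = pd.DataFrame(
            {"s1": [4.0, 6.0], "s2": [6.0, 8.0]}, index=["probe_lo", "probe_hi"]
        )  # means 5.0 and 7.0
        ann = pd.Series({"probe_lo": "GENE1", "probe_hi": "GENE1"})
        out = collapse_probes(self._sm(table), ann)
        np.testing.assert_allclose(out.loc["GENE1"].values, [6.0, 8.0])

    def test_linear_scale_matrix_is_log2_transformed(self):
        table = pd.DataFrame({"s1": [20000.0, 10.0], "s2": [15000.0, 12.0]},
                             index=["p1", "p2"])
        ann = pd.Series({"p1": "A", "p2": "B"})
        out = collapse_probes(self._sm(table), ann)
        assert out.values.max() == pytest.approx(np.log2(20001.0))
        assert out.values.max() < 15

    def test_log_scale_matrix_left_untouched(self):
        table = pd.DataFrame({"s1": [8.0, 9.0], "s2": [7.0, 10.0]}, index=["p1", "p2"])
        ann = pd.Series({"p1": "A", "p2": "B"})
        out = collapse_probes(self._sm(table), ann)
        np.testing.assert_allclose(np.sort(out.values, axis=0), np.sort(table.values, axis=0))

    def test_annotation_missing_all_probes_errors(self):
        table = pd.DataFrame({"s1": [1.0]}, index=["p1"])
        with pytest.raises(ValueError, match="none of the probes"):
            collapse_probes(self._sm(table), pd.Series({"other": "G"}))

    def test_output_gene_ids_unique(self, rng):
        table = pd.DataFrame(
            rng.normal(8, 1, size=(6, 3)),
            index=[f"p{i}" for i in range(6)],
            columns=["s1", "s2", "s3"],
        )
        ann = pd.Series({f"p{i}": f"G{i % 3}" for i in range(6)})
        out = collapse_probes(self._sm(table), ann)
        assert out.index.is_unique
        assert len(out) == 3


class TestMerge:
    def _mat(self, genes, n_samples, rng, prefix):
        return pd.DataFrame(
            rng.normal(8, 1, size=(len(genes), n_samples)),
            index=genes,
            columns=[f"{prefix}{i}" for i in range(n_samples)],
        )

    def test_intersection_join(self, rng):
        a = self._mat([f"G{i}" for i in range(15)], 4, rng, "a")
        b = self._mat([f"G{i}" for i in range(5, 20)], 3, rng, "b")
        merged = merge_cohorts(a, b)
        assert len(merged) == 10
        assert merged.shape[1] == 7

    def test_self_merge_doubles_samples(self, rng):
        a = self._mat([f"G{i}" for i in range(8)], 3, rng, "a")
        with pytest.warns(UserWarning, match="suffixed"):
            merged = merge_cohorts(a, a)
        assert set(merged.index) == set(a.index)
        assert merged.shape[1] == 6

    def test_merge_symmetric_in_gene_content(self, rng):
        a = self._mat([f"G{i}" for i in range(12)], 3, rng, "a")
        b = self._mat([f"G{i}" for i in range(6, 18)], 4, rng, "b")
        assert set(merge_cohorts(a, b).index) == set(merge_cohorts(b, a).index)

    def test_empty_intersection_errors(self, rng):
        a = self._mat(["G1"], 2, rng, "a")
        b = self._mat(["H1"], 2, rng, "b")
        with pytest.raises(ValueError, match="empty"):
            merge_cohorts(a, b)

    def test_quantile_normalization_aligns_sample_distributions(self, rng):
        x = pd.DataFrame(rng.normal(8, 2, size=(100, 4)),
                         index=[f"G{i}" for i in range(100)],
                         columns=list("abcd"))
        qn = quantile_normalize(x)
        ref = np.sort(qn.values[:, 0])
        for j in range(1, 4):
            np.testing.assert_allclose(np.sort(qn.values[:, j]), ref, atol=1e-9)

    def test_matrix_tsv_round_trip(self, tmp_path, rng):
        x = self._mat([f"G{i}" for i in range(5)], 3, rng, "s")
        write_matrix(x, tmp_path / "m.tsv")
        back = read_matrix(tmp_path / "m.tsv")
        np.testing.assert_allclose(back.values, x.values)
        assert list(back.index) == list(x.index)
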