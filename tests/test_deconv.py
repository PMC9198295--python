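import numpy as np
import pandas as pd
import pytest
from itertools import combinations
from scipy import stats

from blcanet import (
    CohortLabels,
    SyntheticMixtureSpec,
    deconvolve,
    fraction_correlations,
    generate_mixtures,
    group_contrast,
    permutation_p,
    rank_sum_test,
    run_deconvolution,
)
from blcanet.deconv import DeconvResult


@pytest.fixture
def noiseless():
    spec = SyntheticMixtureSpec(
        n_marker_genes=100, n_cell_types=4, n_mixtures=12, noise_sd=0.0, seed=1
    )
    return generate_mixtures(spec)


class TestDeconvolve:
    def test_pure_sample_recovers_unit_fraction(self, noiseless):
        sig, _, _ = noiseless
        bulk = pd.DataFrame({"pure": sig.iloc[:, 2]}, index=sig.index)
        fracs = deconvolve(bulk, sig)
        assert fracs.iloc[0, 2] == pytest.approx(1.0, abs=1e-9)
        assert fracs.iloc[0].drop(sig.columns[2]).abs().max() < 1e-9

    def test_noiseless_mixtures_recovered_exactly(self, noiseless):
        sig, bulk, truth = noiseless
        fracs = deconvolve(bulk, sig)
        assert np.abs(fracs.values - truth.values).max() < 1e-6

    def test_fractions_are_simplex_points(self, noiseless):
        sig, bulk, _ = noiseless
        fracs = deconvolve(bulk, sig)
        assert (fracs.values >= 0).all()
        np.testing.assert_allclose(fracs.sum(axis=1).values, 1.0, atol=1e-9)

    def test_scale_invariance_of_bulk_column(self, noiseless):
        sig, bulk, _ = noiseless
        scaled = bulk * 37.5
        np.testing.assert_allclose(
            deconvolve(bulk, sig).values, deconvolve(scaled, sig).values, atol=1e-8
        )

    def test_insufficient_shared_genes_rejected(self, noiseless):
        sig, bulk, _ = noiseless
        tiny = bulk.iloc[:2]
        with pytest.raises(ValueError, match="shared"):
            deconvolve(tiny, sig)

    def test_all_zero_bulk_column_rejected(self, noiseless):
        sig, bulk, _ = noiseless
        bulk = bulk.copy()
        bulk.iloc[:, 0] = 0.0
        with pytest.raises(ValueError, match="zero"):
            deconvolve(bulk, sig)


class TestPermutationP:
    def test_pure_signature_column_attains_minimum_p(self, noiseless):
        sig, _, _ = noiseless
        p = permutation_p(sig.iloc[:, 0], sig, n_perm=100, seed=2)
        assert p == pytest.approx(1 / 101)

    def test_small_n_perm_rejected(self, noiseless):
        sig, _, _ = noiseless
        with pytest.raises(ValueError, match="n_perm"):
            permutation_p(sig.iloc[:, 0], sig, n_perm=5)

    def test_seeded_reproducibility(self, noiseless):
        sig, bulk, _ = noiseless
        p1 = permutation_p(bulk.iloc[:, 0], sig, n_perm=50, seed=3)
        p2 = permutation_p(bulk.iloc[:, 0], sig, n_perm=50, seed=3)
        assert p1 == p2

    def test_noise_bulk_rarely_significant(self, rng):
        sig, _, _ = generate_mixtures(
            SyntheticMixtureSpec(n_marker_genes=60, n_cell_types=3, seed=4)
        )
        hits = 0
        n = 30
        for i in range(n):
            noise = pd.Series(rng.uniform(0, 30, size=60), index=sig.index)
            if permutation_p(noise, sig, n_perm=50, seed=i) < 0.05:
                hits += 1
        assert hits / n <= 0.15


class TestRankSum:
    def test_extreme_separation_exact_p(self):
        assert rank_sum_test([1, 2, 3], [10, 11, 12]) == pytest.approx(0.1)

    def test_identical_tied_groups_give_unit_p(self):
        assert rank_sum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0

    def test_exact_agrees_with_reference_for_all_small_splits(self, rng):
        """For every split (n1, n2) with n <= 8 on tie-free data, the
        enumerated p matches scipy's exact Mann-Whitney p."""
        for n1, n2 in [(a, b) for a in range(2, 7) for b in range(2, 7) if a + b <= 8]:
            for rep in range(3):
                vals = rng.normal(size=n1 + n2)
                a, b = vals[:n1], vals[n1:]
                ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
                assert rank_sum_test(a, b) == pytest.approx(ref.pvalue, abs=1e-12)

    def test_large_samples_use_tie_corrected_normal_approximation(self, rng):
        a = rng.normal(0, 1, 15)
        b = rng.normal(1, 1, 12)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert rank_sum_test(a, b) == pytest.approx(ref.pvalue)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])


class TestSummaries:
    def _result(self, fracs: pd.DataFrame) -> DeconvResult:
        p = pd.Series(0.01, index=fracs.index)
        return DeconvResult(fractions=fracs, p_perm=p, retained=p < 0.05)

    def test_identical_rankings_give_unit_rho(self, rng):
        base = rng.uniform(size=10)
        fracs = pd.DataFrame({"t1": base, "t2": base * 0.5, "t3": rng.uniform(size=10)},
                             index=[f"s{i}" for i in range(10)])
        corr = fraction_correlations(self._result(fracs))
        assert corr.loc["t1", "t2"] == pytest.approx(1.0)
        assert (np.diag(corr.values) == 1.0).all()

    def test_complementary_pair_fully_anticorrelated(self, rng):
        a = rng.uniform(size=12)
        fracs = pd.DataFrame({"t1": a, "t2": 1 - a}, index=[f"s{i}" for i in range(12)])
        corr = fraction_correlations(self._result(fracs))
        assert corr.loc["t1", "t2"] == pytest.approx(-1.0)

    def test_independent_fractions_weakly_correlated(self, rng):
        fracs = pd.DataFrame(rng.uniform(size=(200, 2)), columns=["t1", "t2"],
                             index=[f"s{i}" for i in range(200)])
        corr = fraction_correlations(self._result(fracs))
        assert abs(corr.loc["t1", "t2"]) < 0.2

    def test_too_few_retained_samples_rejected(self, rng):
        fracs = pd.DataFrame(rng.uniform(size=(2, 2)), columns=["t1", "t2"],
                             index=["s0", "s1"])
        with pytest.raises(ValueError, match="retained"):
            fraction_correlations(self._result(fracs))

    def test_planted_shift_attains_smallest_contrast_p(self):
        """A cell type shifted upward in the treatment arm wins the
        contrast in nearly all seeded runs."""
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            fracs = pd.DataFrame(
                rng.dirichlet(np.ones(4), size=20),
                columns=[f"t{i}" for i in range(4)],
                index=[f"s{i}" for i in range(20)],
            )
            groups = pd.Series(["control"] * 10 + ["treatment"] * 10, index=fracs.index)
            fracs.loc[groups == "treatment", "t0"] += 0.5
            fracs = fracs.div(fracs.sum(axis=1), axis=0)
            res = self._result(fracs)
            table = group_contrast(res, CohortLabels(groups))
            if table["p"].idxmin() == "t0" and table.loc["t0", "direction"] == "up":
                wins += 1
        assert wins >= 18

    def test_group_contrast_requires_two_per_group(self, rng):
        fracs = pd.DataFrame(rng.uniform(size=(3, 2)), columns=["t1", "t2"],
                             index=["s0", "s1", "s2"])
        groups = pd.Series(["control", "treatment", "treatment"], index=fracs.index)
        with pytest.raises(ValueError, match=">=2 retained"):
            group_contrast(self._result(fracs), CohortLabels(groups))


class TestRunDeconvolution:
    def test_noisy_recovery_and_retention(self):
        spec = SyntheticMixtureSpec(
            n_marker_genes=150, n_cell_types=5, n_mixtures=15, noise_sd=0.1, seed=6
        )
        sig, bulk, truth = generate_mixtures(spec)
        res = run_deconvolution(bulk, sig, n_perm=50, seed=6)
        assert res.retained.all()  # real mixtures fit far better than chance
        mae = np.abs(res.fractions.values - truth.values).mean()
        assert mae < 0.05
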