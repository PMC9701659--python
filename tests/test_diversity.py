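import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from ecometab.diversity import (
    bootstrap_ci,
    chao1_abundance,
    indices,
    inverse_simpson,
    pielou,
    rarefaction,
    richness_estimators,
    sample_indices,
    shannon,
    species_accumulation,
)
from ecometab.feature_io import IncidenceMatrix


class TestIndices:
    def test_shannon_uniform_is_log_s(self):
        assert shannon([0.25] * 4) == pytest.approx(np.log(4))

    def test_shannon_single_species_zero(self):
        assert shannon([1, 0, 0]) == 0.0

    def test_shannon_derived_value(self):
        # -sum p ln p with p = (0.4, 0.4, 0.2)
        p = np.array([0.4, 0.4, 0.2])
        expected = float(-(p * np.log(p)).sum())
        assert shannon([4, 4, 2]) == pytest.approx(expected)
        assert shannon([4, 4, 2]) == pytest.approx(1.0549, abs=1e-4)

    def test_inverse_simpson_uniform(self):
        assert inverse_simpson([0.1] * 10) == pytest.approx(10.0)
        assert inverse_simpson([1, 0]) == pytest.approx(1.0)

    def test_inverse_simpson_derived(self):
        assert inverse_simpson([0.5, 0.3, 0.2]) == pytest.approx(1 / 0.38)
        assert inverse_simpson([0.5, 0.3, 0.2]) == pytest.approx(2.6316, abs=1e-4)

    def test_pielou_uniform_is_one(self):
        for S in (2, 5, 17):
            assert pielou([1.0] * S) == pytest.approx(1.0)

    def test_pielou_derived(self):
        p = np.array([0.97, 0.01, 0.01, 0.01])
        expected = float(-(p * np.log(p)).sum() / np.log(4))
        assert pielou(p) == pytest.approx(expected)
        assert pielou(p) == pytest.approx(0.1210, abs=1e-3)

    def test_pielou_single_species_signals(self):
        with pytest.raises(ValueError, match="single species"):
            pielou([1, 0])

    def test_all_zero_rejected(self):
        for fn in (shannon, inverse_simpson):
            with pytest.raises(ValueError, match="all-zero"):
                fn([0.0, 0.0])

    @given(st.permutations(list(range(6))))
    def test_permutation_invariance(self, perm):
        base = np.array([5.0, 3.0, 2.0, 1.0, 1.0, 0.5])
        shuffled = base[list(perm)]
        assert shannon(shuffled) == pytest.approx(shannon(base))
        assert inverse_simpson(shuffled) == pytest.approx(inverse_simpson(base))
        assert pielou(shuffled) == pytest.approx(pielou(base))

    def test_invariants_h_le_lns_dsi_le_s(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            p = rng.lognormal(0, 1.5, size=rng.integers(2, 30))
            ix = indices(p)
            assert ix.H <= np.log(ix.S) + 1e-12
            assert ix.DSi <= ix.S + 1e-9
            assert 0 <= ix.J <= 1 + 1e-12

    def test_sample_indices_table(self, small_fm):
        tab = sample_indices(small_fm)
        assert set(["S", "H", "DSi", "J", "concentration"]) <= set(tab.columns)
        assert tab.loc["C27_T0_R1", "S"] == 4


class TestRichnessEstimators:
    def test_fixture_values(self, small_incidence):
        est = richness_estimators(small_incidence)
        assert est["S"] == 10 and est["Q1"] == 4 and est["Q2"] == 2
        assert est["jack1"] == pytest.approx(13.2)
        # chao = S + ((n-1)/n) Q1^2 / (2 Q2) = 10 + 0.8*16/4
        assert est["chao"] == pytest.approx(13.2)
        jack2 = 10 + 4 * (2 * 5 - 3) / 5 - 2 * (5 - 2) ** 2 / (5 * 4)
        assert est["jack2"] == pytest.approx(jack2)

    def test_no_uniques_collapses_to_s(self):
        presence = pd.DataFrame(np.ones((4, 7), dtype=np.int8))
        est = richness_estimators(IncidenceMatrix(presence=presence))
        assert est["Q1"] == est["Q2"] == 0
        assert est["chao"] == est["jack1"] == pytest.approx(7)
        assert est["jack2"] == pytest.approx(7)

    def test_estimators_bounded_below_by_s(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            presence = pd.DataFrame(
                (rng.random((rng.integers(2, 8), rng.integers(3, 20))) < 0.4).astype(np.int8)
            )
            est = richness_estimators(IncidenceMatrix(presence=presence))
            assert est["chao"] >= est["S"] - 1e-9
            assert est["jack1"] >= est["S"] - 1e-9

    def test_single_unit_rejected(self):
        presence = pd.DataFrame([[1, 0, 1]])
        with pytest.raises(ValueError, match=">= 2 units"):
            richness_estimators(IncidenceMatrix(presence=presence))

    def test_abundance_chao1(self):
        # f1=2 singletons, f2=1 doubleton, S=4
        assert chao1_abundance([1, 1, 2, 9]) == pytest.approx(4 + 4 / 2)


class TestSpeciesAccumulation:
    def test_identical_units_flat_curve(self):
        presence = pd.DataFrame(np.tile([1, 1, 0, 1, 0], (6, 1)))
        sac = species_accumulation(IncidenceMatrix(presence=presence), n_perm=30, seed=0)
        np.testing.assert_allclose(sac.mean_richness, 3.0)
        np.testing.assert_allclose(sac.sd, 0.0)

    def test_k1_mean_equals_average_unit_richness(self, small_incidence):
        sac = species_accumulation(small_incidence, n_perm=2000, seed=1)
        expected = small_incidence.unit_richness.mean()
        assert sac.mean_richness[0] == pytest.approx(expected, rel=0.02)

    def test_disjoint_sets_linear_curve(self):
        presence = pd.DataFrame(np.kron(np.eye(4, dtype=np.int8), np.ones((1, 3), dtype=np.int8)))
        sac = species_accumulation(IncidenceMatrix(presence=presence), n_perm=20, seed=0)
        np.testing.assert_allclose(sac.mean_richness, 3 * np.arange(1, 5))

    def test_monotone_and_terminal_identity(self, small_incidence):
        sac = species_accumulation(small_incidence, n_perm=50, seed=3)
        assert (np.diff(sac.mean_richness) >= -1e-12).all()
        assert sac.mean_richness[-1] == 10


class TestRarefaction:
    def test_boundary_values(self, small_incidence):
        n = small_incidence.n_units
        assert rarefaction(small_incidence, n) == pytest.approx(10.0)
        assert rarefaction(small_incidence, 1) == pytest.approx(
            small_incidence.unit_richness.mean()
        )

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(4)
        presence = (rng.random((6, 9)) < 0.5).astype(np.int8)
        im = IncidenceMatrix(presence=pd.DataFrame(presence))
        for k in range(1, 7):
            brute = np.mean(
                [
                    (presence[list(sub)].max(axis=0) > 0).sum()
                    for sub in itertools.combinations(range(6), k)
                ]
            )
            assert rarefaction(im, k) == pytest.approx(brute)

    def test_matches_sac_mean_at_high_permutations(self, small_incidence):
        sac = species_accumulation(small_incidence, n_perm=1000, seed=5)
        for i, k in enumerate(sac.k):
            expected = rarefaction(small_incidence, int(k))
            se = sac.sd[i] / np.sqrt(sac.n_perm) + 1e-9
            assert abs(sac.mean_richness[i] - expected) <= max(3 * se, 0.15)

    def test_out_of_range_rejected(self, small_incidence):
        with pytest.raises(ValueError):
            rarefaction(small_incidence, 0)
        with pytest.raises(ValueError):
            rarefaction(small_incidence, 6)


class TestBootstrap:
    def test_constant_data_zero_width(self):
        lo, hi = bootstrap_ci(lambda d: float(d.mean()), np.ones(10), B=100, seed=0)
        assert lo == hi == 1.0

    def test_interval_contains_mean_estimate(self):
        rng = np.random.default_rng(6)
        data = rng.normal(5, 1, size=40)
        lo, hi = bootstrap_ci(lambda d: float(d.mean()), data, B=200, seed=1)
        assert lo <= data.mean() <= hi

    def test_b_floor_enforced(self):
        with pytest.raises(ValueError, match="at least 50"):
            bootstrap_ci(lambda d: float(d.mean()), np.arange(10.0), B=10)

    def test_shannon_ci_coverage_on_lognormal_communities(self):
        # moderate simulation: CI over replicate resamples should cover the
        # pooled-population H' most of the time
        rng = np.random.default_rng(7)
        cover = 0
        n_trials = 50
        for t in range(n_trials):
            base = rng.lognormal(2, 1, size=60)
            reps = base * rng.lognormal(0, 0.3, size=(8, 60))
            from ecometab.diversity import shannon as H

            truth = H(base)
            lo, hi = bootstrap_ci(
                lambda d: H(d.sum(axis=0)), reps, B=150, seed=t
            )
            cover += lo - 0.05 <= truth <= hi + 0.05
        assert cover / n_trials >= 0.9
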