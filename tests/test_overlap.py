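"""Hypergeometric overlap, bootstrap intersections, battery, proportions."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ahrcore import (
    AlignedResults,
    all_pairwise,
    bootstrap_multiset_overlap,
    chromosome_bias,
    core_battery,
    direction_consistency_test,
    enrichment_ratio,
    pairwise_overlap,
)
from ahrcore.overlap import adjust_pairwise

from conftest import bh_oracle, hypergeom_tail_oracle


class TestPairwiseOverlap:
    def test_reported_rat_tissue_pair_arithmetic(self):
        """|A|=1187, |B|=316, N=10445, 98 shared: expected ~36, ratio 2.7."""
        a = set(range(1187))
        b = set(range(98)) | set(range(5000, 5000 + 218))
        res = pairwise_overlap(a, b, 10445)
        assert res.observed == 98
        assert round(res.expected) == 36
        assert round(res.ratio, 1) == 2.7

    def test_disjoint_sets(self):
        res = pairwise_overlap({1, 2}, {3, 4}, 10)
        assert res.observed == 0
        assert res.ratio == 0.0
        assert res.p == pytest.approx(1.0)

    def test_small_case_against_enumeration(self):
        # N=10, |A|=4, |B|=5, all of B's overlap in A: P[X>=4] = 6/252
        a = set(range(4))
        b = set(range(4)) | {9}
        res = pairwise_overlap(a, b, 10)
        assert res.p == pytest.approx(6 / 252)

    def test_exhaustive_enumeration_all_small_universes(self):
        """Closed-form tail equals combinatorial enumeration for all N <= 12."""
        for n in range(1, 13):
            for size_a in range(n + 1):
                for size_b in range(n + 1):
                    for obs in range(min(size_a, size_b) + 1):
                        got = float(stats.hypergeom.sf(obs - 1, n, size_a, size_b))
                        want = hypergeom_tail_oracle(n, size_a, size_b, obs)
                        assert got == pytest.approx(want, abs=1e-12), (
                            n, size_a, size_b, obs
                        )

    def test_ratio_symmetric_in_set_order(self, rng):
        a = set(rng.choice(200, 40, replace=False))
        b = set(rng.choice(200, 70, replace=False))
        r1 = pairwise_overlap(a, b, 200)
        r2 = pairwise_overlap(b, a, 200)
        assert r1.ratio == pytest.approx(r2.ratio)
        assert r1.p == pytest.approx(r2.p)

    def test_zero_universe_rejected(self):
        with pytest.raises(ValueError):
            pairwise_overlap({1}, {1}, 0)


class TestAdjustPairwise:
    def test_single_pair_q_equals_p(self):
        res = pairwise_overlap({1, 2, 3}, {2, 3, 4}, 20)
        table = adjust_pairwise([res])
        assert table["q"].iloc[0] == pytest.approx(table["p"].iloc[0])

    def test_family_matches_bh_oracle(self, rng):
        sets = {
            f"s{i}": set(rng.choice(300, rng.integers(20, 80), replace=False))
            for i in range(5)
        }
        table = all_pairwise(sets, 300)
        assert len(table) == 10  # all pairs of 5 studies
        assert table["q"].to_numpy() == pytest.approx(bh_oracle(table["p"]))


class TestBootstrap:
    def test_all_sets_equal_universe(self):
        res = bootstrap_multiset_overlap([6, 6, 6], 6, observed=6, reps=100, seed=0)
        assert res.exceed_count == 0  # counts can never exceed N
        assert res.perm_mean == 6.0

    def test_permutation_mean_matches_independence_product(self):
        sizes, n = (3, 3, 3), 6
        res = bootstrap_multiset_overlap(sizes, n, observed=2, reps=40000, seed=1)
        expect = n * math.prod(s / n for s in sizes)  # 0.75
        mc_se = math.sqrt(res.perm_var / res.reps)
        assert abs(res.perm_mean - expect) < 4 * mc_se

    def test_composition_and_direct_sampling_agree_in_distribution(self):
        sizes, n, reps = (40, 50, 60), 120, 10000
        comp = bootstrap_multiset_overlap(
            sizes, n, observed=10, reps=reps, seed=11, method="composition"
        )
        direct = bootstrap_multiset_overlap(
            sizes, n, observed=10, reps=reps, seed=12, method="direct"
        )
        # reconstruct count samples indirectly via mean/var closeness and a KS
        # test on fresh draws from each path
        rng1 = np.random.default_rng(13)
        rng2 = np.random.default_rng(14)
        from ahrcore.overlap import _compose_counts, _direct_counts

        c1 = _compose_counts(sizes, n, reps, rng1)
        c2 = _direct_counts(sizes, n, reps, rng2)
        assert stats.ks_2samp(c1, c2).pvalue > 0.01
        assert comp.perm_mean == pytest.approx(direct.perm_mean, rel=0.05)

    def test_strict_rule_vs_pseudocount_rule(self):
        res = bootstrap_multiset_overlap([5, 5], 100, observed=5, reps=2000, seed=3)
        assert res.exceed_count == 0  # count can never exceed min size 5
        assert res.p_estimate == 0.0
        assert res.p_upper_bound == pytest.approx(1 / 2000)
        assert res.p_report.startswith("<")
        assert res.p_pseudocount >= 1 / 2001

    def test_oversized_set_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_multiset_overlap([10, 3], 5, observed=1, reps=10)


class TestChromosomeBias:
    def test_concentrated_significant_set_minimizes_p(self):
        universe = [f"g{i}" for i in range(100)]
        chrom = {g: f"chr{i % 5}" for i, g in enumerate(universe)}
        sig = [g for i, g in enumerate(universe) if i % 5 == 2][:10]
        table = chromosome_bias(sig, chrom, universe)
        best = table.loc[table["p"].idxmin(), "chrom"]
        assert best == "chr2"

    def test_two_chromosome_toy_enumeration(self):
        # N=10, 5 genes on chr1, all 4 significant genes on chr1:
        # P[X>=4] = C(5,4)C(5,0)/C(10,4) = 5/210
        universe = [f"g{i}" for i in range(10)]
        chrom = {g: ("chr1" if i < 5 else "chr2") for i, g in enumerate(universe)}
        table = chromosome_bias(universe[:4], chrom, universe)
        p_chr1 = table.set_index("chrom").loc["chr1", "p"]
        assert p_chr1 == pytest.approx(5 / 210)

    def test_null_calibration_family_error(self, rng):
        """Across null simulations, any-adjusted-p<0.05 occurs rarely."""
        universe = [f"g{i}" for i in range(400)]
        chrom = {g: f"chr{i % 10}" for i, g in enumerate(universe)}
        hits = 0
        n_sim = 60
        for _ in range(n_sim):
            sig = rng.choice(universe, size=40, replace=False)
            table = chromosome_bias(sig, chrom, universe)
            hits += int((table["q"] < 0.05).any())
        # expected family rate <= 0.05; allow 3 binomial SE head-room
        bound = 0.05 + 3 * math.sqrt(0.05 * 0.95 / n_sim)
        assert hits / n_sim <= bound

    def test_uncovered_universe_rejected(self):
        with pytest.raises(ValueError, match="cover"):
            chromosome_bias({"g0"}, {"g0": "chr1"}, {"g0", "g1"})


def _aligned_from_effects(m_values: pd.DataFrame, q_values: pd.DataFrame,
                          species: dict[str, str]) -> AlignedResults:
    results = {
        key: pd.DataFrame(
            {"M": m_values[key], "q": q_values[key]},
            index=m_values.index,
        )
        for key in m_values.columns
    }
    return AlignedResults(
        universe=list(m_values.index), results=results, species=species
    )


class TestCoreBattery:
    species = {
        "mouse_kidney": "mouse", "mouse_liver": "mouse",
        "rat_liver": "rat", "rat_adipose": "rat", "rat_hypothalamus": "rat",
    }
    keys = list(species)

    def _toy(self, signs_by_key):
        hids = [1, 2, 3]
        m = pd.DataFrame(
            {k: [signs_by_key[k][h] for h in range(3)] for k in self.keys},
            index=hids,
        )
        q = pd.DataFrame(0.01, index=hids, columns=self.keys)
        return _aligned_from_effects(m, q, self.species)

    def test_uniform_positive_effects_classed_consistent(self):
        signs = {k: {0: 1.0, 1: 0.8, 2: 1.2} for k in self.keys}
        battery = core_battery(self._toy(signs), min_studies=4)
        assert set(battery.table["direction_class"]) == {"consistent"}
        assert len(battery.genes) == 3

    def test_species_sign_flip_classed_species_divergent(self):
        signs = {
            k: {0: (1.0 if sp == "rat" else -1.0), 1: 1.0, 2: 1.0}
            for k, sp in self.species.items()
        }
        battery = core_battery(self._toy(signs), min_studies=4)
        assert battery.table.loc[1, "direction_class"] == "species_divergent"
        assert battery.table.loc[2, "direction_class"] == "consistent"

    def test_within_species_flip_classed_tissue_variable(self):
        signs = {k: {0: 1.0, 1: 1.0, 2: 1.0} for k in self.keys}
        signs["rat_liver"] = {0: -1.0, 1: 1.0, 2: 1.0}
        signs["rat_adipose"] = {0: 1.0, 1: 1.0, 2: 1.0}
        battery = core_battery(self._toy(signs), min_studies=4)
        assert battery.table.loc[1, "direction_class"] == "tissue_variable"

    def test_ordering_by_decreasing_mean_abs_effect(self):
        signs = {k: {0: 0.5, 1: 2.0, 2: 1.0} for k in self.keys}
        battery = core_battery(self._toy(signs), min_studies=4)
        assert list(battery.table.index) == [2, 3, 1]

    def test_min_studies_threshold_applies(self):
        signs = {k: {0: 1.0, 1: 1.0, 2: 1.0} for k in self.keys}
        aligned = self._toy(signs)
        aligned.results["rat_liver"].loc[1, "q"] = 0.9
        aligned.results["mouse_liver"].loc[1, "q"] = 0.9
        battery = core_battery(aligned, min_studies=4)
        assert 1 not in battery.genes
        assert {2, 3} <= battery.genes

    def test_recovers_planted_battery_from_powered_simulation(self, small_data):
        """Strong planted effects: battery recovered against ground truth."""
        from ahrcore import align_studies, fit_study

        results = [fit_study(s) for s in small_data.studies]
        aligned = align_studies(results, small_data.homology)
        battery = core_battery(aligned, q_threshold=0.05, min_studies=4)
        truth_hids = small_data.truth.battery_hids() & set(aligned.universe)
        found = battery.genes
        tp = len(found & truth_hids)
        assert tp / len(truth_hids) >= 0.9
        assert (len(found) - tp) <= 0.1 * max(len(found), 1)


class TestDirectionConsistency:
    def test_all_ten_observations_one_direction(self):
        res = direction_consistency_test([1.0] * 10)
        assert res.p_exact == pytest.approx(2.0 ** -10)
        assert res.proportion == 1.0

    def test_five_of_ten(self):
        res = direction_consistency_test([1.0] * 5 + [-1.0] * 5)
        # exact one-sided binomial: P[X >= 5 | n=10, p=.5]
        want = sum(math.comb(10, k) for k in range(5, 11)) / 2 ** 10
        assert res.p_exact == pytest.approx(want)
        assert res.p_exact == pytest.approx(0.62, abs=0.01)

    def test_balanced_split_ci_covers_half(self, rng):
        signs = [1.0] * 50 + [-1.0] * 50
        res = direction_consistency_test(signs)
        assert res.ci[0] <= 0.5 <= res.ci[1]

    def test_chi_square_variant_tracks_exact(self):
        res = direction_consistency_test([1.0] * 18 + [-1.0] * 2)
        assert res.p_chisq == pytest.approx(res.p_exact, abs=0.01)

    def test_zero_observations_rejected(self):
        with pytest.raises(ValueError):
            direction_consistency_test([0.0, 0.0])


def test_enrichment_ratio_printed_values():
    assert round(enrichment_ratio(101, 44), 1) == 2.3
    assert round(enrichment_ratio(25, 0.27)) == 93
    assert enrichment_ratio(0, 5.0) == 0.0
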