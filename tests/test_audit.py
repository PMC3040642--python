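import math

import numpy as np
import pytest

from barcodeaudit.audit import (
    detect_deep_splits,
    detect_sharing,
    global_stats,
    histogram,
    low_divergence_pairs,
    max_intraspecific,
    nearest_neighbor,
    resolution_rate,
    run_audit,
)
from barcodeaudit.k2p import pairwise_matrix
from barcodeaudit.synthetic import SimConfig, simulate_library

from .oracles import mpd_bruteforce, nn_bruteforce


def _sym(entries, n):
    d = np.zeros((n, n))
    for (i, j), v in entries.items():
        d[i, j] = d[j, i] = v
    return d


class TestMaxIntraspecific:
    def test_two_identical_specimens_have_zero_mpd(self, matrix_builder):
        m = matrix_builder(["Ga a", "Ga a"], np.zeros((2, 2)))
        assert max_intraspecific(m) == {"Ga a": 0.0}

    def test_mpd_is_maximum_over_conspecific_pairs(self, matrix_builder):
        d = _sym({(0, 1): 0.001, (0, 2): 0.002, (1, 2): 0.045}, 3)
        m = matrix_builder(["Ga a"] * 3, d)
        assert max_intraspecific(m)["Ga a"] == pytest.approx(0.045)

    def test_singletons_omitted(self, matrix_builder):
        d = _sym({(0, 1): 0.1}, 2)
        m = matrix_builder(["Ga a", "Gb b"], d)
        assert max_intraspecific(m) == {}

    def test_all_missing_conspecific_pairs_warns_and_omits(self, matrix_builder):
        d = _sym({(0, 1): np.nan, (0, 2): 0.1, (1, 2): 0.1}, 3)
        m = matrix_builder(["Ga a", "Ga a", "Gb b"], d)
        with pytest.warns(UserWarning, match="Ga a"):
            assert max_intraspecific(m) == {}


class TestNearestNeighbor:
    def test_two_species_symmetric(self, matrix_builder):
        d = _sym({(0, 1): 0.011}, 2)
        m = matrix_builder(["Ga a", "Gb b"], d)
        assert nearest_neighbor(m) == {
            "Ga a": ("Gb b", pytest.approx(0.011)),
            "Gb b": ("Ga a", pytest.approx(0.011)),
        }

    def test_min_selection_over_three_species(self, matrix_builder):
        d = _sym({(0, 1): 0.02, (0, 2): 0.05, (1, 2): 0.03}, 3)
        m = matrix_builder(["A a", "B b", "C c"], d)
        nn = nearest_neighbor(m)
        assert nn["A a"] == ("B b", pytest.approx(0.02))
        assert nn["B b"] == ("A a", pytest.approx(0.02))
        assert nn["C c"] == ("B b", pytest.approx(0.03))

    def test_ties_broken_lexicographically(self, matrix_builder):
        d = _sym({(0, 1): 0.02, (0, 2): 0.02, (1, 2): 0.05}, 3)
        m = matrix_builder(["M m", "Z z", "A a"], d)
        assert nearest_neighbor(m)["M m"][0] == "A a"

    def test_species_minimum_over_specimen_pairs(self, matrix_builder):
        # two specimens each; NN distance is the min, not the mean
        d = _sym(
            {(0, 1): 0.001, (2, 3): 0.001,
             (0, 2): 0.03, (0, 3): 0.05, (1, 2): 0.02, (1, 3): 0.04},
            4,
        )
        m = matrix_builder(["Ga a", "Ga a", "Gb b", "Gb b"], d)
        assert nearest_neighbor(m)["Ga a"] == ("Gb b", pytest.approx(0.02))

    def test_matches_bruteforce_on_synthetic_library(self):
        lib, _ = simulate_library(
            SimConfig(n_species=12, specimens_per_species=3, n_deep_splits=2,
                      n_sharing_pairs=1, seed=3)
        )
        m = pairwise_matrix(lib)
        assert nearest_neighbor(m) == nn_bruteforce(m)
        assert max_intraspecific(m) == pytest.approx(mpd_bruteforce(m))


class TestGlobalStats:
    def test_single_comparison_has_flagged_zero_se(self, matrix_builder):
        d = _sym({(0, 1): 0.10}, 2)
        m = matrix_builder(["Ga a", "Gb b"], d)
        st_ = global_stats(m)["interspecific"]
        assert (st_.mean, st_.se, st_.n, st_.se_defined) == (0.10, 0.0, 1, False)

    def test_intraspecific_mean_and_deep_split_exclusion(self, matrix_builder):
        # species X: 3 specimens with pairwise {0, 0, 0.03}; species Y: 2 at 0.002
        d = _sym({(0, 1): 0.0, (0, 2): 0.0, (1, 2): 0.03, (3, 4): 0.002}, 5)
        m = matrix_builder(["X x"] * 3 + ["Y y"] * 2, d)
        st_ = global_stats(m, deep_split_species={"X x"})
        assert st_["intraspecific"].mean == pytest.approx(0.032 / 4)
        assert st_["intraspecific"].n == 4
        assert st_["intraspecific_excl_deep"].mean == pytest.approx(0.002)
        assert st_["intraspecific_excl_deep"].n == 1

    def test_congeneric_is_subset_of_interspecific(self, matrix_builder):
        d = _sym({(0, 1): 0.10, (0, 2): 0.13, (1, 2): 0.13}, 3)
        m = matrix_builder(["Ga a", "Ga b", "Gb c"], d)
        st_ = global_stats(m)
        assert st_["congeneric"].n == 1
        assert st_["congeneric"].mean == pytest.approx(0.10)
        assert st_["interspecific"].n == 3

    def test_empty_stratum_reported_undefined(self, matrix_builder):
        d = _sym({(0, 1): 0.1}, 2)
        m = matrix_builder(["Ga a", "Gb b"], d)
        st_ = global_stats(m)["intraspecific"]
        assert st_.n == 0 and math.isnan(st_.mean) and not st_.se_defined

    def test_strata_partition_all_defined_pairs(self):
        lib, _ = simulate_library(
            SimConfig(n_species=10, specimens_per_species=3, n_deep_splits=1,
                      n_sharing_pairs=1, seed=5)
        )
        m = pairwise_matrix(lib)
        st_ = global_stats(m)
        n = len(m)
        iu = np.triu_indices(n, 1)
        total_defined = int((~np.isnan(m.d[iu])).sum())
        assert st_["interspecific"].n + st_["intraspecific"].n == total_defined

    def test_excluding_deep_splits_moves_mean_toward_generated_target(self):
        cfg = SimConfig(n_species=30, specimens_per_species=3, n_deep_splits=3,
                        n_sharing_pairs=0, seed=9)
        lib, truth = simulate_library(cfg)
        m = pairwise_matrix(lib)
        st_ = global_stats(m, deep_split_species=set(truth.deep_splits))
        target = cfg.target_intraspecific_d
        assert abs(st_["intraspecific_excl_deep"].mean - target) < abs(
            st_["intraspecific"].mean - target
        )
        assert st_["intraspecific_excl_deep"].mean == pytest.approx(target, abs=0.002)


class TestDetectSharing:
    def test_planted_identical_haplotypes_reported(self, matrix_builder):
        d = _sym({(0, 1): 0.0, (0, 2): 0.1, (1, 2): 0.1}, 3)
        m = matrix_builder(["Ga a", "Gb b", "Gc c"], d)
        (pair,) = detect_sharing(m)
        assert (pair.species1, pair.species2) == ("Ga a", "Gb b")
        assert pair.specimen_pairs == (("s0", "s1"),)
        assert not pair.regular

    def test_no_zero_distances_gives_empty_list(self, matrix_builder):
        d = _sym({(0, 1): 0.01}, 2)
        assert detect_sharing(matrix_builder(["Ga a", "Gb b"], d)) == []

    def test_conspecific_zero_distances_ignored(self, matrix_builder):
        d = _sym({(0, 1): 0.0, (0, 2): 0.1, (1, 2): 0.1}, 3)
        m = matrix_builder(["Ga a", "Ga a", "Gb b"], d)
        assert detect_sharing(m) == []

    def test_multiple_pairs_aggregated_as_regular(self, matrix_builder):
        d = _sym({(0, 2): 0.0, (1, 3): 0.0, (0, 3): 0.0, (1, 2): 0.01}, 4)
        m = matrix_builder(["Ga a", "Ga a", "Gb b", "Gb b"], d)
        (pair,) = detect_sharing(m)
        assert pair.n_pairs == 3 and pair.regular

    def test_planted_pair_recovered_in_simulation(self):
        lib, truth = simulate_library(
            SimConfig(n_species=50, specimens_per_species=3, n_sharing_pairs=1,
                      n_deep_splits=0, seed=2)
        )
        found = detect_sharing(pairwise_matrix(lib))
        planted = {tuple(sorted(p[:2])) for p in truth.sharing_pairs}
        assert {(p.species1, p.species2) for p in found} == planted


class TestLowDivergencePairs:
    def test_window_is_left_open_right_closed(self, matrix_builder):
        d = _sym({(0, 1): 0.011, (0, 2): 0.04, (1, 2): 0.01}, 3)
        m = matrix_builder(["A a", "B b", "C c"], d)
        got = low_divergence_pairs(m, 0.01, 0.04)
        pairs = {(a, b): v for a, b, v in got}
        assert ("A a", "B b") in pairs  # 1.1% inside
        assert ("A a", "C c") in pairs  # exactly 4.0% included
        assert ("B b", "C c") not in pairs  # exactly 1.0% excluded

    def test_sorted_ascending_by_distance(self, matrix_builder):
        d = _sym({(0, 1): 0.027, (0, 2): 0.014, (1, 2): 0.05}, 3)
        m = matrix_builder(["A a", "B b", "C c"], d)
        assert [v for _, _, v in low_divergence_pairs(m, 0.01, 0.04)] == [
            pytest.approx(0.014),
            pytest.approx(0.027),
        ]

    def test_planted_pairs_recovered_and_window_respected(self):
        cfg = SimConfig(
            n_species=30, specimens_per_species=2, n_sharing_pairs=0,
            n_deep_splits=0, low_divergence_pairs=(0.014, 0.027, 0.05), seed=4,
        )
        lib, truth = simulate_library(cfg)
        m = pairwise_matrix(lib)
        got = {(a, b) for a, b, _ in low_divergence_pairs(m, 0.01, 0.04)}
        want = {tuple(sorted((a, b))) for a, b, d0 in truth.low_divergence if d0 <= 0.04}
        assert want <= got
        far = {tuple(sorted((a, b))) for a, b, d0 in truth.low_divergence if d0 > 0.045}
        assert not far & got

    def test_invalid_bounds_rejected(self, matrix_builder):
        m = matrix_builder(["A a", "B b"], _sym({(0, 1): 0.02}, 2))
        with pytest.raises(ValueError):
            low_divergence_pairs(m, 0.04, 0.01)


class TestDetectDeepSplits:
    def test_mpd_exactly_at_threshold_not_flagged(self, matrix_builder):
        d = _sym({(0, 1): 0.02}, 2)
        m = matrix_builder(["Ga a", "Ga a"], d)
        assert detect_deep_splits(m, 0.02) == {}

    def test_two_clusters_with_singleton_outlier(self, matrix_builder):
        d = _sym({(0, 1): 0.001, (0, 2): 0.05, (1, 2): 0.05}, 3)
        m = matrix_builder(["Ga a"] * 3, d)
        split = detect_deep_splits(m, 0.02)["Ga a"]
        assert split.n_subclusters == 2
        assert split.subclusters == (("s0", "s1"), ("s2",))
        assert split.singleton_outlier

    def test_multi_individual_clusters_detected(self, matrix_builder):
        d = _sym(
            {(0, 1): 0.001, (2, 3): 0.001,
             (0, 2): 0.05, (0, 3): 0.05, (1, 2): 0.05, (1, 3): 0.05},
            4,
        )
        m = matrix_builder(["Ga a"] * 4, d)
        split = detect_deep_splits(m, 0.02)["Ga a"]
        assert split.n_subclusters == 2 and not split.singleton_outlier

    def test_flag_set_monotone_nonincreasing_in_threshold(self):
        lib, _ = simulate_library(
            SimConfig(n_species=20, specimens_per_species=3, n_deep_splits=4,
                      n_sharing_pairs=0, seed=6)
        )
        m = pairwise_matrix(lib)
        prev = None
        for thr in (0.01, 0.02, 0.03, 0.05):
            cur = set(detect_deep_splits(m, thr))
            if prev is not None:
                assert cur <= prev
            prev = cur

    def test_planted_splits_recovered_exactly(self):
        lib, truth = simulate_library(
            SimConfig(n_species=40, specimens_per_species=4, n_deep_splits=5,
                      n_sharing_pairs=0, seed=8)
        )
        m = pairwise_matrix(lib)
        found = detect_deep_splits(m, 0.02)
        assert set(found) == set(truth.deep_splits)
        for sp, split in found.items():
            want = {frozenset(truth.deep_splits[sp][1]), frozenset(truth.deep_splits[sp][2])}
            assert {frozenset(c) for c in split.subclusters} == want


class TestResolutionRate:
    def test_all_distinct_gives_one(self, matrix_builder):
        d = _sym({(0, 1): 0.1}, 2)
        assert resolution_rate(matrix_builder(["A a", "B b"], d)) == (2, 1.0)

    def test_one_sharing_pair_of_three_species(self, matrix_builder):
        d = _sym({(0, 1): 0.0, (0, 2): 0.1, (1, 2): 0.1}, 3)
        n, frac = resolution_rate(matrix_builder(["A a", "B b", "C c"], d))
        assert (n, frac) == (1, pytest.approx(1 / 3))

    def test_two_sharing_pairs_among_many_species(self):
        lib, _ = simulate_library(
            SimConfig(n_species=200, specimens_per_species=2, n_sharing_pairs=2,
                      n_deep_splits=0, seed=10)
        )
        n, frac = resolution_rate(pairwise_matrix(lib))
        assert n == 196
        assert frac == pytest.approx(0.98)


class TestHistogram:
    def test_binning_of_small_values(self):
        h = histogram([0.001, 0.003, 0.006], bin_width=0.005)
        assert h.counts == (2, 1)
        assert h.edges()[0] == (0.0, 0.005)

    def test_empty_input(self):
        assert histogram([]).counts == ()
        assert histogram([]).total == 0

    def test_counts_conserved(self, rng):
        vals = rng.uniform(0, 0.2, size=137)
        assert histogram(vals).total == 137

    def test_negative_or_nan_rejected(self):
        with pytest.raises(ValueError):
            histogram([-0.01])
        with pytest.raises(ValueError):
            histogram([float("nan")])


@pytest.fixture(scope="module")
def small_audit():
    cfg = SimConfig(n_species=15, specimens_per_species=3, n_deep_splits=2,
                    n_sharing_pairs=1, seed=12)
    lib, truth = simulate_library(cfg)
    m = pairwise_matrix(lib)
    return m, truth, run_audit(m)


class TestRunAudit:
    def test_flags_follow_definitions(self, small_audit):
        m, truth, rep = small_audit
        nn = nn_bruteforce(m)
        mpd = mpd_bruteforce(m)
        for a in rep.audits:
            assert ("DEEP_SPLIT" in a.flags) == (
                a.species in mpd and mpd[a.species] > 0.02
            )
            assert ("SHARING" in a.flags) == (
                a.species in nn and nn[a.species][1] == 0
            )
            assert ("SINGLETON" in a.flags) == (a.n_specimens == 1)

    def test_histogram_totals_match_included_species(self, small_audit):
        m, truth, rep = small_audit
        n_nn_included = sum(
            1 for a in rep.audits
            if a.nn_distance is not None and "DEEP_SPLIT" not in a.flags
        )
        n_non_singleton = sum(1 for a in rep.audits if a.mpd is not None)
        assert rep.nn_hist.total == n_nn_included
        assert rep.mpd_hist.total == n_non_singleton

    def test_deep_split_and_sharing_truth_recovered(self, small_audit):
        m, truth, rep = small_audit
        assert set(rep.deep_splits) == set(truth.deep_splits)
        planted = {tuple(sorted(p[:2])) for p in truth.sharing_pairs}
        assert {(p.species1, p.species2) for p in rep.sharing} == planted

    def test_mpd_monotone_under_specimen_deletion(self, small_audit):
        m, truth, rep = small_audit
        mpd_full = mpd_bruteforce(m)
        keep = [i for i in range(len(m)) if i != 1]
        sub = m.subset(keep)
        for sp, v in mpd_bruteforce(sub).items():
            assert v <= mpd_full[sp] + 1e-15

    def test_nn_monotone_under_specimen_deletion(self, small_audit):
        m, truth, rep = small_audit
        nn_full = nn_bruteforce(m)
        keep = [i for i in range(len(m)) if i != 2]
        sub = m.subset(keep)
        for sp, (_, v) in nn_bruteforce(sub).items():
            assert v >= nn_full[sp][1] - 1e-15
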