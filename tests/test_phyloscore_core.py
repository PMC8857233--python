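import itertools
import math

import numpy as np
import pandas as pd
import pytest

import phyloturn as pt
from phyloturn import phyloscore_core as psc


def enumerate_null(asv_i, sample_k, matrix, dist, floor):
    """Independent oracle: brute-force enumeration of ALL N_k-subsets of the
    pool, returning (mean, population sd) of the log nearest distance."""
    n_k = int((matrix[sample_k] > 0).sum())
    pool = [a for a in matrix.index if a != asv_i]
    row = {a: max(dist[asv_i, a], floor) for a in pool}
    logmins = [
        math.log(min(row[a] for a in subset))
        for subset in itertools.combinations(pool, n_k)
    ]
    mean = sum(logmins) / len(logmins)
    var = sum((x - mean) ** 2 for x in logmins) / len(logmins)
    return mean, math.sqrt(var)


class TestNearestBetaDistance:
    def test_worked_tree_minima(self, worked_dist, worked_matrix):
        m = worked_matrix.copy()
        m["bc"] = [0.0, 1.0, 1.0]  # B and C present
        assert pt.nearest_beta_distance("A", "bc", m, worked_dist) == 2.0
        assert pt.nearest_beta_distance("A", "s3", m, worked_dist) == 4.0

    def test_matches_full_scan_oracle(self, small_random_dataset):
        tree, dist, matrix = small_random_dataset
        pres = matrix > 0
        for k in matrix.columns:
            for a in matrix.index:
                if pres.loc[a, k]:
                    continue
                expected = min(
                    dist[a, b] for b in matrix.index if pres.loc[b, k] and b != a
                )
                assert pt.nearest_beta_distance(a, k, matrix, dist) == pytest.approx(expected)

    def test_present_focal_rejected(self, worked_dist, worked_matrix):
        with pytest.raises(ValueError, match="present"):
            pt.nearest_beta_distance("A", "s1", worked_matrix, worked_dist)


class TestNullDistances:
    def test_forced_full_pool_draw(self, worked_dist, worked_matrix):
        """N_k = pool size forces every draw to be the pool-wide minimum."""
        m = worked_matrix.copy()
        m["full"] = [0.0, 1.0, 1.0]  # N_k = 2 = pool size for focal A
        vals = pt.null_nearest_distances("A", "full", m, worked_dist, M=50,
                                         rng=np.random.default_rng(0))
        assert np.all(vals == 2.0)

    def test_two_outcome_null_mean(self, worked_dist, worked_matrix):
        """N_k=1, focal A: outcomes {d(A,B)=2, d(A,C)=4} equally likely."""
        vals = pt.null_nearest_distances("A", "s2", worked_matrix, worked_dist,
                                         M=10000, rng=np.random.default_rng(1))
        assert set(np.unique(vals)) == {2.0, 4.0}
        se = np.std(vals) / np.sqrt(vals.size)
        assert abs(vals.mean() - 3.0) < 3 * se

    def test_seed_determinism(self, worked_dist, worked_matrix):
        a = pt.null_nearest_distances("A", "s2", worked_matrix, worked_dist, 100,
                                      np.random.default_rng(7))
        b = pt.null_nearest_distances("A", "s2", worked_matrix, worked_dist, 100,
                                      np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)


class TestExhaustiveNull:
    def test_full_pool_has_zero_sd(self, worked_dist, worked_matrix):
        m = worked_matrix.copy()
        m["full"] = [0.0, 1.0, 1.0]
        _, sd = pt.exhaustive_null("A", "full", m, worked_dist)
        assert sd == pytest.approx(0.0)

    def test_two_outcome_enumeration(self, worked_dist, worked_matrix):
        mean, sd = pt.exhaustive_null("A", "s2", worked_matrix, worked_dist)
        assert mean == pytest.approx((math.log(2) + math.log(4)) / 2)
        assert sd == pytest.approx((math.log(4) - math.log(2)) / 2)

    @pytest.mark.parametrize("sample", ["s0", "s1", "s2"])
    def test_matches_subset_enumeration_oracle(self, small_random_dataset, sample):
        """Closed-form order-statistic null equals brute-force enumeration on a
        downsampled fixture (10 taxa)."""
        tree, dist, matrix = small_random_dataset
        small = matrix.iloc[:10]
        small = small.loc[:, (small > 0).sum(axis=0) >= 2]
        floor = 0.5 * min(
            dist[a, b] for a in small.index for b in small.index if a < b
        )
        k = small.columns[int(sample[1]) % len(small.columns)]
        pres = small[k] > 0
        focal = [a for a in small.index if not pres[a]][0]
        got = pt.exhaustive_null(focal, k, small, dist, floor=floor)
        want = enumerate_null(focal, k, small, dist, floor)
        assert got[0] == pytest.approx(want[0], rel=1e-10)
        assert got[1] == pytest.approx(want[1], rel=1e-10)


class TestPhyloscore:
    def test_worked_tree_exhaustive_z_is_minus_one(self, worked_dist, worked_matrix):
        """i=A, k={B}: null outcomes {2, 4}; z = (log2 - 1.5 log2)/(0.5 log2) = -1."""
        mean, sd = pt.exhaustive_null("A", "s2", worked_matrix, worked_dist)
        z = (math.log(2.0) - mean) / sd
        assert z == pytest.approx(-1.0, abs=1e-12)

    def test_monte_carlo_converges_to_exhaustive(self, worked_dist, worked_matrix):
        rec = pt.phyloscore("A", "s1", "s2", worked_matrix, worked_dist,
                            M=20000, rng=np.random.default_rng(3))
        assert rec.z == pytest.approx(-1.0, abs=0.03)

    def test_z_zero_at_geometric_mean(self, worked_dist, worked_matrix):
        """d_obs equal to the geometric mean of the null minima gives z = 0."""
        mean, sd = pt.exhaustive_null("A", "s2", worked_matrix, worked_dist)
        geo = math.exp(mean)
        assert (math.log(geo) - mean) / sd == pytest.approx(0.0, abs=1e-12)


class TestAllPhyloscores:
    def test_record_counts(self, worked_dist):
        """An ASV present everywhere yields no records; an ASV present in 1 of
        3 samples yields exactly 2 (one per sample lacking it)."""
        m = pd.DataFrame(
            {"s1": [1.0, 1.0, 1.0], "s2": [0.0, 1.0, 1.0], "s3": [0.0, 1.0, 1.0]},
            index=["A", "B", "C"],
        )
        tab = pt.all_phyloscores(m, worked_dist, M=20, rng=0)
        assert (tab["asv"] == "B").sum() == 0
        assert (tab["asv"] == "C").sum() == 0
        assert (tab["asv"] == "A").sum() == 2
        assert set(tab["recipient_sample"]) == {"s2", "s3"}

    def test_abundance_blind(self, small_random_dataset):
        """Scaling abundances by random positive factors changes no z."""
        tree, dist, matrix = small_random_dataset
        t1 = pt.all_phyloscores(matrix, dist, M=50, rng=123)
        scale = np.random.default_rng(4).uniform(0.1, 10.0, size=matrix.shape)
        t2 = pt.all_phyloscores(matrix * scale, dist, M=50, rng=123)
        pd.testing.assert_frame_equal(t1, t2)

    def test_bit_reproducible(self, small_random_dataset):
        tree, dist, matrix = small_random_dataset
        t1 = pt.all_phyloscores(matrix, dist, M=50, rng=np.random.default_rng(11))
        t2 = pt.all_phyloscores(matrix, dist, M=50, rng=np.random.default_rng(11))
        pd.testing.assert_frame_equal(t1, t2)

    def test_pair_pool_option_runs(self, small_random_dataset):
        tree, dist, matrix = small_random_dataset
        tab = pt.all_phyloscores(matrix, dist, M=20, rng=1, pool="pair")
        assert len(tab) > 0

    def test_pair_filter_restricts(self, small_random_dataset):
        tree, dist, matrix = small_random_dataset
        keep = {"s0", "s1", "s2"}
        tab = pt.all_phyloscores(
            matrix, dist, M=20, rng=1,
            pair_filter=lambda j, k: j in keep and k in keep)
        assert set(tab["donor_sample"]) <= keep
        assert set(tab["recipient_sample"]) <= keep


class TestAggregate:
    def test_hand_arithmetic(self):
        tab = pd.DataFrame(
            {"asv": ["x"] * 3, "donor_sample": "j", "recipient_sample": "k",
             "d_obs": 1.0, "null_mean_log": 0.0, "null_sd_log": 1.0,
             "z": [-1.0, -2.0, 3.0]}
        )
        out = pt.aggregate_phyloscores(tab)
        assert out.loc["x", "total"] == 0.0
        assert out.loc["x", "mean"] == 0.0
        assert out.loc["x", "median"] == -1.0
        assert out.loc["x", "n_pairs"] == 3

    def test_single_record_mean_over_sd_flagged(self):
        tab = pd.DataFrame(
            {"asv": ["x"], "donor_sample": "j", "recipient_sample": "k",
             "d_obs": 1.0, "null_mean_log": 0.0, "null_sd_log": 1.0, "z": [1.5]}
        )
        out = pt.aggregate_phyloscores(tab)
        assert np.isnan(out.loc["x", "mean_over_sd"])

    def test_recordless_asvs_zero_total(self):
        tab = pd.DataFrame(
            {"asv": ["x"], "donor_sample": "j", "recipient_sample": "k",
             "d_obs": 1.0, "null_mean_log": 0.0, "null_sd_log": 1.0, "z": [1.5]}
        )
        out = pt.aggregate_phyloscores(tab, all_asvs=["x", "y"])
        assert out.loc["y", "total"] == 0.0
        assert out.loc["y", "n_pairs"] == 0
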