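import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

import phyloturn as pt
from phyloturn import microdiversity as md, simulate as sim
from phyloturn.microdiversity import AlignmentParams


def gotoh_score(a, b, match=1.0, mismatch=-1.0, gap_open=-2.0, gap_extend=-0.5):
    """Independent affine-gap global alignment score (Gotoh DP).

    Gap of length L costs gap_open + (L - 1) * gap_extend, matching the
    aligner's open/extend semantics.
    """
    n, m = len(a), len(b)
    neg = -1e18
    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)  # gap in b (consume a)
    Y = np.full((n + 1, m + 1), neg)  # gap in a (consume b)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0, j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + gap_open, X[i - 1, j] + gap_extend,
                          Y[i - 1, j] + gap_open)
            Y[i, j] = max(M[i, j - 1] + gap_open, Y[i, j - 1] + gap_extend,
                          X[i, j - 1] + gap_open)
    return max(M[n, m], X[n, m], Y[n, m])


class TestNtd:
    def test_worked_tree(self, worked_tree):
        nt = pt.ntd(worked_tree)
        assert nt["A"] == 2 and nt["B"] == 2 and nt["C"] == 4

    def test_short_cherry(self):
        import io
        from skbio import TreeNode
        tree = TreeNode.read(io.StringIO("(A:0.01,B:0.01);"))
        nt = pt.ntd(tree)
        assert nt["A"] == pytest.approx(0.02)

    def test_matches_row_minimum_oracle_and_bounds(self):
        tree = sim.random_tree(100, np.random.default_rng(31))
        dist = pt.patristic_matrix(tree)
        nt = pt.ntd(dist)
        ids = list(dist.ids)
        for a in ids[:20]:
            others = [dist[a, b] for b in ids if b != a]
            assert nt[a] == pytest.approx(min(others))
            assert all(nt[a] <= d + 1e-12 for d in others)

    def test_invariant_under_rerooting(self):
        tree = sim.random_tree(40, np.random.default_rng(32))
        n1 = pt.ntd(tree)
        n2 = pt.ntd(pt.midpoint_root(tree))
        pd.testing.assert_series_equal(n1.sort_index(), n2.sort_index(),
                                       atol=1e-9, check_exact=False)


class TestPairwiseIdentity:
    def test_identical_and_simple_mismatch(self):
        assert pt.pairwise_identity("ACGT", "ACGT") == 100.0
        assert pt.pairwise_identity("ACGT", "ACGA") == 75.0

    def test_symmetric(self):
        rng = np.random.default_rng(33)
        a = "".join(rng.choice(list("ACGT"), 120))
        b = "".join(rng.choice(list("ACGT"), 110))
        assert pt.pairwise_identity(a, b) == pytest.approx(pt.pairwise_identity(b, a))

    def test_alignment_score_matches_gotoh_oracle(self):
        rng = np.random.default_rng(34)
        params = AlignmentParams()
        aligner = params.aligner()
        for _ in range(5):
            n = int(rng.integers(40, 90))
            a = "".join(rng.choice(list("ACGT"), n))
            # derive b by noisy copy with an indel
            bl = list(a)
            for i in range(len(bl)):
                if rng.random() < 0.1:
                    bl[i] = "ACGT"[rng.integers(4)]
            cut = int(rng.integers(5, n - 5))
            b = "".join(bl[:cut] + bl[cut + 3:])
            assert aligner.align(a, b).score == pytest.approx(gotoh_score(a, b))

    def test_ungapped_identity_equals_column_matches(self):
        """Highly similar equal-length sequences align without gaps, so
        identity equals the per-column match fraction."""
        rng = np.random.default_rng(35)
        a = "".join(rng.choice(list("ACGT"), 200))
        bl = list(a)
        flips = rng.choice(200, size=10, replace=False)
        for i in flips:
            bl[i] = "ACGT"[("ACGT".index(bl[i]) + 1) % 4]
        b = "".join(bl)
        assert pt.pairwise_identity(a, b) == pytest.approx(95.0)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            pt.pairwise_identity("", "ACGT")


class TestBetaNearestSimilarity:
    def test_two_exclusive_asvs_forced_nearest(self, worked_dist):
        m = pd.DataFrame({"s1": [1.0, 0.0], "s2": [0.0, 1.0]}, index=["A", "B"])
        seqs = {"A": "ACGTACGTAC", "B": "ACGTACGAAC"}
        med, long = pt.beta_nearest_similarity(m, worked_dist, seqs)
        expected = pt.pairwise_identity(seqs["A"], seqs["B"])
        assert med["A"] == pytest.approx(expected)
        assert med["B"] == pytest.approx(expected)

    def test_ubiquitous_asv_excluded(self, worked_dist):
        m = pd.DataFrame({"s1": [1.0, 1.0], "s2": [1.0, 0.0]}, index=["A", "B"])
        seqs = {"A": "ACGTACGTAC", "B": "ACGTACGAAC"}
        med, long = pt.beta_nearest_similarity(m, worked_dist, seqs)
        assert "A" not in med.index  # present everywhere
        assert "B" in med.index

    def test_abundance_invariant(self, hos_small):
        data = hos_small
        m = data["matrix"].iloc[:40]
        med1, _ = pt.beta_nearest_similarity(m, data["dist"], data["seqs"])
        scale = np.random.default_rng(0).uniform(0.5, 5.0, size=m.shape)
        med2, _ = pt.beta_nearest_similarity(m * scale, data["dist"], data["seqs"])
        pd.testing.assert_series_equal(med1, med2)


class TestCladeReport:
    def test_planted_microdiverse_clade_discriminated(self, hos_small):
        data = hos_small
        clade = data["clade"]
        rep = pt.clade_microdiversity_report(
            clade, set(data["matrix"].index) - clade, data["tree"],
            data["matrix"], seqs=data["seqs"], dist=data["dist"])
        assert rep.ntd_values.median() < rep.background_ntd.median()
        assert rep.frac_over_97 > rep.background_frac_over_97
        assert rep.p_ntd < 0.01
        assert rep.p_similarity < 0.01

    def test_single_tip_clade_flagged(self, hos_small):
        data = hos_small
        tip = sorted(data["clade"])[0]
        rep = pt.clade_microdiversity_report(
            {tip}, set(data["matrix"].index) - {tip}, data["tree"],
            data["matrix"], dist=data["dist"])
        assert rep.underpowered
        assert np.isnan(rep.p_ntd)


class TestCladeRarefaction:
    def test_full_depth_is_observed_richness(self):
        m = pd.DataFrame({"s": [5.0, 3.0, 2.0]}, index=list("abc"))
        curve = pt.clade_rarefaction(m, list("abc"), [10], reps=20, rng=0)
        assert curve.loc[0, "mean_richness"] == 3.0
        assert curve.loc[0, "sd_richness"] == 0.0

    def test_depth_one_is_one(self):
        m = pd.DataFrame({"s": [5.0, 3.0]}, index=list("ab"))
        curve = pt.clade_rarefaction(m, list("ab"), [1], reps=20, rng=0)
        assert curve.loc[0, "mean_richness"] == 1.0

    def test_matches_hypergeometric_expectation(self):
        counts = [8, 8, 8, 8, 8]
        m = pd.DataFrame({"s": counts}, index=[f"a{i}" for i in range(5)])
        reps = 600
        curve = pt.clade_rarefaction(m, list(m.index), [12], reps=reps, rng=1)
        N, d = sum(counts), 12
        expected = sum(1 - comb(N - c, d) / comb(N, d) for c in counts)
        se = curve.loc[0, "sd_richness"] / np.sqrt(reps)
        assert abs(curve.loc[0, "mean_richness"] - expected) < 4 * se


class TestDepthVsNtd:
    def test_constant_ntd_flagged(self):
        import io
        from skbio import TreeNode
        tree = TreeNode.read(io.StringIO("((A:1,B:1):1,(C:1,D:1):1);"))
        rho, p = pt.depth_vs_ntd(tree)
        assert np.isnan(rho)

    def test_caterpillar_matches_hand_enumeration(self):
        import io
        from skbio import TreeNode
        from scipy import stats
        nwk = "(((((A:1,B:2):1,C:4):1,D:8):1,E:16):1,F:32);"
        tree = TreeNode.read(io.StringIO(nwk))
        rho, p = pt.depth_vs_ntd(tree)
        depths = {t.name: t.accumulate_to_ancestor(tree) for t in tree.tips()}
        nt = pt.ntd(tree)
        want = stats.spearmanr([depths[n] for n in nt.index], nt.values)
        assert rho == pytest.approx(want.statistic)

    def test_random_trees_relationship_is_weak(self):
        """On uniform-attachment random trees the depth-NTD correlation is
        weak (|mean rho| small over an ensemble) — the motivation for leaving
        the depth correction off by default."""
        rhos = []
        for s in range(30):
            tree = sim.random_tree(120, np.random.default_rng(600 + s))
            rho, _ = pt.depth_vs_ntd(tree)
            rhos.append(rho)
        assert abs(np.mean(rhos)) < 0.15
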