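"""Alpha metrics, UniFrac against oracles, PCoA, and clustering."""

import numpy as np
import pytest

from mbstats.core import OtuTable, ValidationError, parse_tree, to_proportions
from mbstats.diversity import (
    observed_otus,
    pcoa,
    presence_absence_clustering,
    rarefaction_curve,
    shannon,
    unweighted_unifrac,
    weighted_unifrac,
)


# ---------------------------------------------------------------------------
# Independent UniFrac oracle: explicit enumeration of every branch
# ---------------------------------------------------------------------------

def unifrac_oracle(tree, sample1, sample2, weighted):
    """Branch-by-branch UniFrac, written independently of the package path."""
    num = den = 0.0
    tot1, tot2 = sum(sample1.values()), sum(sample2.values())
    for node in tree.traverse(include_self=False):
        length = node.length or 0.0
        below = [node.name] if node.is_tip() else [t.name for t in node.tips()]
        a1 = sum(sample1.get(name, 0.0) for name in below)
        a2 = sum(sample2.get(name, 0.0) for name in below)
        if weighted:
            p1 = a1 / tot1 if tot1 else 0.0
            p2 = a2 / tot2 if tot2 else 0.0
            num += length * abs(p1 - p2)
            den += length * (p1 + p2)
        else:
            in1, in2 = a1 > 0, a2 > 0
            num += length * (in1 != in2)
            den += length * (in1 or in2)
    return num / den if den else 0.0


class TestAlphaMetrics:
    @pytest.mark.parametrize("counts,expected", [((0, 0, 0), 0), ((5, 0, 3), 2)])
    def test_observed_otus(self, counts, expected):
        assert observed_otus(counts) == expected

    def test_observed_matches_brute_force(self):
        rng = np.random.default_rng(1)
        v = rng.integers(0, 4, size=200)
        assert observed_otus(v) == sum(1 for c in v if c > 0)

    def test_shannon_uniform_is_log_richness(self):
        assert shannon([5, 5, 5, 5]) == pytest.approx(np.log(4))

    def test_shannon_single_otu_is_zero(self):
        assert shannon([7, 0, 0]) == 0.0

    def test_shannon_closed_form(self):
        # (1,1,2): -2(0.25 ln 0.25) - 0.5 ln 0.5
        expected = -2 * 0.25 * np.log(0.25) - 0.5 * np.log(0.5)
        assert shannon([1, 1, 2]) == pytest.approx(expected, abs=1e-4)
        assert expected == pytest.approx(1.0397, abs=1e-4)

    def test_shannon_all_zero_is_error(self):
        with pytest.raises(ValidationError):
            shannon([0, 0])


class TestRarefactionCurve:
    def test_full_depth_equals_unrarefied(self):
        t = OtuTable([[10, 5, 5]], ["s"], ["a", "b", "c"])
        curve = rarefaction_curve(t, [20], n_reps=3, seed=0)
        assert curve.loc["s", 20] == 3

    def test_small_depth_matches_closed_form(self):
        t = OtuTable([[2, 2]], ["s"], ["a", "b"])
        curve = rarefaction_curve(t, [2], n_reps=4000, seed=0)
        mean = curve.loc["s", 2]
        # closed form 5/3; MC SE of a {1,2}-valued mean is < 0.5/sqrt(n)
        assert abs(mean - 5 / 3) < 3 * 0.5 / np.sqrt(4000)

    def test_monotone_in_depth(self, random_table):
        depths = [20, 50, 100]
        curve = rarefaction_curve(random_table, depths, n_reps=40, seed=1)
        means = curve.mean(axis=0)
        assert means[20] <= means[50] + 0.5 and means[50] <= means[100] + 0.5

    def test_unsorted_depths_rejected(self, random_table):
        with pytest.raises(ValidationError):
            rarefaction_curve(random_table, [50, 20])


class TestUnweightedUnifrac:
    def test_worked_three_leaf_example(self, three_leaf_tree):
        t = OtuTable([[1, 0, 1], [0, 1, 1]], ["S1", "S2"], ["A", "B", "C"])
        d = unweighted_unifrac(t, three_leaf_tree)
        assert d["S1", "S2"] == pytest.approx(0.4)

    def test_identical_profiles_distance_zero(self, three_leaf_tree):
        t = OtuTable([[1, 2, 3], [9, 1, 4]], ["S1", "S2"], ["A", "B", "C"])
        d = unweighted_unifrac(t, three_leaf_tree)
        assert d["S1", "S2"] == 0.0

    def test_disjoint_two_leaf_star_is_one(self):
        tree = parse_tree("(A:1,B:1);")
        t = OtuTable([[3, 0], [0, 2]], ["S1", "S2"], ["A", "B"])
        assert unweighted_unifrac(t, tree)["S1", "S2"] == 1.0

    def test_invariant_to_abundance_rescaling(self, small_sim):
        _, tree, table, *_ = small_sim
        d1 = unweighted_unifrac(table, tree)
        scaled = OtuTable(table.counts * 17, table.sample_ids, table.feature_ids)
        d2 = unweighted_unifrac(scaled, tree)
        np.testing.assert_allclose(d1.data, d2.data, atol=1e-12)

    def test_missing_leaf_listed(self, three_leaf_tree):
        t = OtuTable([[1, 1]], ["S1"], ["A", "ZZZ"])
        with pytest.raises(ValidationError, match="ZZZ"):
            unweighted_unifrac(t, three_leaf_tree)

    def test_matches_scikit_bio(self, small_sim):
        """Cross-check against the reference implementation in scikit-bio."""
        from skbio.diversity import beta_diversity

        _, tree, table, *_ = small_sim
        ours = unweighted_unifrac(table, tree)
        ref = beta_diversity(
            "unweighted_unifrac", table.counts, ids=table.sample_ids,
            tree=tree, taxa=table.feature_ids,
        )
        np.testing.assert_allclose(ours.data, ref.data, atol=1e-10)


class TestWeightedUnifrac:
    def test_worked_three_leaf_example(self, three_leaf_tree):
        t = OtuTable([[5, 0, 5], [0, 5, 5]], ["S1", "S2"], ["A", "B", "C"])
        d = weighted_unifrac(t, three_leaf_tree)
        assert d["S1", "S2"] == pytest.approx(0.25)

    def test_identical_proportions_distance_zero(self, three_leaf_tree):
        t = OtuTable([[2, 4, 6], [1, 2, 3]], ["S1", "S2"], ["A", "B", "C"])
        d = weighted_unifrac(t, three_leaf_tree)
        assert d["S1", "S2"] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_normalized_is_one(self, three_leaf_tree):
        # communities on opposite sides of the root share no branch
        t = OtuTable([[4, 1, 0], [0, 0, 2]], ["S1", "S2"], ["A", "B", "C"])
        assert weighted_unifrac(t, three_leaf_tree)["S1", "S2"] == pytest.approx(1.0)

    def test_matches_scikit_bio_normalized(self, small_sim):
        from skbio.diversity import beta_diversity

        _, tree, table, *_ = small_sim
        ours = weighted_unifrac(table, tree, normalized=True)
        ref = beta_diversity(
            "weighted_unifrac", table.counts, ids=table.sample_ids,
            tree=tree, taxa=table.feature_ids, normalized=True,
        )
        np.testing.assert_allclose(ours.data, ref.data, atol=1e-10)

    def test_matches_branch_enumeration_oracle(self, small_sim):
        _, tree, table, *_ = small_sim
        sub = table.select_samples(table.sample_ids[:5])
        d = weighted_unifrac(sub, tree)
        for i in range(3):
            s1 = dict(zip(sub.feature_ids, sub.counts[i].astype(float)))
            s2 = dict(zip(sub.feature_ids, sub.counts[i + 1].astype(float)))
            expect = unifrac_oracle(tree, s1, s2, weighted=True)
            assert d.data[i, i + 1] == pytest.approx(expect, abs=1e-10)


class TestUnifracInvariants:
    def test_symmetry_zero_diagonal_and_range(self, small_sim):
        _, tree, table, *_ = small_sim
        for dm in (unweighted_unifrac(table, tree), weighted_unifrac(table, tree)):
            assert np.allclose(dm.data, dm.data.T)
            assert np.allclose(np.diag(dm.data), 0)
            assert dm.data.min() >= 0 and dm.data.max() <= 1 + 1e-12


class TestPcoa:
    def test_two_sample_closed_form(self):
        from skbio import DistanceMatrix

        dm = DistanceMatrix([[0, 2], [2, 0]], ids=["a", "b"])
        res = pcoa(dm, k=1)
        assert sorted(res.coordinates["PC1"]) == pytest.approx([-1.0, 1.0])
        assert res.eigenvalues[0] == pytest.approx(2.0)

    def test_recovers_planted_configuration(self):
        from scipy.spatial.distance import pdist, squareform
        from scipy.linalg import orthogonal_procrustes
        from skbio import DistanceMatrix

        rng = np.random.default_rng(5)
        pts = rng.normal(size=(10, 2))
        pts -= pts.mean(axis=0)
        dm = DistanceMatrix(squareform(pdist(pts)), ids=[str(i) for i in range(10)])
        res = pcoa(dm, k=2)
        coords = res.coordinates.to_numpy()
        rot, _ = orthogonal_procrustes(coords, pts)
        err = np.linalg.norm(coords @ rot - pts)
        assert err < 1e-8

    def test_zero_distance_matrix_gives_no_axes(self):
        from skbio import DistanceMatrix

        dm = DistanceMatrix(np.zeros((4, 4)), ids=list("abcd"))
        res = pcoa(dm, k=2)
        assert res.coordinates.shape[1] == 0
        assert np.allclose(res.eigenvalues, 0, atol=1e-12)

    def test_euclidean_input_has_no_negative_spectrum(self):
        from scipy.spatial.distance import pdist, squareform
        from skbio import DistanceMatrix

        rng = np.random.default_rng(9)
        pts = rng.normal(size=(12, 4))
        dm = DistanceMatrix(squareform(pdist(pts)), ids=[str(i) for i in range(12)])
        res = pcoa(dm, k=3)
        assert res.eigenvalues.min() >= -1e-9 * res.eigenvalues.max()

    def test_k_too_large_rejected(self):
        from skbio import DistanceMatrix

        dm = DistanceMatrix(np.zeros((3, 3)), ids=list("abc"))
        with pytest.raises(ValidationError):
            pcoa(dm, k=3)


def brute_force_complete_linkage(profiles):
    """O(n^3) agglomeration oracle returning sorted merge heights."""
    clusters = {i: [i] for i in range(len(profiles))}
    heights = []
    while len(clusters) > 1:
        best = None
        for a in clusters:
            for b in clusters:
                if a >= b:
                    continue
                h = max(
                    np.linalg.norm(profiles[i] - profiles[j])
                    for i in clusters[a]
                    for j in clusters[b]
                )
                if best is None or h < best[0]:
                    best = (h, a, b)
        h, a, b = best
        heights.append(h)
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return sorted(heights)


class TestPresenceAbsenceClustering:
    def test_identical_samples_merge_at_zero(self):
        t = OtuTable([[1, 0], [5, 0], [0, 3]], ["a", "b", "c"], ["x", "y"])
        z = presence_absence_clustering(t)
        assert z[0, 2] == 0.0
        assert sorted(z[0, :2]) == [0, 1]  # the two identical profiles first

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        counts = rng.integers(0, 3, size=(6, 12))
        counts[:, 0] += 1
        t = OtuTable(counts, [f"s{i}" for i in range(6)], [f"f{j}" for j in range(12)])
        z = presence_absence_clustering(t)
        expected = brute_force_complete_linkage((counts > 0).astype(float))
        assert sorted(z[:, 2]) == pytest.approx(expected)

    def test_single_sample_rejected(self):
        t = OtuTable([[1]], ["s"], ["f"])
        with pytest.raises(ValidationError):
            presence_absence_clustering(t)
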