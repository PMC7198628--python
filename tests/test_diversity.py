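import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from meiodiv import (
    DistanceMatrix,
    ValidationError,
    anosim,
    anova_alpha,
    chao1,
    expected_richness,
    jaccard_matrix,
    pairwise_anosim,
    pcoa,
    rarefy,
    rarefy_table,
)
from .conftest import make_table


class TestChao1:
    @pytest.mark.parametrize(
        "counts, s_obs, f1, f2, estimate",
        [
            ([5, 5, 5], 3, 0, 0, 3.0),
            ([1, 1, 1, 1], 4, 4, 0, 10.0),
            ([1, 1, 2, 3], 4, 2, 1, 4.5),
        ],
    )
    def test_hand_cases(self, counts, s_obs, f1, f2, estimate):
        r = chao1(counts)
        assert (r.s_obs, r.f1, r.f2) == (s_obs, f1, f2)
        assert r.estimate == pytest.approx(estimate)

    def test_classic_form(self):
        r = chao1([1, 1, 2, 3], bias_corrected=False)
        assert r.estimate == pytest.approx(4 + 4 / 2)

    def test_classic_falls_back_when_no_doubletons(self):
        r = chao1([1, 1, 1, 1], bias_corrected=False)
        assert r.estimate == pytest.approx(10.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ValidationError):
            chao1([0, 0])

    def test_matches_independent_implementation(self):
        from skbio.diversity.alpha import chao1 as skbio_chao1

        rng = np.random.default_rng(5)
        for _ in range(50):
            v = rng.integers(0, 6, size=30)
            if not v.any():
                continue
            assert chao1(v).estimate == pytest.approx(
                float(skbio_chao1(v, bias_corrected=True))
            )

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.integers(min_value=0, max_value=50), min_size=1, max_size=40))
    def test_estimate_at_least_observed_property(self, counts):
        if not any(counts):
            counts = counts + [1]
        r = chao1(counts)
        assert r.estimate >= r.s_obs
        # equality exactly when at most one singleton (bias-corrected form)
        if r.f1 <= 1:
            assert r.estimate == r.s_obs

    @settings(derandomize=True, max_examples=100)
    @given(
        st.lists(st.integers(min_value=0, max_value=20), min_size=2, max_size=10),
        st.integers(min_value=0, max_value=10**6),
    )
    def test_rarefied_draw_is_valid_subsample(self, counts, seed):
        total = sum(counts)
        depth = seed % (total + 1)
        draw = rarefy(counts, depth, seed=seed)
        assert draw.sum() == depth
        assert (draw <= np.asarray(counts)).all() and (draw >= 0).all()

    def test_estimate_at_least_observed(self):
        rng = np.random.default_rng(6)
        for _ in range(500):
            v = rng.integers(0, 4, size=25)
            if not v.any():
                continue
            r = chao1(v)
            assert r.estimate >= r.s_obs


class TestRarefaction:
    def test_full_depth_is_identity(self):
        v = [4, 0, 7]
        assert rarefy(v, 11, seed=0).tolist() == v

    def test_zero_depth(self):
        assert rarefy([4, 2], 0, seed=0).tolist() == [0, 0]

    def test_depth_exceeding_total_rejected(self):
        with pytest.raises(ValidationError, match="depth"):
            rarefy([1, 1], 3)

    def test_reproducible_and_exact_sum(self):
        v = [10, 20, 5, 0, 3]
        a = rarefy(v, 17, seed=42)
        b = rarefy(v, 17, seed=42)
        assert (a == b).all() and a.sum() == 17 and (a <= np.array(v)).all()

    def test_two_one_depth_two_enumeration(self):
        # exhaustive oracle: the 3 equiprobable 2-subsets of reads {a,a,b}
        # give species counts (1, 2, 2) -> E[S] = 5/3
        draws = np.array([rarefy([2, 1], 2, seed=s) for s in range(4000)])
        richness = (draws > 0).sum(axis=1)
        se = richness.std(ddof=1) / math.sqrt(len(richness))
        assert abs(richness.mean() - 5 / 3) < 3 * se

    def test_rarefy_table_per_sample(self):
        t = make_table([[5, 5], [10, 0]], samples=["a", "b"], otus=["o1", "o2"])
        r = rarefy_table(t, 5, seed=1)
        assert (r.counts.sum(axis=1) == 5).all()


class TestExpectedRichness:
    def test_single_draw_is_one_species(self):
        assert expected_richness([2, 1], 1) == pytest.approx(1.0)

    def test_enumeration_case(self):
        assert expected_richness([2, 1], 2) == pytest.approx(5 / 3)

    def test_full_depth_gives_observed(self):
        assert expected_richness([3, 1, 8], 12) == pytest.approx(3.0)

    def test_matches_hypergeometric_oracle(self):
        # independent route: P(species i present) = 1 - pmf(0) of the
        # hypergeometric distribution
        rng = np.random.default_rng(9)
        for _ in range(20):
            v = rng.integers(1, 20, size=6)
            n = int(v.sum())
            d = int(rng.integers(1, n + 1))
            oracle = sum(1 - stats.hypergeom.pmf(0, n, k, d) for k in v)
            assert expected_richness(v, d) == pytest.approx(float(oracle), rel=1e-9)

    def test_large_total_uses_stable_path(self):
        v = [1500, 1500, 10]
        assert expected_richness(v, 3000) == pytest.approx(3.0, abs=0.2)


class TestAnova:
    def test_identical_groups_give_zero_f(self):
        f, p = anova_alpha({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert f == 0 and p == pytest.approx(1.0)

    def test_hand_computed_f(self):
        f, p = anova_alpha({"a": [1, 2], "b": [5, 6]})
        assert f == pytest.approx(32.0)
        assert 0 < p < 0.05

    def test_matches_scipy(self):
        rng = np.random.default_rng(10)
        groups = {g: rng.normal(size=5).tolist() for g in "abc"}
        f, p = anova_alpha(groups)
        ref = stats.f_oneway(*groups.values())
        assert f == pytest.approx(ref.statistic) and p == pytest.approx(ref.pvalue)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValidationError):
            anova_alpha({"a": [1, 2]})
        with pytest.raises(ValidationError):
            anova_alpha({"a": [1, 2], "b": []})
        with pytest.raises(ValidationError):
            anova_alpha({"a": [1, 1], "b": [1, 1]})


class TestJaccard:
    def test_identical_samples_distance_zero(self):
        t = make_table([[1, 2, 0], [9, 1, 0]], samples=["a", "b"], otus=list("xyz"))
        assert jaccard_matrix(t).data[0, 1] == 0

    def test_disjoint_samples_distance_one(self):
        t = make_table([[1, 0], [0, 4]], samples=["a", "b"], otus=["x", "y"])
        assert jaccard_matrix(t).data[0, 1] == 1

    def test_hand_case(self):
        t = make_table(
            [[1, 1, 1, 0], [0, 1, 1, 1]], samples=["a", "b"], otus=list("wxyz")
        )
        assert jaccard_matrix(t).data[0, 1] == pytest.approx(0.5)

    def test_scaling_invariance(self):
        rng = np.random.default_rng(11)
        c = rng.integers(0, 4, size=(4, 12))
        t1 = make_table(c, samples=list("abcd"), otus=[f"o{i}" for i in range(12)])
        t2 = make_table(c * 7, samples=list("abcd"), otus=[f"o{i}" for i in range(12)])
        assert np.allclose(jaccard_matrix(t1).data, jaccard_matrix(t2).data)

    def test_matches_scipy_pdist(self):
        from scipy.spatial.distance import pdist, squareform

        rng = np.random.default_rng(12)
        c = rng.integers(0, 3, size=(5, 20))
        c[:, 0] = 1  # avoid all-empty pairs (scipy treats 0/0 differently)
        t = make_table(c, samples=list("abcde"), otus=[f"o{i}" for i in range(20)])
        ref = squareform(pdist(c > 0, metric="jaccard"))
        assert np.allclose(jaccard_matrix(t).data, ref)

    def test_both_empty_samples_distance_zero(self):
        t = make_table([[0, 0], [0, 0], [1, 1]], samples=list("abc"), otus=["x", "y"])
        assert jaccard_matrix(t).data[0, 1] == 0


class TestDistanceMatrix:
    def test_asymmetry_rejected(self):
        with pytest.raises(ValidationError):
            DistanceMatrix(sample_ids=["a", "b"], data=np.array([[0, 1], [2, 0]]))

    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(ValidationError):
            DistanceMatrix(sample_ids=["a"], data=np.array([[1.0]]))


class TestPcoa:
    def test_all_zero_matrix_gives_no_axes(self):
        dm = DistanceMatrix(sample_ids=list("abc"), data=np.zeros((3, 3)))
        r = pcoa(dm)
        assert r.coordinates.shape[1] == 0 and len(r.eigenvalues) == 0

    def test_equilateral_triangle(self):
        d = np.ones((3, 3)) - np.eye(3)
        r = pcoa(DistanceMatrix(sample_ids=list("abc"), data=d))
        pts = r.coordinates
        dists = [np.linalg.norm(pts[i] - pts[j]) for i, j in itertools.combinations(range(3), 2)]
        assert np.allclose(dists, dists[0])

    def test_collinear_points_recovered_on_first_axis(self):
        x = np.array([0.0, 1.0, 3.0, 6.0])
        d = np.abs(x[:, None] - x[None, :])
        r = pcoa(DistanceMatrix(sample_ids=list("abcd"), data=d))
        axis1 = r.coordinates[:, 0]
        assert np.allclose(np.abs(axis1[1:] - axis1[:-1]), np.diff(x), atol=1e-8)

    def test_euclidean_distances_reproduced(self):
        rng = np.random.default_rng(13)
        pts = rng.normal(size=(6, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        r = pcoa(DistanceMatrix(sample_ids=[f"s{i}" for i in range(6)], data=d))
        rec = np.linalg.norm(
            r.coordinates[:, None] - r.coordinates[None, :], axis=2
        )
        assert np.allclose(rec, d, rtol=1e-8, atol=1e-10)

    def test_eigenvalues_match_independent_implementation(self):
        from skbio.stats.ordination import pcoa as skbio_pcoa

        rng = np.random.default_rng(14)
        pts = rng.normal(size=(5, 2))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        mine = pcoa(DistanceMatrix(sample_ids=list("abcde"), data=d))
        ref = skbio_pcoa(d, number_of_dimensions=len(mine.eigenvalues))
        assert np.allclose(
            sorted(mine.eigenvalues), sorted(np.asarray(ref.eigvals)[: len(mine.eigenvalues)]),
            atol=1e-8,
        )

    def test_proportions_sum_to_one(self):
        rng = np.random.default_rng(15)
        pts = rng.normal(size=(7, 4))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        r = pcoa(DistanceMatrix(sample_ids=[f"s{i}" for i in range(7)], data=d))
        assert r.proportion_explained.sum() == pytest.approx(1.0)
        assert (r.proportion_explained >= 0).all()


def two_group_matrix(within, between):
    """4 samples (2+2); prescribed within/between distances."""
    d = np.zeros((4, 4))
    d[0, 1] = d[1, 0] = within[0]
    d[2, 3] = d[3, 2] = within[1]
    vals = iter(between)
    for i in (0, 1):
        for j in (2, 3):
            v = next(vals)
            d[i, j] = d[j, i] = v
    return DistanceMatrix(sample_ids=["a1", "a2", "b1", "b2"], data=d)


GROUPS_22 = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}


class TestAnosim:
    def test_perfect_separation_r_one(self):
        dm = two_group_matrix([1, 2], [3, 4, 5, 6])
        res = anosim(dm, GROUPS_22, n_permutations=99, seed=0)
        assert res.r == pytest.approx(1.0)

    def test_matches_independent_implementation(self):
        from skbio import DistanceMatrix as SkbioDM
        from skbio.stats.distance import anosim as skbio_anosim

        rng = np.random.default_rng(16)
        pts = rng.normal(size=(8, 3))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        ids = [f"s{i}" for i in range(8)]
        groups = {s: ("A" if i < 4 else "B") for i, s in enumerate(ids)}
        mine = anosim(DistanceMatrix(sample_ids=ids, data=d), groups,
                      n_permutations=99, seed=1)
        ref = skbio_anosim(SkbioDM(d, ids), [groups[s] for s in ids], permutations=99)
        assert mine.r == pytest.approx(float(ref["test statistic"]))

    def test_null_permutation_mean_near_zero(self):
        rng = np.random.default_rng(17)
        pts = rng.normal(size=(10, 4))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        ids = [f"s{i}" for i in range(10)]
        groups = {s: ("A" if i % 2 else "B") for i, s in enumerate(ids)}
        rs = []
        for rep in range(100):
            perm = rng.permutation(10)
            g = {ids[i]: groups[ids[int(j)]] for i, j in enumerate(perm)}
            rs.append(anosim(DistanceMatrix(sample_ids=ids, data=d), g,
                             n_permutations=9, seed=rep).r)
        assert abs(np.mean(rs)) < 0.05

    def test_r_bounds(self):
        rng = np.random.default_rng(18)
        for rep in range(20):
            pts = rng.normal(size=(6, 2))
            d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
            ids = [f"s{i}" for i in range(6)]
            groups = {s: ("A" if i < 3 else "B") for i, s in enumerate(ids)}
            res = anosim(DistanceMatrix(sample_ids=ids, data=d), groups,
                         n_permutations=9, seed=rep)
            assert -1 - 1e-9 <= res.r <= 1 + 1e-9
            assert res.p_value >= 1 / (res.n_permutations + 1)

    def test_single_sample_group_rejected(self):
        dm = two_group_matrix([1, 2], [3, 4, 5, 6])
        groups = dict(GROUPS_22, a2="C")
        with pytest.raises(ValidationError):
            anosim(dm, groups, n_permutations=9, seed=0)


class TestPairwiseAnosim:
    def _three_group_dm(self, seed=19):
        rng = np.random.default_rng(seed)
        pts = np.concatenate(
            [rng.normal(loc=3 * g, size=(3, 2)) for g in range(3)]
        )
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        ids = [f"s{i}" for i in range(9)]
        groups = {s: f"G{i // 3}" for i, s in enumerate(ids)}
        return DistanceMatrix(sample_ids=ids, data=d), groups

    def test_three_groups_give_three_pairs(self):
        dm, groups = self._three_group_dm()
        out = pairwise_anosim(dm, groups, n_permutations=49, seed=0)
        assert len(out) == 3
        assert sorted(r.group_labels for r in out) == [
            ("G0", "G1"), ("G0", "G2"), ("G1", "G2")
        ]

    def test_pair_matches_global_two_group(self):
        dm = two_group_matrix([1, 2], [3, 4, 5, 6])
        glob = anosim(dm, GROUPS_22, n_permutations=99, seed=3)
        (pair,) = pairwise_anosim(dm, GROUPS_22, n_permutations=99, seed=3)
        assert pair.r == pytest.approx(glob.r)

    def test_strong_site_effects_all_positive(self):
        dm, groups = self._three_group_dm()
        out = pairwise_anosim(dm, groups, n_permutations=49, seed=1)
        assert all(r.r > 0 for r in out)
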