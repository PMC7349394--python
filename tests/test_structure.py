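"""Dissimilarities, Ward clustering, NMDS and the Mantel IBD test."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from pondpop.errors import StatisticError, ValidationError
from pondpop.io_survey import HaplotypeCountTable
from pondpop.structure import (
    DistanceMatrix,
    bray_curtis,
    chao_jaccard_dissimilarity,
    cut_tree,
    geographic_distances,
    kruskal_stress,
    mantel_test,
    nmds,
    pairwise_dissimilarity,
    population_p_distance,
    ward_cluster,
)
from tests.conftest import make_pond


def random_distance_matrix(rng, n, labels=None):
    pts = rng.normal(size=(n, 3))
    values = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
    np.fill_diagonal(values, 0.0)
    values = (values + values.T) / 2
    return DistanceMatrix(tuple(labels or (f"s{i}" for i in range(n))), values)


class TestBrayCurtis:
    def test_identical_and_disjoint_supports(self):
        assert bray_curtis([3, 1], [3, 1]) == 0.0
        assert bray_curtis([3, 0], [0, 2]) == 1.0

    def test_worked_example(self):
        assert bray_curtis([2, 1, 0], [0, 1, 1]) == pytest.approx(0.6)

    def test_both_empty_rejected(self):
        with pytest.raises(StatisticError):
            bray_curtis([0, 0], [0, 0])


def chao_jaccard_oracle(x, y):
    """Independent literal transcription of the published U/V estimator."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n, m = x.sum(), y.sum()
    shared = [i for i in range(len(x)) if x[i] > 0 and y[i] > 0]
    if not shared:
        return 1.0

    def fraction(a, b, na, nb):
        u = sum(a[i] / na for i in shared)
        f1 = sum(1 for i in shared if b[i] == 1)
        f2 = sum(1 for i in shared if b[i] == 2)
        if f1 and nb > 1:
            u += ((nb - 1) / nb) * (f1 / (2 * max(f2, 1))) * sum(
                a[i] / na for i in shared if b[i] == 1
            )
        return min(u, 1.0)

    u = fraction(x, y, n, m)
    v = fraction(y, x, m, n)
    if u == 0 or v == 0:
        return 1.0
    return min(1.0, max(0.0, 1.0 - u * v / (u + v - u * v)))


class TestChaoJaccard:
    def test_identical_and_disjoint(self):
        assert chao_jaccard_dissimilarity([4, 2, 1], [4, 2, 1]) == 0.0
        assert chao_jaccard_dissimilarity([4, 0], [0, 9]) == 1.0

    def test_matches_independent_transcription(self):
        rng = np.random.default_rng(3)
        cases = [np.array([10, 2, 1]), np.array([8, 0, 3])]
        assert chao_jaccard_dissimilarity(cases[0], cases[1]) == pytest.approx(
            chao_jaccard_oracle(cases[0], cases[1]), abs=1e-10
        )
        for _ in range(200):
            k = int(rng.integers(2, 10))
            x = rng.integers(0, 15, size=k)
            y = rng.integers(0, 15, size=k)
            if x.sum() == 0 or y.sum() == 0:
                continue
            assert chao_jaccard_dissimilarity(x, y) == pytest.approx(
                chao_jaccard_oracle(x, y), abs=1e-10
            )

    @given(
        x=arrays(np.int64, 6, elements=st.integers(0, 20)),
        y=arrays(np.int64, 6, elements=st.integers(0, 20)),
    )
    @settings(max_examples=150, deadline=None)
    def test_symmetric_and_bounded(self, x, y):
        if x.sum() == 0 or y.sum() == 0:
            return
        d = chao_jaccard_dissimilarity(x, y)
        assert 0.0 <= d <= 1.0
        assert d == pytest.approx(chao_jaccard_dissimilarity(y, x), abs=1e-12)
        assert chao_jaccard_dissimilarity(x, x) == 0.0


def ward_oracle(d: DistanceMatrix):
    """Greedy Ward agglomeration from cluster memberships (no Lance-Williams).

    Uses the Euclidean-embedding identity for the between-centroid distance:
    ||cA - cB||^2 = mean cross d^2 - mean within d^2 / 2 per cluster, and the
    ward.D2 merge height sqrt(2 |A||B| / (|A|+|B|) * ||cA - cB||^2).
    """
    d2 = d.values**2
    clusters = [[i] for i in range(d.n)]
    heights = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            A, B = clusters[a], clusters[b]
            cross = np.mean([d2[i, j] for i in A for j in B])
            within_a = np.mean([d2[i, j] for i in A for j in A])
            within_b = np.mean([d2[i, j] for i in B for j in B])
            gap = cross - within_a / 2 - within_b / 2
            height = math.sqrt(
                max(0.0, 2 * len(A) * len(B) / (len(A) + len(B)) * gap)
            )
            if best is None or height < best[0]:
                best = (height, a, b)
        height, a, b = best
        heights.append(height)
        merged = clusters[a] + clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)]
        clusters.append(merged)
    return heights


class TestWard:
    def test_two_sites_merge_at_their_distance(self):
        d = DistanceMatrix(("a", "b"), np.array([[0.0, 0.7], [0.7, 0.0]]))
        tree = ward_cluster(d)
        assert tree.merges == ((0, 1, pytest.approx(0.7)),)

    def test_tight_pairs_merge_first(self):
        labels = ("a", "b", "c", "d")
        v = np.array(
            [[0, 0.1, 5, 5.2], [0.1, 0, 5.1, 5], [5, 5.1, 0, 0.12], [5.2, 5, 0.12, 0]]
        )
        tree = ward_cluster(DistanceMatrix(labels, v))
        first_two = {frozenset(m[:2]) for m in tree.merges[:2]}
        assert first_two == {frozenset({0, 1}), frozenset({2, 3})}

    def test_matches_membership_level_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(25):
            n = int(rng.integers(3, 7))
            d = random_distance_matrix(rng, n)
            mine = [h for _, _, h in ward_cluster(d).merges]
            assert mine == pytest.approx(ward_oracle(d), rel=1e-9)

    def test_matches_scipy_linkage(self):
        from scipy.cluster.hierarchy import linkage
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(4)
        for _ in range(10):
            d = random_distance_matrix(rng, 8)
            mine = ward_cluster(d).heights
            ref = linkage(squareform(d.values), method="ward")[:, 2]
            assert mine == pytest.approx(ref, rel=1e-9)

    def test_near_identical_ponds_cluster_before_distinct_one(self, survey_table):
        """Monomorphic-leaning ponds sharing a 19:1 profile group together."""
        rows = np.vstack([survey_table.row(s) for s in ("16", "21", "26", "32")])
        keep = rows.sum(axis=0) > 0
        sub = HaplotypeCountTable(
            ["16", "21", "26", "32"],
            [h for h, k in zip(survey_table.haplotype_ids, keep) if k],
            rows[:, keep],
        )
        d = pairwise_dissimilarity(sub, "chao_jaccard")
        tree = ward_cluster(d)
        assignments = cut_tree(tree, 2)
        assert assignments["16"] == assignments["21"] == assignments["26"]
        assert assignments["32"] != assignments["16"]

    def test_merge_heights_monotone_on_random_fuzz(self):
        rng = np.random.default_rng(123)
        for _ in range(1000):
            n = int(rng.integers(3, 9))
            d = random_distance_matrix(rng, n)
            heights = ward_cluster(d).heights
            assert np.all(np.diff(heights) >= -1e-10)

    def test_cut_tree_extremes_and_range(self):
        rng = np.random.default_rng(5)
        d = random_distance_matrix(rng, 6)
        tree = ward_cluster(d)
        assert set(cut_tree(tree, 1).values()) == {1}
        assert len(set(cut_tree(tree, 6).values())) == 6
        with pytest.raises(ValidationError):
            cut_tree(tree, 7)
        with pytest.raises(ValidationError):
            cut_tree(tree, 0)


class TestNMDS:
    def test_perfect_recovery_of_planar_distances(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(5, 2))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        result = nmds(DistanceMatrix(tuple("abcde"), d), k=2, n_restarts=3, seed=0)
        assert result.stress < 1e-3

    def test_equidistant_four_points_match_numerical_oracle(self):
        """Stress for the regular simplex equals a direct numerical minimum."""
        from scipy.optimize import minimize

        d = DistanceMatrix(tuple("abcd"), np.ones((4, 4)) - np.eye(4))

        def objective(flat):
            return kruskal_stress(d.values, flat.reshape(4, 2))

        rng = np.random.default_rng(0)
        oracle = min(
            minimize(objective, rng.normal(size=8), method="Nelder-Mead",
                     options={"xatol": 1e-9, "fatol": 1e-12, "maxiter": 5000}).fun
            for _ in range(8)
        )
        result = nmds(d, k=2, n_restarts=10, seed=1)
        assert result.stress == pytest.approx(oracle, abs=1e-3)
        # deterministic given the seed
        again = nmds(d, k=2, n_restarts=10, seed=1)
        assert np.array_equal(result.coordinates, again.coordinates)

    def test_planted_two_group_separation(self):
        n = 8
        values = np.full((n, n), 1.0)
        for i, j in itertools.product(range(n), repeat=2):
            if (i < 4) == (j < 4):
                values[i, j] = 0.1
        np.fill_diagonal(values, 0.0)
        d = DistanceMatrix(tuple(f"s{i}" for i in range(n)), values)
        result = nmds(d, k=2, n_restarts=10, seed=2)
        axis = result.coordinates[:, 0]
        gap = abs(axis[:4].mean() - axis[4:].mean())
        spread = max(axis[:4].std(), axis[4:].std())
        assert gap > spread

    def test_dimension_bounds(self):
        rng = np.random.default_rng(3)
        d = random_distance_matrix(rng, 4)
        with pytest.raises(ValidationError):
            nmds(d, k=4)


class TestGeographicDistances:
    def test_identical_points_and_one_degree_latitude(self, pond_factory):
        a = pond_factory("a", latitude=36.0, longitude=138.0)
        b = pond_factory("b", latitude=36.0, longitude=138.0)
        c = pond_factory("c", latitude=37.0, longitude=138.0)
        d = geographic_distances([a, b, c])
        assert d.values[0, 1] == 0.0
        assert d.values[0, 2] == pytest.approx(
            2 * math.pi * 6371.0088 / 360, abs=1e-3
        )

    def test_agrees_with_spherical_law_of_cosines(self, survey_ponds):
        by_id = {p.site_id: p for p in survey_ponds}
        a, b = by_id["1"], by_id["33"]
        d = geographic_distances([a, b]).values[0, 1]
        la, lb = math.radians(a.latitude), math.radians(b.latitude)
        dlon = math.radians(b.longitude - a.longitude)
        oracle = 6371.0088 * math.acos(
            min(1.0, math.sin(la) * math.sin(lb) + math.cos(la) * math.cos(lb) * math.cos(dlon))
        )
        assert d == pytest.approx(oracle, abs=1e-3)  # within 1 m


class TestPopulationPDistance:
    def test_monomorphic_pond_pairs(self):
        table = HaplotypeCountTable(["A", "B"], ["H1", "H2"], [[10, 0], [0, 5]])
        steps = np.array([[0, 2], [2, 0]])
        d = population_p_distance(table, steps, 100)
        assert d.values[0, 1] == pytest.approx(0.02)
        shared = HaplotypeCountTable(["A", "B"], ["H1", "H2"], [[10, 1], [5, 0]])
        # two ponds fixed for the same haplotype differ by ~0
        mono = HaplotypeCountTable(["A", "B"], ["H1"], [[10], [5]])
        assert population_p_distance(mono, np.zeros((1, 1)), 100).values[0, 1] == 0.0

    def test_matches_specimen_level_double_loop(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            k = int(rng.integers(2, 5))
            counts = rng.integers(1, 9, size=(3, k))
            table = HaplotypeCountTable(
                ["A", "B", "C"], [f"H{i}" for i in range(k)], counts
            )
            d = np.triu(rng.integers(0, 6, size=(k, k)), 1)
            d = d + d.T
            length = 200
            result = population_p_distance(table, d, length)
            for a, b in itertools.combinations(range(3), 2):
                sa = np.repeat(np.arange(k), counts[a])
                sb = np.repeat(np.arange(k), counts[b])
                oracle = np.mean([d[i, j] for i in sa for j in sb]) / length
                assert result.values[a, b] == pytest.approx(oracle, abs=1e-12)

    def test_empty_pond_excluded_with_warning(self):
        table = HaplotypeCountTable(["A", "B"], ["H1"], [[10], [0]])
        with pytest.warns(UserWarning, match="B"):
            d = population_p_distance(table, np.zeros((1, 1)), 100)
        assert d.labels == ("A",)


class TestMantel:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(1)
        d = random_distance_matrix(rng, 6)
        result = mantel_test(d, d, n_permutations=99, seed=0)
        assert result.r == pytest.approx(1.0)
        assert result.p <= 0.05

    def test_exact_enumeration_matches_brute_force(self):
        """Exhaustive p at n = 5 equals an independent enumeration oracle."""
        rng = np.random.default_rng(10)
        d1 = random_distance_matrix(rng, 5)
        d2 = random_distance_matrix(rng, 5, labels=d1.labels)
        result = mantel_test(d1, d2, exact=True)
        iu = np.triu_indices(5, 1)
        x = d1.values[iu]
        r_obs = np.corrcoef(x, d2.values[iu])[0, 1]
        count = 0
        total = 0
        for perm in itertools.permutations(range(5)):
            perm = np.asarray(perm)
            r = np.corrcoef(x, d2.values[np.ix_(perm, perm)][iu])[0, 1]
            count += r >= r_obs - 1e-12
            total += 1
        assert total == 120
        assert result.p == pytest.approx(count / total, abs=1e-12)
        assert result.r == pytest.approx(r_obs)

    def test_label_mismatch_rejected(self):
        rng = np.random.default_rng(2)
        d1 = random_distance_matrix(rng, 5)
        d2 = random_distance_matrix(rng, 5, labels=[f"z{i}" for i in range(5)])
        with pytest.raises(ValidationError):
            mantel_test(d1, d2)

    def test_null_p_values_are_uniform(self):
        """Under independent random matrices the p-value is uniform (KS)."""
        from scipy.stats import kstest

        rng = np.random.default_rng(77)
        pvalues = []
        for i in range(500):
            d1 = random_distance_matrix(rng, 8)
            d2 = random_distance_matrix(rng, 8, labels=d1.labels)
            pvalues.append(
                mantel_test(d1, d2, n_permutations=199, seed=1000 + i).p
            )
        statistic, p = kstest(pvalues, "uniform")
        assert p > 0.01


class TestDistanceMatrixContainer:
    def test_symmetry_and_diagonal_enforced(self):
        with pytest.raises(ValidationError):
            DistanceMatrix(("a", "b"), np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(ValidationError):
            DistanceMatrix(("a", "b"), np.array([[0.5, 1.0], [1.0, 0.0]]))

    def test_tsv_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        d = random_distance_matrix(rng, 5)
        path = tmp_path / "d.tsv"
        d.write_tsv(path)
        again = DistanceMatrix.read_tsv(path)
        assert again.labels == d.labels
        assert np.allclose(again.values, d.values)

    def test_all_dissimilarities_symmetric_zero_diag_bounded(self, survey_table):
        for metric in ("bray_curtis", "chao_jaccard"):
            d = pairwise_dissimilarity(survey_table, metric)
            assert np.allclose(d.values, d.values.T)
            assert np.all(np.diag(d.values) == 0)
            assert d.values.min() >= 0 and d.values.max() <= 1
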