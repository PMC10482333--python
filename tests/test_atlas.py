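"""MDS embeddings, Menger curvature, and the group permutation test."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from topopack import (
    DistanceMatrix,
    MotifDistribution,
    classical_mds,
    convex_hull_membership,
    graph_from_edges,
    group_permutation_test,
    menger_curvature,
    trajectory_curvature,
)
from topopack.atlas import write_embedding
from topopack.errors import InputError, NonMetricTripleError


def dm_from_points(pts, labels=None):
    d = np.linalg.norm(pts[:, None] - pts[None], axis=2)
    labels = labels or tuple(str(i) for i in range(len(pts)))
    return DistanceMatrix(labels=tuple(labels), values=d)


class TestClassicalMDS:
    def test_unit_square_exact(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        dm = dm_from_points(np.column_stack([pts, np.zeros(4)]))
        emb = classical_mds(dm, k=2)
        rec = np.linalg.norm(
            emb.coordinates[:, None] - emb.coordinates[None], axis=2
        )
        assert np.allclose(rec, dm.values, atol=1e-8)
        assert emb.stress == pytest.approx(0.0, abs=1e-8)

    def test_zero_matrix(self):
        dm = DistanceMatrix(labels=("a", "b", "c"), values=np.zeros((3, 3)))
        emb = classical_mds(dm, k=2)
        assert np.all(emb.coordinates == 0)

    def test_recovers_random_configuration(self):
        """Exact Euclidean distances from points in R^3 are recovered up to
        rigid motion (Procrustes residual ~ 0)."""
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(12, 3))
        emb = classical_mds(dm_from_points(pts), k=3)
        X = pts - pts.mean(axis=0)
        Y = emb.coordinates
        U, _, Vt = np.linalg.svd(Y.T @ X)
        R = U @ Vt
        resid = np.linalg.norm(Y @ R - X) / np.linalg.norm(X)
        assert resid < 1e-6

    def test_projection_contracts_distances(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(10, 5))
        dm = dm_from_points(pts)
        emb = classical_mds(dm, k=2)
        rec = np.linalg.norm(emb.coordinates[:, None] - emb.coordinates[None], axis=2)
        assert np.all(rec <= dm.values + 1e-8)

    def test_columns_centered_and_ordered(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(9, 3))
        emb = classical_mds(dm_from_points(pts), k=3)
        assert np.allclose(emb.coordinates.mean(axis=0), 0, atol=1e-9)
        assert np.all(np.diff(emb.eigenvalues) <= 1e-9)

    def test_excess_dimension_zero_padded(self):
        pts = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        dm = dm_from_points(pts)
        with pytest.warns(UserWarning, match="zero-padding"):
            emb = classical_mds(dm, k=3)
        assert np.allclose(emb.coordinates[:, 1:], 0)

    def test_bad_k(self):
        dm = DistanceMatrix(labels=("a", "b"), values=np.array([[0.0, 1], [1, 0]]))
        with pytest.raises(InputError):
            classical_mds(dm, k=2)


class TestMengerCurvature:
    def test_closed_forms(self):
        assert menger_curvature(1, 1, 2) == 0.0
        assert menger_curvature(3, 4, 5) == pytest.approx(0.4, abs=1e-10)
        s = 1.7
        assert menger_curvature(s, s, s) == pytest.approx(np.sqrt(3) / s, abs=1e-10)

    @given(
        st.floats(min_value=0.1, max_value=10),
        st.floats(min_value=0.1, max_value=10),
        st.floats(min_value=0.01, max_value=100),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_scale_law(self, a, b, s):
        """Scaling all three distances by s divides the curvature by s."""
        c = abs(a - b) + 0.5 * ((a + b) - abs(a - b))  # strictly inside the triangle range
        base = menger_curvature(a, b, c)
        scaled = menger_curvature(s * a, s * b, s * c)
        assert scaled * s == pytest.approx(base, rel=1e-9)

    def test_non_metric_rejected(self):
        with pytest.raises(NonMetricTripleError, match="non-metric"):
            menger_curvature(1, 1, 3)
        with pytest.raises(NonMetricTripleError):
            menger_curvature(0, 1, 1)


class TestTrajectoryCurvature:
    def path_graph(self, n=21):
        return graph_from_edges(
            [f"{i}" for i in range(n)], [(i, i + 1) for i in range(n - 1)]
        )

    def test_linear_interpolation_flat(self):
        """Series sliding mass steadily along a path graph traces a geodesic:
        distances add exactly, so Menger curvature vanishes."""
        g = self.path_graph()
        series = []
        for t in range(8):
            series.append(
                MotifDistribution(counts={f"{2 * t}": 1.0, f"{2 * t + 1}": 1.0}, n_samples=2)
            )
        tc = trajectory_curvature(series, g, spacing=1)
        assert np.all(np.abs(tc.curvatures) < 1e-6)
        assert np.array_equal(tc.indices, np.arange(1, 7))

    def test_kink_detected(self):
        """A trajectory that runs along a tree (where TDD is exactly
        additive, hence flat) and then wraps around a cycle shows its only
        curvature spike in the window that enters the cycle."""
        edges = [(i, i + 1) for i in range(6)]  # path 0..6
        edges += [(6, 7), (7, 8), (8, 9), (9, 10), (10, 11), (11, 6)]  # cycle
        g = graph_from_edges([f"{i}" for i in range(12)], edges)
        series = [
            MotifDistribution(counts={f"{i}": 1.0}, n_samples=1)
            for i in (1, 2, 3, 4, 5, 6, 8, 10)
        ]
        tc = trajectory_curvature(series, g, spacing=1)
        assert np.all(tc.curvatures[:-1] < 1e-6)  # tree segment is flat
        assert tc.curvatures[-1] > 0.1  # the wrap around the cycle

    def test_constant_series_flagged(self):
        g = self.path_graph(5)
        d = MotifDistribution(counts={"2": 1.0}, n_samples=1)
        tc = trajectory_curvature([d, d, d], g, spacing=1)
        assert np.isnan(tc.curvatures).all()

    def test_too_short_series(self):
        g = self.path_graph(5)
        d = MotifDistribution(counts={"2": 1.0}, n_samples=1)
        with pytest.raises(InputError):
            trajectory_curvature([d, d], g, spacing=1)


class TestGroupPermutationTest:
    def two_blob_matrix(self, na=5, nb=5, gap=10.0, seed=0):
        rng = np.random.default_rng(seed)
        pts = np.vstack(
            [rng.normal(size=(na, 3)), rng.normal(size=(nb, 3)) + [gap, 0, 0]]
        )
        return dm_from_points(pts), ["a"] * na + ["b"] * nb

    def test_separated_groups_minimal_p(self):
        dm, labels = self.two_blob_matrix()
        res = group_permutation_test(dm, labels, n_perm=999, seed=1)
        p = res[("a", "b")]["p_value"]
        # all permutations recreating the true split (or its mirror) tie
        assert p <= 0.02
        assert res[("a", "b")]["statistic"] > 0

    def test_deterministic_given_seed(self):
        dm, labels = self.two_blob_matrix(seed=3)
        r1 = group_permutation_test(dm, labels, n_perm=199, seed=7)
        r2 = group_permutation_test(dm, labels, n_perm=199, seed=7)
        assert r1 == r2

    def test_null_p_values_roughly_uniform(self):
        """With labels assigned at random to i.i.d. samples the p-value is
        uniform; checked with a KS test over repeated label draws."""
        from scipy.stats import kstest

        rng = np.random.default_rng(5)
        pts = rng.normal(size=(10, 3))
        dm = dm_from_points(pts)
        ps = []
        for rep in range(200):
            labels = list("aaaaabbbbb")
            rng.shuffle(labels)
            res = group_permutation_test(dm, labels, n_perm=99, seed=1000 + rep)
            ps.append(res[("a", "b")]["p_value"])
        assert kstest(ps, "uniform").pvalue > 1e-3

    def test_small_group_excluded(self):
        dm, labels = self.two_blob_matrix(na=6, nb=4)
        labels = ["a"] * 6 + ["b"] * 3 + ["c"]
        with pytest.warns(UserWarning, match="excluded"):
            res = group_permutation_test(dm, labels, n_perm=99, seed=0)
        assert set(res) == {("a", "b")}

    def test_needs_two_groups(self):
        dm, _ = self.two_blob_matrix()
        with pytest.raises(InputError):
            group_permutation_test(dm, ["a"] * 10, n_perm=99, seed=0)


def test_convex_hull_membership():
    rng = np.random.default_rng(8)
    inner = rng.normal(size=(20, 3)) * 0.3
    outer = np.array([[5.0, 0, 0], [-5.0, 0, 0]])
    pts = np.vstack([inner, outer])
    emb = classical_mds(dm_from_points(pts), k=3)
    ref = np.zeros(22, dtype=bool)
    ref[:20] = True
    inside = convex_hull_membership(emb, ref)
    assert inside[:20].sum() >= 16  # hull vertices of the reference are inside
    assert not inside[20:].any()


def test_curvature_series_writer(tmp_path):
    from topopack.atlas import write_curvature_series
    from topopack import TrajectoryCurvature

    tc = TrajectoryCurvature(
        curvatures=np.array([0.5, np.nan]), indices=np.array([1, 2]), window=1
    )
    path = tmp_path / "curv.csv"
    write_curvature_series(tc, path)
    text = path.read_text()
    assert "index,curvature" in text and "1,0.5" in text and "nan" in text


def test_embedding_writer(tmp_path):
    rng = np.random.default_rng(9)
    emb = classical_mds(dm_from_points(rng.normal(size=(6, 3))), k=2)
    path = tmp_path / "emb.csv"
    write_embedding(emb, path)
    text = path.read_text()
    assert "pc1,pc2" in text
    assert text.count("\n") >= 8
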