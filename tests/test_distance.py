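"""Topological diffusion distance vs. the exact graph-W1 oracle."""

import dataclasses

import numpy as np
import pytest
import scipy.sparse as sp

from topopack import MotifDistribution, graph_from_edges, pairwise_distance, tdd, w1_oracle
from topopack.distance import DistanceMatrix, read_distance_matrix, write_distance_matrix
from topopack.errors import IllPosedError, InputError


def delta(name):
    return MotifDistribution(counts={name: 1}, n_samples=1)


def random_distribution(names, rng, support=None):
    support = support or max(2, len(names) // 2)
    chosen = rng.choice(len(names), size=min(support, len(names)), replace=False)
    w = rng.exponential(size=len(chosen))
    return MotifDistribution(
        counts={names[i]: float(x) for i, x in zip(chosen, w)}, n_samples=len(chosen)
    )


def random_tree(n, rng):
    edges = [(int(rng.integers(0, i)), i) for i in range(1, n)]
    return graph_from_edges([f"v{i}" for i in range(n)], edges)


def random_connected_graph(n, rng, extra=0.5):
    edges = [(int(rng.integers(0, i)), i) for i in range(1, n)]
    n_extra = int(extra * n)
    for _ in range(n_extra):
        i, j = rng.integers(0, n, size=2)
        if i != j:
            edges.append((int(min(i, j)), int(max(i, j))))
    return graph_from_edges([f"v{i}" for i in range(n)], edges)


PATH = graph_from_edges(["a", "b", "c"], [(0, 1), (1, 2)])
CYCLE5 = graph_from_edges(list("abcde"), [(0, 1), (1, 2), (2, 3), (3, 4), (4, 0)])


class TestFixtures:
    def test_identical_distributions_zero(self):
        r = delta("b")
        assert tdd(r, r, PATH) == 0.0
        assert w1_oracle(r, r, PATH) == pytest.approx(0.0, abs=1e-10)

    def test_path_graph_unique_flow(self):
        """On a tree the feasible flow is unique: two hops of unit mass."""
        assert tdd(delta("a"), delta("c"), PATH) == pytest.approx(2.0, abs=1e-10)
        assert w1_oracle(delta("a"), delta("c"), PATH) == pytest.approx(2.0, abs=1e-8)

    def test_five_cycle_electrical_split(self):
        """The diffusion flow splits 4/5 direct and 1/5 the long way (8/5);
        optimal transport sends everything along the direct edge (1)."""
        t = tdd(delta("a"), delta("b"), CYCLE5)
        w = w1_oracle(delta("a"), delta("b"), CYCLE5)
        assert t == pytest.approx(8 / 5, abs=1e-10)
        assert w == pytest.approx(1.0, abs=1e-8)
        assert t > w + 0.5


class TestOracleRelation:
    def test_tree_equality(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            g = random_tree(int(rng.integers(3, 40)), rng)
            a = random_distribution(g.vertices, rng)
            b = random_distribution(g.vertices, rng)
            assert tdd(a, b, g) == pytest.approx(w1_oracle(a, b, g), abs=1e-8)

    def test_upper_bound_on_graphs(self):
        rng = np.random.default_rng(43)
        for _ in range(25):
            g = random_connected_graph(int(rng.integers(4, 30)), rng)
            a = random_distribution(g.vertices, rng)
            b = random_distribution(g.vertices, rng)
            assert tdd(a, b, g) >= w1_oracle(a, b, g) - 1e-8


class TestDiffusionFlow:
    def test_mass_conservation(self):
        """The diffusion flow is feasible: D^T (D L+ delta) = delta."""
        rng = np.random.default_rng(44)
        from topopack.distance import _as_vector, _solver

        for _ in range(10):
            g = random_connected_graph(int(rng.integers(4, 40)), rng)
            a = random_distribution(g.vertices, rng)
            b = random_distribution(g.vertices, rng)
            d = _as_vector(a, g) - _as_vector(b, g)
            phi = _solver(g).solve(d)
            flow = g.incidence @ phi
            assert np.allclose(g.incidence.T @ flow, d, atol=1e-8)

    def test_orientation_invariance(self):
        """Negating any subset of incidence rows leaves the TDD unchanged."""
        rng = np.random.default_rng(45)
        g = random_connected_graph(20, rng)
        a = random_distribution(g.vertices, rng)
        b = random_distribution(g.vertices, rng)
        base = tdd(a, b, g)
        signs = np.where(rng.random(g.n_edges) < 0.5, -1.0, 1.0)
        D2 = sp.diags(signs) @ g.incidence
        g2 = dataclasses.replace(
            g, incidence=D2.tocsr(), laplacian=(D2.T @ D2).tocsc()
        )
        assert tdd(a, b, g2) == pytest.approx(base, abs=1e-10)

    def test_vertex_permutation_equivariance(self):
        rng = np.random.default_rng(46)
        g = random_connected_graph(15, rng)
        a = random_distribution(g.vertices, rng)
        b = random_distribution(g.vertices, rng)
        perm = rng.permutation(g.n_vertices)
        names = [g.vertices[i] for i in perm]
        inv = np.empty_like(perm)
        inv[perm] = np.arange(len(perm))
        edges2 = [(int(inv[i]), int(inv[j])) for i, j in g.edges]
        g2 = graph_from_edges(names, edges2)
        assert tdd(a, b, g2) == pytest.approx(tdd(a, b, g), abs=1e-10)


class TestMetricAxioms:
    def test_symmetry_identity_triangle(self):
        rng = np.random.default_rng(47)
        g = random_connected_graph(25, rng)
        dists = [random_distribution(g.vertices, rng) for _ in range(6)]
        for i in range(6):
            assert tdd(dists[i], dists[i], g) == 0.0
            for j in range(i + 1, 6):
                dij = tdd(dists[i], dists[j], g)
                assert dij == pytest.approx(tdd(dists[j], dists[i], g), abs=1e-10)
                for k in range(6):
                    if k in (i, j):
                        continue
                    assert dij <= tdd(dists[i], dists[k], g) + tdd(
                        dists[k], dists[j], g
                    ) + 1e-8


class TestDisconnected:
    def test_imbalanced_mass_raises(self):
        g = graph_from_edges(["a", "b", "c", "d"], [(0, 1), (2, 3)])
        with pytest.raises(IllPosedError, match="disconnected"):
            tdd(delta("a"), delta("c"), g)

    def test_balanced_components_solve_independently(self):
        g = graph_from_edges(["a", "b", "c", "d"], [(0, 1), (2, 3)])
        ra = MotifDistribution(counts={"a": 1, "c": 1}, n_samples=2)
        rb = MotifDistribution(counts={"b": 1, "d": 1}, n_samples=2)
        assert tdd(ra, rb, g) == pytest.approx(1.0, abs=1e-10)


class TestPairwise:
    def test_copies_give_zero_matrix(self):
        rng = np.random.default_rng(48)
        g = random_connected_graph(12, rng)
        d = random_distribution(g.vertices, rng)
        dm = pairwise_distance([d, d, d], graph=g)
        assert np.all(dm.values == 0)

    def test_permutation_of_inputs_permutes_matrix(self):
        rng = np.random.default_rng(49)
        g = random_connected_graph(12, rng)
        ds = [random_distribution(g.vertices, rng) for _ in range(4)]
        dm = pairwise_distance(ds, graph=g, labels=list("wxyz"))
        perm = [2, 0, 3, 1]
        dm2 = pairwise_distance(
            [ds[i] for i in perm], graph=g, labels=[dm.labels[i] for i in perm]
        )
        assert np.allclose(dm2.values, dm.values[np.ix_(perm, perm)])

    def test_w1_method(self):
        dm = pairwise_distance(
            [delta("a"), delta("b"), delta("c")], method="W1", graph=PATH
        )
        assert dm.values[0, 2] == pytest.approx(2.0, abs=1e-8)
        assert dm.method == "W1"

    def test_requires_two(self):
        with pytest.raises(InputError):
            pairwise_distance([delta("a")], graph=PATH)


def test_dropped_mass_warns():
    r_in = delta("a")
    r_out = MotifDistribution(counts={"a": 1, "zzz": 1}, n_samples=2)
    with pytest.warns(UserWarning, match="mass"):
        tdd(r_in, r_out, PATH)


def test_distance_matrix_roundtrip(tmp_path):
    rng = np.random.default_rng(50)
    g = random_connected_graph(10, rng)
    ds = [random_distribution(g.vertices, rng) for _ in range(3)]
    dm = pairwise_distance(ds, graph=g, labels=["s1", "s2", "s3"])
    path = tmp_path / "dm.csv"
    write_distance_matrix(dm, path)
    back = read_distance_matrix(path)
    assert back.labels == dm.labels
    assert back.method == dm.method
    assert np.allclose(back.values, dm.values, atol=1e-15)


def test_distance_matrix_validation():
    with pytest.raises(InputError):
        DistanceMatrix(labels=("a", "b"), values=np.array([[0.0, 1.0], [2.0, 0.0]]))
    with pytest.raises(InputError):
        DistanceMatrix(labels=("a", "b"), values=np.array([[1.0, 0.0], [0.0, 0.0]]))
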