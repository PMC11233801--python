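"""Supra-adjacency assembly, thresholding, Q/MPC/LLC metrics."""

import itertools

import numpy as np
import pytest

from mdbn.connectivity import ConnMatrix
from mdbn.multilayer import (
    SupraAdjacency,
    apply_threshold,
    assemble_supra,
    layer_correlation,
    modularity_sweep,
    multilayer_modularity,
    multiplex_participation,
    partition_quality,
    pool_threshold,
)


def _sym(rng, n):
    v = rng.uniform(0, 1, (n, n))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0)
    return v


def _supra_from_blocks(intra_blocks, inter_value=0.0):
    """Supra matrix with given intra-layer blocks and constant inter blocks."""
    L = len(intra_blocks)
    C = intra_blocks[0].shape[0]
    intra = [ConnMatrix(b, (l, l)) for l, b in enumerate(intra_blocks)]
    inter = [
        ConnMatrix(np.full((C, C), inter_value), (l, m))
        for l in range(L) for m in range(l + 1, L)
    ]
    return assemble_supra(intra, inter)


class TestAssemble:
    def test_blocks_round_trip(self, rng):
        C, L = 3, 2
        a0, a1 = _sym(rng, C), _sym(rng, C)
        h = rng.uniform(0, 1, (C, C))
        s = assemble_supra(
            [ConnMatrix(a0, (0, 0)), ConnMatrix(a1, (1, 1))],
            [ConnMatrix(h, (0, 1))],
        )
        assert s.values.shape == (6, 6)
        np.testing.assert_array_equal(s.block(0, 0), a0)
        np.testing.assert_array_equal(s.block(1, 1), a1)
        np.testing.assert_array_equal(s.block(0, 1), h)
        np.testing.assert_array_equal(s.block(1, 0), h.T)

    def test_zero_inter_gives_block_diagonal(self, rng):
        s = _supra_from_blocks([_sym(rng, 3), _sym(rng, 3)])
        assert not s.block(0, 1).any()
        assert np.allclose(s.values, s.values.T)

    def test_missing_block_rejected(self, rng):
        with pytest.raises(ValueError, match="missing inter-layer"):
            assemble_supra(
                [ConnMatrix(_sym(rng, 3), (0, 0)), ConnMatrix(_sym(rng, 3), (1, 1))],
                [],
            )


class TestThreshold:
    def test_constant_pool_quantile(self):
        v = np.full((4, 4), 0.3)
        np.fill_diagonal(v, 0)
        s = SupraAdjacency(v, 2, 2)
        assert pool_threshold([s], 0.95) == pytest.approx(0.3)

    def test_uniform_grid_quantile(self):
        # 105 upper-triangle slots on a 15x15 supra; fill first 100 with the
        # grid 0.01..1.00 and give the rest mid values
        n = 15
        grid = np.concatenate([np.arange(1, 101) / 100.0, np.full(5, 0.5)])
        v = np.zeros((n, n))
        v[np.triu_indices(n, k=1)] = grid
        v = v + v.T
        s = SupraAdjacency(v, 5, 3)
        thr = pool_threshold([s], 0.95)
        assert abs(thr - 0.95) <= 0.02

    def test_condition_order_invariance(self, rng):
        supras = [
            SupraAdjacency(_sym(rng, 6), 3, 2) for _ in range(3)
        ]
        assert pool_threshold(supras, 0.9) == pool_threshold(supras[::-1], 0.9)

    def test_apply_threshold_limits(self, rng):
        s = SupraAdjacency(_sym(rng, 6), 3, 2)
        np.testing.assert_array_equal(apply_threshold(s, 0.0).values, s.values)
        assert not apply_threshold(s, 1.0 + 1e-9).values.any()

    def test_surviving_edges_keep_weights_and_count(self, rng):
        s = SupraAdjacency(_sym(rng, 8), 4, 2)
        thr = 0.5
        out = apply_threshold(s, thr)
        iu = np.triu_indices(8, k=1)
        expected = sum(1 for v in s.values[iu] if v >= thr)
        assert (out.values[iu] > 0).sum() == expected
        surviving = out.values[iu][out.values[iu] > 0]
        assert set(np.round(surviving, 12)) <= set(np.round(s.values[iu], 12))


# ---------------------------------------------------------------------------
# Multilayer modularity
# ---------------------------------------------------------------------------

def _set_partitions(items):
    """All set partitions (restricted growth strings)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in _set_partitions(rest):
        for i, subset in enumerate(smaller):
            yield smaller[:i] + [[first] + subset] + smaller[i + 1:]
        yield [[first]] + smaller


def _newman_q(A, labels, gamma=1.0):
    """Direct single-layer modularity from the definition."""
    k = A.sum(axis=1)
    two_m = k.sum()
    q = 0.0
    n = len(A)
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += A[i, j] - gamma * k[i] * k[j] / two_m
    return q / two_m


def _two_cliques():
    """Two unit-weight 4-cliques joined by one weak edge."""
    A = np.zeros((8, 8))
    for group in ([0, 1, 2, 3], [4, 5, 6, 7]):
        for i, j in itertools.combinations(group, 2):
            A[i, j] = A[j, i] = 1.0
    A[3, 4] = A[4, 3] = 0.1
    return A


class TestModularity:
    def test_one_community_single_layer_q_is_zero(self, rng):
        A = _sym(rng, 6)
        s = SupraAdjacency(A, 6, 1)
        q = partition_quality(s, np.zeros((1, 6), dtype=int), gamma=1.0, omega=1.0)
        assert q == pytest.approx(0.0, abs=1e-12)

    def test_two_cliques_match_exhaustive_search(self):
        A = _two_cliques()
        s = SupraAdjacency(A, 8, 1)
        part = multilayer_modularity(s, gamma=1.0, omega=1.0, n_restarts=20, seed=3)
        # brute force over all 4140 partitions of 8 nodes
        best_q, best_labels = -np.inf, None
        for p in _set_partitions(list(range(8))):
            labels = np.empty(8, dtype=int)
            for cid, members in enumerate(p):
                labels[members] = cid
            q = _newman_q(A, labels)
            if q > best_q:
                best_q, best_labels = q, labels
        assert part.q == pytest.approx(best_q, abs=1e-10)
        found = part.assignment[0]
        assert len(set(found[:4])) == 1 and len(set(found[4:])) == 1
        assert found[0] != found[4]
        assert len(set(best_labels[:4])) == 1 and best_labels[0] != best_labels[4]

    def test_identical_layers_consistent_labels(self, rng):
        A = _two_cliques()
        s = _supra_from_blocks([A, A, A])
        part = multilayer_modularity(s, omega=1.0, n_restarts=10, seed=0)
        for node in range(8):
            assert len(set(part.assignment[:, node])) == 1

    def test_omega_zero_matches_single_layer(self, rng):
        A = _two_cliques()
        s_multi = _supra_from_blocks([A, A, A])
        s_single = SupraAdjacency(A, 8, 1)
        q_multi = multilayer_modularity(s_multi, omega=0.0, n_restarts=10, seed=1).q
        q_single = multilayer_modularity(s_single, omega=0.0, n_restarts=10, seed=1).q
        # identical layers, no coupling: per-layer structure dominates and
        # the 2mu-normalized aggregate equals the single-layer value
        assert q_multi == pytest.approx(q_single, abs=1e-6)

    def test_found_q_beats_trivial_partitions(self, rng):
        A = _sym(rng, 10)
        s = _supra_from_blocks([A, _sym(rng, 10)])
        part = multilayer_modularity(s, n_restarts=10, seed=2)
        singletons = np.arange(20).reshape(2, 10)
        one_comm = np.zeros((2, 10), dtype=int)
        assert part.q >= partition_quality(s, singletons) - 1e-12
        assert part.q >= partition_quality(s, one_comm) - 1e-12

    def test_empty_network_rejected(self):
        s = SupraAdjacency(np.zeros((8, 8)), 4, 2)
        with pytest.raises(ValueError, match="empty"):
            multilayer_modularity(s, omega=0.0)


class TestModularitySweep:
    def test_grid_shape_and_consistency(self, rng):
        s = _supra_from_blocks([_two_cliques(), _two_cliques()])
        df = modularity_sweep(s, gammas=[0.5, 1.0], omegas=[0.5, 1.0],
                              n_restarts=5, seed=4)
        assert len(df) == 4
        ref = multilayer_modularity(s, 1.0, 1.0, n_restarts=5, seed=4).q
        cell = df[(df["gamma"] == 1.0) & (df["omega"] == 1.0)]["Q"].iloc[0]
        assert cell == pytest.approx(ref)
        assert (df["n_communities"] >= 1).all()


class TestMPC:
    def _supra_with_degrees(self, degree_per_layer, n=6):
        """Node 0 connected to the first k nodes in each layer."""
        blocks = []
        for k in degree_per_layer:
            b = np.zeros((n, n))
            for j in range(1, k + 1):
                b[0, j] = b[j, 0] = 0.8
            blocks.append(b)
        return _supra_from_blocks(blocks)

    def test_equal_degree_gives_one(self):
        s = self._supra_with_degrees([3, 3])
        mpc, _ = multiplex_participation(s)
        assert mpc[0] == pytest.approx(1.0)

    def test_single_layer_degree_gives_zero(self):
        s = self._supra_with_degrees([2, 0, 0])
        mpc, _ = multiplex_participation(s)
        assert mpc[0] == pytest.approx(0.0)

    def test_unbalanced_degrees_hand_value(self):
        # degrees (1, 3): o=4, sum of squares 10/16, MPC = 2*(1-10/16) = 0.75
        s = self._supra_with_degrees([1, 3])
        mpc, _ = multiplex_participation(s)
        assert mpc[0] == pytest.approx(0.75)

    def test_isolated_node_and_range(self, rng):
        s = _supra_from_blocks([_sym(rng, 6) > 0.5, _sym(rng, 6) > 0.5])
        mpc, mean = multiplex_participation(s)
        assert ((mpc >= 0) & (mpc <= 1)).all()
        assert 0 <= mean <= 1

    def test_single_layer_rejected(self, rng):
        with pytest.raises(ValueError, match="2 layers"):
            multiplex_participation(SupraAdjacency(_sym(rng, 4), 4, 1))


class TestLLC:
    def test_self_correlation_is_one(self, rng):
        A = _sym(rng, 5)
        R = layer_correlation(_supra_from_blocks([A, A.copy()]))
        assert R[0, 1] == pytest.approx(1.0)
        np.testing.assert_allclose(np.diag(R), 1.0)

    def test_affine_invariance(self, rng):
        A = _sym(rng, 5) * 0.4
        B = 2 * A + 0.1
        np.fill_diagonal(B, 0)
        R = layer_correlation(_supra_from_blocks([A, B]))
        assert R[0, 1] == pytest.approx(1.0)

    def test_hand_computed_anticorrelation(self):
        a = np.zeros((3, 3))
        a[np.triu_indices(3, 1)] = [0.1, 0.2, 0.3]
        a = a + a.T
        b = np.zeros((3, 3))
        b[np.triu_indices(3, 1)] = [0.3, 0.2, 0.1]
        b = b + b.T
        R = layer_correlation(_supra_from_blocks([a, b]))
        assert R[0, 1] == pytest.approx(-1.0)

    def test_zero_variance_block_flagged(self, rng):
        R = layer_correlation(_supra_from_blocks([np.zeros((4, 4)), _sym(rng, 4)]))
        assert np.isnan(R[0, 1])
        assert R[0, 0] == 1.0

    def test_symmetric_with_bounded_entries(self, rng):
        blocks = [_sym(rng, 6) for _ in range(4)]
        R = layer_correlation(_supra_from_blocks(blocks))
        np.testing.assert_allclose(R, R.T)
        assert np.nanmax(np.abs(R)) <= 1 + 1e-12
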