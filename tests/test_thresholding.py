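import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neomux import (
    WeightedConnectome,
    consistency_threshold,
    make_density_grid,
    proportional_threshold,
)
from neomux.thresholding import round_half_up

from oracles import consistency_ranking_oracle


def _conn(w, labels=None, modality="SC"):
    n = w.shape[0]
    labels = labels or [f"n{i:03d}" for i in range(n)]
    hemi = ["L"] * (n // 2) + ["R"] * (n - n // 2)
    return WeightedConnectome(node_labels=labels, hemisphere=hemi,
                              weights=w, modality=modality)


def _sym(vals, n):
    w = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    w[iu] = vals
    return w + w.T


class TestDensityGrid:
    def test_default_grid_has_14_equally_graded_levels(self):
        grid = make_density_grid()
        assert len(grid) == 14
        d = grid.as_array()
        assert d[0] == pytest.approx(0.05)
        assert d[-1] == pytest.approx(0.70)
        assert np.allclose(np.diff(d), 0.05)

    def test_degenerate_single_level(self):
        grid = make_density_grid(0.3, 0.3, 0.05)
        assert list(grid) == [0.3]

    def test_explicit_enumeration(self):
        grid = make_density_grid(0.1, 0.4, 0.1)
        assert list(grid) == pytest.approx([0.1, 0.2, 0.3, 0.4])

    @pytest.mark.parametrize("start,stop,step", [
        (0.1, 0.45, 0.1),   # step does not divide span
        (0.0, 0.5, 0.1),    # start not positive
        (0.2, 0.1, 0.05),   # decreasing
        (0.5, 1.2, 0.1),    # stop beyond 1
    ])
    def test_nonconforming_spans_rejected(self, start, stop, step):
        with pytest.raises(ValueError):
            make_density_grid(start, stop, step)


class TestProportionalThreshold:
    def test_keeps_the_k_strongest_edges(self, rng):
        vals = rng.permutation([10.0, 9.0, 8.0, 3.0, 2.0, 1.0])
        conn = _conn(_sym(vals, 4))
        net = proportional_threshold(conn, 0.5)
        assert net.k == 3
        iu = np.triu_indices(4, 1)
        kept = set(np.flatnonzero(net.adjacency[iu]))
        top3 = set(np.argsort(-vals)[:3])
        assert kept == top3

    def test_full_density_gives_complete_graph(self, rng):
        conn = _conn(_sym(rng.random(6), 4))
        net = proportional_threshold(conn, 1.0)
        assert net.k == 6
        assert net.adjacency.sum() == 4 * 3

    def test_tie_break_is_lexicographic_and_reproducible(self):
        conn = _conn(_sym(np.ones(6), 4), labels=["a", "b", "c", "d"])
        net1 = proportional_threshold(conn, 0.5)
        net2 = proportional_threshold(conn, 0.5)
        assert net1.edge_set() == {("a", "b"), ("a", "c"), ("a", "d")}
        assert np.array_equal(net1.adjacency, net2.adjacency)

    def test_zero_edge_request_rejected(self, rng):
        conn = _conn(_sym(rng.random(6), 4))
        with pytest.raises(ValueError, match="retains no edges"):
            proportional_threshold(conn, 0.05)

    def test_realized_density_is_exact(self, rng):
        n = 10
        conn = _conn(_sym(rng.random(45), n))
        for d in (0.2, 0.5, 0.8):
            net = proportional_threshold(conn, d)
            assert net.k == round_half_up(d * 45)
            iu = np.triu_indices(n, 1)
            assert net.adjacency[iu].sum() == net.k


class TestConsistencyThreshold:
    def test_hand_cv_oracle(self):
        # pairs on 3 nodes: e=(a,b), f=(a,c), g=(b,c)
        rows = [[2.0, 1.0, 0.0], [2.0, 2.0, 0.0], [2.0, 3.0, 6.0]]
        cohort = [_conn(_sym(np.array(r), 3), labels=["a", "b", "c"])
                  for r in rows]
        # CVs: e = 0, f = 0.5, g = sqrt(12)/2; keep 2 -> {e, f}
        net = consistency_threshold(cohort, 0.6)
        assert net.k == 2
        assert net.edge_set() == {("a", "b"), ("a", "c")}

    def test_identical_subjects_fall_back_to_lexicographic(self):
        w = _sym(np.array([1.0, 1.0, 1.0, 1.0, 1.0, 1.0]), 4)
        cohort = [_conn(w, labels=["a", "b", "c", "d"]) for _ in range(3)]
        net = consistency_threshold(cohort, 0.5)
        assert net.edge_set() == {("a", "b"), ("a", "c"), ("a", "d")}

    def test_one_hot_edge_has_cv_sqrt_n_and_is_excluded(self):
        n_subj = 6
        # edge f present in exactly one subject; edge e in all
        rows = []
        for s in range(n_subj):
            e, f, g = 5.0, (6.0 if s == 0 else 0.0), 4.0
            rows.append(_conn(_sym(np.array([e, f, g]), 3),
                              labels=["a", "b", "c"]))
        x = np.vstack([c.triu_values() for c in rows])
        mu, sd = x.mean(0), x.std(0, ddof=1)
        assert sd[1] / mu[1] == pytest.approx(math.sqrt(n_subj))
        net = consistency_threshold(rows, 0.6)
        assert net.edge_set() == {("a", "b"), ("b", "c")}

    def test_invariant_to_subject_order(self, rng):
        cohort = [_conn(_sym(rng.random(28), 8)) for _ in range(6)]
        net1 = consistency_threshold(cohort, 0.3)
        perm = [cohort[i] for i in rng.permutation(6)]
        net2 = consistency_threshold(perm, 0.3)
        assert np.array_equal(net1.adjacency, net2.adjacency)

    def test_mixed_modalities_rejected(self, rng):
        a = _conn(_sym(rng.random(6), 4), modality="SC")
        b = _conn(_sym(rng.random(6), 4), modality="FC")
        with pytest.raises(ValueError, match="mix"):
            consistency_threshold([a, b], 0.5)

    def test_matches_bruteforce_ranking_oracle(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 9))
            n_subj = int(rng.integers(3, 7))
            labels = [f"n{i:03d}" for i in range(n)]
            cohort = [
                _conn(_sym(rng.random(n * (n - 1) // 2) *
                           (rng.random(n * (n - 1) // 2) > 0.2), n),
                      labels=labels)
                for _ in range(n_subj)
            ]
            x = [list(c.triu_values()) for c in cohort]
            ranking = consistency_ranking_oracle(x, labels)
            net = consistency_threshold(cohort, 0.5)
            iu = np.triu_indices(n, 1)
            kept = set(np.flatnonzero(net.adjacency[iu]))
            assert kept == set(ranking[: net.k])


class TestProportionalProperties:
    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        vals=st.lists(st.floats(0, 100, allow_nan=False), min_size=15,
                      max_size=15),
        d=st.sampled_from([0.1, 0.25, 0.5, 0.75, 1.0]),
    )
    def test_edge_count_and_nesting_for_arbitrary_weights(self, vals, d):
        # n=6 -> M=15; any weight vector (ties, zeros included) must give
        # exactly k edges, and lower densities must nest in higher ones
        conn = _conn(_sym(np.array(vals), 6))
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            net = proportional_threshold(conn, d)
            assert net.k == round_half_up(d * 15)
            iu = np.triu_indices(6, 1)
            assert net.adjacency[iu].sum() == net.k
            if d > 0.1:
                smaller = proportional_threshold(conn, 0.1)
                assert smaller.edge_set() <= net.edge_set()


class TestNestedness:
    def test_edge_sets_nested_across_grid(self, rng):
        grid = make_density_grid(0.1, 0.7, 0.1)
        conn = _conn(_sym(rng.random(45), 10))
        cohort = [_conn(_sym(rng.random(45), 10)) for _ in range(5)]
        prev_prop, prev_cons = set(), set()
        for d in grid:
            ep = proportional_threshold(conn, d).edge_set()
            ec = consistency_threshold(cohort, d).edge_set()
            assert prev_prop <= ep
            assert prev_cons <= ec
            prev_prop, prev_cons = ep, ec
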