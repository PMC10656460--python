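import dataclasses
import math

import numpy as np
import pytest

from chainsim.anchors import Anchor, ChainTask
from chainsim.chaining import (
    NO_PARENT,
    UNBOUNDED,
    ChainingParams,
    backtrack_chains,
    brute_force_best_score,
    chain_scores,
    chain_scores_subpartitioned,
    task_mean_span,
    transition_score,
)
from conftest import make_random_task

A = Anchor


@pytest.fixture
def crafted3():
    """A0 -> A2 is the good colinear jump; A1 sits just off the diagonal
    and captures the lookback at H=1."""
    return ChainTask("c3", (A(100, 100, 15), A(150, 101, 15), A(200, 200, 15)))


class TestTransitionScore:
    def test_colinear(self, exact_params):
        s = transition_score(A(100, 100, 15), A(200, 200, 15), exact_params, 15)
        assert s == 15.0

    def test_gap_cost(self, exact_params):
        s = transition_score(A(100, 100, 15), A(130, 120, 15), exact_params, 15)
        expected = 15 - (0.01 * 15 * 10 + 0.5 * math.log2(10))
        assert s == pytest.approx(expected, abs=1e-12)
        assert s == pytest.approx(11.839, abs=1e-3)

    @pytest.mark.parametrize(
        "a_j,a_i",
        [
            (A(100, 100, 15), A(150, 100, 15)),  # y not strictly increasing
            (A(100, 100, 15), A(100, 150, 15)),  # x not strictly increasing
            (A(100, 150, 15), A(150, 100, 15)),  # y decreases
        ],
    )
    def test_ineligible_monotonicity(self, a_j, a_i, exact_params):
        assert transition_score(a_j, a_i, exact_params, 15) is None

    def test_ineligible_distance(self):
        p = ChainingParams(max_dist_x=40, max_dist_y=40)
        assert transition_score(A(100, 100, 15), A(150, 110, 15), p, 15) is None
        assert transition_score(A(100, 100, 15), A(110, 150, 15), p, 15) is None

    def test_ineligible_bandwidth(self):
        p = ChainingParams(bandwidth=5)
        assert transition_score(A(100, 100, 15), A(200, 150, 15), p, 15) is None

    def test_alpha_capped_by_span(self, exact_params):
        # advances 100/100, but span caps alpha at w_i
        s = transition_score(A(100, 100, 15), A(200, 200, 9), exact_params, 15)
        assert s == 9.0


class TestChainScores:
    def test_empty_task(self, exact_params):
        dp = chain_scores(ChainTask("e", ()), exact_params)
        assert dp.n == 0 and dp.best_score() is None

    def test_single_anchor(self, exact_params):
        dp = chain_scores(ChainTask("s", (A(50, 50, 15),)), exact_params)
        assert dp.f.tolist() == [15.0]
        assert dp.parent.tolist() == [NO_PARENT]
        assert dp.trip_count.tolist() == [0]

    def test_two_colinear(self, exact_params):
        task = ChainTask("t", (A(100, 100, 15), A(200, 200, 15)))
        dp = chain_scores(task, exact_params)
        assert dp.f.tolist() == [15.0, 30.0]
        assert dp.parent.tolist() == [NO_PARENT, 0]

    def test_crafted3_exact_vs_H1(self, crafted3, exact_params):
        dp = chain_scores(crafted3, exact_params)
        assert dp.f.tolist() == [15.0, 15.0, 30.0]
        assert dp.parent[2] == 0
        dp1 = chain_scores(crafted3, dataclasses.replace(exact_params, H=1))
        expected = 15 + 15 - (0.01 * 15 * 49 + 0.5 * math.log2(49))
        assert dp1.f[1] == 15.0
        assert dp1.f[2] == pytest.approx(expected, abs=1e-9)
        assert brute_force_best_score(crafted3, exact_params) == 30.0

    def test_f_at_least_span(self, planted_batch, exact_params):
        for task in planted_batch:
            dp = chain_scores(task, exact_params)
            ws = np.array([a.w for a in task.anchors], dtype=float)
            assert np.all(dp.f >= ws)
            assert np.all(dp.parent < np.arange(task.n))

    def test_trip_count_bounds(self, planted_batch):
        for task in planted_batch:
            for H in (1, 7, 64):
                dp = chain_scores(task, ChainingParams(H=H))
                i = np.arange(task.n)
                assert np.all(dp.trip_count <= np.minimum(i, H))

    def test_trip_count_unbounded_equals_window(self, planted_batch, exact_params):
        for task in planted_batch:
            dp = chain_scores(task, exact_params)
            xs = np.array([a.x for a in task.anchors])
            st = np.searchsorted(xs, xs - exact_params.max_dist_x, side="left")
            assert np.array_equal(dp.trip_count, np.arange(task.n) - st)

    def test_oracle_equivalence(self, exact_params):
        rng = np.random.default_rng(11)
        for trial in range(60):
            task = make_random_task(rng, int(rng.integers(1, 128)), coord_range=8000)
            dp = chain_scores(task, exact_params)
            assert dp.best_score() == brute_force_best_score(task, exact_params)

    def test_h_monotone_and_convergence(self, planted_batch, exact_params):
        for task in planted_batch:
            prev = None
            for H in (1, 4, 16, 64, 512):
                f = chain_scores(task, dataclasses.replace(exact_params, H=H)).f
                if prev is not None:
                    assert np.all(f >= prev - 1e-12)
                prev = f
            exact = chain_scores(task, exact_params)
            conv = chain_scores(
                task, dataclasses.replace(exact_params, H=max(1, task.n - 1))
            )
            assert np.array_equal(conv.f, exact.f)
            assert np.array_equal(conv.parent, exact.parent)
            assert np.array_equal(conv.trip_count, exact.trip_count)

    def test_nearest_predecessor_tie_break(self, exact_params):
        # two equally good colinear predecessors: the nearer (larger j) wins
        task = ChainTask("tie", (A(100, 110, 15), A(110, 100, 15), A(200, 200, 15)))
        dp = chain_scores(task, exact_params)
        assert dp.parent[2] == 1


class TestSubpartitioned:
    def test_unbounded_rejected(self, crafted3, exact_params):
        with pytest.raises(ValueError, match="finite"):
            chain_scores_subpartitioned(crafted3, exact_params)

    def test_empty(self, params):
        dp = chain_scores_subpartitioned(ChainTask("e", ()), params)
        assert dp.n == 0 and dp.subparts is not None and len(dp.subparts) == 0

    def test_p_ge_h_single_subpart(self, planted_batch):
        p = ChainingParams(H=16, P=16)
        for task in planted_batch:
            ref = chain_scores(task, p)
            got = chain_scores_subpartitioned(task, p)
            assert np.array_equal(got.f, ref.f)
            assert np.all(got.subparts <= 1)

    @pytest.mark.parametrize("P", [1, 2, 8, 64, 1024])
    def test_equivalence_across_P(self, P):
        rng = np.random.default_rng(7)
        task = make_random_task(rng, 200, coord_range=15_000)
        p = ChainingParams(H=64, P=P)
        ref = chain_scores(task, p)
        got = chain_scores_subpartitioned(task, p)
        assert np.array_equal(got.f, ref.f)
        assert np.array_equal(got.parent, ref.parent)
        assert np.array_equal(got.trip_count, ref.trip_count)

    def test_subpart_counts(self):
        rng = np.random.default_rng(8)
        task = make_random_task(rng, 50, coord_range=4000)
        p = ChainingParams(H=16, P=5)
        got = chain_scores_subpartitioned(task, p)
        expected = np.ceil(got.trip_count / p.P).astype(np.int64)
        assert np.array_equal(got.subparts, expected)


class TestBacktrack:
    def test_filter_all_below_min_score(self, crafted3, exact_params):
        dp = chain_scores(crafted3, exact_params)
        strict = dataclasses.replace(exact_params, min_score=1000.0)
        assert backtrack_chains(crafted3, dp, strict) == []

    def test_two_colinear_single_chain(self):
        p = ChainingParams(H=UNBOUNDED, min_score=0.0, min_cnt=1)
        task = ChainTask("t", (A(100, 100, 15), A(200, 200, 15)))
        dp = chain_scores(task, p)
        chains = backtrack_chains(task, dp, p)
        assert len(chains) == 1
        assert chains[0].anchor_indices == (0, 1)
        assert chains[0].score == 30.0

    def test_two_planted_chains_disjoint(self):
        p = ChainingParams(H=UNBOUNDED, min_score=0.0, min_cnt=1)
        near = [A(100 + 15 * i, 100 + 15 * i, 15) for i in range(10)]
        far = [A(50_000 + 15 * i, 50_000 + 15 * i, 15) for i in range(8)]
        task = ChainTask("t", tuple(near + far))
        dp = chain_scores(task, p)
        chains = backtrack_chains(task, dp, p)
        assert len(chains) == 2
        got = sorted(chains, key=lambda c: c.anchor_indices[0])
        assert got[0].anchor_indices == tuple(range(10))
        assert got[1].anchor_indices == tuple(range(10, 18))

    def test_disjoint_and_filters(self, planted_batch):
        p = ChainingParams(H=UNBOUNDED, min_score=20.0, min_cnt=2)
        for task in planted_batch:
            dp = chain_scores(task, p)
            chains = backtrack_chains(task, dp, p)
            seen = set()
            for c in chains:
                assert c.score >= p.min_score
                assert c.n_anchors >= p.min_cnt
                assert list(c.anchor_indices) == sorted(c.anchor_indices)
                assert not (seen & set(c.anchor_indices))
                seen.update(c.anchor_indices)
            scores = [c.score for c in chains]
            assert scores == sorted(scores, reverse=True)


def test_mean_span():
    assert task_mean_span(ChainTask("e", ())) == 1
    task = ChainTask("t", (A(10, 10, 10), A(20, 20, 11)))
    assert task_mean_span(task) == 10  # mean 10.5 rounds to nearest even -> 10
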