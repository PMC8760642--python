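import itertools
import math

import numpy as np
import pytest

from stratacause import (
    DiscordantCounts,
    adaptive_bh,
    build_pairs,
    mcnemar_yates,
    run_qed,
    stratum_outcome,
)
from stratacause.qed import count_discordant


class TestStratumOutcome:
    def test_single_positive_stratum_equals_global_outcome(self):
        R = np.array([1, 1, -1, -1])
        strata = np.array([0, 0, 1, 1])
        np.testing.assert_array_equal(stratum_outcome(strata, R, 0), R)

    def test_other_positive_strata_labelled_negative(self):
        R = np.array([1, 1, 1, 1, -1, -1])
        strata = np.array([0, 0, 1, 1, 2, 2])
        y = stratum_outcome(strata, R, 0)
        np.testing.assert_array_equal(y, [1, 1, -1, -1, -1, -1])

    def test_each_positive_sample_positive_in_exactly_one_stratum(self):
        R = np.array([1, 1, 1, 1, -1, -1])
        strata = np.array([0, 1, 0, 1, 2, 2])
        ys = np.stack([stratum_outcome(strata, R, k) for k in (0, 1)])
        assert ((ys == 1).sum(axis=0)[R == 1] == 1).all()

    def test_negative_stratum_rejected(self):
        R = np.array([1, -1, -1, -1])
        strata = np.array([0, 1, 1, 1])
        with pytest.raises(ValueError, match="positive majority"):
            stratum_outcome(strata, R, 1)


def brute_force_min_cost(cost):
    """Minimum total cost over all maximal matchings of a rectangular
    cost matrix (the smaller side fully matched)."""
    t, u = cost.shape
    transposed = False
    if t > u:
        cost, (t, u), transposed = cost.T, (u, t), True
    best = math.inf
    for cols in itertools.permutations(range(u), t):
        best = min(best, sum(cost[i, c] for i, c in enumerate(cols)))
    return best


class TestBuildPairs:
    def test_single_treated_single_control(self):
        treatment = np.array([1, 0])
        other = np.array([[0, 1], [1, 1], [0, 0]])
        ps = build_pairs(treatment, np.zeros((0, 2)), other)
        assert ps.pairs == [(0, 1)]
        assert ps.total_distance == 1.0

    def test_confounder_blocking_forbids_cross_block_pairs(self):
        treatment = np.array([1, 1, 0, 0])
        Z = np.array([[0, 0, 1, 1]])
        ps = build_pairs(treatment, Z, np.zeros((2, 4)))
        assert ps.pairs == []

    def test_matches_within_blocks_only(self):
        treatment = np.array([1, 0, 1, 0])
        Z = np.array([[0, 0, 1, 1]])
        ps = build_pairs(treatment, Z, np.zeros((1, 4)))
        assert sorted(ps.pairs) == [(0, 1), (2, 3)]

    @pytest.mark.parametrize("n_treated,n_controls", [(2, 2), (3, 5), (7, 4), (5, 7)])
    def test_hungarian_matches_brute_force_minimum(self, n_treated, n_controls):
        rng = np.random.default_rng(n_treated * 10 + n_controls)
        for _ in range(10):
            n = n_treated + n_controls
            treatment = np.array([1] * n_treated + [0] * n_controls)
            other = rng.integers(0, 2, size=(6, n))
            ps = build_pairs(treatment, np.zeros((0, n)), other)
            cost = np.abs(
                other[:, :n_treated, None].astype(int)
                - other[:, None, n_treated:].astype(int)
            ).sum(axis=0)
            assert len(ps.pairs) == min(n_treated, n_controls)
            assert ps.total_distance == pytest.approx(brute_force_min_cost(cost))


class TestMcNemar:
    def test_hand_computed_example(self):
        stat, p = mcnemar_yates(DiscordantCounts(b=10, c=2))
        assert stat == pytest.approx(49 / 12)
        assert stat == pytest.approx(4.0833, abs=1e-4)
        assert p == pytest.approx(0.0433, abs=1e-3)

    def test_balanced_discordance_is_null(self):
        stat, p = mcnemar_yates(DiscordantCounts(b=4, c=4))
        assert (stat, p) == (0.0, 1.0)

    def test_no_discordant_pairs_is_null(self):
        assert mcnemar_yates(DiscordantCounts(b=0, c=0)) == (0.0, 1.0)

    def test_symmetric_in_b_and_c(self):
        assert mcnemar_yates(DiscordantCounts(b=9, c=3)) == mcnemar_yates(
            DiscordantCounts(b=3, c=9)
        )

    def test_concordant_pairs_do_not_enter(self):
        a = mcnemar_yates(DiscordantCounts(b=7, c=1, concordant_pos=0, concordant_neg=0))
        b = mcnemar_yates(DiscordantCounts(b=7, c=1, concordant_pos=50, concordant_neg=9))
        assert a == b

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            DiscordantCounts(b=-1, c=0)


def bh2000_replay(ps, q):
    """Independent step-by-step replay of the stepwise null-count estimate
    followed by step-up rejection."""
    m = len(ps)
    order = sorted(range(m), key=lambda i: ps[i])
    m0 = m
    s_prev = None
    for rank, idx in enumerate(order, start=1):
        s = (1.0 - ps[idx]) / (m + 1 - rank)
        if s_prev is not None and s < s_prev:
            if s > 0:
                m0 = min(m, math.ceil(1.0 / s) + 1)
            break
        s_prev = s
    m0 = max(m0, 1)
    k = 0
    for rank, idx in enumerate(order, start=1):
        if ps[idx] <= rank * q / m0:
            k = rank
    rejected = [False] * m
    for idx in order[:k]:
        rejected[idx] = True
    return m0, rejected


SPEC_PVALUES = [
    0.001, 0.008, 0.039, 0.041, 0.042, 0.06, 0.074, 0.205, 0.212, 0.216,
    0.222, 0.251, 0.269, 0.275, 0.34, 0.341, 0.384, 0.569, 0.594, 0.696,
    0.762, 0.94, 0.942, 0.975, 0.986,
]


class TestAdaptiveBH:
    def test_all_null_pvalues_reject_nothing(self):
        m0, rej = adaptive_bh(np.ones(10), q=0.05)
        assert m0 == 10
        assert not rej.any()

    def test_single_tiny_pvalue_rejected(self):
        m0, rej = adaptive_bh(np.array([1e-6]), q=0.05)
        assert rej.tolist() == [True]

    def test_matches_stepwise_replay_on_reference_sequence(self):
        m0, rej = adaptive_bh(np.array(SPEC_PVALUES), q=0.05)
        m0_o, rej_o = bh2000_replay(SPEC_PVALUES, 0.05)
        assert m0 == m0_o
        assert rej.tolist() == rej_o

    def test_matches_stepwise_replay_on_random_sequences(self):
        rng = np.random.default_rng(0)
        for trial in range(50):
            m = int(rng.integers(1, 40))
            ps = rng.random(m)
            if trial % 3 == 0:                      # add a signal block
                ps[: m // 3] *= 1e-4
            m0, rej = adaptive_bh(ps, q=0.1)
            m0_o, rej_o = bh2000_replay(ps.tolist(), 0.1)
            assert m0 == m0_o and rej.tolist() == rej_o

    def test_rejections_monotone_in_q(self):
        rng = np.random.default_rng(3)
        ps = rng.random(60) ** 2
        prev = None
        for q in (0.01, 0.05, 0.1, 0.2):
            _, rej = adaptive_bh(ps, q=q)
            cur = set(np.flatnonzero(rej).tolist())
            if prev is not None:
                assert prev <= cur
            prev = cur

    def test_invalid_level_rejected(self):
        with pytest.raises(ValueError):
            adaptive_bh(np.array([0.5]), q=1.5)


def planted_qed_inputs(seed=0, n_null=6):
    """Two positive strata with indicator candidates plus null candidates."""
    rng = np.random.default_rng(seed)
    n = 80
    strata = np.array([0] * 12 + [1] * 12 + [2] * 56)
    R = np.where(strata < 2, 1, -1).astype(np.int8)
    rows = [(strata == 0).astype(np.int8), (strata == 1).astype(np.int8)]
    rows += [(rng.random(n) < 0.3).astype(np.int8) for _ in range(n_null)]
    G = np.array(rows)
    ids = [f"f{i}" for i in range(len(rows))]
    return G, R, strata, ids


class TestRunQed:
    def test_planted_candidates_rejected_nulls_not(self):
        G, R, strata, ids = planted_qed_inputs()
        rep = run_qed(G, np.arange(G.shape[0]), ids, strata=strata,
                      positive_strata=[0, 1], R=R, Z=np.zeros((0, 80)))
        sig = set(rep.significant_pairs())
        assert ("f0", 0) in sig and ("f1", 1) in sig
        assert all(f in ("f0", "f1") for f, _ in sig)

    def test_low_prevalence_candidate_skipped(self):
        G, R, strata, ids = planted_qed_inputs()
        G = np.vstack([G, np.zeros(80, dtype=np.int8)])
        G[-1, 0] = 1
        ids = ids + ["rare"]
        rep = run_qed(G, np.arange(G.shape[0]), ids, strata=strata,
                      positive_strata=[0, 1], R=R, Z=np.zeros((0, 80)),
                      min_prevalence=5)
        assert "rare" in rep.skips and "prevalence" in rep.skips["rare"]

    def test_unmatchable_candidate_recorded_not_silent(self):
        treatment = np.array([[1, 1, 0, 0]], dtype=np.int8)
        Z = np.array([[0, 0, 1, 1]])
        R = np.array([1, 1, -1, -1])
        strata = np.array([0, 0, 1, 1])
        rep = run_qed(treatment, np.array([0]), ["f0"], strata=strata,
                      positive_strata=[0], R=R, Z=Z, min_prevalence=1)
        assert rep.tuples == []
        assert "f0" in rep.skips

    def test_deterministic(self):
        G, R, strata, ids = planted_qed_inputs(seed=5)
        kw = dict(strata=strata, positive_strata=[0, 1], R=R, Z=np.zeros((0, 80)))
        r1 = run_qed(G, np.arange(G.shape[0]), ids, **kw)
        r2 = run_qed(G, np.arange(G.shape[0]), ids, **kw)
        assert [(t.feature_id, t.stratum, t.raw_p, t.significant) for t in r1.tuples] == [
            (t.feature_id, t.stratum, t.raw_p, t.significant) for t in r2.tuples
        ]

    def test_unstratified_mode_tests_global_outcome(self):
        G, R, strata, ids = planted_qed_inputs()
        rep = run_qed(G, np.arange(G.shape[0]), ids, strata=strata,
                      positive_strata=[], R=R, Z=np.zeros((0, 80)), stratified=False)
        assert {t.stratum for t in rep.tuples} == {-1}

    def test_exclusion_variant_drops_cross_stratum_pairs(self):
        G, R, strata, ids = planted_qed_inputs()
        rep_excl = run_qed(G, np.arange(G.shape[0]), ids, strata=strata,
                           positive_strata=[0, 1], R=R, Z=np.zeros((0, 80)),
                           exclude_other_positive=True)
        for t in rep_excl.tuples:
            assert t.n_pairs <= 80

    def test_count_discordant_tabulates(self):
        from stratacause.qed import MatchedPairSet

        pairs = MatchedPairSet(pairs=[(0, 1), (2, 3), (4, 5)], treatment_feature="f",
                               total_distance=0.0)
        y = np.array([1, -1, -1, 1, 1, 1])
        c = count_discordant(pairs, y)
        assert (c.b, c.c, c.concordant_pos, c.concordant_neg) == (1, 1, 1, 0)
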