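"""S1/S2 strategies against brute-force oracles, and evaluation statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from retroranker import (
    PredictionList,
    RerankConfig,
    UsageError,
    apply_s1,
    apply_s2,
    final_accuracy_position,
    grid_search,
    top_k_accuracy,
)
from retroranker.rerank_eval import evaluation_report, rerank_list


# -- independent oracles: literal transcriptions of the strategy definitions


def s1_oracle(ranks, scores, p, k):
    """Select the floor(p * tail) lowest-scored tail candidates one at a
    time (worst original rank demoted first on score ties), then emit
    head / kept / demoted-by-score-descending."""
    items = sorted(range(len(ranks)), key=lambda i: ranks[i])
    head, tail = items[:k], items[k:]
    quota = math.floor(p * len(tail))
    pool = list(tail)
    demoted = []
    for _ in range(quota):
        worst = min(pool, key=lambda i: (scores[i], -ranks[i]))
        pool.remove(worst)
        demoted.append(worst)
    kept = [i for i in tail if i not in demoted]
    demoted.sort(key=lambda i: (-scores[i], ranks[i]))
    return [ranks[i] for i in head + kept + demoted]


def s2_oracle(ranks, scores, p, k):
    """Ascending sort of original rank + S1 rank, ties by original rank."""
    s1 = s1_oracle(ranks, scores, p, k)
    s1_pos = {rank: pos for pos, rank in enumerate(s1, start=1)}
    return sorted(ranks, key=lambda r: (r + s1_pos[r], r))


def random_instance(rng, n_max=50):
    n = int(rng.integers(1, n_max + 1))
    ranks = list(range(1, n + 1))
    if rng.random() < 0.5:  # inject score ties
        scores = rng.integers(0, max(2, n // 2), size=n).astype(float)
    else:
        scores = rng.normal(size=n)
    p = float(rng.choice([0.0, 0.25, 0.5, 0.7, 0.9, 1.0, rng.random()]))
    k = int(rng.integers(0, n + 2))
    return ranks, scores, p, k


class TestStrategyOracles:
    def test_worked_example_s1(self):
        order = apply_s1([1, 2, 3, 4, 5, 6], [0.9, 0.1, 0.8, 0.2, 0.7, 0.3], 0.5, 0)
        assert order.tolist() == [1, 3, 5, 6, 4, 2]

    def test_worked_example_s2(self):
        order = apply_s2([1, 2, 3, 4, 5, 6], [0.9, 0.1, 0.8, 0.2, 0.7, 0.3], 0.5, 0)
        assert order.tolist() == [1, 3, 2, 5, 4, 6]

    def test_matches_oracles_on_random_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(300):
            ranks, scores, p, k = random_instance(rng)
            assert apply_s1(ranks, scores, p, k).tolist() == s1_oracle(ranks, scores, p, k)
            assert apply_s2(ranks, scores, p, k).tolist() == s2_oracle(ranks, scores, p, k)

    def test_s2_full_demotion_equals_rank_plus_score_rank_sort(self):
        # S2(1, 0) reduces to sorting by original rank + score rank
        rng = np.random.default_rng(7)
        for _ in range(200):
            n = int(rng.integers(1, 30))
            ranks = list(range(1, n + 1))
            scores = rng.normal(size=n)
            got = apply_s2(ranks, scores, 1.0, 0).tolist()
            score_rank = {
                ranks[i]: pos
                for pos, i in enumerate(
                    sorted(range(n), key=lambda i: (-scores[i], ranks[i])), start=1
                )
            }
            expected = sorted(ranks, key=lambda r: (r + score_rank[r], r))
            assert got == expected


class TestStrategyInvariants:
    @given(st.data())
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_permutation_and_head_preservation(self, data):
        n = data.draw(st.integers(1, 12))
        scores = data.draw(
            st.lists(st.integers(0, 5), min_size=n, max_size=n).map(
                lambda xs: [float(x) for x in xs]
            )
        )
        p = data.draw(st.floats(0, 1, allow_nan=False))
        k = data.draw(st.integers(0, n + 1))
        ranks = list(range(1, n + 1))
        for fn in (apply_s1, apply_s2):
            order = fn(ranks, scores, p, k)
            assert sorted(order.tolist()) == ranks  # a permutation
        s1 = apply_s1(ranks, scores, p, k)
        assert s1[: min(k, n)].tolist() == ranks[: min(k, n)]  # head untouched

    def test_p_zero_is_identity(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = int(rng.integers(1, 20))
            ranks = list(range(1, n + 1))
            scores = rng.normal(size=n)
            k = int(rng.integers(0, n + 1))
            assert apply_s1(ranks, scores, 0.0, k).tolist() == ranks
            assert apply_s2(ranks, scores, 0.0, k).tolist() == ranks

    def test_full_demotion_no_head_is_score_sort(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            n = int(rng.integers(1, 20))
            ranks = list(range(1, n + 1))
            scores = rng.integers(0, 4, size=n).astype(float)
            got = apply_s1(ranks, scores, 1.0, 0).tolist()
            expected = [
                ranks[i]
                for i in sorted(range(n), key=lambda i: (-scores[i], ranks[i]))
            ]
            assert got == expected

    def test_demotion_set_monotone_in_p(self):
        rng = np.random.default_rng(3)

        def demoted_set(ranks, scores, p, k):
            order = apply_s1(ranks, scores, p, k).tolist()
            n = len(ranks)
            quota = math.floor(p * max(n - k, 0))
            return set(order[n - quota :]) if quota else set()

        for _ in range(100):
            n = int(rng.integers(2, 15))
            ranks = list(range(1, n + 1))
            scores = rng.integers(0, 5, size=n).astype(float)
            k = int(rng.integers(0, n))
            ps = sorted(rng.random(3))
            sets = [demoted_set(ranks, scores, p, k) for p in ps]
            assert sets[0] <= sets[1] <= sets[2]

    def test_s2_respects_unanimity(self):
        rng = np.random.default_rng(4)
        hits = 0
        for _ in range(300):
            ranks, scores, p, k = random_instance(rng, n_max=12)
            s1 = apply_s1(ranks, scores, p, k)
            if s1[0] == 1:  # first both originally and under S1
                assert apply_s2(ranks, scores, p, k)[0] == 1
                hits += 1
        assert hits > 50  # the premise actually occurred

    def test_input_validation(self):
        with pytest.raises(UsageError):
            apply_s1([1, 2], [0.1], 0.5, 0)
        with pytest.raises(UsageError):
            apply_s1([1, 3], [0.1, 0.2], 0.5, 0)
        with pytest.raises(UsageError):
            apply_s1([1, 2], [0.1, 0.2], 1.5, 0)


def _lists_with_positions(positions):
    """Minimal PredictionLists whose recorded candidate sits at the given
    original position (None = no recorded candidate), 12 candidates each."""
    from retroranker import parse_mapped_reaction

    record = parse_mapped_reaction("[CH3:1][OH:2]>>[CH3:1][OH:2]")
    out = []
    for pos in positions:
        cands = []
        for rank in range(1, 13):
            import dataclasses

            cands.append(
                dataclasses.replace(
                    record, original_rank=rank, is_recorded=(pos == rank)
                )
            )
        out.append(PredictionList(product_smiles="CO", candidates=cands))
    return out


class TestEvaluation:
    def test_top_k_accuracy_direct_count(self):
        lists = _lists_with_positions([1, 2, 3, 11])
        acc = top_k_accuracy(lists, [1, 3, 10])
        assert acc[1] == 0.25 and acc[3] == 0.75 and acc[10] == 0.75

    def test_recorded_always_first(self):
        lists = _lists_with_positions([1, 1, 1])
        acc = top_k_accuracy(lists, [1, 5])
        assert acc[1] == 1.0 and acc[5] == 1.0

    def test_missing_recorded_counts_as_miss(self):
        acc = top_k_accuracy(_lists_with_positions([1, None]), [1, 12])
        assert acc[1] == 0.5 and acc[12] == 0.5

    def test_identity_rerank_reproduces_original_accuracy(self):
        lists = _lists_with_positions([1, 4, 7])
        scores = [np.random.default_rng(i).normal(size=12) for i in range(3)]
        config = RerankConfig(strategy="S1", p=0.0, k=0)
        orders = [rerank_list(pl, s, config) for pl, s in zip(lists, scores)]
        base = top_k_accuracy(lists, [1, 3, 5, 10])
        after = top_k_accuracy(lists, [1, 3, 5, 10], orders)
        assert (base == after).all()

    def test_final_accuracy_position(self):
        assert final_accuracy_position(_lists_with_positions([1, 2, 2, 5]), 10) == 5
        assert final_accuracy_position(_lists_with_positions([1, 1]), 10) == 1

    def test_final_position_drops_when_recorded_moves_up(self):
        # recorded at 11 of 12; a strategy that lifts it lowers the position
        lists = _lists_with_positions([11, 1, 2])
        scores = []
        for pl in lists:
            s = -np.arange(12, dtype=float)  # agrees with original order...
            rec = pl.recorded_rank
            s[rec - 1] = 1.0  # ...except the recorded candidate scores best
            scores.append(s)
        before = final_accuracy_position(lists, 12)
        orders = [
            rerank_list(pl, s, RerankConfig("S1", 1.0, 0)) for pl, s in zip(lists, scores)
        ]
        after = final_accuracy_position(lists, 12, orders)
        assert before == 11 and after < before

    def test_grid_search_identity_cell(self):
        lists = _lists_with_positions([1, 4])
        scores = [np.zeros(12), np.zeros(12)]
        best, table = grid_search(lists, scores, [0.0], [0], objective_k=1)
        assert best.p == 0.0 and best.k == 0
        assert len(table) == 1
        assert table.iloc[0, 2] == 0.5
        with pytest.raises(UsageError):
            grid_search(lists, scores, [], [0], objective_k=1)

    def test_evaluation_report_counts_improvements(self):
        lists = _lists_with_positions([6, 1])
        scores = []
        for pl in lists:
            s = -np.arange(12, dtype=float)
            s[pl.recorded_rank - 1] = 1.0
            scores.append(s)
        report = evaluation_report(lists, scores, RerankConfig("S1", 1.0, 0), ks=[1, 3])
        assert report["n_products"] == 2
        assert report["n_recorded_rank_improved"] == 1
        assert report["top_k_accuracy_reranked"]["1"] == 1.0
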