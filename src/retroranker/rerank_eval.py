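"""Re-ranking strategies S1/S2 and top-k evaluation statistics.

S1(p, k) demotes the candidates whose re-ranking scores are in the bottom
ratio ``p`` to the end of the list, re-ordered by score, while the top
``k`` original positions are preserved.  S2(p, k) re-sorts by the sum of
the original rank and the S1 rank, which weighs the original ranking more
heavily — an ensemble of the upstream model and the re-ranker.  Both are
deterministic permutations of the candidate list: every tie falls back to
original rank ascending.

Evaluation covers top-k accuracy (fraction of products whose recorded
reactant set sits within the first k positions), the final-accuracy
position (smallest cutoff at which accuracy stops improving — a proxy for
multi-step search-space size), and a grid search over (p, k).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chem_io import PredictionList
from .errors import UsageError
from .reaction_change import annotate_changes, changed_bond_count


@dataclass
class RerankConfig:
    strategy: str = "S2"
    p: float = 1.0
    k: int = 0
    tie_break: str = "original_rank"
    #: If True, the demotion quota is floor(p*n) over the whole list
    #: (capped at the tail size) instead of floor(p*(n-k)) over the tail.
    ratio_over_all: bool = False

    def validate(self) -> None:
        if self.strategy not in ("S1", "S2"):
            raise UsageError(f"strategy must be 'S1' or 'S2', got {self.strategy!r}")
        if not (0.0 <= self.p <= 1.0):
            raise UsageError("p must be in [0, 1]")
        if self.k < 0:
            raise UsageError("k must be >= 0")
        if self.tie_break != "original_rank":
            raise UsageError("the only supported tie-break policy is 'original_rank'")


def _check_inputs(original_ranks: np.ndarray, rr_scores: np.ndarray, p: float, k: int) -> None:
    if len(original_ranks) != len(rr_scores):
        raise UsageError("original_ranks and rr_scores must have equal length")
    if len(original_ranks) == 0:
        raise UsageError("cannot re-rank an empty candidate list")
    if sorted(original_ranks) != list(range(1, len(original_ranks) + 1)):
        raise UsageError("original_ranks must be a permutation of 1..n")
    if not (0.0 <= p <= 1.0):
        raise UsageError("p must be in [0, 1]")
    if k < 0:
        raise UsageError("k must be >= 0")


def apply_s1(
    original_ranks,
    rr_scores,
    p: float,
    k: int = 0,
    ratio_over_all: bool = False,
) -> np.ndarray:
    """S1(p, k): demote the bottom-p-scored tail candidates to the end.

    Returns the new order as an array of original ranks.  The first k
    original positions are untouchable; among the remaining tail the
    floor(p * tail-size) lowest-scored candidates (ties resolved by keeping
    the candidate with the better original rank) are moved to the end,
    ordered by score descending with ties by original rank ascending.
    Everything not demoted keeps its relative original order.
    """
    ranks = np.asarray(original_ranks, dtype=np.int64)
    scores = np.asarray(rr_scores, dtype=np.float64)
    _check_inputs(ranks, scores, p, k)
    n = len(ranks)
    by_rank = np.argsort(ranks)  # item indices in original order
    head = by_rank[:k]
    tail = by_rank[k:]
    if ratio_over_all:
        quota = min(int(math.floor(p * n)), len(tail))
    else:
        quota = int(math.floor(p * len(tail)))
    if quota > 0:
        # lowest scores first; at equal score the worse original rank is
        # demoted first, so the better-ranked candidate stays out of D
        demote_order = sorted(tail, key=lambda i: (scores[i], -ranks[i]))
        demoted = set(demote_order[:quota])
    else:
        demoted = set()
    kept = [i for i in tail if i not in demoted]
    demoted_sorted = sorted(demoted, key=lambda i: (-scores[i], ranks[i]))
    order = list(head) + kept + demoted_sorted
    return ranks[order]


def _positions_from_order(order: np.ndarray) -> np.ndarray:
    """positions[r-1] = final 1-based position of the item with original rank r."""
    positions = np.empty(len(order), dtype=np.int64)
    for pos, rank in enumerate(order, start=1):
        positions[rank - 1] = pos
    return positions


def apply_s2(
    original_ranks,
    rr_scores,
    p: float,
    k: int = 0,
    ratio_over_all: bool = False,
) -> np.ndarray:
    """S2(p, k): sort by (original rank + S1 rank), ties by original rank.

    Returns the new order as an array of original ranks.
    """
    ranks = np.asarray(original_ranks, dtype=np.int64)
    s1_order = apply_s1(ranks, rr_scores, p, k, ratio_over_all=ratio_over_all)
    s1_positions = _positions_from_order(s1_order)
    items = sorted(range(1, len(ranks) + 1), key=lambda r: (r + s1_positions[r - 1], r))
    return np.array(items, dtype=np.int64)


def rerank_list(
    plist: PredictionList, rr_scores, config: RerankConfig
) -> np.ndarray:
    """Apply the configured strategy to one prediction list.

    ``rr_scores`` is aligned with ``plist.candidates``; returns the new
    order as original ranks.
    """
    config.validate()
    ranks = [c.original_rank for c in plist.candidates]
    fn = apply_s1 if config.strategy == "S1" else apply_s2
    return fn(ranks, rr_scores, config.p, config.k, ratio_over_all=config.ratio_over_all)


# ---------------------------------------------------------------------------
# evaluation


def recorded_positions(
    lists: list[PredictionList], orders: list[np.ndarray] | None = None
) -> list[int | None]:
    """Final position of the recorded candidate per list (None = no recorded).

    With ``orders`` (per-list arrays of original ranks in final order) the
    position is looked up after re-ranking; otherwise the original order is
    used.
    """
    positions: list[int | None] = []
    for i, plist in enumerate(lists):
        rec = plist.recorded_rank
        if rec is None:
            positions.append(None)
        elif orders is None:
            positions.append(rec)
        else:
            positions.append(int(np.where(orders[i] == rec)[0][0]) + 1)
    return positions


def top_k_accuracy(
    lists: list[PredictionList] | list[int | None],
    ks: list[int],
    orders: list[np.ndarray] | None = None,
) -> pd.Series:
    """Fraction of products whose recorded candidate is at position <= k.

    Accepts prediction lists (optionally with re-rank orders) or
    precomputed recorded positions; products without a recorded candidate
    count as misses at every k.
    """
    if isinstance(lists, list) and lists and isinstance(lists[0], PredictionList):
        positions = recorded_positions(lists, orders)
    else:
        positions = list(lists)  # type: ignore[arg-type]
    if not positions:
        raise UsageError("top_k_accuracy needs at least one product")
    n = len(positions)
    accs = {
        k: sum(1 for p in positions if p is not None and p <= k) / n for k in ks
    }
    return pd.Series(accs, name="top_k_accuracy")


def final_accuracy_position(
    lists: list[PredictionList] | list[int | None],
    K_max: int,
    orders: list[np.ndarray] | None = None,
) -> int:
    """Smallest k with top-k accuracy equal to the accuracy at ``K_max``."""
    accs = top_k_accuracy(lists, list(range(1, K_max + 1)), orders)
    final = accs[K_max]
    for k in range(1, K_max + 1):
        if accs[k] == final:
            return k
    return K_max


def grid_search(
    lists: list[PredictionList],
    rr_scores: list[np.ndarray],
    p_grid,
    k_grid,
    objective_k: int,
    strategy: str = "S2",
) -> tuple[RerankConfig, pd.DataFrame]:
    """Exhaustive (p, k) search maximizing top-``objective_k`` accuracy.

    Returns the first argmax in grid order plus the full table.
    """
    p_grid = list(p_grid)
    k_grid = list(k_grid)
    if not p_grid or not k_grid:
        raise UsageError("grid_search needs nonempty p and k grids")
    rows = []
    best: tuple[float, RerankConfig] | None = None
    for p in p_grid:
        for k in k_grid:
            config = RerankConfig(strategy=strategy, p=p, k=k)
            orders = [rerank_list(pl, s, config) for pl, s in zip(lists, rr_scores)]
            acc = float(top_k_accuracy(lists, [objective_k], orders)[objective_k])
            rows.append((p, k, acc))
            if best is None or acc > best[0]:
                best = (acc, config)
    table = pd.DataFrame(rows, columns=["p", "k", f"top_{objective_k}_accuracy"])
    return best[1], table


def evaluation_report(
    lists: list[PredictionList],
    rr_scores: list[np.ndarray],
    config: RerankConfig,
    ks: list[int] = (1, 3, 5, 10),
    change_radius: int = 1,
) -> dict:
    """Full evaluation of one re-rank configuration.

    Reports per-k accuracy before/after, final-accuracy positions, the
    number of products whose recorded rank improved, and the mean
    changed-bond count overall and on the improved subset — the diagnostic
    for whether the gains concentrate on reactions with a greater degree
    of change.
    """
    ks = list(ks)
    if not lists:
        raise UsageError("evaluation_report needs at least one product")
    orders = [rerank_list(pl, s, config) for pl, s in zip(lists, rr_scores)]
    before = recorded_positions(lists)
    after = recorded_positions(lists, orders)
    K_max = min(len(pl.candidates) for pl in lists)
    improved_idx = [
        i for i, (b, a) in enumerate(zip(before, after))
        if b is not None and a is not None and a < b
    ]

    def _mean_changed(indices) -> float | None:
        counts = []
        for i in indices:
            rec = next(
                (c for c in lists[i].candidates if c.is_recorded and not c.unscorable),
                None,
            )
            if rec is not None:
                counts.append(changed_bond_count(annotate_changes(rec, radius=change_radius)))
        return float(np.mean(counts)) if counts else None

    return {
        "config": {"strategy": config.strategy, "p": config.p, "k": config.k},
        "n_products": len(lists),
        "top_k_accuracy_original": {str(k): v for k, v in top_k_accuracy(before, ks).items()},
        "top_k_accuracy_reranked": {str(k): v for k, v in top_k_accuracy(after, ks).items()},
        "final_accuracy_position_original": final_accuracy_position(before, K_max),
        "final_accuracy_position_reranked": final_accuracy_position(after, K_max),
        "n_recorded_rank_improved": len(improved_idx),
        "mean_changed_bonds_all": _mean_changed(range(len(lists))),
        "mean_changed_bonds_improved": _mean_changed(improved_idx),
    }
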