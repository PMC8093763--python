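"""Weighted rank aggregation of per-measure classifier orderings.

Each performance measure orders the M candidate classifiers from best to
worst, yielding K ranked lists whose importance weights are the measure
values themselves.  The consensus ordering minimises the summed weighted
Spearman footrule distance to the K lists.  The minimisation is exact: by
enumeration (with a deterministic lexicographic tie-break) for small M, and
via a linear-assignment formulation above that — the footrule objective is
separable over (candidate, position) pairs, so the optimum is a minimum-cost
bipartite matching.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment


@dataclass
class RankedList:
    """One measure's ordering of the candidates, best first.

    ``weights`` are the measure values attained, aligned to ``ids`` and
    non-increasing along the ordering.
    """

    measure: str
    ids: list
    weights: np.ndarray

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.ids) != len(self.weights):
            raise ValueError("one weight per candidate id")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("candidate ids must be unique")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")
        if np.any(np.diff(self.weights) > 1e-12):
            raise ValueError("weights must be non-increasing along the ordering")

    @classmethod
    def from_scores(cls, measure: str, scores: dict) -> "RankedList":
        """Order candidates by descending measure value.

        Ties keep the candidates' declaration order in ``scores``.
        """
        ids = list(scores)
        order = sorted(range(len(ids)), key=lambda i: (-scores[ids[i]], i))
        ordered = [ids[i] for i in order]
        return cls(measure, ordered, np.array([scores[c] for c in ordered]))

    def rank_of(self) -> dict:
        """Candidate id -> 1-based rank in this list."""
        return {c: r + 1 for r, c in enumerate(self.ids)}

    def normalized_weights(self) -> dict:
        """Min-max normalised importance weights in [0, 1].

        A constant-weight list normalises to all-ones (every candidate
        equally important) rather than all-zeros.
        """
        w = self.weights
        span = w.max() - w.min()
        if span <= 1e-15:
            norm = np.ones_like(w)
        else:
            norm = (w - w.min()) / span
        return dict(zip(self.ids, norm))


def weighted_footrule_distance(ordering, ranked: RankedList) -> float:
    """Weighted Spearman footrule between an ordering and a ranked list.

    Sum over candidates of |rank in ordering - rank in list| times the
    candidate's min-max-normalised importance weight in the list.
    """
    if set(ordering) != set(ranked.ids) or len(ordering) != len(ranked.ids):
        raise ValueError("ordering must be a permutation of the list's ids")
    list_rank = ranked.rank_of()
    w = ranked.normalized_weights()
    return float(
        sum(abs(r + 1 - list_rank[c]) * w[c] for r, c in enumerate(ordering))
    )


def _cost_matrix(ids, lists, list_weights) -> np.ndarray:
    """cost[c, pos] = summed weighted |pos - rank_k(c)| over the K lists."""
    m = len(ids)
    cost = np.zeros((m, m))
    for lw, rl in zip(list_weights, lists):
        rank = rl.rank_of()
        wmap = rl.normalized_weights()
        for ci, c in enumerate(ids):
            r = rank[c]
            w = wmap[c]
            cost[ci] += lw * w * np.abs(np.arange(1, m + 1) - r)
    return cost


def aggregate(lists, list_weights=None, enum_threshold: int = 8):
    """Consensus ordering minimising the summed weighted footrule distance.

    Exact for any M: exhaustive enumeration when M <= ``enum_threshold``
    (ties in the objective broken by lexicographic candidate-id order), a
    linear-assignment solve above that.  Returns the candidate ids, best
    first; the first element is the per-bootstrap winner.
    """
    lists = list(lists)
    if not lists:
        raise ValueError("need at least one ranked list")
    id_set = set(lists[0].ids)
    for rl in lists[1:]:
        if set(rl.ids) != id_set:
            raise ValueError("all ranked lists must cover the same candidate ids")
    if list_weights is None:
        list_weights = np.ones(len(lists))
    list_weights = np.asarray(list_weights, dtype=float)
    if len(list_weights) != len(lists):
        raise ValueError("one weight per list")

    ids = sorted(id_set, key=lambda c: (str(c), lists[0].ids.index(c)))
    cost = _cost_matrix(ids, lists, list_weights)
    m = len(ids)

    if m <= enum_threshold:
        best, best_obj = None, np.inf
        # ids are lexicographically sorted, so itertools yields permutations
        # in lexicographic order and first-strictly-better keeps the tie-break
        for perm in itertools.permutations(range(m)):
            obj = sum(cost[c, pos] for pos, c in enumerate(perm))
            if obj < best_obj - 1e-12:
                best, best_obj = perm, obj
        return [ids[c] for c in best]

    rows, cols = linear_sum_assignment(cost)
    ordering = [None] * m
    for c, pos in zip(rows, cols):
        ordering[pos] = ids[c]
    return ordering


def aggregation_objective(ordering, lists, list_weights=None) -> float:
    """Objective value of an ordering against the K weighted lists."""
    lists = list(lists)
    if list_weights is None:
        list_weights = np.ones(len(lists))
    return float(
        sum(
            lw * weighted_footrule_distance(ordering, rl)
            for lw, rl in zip(list_weights, lists)
        )
    )
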