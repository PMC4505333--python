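"""Consensus rank lists via hierarchical majority voting.

Replicate PRLs of one condition (one disease cohort, one gene silencing) are
combined into a single condition-level PRL by iteratively merging the two
most similar lists: similarity is the Spearman footrule distance between the
permutations, and a merge is a Borda (mean-rank) aggregation.  The process
repeats until one consensus list remains; every step is recorded so the
agglomeration order is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .prl import ProbeRankList

__all__ = [
    "MergeStep",
    "MergeTrace",
    "footrule_distance",
    "borda_merge",
    "merge_condition_prls",
]


@dataclass(frozen=True)
class MergeStep:
    """One agglomeration: which members merged and at what footrule distance."""

    left: tuple[int, ...]
    right: tuple[int, ...]
    distance: float


@dataclass(frozen=True)
class MergeTrace:
    """Ordered record of every merge; members are input-list indices."""

    steps: tuple[MergeStep, ...]

    def __len__(self) -> int:
        return len(self.steps)


def _require_same_universe(a: ProbeRankList, b: ProbeRankList) -> None:
    if not a.same_universe(b):
        raise ValueError("rank lists are over different probe universes")


def footrule_distance(a: ProbeRankList, b: ProbeRankList) -> float:
    """Spearman footrule: sum over probes of absolute rank differences."""
    _require_same_universe(a, b)
    rank_in_b = b.ranks_of(a.ordering)
    rank_in_a = np.arange(1, len(a) + 1)
    return float(np.abs(rank_in_a - rank_in_b).sum())


def borda_merge(a: ProbeRankList, b: ProbeRankList) -> ProbeRankList:
    """Mean-rank (Borda) aggregation of two rank lists.

    Each probe scores the average of its two ranks; the merged list sorts by
    score ascending with ties broken by probe id ascending.
    """
    _require_same_universe(a, b)
    ids = np.sort(a.ordering)
    score = (a.ranks_of(ids) + b.ranks_of(ids)) / 2.0
    # stable sort on an id-ascending array makes the tie-break implicit
    order = np.argsort(score, kind="stable")
    return ProbeRankList(ids[order])


def merge_condition_prls(
    prls: Sequence[ProbeRankList],
) -> tuple[ProbeRankList, MergeTrace]:
    """Agglomerate replicate PRLs into one consensus PRL.

    While more than one list remains, the pair with the smallest footrule
    distance is replaced by its Borda merge.  Merged lists carry no extra
    weight in later comparisons.  Ties between equally close pairs are
    resolved toward the pair whose member-index tuples sort first, so the
    result is deterministic.

    Returns the consensus PRL and a :class:`MergeTrace` with one step per
    merge (``len(prls) - 1`` steps in total).
    """
    if len(prls) == 0:
        raise ValueError("at least one rank list is required")
    for p in prls[1:]:
        _require_same_universe(prls[0], p)
    if len(prls) == 1:
        return prls[0], MergeTrace(steps=())

    clusters: list[tuple[tuple[int, ...], ProbeRankList]] = [
        ((i,), p) for i, p in enumerate(prls)
    ]
    steps: list[MergeStep] = []
    while len(clusters) > 1:
        best: tuple[float, tuple[int, ...], tuple[int, ...], int, int] | None = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = footrule_distance(clusters[i][1], clusters[j][1])
                key = (d, clusters[i][0], clusters[j][0], i, j)
                if best is None or key < best:
                    best = key
        assert best is not None
        d, _, _, i, j = best
        merged = borda_merge(clusters[i][1], clusters[j][1])
        members = tuple(sorted(clusters[i][0] + clusters[j][0]))
        steps.append(MergeStep(left=clusters[i][0], right=clusters[j][0], distance=d))
        clusters = (
            [c for k, c in enumerate(clusters) if k not in (i, j)]
            + [(members, merged)]
        )
    return clusters[0][1], MergeTrace(steps=tuple(steps))
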