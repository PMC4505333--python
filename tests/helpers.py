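"""Shared test utilities: independent oracles and random fixtures."""

from __future__ import annotations

import numpy as np

from sigmatch.prl import ProbeRankList


def random_prl(n_probes: int, rng: np.random.Generator) -> ProbeRankList:
    """A uniformly random permutation of a synthetic probe universe."""
    width = len(str(n_probes - 1))
    ids = np.array([f"P{i:0{width}d}" for i in range(n_probes)])
    return ProbeRankList(rng.permutation(ids))


def naive_enrichment_score(gene_set, reference: ProbeRankList) -> float:
    """Membership-test running-sum oracle: O(N) loop over every rank position.

    Walks the reference list once, adding 1/n at hits and subtracting
    1/(N-n) at misses, keeping every partial sum; returns the extreme of
    largest magnitude, positive winning ties.  Independent of the vectorised
    hit-position implementation it checks.
    """
    gs = set(gene_set)
    n, N = len(gs), len(reference)
    step_hit, step_miss = 1.0 / n, 1.0 / (N - n)
    s = 0.0
    sums = []
    for probe in reference.ordering:
        s = s + step_hit if probe in gs else s - step_miss
        sums.append(s)
    top = max(0.0, max(sums))
    bottom = min(0.0, min(sums))
    return top if top >= -bottom else bottom


def naive_running_sums(gene_set, reference: ProbeRankList) -> list[float]:
    """All partial sums of the oracle walk (for end-at-zero checks)."""
    gs = set(gene_set)
    n, N = len(gs), len(reference)
    s = 0.0
    sums = []
    for probe in reference.ordering:
        s = s + 1.0 / n if probe in gs else s - 1.0 / (N - n)
        sums.append(s)
    return sums
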