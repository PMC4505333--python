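"""Bidirectional equal-weighted GSEA distance between probe rank lists.

Two expression responses are compared through their rank lists alone.  Each
PRL contributes a *signature* — its top-n and bottom-n probes (n = 250 by
default).  A signature is scored against the other PRL with the classic
Kolmogorov–Smirnov running sum: walking the reference list from rank 1 to N,
the sum rises by 1/n at every signature hit and falls by 1/(N−n) at every
miss; the enrichment score (ES) is the signed maximum deviation of the sum
from zero and lies in [−1, 1].  Up- and down-set scores combine as
(ES_up − ES_down)/2, and the distance between PRLs A and B is

    d(A, B) = 1 − (ES_AB + ES_BA) / 2  ∈  [0, 2],

where ES_AB scores A's signature in B and vice versa.  Zero means identical
regulation tendency; two means perfectly opposite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .prl import ProbeRankList

__all__ = [
    "DEFAULT_SIGNATURE_SIZE",
    "Signature",
    "EnrichmentResult",
    "DistanceMatrix",
    "extract_signature",
    "enrichment_score",
    "combine_scores",
    "combined_es",
    "distance_from_scores",
    "prl_distance",
    "distance_matrix",
]

DEFAULT_SIGNATURE_SIZE = 250


@dataclass(frozen=True)
class Signature:
    """Top-n (upregulated) and bottom-n (downregulated) probes of a PRL."""

    up_set: frozenset
    down_set: frozenset
    n: int
    source_label: str | None = None

    def __post_init__(self) -> None:
        if len(self.up_set) != self.n or len(self.down_set) != self.n:
            raise ValueError("up and down sets must both have exactly n probes")
        if self.up_set & self.down_set:
            raise ValueError("up and down sets overlap")


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-direction and combined enrichment of one signature in one PRL."""

    es_up: float
    es_down: float

    @property
    def combined(self) -> float:
        return combine_scores(self.es_up, self.es_down)


class DistanceMatrix:
    """Symmetric condition × condition matrix of GSEA distances in [0, 2]."""

    def __init__(self, labels: Iterable[str], values: np.ndarray):
        labels = [str(x) for x in labels]
        values = np.asarray(values, dtype=float)
        k = len(labels)
        if len(set(labels)) != k:
            raise ValueError("duplicate condition labels")
        if values.shape != (k, k):
            raise ValueError(f"values shape {values.shape} does not match {k} labels")
        if not np.allclose(values, values.T, rtol=0, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(values), 0, atol=1e-9):
            raise ValueError("diagonal must be zero")
        if values.min() < -1e-9 or values.max() > 2 + 1e-9:
            raise ValueError("distances must lie in [0, 2]")
        self.labels = labels
        self.values = values

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DistanceMatrix):
            return NotImplemented
        return self.labels == other.labels and np.array_equal(self.values, other.values)


def extract_signature(
    prl: ProbeRankList, n: int = DEFAULT_SIGNATURE_SIZE, label: str | None = None
) -> Signature:
    """Top-n and bottom-n probes of a PRL as disjoint up/down gene sets."""
    N = len(prl)
    if not 0 < n or 2 * n > N:
        raise ValueError(f"signature size n={n} must satisfy 0 < 2n <= N={N}")
    ordering = prl.ordering
    return Signature(
        up_set=frozenset(ordering[:n].tolist()),
        down_set=frozenset(ordering[N - n :].tolist()),
        n=n,
        source_label=label,
    )


def enrichment_score(gene_set: Iterable[str], reference: ProbeRankList) -> float:
    """Signed maximum deviation of the KS running sum of ``gene_set`` in ``reference``.

    The running sum starts at zero, gains 1/n at each hit and loses 1/(N−n)
    at each miss, returning to zero at rank N.  When the extreme positive
    and negative deviations tie in magnitude the positive one is returned.
    """
    gene_set = set(gene_set)
    n = len(gene_set)
    N = len(reference)
    if not 0 < n < N:
        raise ValueError(f"gene set size n={n} must satisfy 0 < n < N={N}")
    pos = np.sort(reference.ranks_of(gene_set))  # raises on probes outside universe
    j = np.arange(1, n + 1)
    miss_before = pos - j  # misses strictly before the j-th hit
    at_hit = j / n - miss_before / (N - n)  # running sum just after each hit
    before_hit = (j - 1) / n - miss_before / (N - n)  # just before each hit
    top = max(float(at_hit.max()), 0.0)  # the sum returns to 0 at rank N
    bottom = min(float(before_hit.min()), 0.0)
    return top if top >= -bottom else bottom


def combine_scores(es_up: float, es_down: float) -> float:
    """Two-sided enrichment: (ES of up-set − ES of down-set) / 2, in [−1, 1]."""
    return (es_up - es_down) / 2.0


def combined_es(signature: Signature, reference: ProbeRankList) -> EnrichmentResult:
    """Score a signature's up and down sets in a reference PRL."""
    return EnrichmentResult(
        es_up=enrichment_score(signature.up_set, reference),
        es_down=enrichment_score(signature.down_set, reference),
    )


def distance_from_scores(es_ab: float, es_ba: float) -> float:
    """Distance from the two directed combined enrichment scores."""
    return 1.0 - (es_ab + es_ba) / 2.0


def prl_distance(
    a: ProbeRankList, b: ProbeRankList, n: int = DEFAULT_SIGNATURE_SIZE
) -> float:
    """Bidirectional GSEA distance between two PRLs, in [0, 2]."""
    if not a.same_universe(b):
        raise ValueError("rank lists are over different probe universes")
    es_ab = combined_es(extract_signature(a, n), b).combined
    es_ba = combined_es(extract_signature(b, n), a).combined
    return distance_from_scores(es_ab, es_ba)


def distance_matrix(
    prls: Mapping[str, ProbeRankList], n: int = DEFAULT_SIGNATURE_SIZE
) -> DistanceMatrix:
    """All-pairs distance matrix over labelled condition PRLs."""
    labels = list(prls.keys())
    if len(labels) < 2:
        raise ValueError("at least two rank lists are required")
    k = len(labels)
    values = np.zeros((k, k))
    signatures = {lab: extract_signature(prls[lab], n, label=lab) for lab in labels}
    for i in range(k):
        for j in range(i + 1, k):
            a, b = prls[labels[i]], prls[labels[j]]
            es_ab = combined_es(signatures[labels[i]], b).combined
            es_ba = combined_es(signatures[labels[j]], a).combined
            d = distance_from_scores(es_ab, es_ba)
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels, values)
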