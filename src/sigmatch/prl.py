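"""Probe rank lists and the hierarchical threshold-and-sort builder.

A probe rank list (PRL) is a strict permutation of the probe universe of a
microarray platform, ordered from the most upregulated probe (rank 1) to the
most downregulated (rank N) in one experiment sample relative to its paired
control.  Ranking raw experiment-to-control intensity ratios directly is
unstable: a tiny denominator inflates a fold change out of proportion.  The
builder therefore clamps low intensities at the lower quartile of the pooled
pair before taking ratios (the *primary* threshold), and resolves the large
tie block this clamping creates with a second, gentler clamp at one tenth of
that quartile (the *secondary* threshold).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["ProbeRankList", "ThresholdPair", "primary_threshold", "build_prl"]

#: relative tolerance used to treat a ratio as exactly one
RATIO_ONE_RTOL = 1e-12


class ProbeRankList:
    """A strict permutation of probe identifiers, most upregulated first.

    Parameters
    ----------
    ordering
        Probe identifiers in rank order; rank 1 (index 0) is the most
        upregulated probe, rank N the most downregulated.

    Notes
    -----
    Equality is element-wise on the ordering.  Rank lookups are served by a
    lazily built :class:`pandas.Index`.
    """

    __slots__ = ("_ordering", "_index")

    def __init__(self, ordering: Iterable[str]):
        arr = np.asarray(list(ordering), dtype=str)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("ordering must be a non-empty 1-D sequence of probe ids")
        if pd.Index(arr).has_duplicates:
            raise ValueError("ordering is not a permutation: duplicate probe ids")
        self._ordering = arr
        self._index: pd.Index | None = None

    # -- basic container protocol -------------------------------------------------
    @property
    def ordering(self) -> np.ndarray:
        """Probe ids in rank order (read-only view)."""
        view = self._ordering.view()
        view.flags.writeable = False
        return view

    def __len__(self) -> int:
        return int(self._ordering.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ProbeRankList):
            return NotImplemented
        return bool(np.array_equal(self._ordering, other._ordering))

    def __hash__(self) -> int:  # pragma: no cover - convenience only
        return hash(tuple(self._ordering.tolist()))

    def __repr__(self) -> str:  # pragma: no cover
        return f"ProbeRankList(N={len(self)}, top={self._ordering[0]!r})"

    # -- rank lookups -------------------------------------------------------------
    @property
    def index(self) -> pd.Index:
        if self._index is None:
            self._index = pd.Index(self._ordering)
        return self._index

    @property
    def universe(self) -> frozenset:
        return frozenset(self._ordering.tolist())

    def ranks_of(self, probes: Iterable[str]) -> np.ndarray:
        """1-based ranks of ``probes``; raises ``KeyError`` on unknown ids."""
        probes = np.asarray(list(probes), dtype=str)
        pos = self.index.get_indexer(probes)
        if (pos < 0).any():
            missing = probes[pos < 0][:5].tolist()
            raise KeyError(f"probes not in rank-list universe: {missing}")
        return pos + 1

    def rank_of(self, probe: str) -> int:
        return int(self.ranks_of([probe])[0])

    def reverse(self) -> "ProbeRankList":
        """The fully inverted list (upregulated and downregulated swapped)."""
        return ProbeRankList(self._ordering[::-1])

    def same_universe(self, other: "ProbeRankList") -> bool:
        if len(self) != len(other):
            return False
        return bool(np.array_equal(np.sort(self._ordering), np.sort(other._ordering)))


@dataclass(frozen=True)
class ThresholdPair:
    """Primary/secondary clamping thresholds for one sample pair.

    ``primary`` is the lower quartile of the pooled intensities of the
    experiment and control sample; ``secondary`` is exactly one tenth of it.
    """

    primary: float
    secondary: float

    def __post_init__(self) -> None:
        if not (self.primary > 0 and np.isfinite(self.primary)):
            raise ValueError("primary threshold must be positive and finite")
        if self.secondary != self.primary / 10:
            raise ValueError("secondary must equal primary / 10 exactly")


def _check_positive(values: np.ndarray, what: str) -> None:
    if not np.all(np.isfinite(values)) or np.any(values <= 0):
        raise ValueError(f"{what} must be strictly positive and finite")


def primary_threshold(
    experiment_values: Sequence[float], control_values: Sequence[float]
) -> ThresholdPair:
    """Lower-quartile threshold of the pooled pair, with its one-tenth companion.

    The quartile is taken over the union of both samples' intensities using
    the linear-interpolation quantile convention (numpy's default).
    """
    exp = np.asarray(experiment_values, dtype=float)
    ctl = np.asarray(control_values, dtype=float)
    if exp.size != ctl.size:
        raise ValueError("experiment and control must have equal length")
    if exp.size + ctl.size < 4:
        raise ValueError("at least 4 pooled values are required for a quartile")
    _check_positive(exp, "experiment values")
    _check_positive(ctl, "control values")
    pooled = np.concatenate([exp, ctl])
    primary = float(np.percentile(pooled, 25))
    return ThresholdPair(primary=primary, secondary=primary / 10)


def build_prl(
    experiment: Sequence[float],
    control: Sequence[float],
    probe_ids: Sequence[str],
) -> ProbeRankList:
    """Rank probes by clamped experiment-to-control ratio.

    The procedure, applied to one experiment/control pair:

    1. clamp both samples' intensities from below at the primary threshold
       (the pooled lower quartile);
    2. rank probes by the ratio of the clamped values, descending;
    3. for probes whose clamped ratio equals one, re-clamp the *original*
       intensities at the secondary threshold (primary / 10) and recompute
       the ratio;
    4. sub-sort that tie block by the new ratio, descending.

    Residual ties are broken by probe id ascending, making the output a
    deterministic strict permutation of ``probe_ids``.
    """
    exp = np.asarray(experiment, dtype=float)
    ctl = np.asarray(control, dtype=float)
    ids = np.asarray(list(probe_ids), dtype=str)
    if not (exp.size == ctl.size == ids.size):
        raise ValueError("experiment, control and probe_ids must be aligned")
    if exp.size < 4:
        raise ValueError("at least 4 probes are required")
    if pd.Index(ids).has_duplicates:
        raise ValueError("probe_ids contains duplicates")
    _check_positive(exp, "experiment values")
    _check_positive(ctl, "control values")

    thr = primary_threshold(exp, ctl)
    ratio = np.maximum(exp, thr.primary) / np.maximum(ctl, thr.primary)

    # clamping manufactures exact ties at 1; a tight relative tolerance also
    # absorbs representation noise from rescaled inputs
    is_one = np.isclose(ratio, 1.0, rtol=RATIO_ONE_RTOL, atol=0.0)
    ratio = np.where(is_one, 1.0, ratio)

    sub_ratio = np.zeros_like(ratio)
    if is_one.any():
        sub_ratio[is_one] = np.maximum(exp[is_one], thr.secondary) / np.maximum(
            ctl[is_one], thr.secondary
        )

    # lexsort: last key is primary — ratio desc, then sub-ratio desc, then id asc
    order = np.lexsort((ids, -sub_ratio, -ratio))
    return ProbeRankList(ids[order])
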