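"""On-disk formats: expression matrices, pair manifests, PRLs, distance matrices.

Canonical formats are plain TSV.  GCT v1.2 is accepted as a *reader* dialect
for expression matrices only.  Intensities are linear-scale and strictly
positive — log-transformed input must be exponentiated by the caller, since
the ratio and quartile arithmetic downstream is only meaningful on positive
linear values.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .prl import ProbeRankList

__all__ = [
    "FormatError",
    "ValidationError",
    "ExpressionMatrix",
    "PairEntry",
    "PairManifest",
    "read_expression_matrix",
    "harmonize_probes",
    "read_pair_manifest",
    "write_pair_manifest",
    "read_prl",
    "write_prl",
    "read_distance_matrix",
    "write_distance_matrix",
]


class FormatError(ValueError):
    """An input file violates the expected layout or value invariants."""


class ValidationError(ValueError):
    """Cross-references between artifacts do not resolve."""


class ExpressionMatrix:
    """Probe × sample intensity table on a fixed probe universe.

    Wraps a :class:`pandas.DataFrame` whose index holds unique probe ids and
    whose columns hold unique sample ids; every value is finite and > 0.
    """

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates:
            dup = data.index[data.index.duplicated()][0]
            raise FormatError(f"duplicate probe id: {dup!r}")
        if data.columns.has_duplicates:
            dup = data.columns[data.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id: {dup!r}")
        values = data.to_numpy(dtype=float, copy=False)
        bad = ~np.isfinite(values) | (values <= 0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise FormatError(
                f"non-positive or non-finite intensity at probe "
                f"{data.index[i]!r}, sample {data.columns[j]!r}: {values[i, j]!r}"
            )
        self.data = data.astype(float)

    @property
    def probe_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def sample(self, sample_id: str) -> np.ndarray:
        """Intensity column for one sample, aligned with :attr:`probe_ids`."""
        if sample_id not in self.data.columns:
            raise KeyError(f"unknown sample id: {sample_id!r}")
        return self.data[sample_id].to_numpy()

    def restrict(self, probes: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(probes)])

    def write_tsv(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", index_label="probe_id", float_format="%.12g")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return self.data.equals(other.data)


class PairEntry(NamedTuple):
    experiment_id: str
    control_id: str
    condition: str
    dataset: str


@dataclass(frozen=True)
class PairManifest:
    """Experiment/control sample pairings grouped by condition label."""

    entries: tuple[PairEntry, ...]

    def __post_init__(self) -> None:
        for e in self.entries:
            if e.experiment_id == e.control_id:
                raise ValidationError(
                    f"experiment and control sample coincide: {e.experiment_id!r}"
                )

    def __len__(self) -> int:
        return len(self.entries)

    def by_condition(self) -> dict[str, list[PairEntry]]:
        groups: dict[str, list[PairEntry]] = {}
        for e in self.entries:
            groups.setdefault(e.condition, []).append(e)
        return groups

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        """Check every referenced sample id resolves to a matrix column."""
        known = set(matrix.sample_ids)
        for e in self.entries:
            for sid in (e.experiment_id, e.control_id):
                if sid not in known:
                    raise ValidationError(f"sample id not found in matrix: {sid!r}")


# --------------------------------------------------------------------------- #
# expression matrices
# --------------------------------------------------------------------------- #

def read_expression_matrix(path: str | Path, dialect: str = "tsv") -> ExpressionMatrix:
    """Read a probe × sample intensity table.

    ``dialect="tsv"``: header row ``probe_id<TAB>sample1<TAB>...``.
    ``dialect="gct"``: GCT v1.2 (``#1.2`` line, dimensions line, then a table
    with ``Name`` and ``Description`` columns); the Description column is
    dropped.
    """
    path = Path(path)
    if dialect == "tsv":
        raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    elif dialect == "gct":
        with open(path) as fh:
            version = fh.readline().strip()
            if not version.startswith("#1.2"):
                raise FormatError(f"not a GCT v1.2 file: first line {version!r}")
            fh.readline()  # dimensions line; the table itself is authoritative
            raw = pd.read_csv(fh, sep="\t", index_col=0, dtype=str)
        raw = raw.drop(columns=[c for c in raw.columns if c.lower() == "description"])
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")

    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().to_numpy()
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise FormatError(
            f"non-numeric value at probe {raw.index[i]!r}, sample "
            f"{raw.columns[j]!r}: {raw.iat[i, j]!r}"
        )
    numeric.index = numeric.index.astype(str)
    numeric.columns = numeric.columns.astype(str)
    return ExpressionMatrix(numeric)


def harmonize_probes(matrices: Sequence[ExpressionMatrix]) -> list[ExpressionMatrix]:
    """Restrict every matrix to the shared probe universe, sorted ascending.

    Probes absent from any one dataset are excluded from all of them, so
    every downstream stage operates on one common universe.  Raises
    :class:`ValidationError` if the intersection is empty.
    """
    if len(matrices) == 0:
        raise ValueError("at least one matrix is required")
    common = set(matrices[0].probe_ids)
    for m in matrices[1:]:
        common &= set(m.probe_ids)
    if not common:
        raise ValidationError("probe universes have empty intersection")
    shared = sorted(common)
    return [m.restrict(shared) for m in matrices]


# --------------------------------------------------------------------------- #
# pair manifests
# --------------------------------------------------------------------------- #

_MANIFEST_COLUMNS = ["experiment_id", "control_id", "condition", "dataset"]


def read_pair_manifest(path: str | Path) -> PairManifest:
    """Read a TSV manifest with columns experiment_id, control_id, condition, dataset."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"manifest missing column(s): {missing}")
    entries = tuple(
        PairEntry(r.experiment_id, r.control_id, r.condition, r.dataset)
        for r in df.itertuples(index=False)
    )
    return PairManifest(entries)


def write_pair_manifest(manifest: PairManifest, path: str | Path) -> None:
    df = pd.DataFrame(list(manifest.entries), columns=_MANIFEST_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------- #
# probe rank lists
# --------------------------------------------------------------------------- #

def write_prl(prl: ProbeRankList, path: str | Path) -> None:
    """Serialize as two-column TSV ``rank<TAB>probe_id``, rank 1..N."""
    df = pd.DataFrame(
        {"rank": np.arange(1, len(prl) + 1), "probe_id": prl.ordering}
    )
    df.to_csv(path, sep="\t", index=False)


def read_prl(path: str | Path) -> ProbeRankList:
    df = pd.read_csv(path, sep="\t", dtype={"rank": int, "probe_id": str})
    if list(df.columns) != ["rank", "probe_id"]:
        raise FormatError(f"expected columns ['rank', 'probe_id'], got {list(df.columns)}")
    ranks = df["rank"].to_numpy()
    if not np.array_equal(ranks, np.arange(1, len(df) + 1)):
        raise FormatError("ranks are not contiguous 1..N")
    if df["probe_id"].duplicated().any():
        raise FormatError("rank list is not a permutation: duplicate probe ids")
    return ProbeRankList(df["probe_id"].to_numpy(dtype=str))


# --------------------------------------------------------------------------- #
# distance matrices
# --------------------------------------------------------------------------- #

def write_distance_matrix(dm, path: str | Path) -> None:
    """Square TSV with identical row/column labels; 12 significant digits."""
    dm.to_frame().to_csv(path, sep="\t", index_label="", float_format="%.12g")


def read_distance_matrix(path: str | Path):
    from .distance import DistanceMatrix

    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if list(df.index) != list(df.columns):
        raise FormatError("row and column labels differ")
    values = df.to_numpy(dtype=float)
    if not np.allclose(values, values.T, rtol=0, atol=1e-9):
        raise FormatError("distance matrix is not symmetric")
    try:
        return DistanceMatrix(list(df.index), values)
    except ValueError as exc:  # diagonal / range violations
        raise FormatError(str(exc)) from exc
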