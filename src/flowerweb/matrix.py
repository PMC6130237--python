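"""Quantitative bipartite interaction webs.

The central object is :class:`InteractionMatrix`: a rectangular table of
non-negative integer visit counts with plants (the lower trophic level) on
the rows and flower visitors (the higher trophic level) on the columns.
Every downstream metric in this package assumes that orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WebFormatError",
    "WebValidationError",
    "InteractionMatrix",
    "VisitRecord",
    "read_matrix",
    "write_matrix",
    "read_records",
    "write_records",
    "from_records",
    "merge_networks",
    "binarize",
]


class WebFormatError(ValueError):
    """A delimited-text web could not be parsed (ragged rows, non-numeric
    cells, duplicate labels ...)."""


class WebValidationError(ValueError):
    """A parsed web violates an invariant (negative/fractional counts,
    empty rows or columns, label collisions)."""


def _check_labels(labels: Sequence[str], axis: str) -> tuple[str, ...]:
    cleaned = tuple(str(l).strip() for l in labels)
    if any(not l for l in cleaned):
        raise WebValidationError(f"empty {axis} label")
    dupes = sorted({l for l in cleaned if list(cleaned).count(l) > 1})
    if dupes:
        raise WebValidationError(f"duplicate {axis} labels: {dupes}")
    return cleaned


@dataclass(frozen=True)
class InteractionMatrix:
    """A validated plant x visitor visit-count matrix.

    Parameters
    ----------
    row_labels : plant (lower-level) species identifiers.
    col_labels : visitor (higher-level) species identifiers.
    counts : non-negative integer array of shape ``(R, C)``; ``counts[i, j]``
        is the number of recorded visits of visitor *j* on flowers of
        plant *i*.
    habitat : optional free-text tag for the habitat the web came from.

    Validation guarantees unique labels, integral non-negative counts and
    that every species has at least one recorded interaction.
    """

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: np.ndarray
    habitat: str | None = None

    def __post_init__(self) -> None:
        rows = _check_labels(self.row_labels, "row")
        cols = _check_labels(self.col_labels, "column")
        arr = np.asarray(self.counts)
        if arr.ndim != 2 or arr.shape != (len(rows), len(cols)):
            raise WebValidationError(
                f"counts shape {arr.shape} does not match "
                f"{len(rows)} rows x {len(cols)} columns"
            )
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.equal(np.mod(arr, 1), 0)):
                raise WebValidationError("counts must be integral")
            arr = arr.astype(np.int64)
        if np.any(arr < 0):
            raise WebValidationError("counts must be non-negative")
        empty_rows = [rows[i] for i in np.flatnonzero(arr.sum(axis=1) == 0)]
        if empty_rows:
            raise WebValidationError(
                f"species with no interactions (rows): {empty_rows}"
            )
        empty_cols = [cols[j] for j in np.flatnonzero(arr.sum(axis=0) == 0)]
        if empty_cols:
            raise WebValidationError(
                f"species with no interactions (columns): {empty_cols}"
            )
        arr = arr.astype(np.int64)
        arr.setflags(write=False)
        object.__setattr__(self, "row_labels", rows)
        object.__setattr__(self, "col_labels", cols)
        object.__setattr__(self, "counts", arr)

    # -- basic descriptors -------------------------------------------------
    @property
    def R(self) -> int:
        """Number of plant (lower-level) species."""
        return len(self.row_labels)

    @property
    def C(self) -> int:
        """Number of visitor (higher-level) species."""
        return len(self.col_labels)

    @property
    def m(self) -> int:
        """Grand total of visits."""
        return int(self.counts.sum())

    @property
    def links(self) -> int:
        """Number of distinct realised plant-visitor links."""
        return int(np.count_nonzero(self.counts))

    @property
    def size(self) -> int:
        """Network size: total species over both guilds."""
        return self.R + self.C

    @property
    def row_degrees(self) -> np.ndarray:
        return np.count_nonzero(self.counts, axis=1)

    @property
    def col_degrees(self) -> np.ndarray:
        return np.count_nonzero(self.counts, axis=0)

    # -- interop -----------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts.copy(),
            index=list(self.row_labels),
            columns=list(self.col_labels),
        )

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, habitat: str | None = None
    ) -> "InteractionMatrix":
        return cls(
            row_labels=tuple(map(str, frame.index)),
            col_labels=tuple(map(str, frame.columns)),
            counts=frame.to_numpy(),
            habitat=habitat,
        )

    def transpose(self) -> "InteractionMatrix":
        """Swap guilds (rows become columns). Mainly for symmetry checks."""
        return InteractionMatrix(
            self.col_labels, self.row_labels, self.counts.T, self.habitat
        )


@dataclass(frozen=True)
class VisitRecord:
    """One long-format census row: a visitor seen on a plant in a habitat."""

    habitat: str
    plant: str
    butterfly: str
    count: int

    def __post_init__(self) -> None:
        if not (self.habitat and self.plant and self.butterfly):
            raise WebValidationError("record fields must be non-empty")
        if int(self.count) < 1:
            raise WebValidationError("record count must be >= 1")


# ---------------------------------------------------------------------------
# IO

_DELIMS = ("\t", ",", ";")


def _sniff_delimiter(first_line: str) -> str:
    counts = {d: first_line.count(d) for d in _DELIMS}
    best = max(counts, key=counts.get)  # type: ignore[arg-type]
    if counts[best] == 0:
        raise WebFormatError("could not detect delimiter (tab/comma/semicolon)")
    return best


def read_matrix(
    path: str | Path,
    rows_are_plants: bool = True,
    habitat: str | None = None,
) -> InteractionMatrix:
    """Read a wide-format web: header row of visitor labels, first column of
    plant labels, integer body.  If ``rows_are_plants`` is False the file is
    transposed on read so rows are always the lower level."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    delim = _sniff_delimiter(first)
    try:
        frame = pd.read_csv(path, sep=delim, index_col=0)
    except pd.errors.ParserError as exc:
        raise WebFormatError(f"{path.name}: {exc}") from exc
    frame.index = [str(i).strip() for i in frame.index]
    frame.columns = [str(c).strip() for c in frame.columns]
    bad = [c for c in frame.columns if not np.issubdtype(frame[c].dtype, np.number)]
    if bad or frame.isna().any().any():
        raise WebFormatError(
            f"{path.name}: non-numeric or missing cells in columns {bad or '?'}"
        )
    arr = frame.to_numpy()
    if not np.all(np.equal(np.mod(arr, 1), 0)):
        i, j = np.argwhere(np.mod(arr, 1) != 0)[0]
        raise WebFormatError(
            f"{path.name}: fractional count at row {frame.index[i]!r}, "
            f"column {frame.columns[j]!r}"
        )
    if not rows_are_plants:
        frame = frame.T
    return InteractionMatrix.from_frame(frame, habitat=habitat)


def write_matrix(M: InteractionMatrix, path: str | Path, sep: str = "\t") -> None:
    M.to_frame().to_csv(path, sep=sep)


def write_records(records: Iterable[VisitRecord], path: str | Path, sep: str = "\t") -> None:
    frame = pd.DataFrame(
        [(r.habitat, r.plant, r.butterfly, r.count) for r in records],
        columns=["habitat", "plant", "butterfly", "count"],
    )
    frame.to_csv(path, sep=sep, index=False)


def read_records(path: str | Path) -> list[VisitRecord]:
    """Read long-format census records (habitat, plant, butterfly, count)."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    delim = _sniff_delimiter(first)
    frame = pd.read_csv(path, sep=delim)
    expected = ["habitat", "plant", "butterfly", "count"]
    if [c.strip().lower() for c in frame.columns[:4]] != expected:
        raise WebFormatError(f"{path.name}: expected columns {expected}")
    return [
        VisitRecord(str(h).strip(), str(p).strip(), str(b).strip(), int(c))
        for h, p, b, c in frame.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# Construction and algebra


def from_records(records: Sequence[VisitRecord]) -> dict[str, InteractionMatrix]:
    """Pivot long-format records into one validated web per habitat.

    Duplicate (habitat, plant, butterfly) entries are summed; labels are
    sorted lexicographically so the result is deterministic regardless of
    record order.
    """
    if not records:
        raise WebValidationError("empty record list")
    out: dict[str, InteractionMatrix] = {}
    by_hab: dict[str, list[VisitRecord]] = {}
    for r in records:
        by_hab.setdefault(r.habitat, []).append(r)
    for hab in sorted(by_hab):
        recs = by_hab[hab]
        plants = sorted({r.plant for r in recs})
        buts = sorted({r.butterfly for r in recs})
        counts = np.zeros((len(plants), len(buts)), dtype=np.int64)
        pi = {p: i for i, p in enumerate(plants)}
        bi = {b: j for j, b in enumerate(buts)}
        for r in recs:
            counts[pi[r.plant], bi[r.butterfly]] += r.count
        out[hab] = InteractionMatrix(tuple(plants), tuple(buts), counts, habitat=hab)
    return out


def merge_networks(
    matrices: Sequence[InteractionMatrix], new_habitat: str | None = None
) -> InteractionMatrix:
    """Sum webs cell-wise over the union of their species labels.

    The merged grand total equals the sum of the inputs' grand totals; the
    operation is commutative and associative in its effect on counts.
    """
    if not matrices:
        raise WebValidationError("need at least one matrix to merge")
    plants = sorted(set().union(*(m.row_labels for m in matrices)))
    buts = sorted(set().union(*(m.col_labels for m in matrices)))
    counts = np.zeros((len(plants), len(buts)), dtype=np.int64)
    pi = {p: i for i, p in enumerate(plants)}
    bi = {b: j for j, b in enumerate(buts)}
    for M in matrices:
        ridx = [pi[p] for p in M.row_labels]
        cidx = [bi[b] for b in M.col_labels]
        counts[np.ix_(ridx, cidx)] += M.counts
    return InteractionMatrix(tuple(plants), tuple(buts), counts, habitat=new_habitat)


def binarize(M: InteractionMatrix | np.ndarray) -> np.ndarray:
    """Presence/absence incidence: 1 where a visit count is positive."""
    arr = M.counts if isinstance(M, InteractionMatrix) else np.asarray(M)
    return (arr > 0).astype(np.int64)
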