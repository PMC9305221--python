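"""Domain types and I/O for weighted bipartite interaction networks.

The central object is :class:`WeightedBipartiteNetwork`: a labeled matrix of
nonnegative integer interaction counts with rows = consumer taxa (bats) and
columns = resource taxa (plants).  A cell holds the number of observed
interaction events for that bat-plant pair (here: individual bats whose
faeces contained DNA of that plant taxon).

Matrices travel as CSV (header row = plant labels, first column = bat
labels, the R ``write.csv`` convention) or as a three-column TSV edge list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "WeightedBipartiteNetwork",
    "EdgeList",
    "NetworkError",
    "ParseError",
    "ValidationError",
    "DegenerateNetworkError",
    "read_matrix",
    "write_matrix",
    "read_edge_list",
    "write_edge_list",
    "from_edge_list",
    "to_edge_list",
    "drop_empty",
]


class NetworkError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(NetworkError):
    """A file cell could not be interpreted as a nonnegative integer count."""


class ValidationError(NetworkError):
    """An input violates a structural contract (duplicate labels, bad counts...)."""


class DegenerateNetworkError(NetworkError):
    """A network has no rows or no columns left after hygiene."""


#: Relative tolerance used when accepting integral-valued decimals like "3.0".
INTEGER_TOLERANCE = 1e-9


def _check_labels(labels: Sequence[str], guild: str) -> list[str]:
    labels = [str(l).strip() for l in labels]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValidationError(f"duplicate {guild} labels: {dupes}")
    return labels


@dataclass
class WeightedBipartiteNetwork:
    """A labeled consumers x resources count matrix.

    Parameters
    ----------
    row_labels
        Ordered unique consumer (bat) taxon names.
    col_labels
        Ordered unique resource (plant) taxon names.
    weights
        Nonnegative integer matrix, shape ``(len(row_labels), len(col_labels))``.
    meta
        Free-form provenance tags (site, season, year, source path...).
    """

    row_labels: list[str]
    col_labels: list[str]
    weights: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.row_labels = _check_labels(self.row_labels, "consumer (row)")
        self.col_labels = _check_labels(self.col_labels, "resource (column)")
        w = np.asarray(self.weights)
        if w.ndim != 2 or w.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValidationError(
                f"weights shape {w.shape} does not match labels "
                f"({len(self.row_labels)}x{len(self.col_labels)})"
            )
        if w.size and not np.issubdtype(w.dtype, np.integer):
            rounded = np.rint(w)
            if np.nanmax(np.abs(w - rounded)) > INTEGER_TOLERANCE * np.maximum(1, np.abs(rounded)).max():
                raise ValidationError("weights must be integer-valued counts")
            w = rounded
        w = w.astype(np.int64, copy=True)
        if w.size and w.min() < 0:
            raise ValidationError("weights must be nonnegative")
        self.weights = w

    # -- basic descriptors ------------------------------------------------
    @property
    def n_rows(self) -> int:
        return len(self.row_labels)

    @property
    def n_cols(self) -> int:
        return len(self.col_labels)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def total_weight(self) -> int:
        """Total number of interaction events, T."""
        return int(self.weights.sum())

    @property
    def n_links(self) -> int:
        """Number of realized links L (nonzero cells)."""
        return int(np.count_nonzero(self.weights))

    @property
    def row_totals(self) -> np.ndarray:
        return self.weights.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.weights.sum(axis=0)

    def links(self) -> set[tuple[str, str]]:
        """The link set as (bat label, plant label) pairs."""
        ii, jj = np.nonzero(self.weights)
        return {(self.row_labels[i], self.col_labels[j]) for i, j in zip(ii, jj)}

    def is_hygienic(self) -> bool:
        """True when every row and column has at least one interaction."""
        return (
            self.n_rows > 0
            and self.n_cols > 0
            and bool((self.row_totals > 0).all())
            and bool((self.col_totals > 0).all())
        )

    def copy(self, **meta_updates) -> "WeightedBipartiteNetwork":
        meta = dict(self.meta)
        meta.update(meta_updates)
        return WeightedBipartiteNetwork(
            list(self.row_labels), list(self.col_labels), self.weights.copy(), meta
        )

    def with_weights(self, weights: np.ndarray) -> "WeightedBipartiteNetwork":
        """Same labels and meta, new weight matrix (used by null models)."""
        return WeightedBipartiteNetwork(
            list(self.row_labels), list(self.col_labels), np.asarray(weights), dict(self.meta)
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WeightedBipartiteNetwork):
            return NotImplemented
        return (
            self.row_labels == other.row_labels
            and self.col_labels == other.col_labels
            and np.array_equal(self.weights, other.weights)
        )


@dataclass
class EdgeList:
    """Records of (consumer label, resource label, count >= 1), unique per pair."""

    records: list[tuple[str, str, int]]

    def __post_init__(self) -> None:
        cleaned = []
        seen: set[tuple[str, str]] = set()
        for bat, plant, count in self.records:
            bat, plant = str(bat).strip(), str(plant).strip()
            count = int(count)
            if count < 1:
                raise ValidationError(f"edge ({bat}, {plant}) has count {count} < 1")
            if (bat, plant) in seen:
                raise ValidationError(f"duplicate edge ({bat}, {plant})")
            seen.add((bat, plant))
            cleaned.append((bat, plant, count))
        self.records = cleaned

    def __len__(self) -> int:
        return len(self.records)


def _coerce_count(value, row_label: str, col_label: str) -> int:
    try:
        x = float(value)
    except (TypeError, ValueError):
        raise ParseError(
            f"non-numeric cell at row '{row_label}', column '{col_label}': {value!r}"
        ) from None
    if not np.isfinite(x):
        raise ParseError(f"non-finite cell at row '{row_label}', column '{col_label}'")
    if x < 0:
        raise ParseError(f"negative cell at row '{row_label}', column '{col_label}': {x}")
    r = round(x)
    if abs(x - r) > INTEGER_TOLERANCE * max(1.0, abs(r)):
        raise ParseError(
            f"non-integral cell at row '{row_label}', column '{col_label}': {x}"
        )
    return int(r)


def read_matrix(
    path: str | Path, *, transpose: bool = False, meta: Mapping | None = None
) -> WeightedBipartiteNetwork:
    """Read an interaction matrix CSV.

    Layout: first header row holds the plant (column) labels, first column the
    bat (row) labels; the header's first cell may be blank.  Cells must parse
    as nonnegative integers; integral decimals like ``"3.0"`` are accepted.
    ``transpose=True`` reads files written in the plants x bats orientation.
    No hygiene is applied: empty rows/columns are kept as read.
    """
    path = Path(path)
    df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    if transpose:
        df = df.T
    row_labels = [str(x).strip() for x in df.index]
    col_labels = [str(x).strip() for x in df.columns]
    weights = np.empty(df.shape, dtype=np.int64)
    raw = df.to_numpy()
    for i, rl in enumerate(row_labels):
        for j, cl in enumerate(col_labels):
            weights[i, j] = _coerce_count(raw[i, j], rl, cl)
    full_meta = {"source": str(path)}
    if meta:
        full_meta.update(meta)
    return WeightedBipartiteNetwork(row_labels, col_labels, weights, full_meta)


def write_matrix(net: WeightedBipartiteNetwork, path: str | Path) -> Path:
    """Write a network as CSV in the dialect :func:`read_matrix` accepts."""
    if net.n_rows == 0 or net.n_cols == 0:
        raise ValidationError("refusing to write a network with an empty guild")
    path = Path(path)
    df = pd.DataFrame(net.weights, index=net.row_labels, columns=net.col_labels)
    df.to_csv(path)
    return path


def from_edge_list(
    edges: EdgeList, *, meta: Mapping | None = None
) -> WeightedBipartiteNetwork:
    """Build the count matrix whose cell (i, j) is the count of record (i, j).

    An edge list carries no guild ordering, so labels are sorted
    lexicographically within each guild; the matrix round-trip
    ``from_edge_list(to_edge_list(net)) == drop_empty(net)`` therefore holds
    for networks whose labels are already sorted.
    """
    row_labels = sorted({bat for bat, _, _ in edges.records})
    col_labels = sorted({plant for _, plant, _ in edges.records})
    ri = {l: i for i, l in enumerate(row_labels)}
    ci = {l: j for j, l in enumerate(col_labels)}
    weights = np.zeros((len(row_labels), len(col_labels)), dtype=np.int64)
    for bat, plant, count in edges.records:
        weights[ri[bat], ci[plant]] = count
    return WeightedBipartiteNetwork(row_labels, col_labels, weights, dict(meta or {}))


def to_edge_list(net: WeightedBipartiteNetwork) -> EdgeList:
    """Nonzero cells as (bat, plant, count) records; zero cells are omitted."""
    ii, jj = np.nonzero(net.weights)
    records = [
        (net.row_labels[i], net.col_labels[j], int(net.weights[i, j]))
        for i, j in zip(ii, jj)
    ]
    return EdgeList(records)


def read_edge_list(path: str | Path) -> EdgeList:
    """Read a TSV edge list with header ``bat<TAB>plant<TAB>count``."""
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    if list(df.columns[:3]) != ["bat", "plant", "count"]:
        raise ParseError(
            f"edge list {path} must have header 'bat\\tplant\\tcount', got {list(df.columns)}"
        )
    records = [
        (str(r.bat), str(r.plant), _coerce_count(r.count, str(r.bat), str(r.plant)))
        for r in df.itertuples()
    ]
    return EdgeList(records)


def write_edge_list(edges: EdgeList, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(edges.records, columns=["bat", "plant", "count"])
    df.to_csv(path, sep="\t", index=False)
    return path


def drop_empty(net: WeightedBipartiteNetwork) -> WeightedBipartiteNetwork:
    """Remove rows/columns whose marginal total is zero, preserving order.

    Logs the dropped labels.  Raises :class:`DegenerateNetworkError` if
    nothing remains in either guild.
    """
    keep_r = net.row_totals > 0
    keep_c = net.col_totals > 0
    dropped_rows = [l for l, k in zip(net.row_labels, keep_r) if not k]
    dropped_cols = [l for l, k in zip(net.col_labels, keep_c) if not k]
    if dropped_rows or dropped_cols:
        logger.info(
            "drop_empty: removed %d rows %s and %d columns %s",
            len(dropped_rows), dropped_rows, len(dropped_cols), dropped_cols,
        )
    if not keep_r.any() or not keep_c.any():
        raise DegenerateNetworkError("network has no interacting species left")
    return WeightedBipartiteNetwork(
        [l for l, k in zip(net.row_labels, keep_r) if k],
        [l for l, k in zip(net.col_labels, keep_c) if k],
        net.weights[np.ix_(keep_r, keep_c)],
        dict(net.meta, dropped_rows=dropped_rows, dropped_cols=dropped_cols),
    )


def require_hygienic(net: WeightedBipartiteNetwork) -> WeightedBipartiteNetwork:
    """Validate that ``net`` has no empty rows/columns; raise otherwise."""
    if not net.is_hygienic():
        raise DegenerateNetworkError(
            "network has empty rows or columns; apply drop_empty first"
        )
    return net
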