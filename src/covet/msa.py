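"""Reading, validation, redundancy filtering and query mapping of alignments.

The central container is :class:`Alignment`: an aligned set of protein
sequences over the 20 standard amino acids plus the gap character, with one
row designated as the query (reference) sequence.  All downstream scoring is
reported on query positions, so the mapping from alignment columns to
1-based query positions lives here too.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

from .alphabet import ALPHABET, GAP, encode_sequence

__all__ = [
    "Alignment",
    "QueryColumnMap",
    "read_alignment",
    "write_alignment",
    "map_query_columns",
    "filter_redundant",
]


@dataclass(frozen=True)
class Alignment:
    """A validated multiple sequence alignment with a designated query row.

    Parameters
    ----------
    sequence_ids
        Unique identifiers, one per row.
    rows
        Equal-length uppercase strings over the 21-character alphabet.
    query_id
        Identifier of the reference sequence; must be one of ``sequence_ids``.
    """

    sequence_ids: tuple[str, ...]
    rows: tuple[str, ...]
    query_id: str
    _matrix: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.sequence_ids) != len(self.rows):
            raise ValueError("sequence_ids and rows differ in length")
        if len(set(self.sequence_ids)) != len(self.sequence_ids):
            raise ValueError("sequence identifiers are not unique")
        if not self.rows:
            raise ValueError("alignment has no sequences")
        length = len(self.rows[0])
        if length < 1:
            raise ValueError("alignment has zero columns")
        for sid, row in zip(self.sequence_ids, self.rows):
            if len(row) != length:
                raise ValueError(
                    f"ragged alignment: record {sid!r} has length {len(row)}, "
                    f"expected {length}"
                )
            for col, c in enumerate(row):
                if c not in ALPHABET:
                    raise ValueError(
                        f"illegal character {c!r} in record {sid!r} at column "
                        f"{col + 1} (allowed: 20 standard amino acids and '-')"
                    )
        if self.query_id not in self.sequence_ids:
            raise ValueError(f"query id {self.query_id!r} not present in alignment")
        matrix = np.stack([encode_sequence(r) for r in self.rows])
        object.__setattr__(self, "_matrix", matrix)

    # -- basic accessors ---------------------------------------------------
    @property
    def n_sequences(self) -> int:
        return len(self.rows)

    @property
    def column_count(self) -> int:
        return len(self.rows[0])

    @property
    def query_index(self) -> int:
        return self.sequence_ids.index(self.query_id)

    @property
    def query_row(self) -> str:
        return self.rows[self.query_index]

    def as_matrix(self) -> np.ndarray:
        """Integer-encoded alignment, shape (n_sequences, column_count)."""
        return self._matrix

    def row(self, sequence_id: str) -> str:
        return self.rows[self.sequence_ids.index(sequence_id)]

    def subset(self, keep_ids: list[str]) -> "Alignment":
        """Restrict to the given sequences, preserving row order."""
        keep = set(keep_ids)
        ids = tuple(s for s in self.sequence_ids if s in keep)
        rows = tuple(r for s, r in zip(self.sequence_ids, self.rows) if s in keep)
        return Alignment(ids, rows, self.query_id)


@dataclass(frozen=True)
class QueryColumnMap:
    """Mapping between alignment columns and 1-based query positions.

    Holds one ``(column, position)`` entry per alignment column where the
    query row is not a gap; both coordinates are 1-based and strictly
    increasing.
    """

    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        cols = [c for c, _ in self.pairs]
        pos = [p for _, p in self.pairs]
        if sorted(cols) != cols or sorted(pos) != pos:
            raise ValueError("query column map must be strictly increasing")

    @property
    def columns(self) -> tuple[int, ...]:
        """1-based alignment columns carrying query residues."""
        return tuple(c for c, _ in self.pairs)

    @property
    def positions(self) -> tuple[int, ...]:
        """1-based query positions, consecutive from 1."""
        return tuple(p for _, p in self.pairs)

    def column_to_position(self, column: int) -> int:
        for c, p in self.pairs:
            if c == column:
                return p
        raise KeyError(f"alignment column {column} is a gap in the query")

    def __len__(self) -> int:
        return len(self.pairs)


def _normalize(seq: str) -> str:
    return seq.upper().replace(".", GAP)


def read_alignment(path, query_id: str, fmt: str = "fasta") -> Alignment:
    """Read an aligned FASTA (or Stockholm) file into an :class:`Alignment`.

    Characters are uppercased and '.' gaps normalized to '-'.  Raises
    ``ValueError`` for ragged records, illegal characters, or a missing
    query.
    """
    if fmt not in ("fasta", "stockholm"):
        raise ValueError(f"unsupported alignment format {fmt!r}")
    records = list(SeqIO.parse(str(path), fmt))
    if not records:
        raise ValueError(f"no sequences found in {path}")
    ids = tuple(r.id for r in records)
    rows = tuple(_normalize(str(r.seq)) for r in records)
    return Alignment(ids, rows, query_id)


def write_alignment(aln: Alignment, path) -> None:
    """Write the alignment as aligned FASTA (round-trips with read)."""
    with open(path, "w") as fh:
        for sid, row in zip(aln.sequence_ids, aln.rows):
            fh.write(f">{sid}\n{row}\n")


def map_query_columns(aln: Alignment) -> QueryColumnMap:
    """Map non-gap query columns to consecutive 1-based query positions."""
    pairs = []
    pos = 0
    for col, c in enumerate(aln.query_row, start=1):
        if c != GAP:
            pos += 1
            pairs.append((col, pos))
    if not pairs:
        raise ValueError("query row contains only gaps")
    return QueryColumnMap(tuple(pairs))


def pairwise_identity(row_a: str, row_b: str) -> float:
    """Fraction of identical non-gap column pairs.

    Denominator is the number of columns where at least one row is non-gap;
    an all-gap pair of rows has identity 0.
    """
    match = 0
    occupied = 0
    for x, y in zip(row_a, row_b):
        if x == GAP and y == GAP:
            continue
        occupied += 1
        if x == y and x != GAP:
            match += 1
    return match / occupied if occupied else 0.0


def filter_redundant(aln: Alignment, max_identity: float = 0.98) -> Alignment:
    """Collapse clusters of near-identical sequences to one representative.

    Sequences are clustered by single linkage at ``max_identity`` (pairwise
    identity strictly greater than the threshold links two rows).  Each
    cluster keeps the member with the highest identity to the query, ties
    broken by alignment row order; the query itself is always retained.
    Idempotent and deterministic.
    """
    if not (0.0 < max_identity <= 1.0):
        raise ValueError("max_identity must be in (0, 1]")
    n = aln.n_sequences
    qi = aln.query_index
    # single-linkage components under identity > threshold
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if pairwise_identity(aln.rows[i], aln.rows[j]) > max_identity:
                parent[find(i)] = find(j)

    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)

    keep: list[int] = []
    for members in clusters.values():
        if qi in members:
            keep.append(qi)
            continue
        best = max(
            members,
            key=lambda i: (pairwise_identity(aln.rows[i], aln.rows[qi]), -i),
        )
        keep.append(best)
    keep.sort()
    if len(keep) < n:
        warnings.warn(
            f"redundancy filter removed {n - len(keep)} of {n} sequences "
            f"(identity > {max_identity:g})",
            stacklevel=2,
        )
    return aln.subset([aln.sequence_ids[i] for i in keep])
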