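"""Pair covariation scores over a level partition of a phylogenetic tree.

Two methods are implemented on the same tree traversal:

* the perplexity-penalty score (CovET): for every tree level n and every
  group g at that level, the nonconcerted variations observed between
  members of g at a column pair (i, j) are tabulated, and the group is
  penalized by exp(H) of their frequency distribution (H = Shannon entropy,
  natural log).  Groups whose members conserve or co-vary both columns incur
  the minimum penalty 1.  The total score is

      score(i, j) = 1 + sum_{n=1}^{N-1} (1/n) sum_{g in level n} exp(H_g)

  so a pair consistent with the tree everywhere scores exactly N (the
  number of sequences) and every score is >= N; LOWER means more coupled.

* the MI-based comparator (ET-MIp): the same level/group sum applied to the
  average-product-corrected mutual information of the pair within each
  group; HIGHER means more coupled.

A transition between two sequences at a column pair is *conserved* when
both columns agree, *concerted* when both differ, and *nonconcerted* when
exactly one differs.  Only nonconcerted transitions are penalized: they are
the one pattern that directly contradicts a coupling.

Implementation notes: group frequency tables are additive along the tree
(a parent's contingency table is the sum of its children's), and each node
participates in a contiguous range of levels, so every node is scored once
with a harmonic-sum weight instead of once per level.  Entropy sums reduce
to moments of the per-node (character_i, character_j) contingency tables,
which vectorizes over all column pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from itertools import combinations, product
from math import comb

import numpy as np
import pandas as pd

from .alphabet import ALPHABET, ALPHABET_SIZE, is_valid_char
from .msa import Alignment, map_query_columns
from .phylogeny import LevelPartition, TreeNode

__all__ = [
    "TransitionKind",
    "TransitionClass",
    "classify_transition",
    "enumerate_transition_classes",
    "covet_group_penalty",
    "covet_scores",
    "group_mutual_information",
    "apc_correct",
    "etmip_scores",
    "PairScoreTable",
]


class TransitionKind(str, Enum):
    CONSERVATION = "conservation"
    CONCERTED = "concerted"
    NONCONCERTED = "nonconcerted"


@dataclass(frozen=True)
class TransitionClass:
    """Outcome of comparing a column pair between two sequences.

    ``category`` is the ordered observation tuple (xa_i, xa_j, xb_i, xb_j);
    for nonconcerted transitions it identifies the penalized variation v.
    """

    kind: TransitionKind
    category: tuple[str, str, str, str]


def classify_transition(
    xa_i: str, xa_j: str, xb_i: str, xb_j: str
) -> TransitionClass:
    """Classify the change at a column pair between sequences a and b."""
    for c in (xa_i, xa_j, xb_i, xb_j):
        if not is_valid_char(c):
            raise ValueError(f"character {c!r} not in the 21-letter alphabet")
    same_i = xa_i == xb_i
    same_j = xa_j == xb_j
    if same_i and same_j:
        kind = TransitionKind.CONSERVATION
    elif not same_i and not same_j:
        kind = TransitionKind.CONCERTED
    else:
        kind = TransitionKind.NONCONCERTED
    return TransitionClass(kind, (xa_i, xa_j, xb_i, xb_j))


def enumerate_transition_classes(alphabet_size: int = ALPHABET_SIZE):
    """Closed-form counts of the three transition classes.

    Over an alphabet of size a there are a^4 ordered observation tuples:
    a^2 conservations, a^2 (a-1)^2 concerted variations and 2 a^2 (a-1)
    nonconcerted variations.
    """
    a = alphabet_size
    if a < 2:
        raise ValueError("alphabet size must be >= 2")
    total = a**4
    conservation = a**2
    concerted = a**2 * (a - 1) ** 2
    nonconcerted = 2 * a**2 * (a - 1)
    assert conservation + concerted + nonconcerted == total
    return total, conservation, concerted, nonconcerted


def _canonical_nc_category(
    xa_i: str, xa_j: str, xb_i: str, xb_j: str
) -> tuple[str, str, str, str]:
    """Direction-free label for a nonconcerted variation.

    The comparison of two sequences has no intrinsic direction, so the
    tuple is canonicalized by sorting on the varying column; counting is
    then invariant to reordering sequences within a group.
    """
    if xa_i == xb_i:  # column j varies
        lo, hi = sorted((xa_j, xb_j))
        return (xa_i, lo, xb_i, hi)
    lo, hi = sorted((xa_i, xb_i))
    return (lo, xa_j, hi, xb_j)


@dataclass(frozen=True)
class GroupPenalty:
    """Perplexity exp(H) of one group's nonconcerted-variation spectrum."""

    value: float
    frequencies: dict[tuple[str, str, str, str], float]

    def __post_init__(self) -> None:
        if self.value < 1.0 - 1e-12:
            raise ValueError("group penalty must be >= 1")


def covet_group_penalty(
    column_i,
    column_j,
    normalization: str = "comparisons",
) -> GroupPenalty:
    """Penalty of a single group at a column pair.

    All C(m, 2) unordered comparisons between the m group members are
    classified; nonconcerted variation categories v are counted (direction
    canonicalized by character order) and converted to frequencies f_v.  The
    penalty is exp(-sum f_v ln f_v), the perplexity of the nonconcerted
    spectrum: 1 when no nonconcerted variation occurs, larger the more
    diverse the uncoupled variation.

    ``normalization`` selects the frequency denominator: ``"comparisons"``
    (default) divides counts by C(m, 2); ``"events"`` divides by the total
    number of nonconcerted events so the f_v sum to 1.
    """
    ci = list(column_i)
    cj = list(column_j)
    if len(ci) != len(cj):
        raise ValueError("column views must have equal group size")
    m = len(ci)
    if m == 0:
        raise ValueError("empty group")
    if normalization not in ("comparisons", "events"):
        raise ValueError(f"unknown normalization {normalization!r}")
    counts: dict[tuple[str, str, str, str], int] = {}
    for a, b in combinations(range(m), 2):
        tc = classify_transition(ci[a], cj[a], ci[b], cj[b])
        if tc.kind is TransitionKind.NONCONCERTED:
            v = _canonical_nc_category(ci[a], cj[a], ci[b], cj[b])
            counts[v] = counts.get(v, 0) + 1
    if not counts:
        return GroupPenalty(1.0, {})
    denom = comb(m, 2) if normalization == "comparisons" else sum(counts.values())
    freqs = {v: c / denom for v, c in counts.items()}
    entropy = -sum(f * np.log(f) for f in freqs.values())
    return GroupPenalty(float(np.exp(entropy)), freqs)


# ---------------------------------------------------------------------------
# pair score tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PairScoreTable:
    """Raw covariation score for every unordered pair of query positions.

    ``positions`` are 1-based query positions; ``matrix`` holds the score at
    [i, j] for i < j (position indices into ``positions``).  The
    ``lower_is_coupled`` flag records score orientation: True for the
    perplexity-penalty method, False for the MI-based one.
    """

    positions: tuple[int, ...]
    matrix: np.ndarray
    method: str
    lower_is_coupled: bool
    n_sequences: int

    def __post_init__(self) -> None:
        k = len(self.positions)
        if self.matrix.shape != (k, k):
            raise ValueError("score matrix shape does not match positions")

    @property
    def n_positions(self) -> int:
        return len(self.positions)

    def score(self, pos_i: int, pos_j: int) -> float:
        if pos_i == pos_j:
            raise ValueError("pair requires two distinct positions")
        a = self.positions.index(min(pos_i, pos_j))
        b = self.positions.index(max(pos_i, pos_j))
        return float(self.matrix[a, b])

    def iter_pairs(self):
        k = len(self.positions)
        for a in range(k):
            for b in range(a + 1, k):
                yield self.positions[a], self.positions[b], float(self.matrix[a, b])

    def ranked_pairs(self) -> list[tuple[int, int, float]]:
        """Pairs sorted most-coupled first; ties by (smaller, larger) index."""
        sign = 1.0 if self.lower_is_coupled else -1.0
        return sorted(self.iter_pairs(), key=lambda t: (sign * t[2], t[0], t[1]))

    def to_dataframe(self) -> pd.DataFrame:
        ranked = self.ranked_pairs()
        npairs = len(ranked)
        return pd.DataFrame(
            {
                "pos_i": [i for i, _, _ in ranked],
                "pos_j": [j for _, j, _ in ranked],
                "raw_score": [s for _, _, s in ranked],
                "rank": np.arange(1, npairs + 1),
                "coverage": np.arange(1, npairs + 1) / npairs,
            }
        )

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            orient = "lower_is_coupled" if self.lower_is_coupled else "higher_is_coupled"
            fh.write(
                f"# method={self.method} orientation={orient} "
                f"n_sequences={self.n_sequences} n_positions={self.n_positions}\n"
            )
            self.to_dataframe().to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# vectorized per-node machinery
# ---------------------------------------------------------------------------


def _check_levels(aln: Alignment, levels: LevelPartition) -> None:
    if set(levels.tree.leaf_names) != set(aln.sequence_ids):
        raise ValueError("level partition was built from a different sequence set")


def _harmonic_weights(levels: LevelPartition) -> list[tuple[TreeNode, float]]:
    """Each node's total 1/n weight over the levels (1..N-1) it is a group."""
    n = levels.n_sequences
    hcum = np.concatenate(([0.0], np.cumsum(1.0 / np.arange(1, n + 1))))

    def hsum(a: int, b: int) -> float:  # sum_{k=a}^{b} 1/k
        if b < a:
            return 0.0
        return float(hcum[b] - hcum[a - 1])

    out = []
    for node, first, last in levels.node_level_spans():
        w = hsum(first, min(last, n - 1))
        if w > 0.0:
            out.append((node, w))
    return out


def _contingency(sub: np.ndarray) -> np.ndarray:
    """Joint character counts T[i, j, x, y] for an (m, L) coded submatrix."""
    m, ncol = sub.shape
    onehot = np.zeros((m, ncol, ALPHABET_SIZE))
    onehot[np.arange(m)[:, None], np.arange(ncol)[None, :], sub] = 1.0
    return np.einsum("mia,mjb->ijab", onehot, onehot, optimize=True)


def _node_penalty_matrix(
    table: np.ndarray, m: int, normalization: str
) -> np.ndarray:
    """Perplexity penalties for all column pairs of one group.

    Nonconcerted categories at a pair (i, j) are, for each conserved
    character x at i, the unordered pairs {y1, y2} of distinct characters at
    j (count T[x, y1] * T[x, y2]), and symmetrically with the roles of i and
    j swapped.  Their entropy reduces to moments of T: with phi(c) = c ln c,

        sum_cat phi(count) = sum_{x,y} phi(T[x,y]) * (M_col[..] - T[x,y])
        sum_cat count      = (sum_x M_i[x]^2 - sum T^2) / 2  (+ symmetric)

    which avoids enumerating categories.
    """
    ncol = table.shape[0]
    marg_i = table.sum(axis=3)[:, 0, :]  # (L, 21): counts at column i
    with np.errstate(divide="ignore", invalid="ignore"):
        logt = np.where(table > 0, np.log(np.where(table > 0, table, 1.0)), 0.0)
    e1 = table * logt  # phi(T)
    e3_sum = (table * e1).sum(axis=(2, 3))  # sum T^2 ln T
    sq_sum = (table**2).sum(axis=(2, 3))  # sum T^2
    a1 = np.einsum("ijxy,ix->ij", e1, marg_i, optimize=True) - e3_sum
    a2 = np.einsum("ijxy,jy->ij", e1, marg_i, optimize=True) - e3_sum
    p_i = (marg_i**2).sum(axis=1)  # (L,)
    n1 = (p_i[:, None] - sq_sum) / 2.0
    n2 = (p_i[None, :] - sq_sum) / 2.0
    c_ln_c = a1 + a2
    n_events = n1 + n2
    if normalization == "comparisons":
        denom = float(comb(m, 2))
    else:
        denom = np.where(n_events > 0, n_events, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_denom = np.log(denom)
    sum_f_ln_f = np.where(
        n_events > 0, (c_ln_c - n_events * log_denom) / denom, 0.0
    )
    return np.exp(-sum_f_ln_f)


def _iter_node_tables(levels: LevelPartition, coded: np.ndarray, row_index):
    """Yield (node, weight, m, contingency table) bottom-up over the tree.

    Tables are additive (parent = left + right), so each is built once; the
    generator yields only nodes with positive level weight.
    """
    weights = dict(
        (id(node), w) for node, w in _harmonic_weights(levels)
    )

    def build(node: TreeNode):
        """Return (table, m) for node, yielding weighted nodes on the way."""
        if node.is_leaf:
            sub = coded[[row_index[node.name]], :]
            table = _contingency(sub)
            m = 1
        else:
            left, ml = yield from build(node.children[0])
            right, mr = yield from build(node.children[1])
            table = left + right
            m = ml + mr
        w = weights.get(id(node), 0.0)
        if w > 0.0:
            yield node, w, m, table
        return table, m

    gen = build(levels.tree.root)
    yield from gen


def covet_scores(
    aln: Alignment,
    levels: LevelPartition,
    normalization: str = "comparisons",
) -> PairScoreTable:
    """Perplexity-penalty covariation score for all query-position pairs.

    score(i, j) = 1 + sum over tree levels n = 1..N-1 of (1/n) times the sum
    of the group penalties at that level.  Lower is more coupled; the
    minimum N is attained exactly when no group at any level shows
    nonconcerted variation at the pair.
    """
    _check_levels(aln, levels)
    qmap = map_query_columns(aln)
    cols = np.array(qmap.columns) - 1
    coded = aln.as_matrix()[:, cols]
    row_index = {sid: k for k, sid in enumerate(aln.sequence_ids)}
    k = len(cols)
    total = np.zeros((k, k))
    for _node, w, m, table in _iter_node_tables(levels, coded, row_index):
        if m < 2:
            total += w  # singleton groups always contribute penalty 1
        else:
            total += w * _node_penalty_matrix(table, m, normalization)
    matrix = 1.0 + total
    matrix[np.tril_indices(k)] = 0.0
    return PairScoreTable(
        positions=qmap.positions,
        matrix=matrix,
        method="covet",
        lower_is_coupled=True,
        n_sequences=aln.n_sequences,
    )


# ---------------------------------------------------------------------------
# mutual information comparator
# ---------------------------------------------------------------------------


def group_mutual_information(column_i, column_j) -> float:
    """MI(i, j) = H_i + H_j - H_ij within one group, natural log."""
    ci = list(column_i)
    cj = list(column_j)
    m = len(ci)
    if m != len(cj):
        raise ValueError("column views must have equal group size")
    if m == 0:
        raise ValueError("empty group")
    if m == 1:
        return 0.0

    def entropy(symbols) -> float:
        _, counts = np.unique(np.array(symbols, dtype=object), return_counts=True)
        p = counts / m
        return float(-(p * np.log(p)).sum())

    h_i = entropy(ci)
    h_j = entropy(cj)
    h_ij = entropy([x + y for x, y in zip(ci, cj)])
    return h_i + h_j - h_ij


def apc_correct(mi: np.ndarray) -> np.ndarray:
    """Average product correction: MIp = MI - mean_i * mean_j / grand mean.

    ``mi`` is a symmetric matrix over positions (diagonal ignored).  The
    row means and the grand mean are taken over distinct pairs only; a zero
    grand mean (e.g. a fully conserved group) makes the correction zero.
    """
    mi = np.asarray(mi, dtype=float)
    k = mi.shape[0]
    if mi.shape != (k, k) or not np.allclose(mi, mi.T):
        raise ValueError("MI table must be square and symmetric")
    if k < 2:
        return np.zeros_like(mi)
    off = mi.copy()
    np.fill_diagonal(off, 0.0)
    row_mean = off.sum(axis=1) / (k - 1)
    grand = off.sum() / (k * (k - 1))
    if grand == 0.0:
        apc = np.zeros_like(mi)
    else:
        apc = np.outer(row_mean, row_mean) / grand
    out = mi - apc
    np.fill_diagonal(out, 0.0)
    return out


def _node_mi_matrix(table: np.ndarray, m: int) -> np.ndarray:
    """MI for all column pairs of one group from its contingency tensor."""
    p = table / m

    def plogp(x: np.ndarray) -> np.ndarray:
        return np.where(x > 0, x * np.log(np.where(x > 0, x, 1.0)), 0.0)

    marg_i = p.sum(axis=3)[:, 0, :]  # (L, 21)
    h = -plogp(marg_i).sum(axis=1)  # (L,)
    h_joint = -plogp(p).sum(axis=(2, 3))  # (L, L)
    mi = h[:, None] + h[None, :] - h_joint
    np.fill_diagonal(mi, 0.0)
    return np.clip(mi, 0.0, None)


def etmip_scores(aln: Alignment, levels: LevelPartition) -> PairScoreTable:
    """MI-based comparator: level-weighted sum of per-group MIp matrices.

    score(i, j) = sum over levels n = 1..N-1 of (1/n) times the sum over the
    groups of that level of the group's average-product-corrected mutual
    information at (i, j).  Higher is more coupled.
    """
    _check_levels(aln, levels)
    qmap = map_query_columns(aln)
    cols = np.array(qmap.columns) - 1
    coded = aln.as_matrix()[:, cols]
    row_index = {sid: k for k, sid in enumerate(aln.sequence_ids)}
    k = len(cols)
    total = np.zeros((k, k))
    for _node, w, m, table in _iter_node_tables(levels, coded, row_index):
        if m < 2:
            continue  # singleton group: MI identically zero
        total += w * apc_correct(_node_mi_matrix(table, m))
    matrix = total.copy()
    matrix[np.tril_indices(k)] = 0.0
    return PairScoreTable(
        positions=qmap.positions,
        matrix=matrix,
        method="etmip",
        lower_is_coupled=False,
        n_sequences=aln.n_sequences,
    )
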