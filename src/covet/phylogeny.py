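"""ET sequence distances, UPGMA tree construction and level partitions.

The Evolutionary Trace framework scores residue (pair) variation against a
phylogenetic tree built from a similarity-thresholded sequence distance:
two aligned characters count as equivalent when their BLOSUM62 log-odds is
at least 2, the distance between two rows is one minus the fraction of
equivalent columns over the shorter effective (non-gap) length, and a UPGMA
tree over that distance matrix supplies, for every level n, a partition of
the sequences into n groups obtained by cutting the n-1 highest nodes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from Bio.Align import substitution_matrices

from .alphabet import GAP
from .msa import Alignment

__all__ = [
    "SubstitutionThresholdRule",
    "DistanceMatrix",
    "TreeNode",
    "UltrametricTree",
    "LevelPartition",
    "et_distance",
    "distance_matrix",
    "build_upgma",
    "level_partition",
]


class SubstitutionThresholdRule:
    """Binary match rule: f(x, y) = 1 iff BLOSUM62(x, y) >= threshold.

    Gap log-odds against any character (including itself) are fixed at 0, so
    a gap never matches anything at the default threshold of 2.
    """

    def __init__(self, threshold: int = 2):
        self.threshold = threshold
        table = substitution_matrices.load("BLOSUM62")
        self._lookup: dict[tuple[str, str], float] = {}
        for x in table.alphabet:
            for y in table.alphabet:
                self._lookup[(x, y)] = float(table[x, y])

    def log_odds(self, x: str, y: str) -> float:
        if x == GAP or y == GAP:
            return 0.0
        try:
            return self._lookup[(x, y)]
        except KeyError:
            raise ValueError(f"characters {x!r}/{y!r} not in BLOSUM62") from None

    def matches(self, x: str, y: str) -> bool:
        return self.log_odds(x, y) >= self.threshold


_DEFAULT_RULE: SubstitutionThresholdRule | None = None


def default_rule() -> SubstitutionThresholdRule:
    global _DEFAULT_RULE
    if _DEFAULT_RULE is None:
        _DEFAULT_RULE = SubstitutionThresholdRule()
    return _DEFAULT_RULE


def et_distance(
    row_a: str, row_b: str, rule: SubstitutionThresholdRule | None = None
) -> float:
    """ET distance between two aligned rows, in [0, 1].

    1 - (number of columns whose characters match under the BLOSUM62
    threshold rule) / min(non-gap length of a, non-gap length of b).  A row
    of gaps only makes the denominator zero; the distance is then defined as
    the maximum 1.0 (with a warning) since no similarity is measurable.
    """
    if len(row_a) != len(row_b):
        raise ValueError("rows must have equal aligned length")
    rule = rule or default_rule()
    matches = sum(1 for x, y in zip(row_a, row_b) if rule.matches(x, y))
    len_a = sum(1 for x in row_a if x != GAP)
    len_b = sum(1 for x in row_b if x != GAP)
    denom = min(len_a, len_b)
    if denom == 0:
        warnings.warn(
            "row of gaps only: ET distance undefined, returning 1.0", stacklevel=2
        )
        return 1.0
    return 1.0 - matches / denom


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distance matrix indexed by sequence id."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if v.min() < 0 or v.max() > 1 + 1e-12:
            raise ValueError("distances must lie in [0, 1]")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        return float(self.values[self.ids.index(a), self.ids.index(b)])

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\t".join(("id",) + self.ids) + "\n")
            for i, sid in enumerate(self.ids):
                row = "\t".join(f"{x:.10g}" for x in self.values[i])
                fh.write(f"{sid}\t{row}\n")


def distance_matrix(
    aln: Alignment, rule: SubstitutionThresholdRule | None = None
) -> DistanceMatrix:
    """All-pairs ET distance over the alignment rows."""
    rule = rule or default_rule()
    n = aln.n_sequences
    d = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        d[i, j] = d[j, i] = et_distance(aln.rows[i], aln.rows[j], rule)
    return DistanceMatrix(aln.sequence_ids, d)


@dataclass(eq=False)
class TreeNode:
    """Node of a rooted binary ultrametric tree."""

    height: float
    children: tuple["TreeNode", ...] = ()
    name: str | None = None  # leaf label
    min_leaf: str = field(init=False)

    def __post_init__(self) -> None:
        if self.children:
            self.min_leaf = min(c.min_leaf for c in self.children)
        else:
            if self.name is None:
                raise ValueError("leaf node requires a name")
            self.min_leaf = self.name

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()


@dataclass(frozen=True)
class UltrametricTree:
    """Rooted binary tree with merge heights (UPGMA output)."""

    root: TreeNode

    @property
    def leaf_names(self) -> list[str]:
        return self.root.leaves()

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_names)

    def internal_nodes(self) -> list[TreeNode]:
        return [n for n in self.root.walk() if not n.is_leaf]

    def to_newick(self) -> str:
        def fmt(node: TreeNode, parent_height: float) -> str:
            bl = parent_height - node.height
            if node.is_leaf:
                return f"{node.name}:{bl:.10g}"
            inner = ",".join(fmt(c, node.height) for c in node.children)
            return f"({inner}):{bl:.10g}"

        inner = ",".join(fmt(c, self.root.height) for c in self.root.children)
        return f"({inner});"


def build_upgma(d: DistanceMatrix) -> UltrametricTree:
    """Average-linkage (UPGMA) agglomeration of the distance matrix.

    Node heights equal half the merge distance, so leaf-to-root path
    lengths are all equal.  When several candidate merges share the minimal
    distance, the pair whose lexicographically least leaf label is smallest
    (then the smallest label of the partner cluster) is merged, which makes
    the tree reproducible.
    """
    n = len(d.ids)
    if n < 2:
        raise ValueError("UPGMA requires at least two sequences")
    nodes: list[TreeNode] = [TreeNode(0.0, name=sid) for sid in d.ids]
    sizes = [1] * n
    dist = d.values.astype(float).copy()
    active = list(range(n))

    while len(active) > 1:
        best: tuple[float, str, str] | None = None
        best_pair: tuple[int, int] | None = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                lo, hi = sorted((nodes[i].min_leaf, nodes[j].min_leaf))
                key = (dist[i, j], lo, hi)
                if best is None or key < best:
                    best = key
                    best_pair = (i, j)
        i, j = best_pair
        merge_d = dist[i, j]
        new = TreeNode(merge_d / 2.0, children=(nodes[i], nodes[j]))
        # weighted average linkage update
        ni, nj = sizes[i], sizes[j]
        for k in active:
            if k in (i, j):
                continue
            dnew = (ni * dist[i, k] + nj * dist[j, k]) / (ni + nj)
            dist[i, k] = dist[k, i] = dnew
        nodes[i] = new
        sizes[i] = ni + nj
        active.remove(j)

    root = nodes[active[0]]
    return UltrametricTree(root)


@dataclass(frozen=True)
class LevelPartition:
    """Partitions of the sequence set into n groups for n = 1..N.

    Level n is obtained by cutting the n-1 highest internal nodes of the
    tree, starting from the root; each successive level splits exactly one
    group into its two children.  ``cut_order`` records the internal nodes
    in the order they are cut; equal-height candidates are cut in order of
    their lexicographically least leaf.
    """

    tree: UltrametricTree
    cut_order: tuple[TreeNode, ...]

    @property
    def n_sequences(self) -> int:
        return self.tree.n_leaves

    def group_nodes(self, level: int) -> list[TreeNode]:
        """The nodes whose leaf sets form the groups at the given level."""
        n = self.n_sequences
        if not (1 <= level <= n):
            raise ValueError(f"level must be in 1..{n}")
        cut = set(id(node) for node in self.cut_order[: level - 1])
        groups: list[TreeNode] = []

        def descend(node: TreeNode) -> None:
            if id(node) in cut:
                for c in node.children:
                    descend(c)
            else:
                groups.append(node)

        descend(self.tree.root)
        groups.sort(key=lambda g: g.min_leaf)
        return groups

    def groups(self, level: int) -> list[list[str]]:
        """Sequence-id groups at the given level (n groups at level n)."""
        return [g.leaves() for g in self.group_nodes(level)]

    def node_level_spans(self) -> list[tuple[TreeNode, int, int]]:
        """For every tree node, the inclusive level range where it is a group.

        The root is a group at level 1 only; any other node is a group from
        the level after its parent is cut until it is cut itself (leaves:
        until level N).  Together with the 1/n level weights this gives each
        node's total contribution to an ET-style sum without enumerating
        levels explicitly.
        """
        n = self.n_sequences
        cut_index = {id(node): k + 1 for k, node in enumerate(self.cut_order)}
        spans: list[tuple[TreeNode, int, int]] = []
        parent_of: dict[int, TreeNode] = {}
        for node in self.tree.root.walk():
            for c in node.children:
                parent_of[id(c)] = node
        for node in self.tree.root.walk():
            if id(node) in parent_of:
                first = cut_index[id(parent_of[id(node)])] + 1
            else:
                first = 1  # root
            last = cut_index[id(node)] if not node.is_leaf else n
            spans.append((node, first, last))
        return spans


def level_partition(tree: UltrametricTree) -> LevelPartition:
    """Order internal nodes for cutting: highest merge height first.

    Only nodes whose parent is already cut are eligible, so the partitions
    nest; ties in height are broken by the node's lexicographically least
    leaf label.
    """
    cut_order: list[TreeNode] = []
    frontier: list[TreeNode] = [tree.root] if not tree.root.is_leaf else []
    while frontier:
        frontier.sort(key=lambda nd: (-nd.height, nd.min_leaf))
        node = frontier.pop(0)
        cut_order.append(node)
        for c in node.children:
            if not c.is_leaf:
                frontier.append(c)
    return LevelPartition(tree, tuple(cut_order))
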