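"""Synthetic alignments with planted coupled pairs, and toy structures.

The alignment simulator evolves a root sequence down a random bifurcating
tree.  Along every branch each position substitutes independently with a
fixed per-branch probability — except at planted coupled pairs, where a
substitution at one member recruits a simultaneous substitution at its
partner with the coupling probability.  Coupled pairs therefore accumulate
concerted variation and background pairs nonconcerted variation, which is
precisely the contrast the perplexity-penalty score is built to detect;
the planted labels are the ground truth for recovery tests.

Substituted characters are drawn uniformly from the 19 alternatives (no
indels, no substitution-matrix bias), and the tree is a coalescent-style
random bifurcation with exponential depth increments — deliberately
simple, known and reproducible rather than realistic.

The toy structure generator lays residues on an extended chain (consecutive
Ca 3.8 A apart) and collapses designated residue sets into compact spatial
clusters (all intra-cluster atom distances < 4 A), giving exact geometric
ground truth for the contact and clustering statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import AMINO_ACIDS
from .msa import Alignment
from .structure import Residue, StructureModel

__all__ = [
    "SimulationSpec",
    "PlantedTruth",
    "simulate_coupled_alignment",
    "toy_structure",
]

DEFAULT_LEAVES = 64
DEFAULT_LENGTH = 50
DEFAULT_SUBSTITUTION = 0.05
DEFAULT_COUPLING = 0.9
DEFAULT_N_PAIRS = 5


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one simulated family.

    ``coupled_pairs`` are 1-based position pairs, mutually disjoint;
    ``coupling`` is the probability that a substitution at one member of a
    pair forces a simultaneous substitution at the other.  The seed is
    mandatory: every simulation is reproducible by construction.
    """

    seed: int
    n_leaves: int = DEFAULT_LEAVES
    length: int = DEFAULT_LENGTH
    substitution_prob: float = DEFAULT_SUBSTITUTION
    coupled_pairs: tuple[tuple[int, int], ...] = field(default=None)  # type: ignore[assignment]
    coupling: float = DEFAULT_COUPLING

    def __post_init__(self) -> None:
        if self.coupled_pairs is None:
            # default: the first 2k positions paired up (1,2), (3,4), ...
            pairs = tuple(
                (2 * k + 1, 2 * k + 2) for k in range(DEFAULT_N_PAIRS)
            )
            object.__setattr__(self, "coupled_pairs", pairs)
        if self.n_leaves < 2:
            raise ValueError("need at least two leaves")
        if not (0.0 <= self.substitution_prob <= 1.0):
            raise ValueError("substitution probability must be in [0, 1]")
        if not (0.0 <= self.coupling <= 1.0):
            raise ValueError("coupling probability must be in [0, 1]")
        flat = [p for pair in self.coupled_pairs for p in pair]
        if len(set(flat)) != len(flat):
            raise ValueError("planted pairs must be disjoint")
        if self.length < 2 * len(self.coupled_pairs):
            raise ValueError("alignment too short for the planted pairs")
        if any(p < 1 or p > self.length for p in flat):
            raise ValueError("planted pair positions outside the alignment")


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth emitted with a simulated alignment."""

    coupled_pairs: tuple[tuple[int, int], ...]
    newick: str
    root_sequence: str

    def is_coupled(self, i: int, j: int) -> bool:
        return (min(i, j), max(i, j)) in {
            (min(a, b), max(a, b)) for a, b in self.coupled_pairs
        }


def _random_bifurcation(n_leaves: int, rng: np.random.Generator):
    """Random coalescent-style topology with exponential branch lengths.

    Returns (children, branch_len, root) where internal node ids follow the
    leaf ids 0..n_leaves-1.
    """
    lineages = list(range(n_leaves))
    children: dict[int, tuple[int, int]] = {}
    branch_len: dict[int, float] = {}
    heights = {i: 0.0 for i in range(n_leaves)}
    next_id = n_leaves
    height = 0.0
    while len(lineages) > 1:
        height += rng.exponential(1.0 / len(lineages))
        a, b = sorted(rng.choice(len(lineages), size=2, replace=False))
        na, nb = lineages[a], lineages[b]
        children[next_id] = (na, nb)
        branch_len[na] = height - heights[na]
        branch_len[nb] = height - heights[nb]
        heights[next_id] = height
        lineages = [x for k, x in enumerate(lineages) if k not in (a, b)] + [next_id]
        next_id += 1
    root = lineages[0]
    branch_len[root] = 0.0
    return children, branch_len, root


def _newick(children, branch_len, node: int, leaf_name) -> str:
    if node not in children:
        return f"{leaf_name(node)}:{branch_len[node]:.6g}"
    a, b = children[node]
    inner = (
        f"({_newick(children, branch_len, a, leaf_name)},"
        f"{_newick(children, branch_len, b, leaf_name)})"
    )
    return f"{inner}:{branch_len[node]:.6g}"


def simulate_coupled_alignment(
    spec: SimulationSpec,
) -> tuple[Alignment, PlantedTruth]:
    """Evolve a root sequence down a random tree with planted couplings.

    Per branch, each position substitutes with ``substitution_prob``; when
    exactly one member of a planted pair substitutes, its partner is
    recruited with probability ``coupling``.  Substitutions replace the
    character with a uniform random *different* amino acid.  The first leaf
    (``seq000``) is designated the query.  Deterministic given the spec.
    """
    rng = np.random.default_rng(spec.seed)
    children, branch_len, root = _random_bifurcation(spec.n_leaves, rng)
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
    root_seq = rng.integers(0, 20, size=spec.length)
    pair_index = [(a - 1, b - 1) for a, b in spec.coupled_pairs]

    def mutate(seq: np.ndarray) -> np.ndarray:
        out = seq.copy()
        hit = rng.random(spec.length) < spec.substitution_prob
        for ia, ib in pair_index:
            if hit[ia] != hit[ib] and rng.random() < spec.coupling:
                hit[ia] = hit[ib] = True
        for pos in np.nonzero(hit)[0]:
            shift = rng.integers(1, 20)
            out[pos] = (out[pos] + shift) % 20
        return out

    sequences: dict[int, np.ndarray] = {}

    def descend(node: int, seq: np.ndarray) -> None:
        if node not in children:
            sequences[node] = seq
            return
        for child in children[node]:
            descend(child, mutate(seq))

    descend(root, root_seq)

    width = len(str(spec.n_leaves - 1))
    name = lambda k: f"seq{k:0{width}d}"  # noqa: E731
    ids = tuple(name(k) for k in range(spec.n_leaves))
    rows = tuple(
        bytes(aa[sequences[k]]).decode() for k in range(spec.n_leaves)
    )
    aln = Alignment(ids, rows, query_id=ids[0])
    truth = PlantedTruth(
        coupled_pairs=spec.coupled_pairs,
        newick=_newick(children, branch_len, root, name) + ";",
        root_sequence=bytes(aa[root_seq]).decode(),
    )
    return aln, truth


# ---------------------------------------------------------------------------
# toy structures
# ---------------------------------------------------------------------------

CHAIN_SPACING = 3.8  # A between consecutive Ca on the extended chain
CB_OFFSET = 0.8  # A from Ca to Cb in cluster residues
CLUSTER_STANDOFF = 25.0  # A between cluster centers and the chain axis


def toy_structure(
    residue_count: int,
    clusters: list[tuple[set[int], float]] | None = None,
    seed: int = 0,
) -> StructureModel:
    """Extended-chain model with optional planted spatial clusters.

    Non-cluster residues sit on a straight chain with consecutive Ca
    3.8 A apart (only sequence neighbors fall inside the 4 A adjacency
    cutoff).  Each cluster's residues are repositioned on a small sphere of
    the given radius around a center placed well off the chain, so every
    intra-cluster atom pair is < 4 A apart and no cluster residue touches
    the chain.  All residues are alanine-like (Ca + Cb).  Deterministic
    given the seed.
    """
    clusters = clusters or []
    rng = np.random.default_rng(seed)
    in_cluster: set[int] = set()
    for members, radius in clusters:
        if not members <= set(range(1, residue_count + 1)):
            raise ValueError("cluster residues outside 1..residue_count")
        if members & in_cluster:
            raise ValueError("clusters must be disjoint")
        if not (0.0 < radius and 2.0 * (radius + CB_OFFSET) < 4.0):
            raise ValueError(
                f"cluster radius {radius} A cannot keep all atom pairs under 4 A"
            )
        in_cluster |= members

    residues: list[Residue] = []
    placements: dict[int, np.ndarray] = {}
    for k, (members, radius) in enumerate(clusters):
        center = np.array(
            [CHAIN_SPACING * float(np.mean(sorted(members))), CLUSTER_STANDOFF * (k + 1), 0.0]
        )
        for pos in sorted(members):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            placements[pos] = center + radius * direction

    for pos in range(1, residue_count + 1):
        if pos in placements:
            ca = placements[pos]
        else:
            ca = np.array([CHAIN_SPACING * pos, 0.0, 0.0])
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        cb = ca + CB_OFFSET * direction
        residues.append(
            Residue(
                position=pos,
                name="ALA",
                atoms=(
                    ("CA", float(ca[0]), float(ca[1]), float(ca[2])),
                    ("CB", float(cb[0]), float(cb[1]), float(cb[2])),
                ),
            )
        )
    return StructureModel(tuple(residues))
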