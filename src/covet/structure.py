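"""Structural evaluation: contacts, clustering z-scores, functional sites.

Predictions are compared against a structure in several complementary ways:

* contact prediction — the CASP convention: a residue pair at least six
  apart in sequence is a contact when the Cb-Cb distance (Ca for glycine)
  is below 8 A; pairs are split into short [6, 11], medium [12, 23] and
  long [24, inf) sequence-separation classes and scored by AUROC and
  AUPRC (the latter adjusted by the positive rate, the expectation for a
  random predictor);

* selection cluster weighting (SCW) — whether a selected residue set is
  more spatially clustered than a random set of the same size, using the
  any-atom < 4 A adjacency graph.  The statistic w sums A(i,j) b(i,j) over
  selected pairs, with b = 1 (unbiased) or b = |i - j| (biased); the
  z-score compares w with its exact mean and variance under uniform random
  selection (a pair-overlap decomposition), with a seeded Monte-Carlo null
  available as a cross-check;

* functional-site recovery — residues with any atom within 4 A of a ligand
  atom are the gold standard, and recovery of a gold set by a selection is
  scored with the one-sided hypergeometric test.
"""

from __future__ import annotations

from dataclasses import dataclass

import gemmi
import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import hypergeom
from sklearn.metrics import average_precision_score, roc_auc_score

from .ranking import CoverageSelection, ResidueRanking
from .scoring import PairScoreTable

__all__ = [
    "Residue",
    "StructureModel",
    "ContactMap",
    "SCWResult",
    "read_pdb",
    "write_pdb",
    "build_contact_map",
    "evaluate_contact_prediction",
    "evaluate_residue_prediction",
    "scw_w",
    "scw_zscore",
    "functional_residues",
    "hypergeometric_overlap",
    "mean_sequence_separation",
    "selected_pair_components",
]

CONTACT_CUTOFF = 8.0  # A, Cb-Cb (Ca for glycine)
ADJACENCY_CUTOFF = 4.0  # A, any atom pair; also the ligand-proximity cutoff
MIN_SEPARATION = 6


@dataclass(frozen=True)
class Residue:
    position: int  # 1-based query position
    name: str  # three-letter residue name
    atoms: tuple[tuple[str, float, float, float], ...]

    def coords(self) -> np.ndarray:
        return np.array([[x, y, z] for _, x, y, z in self.atoms])

    def atom(self, name: str) -> np.ndarray | None:
        for n, x, y, z in self.atoms:
            if n == name:
                return np.array([x, y, z])
        return None

    def contact_atom(self) -> np.ndarray | None:
        """Cb coordinate, falling back to Ca (always Ca for glycine)."""
        if self.name.upper() == "GLY":
            return self.atom("CA")
        cb = self.atom("CB")
        return cb if cb is not None else self.atom("CA")


@dataclass(frozen=True)
class StructureModel:
    """Per-residue atom coordinates keyed by query position."""

    residues: tuple[Residue, ...]
    resolution: float | None = None

    def __post_init__(self) -> None:
        pos = [r.position for r in self.residues]
        if len(set(pos)) != len(pos):
            raise ValueError("duplicate query positions in structure")
        for r in self.residues:
            if not r.atoms:
                raise ValueError(f"residue {r.position} has no atoms")

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(r.position for r in self.residues)

    def residue(self, position: int) -> Residue:
        for r in self.residues:
            if r.position == position:
                return r
        raise KeyError(f"no residue at position {position}")

    def adjacency(self, cutoff: float = ADJACENCY_CUTOFF) -> dict[tuple[int, int], bool]:
        """Any-atom < cutoff adjacency over residue pairs (i < j)."""
        out: dict[tuple[int, int], bool] = {}
        coords = [r.coords() for r in self.residues]
        pos = self.positions
        for a in range(len(pos)):
            for b in range(a + 1, len(pos)):
                d = cdist(coords[a], coords[b]).min()
                out[(pos[a], pos[b])] = bool(d < cutoff)
        return out


def read_pdb(path, chain: str | None = None) -> StructureModel:
    """Read a single chain of a PDB file into a :class:`StructureModel`.

    Residue numbering in the file is taken as the query position; use an
    explicit mapping upstream if they differ.
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    model = st[0]
    if chain is None:
        if len(model) != 1:
            names = [c.name for c in model]
            raise ValueError(f"multiple chains {names}; select one with chain=")
        ch = model[0]
    else:
        ch = model[chain]
    residues = []
    for res in ch:
        atoms = tuple((a.name, a.pos.x, a.pos.y, a.pos.z) for a in res)
        residues.append(Residue(res.seqid.num, res.name, atoms))
    resolution = st.resolution if st.resolution else None
    return StructureModel(tuple(residues), resolution)


def write_pdb(structure: StructureModel, path, chain: str = "A") -> None:
    """Write the model as a minimal single-chain PDB file."""
    with open(path, "w") as fh:
        serial = 1
        for res in structure.residues:
            for name, x, y, z in res.atoms:
                element = name[0]
                fh.write(
                    f"ATOM  {serial:5d} {name:<4s}{res.name:>3s} {chain}"
                    f"{res.position:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                    f"  1.00  0.00          {element:>2s}\n"
                )
                serial += 1
        fh.write("END\n")


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------

SEPARATION_CLASSES = {
    "short": (6, 11),
    "medium": (12, 23),
    "long": (24, None),
}


def separation_class(sep: int) -> str:
    if sep < MIN_SEPARATION:
        return "excluded"
    for name, (lo, hi) in SEPARATION_CLASSES.items():
        if sep >= lo and (hi is None or sep <= hi):
            return name
    raise AssertionError("unreachable")


@dataclass(frozen=True)
class ContactMap:
    """True contacts and separation classes over structure residue pairs."""

    contacts: dict[tuple[int, int], bool]  # keyed i < j, separation >= 6
    classes: dict[tuple[int, int], str]
    excluded_residues: tuple[int, ...] = ()

    def is_contact(self, i: int, j: int) -> bool:
        return self.contacts[(min(i, j), max(i, j))]

    def pairs_in_class(self, class_filter: str | None = None):
        for pair, cls in self.classes.items():
            if class_filter is None or cls == class_filter:
                yield pair


def build_contact_map(
    structure: StructureModel,
    distance_cutoff: float = CONTACT_CUTOFF,
    min_separation: int = MIN_SEPARATION,
) -> ContactMap:
    """CASP-style contact map from Cb (Ca for glycine) distances.

    Pairs closer than ``min_separation`` in sequence are excluded; residues
    lacking both Cb and Ca are dropped and reported via
    ``excluded_residues``.
    """
    usable: list[tuple[int, np.ndarray]] = []
    excluded: list[int] = []
    for res in structure.residues:
        coord = res.contact_atom()
        if coord is None:
            excluded.append(res.position)
        else:
            usable.append((res.position, coord))
    contacts: dict[tuple[int, int], bool] = {}
    classes: dict[tuple[int, int], str] = {}
    for a in range(len(usable)):
        for b in range(a + 1, len(usable)):
            pi, ci = usable[a]
            pj, cj = usable[b]
            i, j = min(pi, pj), max(pi, pj)
            sep = j - i
            if sep < min_separation:
                continue
            d = float(np.linalg.norm(ci - cj))
            contacts[(i, j)] = d < distance_cutoff
            classes[(i, j)] = separation_class(sep)
    return ContactMap(contacts, classes, tuple(excluded))


def _oriented_scores(pairs: PairScoreTable):
    """Scores with higher = more coupled, for use with rank metrics."""
    sign = -1.0 if pairs.lower_is_coupled else 1.0
    return {(i, j): sign * s for i, j, s in pairs.iter_pairs()}


def evaluate_contact_prediction(
    pairs: PairScoreTable,
    contacts: ContactMap,
    class_filter: str | None = None,
) -> dict[str, float]:
    """AUROC / AUPRC / adjusted AUPRC of pair scores against true contacts.

    All scored pairs of the chosen separation class are evaluated (not a
    top-k subset).  Adjusted AUPRC subtracts the positive rate, the
    expected AUPRC of a random predictor.  Raises if the class contains
    contacts of only one label.
    """
    scores = _oriented_scores(pairs)
    y_true: list[int] = []
    y_score: list[float] = []
    for pair in contacts.pairs_in_class(class_filter):
        if pair in scores:
            y_true.append(int(contacts.contacts[pair]))
            y_score.append(scores[pair])
    if not y_true or len(set(y_true)) < 2:
        raise ValueError(
            f"contact class {class_filter!r} has no evaluable positive/negative split"
        )
    auroc = float(roc_auc_score(y_true, y_score))
    auprc = float(average_precision_score(y_true, y_score))
    positive_rate = float(np.mean(y_true))
    return {
        "auroc": auroc,
        "auprc": auprc,
        "adjusted_auprc": auprc - positive_rate,
        "positive_rate": positive_rate,
        "n_pairs": len(y_true),
    }


def evaluate_residue_prediction(
    ranking: ResidueRanking, gold: set[int], eligible: set[int] | None = None
) -> dict[str, float]:
    """AUROC / adjusted AUPRC of a residue ranking against a gold set."""
    positions = [p for p in ranking.positions if eligible is None or p in eligible]
    sign = -1.0 if ranking.lower_is_coupled else 1.0
    y_true = [int(p in gold) for p in positions]
    y_score = [sign * ranking.score(p) for p in positions]
    if len(set(y_true)) < 2:
        raise ValueError("gold set covers all or none of the ranked residues")
    auroc = float(roc_auc_score(y_true, y_score))
    auprc = float(average_precision_score(y_true, y_score))
    positive_rate = float(np.mean(y_true))
    return {
        "auroc": auroc,
        "auprc": auprc,
        "adjusted_auprc": auprc - positive_rate,
        "positive_rate": positive_rate,
        "n_residues": len(y_true),
    }


# ---------------------------------------------------------------------------
# selection cluster weighting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SCWResult:
    w: float
    expected_w: float
    sd_w: float
    z: float | None  # None when the null variance vanishes
    bias: str  # "unbiased" | "biased"
    null: str  # "analytic" | "montecarlo"


def _edge_weights(
    structure: StructureModel, bias: str
) -> dict[tuple[int, int], float]:
    if bias not in ("unbiased", "biased"):
        raise ValueError(f"bias must be 'unbiased' or 'biased', got {bias!r}")
    adj = structure.adjacency()
    out = {}
    for (i, j), touching in adj.items():
        if touching:
            out[(i, j)] = float(abs(i - j)) if bias == "biased" else 1.0
    return out


def scw_w(
    selected: set[int],
    adjacency: dict[tuple[int, int], bool],
    bias: str = "unbiased",
) -> float:
    """Cluster weight w of a selection over an any-atom adjacency graph.

    Unbiased: the number of adjacent selected pairs.  Biased: the sum of
    sequence separations |i - j| over adjacent selected pairs, which
    up-weights clusters formed by sequence-distant residues.
    """
    if bias not in ("unbiased", "biased"):
        raise ValueError(f"bias must be 'unbiased' or 'biased', got {bias!r}")
    total = 0.0
    for (i, j), touching in adjacency.items():
        if touching and i in selected and j in selected:
            total += float(abs(i - j)) if bias == "biased" else 1.0
    return total


def scw_zscore(
    selected: set[int],
    structure: StructureModel,
    bias: str = "unbiased",
    null: str = "analytic",
    draws: int = 10_000,
    seed: int | None = None,
) -> SCWResult:
    """Clustering z-score of a residue selection on a structure.

    The null model selects |selected| residues uniformly at random from the
    structure.  The analytic moments follow from decomposing E[w^2] over
    pairs of edges sharing two, one or zero residues (inclusion
    probabilities are falling-factorial ratios); the Monte-Carlo null
    redraws selections with a seeded generator and is the validation
    oracle for the analytic route.
    """
    positions = list(structure.positions)
    s = len(selected)
    if s < 2:
        raise ValueError("selection must contain at least 2 residues")
    if not set(selected) <= set(positions):
        raise ValueError("selection contains residues absent from the structure")
    weights = _edge_weights(structure, bias)
    r = len(positions)
    w_obs = sum(
        c for (i, j), c in weights.items() if i in selected and j in selected
    )

    if null == "analytic":
        def falling(n: int, k: int) -> float:
            out = 1.0
            for t in range(k):
                out *= n - t
            return out

        p2 = falling(s, 2) / falling(r, 2)
        p3 = falling(s, 3) / falling(r, 3)
        p4 = falling(s, 4) / falling(r, 4) if r >= 4 else 0.0
        c1 = sum(weights.values())
        c_sq = sum(c * c for c in weights.values())
        deg: dict[int, float] = {}
        for (i, j), c in weights.items():
            deg[i] = deg.get(i, 0.0) + c
            deg[j] = deg.get(j, 0.0) + c
        share1 = sum(d * d for d in deg.values()) - 2.0 * c_sq
        share0 = c1 * c1 - c_sq - share1
        e_w = p2 * c1
        e_w2 = p2 * c_sq + p3 * share1 + p4 * share0
        var = e_w2 - e_w * e_w
        sd = float(np.sqrt(var)) if var > 1e-12 else 0.0
        method = "analytic"
    elif null == "montecarlo":
        rng = np.random.default_rng(seed)
        ws = np.empty(draws)
        pos_arr = np.array(positions)
        for t in range(draws):
            pick = set(rng.choice(pos_arr, size=s, replace=False).tolist())
            ws[t] = sum(
                c for (i, j), c in weights.items() if i in pick and j in pick
            )
        e_w = float(ws.mean())
        sd = float(ws.std(ddof=1))
        method = f"montecarlo(draws={draws})"
    else:
        raise ValueError(f"unknown null method {null!r}")

    z = (w_obs - e_w) / sd if sd > 0 else None
    return SCWResult(float(w_obs), float(e_w), sd, z, bias, method)


# ---------------------------------------------------------------------------
# functional sites and summary statistics
# ---------------------------------------------------------------------------


def functional_residues(
    structure: StructureModel,
    ligand_atoms: np.ndarray,
    cutoff: float = ADJACENCY_CUTOFF,
) -> set[int]:
    """Residues with any atom strictly within ``cutoff`` of a ligand atom."""
    ligand = np.atleast_2d(np.asarray(ligand_atoms, dtype=float))
    if ligand.size == 0:
        raise ValueError("ligand atom list is empty")
    out: set[int] = set()
    for res in structure.residues:
        if cdist(res.coords(), ligand).min() < cutoff:
            out.add(res.position)
    return out


def hypergeometric_overlap(
    selected: set[int], gold: set[int], universe: int
) -> float:
    """One-sided hypergeometric p-value for selection/gold overlap.

    P(X >= |selected & gold|) with X ~ Hypergeom(universe, |gold|,
    |selected|): the chance a random selection of the same size overlaps
    the gold set at least as much.
    """
    if universe <= 0:
        raise ValueError("universe must be positive")
    if len(gold) > universe or len(selected) > universe:
        raise ValueError("selected/gold larger than the universe")
    overlap = len(selected & gold)
    return float(hypergeom.sf(overlap - 1, universe, len(gold), len(selected)))


def mean_sequence_separation(
    selection: CoverageSelection,
    protein_length: int | None = None,
    normalized: bool = False,
) -> float:
    """Mean |i - j| over the selected pairs, optionally / protein length."""
    if not selection.pairs:
        raise ValueError("selection contains no pairs")
    mean = float(np.mean([abs(i - j) for i, j in selection.pairs]))
    if normalized:
        if not protein_length or protein_length <= 0:
            raise ValueError("normalization requires a positive protein length")
        return mean / protein_length
    return mean


def selected_pair_components(selection: CoverageSelection) -> list[list[int]]:
    """Connected components of the graph whose edges are the selected pairs.

    Returns residue clusters sorted by (and internally by) smallest member,
    mirroring the discrete clusters used to color selections on structures.
    """
    import networkx as nx

    if not selection.pairs:
        raise ValueError("selection contains no pairs")
    g = nx.Graph()
    g.add_edges_from(selection.pairs)
    comps = [sorted(c) for c in nx.connected_components(g)]
    return sorted(comps, key=lambda c: c[0])
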