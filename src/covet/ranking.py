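"""Single-residue rankings and coverage-cutoff selections from pair scores.

Evaluations on structures and functional sites operate on residues, not
pairs: a residue is ranked by the best-scoring pair it participates in, and
a "coverage" cutoff of c selects ranked pairs until a fraction c of the
residues appears in at least one selected pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import ceil

import pandas as pd

from .scoring import PairScoreTable

__all__ = ["ResidueRanking", "CoverageSelection", "residue_scores", "coverage_selection"]


@dataclass(frozen=True)
class ResidueRanking:
    """Per-residue best-pair score, rank (1 = most coupled) and coverage."""

    positions: tuple[int, ...]  # ordered by rank
    scores: tuple[float, ...]
    lower_is_coupled: bool

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.scores):
            raise ValueError("positions and scores differ in length")

    def rank(self, position: int) -> int:
        return self.positions.index(position) + 1

    def score(self, position: int) -> float:
        return self.scores[self.positions.index(position)]

    def coverage(self, position: int) -> float:
        return self.rank(position) / len(self.positions)

    def top_fraction(self, fraction: float) -> list[int]:
        """Positions in the best-ranked ``fraction`` (ceil rounding)."""
        if not (0.0 < fraction <= 1.0):
            raise ValueError("fraction must be in (0, 1]")
        k = ceil(fraction * len(self.positions))
        return list(self.positions[:k])

    def to_dataframe(self) -> pd.DataFrame:
        n = len(self.positions)
        return pd.DataFrame(
            {
                "position": self.positions,
                "score": self.scores,
                "rank": range(1, n + 1),
                "coverage": [(r + 1) / n for r in range(n)],
            }
        )


def residue_scores(pairs: PairScoreTable) -> ResidueRanking:
    """Rank residues by the best covariation pair each one participates in.

    Best = minimum raw score when the table is lower-is-coupled, maximum
    otherwise; residues with equal best scores are ordered by ascending
    position index.
    """
    best: dict[int, float] = {}
    pick = min if pairs.lower_is_coupled else max
    for i, j, s in pairs.iter_pairs():
        for p in (i, j):
            best[p] = s if p not in best else pick(best[p], s)
    if not best:
        raise ValueError("pair score table is empty")
    sign = 1.0 if pairs.lower_is_coupled else -1.0
    ordered = sorted(best, key=lambda p: (sign * best[p], p))
    return ResidueRanking(
        positions=tuple(ordered),
        scores=tuple(best[p] for p in ordered),
        lower_is_coupled=pairs.lower_is_coupled,
    )


@dataclass(frozen=True)
class CoverageSelection:
    """Rank-ordered pair prefix covering a target fraction of residues."""

    pairs: tuple[tuple[int, int], ...]
    residues: frozenset[int]
    threshold: float

    def residue_list(self) -> list[int]:
        return sorted(self.residues)


def coverage_selection(
    pairs: PairScoreTable,
    threshold: float,
    residue_count: int | None = None,
    eligible: set[int] | None = None,
) -> CoverageSelection:
    """Select ranked pairs until ``threshold`` of the residues are covered.

    Walks the pair table most-coupled-first, accumulating the union of pair
    members, and stops at the first pair that brings the union to at least
    ceil(threshold * residue_count) residues.  ``residue_count`` defaults to
    the number of positions in the table; ``eligible`` (e.g. the
    structure-resolved positions) restricts both the walked pairs and the
    residues counted toward coverage.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    if residue_count is None:
        residue_count = len(eligible) if eligible is not None else pairs.n_positions
    target = ceil(threshold * residue_count)
    chosen: list[tuple[int, int]] = []
    covered: set[int] = set()
    for i, j, _s in pairs.ranked_pairs():
        if eligible is not None and (i not in eligible or j not in eligible):
            continue
        chosen.append((i, j))
        covered.update((i, j))
        if len(covered) >= target:
            return CoverageSelection(tuple(chosen), frozenset(covered), threshold)
    warnings.warn(
        f"pair table exhausted at {len(covered)}/{target} residues covered",
        stacklevel=2,
    )
    return CoverageSelection(tuple(chosen), frozenset(covered), threshold)
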