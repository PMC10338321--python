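"""Convenience composition of the full scoring pipeline."""

from __future__ import annotations

from .msa import Alignment
from .phylogeny import (
    LevelPartition,
    build_upgma,
    distance_matrix,
    level_partition,
)
from .scoring import PairScoreTable, covet_scores, etmip_scores

__all__ = ["build_levels", "score_alignment"]


def build_levels(aln: Alignment) -> LevelPartition:
    """Distance matrix -> UPGMA tree -> level partition, in one step."""
    return level_partition(build_upgma(distance_matrix(aln)))


def score_alignment(
    aln: Alignment,
    method: str = "covet",
    levels: LevelPartition | None = None,
) -> PairScoreTable:
    """Score all query-position pairs with the chosen method.

    ``method`` is "covet" (perplexity penalty, lower = coupled) or "etmip"
    (MI with average product correction, higher = coupled).  The level
    partition is rebuilt from the alignment unless supplied.
    """
    if levels is None:
        levels = build_levels(aln)
    if method == "covet":
        return covet_scores(aln, levels)
    if method == "etmip":
        return etmip_scores(aln, levels)
    raise ValueError(f"unknown method {method!r} (expected 'covet' or 'etmip')")
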