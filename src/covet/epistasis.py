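"""Epistasis from double-mutant fitness data and correlation with scores.

Deep mutational scans report fitness for single and double mutants on a
wild-type-normalized scale (WT = 1).  An epistasis score is the deviation
of the observed double-mutant fitness M_ab from a null combination of the
single-mutant fitnesses M_a and M_b; four null models are standard:

    product   e = M_ab - M_a * M_b
    additive  e = (M_ab + WT) - (M_a + M_b)
    log       e = M_ab - log2((2^M_a - WT) * (2^M_b - WT) + WT)
    min       e = M_ab - min(M_a, M_b)

Covariation scores carry no mutation identity or sign, so per residue pair
the signed scores over all tested substitution combinations are averaged
first and the absolute value taken; that magnitude (the mean displacement
from wild-type behavior) is what is correlated (Pearson) with the
orientation-adjusted raw covariation score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .scoring import PairScoreTable

__all__ = [
    "FitnessRecord",
    "EPISTASIS_MODELS",
    "epistasis_score",
    "preprocess_fitness",
    "pair_epistasis",
    "correlate_with_covariation",
]

EPISTASIS_MODELS = ("product", "additive", "log", "min")


@dataclass(frozen=True)
class FitnessRecord:
    """One double mutant with its two single-mutant fitness values."""

    pos_a: int
    sub_a: str
    pos_b: int
    sub_b: str
    m_a: float
    m_b: float
    m_ab: float

    def __post_init__(self) -> None:
        if self.pos_a == self.pos_b:
            raise ValueError("double mutant requires two distinct positions")
        for v in (self.m_a, self.m_b, self.m_ab):
            if not np.isfinite(v):
                raise ValueError("fitness values must be finite")

    @property
    def pair(self) -> tuple[int, int]:
        return (min(self.pos_a, self.pos_b), max(self.pos_a, self.pos_b))


def epistasis_score(rec: FitnessRecord, model: str, wt: float = 1.0) -> float:
    """Signed epistasis of one double mutant under the chosen null model.

    The log model is undefined when 2^M_a - WT or 2^M_b - WT make the log2
    argument non-positive; callers should catch the raised ``ValueError``
    and drop the record from that model only.
    """
    ma, mb, mab = rec.m_a, rec.m_b, rec.m_ab
    if model == "product":
        return mab - ma * mb
    if model == "additive":
        return (mab + wt) - (ma + mb)
    if model == "log":
        arg = (2.0**ma - wt) * (2.0**mb - wt) + wt
        if arg <= 0:
            raise ValueError("non-positive log2 argument")
        return mab - float(np.log2(arg))
    if model == "min":
        return mab - min(ma, mb)
    raise ValueError(f"unknown epistasis model {model!r}")


def preprocess_fitness(
    values: pd.Series | np.ndarray,
    transform: str = "none",
    wt_value: float | None = None,
) -> np.ndarray:
    """Bring raw assay scores onto the WT = 1 fitness scale.

    ``exp_lnW`` exponentiates natural-log fitness (lnW = 0 maps to 1);
    ``exp_toxicity_normalized`` exponentiates and divides by the
    transformed wild-type score (``wt_value``, on the raw scale) so the
    wild type lands at 1.
    """
    arr = np.asarray(values, dtype=float)
    if transform == "none":
        return arr
    if transform == "exp_lnW":
        return np.exp(arr)
    if transform == "exp_toxicity_normalized":
        if wt_value is None:
            raise ValueError("normalization requires the wild-type raw score")
        return np.exp(arr) / np.exp(float(wt_value))
    raise ValueError(f"unknown transform {transform!r}")


def pair_epistasis(
    records: list[FitnessRecord], model: str, wt: float = 1.0
) -> dict[tuple[int, int], float]:
    """|mean signed epistasis| per residue pair under one model.

    The mean is over all substitution combinations tested for the pair;
    the absolute value is applied after averaging.  Records with an
    undefined log-model value are skipped (for that model only) and
    reported via a warning.
    """
    sums: dict[tuple[int, int], float] = {}
    counts: dict[tuple[int, int], int] = {}
    skipped = 0
    for rec in records:
        try:
            e = epistasis_score(rec, model, wt)
        except ValueError:
            skipped += 1
            continue
        sums[rec.pair] = sums.get(rec.pair, 0.0) + e
        counts[rec.pair] = counts.get(rec.pair, 0) + 1
    if skipped:
        warnings.warn(
            f"{skipped} records skipped for model {model!r} (undefined value)",
            stacklevel=2,
        )
    return {p: abs(sums[p] / counts[p]) for p in sums}


def read_fitness_tables(doubles_path, singles_path) -> list[FitnessRecord]:
    """Assemble records from a doubles TSV and a singles TSV.

    Doubles columns: pos_a, aa_a, pos_b, aa_b, fitness; singles columns:
    pos, aa, fitness.  Double mutants whose constituent singles were not
    measured are dropped with a warning.
    """
    doubles = pd.read_csv(doubles_path, sep="\t")
    singles = pd.read_csv(singles_path, sep="\t")
    single_map = {
        (int(r.pos), str(r.aa)): float(r.fitness) for r in singles.itertuples()
    }
    records: list[FitnessRecord] = []
    missing = 0
    for r in doubles.itertuples():
        ka, kb = (int(r.pos_a), str(r.aa_a)), (int(r.pos_b), str(r.aa_b))
        if ka not in single_map or kb not in single_map:
            missing += 1
            continue
        records.append(
            FitnessRecord(
                pos_a=ka[0],
                sub_a=ka[1],
                pos_b=kb[0],
                sub_b=kb[1],
                m_a=single_map[ka],
                m_b=single_map[kb],
                m_ab=float(r.fitness),
            )
        )
    if missing:
        warnings.warn(f"{missing} doubles dropped (missing single fitness)", stacklevel=2)
    return records


def correlate_with_covariation(
    pairs: PairScoreTable,
    ep: dict[tuple[int, int], float],
    min_pairs: int = 3,
) -> tuple[float, int]:
    """Pearson r between covariation scores and pair epistasis magnitudes.

    Only pairs present in both tables enter.  Scores are orientation
    adjusted (negated when lower means coupled) so a positive r always
    means "more coupled goes with more epistasis".  Returns (r, n_pairs).
    """
    sign = -1.0 if pairs.lower_is_coupled else 1.0
    xs: list[float] = []
    ys: list[float] = []
    for i, j, s in pairs.iter_pairs():
        key = (min(i, j), max(i, j))
        if key in ep:
            xs.append(sign * s)
            ys.append(ep[key])
    n = len(xs)
    if n < min_pairs:
        raise ValueError(f"only {n} shared pairs (< {min_pairs})")
    if np.std(xs) == 0 or np.std(ys) == 0:
        raise ValueError("zero variance on one side; correlation undefined")
    r, _p = pearsonr(xs, ys)
    return float(r), n
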