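"""Independent brute-force reimplementations used as test oracles.

Everything here is written literal-to-the-definitions with plain Python
dicts and loops, deliberately sharing no numerical code with the package:
the package's vectorized tree-node scoring is checked against these on
small fixtures.
"""

from __future__ import annotations

from itertools import combinations
from math import exp, log

from Bio.Align import substitution_matrices

GAP = "-"
_B62 = substitution_matrices.load("BLOSUM62")


def brute_et_distance(row_a: str, row_b: str) -> float:
    """Literal evaluation of the thresholded-similarity distance."""
    matches = 0
    for x, y in zip(row_a, row_b):
        if x == GAP or y == GAP:
            lo = 0.0
        else:
            lo = _B62[x, y]
        if lo >= 2:
            matches += 1
    len_a = sum(1 for c in row_a if c != GAP)
    len_b = sum(1 for c in row_b if c != GAP)
    return 1.0 - matches / min(len_a, len_b)


def _nc_category(xi_a, xj_a, xi_b, xj_b):
    """Nonconcerted category, canonicalized by character order, else None."""
    if xi_a == xi_b and xj_a != xj_b:
        lo, hi = sorted((xj_a, xj_b))
        return (xi_a, lo, xi_b, hi)
    if xi_a != xi_b and xj_a == xj_b:
        lo, hi = sorted((xi_a, xi_b))
        return (lo, xj_a, hi, xj_b)
    return None


def brute_group_penalty(chars_i, chars_j) -> float:
    """exp(Shannon entropy) of the group's nonconcerted spectrum."""
    m = len(chars_i)
    counts: dict[tuple, int] = {}
    n_comparisons = 0
    for a, b in combinations(range(m), 2):
        n_comparisons += 1
        cat = _nc_category(chars_i[a], chars_j[a], chars_i[b], chars_j[b])
        if cat is not None:
            counts[cat] = counts.get(cat, 0) + 1
    if not counts:
        return 1.0
    h = 0.0
    for c in counts.values():
        f = c / n_comparisons
        h -= f * log(f)
    return exp(h)


def brute_covet(rows: dict[str, str], columns: list[int], level_groups) -> dict:
    """Level-by-level evaluation of the perplexity-penalty score.

    ``rows`` maps sequence id to aligned row; ``columns`` are 0-based
    alignment columns to score; ``level_groups(n)`` returns the id groups
    at level n.  Returns {(col_a, col_b): score} on those columns.
    """
    n_seq = len(rows)
    scores: dict[tuple[int, int], float] = {}
    for ci, cj in combinations(columns, 2):
        total = 1.0
        for n in range(1, n_seq):
            level_sum = 0.0
            for group in level_groups(n):
                chars_i = [rows[sid][ci] for sid in group]
                chars_j = [rows[sid][cj] for sid in group]
                level_sum += brute_group_penalty(chars_i, chars_j)
            total += level_sum / n
        scores[(ci, cj)] = total
    return scores


def brute_mi(chars_i, chars_j) -> float:
    """MI = H_i + H_j - H_ij from explicit frequency dicts, natural log."""
    m = len(chars_i)

    def entropy(items) -> float:
        counts: dict = {}
        for it in items:
            counts[it] = counts.get(it, 0) + 1
        h = 0.0
        for c in counts.values():
            f = c / m
            h -= f * log(f)
        return h

    return entropy(chars_i) + entropy(chars_j) - entropy(list(zip(chars_i, chars_j)))


def brute_mip(rows: dict[str, str], columns: list[int], group) -> dict:
    """Product-corrected MI for one group over the given columns."""
    mi: dict[tuple[int, int], float] = {}
    for ci, cj in combinations(columns, 2):
        chars_i = [rows[sid][ci] for sid in group]
        chars_j = [rows[sid][cj] for sid in group]
        mi[(ci, cj)] = brute_mi(chars_i, chars_j)

    def get(a, b):
        return mi[(min(a, b), max(a, b))] if a != b else 0.0

    k = len(columns)
    mean_i = {
        c: sum(get(c, d) for d in columns if d != c) / (k - 1) for c in columns
    }
    grand = sum(mi.values()) / len(mi) if mi else 0.0
    out = {}
    for (ci, cj), v in mi.items():
        apc = mean_i[ci] * mean_i[cj] / grand if grand != 0.0 else 0.0
        out[(ci, cj)] = v - apc
    return out


def brute_etmip(rows: dict[str, str], columns: list[int], level_groups) -> dict:
    """Level-by-level evaluation of the MI-based comparator score."""
    n_seq = len(rows)
    scores = {(ci, cj): 0.0 for ci, cj in combinations(columns, 2)}
    for n in range(1, n_seq):
        for group in level_groups(n):
            if len(group) < 2:
                continue  # single sequence: all entropies zero
            mip = brute_mip(rows, columns, group)
            for key, v in mip.items():
                scores[key] += v / n
    return scores


def brute_hypergeometric(universe: int, n_gold: int, n_selected: int, overlap: int) -> float:
    """Upper-tail hypergeometric p by exact combinatorics."""
    from math import comb

    total = comb(universe, n_selected)
    p = 0.0
    for k in range(overlap, min(n_gold, n_selected) + 1):
        if n_selected - k > universe - n_gold:
            continue
        p += comb(n_gold, k) * comb(universe - n_gold, n_selected - k) / total
    return p


def brute_scw_moments(edge_weights: dict, positions: list[int], s: int):
    """E[w] and Var[w] under uniform selection by exhaustive enumeration.

    Only feasible for small structures; used to certify the analytic
    pair-overlap decomposition.
    """
    from itertools import combinations as combs

    ws = []
    for pick in combs(positions, s):
        sel = set(pick)
        w = sum(c for (i, j), c in edge_weights.items() if i in sel and j in sel)
        ws.append(w)
    n = len(ws)
    mean = sum(ws) / n
    var = sum((w - mean) ** 2 for w in ws) / n
    return mean, var
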