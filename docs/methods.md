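# Methods

This note records the models, conventions and numerical choices behind the
package, including the decisions taken where the underlying definitions
leave room.

## Tree construction

Pairwise sequence distance is the thresholded-similarity form used by
Evolutionary Trace: two aligned characters are equivalent when their
BLOSUM62 log-odds is ≥ 2 (the threshold is exposed on
`SubstitutionThresholdRule` but 2 is the standard value), gaps have
log-odds 0 against everything and therefore never match, and the match
count is normalized by the smaller non-gap length of the two rows.  A row
consisting only of gaps makes the denominator zero; its distance to
everything is defined as the maximum 1.0 with a warning, on the grounds
that such rows should have been removed upstream.  BLOSUM62 itself comes
from Biopython's `substitution_matrices`.

UPGMA (size-weighted average linkage, node height = merge distance / 2)
is implemented directly rather than through `scipy.cluster.hierarchy`
because reproducibility under ties matters here and scipy does not expose
a tie-break rule.  Ours: among minimal-distance candidate merges, pick the
pair whose lexicographically least leaf label is smallest, then the
smallest label of the partner.  Level partitions cut internal nodes from
the root downward in order of descending height; among equal heights only
nodes whose parent is already cut are eligible, ties broken again by least
leaf label.  These conventions are this package's own choices — any rule
would do scientifically, but a fixed rule makes trees and scores
byte-reproducible.

## The pair score

At a column pair, a comparison of two sequences is conserved, concerted or
nonconcerted (exactly one column differs).  Nonconcerted variation is the
only pattern penalized: it is direct evidence against a coupling, whereas
both conservation and co-variation are compatible with one.  Per group,
the nonconcerted categories observed over all C(m, 2) member comparisons
are counted and the group is charged the perplexity exp(H) of the category
frequency distribution, with f_v = count(v) / C(m, 2) and 0·ln 0 := 0.
The total score is 1 plus the 1/n-weighted sum of group penalties over
tree levels 1..N−1 (the all-singleton level is excluded; singleton groups
at earlier levels contribute the neutral penalty 1).  Consequences worth
knowing:

* the score of a tree-consistent pair is exactly N, and N is a hard floor;
* a two-member group whose single comparison is nonconcerted has f = 1,
  H = 0 and thus penalty 1 — a known degeneracy of the perplexity unit at
  m = 2, left as-is;
* frequencies deliberately do not sum to 1 across categories (the
  denominator counts all comparisons, not just nonconcerted events).  The
  alternative normalization over events only is available as
  `normalization="events"` on `covet_group_penalty`.

Category identity: a comparison has no intrinsic direction, so the
category tuple is canonicalized by character order at the varying column.
An earlier draft keyed categories by alignment row order; that makes the
per-group entropy depend on the order in which sequences happen to be
stored (three rows with pair characters AD, AC, AD yield two categories of
count 1 one way and one category of count 2 the other), violating the
requirement that scores be invariant to reordering sequences within a
group.  Character-canonical counting is permutation-invariant and agrees
with row-order counting whenever each category is observed in a single
direction.

Entropies use natural logarithms throughout, including the mutual
information route, for internal consistency.

The MI comparator applies the same level/group weighting to per-group
average-product-corrected MI.  The APC denominator is the grand mean MI
over distinct pairs (the standard correction); a zero grand mean — fully
conserved group — sets the correction to zero.

### Complexity

Group contingency tables are additive along the tree (parent = left +
right child), and each tree node is a group for a contiguous range of
levels, so every node is scored once with a harmonic-sum weight rather
than once per level.  Entropy sums reduce to moments of the per-node
(char_i, char_j) contingency tensors, vectorized over all column pairs.
The level-by-level literal evaluation is kept in the test suite as the
oracle; the two routes agree to < 1e−9 on the fixtures.  A 64-sequence,
50-column family scores in a few seconds on one core.

## Alignment handling

The alphabet is the 20 standard amino acids plus the gap, which is a
first-class character everywhere (a gap can conserve, co-vary, and appear
in nonconcerted categories).  Other letters (B, Z, X, U, ...) are rejected
at parse time.  Positions are 1-based; only columns where the query row is
non-gap are scored.  Redundancy filtering clusters rows by single linkage
at the identity threshold (identity = identical non-gap pairs / columns
where at least one row is non-gap) and keeps, per cluster, the member most
similar to the query — the query itself always survives.  The identity
denominator is a choice; the alternative (shorter-sequence length) changes
little at the 98% threshold typical for this filter.

## Structural evaluation

Two separate residue graphs are used and never conflated: the CASP contact
definition (Cβ–Cβ < 8 Å, Cα for glycine, sequence separation ≥ 6, classes
short [6, 11], medium [12, 23], long [24, ∞)) for contact prediction
metrics, and the any-atom < 4 Å adjacency for clustering and
ligand-proximity analysis.  AUPRC is reported both raw and adjusted by the
positive rate.  Note the adjusted value for a random predictor is only
approximately zero: the average-precision estimator carries a positive
bias of order 1/(number of positives), about +0.02 at 20 positives in 200
pairs, which the test suite accounts for with a coarse tolerance band.

The SCW statistic is w = Σ_{i<j} S(i) S(j) A(i, j) b(i, j) with S the
selection indicator, A the 4 Å adjacency and b = 1 (unbiased) or |i − j|
(biased).  The null is uniform random selection of the same size.  Its
mean and variance are computed exactly by decomposing E[w²] over edge
pairs sharing two, one or zero residues, whose joint inclusion
probabilities are falling-factorial ratios; this analytic route is the
default and is certified in the tests both against exhaustive enumeration
on 8-residue structures and against a 10,000-draw seeded Monte Carlo on
larger ones.  Variance can vanish (selection = everything); the z-score is
then flagged undefined rather than fabricated.

Hypergeometric overlap p-values are upper-tail (P(X ≥ observed)) via
`scipy.stats.hypergeom.sf`.  Ligand proximity uses strict < 4 Å.

## Epistasis

The four null models follow the deep-mutational-scanning literature
exactly (product, additive, log, min; WT = 1 scale).  Aggregation per
residue pair is mean-of-signed-values, then absolute value — not the mean
of absolute values — so the quantity correlated is the average
displacement from wild-type behavior.  Records whose log-model argument is
non-positive are dropped from the log model only.  Raw assay scales are
brought to WT = 1 by `preprocess_fitness`; "exponential transform" is read
as the natural exponential (the log base differs between source assays, so
it is an explicit argument rather than hard-coded).  Correlations use
Pearson r on orientation-adjusted raw scores (negated when lower means
coupled) over experimentally tested pairs only; fewer than 3 shared pairs
or zero variance raises instead of returning a meaningless number.

## Synthetic data

`simulate_coupled_alignment` is the package's test bed, not a realistic
evolution model.  Defaults: 64 leaves, 50 columns, per-branch substitution
probability 0.05, five planted coupled pairs at coupling 0.9, no gaps or
indels, uniform replacement characters, coalescent-style random topology
with exponential branch-length increments.  The defaults are the standard
conditions for the recovery benchmarks in the tests and acceptance script.
When one member of a planted pair substitutes on a branch, the partner
substitutes too with the coupling probability — concerted in timing but
uncorrelated in identity, which is sufficient for the penalty score to
separate planted from background pairs (mean AUROC ≈ 1.0 at the default
conditions over 20 replicates).  What passing these tests does *not* show:
robustness to alignment error, indels, biased substitution processes,
site-rate heterogeneity, or the deep, unbalanced trees of real Pfam
families.

`toy_structure` places residues on an extended chain (Cα every 3.8 Å, so
only sequence neighbors fall within the 4 Å adjacency) and repositions each
planted cluster onto a small sphere far from the chain so that all
intra-cluster atom pairs are < 4 Å and no cluster residue touches the
chain; radii that cannot satisfy the 4 Å guarantee are rejected.  This
gives exact geometric ground truth for contact-map and SCW tests at the
price of total unreality as protein geometry.

## Problem sizes

Test and acceptance workloads are sized for interactive runs: oracle
equivalence on 4–8-sequence, 8–12-column fixtures; recovery on 20
replicates of the default 64 × 50 simulation; SCW calibration on
20-residue toy structures with 10,000 Monte-Carlo draws; full 21⁴
transition enumeration.  Scores scale to real families (hundreds of
sequences, a few hundred columns) but UPGMA is O(N³) and the per-node
tensors are O(L²·441) memory, so thousands of sequences × long alignments
would need chunking that this implementation does not attempt.

## Known limitations

* The exact tie-break conventions (UPGMA merges, level cuts, equal pair
  scores) are this package's own; other implementations of the same
  score may order ties differently and produce different coverage sets on
  degenerate inputs.
* PDB residue numbering is trusted as the query mapping; no automatic
  re-alignment of structure to query is attempted — mismatches are errors.
* The redundancy filter is O(N²) string comparisons; fine for desk-scale
  alignments, slow for tens of thousands of rows.
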