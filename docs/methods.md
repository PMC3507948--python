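# Methods

This note records the models implemented, the defaults chosen where the
design was genuinely open, and what the synthetic-data tests do and do not
demonstrate.

## Coordinates, alphabets, degenerate inputs

All residue positions and alignment columns are 1-based with inclusive
ranges. The only gap character is `-`; `.` is rejected. `X` is accepted as
a residue but matches nothing — not even another `X` — so identity
percentages, diagnostic scorecards and divergence statistics are never
inflated by unknown residues. Alignments require ≥ 2 members, equal
lengths, and no all-gap column; every member carries a bijection between
residue-bearing columns and ungapped positions, which is the basis for
mapping reference-numbered residues (e.g. "L49") onto alignment columns.

## Distances and neighbor joining

Distances are computed after complete deletion (every column containing a
gap is removed), as p-distance or its Poisson correction −ln(1 − p); the
Poisson model is the default surrogate for model-based protein distances,
and saturated pairs (p = 1) are a hard error rather than an infinity.

Neighbor joining follows the Saitou–Nei Q-criterion. Two determinism rules
are part of the contract: tied minimal Q values are resolved toward the
lexicographically smallest (label-sorted) pair, the sort key of an
internal node being the smallest leaf label beneath it; and a negative
branch-length estimate is clamped to zero with the deficit moved to the
sister branch, preserving the path length through the join. The result is
an unrooted tree (trifurcating seed node). On additive matrices the
algorithm is exact; tests verify this against an exhaustive least-squares
search over all topologies for up to six taxa, and against an independent
library implementation.

Bootstrap supports resample alignment columns with replacement, rebuild
the tree per replicate through the identical distance + NJ path, and
annotate each internal edge of the point-estimate tree with the percentage
of replicates containing the same bipartition (supports go on the point
tree, not a consensus). A replicate whose resampled columns saturate the
Poisson distance carries no split information and is counted against all
splits. All resampling is driven by an explicit seed.

Branch rates divide a branch length by a calibration time (My). The rate
ratio of two calibrated branches is computed from its inputs only; with
one branch twice as long as the other and calibrations of 50 vs 500 My the
ratio is 20.

## Pairwise identity and similarity

Global alignment uses Needleman–Wunsch with affine gaps via Biopython's
`PairwiseAligner`: BLOSUM62, gap open 10, gap extend 0.5, end gaps free
(approximating classic CLUSTAL W defaults). Percent identity is identical
pairs over aligned pairs — columns with a residue in both sequences — and
percent similarity additionally counts pairs within a CLUSTAL strong
group (STA, NEQK, NHQK, NDEQ, QHRK, MILV, MILF, HY, FYW). The summary is
made exactly symmetric by canonicalizing the argument order before
aligning.

## Type-II divergence statistic

Published tools for cluster-specific ("type-II") functional divergence
report an internal divergence score whose definition is not reproducible
from their output alone. This package instead defines a transparent
statistic per column:

    T = f_A · f_B · [cons_A ≠ cons_B]

where cons and f are the modal residue and its frequency among non-gap
members of each clade (ties alphabetical). T is 1 exactly when both clades
are internally fixed for different residues. Significance comes from
re-partitioning the pooled member labels into groups of the original
sizes: when the number of distinct partitions is ≤ 10,000 the p-value is
exact by enumeration; otherwise it is the add-one permutation estimate
p = (1 + #{T* ≥ T}) / (n_perm + 1) over seeded draws. Scores are −log10 p,
giving the conventional "score > 3" cut the exact meaning p < 0.001; the
threshold is configurable. Note that with n permutations the smallest
achievable sampled p is 1/(n+1), so detecting sites at score > 3 requires
n_perm ≥ 9,999 — the default used in recovery analyses here.

Columns where a clade is entirely gapped are reported with p = 1. The
statistic is invariant to swapping the clades and to alignment member
order, and in exact mode a perfect 5+5 split yields p = 2/252 (the two
labelings that reproduce the split among C(10,5) partitions).

## Neighborhood enrichment

Whether predicted sites cluster near known critical residues is tested
with a one-sided hypergeometric tail. The success region is the union —
not the sum, so clustered critical residues are not double-counted — of
the ±w windows around the critical positions, clipped to [1, N]; with K
region positions and n predicted sites of which x fall inside,
p = P(X ≥ x) for X ~ Hypergeom(N, K, n). N defaults to the reference
protein's ungapped length. Tests verify the tail against brute-force
enumeration of all position subsets for N ≤ 12.

## Peptide mass fingerprinting

Trypsin cleaves after K or R except before P; peptides are enumerated for
all runs of up to `max_missed` internal sites, and at zero missed
cleavages the digest exactly partitions the parent. Monoisotopic and
average residue masses are embedded constants, each unit-tested against an
elemental-composition oracle; peptide mass = Σ residues + water
(18.010565 Da). Modification deltas: Met oxidation +15.994915 per site
(tracked by count, not position, since PMF cannot localize), pyroglutamate
−17.026549 (N-terminal Q only), N-terminal acetylation +42.010565 (the
protein's first peptide only; mutually exclusive with pyroGlu since both
occupy the N-terminus). Form enumeration is capped at 16 per peptide,
least-modified first.

Matching is by absolute tolerance (default 0.1 Da, configurable; not ppm).
Each observed centroid pairs with the nearest theoretical mass within
tolerance, ties toward the smaller mass; a peak matches at most one form
while a form may absorb several peaks. Differences are recorded as
observed − theoretical. Observed masses are treated as neutral; a
charge-adduct flag subtracts one proton when peak lists are [M+H]+ m/z.
Coverage is the union of matched peptide ranges over the parent length,
reported to whole percent; matched peaks, matched forms and matched ranges
are all exposed, since the three counts differ whenever modified forms of
one peptide match separately.

The published 17-row fingerprint table of the lamprey RPE65 band ships as
package data. Its printed masses carry three or four decimals while the
printed differences carry up to four, so re-deriving the difference column
is checked to half an ULP of each printed value (and to 1e-4 where all
values carry four decimals). Integration checks that require the deposited
protein sequences (digesting the real lamprey RPE65, its 61.4 kDa average
mass, and the 72%/92% identity/similarity against human RPE65) run against
`data/accessions/`, populated once by `scripts/fetch_accessions.py`.

## Reciprocal-best-hit orthology

Hits are ranked by descending bitscore — database-size independent, so
cross-database comparisons are meaningful — with ascending e-value and
subject id as tie-breaks; self-hits are excluded. Strict RBH requires
rank-1 reciprocation both ways; relaxed-RBH(k) accepts reciprocation
within the top k both ways (default k = 3; k = 1 reproduces strict).
Increasing k can only add calls, never remove them. No minimum-score
filter is applied by default (configurable). A gene family is called
absent only when every member's call is absent — the logic by which a
whole photoisomerase family can be declared lost from a proteome.

## Synthetic data: what it emulates, what it does not

`simulate_family` plants three disjoint column classes on a two-clade
topology: type-II columns (default fraction 0.05) fixed for distinct
residues per clade with within-clade deviation probability 0.02 — the
strong-signal regime of a functionally diverged site; conserved columns
(default 0.25) invariant family-wide; and neutral columns where every
terminal branch independently substitutes with probability 0.1 from a
family ancestor residue. Neutral draws are deliberately star-like: a
clade-correlated neutral process would itself generate clade-diagnostic
columns and make the planted-site ground truth ill-defined. Defaults
(10+10 members, 200 sites) put the permutation test in sampled mode,
which is the regime real families of this size occupy.

`simulate_peaklist` applies per-form detection dropout, Gaussian mass
error (default SD 0.01 Da, 10× smaller than the matching tolerance) and
uniform contaminants with log-normal intensities. `simulate_hit_tables`
gives planted ortholog pairs reciprocal scores exceeding every decoy by
score_gap·(1 − noise) and constructs decoys that never reciprocate, so
only planted pairs can be called present at any k.

Consequences for interpretation: passing recovery tests shows the
statistics behave as designed under their stated assumptions — they do not
show robustness to alignment error, indels (not simulated), rate
heterogeneity, empirical substitution processes (no WAG/JTT simulation),
or correlated evolution among sites. Tree inference here is distance-based
only; likelihood and parsimony methods are out of scope.

## Problem sizes

Recovery analyses use 10–20 replicate seeds of the default family
(20 members × 200 sites) at 9,999 permutations, hit tables of 20 genes,
and trees of up to six taxa for the exhaustive-search oracle; these sizes
make every stochastic check exact or tightly bounded while keeping the
full suite fast on a single CPU.
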