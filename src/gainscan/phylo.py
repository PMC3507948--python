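"""Distance-based phylogenetics and branch-rate analysis.

The tree machinery here is deliberately minimal and fully deterministic:
complete-deletion column filtering, p/Poisson protein distances,
Saitou–Nei neighbor joining with a stated tie-break, and nonparametric
bootstrap by column resampling. Pairwise global alignment statistics
(percent identity / similarity in the CLUSTAL sense) are computed with
Biopython's ``PairwiseAligner``.

Rates are expressed in substitutions/site/My; the rate comparison of two
branches calibrated against different time spans is a single division, but
it is the quantity the tree analysis exists to deliver, so it gets a typed
result.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import dendropy
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from gainscan.errors import DomainError, InvariantError
from gainscan.io_formats import GAP, Alignment, ProteinSequence

#: CLUSTAL "strong" conservation groups used for percent similarity
STRONG_GROUPS = (
    "STA",
    "NEQK",
    "NHQK",
    "NDEQ",
    "QHRK",
    "MILV",
    "MILF",
    "HY",
    "FYW",
)

_STRONG_PAIRS = frozenset(
    frozenset(p) for g in STRONG_GROUPS for p in itertools.combinations(g, 2)
)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric matrix of pairwise distances (substitutions/site)."""

    labels: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if d.shape != (n, n):
            raise InvariantError("matrix shape does not match label count")
        if len(set(self.labels)) != n:
            raise InvariantError("duplicate labels")
        if not np.isfinite(d).all():
            raise InvariantError("distances must be finite")
        if (d < 0).any():
            raise InvariantError("distances must be non-negative")
        if not np.allclose(d, d.T):
            raise InvariantError("matrix must be symmetric")
        if not np.allclose(np.diag(d), 0):
            raise InvariantError("diagonal must be zero")
        object.__setattr__(self, "d", d)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.d[i, j])


@dataclass(frozen=True)
class RateEstimate:
    """A branch length calibrated against a time span."""

    branch_length: float  # substitutions/site
    time_my: float  # million years
    rate: float  # substitutions/site/My


@dataclass(frozen=True)
class PairwiseAlignmentSummary:
    identity: float  # percent
    similarity: float  # percent
    aligned_cols: int  # alignment length including gap columns
    aligned_pairs: int  # columns with a residue in both sequences

    def __post_init__(self) -> None:
        if not 0 <= self.identity <= self.similarity <= 100:
            raise InvariantError("need 0 <= identity <= similarity <= 100")


# ---------------------------------------------------------------------------
# Alignment filtering and distances


def complete_deletion(alignment: Alignment) -> Alignment:
    """Drop every column that contains at least one gap.

    This is the usual "complete deletion" treatment applied before distance
    computation, so all pairwise distances are computed over the same sites.
    """
    mat = np.array([list(m.residues) for m in alignment.members])
    keep = ~(mat == GAP).any(axis=0)
    if not keep.any():
        raise DomainError("complete deletion removed every column")
    members = [
        ProteinSequence(m.id, "".join(row[keep]), m.description)
        for m, row in zip(alignment.members, mat)
    ]
    return Alignment(members)


def _encode(alignment: Alignment) -> np.ndarray:
    return np.array([list(m.residues) for m in alignment.members])


def _pairwise_p(mat: np.ndarray) -> np.ndarray:
    """Pairwise p-distances on a gap-free residue matrix.

    'X' counts as differing from everything, including another 'X'.
    """
    n = mat.shape[0]
    is_x = mat == "X"
    p = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            diff = (mat[i] != mat[j]) | is_x[i] | is_x[j]
            p[i, j] = p[j, i] = diff.mean()
    return p


def distance_matrix(alignment: Alignment, model: str = "poisson") -> DistanceMatrix:
    """Pairwise distances from a (complete-deletion filtered) alignment.

    model 'p': proportion of differing residues per column.
    model 'poisson': −ln(1 − p), the multiple-hit correction; saturated
    pairs (p ≥ 1) have no finite Poisson distance and raise.
    """
    if model not in ("p", "poisson"):
        raise ValueError(f"unknown distance model {model!r}")
    mat = _encode(alignment)
    if (mat == GAP).any():
        raise DomainError(
            "alignment contains gaps; apply complete_deletion before distances"
        )
    p = _pairwise_p(mat)
    if model == "p":
        return DistanceMatrix(alignment.ids, p)
    if (p >= 1).any():
        i, j = np.argwhere(p >= 1)[0]
        raise DomainError(
            "Poisson distance undefined (p = 1) for pair "
            f"({alignment.ids[i]}, {alignment.ids[j]})"
        )
    return DistanceMatrix(alignment.ids, -np.log1p(-p))


# ---------------------------------------------------------------------------
# Neighbor joining


def _min_leaf_key(node: dendropy.Node) -> str:
    if node.is_leaf():
        return node.taxon.label
    return min(leaf.taxon.label for leaf in node.leaf_iter())


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor joining, fully deterministic.

    When two pairs tie on the Q criterion the lexicographically smallest
    (label-sorted) pair is joined. Negative branch-length estimates are
    clamped to 0 with the deficit moved onto the sister branch, so total
    path lengths through a join are preserved. The result is unrooted
    (trifurcating seed node).
    """
    n = len(dm.labels)
    if n < 3:
        raise DomainError(f"neighbor joining needs >= 3 taxa, got {n}")

    taxa = dendropy.TaxonNamespace(list(dm.labels))
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes: list[dendropy.Node] = []
    for label in dm.labels:
        node = dendropy.Node(taxon=taxa.get_taxon(label))
        nodes.append(node)
    # active-node sort keys for tie-breaking (min leaf label in subtree)
    keys = {id(node): node.taxon.label for node in nodes}
    D = {
        (id(a), id(b)): dm.d[i, j]
        for i, a in enumerate(nodes)
        for j, b in enumerate(nodes)
        if i != j
    }

    def dist(a: dendropy.Node, b: dendropy.Node) -> float:
        return D[(id(a), id(b))]

    active = list(nodes)
    while len(active) > 3:
        m = len(active)
        r = {id(a): sum(dist(a, b) for b in active if b is not a) for a in active}
        best = None
        best_q = np.inf
        for a, b in itertools.combinations(active, 2):
            q = (m - 2) * dist(a, b) - r[id(a)] - r[id(b)]
            pair_key = tuple(sorted((keys[id(a)], keys[id(b)])))
            if q < best_q - 1e-12 or (
                abs(q - best_q) <= 1e-12 and (best is None or pair_key < best[2])
            ):
                best_q = q
                best = (a, b, pair_key)
        a, b, _ = best
        d_ab = dist(a, b)
        la = d_ab / 2 + (r[id(a)] - r[id(b)]) / (2 * (m - 2))
        lb = d_ab - la
        if la < 0:
            lb += -la  # keep la + lb = d_ab
            la = 0.0
        elif lb < 0:
            la += -lb
            lb = 0.0
        u = dendropy.Node()
        u.add_child(a)
        u.add_child(b)
        a.edge.length = la
        b.edge.length = lb
        keys[id(u)] = min(keys[id(a)], keys[id(b)])
        for c in active:
            if c is a or c is b:
                continue
            d_uc = max(0.0, (dist(a, c) + dist(b, c) - d_ab) / 2)
            D[(id(u), id(c))] = D[(id(c), id(u))] = d_uc
        active = [c for c in active if c is not a and c is not b] + [u]

    # final three-way join at the unrooted seed node
    a, b, c = sorted(active, key=lambda nd: keys[id(nd)])
    la = (dist(a, b) + dist(a, c) - dist(b, c)) / 2
    lb = (dist(a, b) + dist(b, c) - dist(a, c)) / 2
    lc = (dist(a, c) + dist(b, c) - dist(a, b)) / 2
    root = tree.seed_node
    for node, length in ((a, la), (b, lb), (c, lc)):
        root.add_child(node)
        node.edge.length = max(0.0, length)
    tree.is_rooted = False
    tree.update_bipartitions(suppress_unifurcations=False)
    return tree


def bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Nontrivial bipartitions of an unrooted tree.

    Each internal edge splits the leaves in two; the split is canonicalized
    as the side NOT containing the lexicographically smallest leaf label.
    """
    labels = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    ref = labels[0]
    all_labels = frozenset(labels)
    out: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if ref in side:
            side = all_labels - side
        if 2 <= len(side) <= len(all_labels) - 2:
            out.add(side)
    return out


def bootstrap_support(
    alignment: Alignment,
    n_reps: int = 1000,
    seed: int | None = None,
    model: str = "poisson",
) -> dendropy.Tree:
    """NJ point-estimate tree with bootstrap supports on internal edges.

    Columns are resampled with replacement ``n_reps`` times; each replicate
    is run through the same distance + NJ path, and every internal edge of
    the point tree is annotated with the percentage of replicates whose tree
    contains the same bipartition (stored as the internal node label).
    """
    if n_reps < 1:
        raise DomainError("n_reps must be >= 1")
    filtered = complete_deletion(alignment)
    mat = _encode(filtered)
    ids = filtered.ids
    point = nj_tree(distance_matrix(filtered, model=model))
    point_splits = bipartitions(point)
    counts = {split: 0 for split in point_splits}
    rng = np.random.default_rng(seed)
    n_cols = mat.shape[1]
    for _ in range(n_reps):
        cols = rng.integers(0, n_cols, size=n_cols)
        sub = mat[:, cols]
        p = _pairwise_p(sub)
        if model == "poisson":
            if (p >= 1).any():
                continue  # saturated replicate carries no split information
            d = -np.log1p(-p)
        else:
            d = p
        rep_tree = nj_tree(DistanceMatrix(ids, d))
        rep_splits = bipartitions(rep_tree)
        for split in point_splits:
            if split in rep_splits:
                counts[split] += 1
    # attach supports as internal node labels
    labels = sorted(ids)
    ref = labels[0]
    all_labels = frozenset(labels)
    for node in point.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if ref in side:
            side = all_labels - side
        if side in counts:
            node.label = f"{100.0 * counts[side] / n_reps:g}"
    return point


# ---------------------------------------------------------------------------
# Pairwise alignment summary


def _make_aligner(gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    # free end gaps: percent identity should not be distorted by overhangs
    try:
        aligner.open_end_insertion_score = 0.0
        aligner.extend_end_insertion_score = 0.0
        aligner.open_end_deletion_score = 0.0
        aligner.extend_end_deletion_score = 0.0
    except AttributeError:  # older Biopython naming
        aligner.target_end_open_gap_score = 0.0
        aligner.target_end_extend_gap_score = 0.0
        aligner.query_end_open_gap_score = 0.0
        aligner.query_end_extend_gap_score = 0.0
    return aligner


def align_pair(
    a: ProteinSequence,
    b: ProteinSequence,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> PairwiseAlignmentSummary:
    """Global (Needleman–Wunsch, affine-gap) alignment summary of two proteins.

    identity = identical pairs / aligned pairs; similarity additionally
    counts pairs within a CLUSTAL strong conservation group. 'X' matches
    nothing, including 'X'. Symmetric in its arguments by construction.
    """
    if not a.residues or not b.residues:
        raise DomainError("cannot align an empty sequence")
    if GAP in a.residues or GAP in b.residues:
        raise DomainError("align_pair expects ungapped sequences")
    # canonical argument order => summary is exactly symmetric
    if (b.residues, b.id) < (a.residues, a.id):
        a, b = b, a
    aligner = _make_aligner(gap_open, gap_extend)
    aln = aligner.align(a.residues, b.residues)[0]
    sa, sb = str(aln[0]), str(aln[1])
    identical = similar = pairs = 0
    for x, y in zip(sa, sb):
        if x == "-" or y == "-":
            continue
        pairs += 1
        if x == "X" or y == "X":
            continue
        if x == y:
            identical += 1
        elif frozenset((x, y)) in _STRONG_PAIRS:
            similar += 1
    if pairs == 0:
        raise DomainError("alignment produced no aligned residue pairs")
    return PairwiseAlignmentSummary(
        identity=100.0 * identical / pairs,
        similarity=100.0 * (identical + similar) / pairs,
        aligned_cols=len(sa),
        aligned_pairs=pairs,
    )


# ---------------------------------------------------------------------------
# Branch rates


def branch_rate(branch_length: float, time_my: float) -> RateEstimate:
    """Substitution rate of a branch calibrated against a divergence time."""
    if time_my <= 0:
        raise DomainError("time must be positive")
    if branch_length < 0:
        raise DomainError("branch length must be non-negative")
    return RateEstimate(branch_length, time_my, branch_length / time_my)


def rate_ratio(r1: RateEstimate, r2: RateEstimate) -> float:
    """How many times faster ``r1`` is than ``r2``."""
    if r2.rate == 0:
        raise DomainError("cannot divide by a zero rate")
    return r1.rate / r2.rate
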