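"""Type-II functional-divergence detection between two clades.

A type-II diverged site is conserved within each of two clades but fixed
for *different* residues between them — the signature expected when one
paralog acquires a new function after a duplication. The statistic here is
deliberately transparent:

    T(column) = freq_a * freq_b * [consensus_a != consensus_b]

where ``freq`` is the within-clade frequency of the clade consensus residue
(gaps excluded). Significance comes from re-partitioning the member labels
into two groups of the same sizes: exhaustively when the number of distinct
partitions is small (exact mode), otherwise by seeded random sampling with
the standard add-one permutation p-value. Scores are −log10(p), so a score
threshold of 3 means p < 0.001.

The module also maps reference-numbered residue positions onto alignment
columns, scores "diagnostic residue" checklists against any member, and
tests whether predicted sites cluster near known critical residues with a
windowed hypergeometric (one-sided Fisher) test.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from math import comb
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from gainscan.errors import DomainError, InvariantError
from gainscan.io_formats import AMINO_ACIDS, GAP, Alignment

_RESIDUE_ORDER = AMINO_ACIDS + "X"  # X sorts last; argmax tie-break = alphabetical
_CODE = {ch: i for i, ch in enumerate(_RESIDUE_ORDER)}
_GAP_CODE = len(_RESIDUE_ORDER)
_X_CODE = _CODE["X"]

#: exact-mode bound: enumerate all label partitions when there are at most this many
EXACT_PARTITION_BOUND = 10_000


@dataclass(frozen=True)
class CladePartition:
    """Two disjoint, named groups of alignment member ids."""

    clade_a: frozenset[str]
    clade_b: frozenset[str]

    def __init__(self, clade_a: Iterable[str], clade_b: Iterable[str]):
        object.__setattr__(self, "clade_a", frozenset(clade_a))
        object.__setattr__(self, "clade_b", frozenset(clade_b))
        if self.clade_a & self.clade_b:
            raise InvariantError("clades must be disjoint")
        if len(self.clade_a) < 2 or len(self.clade_b) < 2:
            raise InvariantError("each clade needs at least 2 members")


@dataclass(frozen=True)
class SiteDivergenceProfile:
    """Per-column type-II divergence statistics for one clade pair.

    Arrays are indexed 0..n_cols−1 for alignment columns 1..n_cols.
    ``consensus_a``/``consensus_b`` hold ``None`` where a clade is entirely
    gapped (the column is reported with p = 1 / score 0).
    """

    n_cols: int
    consensus_a: tuple[str | None, ...]
    freq_a: np.ndarray
    consensus_b: tuple[str | None, ...]
    freq_b: np.ndarray
    statistic: np.ndarray  # T in [0, 1]
    p: np.ndarray  # (0, 1]
    score: np.ndarray  # -log10(p) >= 0
    exact: bool  # True if p came from exhaustive enumeration
    n_partitions: int  # partitions enumerated or sampled

    def sites_above(self, threshold: float = 3.0) -> list[int]:
        """1-based columns with score > threshold (i.e. p < 10^-threshold)."""
        return [int(i) + 1 for i in np.flatnonzero(self.score > threshold)]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "column": np.arange(1, self.n_cols + 1),
                "consensus_a": self.consensus_a,
                "freq_a": self.freq_a,
                "consensus_b": self.consensus_b,
                "freq_b": self.freq_b,
                "T": self.statistic,
                "p": self.p,
                "score": self.score,
            }
        )


@dataclass(frozen=True)
class DiagnosticResidueSet:
    """Expected residues at reference-numbered (ungapped, 1-based) positions."""

    reference_id: str
    entries: tuple[tuple[int, str], ...]

    def __post_init__(self) -> None:
        positions = [p for p, _ in self.entries]
        if any(p2 <= p1 for p1, p2 in zip(positions, positions[1:])):
            raise InvariantError("positions must be strictly increasing")
        if any(p < 1 for p in positions):
            raise InvariantError("positions are 1-based and must be >= 1")
        for _, res in self.entries:
            if res not in AMINO_ACIDS:
                raise InvariantError(f"expected residue {res!r} is not canonical")

    @classmethod
    def from_tsv(cls, path: str | Path, reference_id: str) -> "DiagnosticResidueSet":
        """Load position<TAB>residue rows ('#' comments skipped)."""
        entries = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                pos, res = line.split("\t")[:2]
                entries.append((int(pos), res.strip().upper()))
        return cls(reference_id, tuple(sorted(entries)))


@dataclass(frozen=True)
class ScorecardEntry:
    position: int
    expected: str
    column: int
    query_residue: str  # '-' when gapped
    present: bool
    reference_consistent: bool


@dataclass(frozen=True)
class Scorecard:
    query_id: str
    reference_id: str
    entries: tuple[ScorecardEntry, ...]

    @property
    def n_present(self) -> int:
        return sum(e.present for e in self.entries)

    @property
    def n_total(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class EnrichmentResult:
    """Windowed overlap of predicted sites with critical residues."""

    N: int  # protein length
    critical: frozenset[int]
    w: int  # window half-width
    predicted: frozenset[int]
    K: int  # size of the union of clipped +/-w windows
    x: int  # predicted sites falling inside the window union
    p: float  # upper-tail hypergeometric probability


# ---------------------------------------------------------------------------
# Consensus and the type-II statistic


def clade_consensus(
    alignment: Alignment, clade: Iterable[str], column: int
) -> tuple[str, float] | None:
    """Modal residue and its frequency among non-gap clade members at a column.

    Ties break alphabetically; returns ``None`` when every clade member is
    gapped at the column.
    """
    clade = set(clade)
    missing = clade - set(alignment.ids)
    if missing:
        raise InvariantError(f"ids not in alignment: {sorted(missing)}")
    residues = [
        alignment.member(mid).residues[column - 1] for mid in sorted(clade)
    ]
    residues = [r for r in residues if r != GAP]
    if not residues:
        return None
    counts: dict[str, int] = {}
    for r in residues:
        counts[r] = counts.get(r, 0) + 1
    best = min(counts, key=lambda r: (-counts[r], r))
    return best, counts[best] / len(residues)


def _encode_members(alignment: Alignment, ids: Sequence[str]) -> np.ndarray:
    rows = []
    for mid in ids:
        rows.append([_CODE.get(ch, _GAP_CODE) for ch in alignment.member(mid).residues])
    return np.array(rows, dtype=np.int64)


def _onehot(mat: np.ndarray) -> np.ndarray:
    """(members, residue-code, column) one-hot encoding, gap channel last."""
    n, c = mat.shape
    oh = np.zeros((n, _GAP_CODE + 1, c), dtype=np.int32)
    oh[np.arange(n)[:, None], mat, np.arange(c)[None, :]] = 1
    return oh


def _stats_from_counts(counts: np.ndarray):
    """Per-column consensus code, consensus frequency, non-gap count."""
    res_counts = counts[:_GAP_CODE]  # exclude the gap channel
    nongap = res_counts.sum(axis=0)
    cons = res_counts.argmax(axis=0)  # first max => alphabetical tie-break
    top = res_counts.max(axis=0)
    freq = np.where(nongap > 0, top / np.maximum(nongap, 1), 0.0)
    return cons, freq, nongap


def _t_from_counts(counts_a: np.ndarray, counts_b: np.ndarray):
    cons_a, freq_a, n_a = _stats_from_counts(counts_a)
    cons_b, freq_b, n_b = _stats_from_counts(counts_b)
    # 'X' consensus never counts as agreement, even with another 'X'
    differs = (cons_a != cons_b) | ((cons_a == _X_CODE) & (cons_b == _X_CODE))
    defined = (n_a > 0) & (n_b > 0)
    t = np.where(defined, freq_a * freq_b * differs, 0.0)
    return t, cons_a, freq_a, cons_b, freq_b, defined


def type2_site_scores(
    alignment: Alignment,
    partition: CladePartition,
    n_perm: int = 999,
    seed: int | None = None,
) -> SiteDivergenceProfile:
    """Score every column for type-II divergence between two clades.

    The null distribution re-partitions the pooled clade members into groups
    of the original sizes. With at most :data:`EXACT_PARTITION_BOUND`
    distinct partitions the p-value is exact (enumeration); otherwise it is
    the add-one permutation estimate over ``n_perm`` seeded draws.
    """
    ids = set(alignment.ids)
    missing = (partition.clade_a | partition.clade_b) - ids
    if missing:
        raise InvariantError(f"partition ids not in alignment: {sorted(missing)}")
    if n_perm < 99:
        raise DomainError("n_perm must be >= 99")

    members = sorted(partition.clade_a) + sorted(partition.clade_b)
    n_a = len(partition.clade_a)
    n_total = len(members)
    mat = _encode_members(alignment, members)
    onehot = _onehot(mat)
    total_counts = onehot.sum(axis=0)
    counts_a = onehot[:n_a].sum(axis=0)
    t_obs, cons_a, freq_a, cons_b, freq_b, defined = _t_from_counts(
        counts_a, total_counts - counts_a
    )

    n_partitions = comb(n_total, n_a)
    exact = n_partitions <= EXACT_PARTITION_BOUND
    n_cols = alignment.n_cols
    ge_counts = np.zeros(n_cols, dtype=np.int64)
    threshold = t_obs - 1e-12
    if exact:
        for combo in itertools.combinations(range(n_total), n_a):
            ca = onehot[list(combo)].sum(axis=0)
            t_perm = _t_from_counts(ca, total_counts - ca)[0]
            ge_counts += t_perm >= threshold
        p = ge_counts / n_partitions
        total = n_partitions
    else:
        rng = np.random.default_rng(seed)
        for _ in range(n_perm):
            ra = rng.permutation(n_total)[:n_a]
            ca = onehot[ra].sum(axis=0)
            t_perm = _t_from_counts(ca, total_counts - ca)[0]
            ge_counts += t_perm >= threshold
        p = (1 + ge_counts) / (n_perm + 1)
        total = n_perm

    p = np.where(defined, p, 1.0)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    score = -np.log10(p)
    decode = lambda code, ok: _RESIDUE_ORDER[code] if ok else None  # noqa: E731
    return SiteDivergenceProfile(
        n_cols=n_cols,
        consensus_a=tuple(
            decode(c, d and f > 0) for c, f, d in zip(cons_a, freq_a, defined)
        ),
        freq_a=np.where(defined, freq_a, 0.0),
        consensus_b=tuple(
            decode(c, d and f > 0) for c, f, d in zip(cons_b, freq_b, defined)
        ),
        freq_b=np.where(defined, freq_b, 0.0),
        statistic=t_obs,
        p=p,
        score=score,
        exact=exact,
        n_partitions=total,
    )


# ---------------------------------------------------------------------------
# Reference-coordinate mapping and scorecards


def map_reference_positions(
    alignment: Alignment, reference_id: str, positions: Iterable[int]
) -> list[int]:
    """Alignment columns of reference-numbered ungapped positions (1-based)."""
    return [alignment.position_to_column(reference_id, p) for p in positions]


def diagnostic_scorecard(
    alignment: Alignment, dset: DiagnosticResidueSet, query_id: str
) -> Scorecard:
    """Check which diagnostic residues a query sequence carries.

    A position counts as present iff the query residue in the mapped column
    equals the expected residue; a gap or mismatch (including 'X') counts as
    absent. If the *reference* residue itself disagrees with the expected
    residue the entry is still counted but flagged, with a warning.
    """
    ref = alignment.member(dset.reference_id)
    query = alignment.member(query_id)
    entries = []
    for pos, expected in dset.entries:
        col = alignment.position_to_column(dset.reference_id, pos)
        ref_res = ref.residues[col - 1]
        q_res = query.residues[col - 1]
        consistent = ref_res == expected
        if not consistent:
            warnings.warn(
                f"reference {dset.reference_id!r} has {ref_res!r} at position "
                f"{pos}, expected {expected!r}: residue set and alignment "
                "disagree",
                stacklevel=2,
            )
        present = q_res == expected and expected != "X"
        entries.append(
            ScorecardEntry(pos, expected, col, q_res, present, consistent)
        )
    return Scorecard(query_id, dset.reference_id, tuple(entries))


# ---------------------------------------------------------------------------
# Windowed critical-residue enrichment


def neighborhood_enrichment(
    N: int,
    critical: Iterable[int],
    predicted: Iterable[int],
    w: int = 1,
) -> EnrichmentResult:
    """One-sided Fisher (hypergeometric upper-tail) test for window overlap.

    The success region is the union of the ±``w`` neighborhoods of the
    critical positions, clipped to [1, N] (union, so clustered critical
    residues are not double-counted). With K region positions, n predicted
    sites and x of them inside the region,

        p = P(X >= x),  X ~ Hypergeometric(N, K, n).
    """
    critical = frozenset(int(c) for c in critical)
    predicted = frozenset(int(q) for q in predicted)
    if not critical or not predicted:
        raise DomainError("critical and predicted sets must be non-empty")
    if N < 1:
        raise DomainError("N must be >= 1")
    if w < 0:
        raise DomainError("window half-width must be >= 0")
    out_of_range = [p for p in critical | predicted if not 1 <= p <= N]
    if out_of_range:
        raise DomainError(f"positions outside [1, {N}]: {sorted(out_of_range)}")
    region: set[int] = set()
    for c in critical:
        region.update(range(max(1, c - w), min(N, c + w) + 1))
    K = len(region)
    x = len(predicted & region)
    n = len(predicted)
    p = float(min(1.0, hypergeom.sf(x - 1, N, K, n)))
    return EnrichmentResult(
        N=N, critical=critical, w=w, predicted=predicted, K=K, x=x, p=p
    )
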