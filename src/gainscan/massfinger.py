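"""In-silico tryptic digestion and peptide mass fingerprinting (PMF).

PMF identifies a protein by digesting a candidate sequence in silico with
trypsin (cleave after K/R unless the next residue is proline), predicting
the monoisotopic mass of every peptide — including common MALDI artifact
forms (N-terminal acetylation, pyroglutamate from N-terminal Gln,
methionine oxidation) — and matching the predictions against observed
centroid masses within an absolute tolerance (default 0.1 Da). The report
carries, per match, observed mass, theoretical mass and their signed
difference, plus the sequence coverage of the matched peptide ranges.

Residue masses are embedded as constants (monoisotopic and average); each
is unit-tested against an elemental-composition oracle. Observed masses
are treated as neutral; pass ``charge_adduct=True`` to :func:`match_peaks`
when the peak list holds singly protonated m/z values.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from gainscan.errors import DomainError, InvariantError
from gainscan.io_formats import PeakList, ProteinSequence

# monoisotopic residue masses (Da), from C/H/N/O/S monoisotopic atomic masses
MONO_RESIDUE_MASS = {
    "G": 57.021464,
    "A": 71.037114,
    "S": 87.032028,
    "P": 97.052764,
    "V": 99.068414,
    "T": 101.047678,
    "C": 103.009185,
    "L": 113.084064,
    "I": 113.084064,
    "N": 114.042927,
    "D": 115.026943,
    "Q": 128.058578,
    "K": 128.094963,
    "E": 129.042593,
    "M": 131.040485,
    "H": 137.058912,
    "F": 147.068414,
    "R": 156.101111,
    "Y": 163.063329,
    "W": 186.079313,
}

# average residue masses (Da)
AVERAGE_RESIDUE_MASS = {
    "G": 57.0519,
    "A": 71.0788,
    "S": 87.0782,
    "P": 97.1167,
    "V": 99.1326,
    "T": 101.1051,
    "C": 103.1388,
    "L": 113.1594,
    "I": 113.1594,
    "N": 114.1038,
    "D": 115.0886,
    "Q": 128.1307,
    "K": 128.1741,
    "E": 129.1155,
    "M": 131.1926,
    "H": 137.1411,
    "F": 147.1766,
    "R": 156.1875,
    "Y": 163.1760,
    "W": 186.2132,
}

WATER_MONO = 18.010565
WATER_AVERAGE = 18.01528
PROTON = 1.007276

ACETYL_NTERM = "acetyl-Nterm"
PYROGLU_Q = "pyroGlu-Q"
OXIDATION_M = "oxidation-M"

#: mass shift of each supported modification (Da, monoisotopic)
MODIFICATION_DELTA = {
    ACETYL_NTERM: 42.010565,  # +C2H2O
    PYROGLU_Q: -17.026549,  # -NH3
    OXIDATION_M: 15.994915,  # +O
}

#: cap on enumerated modification forms per peptide
MAX_FORMS = 16


@dataclass(frozen=True)
class Peptide:
    """A digest product (possibly carrying modifications).

    ``start``/``end`` are 1-based inclusive positions on the parent protein;
    ``modifications`` is a sorted tuple and may repeat ``oxidation-M`` once
    per oxidized methionine (sites are not localized, only counted).
    """

    parent_id: str
    start: int
    end: int
    sequence: str
    missed_cleavages: int
    modifications: tuple[str, ...] = ()
    mono_mass: float = 0.0

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise InvariantError("need 1 <= start <= end")
        if len(self.sequence) != self.end - self.start + 1:
            raise InvariantError("sequence length does not match start..end")
        mods = Counter(self.modifications)
        unknown = set(mods) - set(MODIFICATION_DELTA)
        if unknown:
            raise InvariantError(f"unknown modification(s): {sorted(unknown)}")
        if mods[ACETYL_NTERM] > 1 or mods[PYROGLU_Q] > 1:
            raise InvariantError("N-terminal modifications cannot repeat")
        if mods[PYROGLU_Q] and not self.sequence.startswith("Q"):
            raise InvariantError("pyroGlu requires an N-terminal Q")
        if mods[ACETYL_NTERM] and self.start != 1:
            raise InvariantError("N-terminal acetylation requires start = 1")
        if mods[OXIDATION_M] > self.sequence.count("M"):
            raise InvariantError("more oxidations than methionines")
        if self.mono_mass <= 0:
            object.__setattr__(
                self, "mono_mass", mono_mass(self.sequence, self.modifications)
            )

    @property
    def label(self) -> str:
        """Human-readable form label, e.g. ``414-420 pyroGlu-Q``."""
        mods = "+".join(self.modifications)
        return f"{self.start}-{self.end}" + (f" {mods}" if mods else "")


@dataclass(frozen=True)
class Match:
    observed_mass: float
    theoretical_mass: float
    difference: float  # observed - theoretical, Da
    peptide: Peptide


@dataclass(frozen=True)
class MatchReport:
    """Outcome of matching observed centroids against a theoretical digest."""

    matches: tuple[Match, ...]
    unmatched_observed: tuple[float, ...]
    coverage: float  # fraction of the parent covered by matched peptides
    parent_length: int
    tolerance: float

    @property
    def n_matched_peaks(self) -> int:
        return len(self.matches)

    @property
    def n_matched_forms(self) -> int:
        return len({(m.peptide.start, m.peptide.end, m.peptide.modifications)
                    for m in self.matches})

    @property
    def matched_ranges(self) -> list[tuple[int, int]]:
        return sorted({(m.peptide.start, m.peptide.end) for m in self.matches})


# ---------------------------------------------------------------------------
# Masses


def mono_mass(sequence: str, modifications: Iterable[str] = ()) -> float:
    """Neutral monoisotopic mass of a peptide with optional modifications."""
    if not sequence:
        raise DomainError("mass undefined for an empty sequence")
    try:
        mass = sum(MONO_RESIDUE_MASS[r] for r in sequence) + WATER_MONO
    except KeyError as exc:
        raise DomainError(
            f"mass undefined: non-canonical residue {exc.args[0]!r}"
        ) from None
    for mod in modifications:
        try:
            mass += MODIFICATION_DELTA[mod]
        except KeyError:
            raise DomainError(f"unknown modification {mod!r}") from None
    return mass


def average_mw(protein: ProteinSequence) -> float:
    """Average molecular weight in kDa (report to 0.1 kDa)."""
    seq = protein.ungapped
    if not seq:
        raise DomainError("empty sequence")
    try:
        da = sum(AVERAGE_RESIDUE_MASS[r] for r in seq) + WATER_AVERAGE
    except KeyError as exc:
        raise DomainError(
            f"mass undefined: non-canonical residue {exc.args[0]!r}"
        ) from None
    return da / 1000.0


# ---------------------------------------------------------------------------
# Digestion


def cleavage_sites(sequence: str) -> list[int]:
    """0-based indices i such that trypsin cuts between i and i+1.

    Trypsin cleaves C-terminal to K or R except when the next residue is P.
    """
    return [
        i
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]


def tryptic_digest(protein: ProteinSequence, max_missed: int = 0) -> list[Peptide]:
    """All tryptic peptides with up to ``max_missed`` missed cleavages.

    Peptides are returned in (start, end) order with 1-based inclusive
    coordinates. The parent must contain canonical residues only (masses
    would otherwise be undefined).
    """
    if max_missed < 0:
        raise DomainError("max_missed must be >= 0")
    seq = protein.ungapped
    if "X" in seq:
        raise DomainError("cannot digest a sequence containing 'X'")
    cuts = cleavage_sites(seq)
    starts = [0] + [c + 1 for c in cuts]
    ends = [c for c in cuts] + [len(seq) - 1]  # fragment end indices, 0-based
    peptides = []
    n_frag = len(starts)
    for i in range(n_frag):
        for j in range(i, min(i + max_missed + 1, n_frag)):
            s, e = starts[i], ends[j]
            peptides.append(
                Peptide(
                    parent_id=protein.id,
                    start=s + 1,
                    end=e + 1,
                    sequence=seq[s : e + 1],
                    missed_cleavages=j - i,
                )
            )
    peptides.sort(key=lambda p: (p.start, p.end))
    return peptides


def modification_forms(
    peptide: Peptide,
    enabled: Iterable[str] = (ACETYL_NTERM, PYROGLU_Q, OXIDATION_M),
) -> list[Peptide]:
    """The unmodified peptide plus every admissible modified form.

    pyroGlu applies only to an N-terminal Q; acetylation only to the
    protein's first peptide (start = 1); oxidation is enumerated by count
    over 0..#M (PMF cannot localize sites). Acetylation and pyroGlu are
    mutually exclusive (both block the same N-terminus). Enumeration is
    capped at :data:`MAX_FORMS` forms, least-modified first.
    """
    enabled = set(enabled)
    unknown = enabled - set(MODIFICATION_DELTA)
    if unknown:
        raise DomainError(f"unknown modification(s): {sorted(unknown)}")
    nterm_options: list[tuple[str, ...]] = [()]
    if ACETYL_NTERM in enabled and peptide.start == 1:
        nterm_options.append((ACETYL_NTERM,))
    if PYROGLU_Q in enabled and peptide.sequence.startswith("Q"):
        nterm_options.append((PYROGLU_Q,))
    max_ox = peptide.sequence.count("M") if OXIDATION_M in enabled else 0
    forms = []
    for n_ox in range(max_ox + 1):
        for nterm in nterm_options:
            mods = tuple(sorted(nterm + (OXIDATION_M,) * n_ox))
            forms.append(
                Peptide(
                    parent_id=peptide.parent_id,
                    start=peptide.start,
                    end=peptide.end,
                    sequence=peptide.sequence,
                    missed_cleavages=peptide.missed_cleavages,
                    modifications=mods,
                )
            )
    forms.sort(key=lambda p: (len(p.modifications), p.modifications))
    return forms[:MAX_FORMS]


# ---------------------------------------------------------------------------
# Matching and coverage


def coverage(ranges: Iterable[tuple[int, int]], parent_length: int) -> float:
    """Fraction of the parent inside the union of inclusive 1-based ranges."""
    if parent_length < 1:
        raise DomainError("parent_length must be >= 1")
    covered: set[int] = set()
    for start, end in ranges:
        if not 1 <= start <= end <= parent_length:
            raise DomainError(
                f"range {start}-{end} outside [1, {parent_length}]"
            )
        covered.update(range(start, end + 1))
    return len(covered) / parent_length


def match_peaks(
    theoretical: Sequence[Peptide],
    observed: PeakList,
    tol: float = 0.1,
    parent_length: int | None = None,
    charge_adduct: bool = False,
) -> MatchReport:
    """Match observed centroid masses to the nearest theoretical form.

    Each observed peak is paired with the closest theoretical mass within
    ``tol`` Da (ties toward the smaller theoretical mass); a peak matches at
    most one form while a form may match several peaks. ``charge_adduct``
    subtracts one proton from the observed masses first (peak lists in
    [M+H]+ m/z). Coverage is the union of matched ranges over the parent
    length (inferred as the largest peptide ``end`` when not given).
    """
    if tol <= 0:
        raise DomainError("tolerance must be positive")
    if parent_length is None:
        parent_length = max((p.end for p in theoretical), default=0)
    theo = sorted(theoretical, key=lambda p: p.mono_mass)
    theo_masses = np.array([p.mono_mass for p in theo])
    matches: list[Match] = []
    unmatched: list[float] = []
    for raw in observed.masses.tolist():
        obs = raw - PROTON if charge_adduct else raw
        if len(theo) == 0:
            unmatched.append(raw)
            continue
        idx = int(np.searchsorted(theo_masses, obs))
        candidates = [i for i in (idx - 1, idx) if 0 <= i < len(theo)]
        # nearest within tolerance; ties toward the smaller theoretical mass
        best = min(
            (
                (abs(obs - theo_masses[i]), theo_masses[i], i)
                for i in candidates
                if abs(obs - theo_masses[i]) <= tol
            ),
            default=None,
        )
        if best is None:
            unmatched.append(raw)
        else:
            i = best[2]
            matches.append(
                Match(
                    observed_mass=obs,
                    theoretical_mass=float(theo_masses[i]),
                    difference=float(obs - theo_masses[i]),
                    peptide=theo[i],
                )
            )
    ranges = {(m.peptide.start, m.peptide.end) for m in matches}
    cov = coverage(ranges, parent_length) if ranges and parent_length else 0.0
    return MatchReport(
        matches=tuple(matches),
        unmatched_observed=tuple(unmatched),
        coverage=cov,
        parent_length=parent_length,
        tolerance=tol,
    )
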