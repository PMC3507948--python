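"""Generators for inputs with the statistical structure the pipeline assumes.

Three generators cover the three data-dependent stages:

* :func:`simulate_family` — a two-clade protein family descended from a
  duplication, with a planted fraction of type-II diverged columns
  (conserved within each clade, fixed for different residues between them),
  a fraction of family-wide conserved columns, and neutral columns evolved
  by a simple per-branch substitution draw.
* :func:`simulate_peaklist` — a noisy MALDI-style centroid list from a
  theoretical digest: per-form detection dropout, Gaussian mass error,
  uniform contaminant peaks, log-normal intensities.
* :func:`simulate_hit_tables` — paired similarity hit tables with a planted
  one-to-one ortholog map; non-ortholog genes (emulating a gene family lost
  from one lineage) receive decoy hits only.

Every generator is bit-reproducible given a seed. Substreams are derived
per generator name, so composing several generators in one pipeline under
one master seed stays reproducible regardless of call order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from gainscan.errors import DomainError
from gainscan.io_formats import AMINO_ACIDS, Alignment, HitTable, PeakList, ProteinSequence
from gainscan.massfinger import Peptide

import pandas as pd


def substream(seed: int | None, name: str) -> np.random.Generator:
    """Named, independent random substream under one master seed."""
    label = zlib.crc32(name.encode())
    if seed is None:
        return np.random.default_rng(np.random.SeedSequence([label]))
    return np.random.default_rng(np.random.SeedSequence([int(seed), label]))


@dataclass(frozen=True)
class FamilySimulationTruth:
    """Ground truth for one simulated two-clade family."""

    tree_newick: str
    clade_a: tuple[str, ...]
    clade_b: tuple[str, ...]
    type2_columns: frozenset[int]  # 1-based
    conserved_columns: frozenset[int]  # 1-based
    neutral_columns: frozenset[int]  # 1-based
    seed: int | None


def _draw_residue(rng: np.random.Generator, exclude: str = "") -> str:
    choices = [a for a in AMINO_ACIDS if a not in exclude]
    return choices[int(rng.integers(len(choices)))]


def simulate_family(
    n_per_clade: int = 10,
    n_sites: int = 200,
    frac_type2: float = 0.05,
    frac_conserved: float = 0.25,
    sub_prob: float = 0.1,
    within_clade_sub_prob: float = 0.02,
    seed: int | None = None,
) -> tuple[Alignment, FamilySimulationTruth]:
    """Simulate a gap-free two-clade family with planted type-II columns.

    Column classes (disjoint, together covering all columns):

    * type-II (``frac_type2``): residue ``r_a`` fixed within clade A and a
      distinct ``r_b`` fixed within clade B, each member deviating with
      probability ``within_clade_sub_prob`` (strong signal by default);
    * conserved (``frac_conserved``): one residue family-wide;
    * neutral (the rest): a family ancestor residue mutated independently
      with probability ``sub_prob`` on the branch to each clade ancestor
      and again on the branch to each member.
    """
    if n_per_clade < 2:
        raise DomainError("n_per_clade must be >= 2")
    if n_sites < 1:
        raise DomainError("n_sites must be >= 1")
    for name, frac in (("frac_type2", frac_type2), ("frac_conserved", frac_conserved)):
        if not 0 <= frac <= 1:
            raise DomainError(f"{name} must be in [0, 1]")
    if frac_type2 + frac_conserved > 1:
        raise DomainError("column class fractions must sum to <= 1")
    if not 0 <= sub_prob <= 1 or not 0 <= within_clade_sub_prob <= 1:
        raise DomainError("substitution probabilities must be in [0, 1]")

    rng = substream(seed, "family")
    n_type2 = round(frac_type2 * n_sites)
    n_conserved = round(frac_conserved * n_sites)
    order = rng.permutation(n_sites)
    type2_cols = set(order[:n_type2].tolist())
    conserved_cols = set(order[n_type2 : n_type2 + n_conserved].tolist())
    neutral_cols = set(range(n_sites)) - type2_cols - conserved_cols

    ids_a = tuple(f"A{i + 1}" for i in range(n_per_clade))
    ids_b = tuple(f"B{i + 1}" for i in range(n_per_clade))
    n_total = 2 * n_per_clade
    mat = np.empty((n_total, n_sites), dtype="<U1")

    for col in range(n_sites):
        if col in type2_cols:
            r_a = _draw_residue(rng)
            r_b = _draw_residue(rng, exclude=r_a)
            for row in range(n_total):
                base = r_a if row < n_per_clade else r_b
                if rng.random() < within_clade_sub_prob:
                    base = _draw_residue(rng, exclude=base)
                mat[row, col] = base
        elif col in conserved_cols:
            mat[:, col] = _draw_residue(rng)
        else:
            # neutral: every terminal branch substitutes independently, so a
            # clade-specific fixation can arise only by (rare) coincidence
            ancestor = _draw_residue(rng)
            for row in range(n_total):
                res = ancestor
                if rng.random() < sub_prob:
                    res = _draw_residue(rng, exclude=res)
                mat[row, col] = res

    members = [
        ProteinSequence(mid, "".join(mat[row]))
        for row, mid in enumerate(ids_a + ids_b)
    ]
    newick = (
        "((" + ",".join(f"{m}:1" for m in ids_a) + "):1,("
        + ",".join(f"{m}:1" for m in ids_b) + "):1);"
    )
    truth = FamilySimulationTruth(
        tree_newick=newick,
        clade_a=ids_a,
        clade_b=ids_b,
        type2_columns=frozenset(c + 1 for c in type2_cols),
        conserved_columns=frozenset(c + 1 for c in conserved_cols),
        neutral_columns=frozenset(c + 1 for c in neutral_cols),
        seed=seed,
    )
    return Alignment(members), truth


def simulate_peaklist(
    theoretical: Sequence[Peptide],
    detect_prob: float = 0.9,
    mass_sd: float = 0.01,
    n_contaminants: int = 5,
    seed: int | None = None,
) -> PeakList:
    """Noisy centroid peak list derived from a theoretical digest.

    Each theoretical form is detected with probability ``detect_prob``; a
    detected mass is perturbed by Gaussian error of SD ``mass_sd`` Da.
    Contaminant peaks are uniform over the observed mass span and
    intensities are log-normal (unit-free relative intensities).
    """
    if not 0 < detect_prob <= 1:
        raise DomainError("detect_prob must be in (0, 1]")
    if mass_sd < 0:
        raise DomainError("mass_sd must be >= 0")
    if n_contaminants < 0:
        raise DomainError("n_contaminants must be >= 0")
    rng = substream(seed, "peaks")
    masses: list[float] = []
    theo_masses = np.array(sorted(p.mono_mass for p in theoretical))
    for mass in theo_masses:
        if rng.random() < detect_prob:
            masses.append(float(mass + rng.normal(0.0, mass_sd)))
    if len(theo_masses):
        lo, hi = float(theo_masses[0]), float(theo_masses[-1])
    else:
        lo, hi = 500.0, 3000.0
    if hi <= lo:
        hi = lo + 1.0
    for _ in range(n_contaminants):
        masses.append(float(rng.uniform(lo, hi)))
    intensities = rng.lognormal(mean=2.0, sigma=1.0, size=len(masses))
    return PeakList(np.array(masses), intensities)


def simulate_hit_tables(
    n_genes: int = 20,
    ortholog_fraction: float = 0.8,
    score_gap: float = 50.0,
    noise: float = 0.0,
    n_decoys: int = 3,
    seed: int | None = None,
) -> tuple[HitTable, HitTable, dict[str, str | None]]:
    """Paired hit tables with a planted one-to-one ortholog map.

    The first ``round(ortholog_fraction * n_genes)`` species-A genes have a
    true ortholog in species B whose reciprocal bitscores exceed every decoy
    hit by at least ``score_gap * (1 - noise)``; the remaining genes (the
    lost-family scenario) receive decoy hits only. The truth map sends each
    A-side gene to its partner id or ``None``.
    """
    if n_genes < 1:
        raise DomainError("n_genes must be >= 1")
    if not 0 <= ortholog_fraction <= 1:
        raise DomainError("ortholog_fraction must be in [0, 1]")
    if score_gap <= 0:
        raise DomainError("score_gap must be positive")
    if not 0 <= noise < 1:
        raise DomainError("noise must be in [0, 1)")
    rng = substream(seed, "hits")
    a_ids = [f"a{i + 1:03d}" for i in range(n_genes)]
    b_ids = [f"b{i + 1:03d}" for i in range(n_genes)]
    n_orth = round(ortholog_fraction * n_genes)
    truth: dict[str, str | None] = {
        aid: (b_ids[i] if i < n_orth else None) for i, aid in enumerate(a_ids)
    }

    def one_direction(queries, subjects, partner_of, forbidden):
        rows = []
        for q in queries:
            partner = partner_of.get(q)
            pool = [s for s in subjects if s != partner and s not in forbidden.get(q, ())]
            k = min(n_decoys, len(pool))
            decoys = list(rng.choice(pool, size=k, replace=False)) if k else []
            decoy_scores = rng.uniform(50.0, 150.0, size=len(decoys))
            for s, score in zip(decoys, decoy_scores):
                rows.append((q, s, float(score), 10.0 ** (-float(score) / 10)))
            if partner is not None:
                top = float(decoy_scores.max()) if len(decoys) else 100.0
                score = top + score_gap * (1 - noise) + float(
                    rng.uniform(0, noise * score_gap + 1e-9)
                )
                rows.append((q, partner, score, 10.0 ** (-score / 10)))
        return HitTable(
            pd.DataFrame(rows, columns=["query", "subject", "bitscore", "evalue"])
        )

    ab = one_direction(a_ids, b_ids, truth, {})
    # decoy hits never reciprocate: a gene that was listed as someone's decoy
    # must not list that someone back (only planted pairs are symmetric)
    forbidden: dict[str, set[str]] = {}
    for row in ab.rows.itertuples():
        if truth.get(row.query) != row.subject:
            forbidden.setdefault(row.subject, set()).add(row.query)
    reverse = {b: a for a, b in truth.items() if b is not None}
    ba = one_direction(b_ids, a_ids, reverse, forbidden)
    return ab, ba, truth
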