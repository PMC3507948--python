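"""Readers and writers for the formats the pipeline touches.

Sequence formats (FASTA, aligned FASTA, CLUSTAL) are parsed with Biopython,
Newick trees with dendropy, and the two tabular formats (BLAST-style hit
tables, centroid peak lists) with pandas; this module adds the strict
validation and the coordinate bookkeeping the downstream analyses rely on.

Conventions used throughout the package:

* coordinates are 1-based and ranges are inclusive;
* the only gap character is ``'-'`` (``'.'`` is rejected);
* ``'X'`` is an allowed residue but is treated as matching nothing,
  including another ``'X'``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import AlignIO, SeqIO

from gainscan.errors import FormatError, InvariantError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: residues permitted in a ProteinSequence ('X' = unknown)
ALPHABET = frozenset(AMINO_ACIDS + "X")
GAP = "-"
_ALIGNED_ALPHABET = ALPHABET | {GAP}


@dataclass(frozen=True)
class ProteinSequence:
    """A named protein sequence.

    ``residues`` may contain ``'-'`` only for members of an :class:`Alignment`;
    plain sequences read through :func:`read_fasta` are gap-free.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise InvariantError("sequence id must be non-empty")
        if not self.residues:
            raise InvariantError(f"sequence {self.id!r} has no residues")
        bad = set(self.residues) - _ALIGNED_ALPHABET
        if bad:
            raise InvariantError(
                f"sequence {self.id!r} contains illegal character(s) "
                f"{''.join(sorted(bad))!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def ungapped(self) -> str:
        """Residues with gap characters removed."""
        return self.residues.replace(GAP, "")


class Alignment:
    """A multiple protein alignment: ≥2 members, all the same length.

    Columns are 1-based. Each member carries a bijection between alignment
    columns holding a residue and ungapped residue positions, exposed through
    :meth:`column_to_position` and :meth:`position_to_column`.
    """

    def __init__(self, members: Iterable[ProteinSequence]):
        members = tuple(members)
        if len(members) < 2:
            raise InvariantError("an alignment needs at least 2 members")
        ids = [m.id for m in members]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise InvariantError(f"duplicate member id(s): {', '.join(dupes)}")
        lengths = {len(m) for m in members}
        if len(lengths) != 1:
            ragged = [m.id for m in members if len(m) != len(members[0])]
            raise FormatError(
                "members are not all the same length; offending id(s): "
                + ", ".join(ragged)
            )
        self._members = members
        self._index = {m.id: m for m in members}
        n_cols = len(members[0])
        cols = np.array([list(m.residues) for m in members])
        if ((cols == GAP).all(axis=0)).any():
            raise InvariantError("alignment contains an all-gap column")
        self._n_cols = n_cols
        # per-member column<->ungapped-position maps (both 1-based)
        self._col_to_pos: dict[str, dict[int, int]] = {}
        self._pos_to_col: dict[str, dict[int, int]] = {}
        for m in members:
            c2p: dict[int, int] = {}
            p2c: dict[int, int] = {}
            pos = 0
            for col, ch in enumerate(m.residues, start=1):
                if ch != GAP:
                    pos += 1
                    c2p[col] = pos
                    p2c[pos] = col
            self._col_to_pos[m.id] = c2p
            self._pos_to_col[m.id] = p2c

    @property
    def members(self) -> tuple[ProteinSequence, ...]:
        return self._members

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(m.id for m in self._members)

    @property
    def n_cols(self) -> int:
        return self._n_cols

    def member(self, member_id: str) -> ProteinSequence:
        try:
            return self._index[member_id]
        except KeyError:
            raise InvariantError(f"no member with id {member_id!r}") from None

    def column(self, col: int) -> str:
        """Residues (and gaps) of 1-based column ``col``, in member order."""
        if not 1 <= col <= self._n_cols:
            raise InvariantError(f"column {col} outside 1..{self._n_cols}")
        return "".join(m.residues[col - 1] for m in self._members)

    def column_to_position(self, member_id: str, col: int) -> int | None:
        """Ungapped residue position at ``col`` for ``member_id``; None at a gap."""
        self.member(member_id)
        if not 1 <= col <= self._n_cols:
            raise InvariantError(f"column {col} outside 1..{self._n_cols}")
        return self._col_to_pos[member_id].get(col)

    def position_to_column(self, member_id: str, pos: int) -> int:
        """Alignment column of ungapped residue ``pos`` (1-based) of ``member_id``."""
        self.member(member_id)
        try:
            return self._pos_to_col[member_id][pos]
        except KeyError:
            n = len(self._pos_to_col[member_id])
            raise InvariantError(
                f"position {pos} outside 1..{n} for member {member_id!r}"
            ) from None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Alignment):
            return NotImplemented
        return [(m.id, m.residues) for m in self._members] == [
            (m.id, m.residues) for m in other._members
        ]

    def __repr__(self) -> str:
        return f"Alignment({len(self._members)} members x {self._n_cols} cols)"


@dataclass(frozen=True)
class HitTable:
    """Tabular similarity hits: (query, subject, bitscore, evalue) rows."""

    rows: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["query", "subject", "bitscore", "evalue"]
        )
    )

    def __post_init__(self) -> None:
        df = self.rows
        expected = ["query", "subject", "bitscore", "evalue"]
        if list(df.columns) != expected:
            raise InvariantError(f"hit table columns must be {expected}")
        if df.duplicated(subset=["query", "subject"]).any():
            dup = df[df.duplicated(subset=["query", "subject"])].iloc[0]
            raise InvariantError(
                f"duplicate (query, subject) pair: ({dup['query']}, {dup['subject']})"
            )
        if len(df):
            if not np.isfinite(df["bitscore"].to_numpy(dtype=float)).all():
                raise InvariantError("bitscore must be finite")
            if (df["bitscore"].to_numpy(dtype=float) < 0).any():
                raise InvariantError("bitscore must be non-negative")
            if (df["evalue"].to_numpy(dtype=float) < 0).any():
                raise InvariantError("evalue must be non-negative")

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def query_ids(self) -> list[str]:
        return list(dict.fromkeys(self.rows["query"]))

    @property
    def subject_ids(self) -> list[str]:
        return list(dict.fromkeys(self.rows["subject"]))


@dataclass(frozen=True)
class PeakList:
    """Centroided peaks: masses (Da, ascending) with relative intensities."""

    masses: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        masses = np.asarray(self.masses, dtype=float)
        intensities = np.asarray(self.intensities, dtype=float)
        if masses.shape != intensities.shape or masses.ndim != 1:
            raise InvariantError("masses and intensities must be 1-D and equal length")
        if len(masses) and (masses <= 0).any():
            raise InvariantError("peak masses must be strictly positive")
        if len(intensities) and (intensities < 0).any():
            raise InvariantError("intensities must be non-negative")
        order = np.argsort(masses, kind="stable")
        object.__setattr__(self, "masses", masses[order])
        object.__setattr__(self, "intensities", intensities[order])

    def __len__(self) -> int:
        return len(self.masses)

    def __iter__(self) -> Iterator[tuple[float, float]]:
        return iter(zip(self.masses.tolist(), self.intensities.tolist()))


# ---------------------------------------------------------------------------
# FASTA


def _clean_record(raw_id: str, raw_seq: str, path: str) -> tuple[str, str]:
    seq = "".join(raw_seq.split()).upper()
    if seq.endswith("*"):
        seq = seq[:-1]
    return raw_id, seq


def _locate_bad_char(path: str | Path, bad: str) -> int:
    """1-based line number of the first occurrence of a bad character."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">"):
                continue
            if bad in line.upper():
                return lineno
    return 0


def read_fasta(path: str | Path, *, allow_gaps: bool = False) -> list[ProteinSequence]:
    """Read a (possibly empty) FASTA file of protein sequences.

    Sequences are uppercased, whitespace is removed and a single terminal
    ``'*'`` stop is stripped. Duplicate ids and characters outside the
    amino-acid alphabet raise :class:`FormatError`.
    """
    path = Path(path)
    allowed = _ALIGNED_ALPHABET if allow_gaps else ALPHABET
    records: list[ProteinSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        rid, seq = _clean_record(rec.id, str(rec.seq), str(path))
        if rid in seen:
            raise FormatError(f"{path}: duplicate sequence id {rid!r}")
        seen.add(rid)
        bad = set(seq) - allowed
        if bad:
            ch = sorted(bad)[0]
            lineno = _locate_bad_char(path, ch)
            raise FormatError(
                f"{path}:{lineno}: illegal character {ch!r} in sequence {rid!r}"
            )
        records.append(ProteinSequence(rid, seq, rec.description))
    return records


def write_fasta(
    sequences: Sequence[ProteinSequence], path: str | Path, *, width: int = 60
) -> None:
    """Write sequences as FASTA, wrapping at ``width`` columns."""
    with open(path, "w") as fh:
        for seq in sequences:
            header = seq.id
            if seq.description and seq.description != seq.id:
                header = seq.description
            fh.write(f">{header}\n")
            for i in range(0, len(seq.residues), width):
                fh.write(seq.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Alignments


def read_alignment(path: str | Path, dialect: str = "fasta") -> Alignment:
    """Read a multiple alignment in aligned-FASTA or CLUSTAL dialect.

    The CLUSTAL reader tolerates the header line, interleaved blocks and the
    conservation line (``* : .``), which is discarded.
    """
    path = Path(path)
    if dialect == "fasta":
        members = read_fasta(path, allow_gaps=True)
        if len(members) < 2:
            raise InvariantError(f"{path}: an alignment needs at least 2 members")
        return Alignment(members)
    if dialect == "clustal":
        try:
            msa = AlignIO.read(str(path), "clustal")
        except ValueError as exc:
            raise FormatError(f"{path}: not a valid CLUSTAL file ({exc})") from exc
        members = []
        for rec in msa:
            seq = str(rec.seq).upper()
            if "." in seq:
                raise FormatError(
                    f"{path}: '.' gaps are not supported (member {rec.id!r})"
                )
            members.append(ProteinSequence(rec.id, seq))
        return Alignment(members)
    raise ValueError(f"unknown alignment dialect {dialect!r}")


def write_alignment(alignment: Alignment, path: str | Path) -> None:
    """Write an alignment as aligned FASTA."""
    write_fasta(alignment.members, path)


# ---------------------------------------------------------------------------
# Newick trees (dendropy containers)


def read_newick(source: str | Path) -> dendropy.Tree:
    """Read a Newick tree (branch lengths, optional internal support labels).

    ``source`` may be a path or a Newick string. Raises :class:`FormatError`
    with the parser's position information on malformed input.
    """
    text = None
    if isinstance(source, str) and (
        source.lstrip().startswith("(") or source.rstrip().endswith(";")
    ):
        text = source
    try:
        if text is not None:
            tree = dendropy.Tree.get(
                data=text,
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
        else:
            tree = dendropy.Tree.get(
                path=str(source),
                schema="newick",
                preserve_underscores=True,
                suppress_internal_node_taxa=True,
            )
    except Exception as exc:  # dendropy raises several error types
        raise FormatError(f"newick parse error: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise InvariantError("duplicate leaf labels in tree")
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path | None = None) -> str:
    """Serialize a tree to Newick (10 significant digits on branch lengths)."""
    text = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".10g",
    )
    text = text.strip() + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# Tabular formats


def _read_tsv(path: str | Path, names: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            header=None,
            names=names,
            dtype=str,
            skip_blank_lines=True,
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=names)
    return df


def read_hit_table(path: str | Path) -> HitTable:
    """Read a BLAST-tabular-style TSV: query, subject, bitscore, evalue."""
    df = _read_tsv(path, ["query", "subject", "bitscore", "evalue"])
    if len(df):
        for col in ("bitscore", "evalue"):
            converted = pd.to_numeric(df[col], errors="coerce")
            bad = converted.isna() & df[col].notna()
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
                raise FormatError(
                    f"{path}: non-numeric {col} {df[col][bad].iloc[0]!r} at data row {row}"
                )
            if converted.isna().any():
                row = int(np.flatnonzero(converted.isna().to_numpy())[0]) + 1
                raise FormatError(f"{path}: missing {col} at data row {row}")
            df[col] = converted.astype(float)
    return HitTable(df.reset_index(drop=True))


def read_peaklist(path: str | Path) -> PeakList:
    """Read a centroid peak list TSV: mass [<TAB> relative intensity].

    ``#`` comment lines are skipped; a missing intensity column defaults to 0.
    Peaks are sorted ascending by mass.
    """
    rows: list[tuple[float, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                mass = float(fields[0])
                inten = float(fields[1]) if len(fields) > 1 and fields[1] else 0.0
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric field in {line!r}"
                ) from exc
            if not math.isfinite(mass):
                raise FormatError(f"{path}:{lineno}: non-finite mass")
            rows.append((mass, inten))
    if not rows:
        return PeakList(np.empty(0), np.empty(0))
    masses, intens = zip(*rows)
    return PeakList(np.array(masses), np.array(intens))


def write_peaklist(peaks: PeakList, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# mass\tintensity\n")
        for mass, inten in peaks:
            fh.write(f"{mass:.4f}\t{inten:.4f}\n")
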