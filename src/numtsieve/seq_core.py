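"""Sequence and alignment primitives for codon-aware mtDNA screening.

The screening pipeline operates on a multiple sequence alignment of
protein-coding mitochondrial haplotypes.  This module provides the
alignment container, FASTA I/O, haplotype collapsing, majority-rule
consensus, reading-frame detection by stop-codon minimisation, and
translation under the invertebrate mitochondrial genetic code (NCBI
translation table 5, the code used by beetle COI).

Coordinate convention: all internal coordinates are 0-based half-open;
anything reported to a user (error messages, site tables) is 1-based.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Data import CodonTable

__all__ = [
    "GAP",
    "IUPAC_SETS",
    "ALPHABET",
    "NucleotideSequence",
    "CodonAwareAlignment",
    "GeneticCode",
    "AlignmentError",
    "FastaFormatError",
    "NoReadingFrameError",
    "read_aligned_fasta",
    "write_fasta",
    "collapse_haplotypes",
    "consensus",
    "detect_reading_frame",
    "translate",
    "reverse_complement",
]

GAP = "-"

#: IUPAC nucleotide one-letter codes mapped to the set of unambiguous
#: bases each one covers.  Gap is not an IUPAC code and is handled
#: separately throughout.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: Inverse of :data:`IUPAC_SETS`: base set -> degenerate letter.
SET_TO_IUPAC: dict[frozenset[str], str] = {v: k for k, v in IUPAC_SETS.items()}

ALPHABET = frozenset(IUPAC_SETS) | {GAP}
UNAMBIGUOUS = frozenset("ACGT")

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN-",
    "TGCAYRSWMKVHDBN-",
)


class AlignmentError(ValueError):
    """Sequences do not form a valid alignment (e.g. unequal lengths)."""


class FastaFormatError(ValueError):
    """Input is not parseable FASTA or contains illegal characters."""


class NoReadingFrameError(ValueError):
    """No frame offset yields a plausibly coding translation."""


@dataclass(frozen=True)
class NucleotideSequence:
    """A named nucleotide string over the IUPAC alphabet plus gap.

    Residues are stored upper-case; lower-case input is accepted and
    normalised.  Any character outside the alphabet raises
    :class:`FastaFormatError` naming the 1-based offending column.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        residues = self.residues.upper()
        if len(residues) < 1:
            raise FastaFormatError(f"sequence {self.id!r} is empty")
        for i, ch in enumerate(residues):
            if ch not in ALPHABET:
                raise FastaFormatError(
                    f"illegal character {ch!r} in sequence {self.id!r} "
                    f"at column {i + 1}"
                )
        object.__setattr__(self, "residues", residues)

    def __len__(self) -> int:
        return len(self.residues)

    def ungapped(self) -> "NucleotideSequence":
        return replace(self, residues=self.residues.replace(GAP, "") or GAP)

    def reverse_complement(self) -> "NucleotideSequence":
        return replace(self, residues=reverse_complement(self.residues))


def reverse_complement(residues: str) -> str:
    """Reverse complement honouring IUPAC degeneracy letters."""
    return residues.upper().translate(_COMPLEMENT)[::-1]


@dataclass
class CodonAwareAlignment:
    """Equal-length nucleotide sequences with a reading-frame offset.

    ``frame_offset`` is the number of leading alignment columns before
    the first complete codon (0, 1 or 2).  It starts at 0 on parse and
    is normally set by :func:`detect_reading_frame`.
    """

    sequences: list[NucleotideSequence]
    frame_offset: int = 0
    source: str = ""

    def __post_init__(self) -> None:
        if not self.sequences:
            raise AlignmentError("alignment must contain at least one sequence")
        length = len(self.sequences[0])
        for seq in self.sequences[1:]:
            if len(seq) != length:
                raise AlignmentError(
                    f"sequence {seq.id!r} has length {len(seq)}, "
                    f"expected {length} (alignment must be equal-length)"
                )
        if self.frame_offset not in (0, 1, 2):
            raise AlignmentError(
                f"frame_offset must be 0, 1 or 2, got {self.frame_offset}"
            )

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self) -> Iterator[NucleotideSequence]:
        return iter(self.sequences)

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0])


@dataclass(frozen=True)
class GeneticCode:
    """A total map from the 64 unambiguous codons to amino-acid letters.

    The default is the invertebrate mitochondrial code (NCBI translation
    table 5): ATA encodes Met, AGA/AGG encode Ser, TGA encodes Trp, and
    only TAA/TAG are stops.
    """

    table_id: int
    codon_to_aa: dict[str, str]
    stops: frozenset[str]

    STOP = "*"
    UNKNOWN = "X"

    def __post_init__(self) -> None:
        if len(self.codon_to_aa) != 64:
            raise ValueError(
                f"genetic code must define all 64 codons, got {len(self.codon_to_aa)}"
            )
        derived_stops = frozenset(
            c for c, aa in self.codon_to_aa.items() if aa == self.STOP
        )
        if derived_stops != self.stops:
            raise ValueError("stops set inconsistent with codon_to_aa")

    @classmethod
    def from_ncbi_id(cls, table_id: int = 5) -> "GeneticCode":
        table = CodonTable.unambiguous_dna_by_id[table_id]
        codon_to_aa = dict(table.forward_table)
        for stop in table.stop_codons:
            codon_to_aa[stop] = cls.STOP
        return cls(
            table_id=table_id,
            codon_to_aa=codon_to_aa,
            stops=frozenset(table.stop_codons),
        )

    def aa(self, codon: str) -> str:
        """Amino acid for a codon; 'X' if the codon is not unambiguous ACGT."""
        return self.codon_to_aa.get(codon.upper(), self.UNKNOWN)

    def is_stop(self, codon: str) -> bool:
        return codon.upper() in self.stops


INVERTEBRATE_MITO = GeneticCode.from_ncbi_id(5)


def _open_maybe_gzip(path: Path):
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_aligned_fasta(path: str | Path, source: str | None = None) -> CodonAwareAlignment:
    """Read a multi-record FASTA file as an alignment.

    Accepts wrapped or unwrapped records and gzip-compressed input.
    Residues are upper-cased; the frame offset is initialised to 0.

    Raises
    ------
    FastaFormatError
        If the file holds no records or a record contains characters
        outside the IUPAC-plus-gap alphabet.
    AlignmentError
        If the records do not all share one length; the message names
        the offending record.
    """
    path = Path(path)
    with _open_maybe_gzip(path) as handle:
        records = [
            NucleotideSequence(id=rec.id, residues=str(rec.seq))
            for rec in SeqIO.parse(handle, "fasta")
        ]
    if not records:
        raise FastaFormatError(f"{path}: no FASTA records found")
    return CodonAwareAlignment(
        sequences=records, frame_offset=0, source=source or str(path)
    )


def write_fasta(aln: CodonAwareAlignment | Iterable[NucleotideSequence], path: str | Path) -> None:
    """Write sequences as unwrapped FASTA (byte-for-byte round-trippable)."""
    seqs = aln.sequences if isinstance(aln, CodonAwareAlignment) else list(aln)
    with open(path, "w") as out:
        for seq in seqs:
            out.write(f">{seq.id}\n{seq.residues}\n")


def collapse_haplotypes(aln: CodonAwareAlignment) -> CodonAwareAlignment:
    """Collapse identical residue strings to unique haplotypes.

    One representative (the first seen) is kept per distinct residue
    string, preserving input order.  Screening statistics are defined on
    unique haplotypes, not on individuals, so this is the first step of
    every screen.
    """
    seen: dict[str, NucleotideSequence] = {}
    for seq in aln:
        seen.setdefault(seq.residues, seq)
    collapsed = list(seen.values())
    note = f"{aln.source} [collapsed {len(aln)} -> {len(collapsed)} haplotypes]"
    return CodonAwareAlignment(
        sequences=collapsed, frame_offset=aln.frame_offset, source=note
    )


def consensus(aln: CodonAwareAlignment) -> NucleotideSequence:
    """Column-wise majority consensus over unambiguous bases.

    Per column, the most frequent base among {A,C,G,T} wins; ambiguity
    codes are excluded from the tally and ties resolve to the
    alphabetically first base (A < C < G < T).  A column where gap
    characters outnumber the most frequent base — an insertion carried
    by a minority of haplotypes, or an all-gap column — yields a gap,
    so that indel counting sees insertions as such.
    """
    if len(aln) < 2:
        raise AlignmentError("consensus requires at least 2 sequences")
    cols = []
    n = aln.n_columns
    seqs = [s.residues for s in aln]
    for j in range(n):
        counts = {"A": 0, "C": 0, "G": 0, "T": 0}
        gaps = 0
        for s in seqs:
            ch = s[j]
            if ch in counts:
                counts[ch] += 1
            elif ch == GAP:
                gaps += 1
        best = max(counts, key=lambda b: (counts[b], -ord(b)))
        cols.append(GAP if gaps > counts[best] or counts[best] == 0 else best)
    return NucleotideSequence(id="consensus", residues="".join(cols))


def _count_internal_stops(residues: str, offset: int, code: GeneticCode) -> tuple[int, int]:
    """(number of stop codons, number of complete codons) at an offset.

    A stop in the final complete codon is a legitimate terminator and is
    not counted as internal.
    """
    n_codons = (len(residues) - offset) // 3
    stops = 0
    for k in range(n_codons):
        codon = residues[offset + 3 * k : offset + 3 * k + 3]
        if code.is_stop(codon) and k != n_codons - 1:
            stops += 1
    return stops, n_codons


def detect_reading_frame(
    cons: NucleotideSequence,
    code: GeneticCode = INVERTEBRATE_MITO,
    max_stop_fraction: float = 0.10,
) -> int:
    """Choose the frame offset whose translation has fewest internal stops.

    Works on the ungapped consensus.  Ties break to the smaller offset.
    If every frame translates with more than ``max_stop_fraction`` stop
    codons the sequence is not plausibly protein-coding and
    :class:`NoReadingFrameError` is raised.
    """
    residues = cons.residues.replace(GAP, "")
    if len(residues) < 30:
        raise AlignmentError(
            f"consensus too short for frame detection ({len(residues)} bp, need >= 30)"
        )
    results = []
    for offset in (0, 1, 2):
        stops, n_codons = _count_internal_stops(residues, offset, code)
        results.append((stops, offset, n_codons))
    results.sort()
    best_stops, best_offset, best_n = results[0]
    if all(stops > max_stop_fraction * n for stops, _, n in results):
        raise NoReadingFrameError(
            "no plausible coding frame: all three frames exceed "
            f"{max_stop_fraction:.0%} internal stop codons"
        )
    return best_offset


def translate(
    seq: NucleotideSequence,
    frame_offset: int = 0,
    code: GeneticCode = INVERTEBRATE_MITO,
) -> str:
    """Translate complete codons from ``frame_offset``; gaps are stripped.

    A trailing partial codon is dropped; any codon containing N or an
    ambiguity letter translates to 'X'; stops appear as '*'.
    """
    if frame_offset not in (0, 1, 2):
        raise ValueError(f"frame_offset must be 0, 1 or 2, got {frame_offset}")
    residues = seq.residues.replace(GAP, "")
    n_codons = (len(residues) - frame_offset) // 3
    out = []
    for k in range(n_codons):
        codon = residues[frame_offset + 3 * k : frame_offset + 3 * k + 3]
        out.append(code.aa(codon))
    return "".join(out)
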