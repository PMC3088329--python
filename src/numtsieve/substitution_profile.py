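"""Classify every mutational event in a haplotype alignment.

Substitutions are counted against the majority consensus as distinct
(column, non-consensus allele) pairs: a variant shared by many
haplotypes is one event, two different alternative bases at one column
are two events.  Each event is classified by codon position,
synonymous/nonsynonymous status under the genetic code, transition vs
transversion, C->T identity on the given strand, and 5'-G dinucleotide
context (the GpC -> GpT class elevated by cytosine methylation in
nuclear DNA but absent from mtDNA).  Indel events and stop codons not
present in the consensus are counted separately.

Only columns inside complete codons (as set by the alignment's frame
offset) contribute substitution events; partial leading/trailing
columns still contribute to GC content.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .seq_core import (
    GAP,
    UNAMBIGUOUS,
    CodonAwareAlignment,
    GeneticCode,
    INVERTEBRATE_MITO,
    NucleotideSequence,
    collapse_haplotypes,
    consensus,
)

logger = logging.getLogger(__name__)

__all__ = [
    "VariableSite",
    "SubstitutionClass",
    "SubstitutionCounts",
    "find_variable_columns",
    "classify_substitution",
    "count_indel_events",
    "count_extra_stops",
    "gc_content",
    "profile_alignment",
]

_TRANSITION_PAIRS = {frozenset("AG"), frozenset("CT")}


@dataclass(frozen=True)
class VariableSite:
    """One alignment column carrying at least one non-consensus base.

    ``column`` is 1-based.  Codon fields are ``None`` when the column
    falls outside the complete-codon region defined by the frame
    offset (such sites carry no classifiable substitution events).
    """

    column: int
    consensus_base: str
    alt_alleles: frozenset[str]
    codon_index: int | None
    codon_position: int | None
    consensus_codon: str | None
    five_prime_base: str | None

    def __post_init__(self) -> None:
        if not self.alt_alleles:
            raise ValueError("alt_alleles must be nonempty")
        if self.consensus_base in self.alt_alleles:
            raise ValueError("alt_alleles must exclude the consensus base")


@dataclass(frozen=True)
class SubstitutionClass:
    """Classification flags for one substitution event."""

    codon_position: int
    synonymous: bool
    transition: bool
    c_to_t: bool
    gc_to_gt: bool
    creates_stop: bool = False

    def __post_init__(self) -> None:
        if self.gc_to_gt and not self.c_to_t:
            raise ValueError("gc_to_gt implies c_to_t")


@dataclass
class SubstitutionCounts:
    """Raw counts of every classified mutational event in an alignment.

    Invariants (asserted after every profile run): pos1+pos2+pos3 ==
    total, ts3+tv3 == pos3, ts_all+tv_all == total, gc_to_gt <= c_to_t.
    """

    total: int = 0
    pos1: int = 0
    pos2: int = 0
    pos3: int = 0
    nonsyn: int = 0
    c_to_t: int = 0
    c_to_t_with_context: int = 0  # C->T events with a defined 5' base
    gc_to_gt: int = 0
    insertions: int = 0
    deletions: int = 0
    frameshift_indels: int = 0  # indel events whose length is not 0 mod 3
    extra_stops: int = 0
    ts3: int = 0
    tv3: int = 0
    ts_all: int = 0
    tv_all: int = 0
    gc_percent: float = 0.0
    n_columns: int = 0
    n_haplotypes: int = 0
    skipped_sites: int = 0  # variable sites unclassifiable (ambiguous/partial)

    def check_invariants(self) -> None:
        assert self.pos1 + self.pos2 + self.pos3 == self.total
        assert self.ts3 + self.tv3 == self.pos3
        assert self.ts_all + self.tv_all == self.total
        assert self.gc_to_gt <= self.c_to_t <= self.total
        assert self.c_to_t_with_context <= self.c_to_t
        assert min(
            self.total, self.pos1, self.pos2, self.pos3, self.nonsyn,
            self.c_to_t, self.gc_to_gt, self.insertions, self.deletions,
            self.extra_stops, self.ts3, self.tv3,
        ) >= 0


def is_transition(a: str, b: str) -> bool:
    return frozenset((a, b)) in _TRANSITION_PAIRS


def _codon_region(aln: CodonAwareAlignment) -> tuple[int, int]:
    """Half-open column range [start, stop) covered by complete codons."""
    start = aln.frame_offset
    n_codons = (aln.n_columns - start) // 3
    return start, start + 3 * n_codons


def find_variable_columns(
    aln: CodonAwareAlignment, cons: NucleotideSequence
) -> list[VariableSite]:
    """One :class:`VariableSite` per column with a non-consensus base.

    Columns whose only deviations from the consensus are gaps or
    ambiguity codes are not variable (gaps are indel territory,
    ambiguity codes carry no allele call).  Columns where the consensus
    itself is a gap are likewise excluded here; they are handled by
    :func:`count_indel_events`.
    """
    region_start, region_stop = _codon_region(aln)
    sites: list[VariableSite] = []
    cres = cons.residues
    for j in range(aln.n_columns):
        cons_base = cres[j]
        if cons_base not in UNAMBIGUOUS:
            continue
        alts = {
            s.residues[j]
            for s in aln
            if s.residues[j] in UNAMBIGUOUS and s.residues[j] != cons_base
        }
        if not alts:
            continue
        if region_start <= j < region_stop:
            codon_index = (j - aln.frame_offset) // 3
            codon_position = (j - aln.frame_offset) % 3 + 1
            cstart = aln.frame_offset + 3 * codon_index
            consensus_codon = cres[cstart : cstart + 3]
            codon_index += 1  # report 1-based
        else:
            codon_index = codon_position = consensus_codon = None
        sites.append(
            VariableSite(
                column=j + 1,
                consensus_base=cons_base,
                alt_alleles=frozenset(alts),
                codon_index=codon_index,
                codon_position=codon_position,
                consensus_codon=consensus_codon,
                five_prime_base=cres[j - 1] if j > 0 else None,
            )
        )
    return sites


def classify_substitution(
    site: VariableSite, alt: str, code: GeneticCode = INVERTEBRATE_MITO
) -> SubstitutionClass:
    """Classify one substitution event (one change at a time).

    The mutated codon is the consensus codon with ``alt`` substituted at
    the site's codon position; multiple substitutions within one codon
    are deliberately classified independently against the consensus
    context.  A change producing a stop codon is nonsynonymous.
    """
    if alt not in site.alt_alleles:
        raise ValueError(f"alt {alt!r} not among observed alleles at column {site.column}")
    if site.codon_position is None or site.consensus_codon is None:
        raise ValueError(f"column {site.column} lies outside the codon region")
    codon = site.consensus_codon
    if any(ch not in UNAMBIGUOUS for ch in codon):
        raise ValueError(
            f"consensus codon {codon!r} at column {site.column} is ambiguous"
        )
    pos0 = site.codon_position - 1
    mutated = codon[:pos0] + alt + codon[pos0 + 1 :]
    synonymous = code.aa(codon) == code.aa(mutated)
    c_to_t = site.consensus_base == "C" and alt == "T"
    return SubstitutionClass(
        codon_position=site.codon_position,
        synonymous=synonymous,
        transition=is_transition(site.consensus_base, alt),
        c_to_t=c_to_t,
        gc_to_gt=c_to_t and site.five_prime_base == "G",
        creates_stop=code.is_stop(mutated) and not code.is_stop(codon),
    )


def _gap_runs(mask: list[bool]) -> list[tuple[int, int]]:
    """Maximal [start, stop) runs of True in a boolean mask."""
    runs = []
    start = None
    for i, flag in enumerate(mask):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(mask)))
    return runs


def count_indel_events(
    aln: CodonAwareAlignment, cons: NucleotideSequence
) -> tuple[int, int, int]:
    """Count (insertions, deletions, frameshift_indels) per haplotype.

    A deletion event is a maximal run of gap characters in a haplotype
    where the consensus has bases; an insertion event is a maximal run
    where the haplotype has bases and the consensus has gaps.  Each
    distinct haplotype contributes its runs once (the alignment should
    already be collapsed).  Events whose length is not a multiple of 3
    additionally count as frameshifts.
    """
    ins = dels = frameshifts = 0
    cres = cons.residues
    for seq in aln:
        sres = seq.residues
        del_mask = [s == GAP and c != GAP for s, c in zip(sres, cres)]
        ins_mask = [s != GAP and c == GAP for s, c in zip(sres, cres)]
        for start, stop in _gap_runs(del_mask):
            dels += 1
            if (stop - start) % 3:
                frameshifts += 1
        for start, stop in _gap_runs(ins_mask):
            ins += 1
            if (stop - start) % 3:
                frameshifts += 1
    return ins, dels, frameshifts


def count_extra_stops(
    aln: CodonAwareAlignment,
    cons: NucleotideSequence,
    code: GeneticCode = INVERTEBRATE_MITO,
) -> int:
    """Stop codons present in haplotypes but not in the consensus.

    Counts (haplotype, codon index) pairs where the haplotype codon is a
    stop while the consensus codon at that index is not.  Codons with
    gaps or ambiguity letters are skipped; a terminal stop shared with
    the consensus therefore never counts.
    """
    start, stop = _codon_region(aln)
    count = 0
    cres = cons.residues
    for seq in aln:
        sres = seq.residues
        for cstart in range(start, stop, 3):
            codon = sres[cstart : cstart + 3]
            if any(ch not in UNAMBIGUOUS for ch in codon):
                continue
            if code.is_stop(codon) and not code.is_stop(cres[cstart : cstart + 3]):
                count += 1
    return count


def gc_content(aln: CodonAwareAlignment) -> float:
    """Percent G+C among unambiguous bases over all haplotypes."""
    gc = total = 0
    for seq in aln:
        for ch in seq.residues:
            if ch in UNAMBIGUOUS:
                total += 1
                if ch in "GC":
                    gc += 1
    if total == 0:
        raise ValueError("GC content undefined: alignment has no unambiguous bases")
    return 100.0 * gc / total


def profile_alignment(
    aln: CodonAwareAlignment,
    code: GeneticCode = INVERTEBRATE_MITO,
    collapse: bool = True,
) -> SubstitutionCounts:
    """Aggregate every classified event into :class:`SubstitutionCounts`.

    The alignment is collapsed to unique haplotypes first (idempotent),
    so duplicating input records never changes any count.  Each distinct
    (column, alternative allele) pair contributes exactly one
    substitution event regardless of carrier count.
    """
    if collapse:
        aln = collapse_haplotypes(aln)
    counts = SubstitutionCounts(
        n_columns=aln.n_columns, n_haplotypes=len(aln), gc_percent=gc_content(aln)
    )
    if len(aln) == 1:
        return counts  # a single haplotype carries no events by definition
    cons = consensus(aln)
    for site in find_variable_columns(aln, cons):
        if site.codon_position is None:
            counts.skipped_sites += 1
            continue
        if any(ch not in UNAMBIGUOUS for ch in site.consensus_codon):
            logger.warning(
                "skipping column %d: ambiguous consensus codon %r",
                site.column, site.consensus_codon,
            )
            counts.skipped_sites += 1
            continue
        for alt in sorted(site.alt_alleles):
            cls = classify_substitution(site, alt, code)
            counts.total += 1
            if cls.codon_position == 1:
                counts.pos1 += 1
            elif cls.codon_position == 2:
                counts.pos2 += 1
            else:
                counts.pos3 += 1
                if cls.transition:
                    counts.ts3 += 1
                else:
                    counts.tv3 += 1
            if cls.transition:
                counts.ts_all += 1
            else:
                counts.tv_all += 1
            if not cls.synonymous:
                counts.nonsyn += 1
            if cls.c_to_t:
                counts.c_to_t += 1
                if site.five_prime_base is not None:
                    counts.c_to_t_with_context += 1
                if cls.gc_to_gt:
                    counts.gc_to_gt += 1
    ins, dels, frameshifts = count_indel_events(aln, cons)
    counts.insertions = ins
    counts.deletions = dels
    counts.frameshift_indels = frameshifts
    counts.extra_stops = count_extra_stops(aln, cons, code)
    counts.check_invariants()
    return counts
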