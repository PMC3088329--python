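"""Degenerate-primer design from conserved windows of a mitogenome alignment.

For long-PCR numt exclusion the amplified stretch must be longer than
any plausible nuclear copy, so primers are placed in regions conserved
across the taxa of interest.  This module scans a pre-built alignment
for maximal windows whose per-column base sets (over a configurable
core-taxon subset) stay below a degeneracy budget, renders each window
as an IUPAC-degenerate primer, counts primer/target mismatches, and
predicts amplicon lengths on ungapped templates.

Only sequence conservation is evaluated; melting temperature and
secondary structure are out of scope, as in the screen this supports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .seq_core import (
    GAP,
    IUPAC_SETS,
    SET_TO_IUPAC,
    UNAMBIGUOUS,
    CodonAwareAlignment,
    NucleotideSequence,
    reverse_complement,
)

__all__ = [
    "ConservedWindow",
    "find_conserved_windows",
    "window_to_primer",
    "degenerate_match",
    "amplicon_length",
    "AmbiguousSiteError",
]


class AmbiguousSiteError(ValueError):
    """A primer matches a template equally well at several positions."""

    def __init__(self, primer_id: str, positions: list[int], mismatches: int):
        self.positions = positions
        self.mismatches = mismatches
        super().__init__(
            f"primer {primer_id!r} matches at {len(positions)} equally good sites "
            f"(1-based positions {[p + 1 for p in positions]}, {mismatches} mismatches each)"
        )


@dataclass(frozen=True)
class ConservedWindow:
    """A gap-free alignment window conserved across the core taxa.

    ``start``/``end`` are 1-based inclusive alignment columns;
    ``column_sets`` holds the unambiguous base set observed in the core
    taxa at each column; ``degeneracy`` is the product of set sizes;
    ``max_mismatch_per_seq`` the worst mismatch count of any aligned
    sequence (core or not) against the window's degenerate consensus.
    """

    start: int
    end: int
    column_sets: tuple[frozenset[str], ...]
    degeneracy: int
    max_mismatch_per_seq: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _column_base_set(residues: list[str]) -> frozenset[str] | None:
    """Unambiguous base set of a column; None if it contains a gap.

    Ambiguity letters are expanded to the bases they cover.
    """
    bases: set[str] = set()
    for ch in residues:
        if ch == GAP:
            return None
        bases |= IUPAC_SETS[ch]
    return frozenset(bases)


def find_conserved_windows(
    aln: CodonAwareAlignment,
    min_len: int = 18,
    max_degeneracy: int = 8,
    core_taxa: list[str] | None = None,
) -> list[ConservedWindow]:
    """All maximal windows of length >= ``min_len`` within budget.

    Degeneracy (the product of per-column base-set sizes) is evaluated
    over ``core_taxa`` only (default: every sequence), so primers can be
    made specific to a clade while the remaining taxa still inform
    conservation through the reported mismatch counts.  Windows must be
    gap-free in the core taxa.  Output is sorted by (degeneracy
    ascending, length descending).
    """
    if len(aln) < 2:
        raise ValueError("window scan requires at least 2 sequences")
    if min_len < 10:
        raise ValueError("min_len must be >= 10")
    if core_taxa:
        ids = {s.id: s for s in aln}
        missing = [t for t in core_taxa if t not in ids]
        if missing:
            raise ValueError(f"core taxa not in alignment: {missing}")
        core = [ids[t] for t in core_taxa]
    else:
        core = list(aln.sequences)
    n = aln.n_columns
    col_sets: list[frozenset[str] | None] = [
        _column_base_set([s.residues[j] for s in core]) for j in range(n)
    ]
    col_deg = [len(s) if s is not None else None for s in col_sets]

    # two-pointer over log-degeneracy; None columns are hard breaks
    windows: list[tuple[int, int]] = []
    left = 0
    log_budget = math.log(max_degeneracy) + 1e-12
    log_sum = 0.0
    prev_right = -1
    for right in range(n):
        if col_deg[right] is None:
            left = right + 1
            log_sum = 0.0
            continue
        log_sum += math.log(col_deg[right])
        while log_sum > log_budget:
            log_sum -= math.log(col_deg[left])
            left += 1
        # (left, right) is the widest valid window ending at right
        if right - left + 1 >= min_len:
            if windows and windows[-1][0] == left:
                windows[-1] = (left, right)  # extend: same maximal window
            elif not windows or right > windows[-1][1]:
                windows.append((left, right))
    out = []
    for lo, hi in windows:
        sets = tuple(col_sets[j] for j in range(lo, hi + 1))
        degeneracy = math.prod(len(s) for s in sets)
        primer = "".join(SET_TO_IUPAC[s] for s in sets)
        worst = 0
        for s in aln:
            segment = s.residues[lo : hi + 1]
            if any(ch not in UNAMBIGUOUS for ch in segment):
                continue
            worst = max(
                worst,
                degenerate_match(
                    NucleotideSequence(id="w", residues=primer),
                    NucleotideSequence(id=s.id, residues=segment),
                ),
            )
        out.append(
            ConservedWindow(
                start=lo + 1,
                end=hi + 1,
                column_sets=sets,
                degeneracy=degeneracy,
                max_mismatch_per_seq=worst,
            )
        )
    out.sort(key=lambda w: (w.degeneracy, -w.length, w.start))
    return out


def window_to_primer(window: ConservedWindow, reverse: bool = False) -> NucleotideSequence:
    """Render a window as an IUPAC-degenerate primer.

    Each column becomes the IUPAC letter covering exactly its observed
    base set.  With ``reverse=True`` the primer is reverse-complemented,
    i.e. written 5'->3' as it would be synthesized for the opposite
    strand.
    """
    residues = "".join(SET_TO_IUPAC[s] for s in window.column_sets)
    if reverse:
        residues = reverse_complement(residues)
    name = f"window_{window.start}_{window.end}" + ("_rev" if reverse else "")
    return NucleotideSequence(id=name, residues=residues)


def degenerate_match(primer: NucleotideSequence, target: NucleotideSequence) -> int:
    """Mismatches between a degenerate primer and an unambiguous target.

    A position matches when the target base belongs to the set covered
    by the primer's IUPAC letter.
    """
    p, t = primer.residues, target.residues
    if len(p) != len(t):
        raise ValueError(
            f"primer length {len(p)} != target length {len(t)}"
        )
    mismatches = 0
    for pc, tc in zip(p, t):
        if tc not in UNAMBIGUOUS:
            raise ValueError(f"target contains non-ACGT character {tc!r}")
        if tc not in IUPAC_SETS[pc]:
            mismatches += 1
    return mismatches


def _best_site(primer: str, template: str, max_mismatch: int, primer_id: str):
    """Best (fewest-mismatch) primer site on a strand, or None.

    Raises :class:`AmbiguousSiteError` when several sites tie at the
    best admissible mismatch count.
    """
    k = len(primer)
    best = None
    positions: list[int] = []
    for i in range(len(template) - k + 1):
        mm = 0
        segment = template[i : i + k]
        for pc, tc in zip(primer, segment):
            if tc not in IUPAC_SETS[pc]:
                mm += 1
                if best is not None and mm > best:
                    break
        if mm > max_mismatch:
            continue
        if best is None or mm < best:
            best, positions = mm, [i]
        elif mm == best:
            positions.append(i)
    if best is None:
        return None
    if len(positions) > 1:
        raise AmbiguousSiteError(primer_id, positions, best)
    return positions[0]


def amplicon_length(
    template: NucleotideSequence,
    fwd: NucleotideSequence,
    rev: NucleotideSequence,
    max_mismatch: int = 0,
) -> int | None:
    """Predicted PCR product length, or None when a primer finds no site.

    The forward primer is matched on the given strand, the reverse
    primer (supplied 5'->3' as synthesized) on the reverse complement.
    The product length runs from the 5' end of the forward site to the
    5' end of the reverse site inclusive, i.e. both primer footprints
    are included, matching how product sizes are conventionally quoted.
    """
    if GAP in template.residues:
        raise ValueError("template must be ungapped")
    if len(fwd) < 10 or len(rev) < 10:
        raise ValueError("primers must be at least 10 bases")
    tpl = template.residues
    i = _best_site(fwd.residues, tpl, max_mismatch, fwd.id)
    if i is None:
        return None
    rc = reverse_complement(tpl)
    j = _best_site(rev.residues, rc, max_mismatch, rev.id)
    if j is None:
        return None
    rev_five_prime = len(tpl) - 1 - j  # template coordinate of reverse 5' end
    length = rev_five_prime - i + 1
    return length if length >= len(fwd) + len(rev) else None
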