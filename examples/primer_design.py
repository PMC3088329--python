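"""Degenerate-primer design on the published six-mitogenome primer sites.

Rebuilds the printed primer-site alignment (three coleopteran and three
other insect mitogenomes), scans it for conserved windows, renders the
degenerate consensus primers, counts per-taxon mismatches, and predicts
the product length of the published long-PCR primer pair on a synthetic
template of the published size.
"""

import numpy as np

from numtsieve import (
    CodonAwareAlignment,
    NucleotideSequence,
    amplicon_length,
    degenerate_match,
    find_conserved_windows,
    window_to_primer,
)
from numtsieve.datasets import CO2_R_PRIMER, MET_F_PRIMER, PRIMER_SITE_ROWS
from numtsieve.seq_core import reverse_complement

rows = PRIMER_SITE_ROWS["met_f"]
alignment = CodonAwareAlignment(
    sequences=[NucleotideSequence(id=t, residues=r) for t, r in rows.items()]
)

coleoptera = [t for t in rows if t.split()[0] in
              ("Crioceris", "Pyrocoelia", "Tribolium")]
windows = find_conserved_windows(
    alignment, min_len=18, max_degeneracy=4, core_taxa=coleoptera
)
primer = window_to_primer(windows[0])
print(f"coleopteran-core window: degeneracy {windows[0].degeneracy}, "
      f"primer {primer.residues}")
for taxon, residues in rows.items():
    mm = degenerate_match(primer, NucleotideSequence(id=taxon, residues=residues))
    print(f"  {taxon:28s} {mm} mismatch(es)")

# published pair on a synthetic template of the published product size
met_f = NucleotideSequence("Met/F", MET_F_PRIMER)
co2_r = NucleotideSequence("CO2/R", CO2_R_PRIMER)
rng = np.random.default_rng(0)
filler = "".join(rng.choice(list("ACGT"), size=3463 - len(MET_F_PRIMER) - len(CO2_R_PRIMER)))
template = NucleotideSequence(
    "template",
    rows["Crioceris duodecimpunctata"] + filler
    + reverse_complement(PRIMER_SITE_ROWS["co2_r"]["Crioceris duodecimpunctata"]),
)
print(f"\npredicted product: {amplicon_length(template, met_f, co2_r)} bp "
      "(both primer footprints included)")
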