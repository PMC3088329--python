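import pytest

from numtsieve import (
    CodonAwareAlignment,
    INVERTEBRATE_MITO,
    NucleotideSequence,
)


@pytest.fixture(scope="session")
def code():
    return INVERTEBRATE_MITO


def make_alignment(residue_strings, frame_offset=0, ids=None):
    ids = ids or [f"s{i + 1}" for i in range(len(residue_strings))]
    return CodonAwareAlignment(
        sequences=[
            NucleotideSequence(id=i, residues=r)
            for i, r in zip(ids, residue_strings)
        ],
        frame_offset=frame_offset,
    )


@pytest.fixture
def toy_pair():
    """Two haplotypes differing by one 3rd-position transition (Leu->Leu)."""
    return make_alignment(["TTATTA", "TTGTTA"])


#: NCBI translation table 5 (invertebrate mitochondrial), transcribed by
#: hand from the NCBI genetic-code listing.  Deliberately independent of
#: the package's Biopython-backed table: tests compare the two.
HAND_TABLE_5 = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "M", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "W", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "S", "AGG": "S",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
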