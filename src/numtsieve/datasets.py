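"""Access to the reference COI haplotype dataset.

The screen's reference dataset is the set of 58 European *Pityogenes
chalcographus* COI haplotypes (GenBank DQ515997–DQ516054, a 1557 bp
coding stretch representing 262 sequenced individuals).  The sequences
are not redistributed here; :func:`fetch_coi_haplotypes` downloads them
once from GenBank and :func:`load_coi_haplotypes` reads the resulting
FASTA (or any user-supplied path).
"""

from __future__ import annotations

from pathlib import Path

from .seq_core import CodonAwareAlignment, read_aligned_fasta

__all__ = [
    "COI_ACCESSIONS",
    "DEFAULT_DATA_PATH",
    "DatasetUnavailableError",
    "fetch_coi_haplotypes",
    "load_coi_haplotypes",
]

#: GenBank accessions of the 58 European P. chalcographus COI haplotypes.
COI_ACCESSIONS: tuple[str, ...] = tuple(f"DQ{n}" for n in range(515997, 516055))

#: The published long-PCR primer pair (Met-tRNA forward, CO2 reverse)
#: and the aligned rows of six insect reference mitogenomes at the two
#: primer sites, as printed (dot notation expanded back into bases).
MET_F_PRIMER = "GCTWHTGGGTTCATACCC"
CO2_R_PRIMER = "CAAATTTCTGAACATTG"
PRIMER_SITE_ROWS: dict[str, dict[str, str]] = {
    "met_f": {
        "Crioceris duodecimpunctata": "GCTATTGGGTTCATACCC",
        "Pyrocoelia rufa": "GCTTTTGGGTTCATACCC",
        "Tribolium castaneum": "GCTATTAGGTTCATACCC",
        "Apis mellifera ligustica": "GCTAACAGGTTCATACCC",
        "Bombyx mori": "GCTATTGGGCTCATACCC",
        "Drosophila simulans": "GCTACTGGGTTCATACCC",
    },
    "co2_r": {
        "Crioceris duodecimpunctata": "CAAATTTCTGAACATTG",
        "Pyrocoelia rufa": "CGAATTTCTGAACATTG",
        "Tribolium castaneum": "CAAATTTCTGAACATTG",
        "Apis mellifera ligustica": "CAAATTTCTGAACATTG",
        "Bombyx mori": "CAAATTTCTGAACATTG",
        "Drosophila simulans": "CAAATTTCTGAACATTG",
    },
}

#: Where the fetched FASTA is stored inside a repository checkout.
DEFAULT_DATA_PATH = Path(__file__).resolve().parents[2] / "data" / "pchalcographus_coi_haplotypes.fasta"


class DatasetUnavailableError(FileNotFoundError):
    """The reference dataset has not been fetched and no path was given."""


def fetch_coi_haplotypes(
    out_path: str | Path = DEFAULT_DATA_PATH, email: str = "user@example.org"
) -> Path:
    """Download the 58 haplotype sequences from GenBank (needs network).

    Writes an unwrapped FASTA to ``out_path`` and returns the path.
    """
    from Bio import Entrez, SeqIO

    Entrez.email = email
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    with Entrez.efetch(
        db="nucleotide",
        id=",".join(COI_ACCESSIONS),
        rettype="fasta",
        retmode="text",
    ) as handle:
        records = list(SeqIO.parse(handle, "fasta"))
    if len(records) != len(COI_ACCESSIONS):
        raise RuntimeError(
            f"expected {len(COI_ACCESSIONS)} records, got {len(records)}"
        )
    with open(out_path, "w") as out:
        for rec in records:
            out.write(f">{rec.id}\n{str(rec.seq).upper()}\n")
    return out_path


def load_coi_haplotypes(path: str | Path | None = None) -> CodonAwareAlignment:
    """Load the reference haplotype alignment from disk.

    The haplotypes are equal-length, so the FASTA is itself a trivial
    alignment.  Raises :class:`DatasetUnavailableError` with fetch
    instructions when the file is absent.
    """
    path = Path(path) if path is not None else DEFAULT_DATA_PATH
    if not path.exists():
        raise DatasetUnavailableError(
            f"reference COI haplotype dataset not found at {path}; run "
            "scripts/fetch_coi_haplotypes.py (requires network access to "
            "GenBank) or pass the path to a local copy"
        )
    return read_aligned_fasta(path, source=f"P. chalcographus COI haplotypes ({path})")
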