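#!/usr/bin/env python
"""Fetch the 58 reference COI haplotypes (GenBank DQ515997-DQ516054).

Requires network access to NCBI.  Writes the FASTA to
data/pchalcographus_coi_haplotypes.fasta by default, where the test
suite and acceptance script pick it up automatically.

Usage:
    python scripts/fetch_coi_haplotypes.py [--out PATH] [--email YOU@host]
"""

import argparse

from numtsieve.datasets import DEFAULT_DATA_PATH, fetch_coi_haplotypes


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", default=DEFAULT_DATA_PATH)
    parser.add_argument("--email", default="user@example.org",
                        help="Contact address passed to NCBI Entrez.")
    args = parser.parse_args()
    path = fetch_coi_haplotypes(args.out, email=args.email)
    print(f"wrote {path}")


if __name__ == "__main__":
    main()
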