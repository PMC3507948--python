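#!/usr/bin/env python
"""Fetch the deposited RPE65 sequences needed for the integration checks.

The library itself never touches the network; this helper downloads the two
protein sequences used by the accession-dependent tests and writes them to
``data/accessions/``:

* lamprey RPE65 — the protein translation of GenBank nucleotide record
  JX115001 (537 residues);
* human RPE65 — RefSeq protein NP_000320.

Usage (requires network access)::

    python scripts/fetch_accessions.py
"""

from __future__ import annotations

import sys
import urllib.parse
import urllib.request
from pathlib import Path

EUTILS = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
OUTDIR = Path(__file__).resolve().parent.parent / "data" / "accessions"

TARGETS = [
    # (filename, db, accession, rettype)
    ("lamprey_rpe65_JX115001.fasta", "nuccore", "JX115001", "fasta_cds_aa"),
    ("human_rpe65_NP_000320.fasta", "protein", "NP_000320", "fasta"),
]


def fetch(db: str, accession: str, rettype: str) -> str:
    query = urllib.parse.urlencode(
        {"db": db, "id": accession, "rettype": rettype, "retmode": "text"}
    )
    with urllib.request.urlopen(f"{EUTILS}?{query}", timeout=60) as response:
        return response.read().decode()


def main() -> int:
    OUTDIR.mkdir(parents=True, exist_ok=True)
    for filename, db, accession, rettype in TARGETS:
        dest = OUTDIR / filename
        if dest.exists():
            print(f"{dest} already present, skipping")
            continue
        text = fetch(db, accession, rettype)
        if not text.startswith(">"):
            print(f"unexpected response for {accession}", file=sys.stderr)
            return 1
        # normalize the header to the bare accession
        lines = text.strip().splitlines()
        lines[0] = f">{accession}"
        dest.write_text("\n".join(lines) + "\n")
        print(f"wrote {dest}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
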