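#!/usr/bin/env python
"""Fetch the deposited GenBank mitogenomes and build the aligned inputs for
the accession-based checks (network required; nothing in the test suite
depends on this script having run).

    python scripts/fetch_accessions.py --email you@example.org

Writes, under data/accessions/:
  raw/<accession>.fasta          one FASTA per record
  lutreola_six.aln.fasta         MAFFT alignment of the six conspecific genomes
  mustela_outgroup.aln.fasta     MAFFT alignment of all genomes + outgroup

MAFFT must be on PATH.
"""

from __future__ import annotations

import argparse
import subprocess
import time
from pathlib import Path

from Bio import Entrez, SeqIO

CONSPECIFIC = ["MW148603", "MW197423", "MW197424", "MW197425", "MW197426", "MT304869"]
COMPARATORS = [
    "HM106318", "NC_028013", "NC_024942", "MN206976", "NC_034330", "NC_021751",
    "MF459691", "MW257230", "HM106320", "HM106321", "NC_020641", "NC_011358",
    "NC_009685", "NC_020643", "NC_011125",
]
OUTGROUP = ["AJ303116"]


def fetch(accession: str, raw_dir: Path) -> Path:
    path = raw_dir / f"{accession}.fasta"
    if path.exists():
        return path
    with Entrez.efetch(
        db="nuccore", id=accession, rettype="fasta", retmode="text"
    ) as handle:
        record = SeqIO.read(handle, "fasta")
    record.id = accession
    record.description = ""
    SeqIO.write(record, path, "fasta")
    time.sleep(0.4)  # NCBI rate limit
    return path


def align(inputs: list[Path], out: Path) -> None:
    cat = out.with_suffix(".cat.fasta")
    with open(cat, "w") as fh:
        for p in inputs:
            fh.write(p.read_text())
    with open(out, "w") as fh:
        subprocess.run(
            ["mafft", "--auto", "--thread", "1", str(cat)],
            stdout=fh, check=True,
        )
    cat.unlink()
    print(f"wrote {out}")


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--email", required=True, help="identity for NCBI E-utilities")
    ap.add_argument(
        "--out-dir", type=Path,
        default=Path(__file__).resolve().parent.parent / "data" / "accessions",
    )
    args = ap.parse_args()
    Entrez.email = args.email

    raw = args.out_dir / "raw"
    raw.mkdir(parents=True, exist_ok=True)
    six = [fetch(a, raw) for a in CONSPECIFIC]
    rest = [fetch(a, raw) for a in COMPARATORS + OUTGROUP]
    align(six, args.out_dir / "lutreola_six.aln.fasta")
    align(six + rest, args.out_dir / "mustela_outgroup.aln.fasta")


if __name__ == "__main__":
    main()
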