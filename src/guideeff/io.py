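"""Readers/writers shared by the pipeline: FASTA/FASTQ in, TSV/JSON out."""

from __future__ import annotations

import json
import sys
from pathlib import Path

import pandas as pd
from Bio import SeqIO


def read_fasta(path) -> list[tuple[str, str]]:
    """(id, sequence) pairs; sequences upper-cased."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def read_reads(path) -> list[str]:
    """Merged read sequences from FASTA or FASTQ (qualities ignored)."""
    p = Path(path)
    fmt = "fastq" if p.suffix.lower() in {".fastq", ".fq"} else "fasta"
    return [str(rec.seq).upper() for rec in SeqIO.parse(str(p), fmt)]


def write_fasta(records, path):
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n{seq}\n")


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path):
    df.to_csv(path, sep="\t", index=False)


def write_manifest(path, config: dict):
    """Record run configuration, seed and package version alongside outputs."""
    from . import __version__

    payload = {"package": "guideeff", "version": __version__,
               "python": sys.version.split()[0], **config}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
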