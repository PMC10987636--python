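"""Readers and writers for the plain-text formats used across the pipeline.

All tabular files are TSV. Files written by scartrace carry a small
reproducibility header of ``# key=value`` comment lines which the readers
skip transparently.
"""

from __future__ import annotations

import os
from typing import Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def write_tsv(df: pd.DataFrame, path: str | os.PathLike, header: Mapping | None = None) -> None:
    """Write a DataFrame as TSV, optionally preceded by ``# key=value`` comment lines."""
    with open(path, "w") as fh:
        if header:
            from . import __version__

            fh.write(f"# scartrace={__version__}\n")
            for key, value in header.items():
                fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | os.PathLike, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a FASTA file into an ``{name: sequence}`` dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_cutsites_bed(path: str | os.PathLike) -> dict[str, int]:
    """Read cut sites from a BED file (0-based, half-open, one length-1 interval per target)."""
    sites: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            target, start, end = fields[0], int(fields[1]), int(fields[2])
            if end != start + 1:
                raise ValueError(
                    f"cut-site interval for {target!r} must have length 1, got [{start}, {end})"
                )
            sites[target] = start
    return sites


def write_cutsites_bed(sites: Mapping[str, int], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for target, cut in sites.items():
            fh.write(f"{target}\t{cut}\t{cut + 1}\t{target}_cut\n")


def read_barcodes(path: str | os.PathLike) -> set[str]:
    """Read a plain-text list of valid cell barcodes, one per line."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def write_barcodes(barcodes, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for bc in barcodes:
            fh.write(f"{bc}\n")
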