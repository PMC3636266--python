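"""Readers and writers for the plain-text formats used throughout the package.

Everything is 0-based half-open (BED convention). FASTA/FASTQ writing is
deliberately minimal and deterministic (fixed line width, fixed quality
string); reading genome FASTA goes through :mod:`pyfaidx`.
"""
from __future__ import annotations

import os
from typing import Iterable, Iterator

import pandas as pd
from pyfaidx import Fasta

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def write_fasta(path: str | os.PathLike, records: Iterable[tuple[str, str]],
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Load a whole FASTA file into a {name: sequence} dict (uppercased)."""
    fa = Fasta(str(path), rebuild=True)
    out = {name: str(fa[name][:]).upper() for name in fa.keys()}
    fa.close()
    return out


def write_fastq(path: str | os.PathLike, reads: Iterable[tuple[str, str]],
                quality_char: str = "I") -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{quality_char * len(seq)}\n")


def read_fastq(path: str | os.PathLike) -> Iterator[tuple[str, str]]:
    """Yield (read id, sequence) from an uncompressed FASTQ file."""
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().strip()
            fh.readline()  # '+'
            fh.readline()  # qualities
            yield header.strip().lstrip("@"), seq


def write_bed6(path: str | os.PathLike, df: pd.DataFrame) -> None:
    df.loc[:, BED6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df.columns = BED6_COLUMNS[: df.shape[1]]
    return df


def write_tsv(path: str | os.PathLike, df: pd.DataFrame,
              float_format: str = "%.6g") -> None:
    df.to_csv(path, sep="\t", index=False, float_format=float_format)


def read_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_bedgraph(path: str | os.PathLike, track) -> None:
    """Write a SignalTrack as 4-column bedGraph; NaN windows are skipped."""
    import numpy as np

    w = track.window
    with open(path, "w") as fh:
        for chrom in sorted(track.data):
            values = track.data[chrom]
            length = track.chrom_sizes[chrom]
            for i, v in enumerate(values):
                if np.isnan(v):
                    continue
                start = i * w
                end = min(start + w, length)
                fh.write(f"{chrom}\t{start}\t{end}\t{v:.6g}\n")
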