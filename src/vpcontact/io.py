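"""Plain-text genomics I/O helpers: FASTA, FASTQ, BED, bedGraph.

All coordinates are 0-based, half-open (BED convention). FASTA input may be
gzip-compressed (detected from the ``.gz`` suffix).
"""
from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path) -> dict[str, str]:
    """Read a (optionally gzipped) FASTA file into ``{name: sequence}``.

    Sequences are upper-cased; record order is preserved.
    """
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(genome: Mapping[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path) -> Iterator[tuple[str, str, str]]:
    """Yield ``(read_id, sequence, quality)`` from a 4-line FASTQ file."""
    with _open_text(path) as fh:
        yield from FastqGeneralIterator(fh)


def write_fastq(reads: Iterable[tuple[str, str, str]], path) -> None:
    with open(path, "w") as fh:
        for name, seq, qual in reads:
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


def write_fastq_pairs(pairs, path1, path2) -> None:
    """Write paired reads ``(id, seq1, qual1, seq2, qual2)`` to two FASTQ files."""
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for name, s1, q1, s2, q2 in pairs:
            f1.write(f"@{name}/1\n{s1}\n+\n{q1}\n")
            f2.write(f"@{name}/2\n{s2}\n+\n{q2}\n")


def read_fastq_pairs(path1, path2) -> Iterator[tuple[str, str, str, str, str]]:
    for (n1, s1, q1), (n2, s2, q2) in zip(read_fastq(path1), read_fastq(path2)):
        name = n1.split("/")[0].split()[0]
        yield (name, s1, q1, s2, q2)


class BedParseError(ValueError):
    """A malformed BED line; the message names the offending line number."""


def read_bed(path, min_fields: int = 3) -> pd.DataFrame:
    """Parse a BED file into a DataFrame with chrom/start/end (+ name, strand).

    Header lines starting with ``#``, ``track`` or ``browser`` are skipped.
    Raises :class:`BedParseError` naming the line on malformed input.
    """
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < min_fields:
                raise BedParseError(
                    f"{path}: line {lineno}: expected >= {min_fields} fields, got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except (IndexError, ValueError) as exc:
                raise BedParseError(f"{path}: line {lineno}: {exc}") from exc
            if start < 0 or end < start:
                raise BedParseError(
                    f"{path}: line {lineno}: invalid interval [{start}, {end})"
                )
            rows.append(
                {
                    "chrom": fields[0],
                    "start": start,
                    "end": end,
                    "name": fields[3] if len(fields) > 3 else f"feature_{lineno}",
                    "strand": fields[5] if len(fields) > 5 else "+",
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "strand"])


def write_bed(intervals, path, header: list[str] | None = None) -> None:
    """Write intervals (iterables of chrom, start, end[, extra fields]) as BED."""
    with open(path, "w") as fh:
        for line in header or []:
            fh.write(line.rstrip("\n") + "\n")
        for iv in intervals:
            fh.write("\t".join(str(x) for x in iv) + "\n")


def write_bedgraph(intervals, path, name: str = "track") -> None:
    """Write a 4-column UCSC bedGraph: chrom, start, end, value."""
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{name}"\n')
        for chrom, start, end, value in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{value}\n")
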