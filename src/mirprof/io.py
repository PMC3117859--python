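"""File-format boundaries: FASTQ/FASTA via Biopython, GFF3 and TSV tables.

All coordinates are 0-based half-open in memory and 1-based inclusive in
GFF3 files.
"""
from __future__ import annotations

import os
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._util import Interval


def write_fastq(reads: Iterable[tuple[str, str]], path: str | os.PathLike, prefix: str = "read") -> int:
    """Write (sequence, quality-string) pairs as Sanger FASTQ; returns read count."""
    n = 0
    with open(path, "w") as fh:
        for i, (seq, qual) in enumerate(reads):
            fh.write(f"@{prefix}{i}\n{seq}\n+\n{qual}\n")
            n = i + 1
    return n


def read_fastq(path: str | os.PathLike) -> list[tuple[str, str]]:
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        out.append((str(rec.seq), qual))
    return out


def write_fasta(records: Iterable[tuple[str, str]], path: str | os.PathLike) -> None:
    """Write (name, sequence) pairs as FASTA."""
    seqs = [SeqRecord(Seq(s), id=name, description="") for name, s in records]
    SeqIO.write(seqs, str(path), "fasta")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_tags_fasta(tags: pd.DataFrame, path: str | os.PathLike) -> None:
    """Collapsed tags as FASTA with ``>tagN_xCOUNT`` headers (COUNT = total over libraries)."""
    totals = tags.sum(axis=1)
    write_fasta(
        ((f"tag{i}_x{int(totals.iloc[i])}", seq) for i, seq in enumerate(tags.index)),
        path,
    )


def write_gff3(intervals: Sequence[Interval], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for iv in intervals:
            attrs = f"category={iv.category}"
            if iv.name:
                attrs += f";Name={iv.name}"
            src = iv.source or "mirprof"
            fh.write(
                f"{iv.chrom}\t{src}\t{iv.category or 'region'}\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t{attrs}\n"
            )


def read_gff3(path: str | os.PathLike) -> list[Interval]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, source, ftype, start, end, _score, strand, _frame, attrs = line.rstrip("\n").split("\t")
            fields = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            out.append(
                Interval(
                    chrom=chrom,
                    start=int(start) - 1,
                    end=int(end),
                    strand=strand,
                    category=fields.get("category", ftype),
                    source=source,
                    name=fields.get("Name", ""),
                )
            )
    return out


def write_table(df: pd.DataFrame, path: str | os.PathLike, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_table(path: str | os.PathLike, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)
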