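"""Genome mapping, known-miRNA quantification and hierarchical category calls.

Mapping is exact-match on both strands (the simulator emits error-free
reads; a mismatch-tolerant mode for the precursor matcher sits behind a
flag).  Each mapped tag receives exactly one category by the priority

    rRNA/tRNA/scRNA/snRNA/snoRNA (Genbank > Rfam) > known miRNA
        > repeat > exon > intron > unann

applied over *all* genomic hits of the tag: a multi-mapping tag is called
miRNA if any hit overlaps an annotated precursor, unless a hit also
overlaps a higher-tier ncRNA.  Overlap means >=1 shared base and is
strand-aware for the ncRNA/miRNA tiers, strandless for repeat/exon/intron.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from ._util import Interval, revcomp
from .simulate import NCRNA_TYPES, Precursor


@dataclass(frozen=True)
class TagAlignment:
    """An exact occurrence of a tag on the genome (0-based half-open)."""

    tag: str
    chrom: str
    start: int
    strand: str

    @property
    def end(self) -> int:
        return self.start + len(self.tag)


_SOURCE_RANK = {"genbank": 0, "rfam": 1}
_NCRNA_RANK = {t: i for i, t in enumerate(NCRNA_TYPES)}


def map_tags(
    tags, genome: dict[str, str], max_hits: int = 20
) -> tuple[dict[str, list[TagAlignment]], set[str]]:
    """All exact occurrences of each tag on both strands, up to max_hits per tag.

    Implemented as a single sliding-window membership scan of the genome per
    tag length (cost independent of the number of tags).  Returns
    ``(hits, unmapped)``.
    """
    tag_list = list(tags)
    by_len: dict[int, dict[int, str]] = {}
    trans = str.maketrans("ACGT", "\x00\x01\x02\x03")

    def encode(s: str) -> int:
        v = 0
        for b in s.translate(trans):
            v = (v << 2) | ord(b)
        return v

    for t in tag_list:
        if set(t) - set("ACGT"):
            continue  # ambiguous bases can never exact-match an ACGT genome
        by_len.setdefault(len(t), {})[encode(t)] = t
    hits: dict[str, list[TagAlignment]] = {}

    def record(tag: str, chrom: str, start: int, strand: str) -> None:
        lst = hits.setdefault(tag, [])
        if len(lst) < max_hits:
            lst.append(TagAlignment(tag, chrom, start, strand))

    for chrom, seq in genome.items():
        n = len(seq)
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            codes = np.frombuffer(s.translate(trans).encode("latin1"), dtype=np.uint8).astype(np.int64)
            for L, code_map in by_len.items():
                if n < L:
                    continue
                # exact 2-bit window encoding, rolled vectorized over the genome
                win = np.zeros(n - L + 1, dtype=np.int64)
                for k in range(L):
                    win = (win << 2) | codes[k:k + n - L + 1]
                keys = np.fromiter(code_map.keys(), dtype=np.int64, count=len(code_map))
                for i in np.nonzero(np.isin(win, keys))[0]:
                    tag = code_map[int(win[i])]
                    start = int(i) if strand == "+" else n - int(i) - L
                    record(tag, chrom, start, strand)
    unmapped = set(tag_list) - set(hits)
    return hits, unmapped


def _match_positions(tag: str, seq: str, max_mismatch: int = 0, around: int | None = None,
                     window: int = 4) -> list[int]:
    """Start positions of tag in seq; with mismatches only near ``around``."""
    out = []
    p = seq.find(tag)
    while p != -1:
        out.append(p)
        p = seq.find(tag, p + 1)
    if max_mismatch > 0 and around is not None:
        for p in range(max(0, around - window), min(len(seq) - len(tag), around + window) + 1):
            if p in out:
                continue
            mm = sum(a != b for a, b in zip(tag, seq[p:p + len(tag)]))
            if mm <= max_mismatch:
                out.append(p)
    return sorted(out)


def quantify_known(
    tags: pd.DataFrame,
    precursors: list[Precursor],
    max_shift: int = 4,
    allow_mismatch: bool = False,
) -> pd.DataFrame:
    """Per-mature-miRNA counts: tags matching a precursor within +-max_shift
    of an annotated mature arm credit that arm's miRNA in their library.

    A tag matching k precursors credits each (the multi-match rule); a tag
    sitting on the loop only (shift > max_shift from both arms) is not
    counted.  Precursor expression is the sum over its mature products.
    """
    mature_names = [p.mature_name(arm) for p in precursors for arm in ("5p", "3p")]
    expr = pd.DataFrame(0, index=mature_names, columns=tags.columns, dtype=int)
    arm_start = {
        p.name: {"5p": 0, "3p": len(p.hairpin) - len(p.mature_seq["3p"])}
        for p in precursors
    }
    # cheap prefilter: exact-matching tags must occur in some hairpin
    combined = "#".join(p.hairpin for p in precursors)
    counts_arr = tags.to_numpy()
    for row, tag in enumerate(tags.index):
        if not allow_mismatch and tag not in combined:
            continue
        counts = counts_arr[row]
        for p in precursors:
            if len(tag) > len(p.hairpin):
                continue
            for arm in ("5p", "3p"):
                a0 = arm_start[p.name][arm]
                positions = _match_positions(
                    tag, p.hairpin,
                    max_mismatch=1 if allow_mismatch else 0,
                    around=a0 if allow_mismatch else None,
                )
                if any(abs(pos - a0) <= max_shift for pos in positions):
                    expr.loc[p.mature_name(arm)] += counts
    return expr


def assign_categories(
    hits: dict[str, list[TagAlignment]],
    tags: pd.DataFrame,
    tracks: list[Interval],
    mirna_track: list[Interval],
) -> tuple[dict[str, tuple[str, str]], pd.DataFrame]:
    """Resolve one (category, source) per mapped tag and tabulate per library.

    Returns ``(calls, summary)``; summary rows are categories (ncRNA types,
    known_miRNA, repeat, exon, intron, unann), columns libraries, values
    read-weighted counts.
    """
    trees: dict[str, IntervalTree] = {}
    for iv in list(tracks) + list(mirna_track):
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
    # cheap prefilter: sorted starts + running max of ends per chromosome,
    # so the (many) intergenic tags never touch the interval tree
    prefilter: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, tree in trees.items():
        ivs = sorted((n.begin, n.end) for n in tree)
        starts = np.array([s for s, _ in ivs], dtype=np.int64)
        maxend = np.maximum.accumulate(np.array([e for _, e in ivs], dtype=np.int64))
        prefilter[chrom] = (starts, maxend)

    known = set(NCRNA_TYPES) | {"known_miRNA", "repeat", "exon", "intron"}
    calls: dict[str, tuple[str, str]] = {}
    for tag, alns in hits.items():
        best = None  # (tier, source_rank, type_rank, category, source)
        for a in alns:
            tree = trees.get(a.chrom)
            if tree is None:
                continue
            starts, maxend = prefilter[a.chrom]
            i0 = np.searchsorted(starts, a.end)
            if i0 == 0 or maxend[i0 - 1] <= a.start:
                continue
            for node in tree.overlap(a.start, a.end):
                iv: Interval = node.data
                if iv.category not in known:
                    raise ValueError(f"unknown annotation category {iv.category!r}")
                if iv.category in NCRNA_TYPES:
                    if iv.strand != a.strand:
                        continue
                    key = (0, _SOURCE_RANK.get(iv.source, 2), _NCRNA_RANK[iv.category],
                           iv.category, iv.source)
                elif iv.category == "known_miRNA":
                    if iv.strand != a.strand:
                        continue
                    key = (1, 0, 0, "known_miRNA", iv.source)
                else:
                    tier = {"repeat": 2, "exon": 3, "intron": 4}[iv.category]
                    key = (tier, 0, 0, iv.category, "n/a")
                if best is None or key < best:
                    best = key
        calls[tag] = (best[3], best[4]) if best else ("unann", "n/a")

    categories = list(NCRNA_TYPES) + ["known_miRNA", "repeat", "exon", "intron", "unann"]
    cat_row = {c: i for i, c in enumerate(categories)}
    tag_names = list(calls)
    rows = tags.index.get_indexer(tag_names)
    acc = np.zeros((len(categories), tags.shape[1]), dtype=np.int64)
    np.add.at(acc, [cat_row[calls[t][0]] for t in tag_names], tags.to_numpy()[rows])
    summary = pd.DataFrame(acc, index=categories, columns=tags.columns)
    return calls, summary


def category_fractions(summary: pd.DataFrame) -> pd.DataFrame:
    return summary / summary.sum(axis=0)


def mapped_totals(tags: pd.DataFrame, hits: dict[str, list[TagAlignment]]) -> pd.Series:
    """Per-library totals of reads whose tag mapped to the genome."""
    mapped = tags.index.isin(hits.keys())
    return tags.loc[mapped].sum(axis=0)


def length_histogram(tags: pd.DataFrame) -> pd.Series:
    """Clean-read length distribution, weighted by tag counts over all libraries."""
    if len(tags) == 0:
        return pd.Series(dtype=int)
    lengths = tags.index.str.len()
    totals = tags.sum(axis=1)
    return totals.groupby(lengths).sum().astype(int).rename("reads")


@dataclass
class AnnotationResult:
    hits: dict[str, list[TagAlignment]]
    unmapped: set[str]
    calls: dict[str, tuple[str, str]]
    summary: pd.DataFrame
    expression: pd.DataFrame
    mapped_totals: pd.Series
    lengths: pd.Series = field(default=None)


def annotate_pipeline(
    tags: pd.DataFrame,
    genome: dict[str, str],
    tracks: list[Interval],
    precursors: list[Precursor],
    mirna_track: list[Interval],
    max_hits: int = 20,
    allow_mismatch: bool = False,
) -> AnnotationResult:
    """Map, quantify and categorize a collapsed-tag table in one pass."""
    hits, unmapped = map_tags(tags.index, genome, max_hits=max_hits)
    calls, summary = assign_categories(hits, tags, tracks, mirna_track)
    expression = quantify_known(tags, precursors, allow_mismatch=allow_mismatch)
    return AnnotationResult(
        hits=hits,
        unmapped=unmapped,
        calls=calls,
        summary=summary,
        expression=expression,
        mapped_totals=mapped_totals(tags, hits),
        lengths=length_histogram(tags),
    )
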