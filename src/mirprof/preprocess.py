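"""Raw multiplexed reads -> clean collapsed tags (18-30 nt) with per-library counts.

Stages mirror a standard small-RNA-seq filtering pipeline: demultiplex on
the exact 6 bp index, trim the 3' adapter by exact-prefix match, drop
inadequate (<18 nt), over-long (>30 nt), ambiguous and contaminant inserts,
then collapse identical inserts into counted tags.  The bookkeeping
invariant ``raw = clean + sum(discards)`` holds exactly per library.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .simulate import ConfigurationError


@dataclass
class LibraryStats:
    library_id: str
    raw_reads: int = 0
    clean_reads: int = 0
    mapped_reads: int = 0
    discards: Counter = field(default_factory=Counter)

    def check(self) -> None:
        assert self.raw_reads == self.clean_reads + sum(self.discards.values())
        assert self.mapped_reads <= self.clean_reads <= self.raw_reads


def _seq_of(read) -> str:
    return read[0] if isinstance(read, (tuple, list)) else read


def demultiplex(
    reads: Iterable, index_map: dict[str, str]
) -> tuple[dict[str, list[str]], int]:
    """Assign each read to the library whose 6 bp index matches its first bases.

    The index is removed from assigned reads; returns ``(by_library,
    n_unassigned)``.  Raises on duplicate indices or unequal index lengths.
    """
    if len(set(index_map.values())) != len(index_map):
        raise ConfigurationError("two indices map to the same library")
    lengths = {len(ix) for ix in index_map}
    if len(lengths) != 1:
        raise ConfigurationError("all multiplex indices must have equal length")
    (ix_len,) = lengths
    by_lib: dict[str, list[str]] = {lib: [] for lib in index_map.values()}
    unassigned = 0
    for read in reads:
        seq = _seq_of(read)
        lib = index_map.get(seq[:ix_len])
        if lib is None:
            unassigned += 1
        else:
            by_lib[lib].append(seq[ix_len:])
    return by_lib, unassigned


def trim_adapter3(seq: str, adapter3: str, min_overlap: int = 6) -> str | None:
    """Insert before the leftmost match of >=min_overlap leading adapter bases.

    The match must extend to the end of the read (read = insert + adapter
    prefix); returns None when no adapter is found.
    """
    if len(adapter3) < min_overlap:
        raise ConfigurationError("adapter shorter than min_overlap")
    anchor = adapter3[:min_overlap]
    p = seq.find(anchor)
    while p != -1:
        k = min(len(adapter3), len(seq) - p)
        if seq[p:p + k] == adapter3[:k]:
            return seq[:p]
        p = seq.find(anchor, p + 1)
    return None


def filter_clean(
    inserts: Iterable[str],
    min_len: int = 18,
    max_len: int = 30,
    max_ambiguous: int = 0,
    blocklist: Sequence[str] = (),
) -> tuple[list[str], Counter]:
    """Keep 18-30 nt inserts with <= max_ambiguous non-ACGT bases.

    Returns ``(kept, discard_reasons)`` with reasons in
    {short, long, ambiguous, contaminant}.
    """
    block = set(blocklist)
    kept: list[str] = []
    reasons: Counter = Counter()
    for ins in inserts:
        if len(ins) < min_len:
            reasons["short"] += 1
        elif len(ins) > max_len:
            reasons["long"] += 1
        elif sum(b not in "ACGT" for b in ins) > max_ambiguous:
            reasons["ambiguous"] += 1
        elif ins in block:
            reasons["contaminant"] += 1
        else:
            kept.append(ins)
    return kept, reasons


def collapse_tags(clean_by_library: dict[str, list[str]]) -> pd.DataFrame:
    """One row per distinct insert, one integer count column per library."""
    counters = {lib: Counter(seqs) for lib, seqs in clean_by_library.items()}
    df = pd.DataFrame(counters).fillna(0).astype(int)
    df.index.name = "tag"
    df = df[sorted(df.columns)]
    return df.sort_index()


def preprocess_reads(
    reads: Iterable,
    index_map: dict[str, str],
    adapter3: str,
    min_overlap: int = 6,
    min_len: int = 18,
    max_len: int = 30,
    max_ambiguous: int = 0,
    blocklist: Sequence[str] = (),
) -> tuple[pd.DataFrame, dict[str, LibraryStats], int]:
    """Full preprocessing: demultiplex, trim, filter, collapse.

    Returns ``(tags, stats, n_unassigned)`` where tags is a tag x library
    count DataFrame.
    """
    by_lib, unassigned = demultiplex(reads, index_map)
    stats: dict[str, LibraryStats] = {}
    clean_by_lib: dict[str, list[str]] = {}
    for lib, raw in by_lib.items():
        st = LibraryStats(library_id=lib, raw_reads=len(raw))
        inserts = []
        for seq in raw:
            ins = trim_adapter3(seq, adapter3, min_overlap)
            if ins is None:
                st.discards["no_adapter"] += 1
            else:
                inserts.append(ins)
        kept, reasons = filter_clean(inserts, min_len, max_len, max_ambiguous, blocklist)
        st.discards.update(reasons)
        st.clean_reads = len(kept)
        st.check()
        stats[lib] = st
        clean_by_lib[lib] = kept
    return collapse_tags(clean_by_lib), stats, unassigned
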