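"""Novel miRNA discovery from unannotated mapped tags (hairpin criteria).

The discovery chain mirrors hairpin-based predictors: cluster unannotated
tags into loci, extract flanking windows under both arm hypotheses, fold
with a stacking-aware base-pair-maximization dynamic program, trim to the
mature-tag-anchored stem, and accept candidates that form a single hairpin
with the mature tag on one arm, >=14 of its bases paired to the opposite
arm (including one contiguous helix of >= 7 pairs), a 3-20 nt terminal
loop and an energy estimate <= -18 kcal/mol.  Called novel miRNAs
additionally need >= 30 supporting reads in every library, and -5p/-3p
products of one hairpin are grouped under one precursor.

The energy estimate is a linear proxy (-0.9 kcal/mol per score unit) of the
pairing score (GC=3, AU=2, GU=1, +1 per stacked pair), not a thermodynamic
nearest-neighbor energy; a conforming external folding backend can be
substituted wherever a ``fold_fn`` argument is accepted.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

from ._util import Interval, revcomp
from .annotate import TagAlignment

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}
_PAIR = np.zeros((4, 4), dtype=np.int32)
_PAIR[0, 3] = _PAIR[3, 0] = 2  # A:U
_PAIR[1, 2] = _PAIR[2, 1] = 3  # C:G
_PAIR[2, 3] = _PAIR[3, 2] = 1  # G:U wobble
MIN_LOOP = 3
ENERGY_PER_SCORE = -0.9  # kcal/mol proxy per score unit


@njit(cache=True)
def _fold_tables(codes, pair):  # pragma: no cover - exercised via fold()
    n = codes.shape[0]
    W = np.zeros((n, n), dtype=np.int32)
    P = np.full((n, n), -1, dtype=np.int32)
    for span in range(MIN_LOOP + 1, n):
        for i in range(n - span):
            j = i + span
            s = pair[codes[i], codes[j]]
            if s > 0:
                inner = W[i + 1, j - 1]
                if P[i + 1, j - 1] >= 0 and P[i + 1, j - 1] + 1 > inner:
                    inner = P[i + 1, j - 1] + 1  # stacking bonus
                P[i, j] = s + inner
            best = W[i + 1, j]
            if W[i, j - 1] > best:
                best = W[i, j - 1]
            if P[i, j] > best:
                best = P[i, j]
            for k in range(i + MIN_LOOP + 1, j - MIN_LOOP - 1):
                v = W[i, k] + W[k + 1, j]
                if v > best:
                    best = v
            W[i, j] = best
    return W, P


def _traceback(codes, W, P) -> str:
    n = len(codes)
    struct = ["."] * n
    stack = [(0, n - 1, "W")]
    while stack:
        i, j, mode = stack.pop()
        if j - i < MIN_LOOP + 1:
            continue
        if mode == "W":
            target = W[i, j]
            if target == 0:
                continue
            if W[i + 1, j] == target:
                stack.append((i + 1, j, "W"))
            elif W[i, j - 1] == target:
                stack.append((i, j - 1, "W"))
            elif P[i, j] == target:
                stack.append((i, j, "P"))
            else:
                for k in range(i + MIN_LOOP + 1, j - MIN_LOOP - 1):
                    if W[i, k] + W[k + 1, j] == target:
                        stack.append((i, k, "W"))
                        stack.append((k + 1, j, "W"))
                        break
        else:
            struct[i], struct[j] = "(", ")"
            s = int(_PAIR[codes[i], codes[j]])
            inner_target = P[i, j] - s
            if j - 1 - (i + 1) >= MIN_LOOP + 1:
                if P[i + 1, j - 1] >= 0 and P[i + 1, j - 1] + 1 == inner_target:
                    stack.append((i + 1, j - 1, "P"))
                else:
                    stack.append((i + 1, j - 1, "W"))
    return "".join(struct)


def fold(seq: str) -> tuple[str, float]:
    """Best nested structure by stacking-aware pair maximization.

    Pair scores GC=3, AU=2, GU=1 plus 1 per stacked pair, minimum loop 3;
    returns ``(dot_bracket, energy_estimate)`` with energy = -0.9 x score
    (kcal/mol proxy, <= 0).
    """
    s = seq.upper()
    try:
        codes = np.array([_CODE[b] for b in s], dtype=np.int8)
    except KeyError as e:
        raise ValueError(f"invalid base {e.args[0]!r} in sequence") from None
    if len(codes) < 2:
        return "." * len(codes), 0.0
    W, P = _fold_tables(codes, _PAIR)
    structure = _traceback(codes, W, P)
    return structure, ENERGY_PER_SCORE * float(W[0, len(codes) - 1])


def parse_structure(structure: str) -> list[int]:
    """Partner index per position (-1 if unpaired); validates balance."""
    partner = [-1] * len(structure)
    stack: list[int] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced structure")
            j = stack.pop()
            partner[i], partner[j] = j, i
        elif c != ".":
            raise ValueError(f"invalid structure character {c!r}")
    if stack:
        raise ValueError("unbalanced structure")
    return partner


def structure_score(seq: str, pairs: set[tuple[int, int]]) -> int:
    """Score of an explicit pair set under the fold() scoring (test oracle hook)."""
    s = seq.upper()
    total = 0
    for i, j in pairs:
        total += int(_PAIR[_CODE[s[i]], _CODE[s[j]]])
        if (i + 1, j - 1) in pairs:
            total += 1
    return total


# ---------------------------------------------------------------------------
# locus clustering and window extraction
# ---------------------------------------------------------------------------

@dataclass
class Locus:
    chrom: str
    strand: str
    start: int
    end: int
    tags: list[TagAlignment] = field(default_factory=list)
    support: pd.Series = None  # per-library summed tag counts
    top_tag: TagAlignment = None


def cluster_unannotated(
    hits: dict[str, list[TagAlignment]],
    calls: dict[str, tuple[str, str]],
    tags: pd.DataFrame,
    max_gap: int = 200,
) -> list[Locus]:
    """Merge same-strand unannotated tag alignments within max_gap into loci.

    Locus support is the per-library sum of member tag counts; the
    representative (mature-candidate) tag is the member with the highest
    total count.
    """
    points: dict[tuple[str, str], list[TagAlignment]] = {}
    for tag, alns in hits.items():
        if calls.get(tag, ("unann",))[0] != "unann":
            continue
        for a in alns:
            points.setdefault((a.chrom, a.strand), []).append(a)
    loci: list[Locus] = []
    for (chrom, strand), alns in sorted(points.items()):
        alns.sort(key=lambda a: (a.start, a.end))
        current: list[TagAlignment] = []
        cur_end = None
        for a in alns + [None]:
            if a is not None and current and a.start - cur_end <= max_gap:
                current.append(a)
                cur_end = max(cur_end, a.end)
            else:
                if current:
                    loci.append(_finish_locus(chrom, strand, current, tags))
                if a is not None:
                    current = [a]
                    cur_end = a.end
    return loci


def _finish_locus(chrom, strand, members, tags) -> Locus:
    support = tags.loc[[m.tag for m in members]].groupby(level=0).first().sum(axis=0)
    top = max(members, key=lambda m: (int(tags.loc[m.tag].sum()), m.tag))
    return Locus(
        chrom=chrom, strand=strand,
        start=min(m.start for m in members), end=max(m.end for m in members),
        tags=members, support=support, top_tag=top,
    )


@dataclass
class CandidateWindow:
    locus: Locus
    arm_hypothesis: str  # mature tag assumed on the 5p or 3p arm
    chrom: str
    start: int
    end: int
    strand: str
    sequence: str  # transcript orientation
    tag_offset: int  # tag start within sequence
    tag_length: int


def extract_windows(
    locus: Locus,
    genome: dict[str, str],
    flank_up: int = 20,
    flank_down: int = 160,
) -> list[CandidateWindow]:
    """Two candidate windows per locus: mature tag as the 5p arm (short
    upstream / long downstream flank) and as the 3p arm (mirrored).

    Windows are clipped at chromosome edges and returned strand-oriented.
    """
    s, e = locus.top_tag.start, locus.top_tag.end
    n = len(genome[locus.chrom])
    windows = []
    for arm in ("5p", "3p"):
        if (arm == "5p") == (locus.strand == "+"):
            g0, g1 = s - flank_up, e + flank_down
        else:
            g0, g1 = s - flank_down, e + flank_up
        g0, g1 = max(0, g0), min(n, g1)
        seq = genome[locus.chrom][g0:g1]
        if locus.strand == "+":
            off = s - g0
        else:
            seq = revcomp(seq)
            off = g1 - e
        windows.append(
            CandidateWindow(
                locus=locus, arm_hypothesis=arm, chrom=locus.chrom,
                start=g0, end=g1, strand=locus.strand,
                sequence=seq, tag_offset=off, tag_length=e - s,
            )
        )
    return windows


# ---------------------------------------------------------------------------
# candidate evaluation
# ---------------------------------------------------------------------------

_LOOP_RE = re.compile(r"\((\.*)\)")


@dataclass
class Evaluation:
    passed: bool
    reasons: list[str]
    trimmed_span: tuple[int, int]  # within the window sequence
    structure: str  # pruned topology of the trimmed precursor
    energy: float
    n_tag_paired: int
    loop_length: int | None
    mature_arm: str | None  # side of the terminal loop carrying the tag
    dicer_offset: int | None  # deviation from a blunt mature/star duplex; ~2 expected


def _helices(pairs: set[tuple[int, int]]) -> list[list[tuple[int, int]]]:
    """Group pairs into maximal stacked runs (helices)."""
    out: list[list[tuple[int, int]]] = []
    used: set[tuple[int, int]] = set()
    for p in sorted(pairs):
        if p in used:
            continue
        run = [p]
        used.add(p)
        i, j = p
        while (i + 1, j - 1) in pairs:
            i, j = i + 1, j - 1
            run.append((i, j))
            used.add((i, j))
        out.append(run)
    return out


def _partner_group(partner: list[int], off: int, length: int, max_gap: int) -> list[int]:
    """Largest gap-free group of the tag's pairing partners (the putative star arm).

    Partners inside the tag itself are ignored: the star arm is a distinct
    sequence, so a mature candidate folding back onto itself is not a duplex.
    """
    ps = sorted(p for x in range(off, off + length)
                if 0 <= x < len(partner) and (p := partner[x]) >= 0
                and not off <= p < off + length)
    if not ps:
        return []
    groups: list[list[int]] = [[ps[0]]]
    for p in ps[1:]:
        if p - groups[-1][-1] <= max_gap:
            groups[-1].append(p)
        else:
            groups.append([p])
    return max(groups, key=len)


def evaluate_candidate(
    window_seq: str,
    structure: str,
    energy: float,
    tag_offset: int,
    tag_length: int,
    energy_max: float = -18.0,
    min_paired: int = 14,
    loop_min: int = 3,
    loop_max: int = 20,
    min_helix_run: int = 7,
    prune_helix: int = 3,
    partner_gap: int = 12,
    arm_hypothesis: str | None = None,
    fold_fn=fold,
) -> Evaluation:
    """Apply the hairpin criteria to a folded window around a mature tag.

    The putative precursor is the span of the tag plus the largest coherent
    group of its pairing partners.  If that group is not compact at the
    window scale (base-pair maximization over a wide window routinely pairs
    a few tag bases into the flanks), progressively smaller tag-anchored
    subwindows are folded until the duplex is compact; exactly one scale is
    then judged.  On the fold restricted to the precursor span (helices
    shorter than ``prune_helix`` ignored for the topology) the candidate
    must form a single hairpin: exactly one terminal loop of ``loop_min`` to
    ``loop_max`` nt, the tag confined to one arm (it may not cross the loop
    midpoint), >= ``min_paired`` of its bases paired to the opposite arm
    including one contiguous helix of >= ``min_helix_run`` pairs, and an
    energy estimate <= ``energy_max``.  The Dicer two-nucleotide-overhang
    offset is reported but not required.  A conforming external folding
    backend can be supplied via ``fold_fn``.
    """
    n, off, L = len(window_seq), tag_offset, tag_length
    if arm_hypothesis == "5p":
        scales = [(0, n), (off - 20, off + L + 100), (off - 8, off + L + 60)]
    elif arm_hypothesis == "3p":
        scales = [(0, n), (off - 100, off + L + 20), (off - 60, off + L + 8)]
    else:
        scales = [(0, n), (off - 20, off + L + 100), (off - 100, off + L + 20),
                  (off - 8, off + L + 60), (off - 60, off + L + 8)]
    compact = 2 * L + loop_max + 16
    chosen = None
    seen = set()
    for a, b in scales:
        a, b = max(0, a), min(n, b)
        if (a, b) in seen or b - a < L + loop_min:
            continue
        seen.add((a, b))
        st = structure if (a, b) == (0, n) else fold_fn(window_seq[a:b])[0]
        partner = parse_structure(st)
        grp = _partner_group(partner, off - a, L, partner_gap)
        chosen = (a, b, st, grp)
        if len(grp) >= min_paired and \
                max(off - a + L, grp[-1] + 1) - min(off - a, grp[0]) <= compact:
            break
    a, b, st, grp = chosen
    o_scale = off - a
    if len(grp) < min_paired:
        return Evaluation(False, ["pairing"], (a, b), st, 0.0, len(grp),
                          None, None, None)
    partner = parse_structure(st)
    lo = min(o_scale, grp[0])
    hi = max(o_scale + L, grp[-1] + 1)
    m = hi - lo
    pairs = {(x - lo, partner[x] - lo) for x in range(lo, hi)
             if lo <= partner[x] < hi and partner[x] > x}
    o = o_scale - lo
    part_all = [-1] * m
    for i, j in pairs:
        part_all[i], part_all[j] = j, i
    runs = _helices(pairs)
    kept: set[tuple[int, int]] = set()
    for run in runs:
        if len(run) >= prune_helix:
            kept |= set(run)
    part = [-1] * m
    for i, j in kept:
        part[i], part[j] = j, i
    topo = "".join("(" if part[i] >= 0 and part[i] > i
                   else (")" if part[i] >= 0 else ".") for i in range(m))

    reasons: list[str] = []
    loop_len = mature_arm = None
    mid = None
    loops = list(_LOOP_RE.finditer(topo))
    if len(loops) != 1:
        reasons.append("structure")
        n_paired = sum(1 for x in range(o, o + L) if 0 <= x < m and part_all[x] >= 0)
    else:
        lm = loops[0]
        loop_start, loop_end = lm.start() + 1, lm.end() - 1
        # loop size counts unpaired bases only: short pruned helices inside
        # the loop are folding noise, not loop sequence
        loop_len = sum(1 for x in range(loop_start, loop_end) if part_all[x] < 0)
        if not (loop_min <= loop_len <= loop_max):
            reasons.append("loop")
        mid = (loop_start + loop_end) / 2.0
        if o + L <= mid:
            mature_arm = "5p"
        elif o >= mid:
            mature_arm = "3p"
        else:
            reasons.append("arm")
        # criterion (b): pairs must reach across the loop to the star arm
        n_paired = sum(1 for x in range(o, o + L)
                       if 0 <= x < m and part_all[x] >= 0
                       and (x < mid) != (part_all[x] < mid))
    if n_paired < min_paired:
        reasons.append("pairing")
    tag_runs = [len(r) for r in runs
                if any(o <= i < o + L or o <= j < o + L for i, j in r)]
    if not tag_runs or max(tag_runs) < min_helix_run:
        reasons.append("helix")
    sub_energy = ENERGY_PER_SCORE * structure_score(window_seq[a + lo:a + hi], pairs)
    if sub_energy > energy_max:
        reasons.append("energy")

    dicer_offset = None
    if mature_arm is not None:
        ends = [part_all[x] for x in (o, o + L - 1)
                if 0 <= x < m and part_all[x] >= 0]
        if len(ends) == 2:
            # blunt duplex would give 0; canonical Dicer product ~2 nt 3' overhang
            dicer_offset = abs(abs(ends[0] - ends[1]) - (L - 1))
    return Evaluation(
        passed=not reasons, reasons=reasons, trimmed_span=(a + lo, a + hi),
        structure=topo, energy=sub_energy, n_tag_paired=n_paired,
        loop_length=loop_len, mature_arm=mature_arm, dicer_offset=dicer_offset,
    )


# ---------------------------------------------------------------------------
# calling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NovelCall:
    mature_sequence: str
    location: str
    name: str
    counts: dict[str, int]
    group: str
    arm: str | None = None


@dataclass
class NovelSet:
    records: list
    n_mature: int
    n_precursors: int


def call_novel(records, min_reads: int = 30, require_all_libraries: bool = True) -> NovelSet:
    """Filter mature products by read support and group them per precursor.

    With ``require_all_libraries`` a product needs >= min_reads in *every*
    library (the shared-novel-miRNA rule); otherwise the summed support must
    reach min_reads.  Products sharing a ``group`` key (one hairpin, or one
    name stripped of its -5p/-3p suffix) count as one precursor.
    """
    kept = []
    for r in records:
        counts = list(r.counts.values())
        if not counts:
            continue
        ok = min(counts) >= min_reads if require_all_libraries else sum(counts) >= min_reads
        if ok:
            kept.append(r)
    return NovelSet(records=kept, n_mature=len(kept),
                    n_precursors=len({r.group for r in kept}))


def novel_pipeline(
    hits: dict[str, list[TagAlignment]],
    calls: dict[str, tuple[str, str]],
    tags: pd.DataFrame,
    genome: dict[str, str],
    max_gap: int = 200,
    min_locus_support: int = 30,
    min_reads: int = 30,
    require_all_libraries: bool = True,
    flank_up: int = 20,
    flank_down: int = 160,
    energy_max: float = -18.0,
    min_paired: int = 14,
) -> tuple[NovelSet, list[tuple[CandidateWindow, Evaluation]]]:
    """Full discovery: cluster unann tags, fold windows, evaluate, call.

    For each passing hairpin the representative tag becomes a mature
    product; the best-supported member tag on the opposite arm (if any)
    is emitted as the partner -5p/-3p product under the same precursor
    group.  Returns the called set and all (window, evaluation) pairs.
    """
    loci = cluster_unannotated(hits, calls, tags, max_gap=max_gap)
    evaluations: list[tuple[CandidateWindow, Evaluation]] = []
    records: list[NovelCall] = []
    n_called = 0
    for locus in loci:
        if int(locus.support.sum()) < min_locus_support:
            continue
        best: tuple[CandidateWindow, Evaluation] | None = None
        for win in extract_windows(locus, genome, flank_up, flank_down):
            structure, energy = fold(win.sequence)
            ev = evaluate_candidate(
                win.sequence, structure, energy, win.tag_offset, win.tag_length,
                energy_max=energy_max, min_paired=min_paired,
                arm_hypothesis=win.arm_hypothesis,
            )
            evaluations.append((win, ev))
            if ev.passed:
                best = (win, ev)
                break
        if best is None:
            continue
        win, ev = best
        lo, hi = ev.trimmed_span
        if win.strand == "+":
            g0, g1 = win.start + lo, win.start + hi
        else:
            g0, g1 = win.end - hi, win.end - lo
        group = f"{win.chrom}:{g0 + 1}-{g1}:{win.strand}"
        n_called += 1
        name = f"novel-{n_called}"
        top = locus.top_tag
        records.append(NovelCall(
            mature_sequence=top.tag, location=group, name=f"{name}-{ev.mature_arm}",
            counts=_product_counts(locus, top, tags),
            group=group, arm=ev.mature_arm,
        ))
        star = _opposite_arm_tag(locus, win, ev, tags)
        if star is not None:
            other = "3p" if ev.mature_arm == "5p" else "5p"
            records.append(NovelCall(
                mature_sequence=star.tag, location=group, name=f"{name}-{other}",
                counts=_product_counts(locus, star, tags),
                group=group, arm=other,
            ))
    return call_novel(records, min_reads, require_all_libraries), evaluations


def _product_counts(locus: Locus, anchor: TagAlignment, tags, shift: int = 4) -> dict[str, int]:
    """Per-library support of one mature product: summed counts of the locus
    tags stacking on the anchor (start and end within ``shift`` nt), i.e. the
    ragged length/trimming variants of the same processing product."""
    members = {
        m.tag for m in locus.tags
        if abs(m.start - anchor.start) <= shift and abs(m.end - anchor.end) <= shift
    }
    sub = tags.loc[sorted(members)]
    return {lib: int(sub[lib].sum()) for lib in tags.columns}


def _opposite_arm_tag(locus: Locus, win: CandidateWindow, ev: Evaluation, tags):
    """Best-supported locus tag on the far side of the hairpin loop from the mature tag."""
    lo, hi = ev.trimmed_span
    loops = list(_LOOP_RE.finditer(ev.structure))
    if not loops:
        return None
    mid = lo + (loops[0].start() + loops[0].end()) // 2
    if win.strand == "+":
        g_mid = win.start + mid
    else:
        g_mid = win.end - mid
    mature_before = locus.top_tag.start < g_mid
    candidates = [
        m for m in locus.tags
        if m.tag != locus.top_tag.tag and (m.start >= g_mid) == mature_before
    ]
    if not candidates:
        return None
    return max(candidates, key=lambda m: (int(tags.loc[m.tag].sum()), m.tag))


def shuffle_dinucleotide(seq: str, rng: np.random.Generator) -> str:
    """Dinucleotide-preserving shuffle (Altschul-Erikson style Euler walk).

    Used as the negative control for the hairpin criteria: shuffled windows
    keep base and dinucleotide composition but lose the stem.
    """
    if len(seq) < 3:
        return seq
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    for a in edges:
        perm = rng.permutation(len(edges[a]))
        edges[a] = [edges[a][i] for i in perm]
    # random walk with edge removal; restart until all edges consumed
    total = len(seq) - 1
    for _ in range(200):
        pool = {a: list(bs) for a, bs in edges.items()}
        out = [seq[0]]
        node = seq[0]
        while pool.get(node):
            nxt = pool[node].pop()
            out.append(nxt)
            node = nxt
        if len(out) == total + 1:
            return "".join(out)
        for a in edges:
            perm = rng.permutation(len(edges[a]))
            edges[a] = [edges[a][i] for i in perm]
    # walk got stuck (rare); fall back to a plain shuffle
    arr = list(seq)
    rng.shuffle(arr)
    return "".join(arr)
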