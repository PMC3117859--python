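"""Synthetic small-RNA sequencing data with planted ground truth.

The generator emulates the statistical structure of a multiplexed
small-RNA-seq experiment on embryonic stem cell lines: a random genome
carrying annotated non-miRNA RNA classes, planted miRNA hairpin precursors
(some clustered, some isolated), and three concordant sequencing libraries
whose 35 nt raw reads are ``6 nt index + insert + 3' adapter prefix``.
Insert lengths peak at 22-23 nt, ~60% of reads derive from mature miRNA
arms, <15% from other annotated RNA, and ~25% from unannotated intergenic
sequence.  Per-miRNA abundances are log-normal (heavy-tailed, spanning
several orders of magnitude) and shared across libraries up to
multiplicative between-library noise, so that downstream read-count
thresholds and consistency statistics are actually exercised.

Everything is deterministic given ``SimulationConfig.seed``.
"""
from __future__ import annotations

import bisect
import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import DNA, Interval, revcomp

NCRNA_TYPES = ("rRNA", "tRNA", "scRNA", "snRNA", "snoRNA")
CATEGORIES = ("mirna", "other_ncrna", "repeat", "exon", "intron", "unannotated")

#: default read composition: ~60% miRNA, <15% other annotated RNA, ~25% unannotated
DEFAULT_COMPOSITION = {
    "mirna": 0.60,
    "other_ncrna": 0.07,
    "repeat": 0.04,
    "exon": 0.02,
    "intron": 0.02,
    "unannotated": 0.25,
}

#: Illumina TruSeq-style 6 bp multiplex indices, one per library
DEFAULT_INDICES = ("ATCACG", "CGATGT", "TTAGGC")

# mature arm length distribution: mode at 22 with substantial 23, per the
# observed clean-read length peak at 22-23 nt
_ARM_LENGTHS = np.array([19, 20, 21, 22, 23])
_ARM_PROBS = np.array([0.05, 0.10, 0.20, 0.40, 0.25])


class ConfigurationError(ValueError):
    pass


class PlacementError(RuntimeError):
    pass


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chromosomes: int = 4
    chromosome_length: int = 250_000
    n_precursors: int = 16
    n_novel: int = 0  # trailing precursors withheld from the known annotation
    n_clusters: int = 2
    cluster_size: int = 3
    cluster_gap_bases: int = 5_000
    library_depth: int = 100_000
    n_libraries: int = 3
    composition: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_COMPOSITION))
    expression_dispersion: float = 1.0  # log10-scale SD of planted abundances
    between_library_noise: float = 0.15  # log-scale SD of multiplicative library noise
    star_fraction: float = 0.1  # minor-arm abundance relative to the dominant arm
    adapter5: str = "GTTCAGAGTTCTACAGTCCGACGATC"
    adapter3: str = "TCGTATGCCGTCTTCTGCTTG"
    indices: tuple[str, ...] = DEFAULT_INDICES
    read_length: int = 35

    def validate(self) -> None:
        if set(self.composition) != set(CATEGORIES):
            raise ConfigurationError(f"composition must cover {CATEGORIES}")
        total = sum(self.composition.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"composition sums to {total}, not 1")
        for name in ("n_chromosomes", "chromosome_length", "n_precursors", "library_depth", "n_libraries"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if any(len(ix) != 6 for ix in self.indices):
            raise ConfigurationError("multiplex indices must be 6 nt")
        if len(set(self.indices)) != len(self.indices):
            raise ConfigurationError("multiplex indices must be distinct")
        if self.n_libraries > len(self.indices):
            raise ConfigurationError("need one 6 bp index per library")
        if self.n_novel > self.n_precursors:
            raise ConfigurationError("n_novel exceeds n_precursors")
        if self.n_clusters * self.cluster_size > self.n_precursors:
            raise ConfigurationError("clusters require more precursors than available")

    def library_ids(self) -> list[str]:
        return [f"lib{i + 1}" for i in range(self.n_libraries)]

    def index_map(self) -> dict[str, str]:
        return {self.indices[i]: lib for i, lib in enumerate(self.library_ids())}


@dataclass
class Precursor:
    """A planted hairpin locus with its mature-arm products."""

    name: str
    chrom: str
    start: int
    end: int
    strand: str
    hairpin: str  # transcript-orientation sequence (DNA alphabet)
    arm_len: int
    loop_len: int
    mature_genomic: dict[str, tuple[int, int]]  # arm -> genomic [start, end)
    mature_seq: dict[str, str]  # arm -> transcript-orientation sequence
    dominant_arm: str
    is_novel: bool = False

    def mature_name(self, arm: str) -> str:
        return f"{self.name}-{arm}"


@dataclass
class GroundTruth:
    """Planted simulation truth: loci, abundances and realized read counts."""

    config: SimulationConfig
    precursors: list[Precursor]
    abundance: pd.Series  # per mature miRNA, arbitrary units
    true_counts: pd.DataFrame | None = None  # mature x library, filled by simulate_libraries
    category_counts: pd.DataFrame | None = None  # category x library

    def mature_names(self) -> list[str]:
        return list(self.abundance.index)

    def mature_sequences(self) -> dict[str, str]:
        return {
            p.mature_name(arm): p.mature_seq[arm]
            for p in self.precursors
            for arm in ("5p", "3p")
        }


@dataclass
class SimulatedReads:
    """Multiplexed raw reads plus the per-library demultiplexing key."""

    reads: list[tuple[str, str]]  # (sequence, quality) over all libraries, shuffled
    index_map: dict[str, str]


@dataclass
class Dataset:
    config: SimulationConfig
    genome: dict[str, str]
    tracks: list[Interval]
    truth: GroundTruth
    reads: SimulatedReads

    def known_precursors(self) -> list[Precursor]:
        return [p for p in self.truth.precursors if not p.is_novel]

    def mirna_track(self) -> list[Interval]:
        """Annotated (non-novel) precursor spans as strand-aware known_miRNA intervals."""
        return [
            Interval(p.chrom, p.start, p.end, p.strand, "known_miRNA", "mirbase", p.name)
            for p in self.known_precursors()
        ]


# ---------------------------------------------------------------------------
# genome + annotation
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(DNA))[rng.integers(0, 4, length)])


def _overlaps(occ: list[tuple[int, int]], start: int, end: int, margin: int) -> bool:
    i = bisect.bisect_left(occ, (start - margin, -1))
    for s, e in occ[max(0, i - 1):i + 2]:
        if s < end + margin and start - margin < e:
            return True
    return False


# per-category (count, interval length) for the non-miRNA annotation tracks
_TRACK_GEOMETRY = {
    "rRNA": (8, 120), "tRNA": (8, 120), "scRNA": (8, 120),
    "snRNA": (8, 120), "snoRNA": (8, 120),
    "repeat": (20, 300), "exon": (24, 400), "intron": (24, 600),
}


def generate_genome(config: SimulationConfig) -> tuple[dict[str, str], list[Interval]]:
    """Random chromosomes plus non-overlapping annotation intervals per category.

    Intervals are mutually disjoint across *all* categories (with a margin
    wider than the longest insert) so each simulated read has exactly one
    source category.
    """
    config.validate()
    rng = np.random.default_rng([1, config.seed])
    genome = {
        f"chr{i + 1}": _random_seq(rng, config.chromosome_length)
        for i in range(config.n_chromosomes)
    }
    chroms = list(genome)
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    tracks: list[Interval] = []
    for cat, (count, size) in _TRACK_GEOMETRY.items():
        for k in range(count):
            for _ in range(500):
                chrom = chroms[rng.integers(len(chroms))]
                start = int(rng.integers(100, config.chromosome_length - size - 100))
                if not _overlaps(occupied[chrom], start, start + size, margin=60):
                    break
            else:  # pragma: no cover - genome saturated
                raise PlacementError(f"could not place {cat} interval")
            bisect.insort(occupied[chrom], (start, start + size))
            strand = "+-"[rng.integers(2)]
            source = "genbank" if rng.random() < 0.5 else "rfam"
            if cat in ("repeat", "exon", "intron"):
                source = "n/a"
            tracks.append(Interval(chrom, start, start + size, strand, cat, source, f"{cat}_{k}"))
    return genome, tracks


# ---------------------------------------------------------------------------
# precursor planting
# ---------------------------------------------------------------------------

def _make_hairpin(rng: np.random.Generator) -> tuple[str, int, int]:
    """A stem-loop: 5' arm + loop + (mutated) reverse complement of the arm.

    Two interior positions of the 3' arm are mutated so the two mature
    products are not exact reverse complements of each other; >=16
    Watson-Crick pairs always remain (arm >= 19 nt).
    """
    arm_len = int(rng.choice(_ARM_LENGTHS, p=_ARM_PROBS))
    loop_len = int(rng.integers(4, 16))
    arm5 = _random_seq(rng, arm_len)
    arm3 = list(revcomp(arm5))
    for pos in rng.choice(np.arange(2, arm_len - 2), size=2, replace=False):
        current = arm3[pos]
        arm3[pos] = rng.choice([b for b in DNA if b != current])
    return arm5 + _random_seq(rng, loop_len) + "".join(arm3), arm_len, loop_len


def plant_precursors(
    genome: dict[str, str],
    config: SimulationConfig,
    tracks: list[Interval] = (),
) -> tuple[dict[str, str], GroundTruth]:
    """Write hairpin precursors into the genome and return the edited genome + truth.

    ``n_clusters`` groups of ``cluster_size`` consecutive precursors sit
    within ``cluster_gap_bases`` of each other; all remaining precursors are
    >= 50 kb from any other.  Placement avoids the annotation tracks.
    """
    config.validate()
    rng = np.random.default_rng([2, config.seed])
    chroms = list(genome)
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for iv in tracks:
        bisect.insort(occupied[iv.chrom], (iv.start, iv.end))

    # anchor slots spaced so that a cluster's full span still leaves >= 50 kb
    # to the next anchor
    step = 50_000 + config.cluster_size * (config.cluster_gap_bases + 120) + 5_000
    slots = [
        (chrom, base)
        for chrom in chroms
        for base in range(10_000, config.chromosome_length - 15_000, step)
    ]
    n_singletons = config.n_precursors - config.n_clusters * config.cluster_size
    if config.n_clusters + n_singletons > len(slots):
        raise PlacementError(
            f"genome holds {len(slots)} precursor anchor sites; "
            f"{config.n_clusters + n_singletons} needed"
        )
    order = rng.permutation(len(slots))
    slot_iter = iter(order)

    def place_at(chrom: str, pos: int, hairpin: str, max_offset: int = 5_000) -> int:
        for offset in range(0, max_offset, 97):
            start = pos + offset
            if start + len(hairpin) + 100 > config.chromosome_length:
                continue
            if not _overlaps(occupied[chrom], start, start + len(hairpin), margin=60):
                bisect.insort(occupied[chrom], (start, start + len(hairpin)))
                return start
        raise PlacementError("no free position near anchor slot")

    precursors: list[Precursor] = []
    genome = dict(genome)
    idx = 0

    def plant_one(chrom: str, pos: int, max_offset: int = 5_000) -> Precursor:
        nonlocal idx
        hairpin, arm_len, loop_len = _make_hairpin(rng)
        start = place_at(chrom, pos, hairpin, max_offset)
        end = start + len(hairpin)
        strand = "+-"[rng.integers(2)]
        inserted = hairpin if strand == "+" else revcomp(hairpin)
        genome[chrom] = genome[chrom][:start] + inserted + genome[chrom][end:]
        n = len(hairpin)
        if strand == "+":
            mg = {"5p": (start, start + arm_len), "3p": (start + arm_len + loop_len, end)}
        else:
            mg = {"5p": (end - arm_len, end), "3p": (start, start + (n - arm_len - loop_len))}
        idx += 1
        p = Precursor(
            name=f"sim-mir-{idx}", chrom=chrom, start=start, end=end, strand=strand,
            hairpin=hairpin, arm_len=arm_len, loop_len=loop_len,
            mature_genomic=mg,
            mature_seq={"5p": hairpin[:arm_len], "3p": hairpin[arm_len + loop_len:]},
            dominant_arm="5p" if rng.random() < 0.5 else "3p",
        )
        precursors.append(p)
        return p

    # inter-member gap draw + bounded placement offset stay <= cluster_gap_bases
    gap_hi = max(301, config.cluster_gap_bases - 600)
    for _ in range(config.n_clusters):
        chrom, base = slots[next(slot_iter)]
        pos = base
        for _ in range(config.cluster_size):
            p = plant_one(chrom, pos, max_offset=500)
            pos = p.end + int(rng.integers(200, gap_hi))
    for _ in range(n_singletons):
        chrom, base = slots[next(slot_iter)]
        plant_one(chrom, base)

    # trailing precursors are the "novel" ones withheld from the annotation
    for p in precursors[len(precursors) - config.n_novel:]:
        p.is_novel = True

    # planted log-normal abundances, dominant arm >> star arm
    arng = np.random.default_rng([3, config.seed])
    names, values = [], []
    for p in precursors:
        a = 10.0 ** arng.normal(1.5, config.expression_dispersion)
        for arm in ("5p", "3p"):
            names.append(p.mature_name(arm))
            values.append(a if arm == p.dominant_arm else a * config.star_fraction)
    abundance = pd.Series(values, index=names, name="abundance")
    return genome, GroundTruth(config=config, precursors=precursors, abundance=abundance)


# ---------------------------------------------------------------------------
# library simulation
# ---------------------------------------------------------------------------

def _merged_occupied(genome, tracks, precursors) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    by_chrom: dict[str, list[tuple[int, int]]] = {c: [] for c in genome}
    for iv in tracks:
        by_chrom[iv.chrom].append((iv.start, iv.end))
    for p in precursors:
        by_chrom[p.chrom].append((p.start, p.end))
    out = {}
    for c, spans in by_chrom.items():
        spans.sort()
        merged = []
        for s, e in spans:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        starts = np.array([s for s, _ in merged], dtype=np.int64)
        ends = np.array([e for _, e in merged], dtype=np.int64)
        out[c] = (starts, ends)
    return out


# per-read miRNA insert length distribution (mode 22, strong 23 shoulder)
_READ_LENGTHS = np.array([20, 21, 22, 23])
_READ_LENGTH_P = np.array([0.05, 0.15, 0.45, 0.35])


def _insert_length(rng: np.random.Generator) -> int:
    return int(np.clip(round(rng.normal(21.5, 2.0)), 18, 23))


def simulate_libraries(
    genome: dict[str, str],
    truth: GroundTruth,
    config: SimulationConfig,
    tracks: list[Interval],
) -> SimulatedReads:
    """Draw multiplexed 35 nt raw reads for every library and record truth counts.

    Per library, the category split is a single multinomial draw over the
    configured composition (so truth category counts sum to the depth
    exactly); miRNA reads are mature-arm sequences drawn with log-normal
    abundances shared across libraries up to multiplicative noise.
    """
    config.validate()
    if config.library_depth < 1000:
        import warnings

        warnings.warn("library_depth < 1000: composition statistics will be unstable")
    rng = np.random.default_rng([4, config.seed])
    libs = config.library_ids()
    index_of = {lib: config.indices[i] for i, lib in enumerate(libs)}
    comp = np.array([config.composition[c] for c in CATEGORIES])

    mature = truth.mature_names()
    abundance = truth.abundance.to_numpy()
    arm_of = {p.mature_name(arm): (p, arm) for p in truth.precursors for arm in ("5p", "3p")}

    tracks_by_cat: dict[str, list[Interval]] = {}
    for iv in tracks:
        key = "other_ncrna" if iv.category in NCRNA_TYPES else iv.category
        tracks_by_cat.setdefault(key, []).append(iv)
    occ = _merged_occupied(genome, tracks, truth.precursors)

    def draw_interval_read(iv: Interval) -> str:
        L = _insert_length(rng)
        s = int(rng.integers(iv.start, iv.end - L + 1))
        frag = genome[iv.chrom][s:s + L]
        return frag if iv.strand == "+" else revcomp(frag)

    def draw_background_read() -> str:
        L = _insert_length(rng)
        chroms = list(genome)
        for _ in range(1000):
            chrom = chroms[rng.integers(len(chroms))]
            s = int(rng.integers(0, len(genome[chrom]) - L))
            starts, ends = occ[chrom]
            i = np.searchsorted(starts, s + L + 30)
            if i > 0 and ends[i - 1] + 30 > s:
                continue
            return genome[chrom][s:s + L]
        raise PlacementError("could not draw intergenic background read")

    true_counts = pd.DataFrame(0, index=mature, columns=libs, dtype=int)
    category_counts = pd.DataFrame(0, index=list(CATEGORIES), columns=libs, dtype=int)
    all_reads: list[tuple[str, str]] = []

    for lib in libs:
        n_cat = rng.multinomial(config.library_depth, comp)
        category_counts[lib] = n_cat
        inserts: list[str] = []
        # miRNA reads
        if config.between_library_noise > 0:
            weights = abundance * np.exp(rng.normal(0.0, config.between_library_noise, len(abundance)))
        else:
            weights = abundance
        probs = weights / weights.sum()
        counts = rng.multinomial(n_cat[0], probs)
        true_counts[lib] = counts
        for name, c in zip(mature, counts):
            if c == 0:
                continue
            prec, arm = arm_of[name]
            # ragged processing ends: per-read length peaked at 22-23 nt,
            # within +-2 of the arm and capped so the adapter anchor survives
            lengths = rng.choice(_READ_LENGTHS, size=int(c), p=_READ_LENGTH_P)
            lo, hi = prec.arm_len - 2, min(prec.arm_len + 2, 23)
            for L in np.clip(lengths, lo, hi):
                if arm == "5p":
                    inserts.append(prec.hairpin[: int(L)])
                else:
                    inserts.append(prec.hairpin[len(prec.hairpin) - int(L):])
        # annotated non-miRNA categories
        for cat, n in zip(CATEGORIES[1:-1], n_cat[1:-1]):
            ivs = tracks_by_cat.get(cat, [])
            for _ in range(int(n)):
                inserts.append(draw_interval_read(ivs[rng.integers(len(ivs))]))
        # unannotated intergenic background
        for _ in range(int(n_cat[-1])):
            inserts.append(draw_background_read())
        ix = index_of[lib]
        qual = "I" * config.read_length
        for ins in inserts:
            read = (ix + ins + config.adapter3)[:config.read_length]
            all_reads.append((read, qual))

    perm = rng.permutation(len(all_reads))
    all_reads = [all_reads[i] for i in perm]
    truth.true_counts = true_counts
    truth.category_counts = category_counts
    return SimulatedReads(reads=all_reads, index_map=config.index_map())


def simulate_dataset(config: SimulationConfig) -> Dataset:
    """End-to-end generator: genome -> annotation -> planted hairpins -> libraries."""
    genome, tracks = generate_genome(config)
    genome, truth = plant_precursors(genome, config, tracks)
    reads = simulate_libraries(genome, truth, config, tracks)
    return Dataset(config=config, genome=genome, tracks=tracks, truth=truth, reads=reads)


# ---------------------------------------------------------------------------
# target / evolution tables
# ---------------------------------------------------------------------------

def generate_target_table(
    n_mirnas: int,
    n_genes: int,
    slope: float,
    seed: int = 0,
    intercept: float = 0.35,
    noise_sd: float = 0.08,
    degree_max: int = 12,
    utr_log10_mean: float = 3.0,
    utr_log10_sd: float = 0.25,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Planted miRNA->gene target table with a linear degree-dN/dS relation.

    Per-gene degree ~ Uniform{1..degree_max} so every degree bin of the
    downstream correlation is comparably occupied (the binned Pearson test
    is calibrated in this balanced regime); expected dN/dS = intercept +
    slope * degree (clipped below at 1e-3); 3'UTR lengths log-normal and
    independent of dN/dS.  ``slope=0`` plants no relation.
    """
    if slope > 0:
        raise ValueError("slope must be <= 0 (negative plants the relation, 0 plants none)")
    rng = np.random.default_rng(seed)
    if n_genes == 0:
        return (
            pd.DataFrame(columns=["mirna", "gene"]),
            pd.DataFrame(columns=["gene", "dnds", "utr_length"]).set_index("gene"),
        )
    degrees = rng.integers(1, degree_max + 1, n_genes)
    degrees = np.minimum(degrees, n_mirnas)
    mirnas = [f"mir{i}" for i in range(n_mirnas)]
    rows = []
    for g in range(n_genes):
        for m in rng.choice(n_mirnas, size=int(degrees[g]), replace=False):
            rows.append((mirnas[m], f"gene{g}"))
    targets = pd.DataFrame(rows, columns=["mirna", "gene"])
    dnds = np.clip(intercept + slope * degrees + rng.normal(0.0, noise_sd, n_genes), 1e-3, None)
    utr = np.round(10.0 ** rng.normal(utr_log10_mean, utr_log10_sd, n_genes)).astype(int)
    evolution = pd.DataFrame(
        {"dnds": dnds, "utr_length": utr},
        index=pd.Index([f"gene{g}" for g in range(n_genes)], name="gene"),
    )
    return targets, evolution


# ---------------------------------------------------------------------------
# cross-species profiles
# ---------------------------------------------------------------------------

def simulate_species_profiles(
    seed: int = 0,
    n_core: int = 80,
    n_specific: int = 10,
    species: tuple[str, ...] = ("hsa", "mml", "mmu"),
    n_samples: int = 3,
    correlated_pair: tuple[str, str] = ("hsa", "mml"),
    pair_sd: float = 0.3,
    indep_sd: float = 1.6,
    sample_sd: float = 0.15,
    cluster_spec: dict[str, tuple[str, ...]] | None = None,
    cluster_size: int = 5,
) -> tuple[dict[str, pd.DataFrame], dict]:
    """Per-species RPM sample matrices with a planted shared core and named clusters.

    A core family set is expressed in every species; the ``correlated_pair``
    species share a common expression deviation (so they cluster together);
    each species also carries ``n_specific`` private families, and each named
    cluster in ``cluster_spec`` is expressed only in the listed species.
    Returns ``(profiles, truth)`` where profiles maps species to a
    family x sample RPM DataFrame.
    """
    if cluster_spec is None:
        cluster_spec = {
            "miR-467-like": ("mmu",),
            "imprinted-region-like": ("mml", "mmu"),
            "C19MC-like": ("hsa", "mml"),
        }
    rng = np.random.default_rng(seed)
    core = [f"fam{i}" for i in range(n_core)]
    base = rng.normal(5.0, 2.0, n_core)
    shared_dev = rng.normal(0.0, 1.0, n_core)
    profiles: dict[str, pd.DataFrame] = {}
    truth = {"core": list(core), "clusters": {}, "specific": {}}
    cluster_members = {
        name: [f"{name}-m{j}" for j in range(cluster_size)] for name in cluster_spec
    }
    truth["clusters"] = {
        name: {"members": members, "species": tuple(cluster_spec[name])}
        for name, members in cluster_members.items()
    }
    for sp in species:
        fams = list(core)
        if sp in correlated_pair:
            log2 = base + shared_dev + rng.normal(0.0, pair_sd, n_core)
        else:
            log2 = base + rng.normal(0.0, indep_sd, n_core)
        values = list(2.0 ** log2)
        specific = [f"{sp}-only{j}" for j in range(n_specific)]
        truth["specific"][sp] = specific
        fams += specific
        values += list(2.0 ** rng.normal(4.0, 1.0, n_specific))
        for name, members in cluster_members.items():
            fams += members
            if sp in cluster_spec[name]:
                values += list(2.0 ** rng.normal(6.0, 0.5, cluster_size))
            else:
                values += [0.0] * cluster_size
        mean_rpm = np.array(values)
        samples = {
            f"{sp}_s{k + 1}": mean_rpm * np.exp(rng.normal(0.0, sample_sd, len(fams)))
            for k in range(n_samples)
        }
        profiles[sp] = pd.DataFrame(samples, index=pd.Index(fams, name="family"))
    return profiles, truth


# ---------------------------------------------------------------------------
# packaged fixture: the printed novel-miRNA table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NovelMiRNARecord:
    mature_sequence: str
    locations: tuple[str, ...]
    name: str
    counts: dict[str, int]
    group: str


def _group_of(name: str) -> str:
    for suffix in ("-5p", "-3p"):
        if name.endswith(suffix):
            return name[: -len(suffix)]
    return name


def load_table1_fixture() -> list[NovelMiRNARecord]:
    """The 23 printed novel mature miRNAs of the rESC study, packaged verbatim.

    Counts are per cell line (IVF1.2, IVF3.2, IVF3.3); precursor locations
    are 1-based inclusive as printed; one name (miR-1185-3p) carries two
    precursor loci.
    """
    text = (
        importlib.resources.files("mirprof").joinpath("data/table1_novel_mirnas.tsv").read_text()
    )
    lines = [l for l in text.splitlines() if l and not l.startswith("#")]
    header = lines[0].split("\t")
    libs = header[3:]
    records = []
    for line in lines[1:]:
        fields = line.split("\t")
        seq, locs, name = fields[0], fields[1], fields[2]
        counts = {lib: int(v) for lib, v in zip(libs, fields[3:])}
        records.append(
            NovelMiRNARecord(
                mature_sequence=seq,
                locations=tuple(locs.split(";")),
                name=name,
                counts=counts,
                group=_group_of(name),
            )
        )
    return records
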