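# Methods

This note records the models, algorithms and numerical choices behind
`mirprof`, in the spirit of a methods supplement: what is computed, under
which assumptions, and where the design was genuinely open.

## Synthetic data model

The generator (`mirprof.simulate`) emulates a multiplexed small-RNA-seq
experiment on three concordant ESC lines.

**Genome and annotation.** Chromosomes are i.i.d. uniform ACGT
(default 4 × 250 kb). Non-miRNA annotation intervals (five ncRNA classes of
120 nt, repeats 300 nt, exons 400 nt, introns 600 nt) are placed mutually
disjoint with a ≥60 nt margin — wider than the longest insert — so every
simulated read has exactly one source category and recovered composition is
directly comparable to the configured one. ncRNA intervals carry a
Genbank/Rfam source label for the annotation-priority tier.

**Planted hairpins.** A precursor is `arm + loop + mutated
reverse-complement(arm)` with arm length 19–23 nt (mode 22), loop 4–15 nt,
and two interior substitutions in the 3' arm, leaving ≥16 Watson–Crick
pairs and making the two arms distinguishable. Precursors are written into
the genome on random strands at anchor slots spaced so isolated precursors
sit ≥50 kb apart, while `n_clusters` groups of `cluster_size` members sit
within `cluster_gap_bases` of each other (the genomic-cluster statistics
need both regimes). The trailing `n_novel` precursors are withheld from the
known annotation and precursor reference; their reads surface as
unannotated tags for the discovery stage.

**Libraries.** Per library, a single multinomial draw over the composition
(default 60% miRNA, 7% other ncRNA, 4% repeat, 2% exon, 2% intron, 25%
unannotated — the annotated-non-miRNA total stays below 15%) fixes the
category counts, so truth counts sum to the depth exactly. Mature
abundances are log-normal (log10 SD 1.0, spanning several orders of
magnitude so count thresholds are exercised); the dominant arm is drawn per
precursor with the star arm at 10% of its abundance; per-library
multiplicative noise is log-normal with SD 0.15, which reproduces the
"three highly concordant libraries" regime (pairwise κ ≈ 0.9 at the
30-read threshold). miRNA reads have ragged processing ends: per-read
insert length is drawn from {20, 21, 22, 23} with weights
{0.05, 0.15, 0.45, 0.35}, clipped to ±2 nt of the arm and anchored at the
arm's 5' end (5p products) or 3' end (3p products), so the clean-read
length mode lands at 22–23 nt and every variant still matches its mature
arm within the ±4 nt quantification window. Non-miRNA inserts are interval
substrings (sense strand); unannotated inserts come from intergenic
sequence ≥30 nt away from any annotation. Raw reads are exactly 35 nt:
`6 bp library index + insert + 3' adapter prefix`. Because the index
occupies 6 of the 35 cycles, inserts are capped at 23 nt so that at least
6 nt of adapter always remain for anchored trimming; the 19–25 nt mature
band of real miRNAs is represented by its 19–23 nt portion.

What the generator does **not** model: sequencing errors, base-quality
variation (qualities are a constant Q40 placeholder), PCR duplication,
isomiR 5'-end heterogeneity beyond the ±2 nt raggedness, genomic repeats
long enough to cause systematic multi-mapping, and cross-mapping homologous
miRNA families. Tests passing on this data therefore demonstrate the
correctness of the bookkeeping and the statistical machinery under clean
conditions, not robustness to real-data noise.

**Planted target tables.** `generate_target_table` draws per-gene degrees
uniformly on {1..12} and sets E[dN/dS] = 0.35 + slope·degree (noise SD
0.08, clipped at 10⁻³); 3'UTR lengths are log-normal (median ~1 kb) and
independent of dN/dS. Degrees are uniform rather than heavy-tailed so each
degree bin of the downstream correlation is comparably occupied; with
strongly unequal bin sizes the bin means are heteroscedastic and the
Pearson t-test on ~10 bins becomes anticonservative (we measured ~13%
type-I error with Poisson degrees vs ~5–7% with uniform ones). Heavy-tailed
degree structure is exercised separately through the preferential-
attachment null model.

## Preprocessing

Demultiplexing assigns a read to the library whose 6 bp index equals its
first 6 bases; 3' adapter trimming takes the insert before the leftmost
position where ≥`min_overlap` (6) leading adapter bases match and the match
extends to the read end. Matching is exact because the simulator emits
exact adapters; a mismatch-tolerant mode would be an extension. The "low
quality" filter is implemented as ≤`max_ambiguous` (0) non-ACGT bases —
the source analysis does not state its quality rule, and simulated
qualities are constant — and contaminant removal is an optional sequence
blocklist (default empty). `raw = clean + Σ discards` holds exactly per
library and is asserted in the pipeline.

## Annotation and quantification

Mapping is exact-match on both strands, implemented as a rolling 2-bit
encoding of all genome windows per tag length checked against the tag set
(cost independent of tag count); up to `max_hits` (20) placements are kept
per tag. Known-miRNA quantification credits a tag to a mature miRNA when it
occurs in the precursor within ±4 nt of the annotated arm start; a tag
matching k precursors credits all k (fractional counting would be the
alternative; the all-hits rule mirrors reporting every alignment hit).
An optional ≤1-mismatch mode exists behind a flag. Category calls apply
the priority `rRNA/tRNA/scRNA/snRNA/snoRNA (Genbank > Rfam) > known miRNA >
repeat > exon > intron` over **all** hits of a multi-mapping tag,
strand-aware for the ncRNA/miRNA tiers and strandless for
repeat/exon/intron; tags with no overlap anywhere are `unann`. Coordinates
are 0-based half-open in memory and 1-based inclusive in GFF3 files.

## Novel miRNA discovery

Unannotated mapped tags on one strand within 200 nt merge into loci; the
best-supported tag is the mature candidate. Two windows are extracted per
locus — tag as the 5' arm (20 nt upstream, 160 nt downstream flank) and
mirrored — and folded.

**Folding.** `fold` maximizes a stacking-aware pairing score (GC=3, AU=2,
GU=1, +1 per stacked pair, minimum loop 3) by an O(n³) dynamic program
(numba-compiled, Python traceback) and reports
`energy = −0.9 × score` kcal/mol. This is a pairing-capacity proxy, not a
nearest-neighbor thermodynamic energy; an external folding backend
honouring the same `(structure, energy)` contract can be passed wherever a
`fold_fn` argument appears. Maximum-pairing folds are deliberately
promiscuous — a random 200 nt window folds into many stems — and the
candidate evaluation is designed around that fact.

**Candidate evaluation.** The putative precursor is the mature tag plus the
largest gap-free group (gap ≤ 12 nt) of its pairing partners, partners
inside the tag excluded (a tag folding onto itself is not a mature/star
duplex). If the group is not compact (≤ 2·tag + 36 nt) at the window scale,
progressively smaller tag-anchored subwindows (120 nt, then ~82 + tag nt)
are folded and exactly one scale — the first compact one — is judged, so a
candidate gets a single accept chance. On the fold restricted to the
precursor span (pairs crossing the boundary dropped; helices shorter than
3 pairs ignored for the topology, since max-pairing decorates real
hairpins with 1–2-pair noise stems), the candidate passes iff:

1. exactly one terminal loop (a single hairpin);
2. loop size — counting unpaired bases — between 3 and 20 nt;
3. the mature tag does not cross the loop midpoint (mature products
   commonly end 1–2 nt into the loop, so "entirely on one arm" is judged
   against the hairpin axis);
4. ≥14 tag bases paired across the loop to the star arm, among them one
   contiguous helix of ≥7 pairs — genuine mature/star duplexes carry a long
   helix, whereas shuffled-sequence foldbacks are patchworks of 2–6-pair
   stems, and this requirement is what separates the two populations;
5. energy of the restricted structure ≤ −18 kcal/mol.

The Dicer-style two-nucleotide-overhang offset is reported but not
required. The thresholds (−18 kcal/mol, 14 pairs, loop 3–20, helix ≥7,
helix-prune 3, partner gap 12) are all keyword arguments. Measured on the
default study conditions: 132/132 planted withheld hairpins with ≥30 true
reads per library recovered across 20 simulated datasets, and
dinucleotide-shuffled candidate windows pass at ~2–4%.

**Calling.** A passing locus emits its mature product and, when present,
the best-supported opposite-arm product under the same precursor group.
Per-library support sums all stacked length/trimming variants of the
product (alignment ends within ±4 nt of the anchor), matching per-precursor
read counting; shared novel miRNAs need ≥30 reads in every library
(inclusive, so a product with exactly 30 reads survives — table rows with a
printed 30 demand the ≥ reading), and −5p/−3p products of one hairpin
count as a single precursor.

## Expression statistics

RPM = count / mapped reads × 10⁶. The Poisson background threshold takes
λ = mapped reads × window / genome length (or, in empirical mode, the mean
count over `n_bins` random windows of the read-start positions) and returns
the smallest integer T with P(X ≥ T) < α under Poisson(λ); it is
non-increasing in α and non-decreasing in λ. Genomic miRNA clusters chain
loci with consecutive start-to-start distance ≤ 10 kb (inclusive).

The four consistency statistics, chosen to match their verbal
descriptions since the original formulas are in an unavailable supplement:

* **Var** = Jensen–Shannon divergence (log base 2) between the
  within-cluster member-count proportions of two libraries, with a 0.5
  pseudocount per member; symmetric, 0 ≤ Var ≤ 1 bit, zero iff the
  pre-pseudocount proportions agree.
* **C.V.** = sample SD / mean of cluster-summed expression across
  libraries.
* **D.I.** = (x − mean)/mean per miRNA per library; rows sum to zero
  exactly and rows with zero mean are excluded.
* **κ** = Cohen's kappa on binary expressed calls (default threshold 30
  reads) between two libraries, P_e from the marginal call frequencies,
  with Z = κ / √(P_e / (N(1−P_e))) under the no-agreement null.

The sharing summary divides the number of miRNAs expressed in every
library by the largest per-library detected count (×100), which reproduces
the printed 92.4% from detections of 326/329/326 with 304 shared.

## Target network and evolution analysis

Seed sites are canonical matches of the reverse complement of miRNA
positions 2–7 (6-mer core), extended by the m8 complement and/or a
downstream adenosine into 7mer-m8, 7mer-A1 and 8mer types; overlapping
sites are all reported, and a site is conserved when the same type occurs
at the aligned position in ≥`min_species` orthologous UTRs. Distinct
miRNA–gene pairs form the edges of the bipartite MT network (sites
deduplicate to interactions); Σ miRNA degrees = Σ gene degrees = edges by
construction.

The degree–dN/dS analysis groups genes by rounded degree (optionally
degree / (UTR kb · k), k ∈ {1,2}), drops bins under `min_genes_per_bin`
(10), and computes Pearson r between bin degree and bin mean dN/dS with the
two-sided t transform on bins − 2 df (r = −0.564 over 17 points gives
p ≈ 0.018 under this transform). Binning is the default because a printed
(r, p) pair of that size implies ~17 aggregated points; raw per-gene
correlation is available via `binned=False`. The random-network null is a
bipartite preferential-attachment construction (new nodes attach to
opposite-side nodes with probability ∝ degree+1, then degree+1-weighted
sampling tops up to exactly m distinct edges); classic preferential
attachment is unipartite, so this adaptation with +1 smoothing is our
design. Degree distributions are compared with a two-sided Wilcoxon
rank-sum test: exact enumeration over all C(n, n₁) labelings (tie-aware
through midranks) for combined n ≤ 12, otherwise the tie-corrected normal
approximation with continuity correction (the two agree within 0.02 at
n = 12). Pathway enrichment is the hypergeometric upper tail per pathway
with Benjamini–Hochberg q-values; q ≥ p and q is monotone in p.

## Cross-species comparison

Species profiles are per-miRNA means of per-sample RPM; names map to
family keys through a homology table (identity by default) and family
members sum within species. The shared set keeps families with RPM > 0 in
every species. Species cluster on 1 − Pearson correlation of log2(RPM+1)
with average linkage — a standard choice for expression profiles, exposed
as configuration since the original analysis does not state its metric —
and the dendrogram exports merges, heights and a Newick string. Named
cluster contrasts sum member RPM per species and call presence when any
member reaches 1 RPM (the qualitative "almost absent"/"rarely expressed"
judgements need some threshold; 1 RPM is the documented stand-in).

## Problem sizes and determinism

Tests and the acceptance script run the full pipeline at 10⁵ reads per
library on 1 Mb genomes — large enough that binomial noise on composition
fractions (±0.15 points) and threshold statistics are far inside the
tolerances being checked, while a full dataset simulates and analyzes in
well under a minute. Recovery rates for novel-miRNA discovery pool four
datasets (~26 qualifying planted loci) and 800 shuffled windows so the
rates are estimated, not anecdotal. All randomness flows from explicit
seeds through `numpy.random.default_rng`; identical seeds reproduce
identical reads, truth tables and results byte-for-byte.

## Known limitations

* The energy proxy tracks pairing capacity, not thermodynamics; absolute
  energies are not comparable to nearest-neighbor minimum free energies,
  and the −18 kcal/mol default is calibrated to this proxy only.
* Exact-match mapping and trimming presume error-free reads; real
  libraries need the mismatch-tolerant flags plus upstream quality control.
* The conservation classifier requires pre-aligned orthologous UTRs; it
  does not align.
* Cohen's κ uses the normal-approximation Z; small miRNA sets (N ≲ 30)
  deserve an exact test.
* The discovery stage anchors hairpins on the best-supported tag per
  locus; antisense overlapping transcription collapses into strand-split
  loci but mixed-arm loci with co-dominant products report at most two
  products.
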