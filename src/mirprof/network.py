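"""miRNA-target site prediction, the bipartite MT network and its evolution analysis.

Target sites are canonical seed matches in 3'UTRs (8mer, 7mer-m8, 7mer-A1,
seed = miRNA positions 2-8), optionally classified as conserved across
aligned orthologous UTRs.  Distinct miRNA-gene pairs form the edges of the
bipartite miRNA-target (MT) network; a gene's degree is the number of
miRNAs targeting it.  The degree-vs-dN/dS analysis bins genes by (optionally
3'UTR-length-normalized) degree and correlates bin degree with mean dN/dS
(Pearson, two-sided t test); a bipartite preferential-attachment random
network serves as the null for the degree distribution, compared with a
Wilcoxon rank-sum test (exact enumeration at small n).  Pathway
over-representation uses the hypergeometric upper tail with
Benjamini-Hochberg correction.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from ._util import revcomp

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1")


@dataclass(frozen=True)
class TargetSite:
    mirna: str
    gene: str
    position: int  # 0-based start of the 6-mer seed-core match in the UTR
    site_type: str
    conserved: bool | None = None


def _site_type_at(mirna: str, utr: str, pos: int) -> str | None:
    """Canonical site type of the seed-core match at ``pos`` (None if no core)."""
    m = mirna.upper().replace("U", "T")
    core = revcomp(m[1:7])  # matches miRNA positions 2-7
    if utr[pos:pos + 6] != core:
        return None
    has_m8 = pos >= 1 and utr[pos - 1] == revcomp(m[7])
    has_a1 = pos + 6 < len(utr) and utr[pos + 6] == "A"
    if has_m8 and has_a1:
        return "8mer"
    if has_m8:
        return "7mer-m8"
    if has_a1:
        return "7mer-A1"
    return None


def predict_sites(mirna: str, utr: str, gene: str = "", mirna_name: str = "") -> list[TargetSite]:
    """All canonical seed-match sites of one miRNA in one 3'UTR.

    The seed is miRNA positions 2-8; a UTR 7-mer equal to its reverse
    complement is 7mer-m8, followed by an A (opposite position 1) it is
    8mer; the 6-mer match for positions 2-7 followed by A is 7mer-A1.
    Overlapping sites are all reported.
    """
    if len(mirna) < 8:
        raise ValueError("miRNA must be >= 8 nt")
    utr = utr.upper().replace("U", "T")
    m = mirna.upper().replace("U", "T")
    core = revcomp(m[1:7])
    sites = []
    p = utr.find(core)
    while p != -1:
        stype = _site_type_at(m, utr, p)
        if stype is not None:
            sites.append(TargetSite(mirna_name or mirna, gene, p, stype))
        p = utr.find(core, p + 1)
    return sites


def classify_conservation(
    site: TargetSite,
    aligned_utrs: dict[str, str],
    ref_species: str,
    mirna: str,
    min_species: int = 4,
) -> bool:
    """Conserved iff the same site type occurs at the aligned position in
    >= min_species of the species present (the reference included)."""
    ref = aligned_utrs[ref_species]
    colmap = [i for i, c in enumerate(ref) if c != "-"]
    if site.position >= len(colmap):
        raise ValueError("site position outside the alignment")
    col = colmap[site.position]
    n_same = 0
    for aln in aligned_utrs.values():
        if aln[col] == "-":
            continue
        ungapped = aln.replace("-", "")
        pos = sum(1 for c in aln[:col] if c != "-")
        if _site_type_at(mirna, ungapped.upper().replace("U", "T"), pos) == site.site_type:
            n_same += 1
    return n_same >= min_species


# ---------------------------------------------------------------------------
# the MT network
# ---------------------------------------------------------------------------

@dataclass
class MTNetwork:
    graph: nx.Graph
    mirnas: set[str]
    genes: set[str]

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def mirna_degrees(self) -> pd.Series:
        return pd.Series({m: self.graph.degree(m) for m in self.mirnas}, dtype=int)

    def gene_degrees(self) -> pd.Series:
        """Per gene, the number of miRNAs targeting it."""
        return pd.Series({g: self.graph.degree(g) for g in self.genes}, dtype=int)

    def all_degrees(self) -> np.ndarray:
        return np.array([d for _, d in self.graph.degree()], dtype=int)


def build_network(targets: pd.DataFrame) -> MTNetwork:
    """Bipartite miRNA-gene graph from a (mirna, gene) pair table.

    Duplicate pairs (multiple sites for one pair) collapse to a single edge:
    the network counts interactions, not sites.
    """
    g = nx.Graph()
    mirnas = set(targets["mirna"].astype(str))
    genes = set(targets["gene"].astype(str))
    clash = mirnas & genes
    if clash:
        raise ValueError(f"names used on both sides of the bipartite graph: {sorted(clash)[:3]}")
    g.add_nodes_from(mirnas, side="mirna")
    g.add_nodes_from(genes, side="gene")
    g.add_edges_from({(str(m), str(t)) for m, t in zip(targets["mirna"], targets["gene"])})
    return MTNetwork(graph=g, mirnas=mirnas, genes=genes)


def pearson_p_from_r(r: float, n: int) -> float:
    """Two-sided p for a Pearson r via the t transform with n-2 df."""
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1 - r * r))
    return float(2 * sps.t.sf(abs(t), df=n - 2))


def degree_dnds_correlation(
    network: MTNetwork,
    evolution: pd.DataFrame,
    min_genes_per_bin: int = 10,
    normalize_per_kb: int | None = None,
    binned: bool = True,
) -> tuple[float, float, int]:
    """Pearson correlation between (binned) gene degree and mean dN/dS.

    With ``normalize_per_kb`` in {1, 2}, degree is divided by
    utr_length/1000 * k before binning (controls for 3'UTR length).  Genes
    are grouped by rounded degree; bins with fewer than min_genes_per_bin
    genes are dropped; needs >= 3 bins.  ``binned=False`` correlates raw
    per-gene degree with dN/dS instead.
    """
    deg = network.gene_degrees()
    df = evolution.join(deg.rename("degree"), how="inner").dropna(subset=["degree", "dnds"]).copy()
    if normalize_per_kb is not None:
        if normalize_per_kb not in (1, 2):
            raise ValueError("normalize_per_kb must be 1 or 2")
        df = df[df["utr_length"] > 0]
        df["degree"] = df["degree"] / (df["utr_length"] / 1000.0 * normalize_per_kb)
    if not binned:
        r, p = sps.pearsonr(df["degree"], df["dnds"])
        return float(r), float(p), len(df)
    df["bin"] = df["degree"].round().astype(int)
    grouped = df.groupby("bin").agg(n=("dnds", "size"), dnds=("dnds", "mean"))
    grouped = grouped[grouped["n"] >= min_genes_per_bin]
    if len(grouped) < 3:
        raise ValueError(f"only {len(grouped)} degree bins after filtering; need >= 3")
    r, p = sps.pearsonr(grouped.index.to_numpy(float), grouped["dnds"].to_numpy())
    return float(r), float(p), len(grouped)


def ba_random_network(n_mirnas: int, n_genes: int, n_edges: int, seed: int = 0) -> MTNetwork:
    """Bipartite preferential-attachment null network with exactly n_edges.

    Nodes are added in random order; each new node attaches to an existing
    opposite-side node with probability proportional to degree+1; remaining
    edges are then drawn by degree+1-weighted sampling on both sides until
    exactly n_edges distinct edges exist.  Deterministic given seed.
    """
    if n_mirnas < 1 or n_genes < 1:
        raise ValueError("both sides need at least one node")
    if not 0 < n_edges <= n_mirnas * n_genes:
        raise ValueError("infeasible edge count for a simple bipartite graph")
    rng = np.random.default_rng(seed)
    mirnas = [f"mir{i}" for i in range(n_mirnas)]
    genes = [f"gene{i}" for i in range(n_genes)]
    order = [("m", m) for m in mirnas] + [("g", g) for g in genes]
    order = [order[i] for i in rng.permutation(len(order))]
    deg: dict[str, int] = {}
    present = {"m": [], "g": []}
    edges: set[tuple[str, str]] = set()

    def attach(side: str, node: str) -> None:
        opposite = present["g" if side == "m" else "m"]
        if not opposite:
            return
        w = np.array([deg[o] + 1 for o in opposite], dtype=float)
        other = opposite[rng.choice(len(opposite), p=w / w.sum())]
        edge = (node, other) if side == "m" else (other, node)
        if edge not in edges and len(edges) < n_edges:
            edges.add(edge)
            deg[node] += 1
            deg[other] += 1

    for side, node in order:
        deg[node] = 0
        attach(side, node)
        present[side].append(node)
    while len(edges) < n_edges:
        wm = np.array([deg[m] + 1 for m in mirnas], dtype=float)
        wg = np.array([deg[g] + 1 for g in genes], dtype=float)
        m = mirnas[rng.choice(n_mirnas, p=wm / wm.sum())]
        t = genes[rng.choice(n_genes, p=wg / wg.sum())]
        if (m, t) not in edges:
            edges.add((m, t))
            deg[m] += 1
            deg[t] += 1
    g = nx.Graph()
    g.add_nodes_from(mirnas, side="mirna")
    g.add_nodes_from(genes, side="gene")
    g.add_edges_from(edges)
    return MTNetwork(graph=g, mirnas=set(mirnas), genes=set(genes))


# ---------------------------------------------------------------------------
# rank-sum comparison and enrichment
# ---------------------------------------------------------------------------

def exact_ranksum_p(x, y) -> float:
    """Two-sided exact rank-sum p by enumerating all C(n, |x|) labelings.

    Ties are handled through midranks; p = P(|W - E[W]| >= |W_obs - E[W]|).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n = len(pooled)
    k = len(x)
    w_obs = ranks[:k].sum()
    mean_w = k * (n + 1) / 2.0
    hits = total = 0
    for idx in combinations(range(n), k):
        w = ranks[list(idx)].sum()
        total += 1
        if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-9:
            hits += 1
    return hits / total


def compare_degree_distributions(net_a: MTNetwork, net_b: MTNetwork,
                                 exact_max_n: int = 12) -> float:
    """Two-sided Wilcoxon rank-sum p between the degree samples of two networks.

    Exact enumeration when the combined sample size is <= exact_max_n,
    otherwise the tie-corrected normal approximation.
    """
    a = net_a.all_degrees() if isinstance(net_a, MTNetwork) else np.asarray(net_a)
    b = net_b.all_degrees() if isinstance(net_b, MTNetwork) else np.asarray(net_b)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both degree samples must be non-empty")
    if len(a) + len(b) <= exact_max_n:
        return exact_ranksum_p(a, b)
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                           use_continuity=True)
    return float(res.pvalue)


def enrichment(
    target_genes, universe, pathways: dict[str, set], alpha: float = 0.05
) -> pd.DataFrame:
    """Hypergeometric over-representation of targets in each pathway, BH-corrected.

    Returns one row per pathway with overlap, p, q and a significance flag
    (q <= alpha).
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    targets = set(target_genes)
    if targets - universe:
        raise ValueError("target genes must be a subset of the universe")
    rows = []
    for name, members in pathways.items():
        members = set(members) & universe
        k = len(targets & members)
        p = float(sps.hypergeom.sf(k - 1, len(universe), len(members), len(targets)))
        rows.append((name, k, len(members), p))
    df = pd.DataFrame(rows, columns=["pathway", "overlap", "size", "p"]).set_index("pathway")
    if len(df):
        _, q, _, _ = multipletests(df["p"].to_numpy(), method="fdr_bh")
        df["q"] = q
    else:
        df["q"] = []
    df["significant"] = df["q"] <= alpha
    return df
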