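"""Expression thresholding and consistency statistics for miRNA profiles.

Implements RPM normalization, the Poisson background read threshold (random
genomic bins of fixed window size), genomic miRNA cluster definition
(inter-miRNA distance <= 10 kb), and four between-library consistency
statistics:

* ``Var`` - Jensen-Shannon divergence (log base 2) between the within-cluster
  member proportions of two libraries; 0 for identical profiles, at most
  1 bit.
* ``C.V.`` - coefficient of variation of cluster-summed expression over
  libraries.
* ``D.I.`` - differential index, the relative deviation of each miRNA from
  its across-library mean; rows sum to zero exactly.
* ``kappa`` - Cohen's kappa on binary expressed/not-expressed calls between
  two libraries, with a normal-approximation Z score against the
  no-agreement null.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


def normalize_rpm(count, mapped_total):
    """Reads per million mapped reads: count / mapped_total * 1e6."""
    if np.any(np.asarray(mapped_total) <= 0):
        raise ValueError("mapped_total must be positive")
    return count / mapped_total * 1e6


def rpm_matrix(matrix: pd.DataFrame, mapped_totals: pd.Series) -> pd.DataFrame:
    """Column-wise RPM normalization of a miRNA x library count matrix."""
    totals = mapped_totals.reindex(matrix.columns)
    if (totals <= 0).any():
        raise ValueError("mapped totals must be positive")
    return matrix / totals * 1e6


def poisson_threshold(
    total_mapped_reads: int,
    genome_length: int,
    window: int = 50,
    alpha: float = 1e-4,
    mode: str = "analytic",
    n_bins: int = 210_000,
    seed: int | None = None,
    read_positions=None,
) -> int:
    """Smallest integer T with P(X >= T | Poisson(lambda)) < alpha.

    ``analytic`` takes lambda = total_mapped_reads * window / genome_length
    (reads uniform over the genome); ``empirical`` samples ``n_bins`` random
    windows over the supplied read start positions and uses the mean
    observed count.  Counts above T are unlikely to arise from uniform
    background at level alpha.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if mode == "analytic":
        lam = total_mapped_reads * window / genome_length
    elif mode == "empirical":
        if read_positions is None:
            raise ValueError("empirical mode needs read start positions")
        rng = np.random.default_rng(seed)
        pos = np.sort(np.asarray(read_positions))
        starts = rng.integers(0, max(1, genome_length - window), size=n_bins)
        counts = np.searchsorted(pos, starts + window) - np.searchsorted(pos, starts)
        lam = counts.mean()
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if lam <= 0:
        raise ValueError("background rate lambda must be positive")
    t = 1
    while sps.poisson.sf(t - 1, lam) >= alpha:
        t += 1
    return t


def sharing_summary(detected_counts, n_shared) -> float:
    """Percent of expressed miRNAs shared by all libraries.

    The sharing percentage is the shared count over the largest per-library
    detected count, x100 (e.g. 304 shared of 326/329/326 detected -> 92.4%).
    """
    detected = list(detected_counts)
    if not detected or max(detected) <= 0:
        raise ValueError("need positive detected counts")
    if n_shared > min(detected):
        raise ValueError("shared count exceeds a per-library detected count")
    return 100.0 * n_shared / max(detected)


def expressed_sharing(matrix: pd.DataFrame, min_count: int = 1):
    """Detected-per-library counts, shared count and sharing percent from a matrix."""
    detected = (matrix >= min_count).sum(axis=0)
    shared = int((matrix >= min_count).all(axis=1).sum())
    return detected, shared, sharing_summary(detected.tolist(), shared)


# ---------------------------------------------------------------------------
# clusters
# ---------------------------------------------------------------------------

@dataclass
class MiRNACluster:
    members: list[str]
    chrom: str
    start: int
    end: int

    def __len__(self) -> int:
        return len(self.members)


def define_clusters(loci: pd.DataFrame, mid: int = 10_000) -> list[MiRNACluster]:
    """Chain consecutive miRNAs with inter-miRNA distance <= mid (inclusive).

    ``loci`` needs columns chrom and start (index = miRNA names); distance
    is between consecutive start positions on a chromosome.  Singletons are
    returned as one-member clusters.
    """
    clusters: list[MiRNACluster] = []
    for chrom, sub in loci.groupby("chrom", sort=True):
        sub = sub.sort_values("start")
        members: list[str] = []
        prev = None
        for name, row in sub.iterrows():
            if members and row["start"] - prev > mid:
                clusters.append(MiRNACluster(members, chrom, first, prev))
                members = []
            if not members:
                first = int(row["start"])
            members.append(name)
            prev = int(row["start"])
        if members:
            clusters.append(MiRNACluster(members, chrom, first, prev))
    return clusters


# ---------------------------------------------------------------------------
# consistency statistics
# ---------------------------------------------------------------------------

def _entropy2(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def jsd_bits(p, q) -> float:
    """Jensen-Shannon divergence in bits: H((p+q)/2) - (H(p)+H(q))/2."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    p = p / p.sum()
    q = q / q.sum()
    return _entropy2((p + q) / 2) - (_entropy2(p) + _entropy2(q)) / 2


def cluster_var(
    members, library_a: str, library_b: str, matrix: pd.DataFrame,
    pseudocount: float = 0.5,
) -> float:
    """Between-library divergence (bits) of within-cluster member proportions.

    A pseudocount is added to member counts before forming proportions; an
    all-zero cluster in both libraries is reported as missing (NaN).
    """
    members = list(getattr(members, "members", members))
    if len(members) < 2:
        raise ValueError("cluster Var needs >= 2 members")
    a = matrix.loc[members, library_a].to_numpy(dtype=float)
    b = matrix.loc[members, library_b].to_numpy(dtype=float)
    if a.sum() == 0 and b.sum() == 0:
        return float("nan")
    return jsd_bits(a + pseudocount, b + pseudocount)


def cluster_cv(members, matrix: pd.DataFrame) -> float:
    """Coefficient of variation of cluster-summed expression across libraries."""
    members = list(getattr(members, "members", members))
    totals = matrix.loc[members].sum(axis=0).to_numpy(dtype=float)
    if len(totals) < 2:
        raise ValueError("C.V. needs >= 2 libraries")
    mean = totals.mean()
    if mean == 0:
        return float("nan")
    return float(totals.std(ddof=1) / mean)


def diff_index(matrix: pd.DataFrame) -> pd.DataFrame:
    """Relative deviation from the per-miRNA mean: (x - mean) / mean.

    Rows with zero mean are excluded; each remaining row sums to zero
    exactly (up to float round-off).
    """
    means = matrix.mean(axis=1)
    kept = matrix.loc[means > 0]
    return kept.sub(means[means > 0], axis=0).div(means[means > 0], axis=0)


def kappa_agreement(
    matrix: pd.DataFrame, library_a: str, library_b: str,
    expressed_threshold: float = 30,
) -> tuple[float, float]:
    """Cohen's kappa and Z on binary expressed calls between two libraries.

    kappa = (P_o - P_e) / (1 - P_e) with P_e from the marginal call
    frequencies; Z = kappa / SE_0, SE_0 = sqrt(P_e / (N (1 - P_e))) under
    the no-agreement null.
    """
    n = len(matrix)
    if n == 0:
        raise ValueError("empty miRNA set")
    a = (matrix[library_a] >= expressed_threshold).to_numpy()
    b = (matrix[library_b] >= expressed_threshold).to_numpy()
    p_o = float((a == b).mean())
    pa, pb = float(a.mean()), float(b.mean())
    p_e = pa * pb + (1 - pa) * (1 - pb)
    if p_e == 1.0:
        kappa = 1.0 if p_o == 1.0 else 0.0
        return kappa, float("inf") if kappa == 1.0 else 0.0
    kappa = (p_o - p_e) / (1 - p_e)
    se0 = np.sqrt(p_e / (n * (1 - p_e)))
    return kappa, float(kappa / se0)


@dataclass
class ConsistencyReport:
    var: pd.DataFrame  # cluster x library-pair JSD (bits)
    cv: pd.Series  # per cluster
    di: pd.DataFrame  # miRNA x library differential index
    kappa: pd.DataFrame  # library-pair -> (kappa, Z)


def consistency_report(
    matrix: pd.DataFrame,
    loci: pd.DataFrame,
    mapped_totals: pd.Series,
    mid: int = 10_000,
    expressed_threshold: float = 30,
) -> ConsistencyReport:
    """Cluster Var/C.V. plus per-miRNA D.I. and pairwise kappa in one report."""
    rpm = rpm_matrix(matrix, mapped_totals)
    clusters = [c for c in define_clusters(loci.loc[loci.index.intersection(matrix.index)], mid)
                if len(c) >= 2]
    libs = list(matrix.columns)
    pairs = [(a, b) for i, a in enumerate(libs) for b in libs[i + 1:]]
    var = pd.DataFrame(
        {
            f"{a}|{b}": [cluster_var(c, a, b, matrix) for c in clusters]
            for a, b in pairs
        },
        index=[f"{c.chrom}:{c.start}" for c in clusters],
    )
    cv = pd.Series([cluster_cv(c, rpm) for c in clusters],
                   index=var.index, name="cv")
    expressed = matrix[(matrix >= expressed_threshold).any(axis=1)]
    di = diff_index(rpm.loc[expressed.index])
    kap = pd.DataFrame(
        [kappa_agreement(matrix, a, b, expressed_threshold) for a, b in pairs],
        index=[f"{a}|{b}" for a, b in pairs], columns=["kappa", "z"],
    )
    return ConsistencyReport(var=var, cv=cv, di=di, kappa=kap)
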