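"""Cross-species comparison of ESC miRNA expression profiles.

Profiles from different species (each the mean RPM over replicate samples)
are harmonized through a miRNA-name -> family homology map, restricted to
the family set detected in every species, and clustered hierarchically
(distance 1 - Pearson on log2(RPM+1), average linkage).  Named miRNA
clusters (e.g. a primate-specific cluster, an imprinted-region cluster)
are contrasted across species by summed RPM and a presence call.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform


def mean_profile(samples: pd.DataFrame) -> pd.Series:
    """Per-miRNA arithmetic mean of per-sample RPM columns."""
    if samples.shape[1] < 1:
        raise ValueError("need at least one sample")
    return samples.mean(axis=1)


def shared_set(
    profiles: dict[str, pd.Series],
    homology: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Family x species RPM matrix over families detected (RPM > 0) in every species.

    ``homology`` maps miRNA names to family keys (identity by default);
    members of one family are summed within a species.
    """
    if len(profiles) < 2:
        raise ValueError("need >= 2 species profiles")
    by_species = {}
    for sp, prof in profiles.items():
        fams = prof.index.to_series().map(lambda n: homology.get(n, n)) if homology else prof.index
        by_species[sp] = prof.groupby(list(fams)).sum()
    matrix = pd.DataFrame(by_species).fillna(0.0)
    shared = matrix.index[(matrix > 0).all(axis=1)]
    return matrix.loc[shared]


@dataclass
class SpeciesDendrogram:
    labels: list[str]
    linkage: np.ndarray  # scipy linkage matrix
    merges: list[tuple[frozenset, frozenset, float]]  # (left, right, height)
    newick: str

    def first_merge(self) -> frozenset:
        left, right, _ = self.merges[0]
        return left | right


def cluster_species(common: pd.DataFrame, linkage_method: str = "average") -> SpeciesDendrogram:
    """Hierarchical clustering of species on 1 - Pearson over log2(RPM+1)."""
    if common.shape[1] < 3:
        raise ValueError("need >= 3 species to cluster")
    if common.shape[0] < 2:
        raise ValueError("need >= 2 shared families")
    x = np.log2(common.to_numpy(dtype=float) + 1.0)
    if np.any(x.std(axis=0) == 0):
        bad = [c for c, s in zip(common.columns, x.std(axis=0)) if s == 0]
        raise ValueError(f"constant profile (zero variance): {bad}")
    corr = np.corrcoef(x.T)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    z = hierarchy.linkage(squareform(dist, checks=False), method=linkage_method)
    labels = list(common.columns)
    sets: list[frozenset] = [frozenset([l]) for l in labels]
    merges = []
    for a, b, h, _n in z:
        left, right = sets[int(a)], sets[int(b)]
        merges.append((left, right, float(h)))
        sets.append(left | right)
    tree = hierarchy.to_tree(z)

    def to_newick(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        length_l = (node.dist - node.left.dist) / 2
        length_r = (node.dist - node.right.dist) / 2
        return (f"({to_newick(node.left)}:{length_l:.6g},"
                f"{to_newick(node.right)}:{length_r:.6g})")

    return SpeciesDendrogram(labels=labels, linkage=z, merges=merges,
                             newick=to_newick(tree) + ";")


def contrast_named_clusters(
    profiles: dict[str, pd.Series],
    cluster_defs: dict[str, list[str]],
    presence_threshold_rpm: float = 1.0,
    clusters: list[str] | None = None,
) -> pd.DataFrame:
    """Summed RPM and presence call per named miRNA cluster per species.

    A cluster is present in a species when any member reaches the RPM
    threshold.  Requesting an undefined cluster name raises KeyError.
    """
    names = clusters if clusters is not None else list(cluster_defs)
    rows = []
    for name in names:
        if name not in cluster_defs:
            raise KeyError(f"undefined cluster {name!r}")
        members = cluster_defs[name]
        for sp, prof in profiles.items():
            vals = prof.reindex(members).fillna(0.0)
            rows.append((name, sp, float(vals.sum()),
                         bool((vals >= presence_threshold_rpm).any())))
    return pd.DataFrame(rows, columns=["cluster", "species", "total_rpm", "present"])
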