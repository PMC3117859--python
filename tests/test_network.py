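"""Seed-match prediction, MT network construction, degree-dN/dS and enrichment."""
import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import mirprof as mp
from mirprof._util import revcomp


# ---------------------------------------------------------------------------
# seed matching
# ---------------------------------------------------------------------------

MIRNA = "AUCAAGUAGGCUGUCCAUGUCU"  # seed (positions 2-8) = UCAAGUA


def test_predict_8mer():
    sites = mp.predict_sites(MIRNA, "GGGG" + "TACTTGAA" + "GGGG")
    assert [s.site_type for s in sites] == ["8mer"]


def test_predict_7mer_m8_without_trailing_a():
    sites = mp.predict_sites(MIRNA, "GGGG" + "TACTTGA" + "GGGG")
    assert [s.site_type for s in sites] == ["7mer-m8"]


def test_predict_7mer_a1():
    # core match for positions 2-7 followed by A, no m8 complement upstream
    sites = mp.predict_sites(MIRNA, "GGCC" + "ACTTGAA" + "GGGG")
    assert [s.site_type for s in sites] == ["7mer-A1"]


def test_predict_no_core_match_empty():
    assert mp.predict_sites(MIRNA, "GGGGGGGGGGGGGGGG") == []


def test_predict_overlapping_sites_all_reported():
    utr = "TACTTGAA" * 2
    sites = mp.predict_sites(MIRNA, utr)
    assert len(sites) >= 2


def test_predict_short_mirna_rejected():
    with pytest.raises(ValueError):
        mp.predict_sites("ACGUACG", "ACGT" * 10)


def test_classify_conservation_threshold_enumeration():
    site_block = "TACTTGAA"
    with_site = "GGGG" + site_block + "CCCC"
    without = "GGGG" + "TTTTTTTT" + "CCCC"
    ref_sites = mp.predict_sites(MIRNA, with_site)
    site = ref_sites[0]
    species = ["hsa", "ptr", "mml", "mmu", "rno", "cfa"]
    for n_with in (4, 6, 1):
        aligned = {sp: with_site if i < n_with else without
                   for i, sp in enumerate(species)}
        conserved4 = mp.classify_conservation(site, aligned, "hsa", MIRNA, min_species=4)
        conserved5 = mp.classify_conservation(site, aligned, "hsa", MIRNA, min_species=5)
        assert conserved4 == (n_with >= 4)
        assert conserved5 == (n_with >= 5)


def test_classify_conservation_handles_gaps():
    site_block = "TACTTGAA"
    ref = "GG--GG" + site_block + "CC"
    other = "GGAAGG" + site_block + "CC"
    site = mp.predict_sites(MIRNA, ref.replace("-", ""))[0]
    assert mp.classify_conservation(site, {"hsa": ref, "ptr": other}, "hsa",
                                    MIRNA, min_species=2)


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

def test_build_network_counting_and_dedup():
    pairs = pd.DataFrame({"mirna": ["m1", "m1", "m2", "m1"],
                          "gene": ["g1", "g2", "g1", "g1"]})
    net = mp.build_network(pairs)
    assert net.n_edges == 3
    assert net.gene_degrees()["g1"] == 2
    assert net.mirna_degrees()["m1"] == 2


def test_build_network_random_pairs_edge_count():
    rng = np.random.default_rng(1)
    pairs = pd.DataFrame({"mirna": [f"m{i}" for i in rng.integers(0, 20, 200)],
                          "gene": [f"g{i}" for i in rng.integers(0, 50, 200)]})
    net = mp.build_network(pairs)
    assert net.n_edges == len(pairs.drop_duplicates())


def test_degree_sum_conservation():
    targets, _ = mp.generate_target_table(30, 200, slope=-0.02, seed=3)
    net = mp.build_network(targets)
    assert net.mirna_degrees().sum() == net.gene_degrees().sum() == net.n_edges


# ---------------------------------------------------------------------------
# degree vs dN/dS
# ---------------------------------------------------------------------------

def test_pearson_p_matches_printed_pair():
    # r=-0.564 with 17 points -> p ~ 0.018 (t transform, df=15)
    assert mp.pearson_p_from_r(-0.564, 17) == pytest.approx(0.018, abs=0.001)


def test_perfect_anticorrelation_across_bins():
    rows = []
    for deg in (1, 2, 3):
        for k in range(12):
            rows.append((f"g{deg}_{k}", deg, 0.5 - 0.1 * deg))
    genes = pd.DataFrame(rows, columns=["gene", "degree", "dnds"]).set_index("gene")
    pairs = [(f"m{j}", g) for g, row in genes.iterrows()
             for j in range(int(row["degree"]))]
    net = mp.build_network(pd.DataFrame(pairs, columns=["mirna", "gene"]))
    evolution = genes[["dnds"]].assign(utr_length=1000)
    r, p, n_bins = mp.degree_dnds_correlation(net, evolution, min_genes_per_bin=10)
    assert n_bins == 3
    assert r == pytest.approx(-1.0)


def test_too_few_bins_errors():
    genes = pd.DataFrame({"gene": ["g1", "g2"], "dnds": [0.1, 0.2],
                          "utr_length": [500, 700]}).set_index("gene")
    net = mp.build_network(pd.DataFrame({"mirna": ["m1", "m1"], "gene": ["g1", "g2"]}))
    with pytest.raises(ValueError):
        mp.degree_dnds_correlation(net, genes, min_genes_per_bin=1)


def test_utr_normalization_modes():
    targets, evolution = mp.generate_target_table(30, 400, slope=-0.02, seed=5)
    net = mp.build_network(targets)
    for k in (1, 2):
        r, p, n = mp.degree_dnds_correlation(net, evolution, normalize_per_kb=k,
                                             min_genes_per_bin=5)
        assert -1 <= r <= 1 and 0 <= p <= 1
    with pytest.raises(ValueError):
        mp.degree_dnds_correlation(net, evolution, normalize_per_kb=3)


# ---------------------------------------------------------------------------
# BA null network
# ---------------------------------------------------------------------------

def test_ba_network_contract_and_determinism():
    net = mp.ba_random_network(50, 500, 1500, seed=0)
    assert net.n_edges == 1500
    assert all(net.graph.nodes[n]["side"] in ("mirna", "gene") for n in net.graph)
    for u, v in net.graph.edges():
        assert net.graph.nodes[u]["side"] != net.graph.nodes[v]["side"]
    net2 = mp.ba_random_network(50, 500, 1500, seed=0)
    assert sorted(net.graph.edges()) == sorted(net2.graph.edges())
    net3 = mp.ba_random_network(50, 500, 1500, seed=1)
    assert sorted(net.graph.edges()) != sorted(net3.graph.edges())


def test_ba_network_infeasible_edges():
    with pytest.raises(ValueError):
        mp.ba_random_network(3, 3, 10, seed=0)


def test_ba_heavier_tailed_than_erdos_renyi():
    """Preferential attachment produces larger hub degrees than a uniform
    random bipartite graph with the same n and m."""
    rng = np.random.default_rng(0)
    n_m, n_g, m = 30, 200, 600
    wins = 0
    trials = 100
    for seed in range(trials):
        ba = mp.ba_random_network(n_m, n_g, m, seed=seed)
        # Erdos-Renyi style null: m distinct uniform pairs
        er_edges = set()
        while len(er_edges) < m:
            er_edges.add((int(rng.integers(n_m)), int(rng.integers(n_g))))
        er_deg = np.zeros(n_m + n_g, dtype=int)
        for a, b in er_edges:
            er_deg[a] += 1
            er_deg[n_m + b] += 1
        wins += ba.all_degrees().max() > er_deg.max()
    assert wins >= 90


# ---------------------------------------------------------------------------
# rank-sum and enrichment
# ---------------------------------------------------------------------------

def test_ranksum_identical_samples():
    d = np.array([1, 2, 3])
    assert mp.exact_ranksum_p(d, d) == pytest.approx(1.0)


def test_ranksum_exact_enumeration_example():
    assert mp.exact_ranksum_p([1, 2, 3], [10, 11, 12]) == pytest.approx(0.1)


def test_ranksum_exact_vs_asymptotic_at_n12():
    rng = np.random.default_rng(4)
    a = rng.normal(0, 1, 6)
    b = rng.normal(1.0, 1, 6)
    exact = mp.exact_ranksum_p(a, b)
    approx = float(sps.mannwhitneyu(a, b, alternative="two-sided",
                                    method="asymptotic", use_continuity=True).pvalue)
    assert abs(exact - approx) < 0.02


def test_compare_degree_distributions_detects_inflation():
    planted = mp.build_network(mp.generate_target_table(30, 400, slope=0.0, seed=7,
                                                        degree_max=22)[0])
    null = mp.ba_random_network(30, 400, planted.n_edges // 3, seed=7)
    p = mp.compare_degree_distributions(planted, null)
    assert p < 1e-6


def test_enrichment_exact_combinatorics():
    universe = [f"g{i}" for i in range(20)]
    pathways = {"pw": set(universe[:5])}
    res = mp.enrichment(universe[:5], universe, pathways)
    assert res.loc["pw", "p"] == pytest.approx(1 / math.comb(20, 5))
    assert res.loc["pw", "overlap"] == 5


def test_enrichment_at_expectation_not_significant():
    universe = [f"g{i}" for i in range(100)]
    pathway = set(universe[:20])
    targets = universe[:4] + universe[20:36]  # overlap 4 = expectation of 20%*20
    res = mp.enrichment(targets, universe, {"pw": pathway})
    assert res.loc["pw", "p"] > 0.5


def test_bh_step_up_formula_oracle():
    universe = [f"g{i}" for i in range(10)]
    df = mp.enrichment(universe[:2], universe, {"a": set(universe[:2]),
                                                "b": set(universe[:3]),
                                                "c": set(universe[2:])})
    # independent oracle: the textbook step-up on the same p-values
    ps = df["p"].to_numpy()
    order = np.argsort(ps)
    m = len(ps)
    q_sorted = np.minimum.accumulate((ps[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    q_expected = np.empty(m)
    q_expected[order] = np.clip(q_sorted, 0, 1)
    assert np.allclose(df["q"].to_numpy(), q_expected)
    assert (df["q"] >= df["p"] - 1e-12).all()


def test_bh_printed_example():
    from statsmodels.stats.multitest import multipletests

    _, q, _, _ = multipletests([0.01, 0.02, 0.04], method="fdr_bh")
    assert np.allclose(q, [0.03, 0.03, 0.04])


def test_enrichment_errors():
    with pytest.raises(ValueError):
        mp.enrichment(["g1"], [], {})
    with pytest.raises(ValueError):
        mp.enrichment(["gX"], ["g1"], {})
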