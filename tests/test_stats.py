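"""RPM, Poisson threshold, miRNA clusters and the four consistency statistics."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import mirprof as mp


# ---------------------------------------------------------------------------
# RPM
# ---------------------------------------------------------------------------

def test_rpm_examples():
    assert mp.normalize_rpm(500, 10**6) == 500.0
    assert mp.normalize_rpm(0, 10**6) == 0.0
    assert mp.normalize_rpm(123, 7.5e6) == pytest.approx(16.4)
    with pytest.raises(ValueError):
        mp.normalize_rpm(1, 0)


def test_rpm_matrix_columns():
    m = pd.DataFrame({"L1": [10, 20], "L2": [5, 5]}, index=["a", "b"])
    rpm = mp.rpm_matrix(m, pd.Series({"L1": 100, "L2": 50}))
    assert rpm.loc["a", "L1"] == pytest.approx(1e5)
    assert rpm.loc["a", "L2"] == pytest.approx(1e5)


# ---------------------------------------------------------------------------
# Poisson threshold
# ---------------------------------------------------------------------------

def test_poisson_threshold_lambda_01():
    # direct pmf-summation oracle gives T=4 for lambda=0.1, alpha=1e-4
    t = mp.poisson_threshold(total_mapped_reads=2000, genome_length=1_000_000,
                             window=50, alpha=1e-4)
    assert t == 4


def test_poisson_threshold_small_lambda_limit():
    assert mp.poisson_threshold(1, 10**9, window=50, alpha=1e-4) == 1


def test_poisson_threshold_against_pmf_summation_oracle():
    for lam_reads, glen in [(2000, 1_000_000), (100_000, 1_000_000), (5_000, 200_000)]:
        for alpha in (1e-4, 1e-3, 0.01):
            t = mp.poisson_threshold(lam_reads, glen, window=50, alpha=alpha)
            lam = lam_reads * 50 / glen
            # brute-force tail: 1 - sum of pmf below t
            tail_at_t = 1.0 - sum(math.exp(-lam) * lam**k / math.factorial(k)
                                  for k in range(t))
            tail_below = 1.0 - sum(math.exp(-lam) * lam**k / math.factorial(k)
                                   for k in range(t - 1))
            assert tail_at_t < alpha <= tail_below or t == 1


def test_poisson_threshold_monotonicity():
    t_loose = mp.poisson_threshold(10**5, 10**6, alpha=1e-2)
    t_tight = mp.poisson_threshold(10**5, 10**6, alpha=1e-5)
    assert t_tight >= t_loose
    t_lo = mp.poisson_threshold(10**4, 10**6, alpha=1e-4)
    t_hi = mp.poisson_threshold(10**6, 10**6, alpha=1e-4)
    assert t_hi >= t_lo


def test_poisson_threshold_empirical_agrees_with_analytic():
    rng = np.random.default_rng(0)
    glen = 500_000
    agree = 0
    for seed in range(20):
        positions = rng.integers(0, glen, size=20_000)
        t_emp = mp.poisson_threshold(20_000, glen, mode="empirical", n_bins=20_000,
                                     seed=seed, read_positions=positions)
        t_ana = mp.poisson_threshold(20_000, glen, mode="analytic")
        agree += t_emp == t_ana
    assert agree >= 19


def test_poisson_threshold_errors():
    with pytest.raises(ValueError):
        mp.poisson_threshold(0, 10**6)
    with pytest.raises(ValueError):
        mp.poisson_threshold(100, 10**6, alpha=1.5)
    with pytest.raises(ValueError):
        mp.poisson_threshold(100, 10**6, mode="empirical")


# ---------------------------------------------------------------------------
# sharing and clusters
# ---------------------------------------------------------------------------

def test_sharing_summary_printed_counts():
    assert mp.sharing_summary([326, 329, 326], 304) == pytest.approx(92.4, abs=0.01)


def test_expressed_sharing_from_matrix():
    m = pd.DataFrame({"L1": [5, 3, 0, 2], "L2": [1, 0, 4, 2], "L3": [2, 1, 1, 2]})
    detected, shared, pct = mp.expressed_sharing(m)
    assert detected.tolist() == [3, 3, 4]
    assert shared == 2
    assert pct == pytest.approx(50.0)


def _loci(starts, chrom="chr1"):
    return pd.DataFrame({"chrom": chrom, "start": starts},
                        index=[f"m{i}" for i in range(len(starts))])


def test_define_clusters_partition():
    clusters = mp.define_clusters(_loci([0, 5_000, 17_000]))
    assert sorted(len(c) for c in clusters) == [1, 2]


def test_define_clusters_singleton():
    clusters = mp.define_clusters(_loci([100]))
    assert len(clusters) == 1 and len(clusters[0]) == 1


def test_define_clusters_gap_exactly_mid_is_inclusive():
    clusters = mp.define_clusters(_loci([0, 10_000]))
    assert len(clusters) == 1 and len(clusters[0]) == 2


# ---------------------------------------------------------------------------
# Var (JSD), C.V., D.I., kappa
# ---------------------------------------------------------------------------

def _matrix(rows):
    return pd.DataFrame(rows, columns=["L1", "L2", "L3"]).rename(
        index=lambda i: f"m{i}")


def test_var_identical_proportions_is_zero():
    m = _matrix([[10, 10, 5], [30, 30, 15]])
    assert mp.cluster_var(["m0", "m1"], "L1", "L2", m) == pytest.approx(0.0, abs=1e-12)
    # identical underlying proportions at different depth: pseudocount keeps
    # the divergence near (but not exactly) zero
    m2 = _matrix([[10, 20, 5], [30, 60, 15]])
    assert mp.cluster_var(["m0", "m1"], "L1", "L2", m2) < 1e-4


def test_jsd_maximal_one_bit():
    assert mp.jsd_bits([1, 0], [0, 1]) == pytest.approx(1.0)


def test_var_hand_formula_oracle():
    # p=(0.5,0.5), q=(0.9,0.1): H(m)-((H(p)+H(q))/2 with m=(0.7,0.3)
    def h(p):
        return -sum(x * math.log2(x) for x in p if x > 0)

    expected = h([0.7, 0.3]) - (h([0.5, 0.5]) + h([0.9, 0.1])) / 2
    assert expected == pytest.approx(0.146793, abs=1e-6)
    assert mp.jsd_bits([0.5, 0.5], [0.9, 0.1]) == pytest.approx(expected)


def test_var_all_zero_cluster_missing():
    m = _matrix([[0, 0, 5], [0, 0, 15]])
    assert math.isnan(mp.cluster_var(["m0", "m1"], "L1", "L2", m))


@settings(derandomize=True, max_examples=50)
@given(st.lists(st.tuples(st.integers(0, 1000), st.integers(0, 1000)),
                min_size=2, max_size=8))
def test_var_symmetric_and_bounded(counts):
    m = pd.DataFrame({"L1": [a for a, _ in counts], "L2": [b for _, b in counts],
                      "L3": 0}, index=[f"m{i}" for i in range(len(counts))])
    v_ab = mp.cluster_var(list(m.index), "L1", "L2", m)
    v_ba = mp.cluster_var(list(m.index), "L2", "L1", m)
    if math.isnan(v_ab):
        assert math.isnan(v_ba)
        return
    assert v_ab == pytest.approx(v_ba)
    assert -1e-12 <= v_ab <= 1.0 + 1e-12


def test_cv_examples():
    m = _matrix([[100, 100, 100]])
    assert mp.cluster_cv(["m0"], m) == 0.0
    m744 = _matrix([[11447, 24797, 14171]])
    assert mp.cluster_cv(["m0"], m744) == pytest.approx(0.4198, abs=2e-4)
    m3 = _matrix([[0, 0, 10]])
    assert mp.cluster_cv(["m0"], m3) == pytest.approx(math.sqrt(3))


def test_cv_zero_mean_missing():
    assert math.isnan(mp.cluster_cv(["m0"], _matrix([[0, 0, 0]])))


def test_diff_index_examples():
    m = _matrix([[100, 100, 100], [90, 100, 110], [30, 60, 90]])
    di = mp.diff_index(m)
    assert di.loc["m0"].tolist() == [0, 0, 0]
    assert di.loc["m1"].tolist() == pytest.approx([-0.1, 0, 0.1])
    assert di.loc["m2"].tolist() == pytest.approx([-0.5, 0, 0.5])


def test_diff_index_rows_sum_to_zero(deep_pipeline):
    rpm = mp.rpm_matrix(deep_pipeline.ann.expression, deep_pipeline.ann.mapped_totals)
    di = mp.diff_index(rpm)
    assert np.allclose(di.sum(axis=1).to_numpy(), 0.0, atol=1e-9)


def test_kappa_identical_calls():
    m = _matrix([[100, 100, 0], [0, 0, 0], [50, 50, 0], [10, 10, 0]])
    kappa, z = mp.kappa_agreement(m, "L1", "L2", expressed_threshold=30)
    assert kappa == pytest.approx(1.0)
    assert z > 0


def test_kappa_formula_oracle():
    # N=100; both libraries call 80 expressed; 70 jointly expressed ->
    # P_o=0.8, P_e=0.68, kappa=0.375
    a = np.zeros(100)
    b = np.zeros(100)
    a[:80] = 100
    b[:70] = 100
    b[80:90] = 100
    m = pd.DataFrame({"L1": a, "L2": b})
    kappa, z = mp.kappa_agreement(m, "L1", "L2", expressed_threshold=30)
    assert kappa == pytest.approx(0.375)
    se0 = math.sqrt(0.68 / (100 * 0.32))
    assert z == pytest.approx(0.375 / se0)


def test_kappa_independent_calls_near_zero():
    rng = np.random.default_rng(0)
    a = (rng.random(1000) < 0.6) * 100
    b = (rng.random(1000) < 0.6) * 100
    kappa, _ = mp.kappa_agreement(pd.DataFrame({"L1": a, "L2": b}), "L1", "L2")
    assert abs(kappa) < 0.05


def test_kappa_symmetric(deep_pipeline):
    expr = deep_pipeline.ann.expression
    k_ab = mp.kappa_agreement(expr, expr.columns[0], expr.columns[1])
    k_ba = mp.kappa_agreement(expr, expr.columns[1], expr.columns[0])
    assert k_ab == pytest.approx(k_ba)


def test_kappa_empty_matrix_errors():
    with pytest.raises(ValueError):
        mp.kappa_agreement(pd.DataFrame({"L1": [], "L2": []}), "L1", "L2")


def test_consistency_report_shapes(deep_pipeline):
    ds = deep_pipeline.dataset
    loci = pd.DataFrame(
        {"chrom": [p.chrom for p in ds.truth.precursors for _ in ("5p", "3p")],
         "start": [p.start for p in ds.truth.precursors for _ in ("5p", "3p")]},
        index=[p.mature_name(a) for p in ds.truth.precursors for a in ("5p", "3p")],
    )
    report = mp.consistency_report(deep_pipeline.ann.expression, loci,
                                   deep_pipeline.ann.mapped_totals)
    assert set(report.kappa.columns) == {"kappa", "z"}
    assert len(report.kappa) == 3  # three library pairs
    assert ((report.var.dropna() >= 0) & (report.var.dropna() <= 1)).all().all()
    assert (report.kappa["kappa"] > 0.5).all()  # concordant libraries agree
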