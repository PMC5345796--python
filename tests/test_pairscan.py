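import itertools
from math import comb, inf, log10

import numpy as np
import pytest
from scipy.stats import binom, kstest

from epistax.pairscan import (
    GssResult,
    PairTable,
    bonferroni_threshold,
    calibrate_pvalues,
    exhaustive_scan,
    genomic_lambda,
    gss_statistic,
    n_pairs,
    or_gss,
    pair_contingency,
    permuted_scan_pvalues,
    scan_pvalues,
    single_snp_roc,
)
from epistax.cohort import MISSING
from epistax.simulate import SimulationConfig, simulate_cohort
from tests.conftest import make_study


def table_from_counts(case_cells, ctrl_cells):
    counts = np.zeros((2, 9), dtype=np.int64)
    counts[1] = case_cells
    counts[0] = ctrl_cells
    return PairTable(counts)


# ---------------------------------------------------------------------------
# pair_contingency
# ---------------------------------------------------------------------------


def test_pair_contingency_cells():
    geno = np.array([[0, 0], [0, 0], [2, 2]], dtype=np.int8)
    study = make_study(geno, [1, 1, 0])
    t = pair_contingency(study, 0, 1)
    assert t.counts[1, 0] == 2  # two cases at cell 1
    assert t.counts[0, 8] == 1  # one control at cell 9
    assert t.counts.sum() == 3


def test_pair_contingency_excludes_missing():
    geno = np.array([[0, 0], [1, MISSING], [2, 2]], dtype=np.int8)
    study = make_study(geno, [1, 1, 0])
    t = pair_contingency(study, 0, 1)
    assert t.n_cases == 1 and t.n_controls == 1


def test_pair_contingency_same_snp_errors(tiny_study):
    with pytest.raises(ValueError):
        pair_contingency(tiny_study, 1, 1)


def test_pair_contingency_matches_naive_counting(rng):
    geno = rng.integers(0, 3, size=(60, 4)).astype(np.int8)
    geno[rng.random(geno.shape) < 0.1] = MISSING
    pheno = rng.integers(0, 2, size=60)
    study = make_study(geno, pheno)
    t = pair_contingency(study, 0, 3)
    # naive per-sample iteration oracle
    naive = np.zeros((2, 9), dtype=int)
    for i in range(60):
        ga, gb = geno[i, 0], geno[i, 3]
        if ga == MISSING or gb == MISSING:
            continue
        naive[pheno[i], 3 * ga + gb] += 1
    np.testing.assert_array_equal(t.counts, naive)


# ---------------------------------------------------------------------------
# single-SNP ROC
# ---------------------------------------------------------------------------


def test_roc_perfect_separation():
    t = table_from_counts([10, 0, 0, 0, 0, 0, 0, 0, 0], [0, 0, 0, 10, 0, 0, 0, 0, 0])
    pts = single_snp_roc(t, "A")
    assert (1.0, 1.0) in pts


def test_roc_identical_margins_collapse_to_diagonal_endpoints():
    t = table_from_counts([3, 3, 3, 0, 0, 0, 0, 0, 0], [3, 3, 3, 0, 0, 0, 0, 0, 0])
    pts = single_snp_roc(t, "B")
    assert pts[0] == (0.0, 1.0)
    assert pts[-1] == (1.0, 0.0)
    # all odds tie -> single merged step
    assert len(pts) == 2


def test_roc_dominates_all_genotype_subsets(rng):
    for _ in range(20):
        case = rng.integers(0, 20, size=9)
        ctrl = rng.integers(0, 20, size=9)
        if case.sum() == 0 or ctrl.sum() == 0:
            continue
        t = table_from_counts(case, ctrl)
        pts = single_snp_roc(t, "A")
        mc = case.reshape(3, 3).sum(axis=1)
        md = ctrl.reshape(3, 3).sum(axis=1)
        # staircase through the hull points
        xs = np.array([1 - sp for se, sp in pts])
        ys = np.array([se for se, sp in pts])
        # oracle: every one of the 2^3 genotype subsets lies on/below the hull
        for subset in itertools.product([0, 1], repeat=3):
            sens = sum(mc[g] for g in range(3) if subset[g]) / mc.sum()
            fpr = sum(md[g] for g in range(3) if subset[g]) / md.sum()
            hull_sens = np.interp(fpr, xs, np.maximum.accumulate(ys))
            assert sens <= hull_sens + 1e-12


# ---------------------------------------------------------------------------
# the pair statistic
# ---------------------------------------------------------------------------


def test_gss_duplicate_locus_not_significant():
    # snp_b identical to snp_a: only diagonal cells occupied
    case = np.zeros(9, int)
    ctrl = np.zeros(9, int)
    case[[0, 4, 8]] = [30, 50, 20]
    ctrl[[0, 4, 8]] = [40, 45, 15]
    r = gss_statistic(table_from_counts(case, ctrl))
    assert r.p_raw > 0.01


def test_gss_xor_table_extreme():
    case = np.zeros(9, int)
    ctrl = np.zeros(9, int)
    case[[0, 4, 8]] = [50, 100, 50]
    ctrl[[2, 6]] = [100, 100]
    t = table_from_counts(case, ctrl)
    r = gss_statistic(t)
    # neither margin gets close; pair must win by >= 6 orders of magnitude
    worst_margin = max(
        gss_statistic(table_from_counts(case * 0 + case, ctrl * 0 + ctrl)).log10_p_raw, -300
    )
    assert r.log10_p_raw < -6
    assert r.high_risk_cells == frozenset({1, 5, 9})


def test_gss_symmetric_in_pair_order(rng):
    for _ in range(30):
        case = rng.integers(0, 30, size=(3, 3))
        ctrl = rng.integers(0, 30, size=(3, 3))
        if case.sum() == 0 or ctrl.sum() == 0:
            continue
        t1 = table_from_counts(case.reshape(9), ctrl.reshape(9))
        t2 = table_from_counts(case.T.reshape(9), ctrl.T.reshape(9))
        assert gss_statistic(t1).log10_p_raw == pytest.approx(
            gss_statistic(t2).log10_p_raw, abs=1e-9
        )


def test_gss_empty_class_errors():
    t = table_from_counts([1, 0, 0, 0, 0, 0, 0, 0, 0], [0] * 9)
    with pytest.raises(ValueError):
        gss_statistic(t)


def test_gss_p_floor_never_zero():
    case = np.zeros(9, int)
    ctrl = np.zeros(9, int)
    case[[0, 4, 8]] = [500, 1000, 500]
    ctrl[[2, 6]] = [1000, 1000]
    r = gss_statistic(table_from_counts(case, ctrl))
    assert r.p_raw > 0.0
    assert r.log10_p_raw >= -300


def test_gss_rank_uniform_under_label_permutation(rng):
    # permuting labels of a fixed genotype draw: the observed statistic's
    # randomized rank (PIT with uniform tie-breaking, exact under
    # exchangeability) among permutation replicates is uniform
    n = 80
    ga = rng.integers(0, 3, size=n).astype(np.int8)
    gb = rng.integers(0, 3, size=n).astype(np.int8)
    pheno = np.array([1] * (n // 2) + [0] * (n // 2), dtype=np.int8)

    def stat():
        perm = rng.permutation(n)
        cnt = np.zeros((2, 9), dtype=int)
        np.add.at(cnt, (pheno[perm], 3 * ga + gb), 1)
        return gss_statistic(PairTable(cnt)).log10_p_raw

    ranks = []
    for rep in range(300):
        stats = np.array([stat() for _ in range(19)])
        obs = stat()
        less, equal = np.sum(stats < obs), np.sum(stats == obs)
        ranks.append((less + rng.uniform() * (equal + 1)) / 20)
    assert kstest(ranks, "uniform").pvalue > 0.01


# ---------------------------------------------------------------------------
# OR_GSS
# ---------------------------------------------------------------------------


def test_or_gss_printed_formula():
    # pi(1,HR)=0.6, pi(0,HR)=0.3 -> (0.6*0.7)/(0.3*0.4) = 3.5
    case = [60, 0, 0, 0, 0, 0, 40, 0, 0]
    ctrl = [30, 0, 0, 0, 0, 0, 70, 0, 0]
    val, flag = or_gss(table_from_counts(case, ctrl), {1})
    assert val == pytest.approx(3.5)
    assert not flag


def test_or_gss_identical_distributions_is_one():
    case = [10, 20, 5, 0, 0, 0, 0, 0, 15]
    val, _ = or_gss(table_from_counts(case, case), {1, 2})
    assert val == pytest.approx(1.0)


def test_or_gss_degenerate_infinite():
    case = [50, 0, 0, 0, 0, 0, 0, 0, 0]
    ctrl = [0, 0, 0, 0, 0, 0, 0, 0, 50]
    val, flag = or_gss(table_from_counts(case, ctrl), {1})
    assert val == inf and flag


def test_or_gss_bad_hr_sets_error():
    t = table_from_counts([5, 5, 0, 0, 0, 0, 0, 0, 0], [5, 5, 0, 0, 0, 0, 0, 0, 0])
    with pytest.raises(ValueError):
        or_gss(t, set())
    with pytest.raises(ValueError):
        or_gss(t, {1, 2})


# ---------------------------------------------------------------------------
# thresholds and pair counts
# ---------------------------------------------------------------------------


def test_bonferroni_uk1_panel():
    assert bonferroni_threshold(301546) == pytest.approx(1.1e-12, rel=0.005)


def test_bonferroni_single_pair():
    assert bonferroni_threshold(2) == 0.05


def test_bonferroni_670quad_panel():
    # direct arithmetic gives 3.764e-13 (the printed 3.75e-13 differs)
    assert bonferroni_threshold(515413) == pytest.approx(0.05 / comb(515413, 2))
    assert bonferroni_threshold(515413) == pytest.approx(3.764e-13, rel=0.001)


def test_pair_counts_from_panel_sizes():
    assert round(n_pairs(301546) / 1e9) == 45
    assert round(n_pairs(515413) / 1e9) == 133
    assert n_pairs(3) == 3


# ---------------------------------------------------------------------------
# scan engine
# ---------------------------------------------------------------------------


def _random_study(rng, n=80, m=8, missing=0.0):
    geno = rng.integers(0, 3, size=(n, m)).astype(np.int8)
    if missing:
        geno[rng.random(geno.shape) < missing] = MISSING
    pheno = np.array([1] * (n // 2) + [0] * (n - n // 2))
    return make_study(geno, pheno)


def test_scan_touches_all_pairs(rng):
    study = _random_study(rng, m=7)
    iu, ju, lp, hb = scan_pvalues(study)
    assert len(iu) == comb(7, 2)


def test_scan_engine_matches_naive_loop(rng):
    study = _random_study(rng, m=8, missing=0.05)
    iu, ju, lp, hb = scan_pvalues(study)
    for k in range(len(iu)):
        r = gss_statistic(pair_contingency(study, int(iu[k]), int(ju[k])))
        assert lp[k] == pytest.approx(r.log10_p_raw, abs=1e-9)
        bits = sum(1 << (c - 1) for c in r.high_risk_cells)
        assert hb[k] == bits


def test_scan_results_invariant_to_column_order(rng):
    study = _random_study(rng, m=6)
    perm = rng.permutation(6)
    geno2 = study.genotypes[:, perm]
    study2 = make_study(geno2, study.phenotype)
    _, _, lp1, _ = scan_pvalues(study)
    _, _, lp2, _ = scan_pvalues(study2)
    assert sorted(np.round(lp1, 9)) == sorted(np.round(lp2, 9))


def test_exhaustive_scan_stream(rng):
    study = _random_study(rng, m=5)
    results = list(exhaustive_scan(study, report_threshold=1.0))
    assert len(results) == comb(5, 2)
    assert all(isinstance(r, GssResult) for r in results)
    assert all(0 < r.p_raw <= 1 for r in results)


def test_scan_too_few_snps_errors(rng):
    study = _random_study(rng, m=1)
    with pytest.raises(ValueError):
        scan_pvalues(study)


# ---------------------------------------------------------------------------
# permutation calibration
# ---------------------------------------------------------------------------


def test_calibration_identity_on_uniform_null(rng):
    null = rng.uniform(size=100_000)
    obs = rng.uniform(size=5_000)
    adj = calibrate_pvalues(obs, null)
    assert np.max(np.abs(adj - obs)) < 0.02


def test_calibration_preserves_monotonicity(rng):
    null = rng.uniform(size=10_000)
    obs = np.sort(rng.uniform(1e-9, 1, size=500))
    adj = calibrate_pvalues(obs, null)
    assert (np.diff(adj) >= -1e-15).all()


def test_calibration_empty_pool_errors():
    with pytest.raises(ValueError):
        calibrate_pvalues([0.5], [])


def test_calibrated_null_scan_lambda_near_one():
    cfg = SimulationConfig(
        n_cases=500,
        n_controls=500,
        seed=3,
        n_blocks=400,
        snps_per_block=1,
        prevalence=0.1,
    )
    study = simulate_cohort(cfg)
    _, _, lp, _ = scan_pvalues(study)
    null_pool = permuted_scan_pvalues(study, seed=11)
    adj = calibrate_pvalues(lp, null_pool, include_observed=True)
    lam = genomic_lambda(adj)
    assert lam == pytest.approx(1.0, abs=0.05)
    # central quantiles of the adjusted distribution stay near uniform
    # (a literal KS test is over-sensitive here: pair statistics are
    # strongly correlated through the shared samples)
    for q in (0.25, 0.5, 0.75):
        assert np.quantile(adj, q) == pytest.approx(q, abs=0.05)


def test_adjusted_pvalues_uniform_under_global_null(rng):
    # spec invariant: adjusted p-values from the identity-like map on a
    # uniform pool are uniform at n = 1e4
    null = rng.uniform(size=50_000)
    obs = rng.uniform(size=10_000)
    adj = calibrate_pvalues(obs, null)
    assert kstest(adj, "uniform").pvalue > 0.01
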