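"""Exhaustive SNP-pair scan with a discrimination-gain statistic.

The pair statistic asks whether the 9-cell genotype combination of two SNPs
discriminates cases from controls significantly better than either SNP
alone.  Cells are ranked by case:control odds; each prefix of the ranking is
an ROC operating point, and the pair's p-value is the chance that a
classifier no better than the best single SNP attains the pair's best
operating point.  Raw p-values are computed in log space and recalibrated
against a label-permuted scan of the same study.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import comb, inf, log

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import binom, chi2

from epistax.cohort import MISSING, GenotypeStudy

logger = logging.getLogger(__name__)

#: natural-log floor corresponding to p = 1e-300
_LOG_P_FLOOR = log(1e-300)


@dataclass
class PairTable:
    """2 x 9 case/control counts over the genotype combinations of a pair.

    Cell ``v`` (1..9) holds samples with ``3*g_a + g_b + 1 == v``; row 0 is
    controls, row 1 cases.  Totals cover pairwise-complete samples only.
    """

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (2, 9):
            raise ValueError("counts must be 2x9")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def n_controls(self) -> int:
        return int(self.counts[0].sum())

    @property
    def n_cases(self) -> int:
        return int(self.counts[1].sum())


@dataclass
class GssResult:
    """Scan result for one SNP pair."""

    pair: tuple[str, str] | tuple[int, int] | None
    p_raw: float
    log10_p_raw: float
    high_risk_cells: frozenset
    gain_over: str
    p_adjusted: float | None = None
    or_gss: float | None = None
    or_infinite: bool = False


def pair_contingency(study: GenotypeStudy, snp_a: int, snp_b: int) -> PairTable:
    """Count the 2x9 case/control table for a SNP pair.

    Samples missing either genotype are excluded.
    """
    if snp_a == snp_b:
        raise ValueError("snp_a and snp_b must differ")
    ga = study.genotypes[:, snp_a]
    gb = study.genotypes[:, snp_b]
    ok = (ga != MISSING) & (gb != MISSING)
    cell = 3 * ga[ok].astype(np.int64) + gb[ok]
    pheno = study.phenotype[ok]
    counts = np.zeros((2, 9), dtype=np.int64)
    for i in (0, 1):
        counts[i] = np.bincount(cell[pheno == i], minlength=9)
    return PairTable(counts)


# ---------------------------------------------------------------------------
# cell ordering / ROC machinery
# ---------------------------------------------------------------------------


def _odds_key(case_counts: np.ndarray, ctrl_counts: np.ndarray) -> np.ndarray:
    """Ranking key: case:control odds; empty cells rank below everything."""
    case_counts = np.asarray(case_counts, dtype=float)
    ctrl_counts = np.asarray(ctrl_counts, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        key = case_counts / ctrl_counts
    key = np.where((ctrl_counts == 0) & (case_counts > 0), np.inf, key)
    key = np.where((case_counts == 0) & (ctrl_counts > 0), 0.0, key)
    key = np.where((case_counts == 0) & (ctrl_counts == 0), -1.0, key)
    return key


def _merged_prefixes(case_counts, ctrl_counts):
    """Order cells by decreasing odds, merge ties, return prefix points.

    Returns (cells_sorted, group_end_mask, cum_cases, cum_ctrls) where
    ``group_end_mask[i]`` marks the last cell of each merged tie group; only
    those positions are ROC operating points.
    """
    key = _odds_key(case_counts, ctrl_counts)
    order = np.argsort(-key, kind="stable")
    key_s = key[order]
    end = np.empty(len(order), dtype=bool)
    end[:-1] = key_s[:-1] != key_s[1:]
    end[-1] = True
    return order, end, np.cumsum(np.asarray(case_counts)[order]), np.cumsum(
        np.asarray(ctrl_counts)[order]
    )


def single_snp_roc(table: PairTable, which: str) -> list[tuple[float, float]]:
    """Marginal ROC points (sensitivity, specificity) for one SNP of a pair.

    The three genotype classes are ordered by decreasing case:control odds
    with ties merged; cumulative prefixes give points on the upper-left
    hull, anchored at (0, 1).
    """
    axis = {"A": 1, "B": 0}[which.upper()]
    case = table.counts[1].reshape(3, 3).sum(axis=axis)
    ctrl = table.counts[0].reshape(3, 3).sum(axis=axis)
    n1, n0 = case.sum(), ctrl.sum()
    if n1 == 0 or n0 == 0:
        raise ValueError("both phenotype classes must be non-empty")
    _, end, cum1, cum0 = _merged_prefixes(case, ctrl)
    points = [(0.0, 1.0)]
    for i in np.flatnonzero(end):
        points.append((cum1[i] / n1, 1.0 - cum0[i] / n0))
    return points


# ---------------------------------------------------------------------------
# binomial log tails (never underflow to -inf)
# ---------------------------------------------------------------------------


def _log_binom_terms(ks: np.ndarray, n: float, p: float) -> np.ndarray:
    return (
        gammaln(n + 1)
        - gammaln(ks + 1)
        - gammaln(n - ks + 1)
        + ks * log(p)
        + (n - ks) * np.log1p(-p)
    )


def _log_sf_series(k: float, n: float, p: float) -> float:
    """log P(X >= k) summed term-wise; used when betainc underflows."""
    hi = min(n, k + 400)
    ks = np.arange(k, hi + 1)
    return float(logsumexp(_log_binom_terms(ks, n, p)))


def _log_cdf_series(k: float, n: float, p: float) -> float:
    lo = max(0, k - 400)
    ks = np.arange(lo, k + 1)
    return float(logsumexp(_log_binom_terms(ks, n, p)))


def log_binom_ge(k, n, p):
    """log P(Binom(n, p) >= k), elementwise, finite for p in (0, 1)."""
    k = np.asarray(k, dtype=float)
    out = np.where(k <= 0, 0.0, binom.logsf(k - 1, n, p))
    bad = ~np.isfinite(out)
    if np.any(bad):
        out = np.atleast_1d(out)
        kb, nb, pb = np.broadcast_arrays(k, n, p)
        for idx in np.argwhere(np.atleast_1d(bad)):
            t = tuple(idx)
            out[t] = _log_sf_series(
                float(np.atleast_1d(kb)[t]), float(np.atleast_1d(nb)[t]), float(np.atleast_1d(pb)[t])
            )
        out = out.reshape(np.shape(k))
    return out


def log_binom_le(k, n, p):
    """log P(Binom(n, p) <= k), elementwise, finite for p in (0, 1)."""
    k = np.asarray(k, dtype=float)
    out = np.where(k >= n, 0.0, binom.logcdf(k, n, p))
    bad = ~np.isfinite(out)
    if np.any(bad):
        out = np.atleast_1d(out)
        kb, nb, pb = np.broadcast_arrays(k, n, p)
        for idx in np.argwhere(np.atleast_1d(bad)):
            t = tuple(idx)
            out[t] = _log_cdf_series(
                float(np.atleast_1d(kb)[t]), float(np.atleast_1d(nb)[t]), float(np.atleast_1d(pb)[t])
            )
        out = out.reshape(np.shape(k))
    return out


# ---------------------------------------------------------------------------
# the pair statistic
# ---------------------------------------------------------------------------


def _hull_sens(xp: np.ndarray, yp: np.ndarray, fq: float) -> float:
    """Sensitivity of the marginal ROC hull at FP-rate ``fq``.

    Knots are non-decreasing in x; at a duplicated x (vertical segment) the
    upper point is used.
    """
    idx = int(np.searchsorted(xp, fq, side="right")) - 1
    if idx >= len(xp) - 1:
        return float(yp[-1])
    x0, x1 = xp[idx], xp[idx + 1]
    t = (fq - x0) / (x1 - x0)
    return float(yp[idx] + t * (yp[idx + 1] - yp[idx]))


def gss_statistic(table: PairTable) -> GssResult:
    """Discrimination-gain p-value for one pair table.

    For each single SNP and each pair operating point q, the gain p-value is
    the probability that a classifier no better than the SNP alone attains
    q's sensitivity and specificity simultaneously: a binomial tail for the
    case count at the sensitivity of the SNP's ROC hull interpolated at q's
    FP-rate, times a binomial tail for the control count at that FP-rate.
    The pair must beat BOTH SNPs: p_raw = max over SNPs of the minimum over
    operating points.
    """
    n1, n0 = table.n_cases, table.n_controls
    if n1 == 0 or n0 == 0:
        raise ValueError("both phenotype classes must be non-empty")
    case, ctrl = table.counts[1], table.counts[0]
    order, end, cum1, cum0 = _merged_prefixes(case, ctrl)
    q_idx = np.flatnonzero(end)
    tp, fp = cum1[q_idx], cum0[q_idx]

    eps1, eps0 = 0.5 / n1, 0.5 / n0
    best_log, best_q, best_m = -inf, None, None
    for m, axis in (("A", 1), ("B", 0)):
        mc = case.reshape(3, 3).sum(axis=axis)
        md = ctrl.reshape(3, 3).sum(axis=axis)
        _, _, mcum1, mcum0 = _merged_prefixes(mc, md)
        # hull knots anchored at (0, 0); mid-tie prefixes lie on the hull
        xp = np.concatenate([[0.0], mcum0 / n0])
        yp = np.concatenate([[0.0], mcum1 / n1])

        g_min, g_arg = inf, None
        for qi, (t, f) in enumerate(zip(tp, fp)):
            fpr_q = f / n0
            ps = _hull_sens(xp, yp, fpr_q)
            ps = min(max(ps, eps1), 1 - eps1)
            pf = min(max(fpr_q, eps0), 1 - eps0)
            g = float(log_binom_ge(t, n1, ps)) + float(log_binom_le(f, n0, pf))
            if g < g_min:
                g_min, g_arg = g, qi
        if g_min > best_log:
            best_log, best_q, best_m = g_min, g_arg, m

    best_log = max(best_log, _LOG_P_FLOOR)
    best_log = min(best_log, 0.0)
    hr = frozenset(int(c) + 1 for c in order[: q_idx[best_q] + 1])
    return GssResult(
        pair=None,
        p_raw=float(np.exp(best_log)),
        log10_p_raw=best_log / log(10),
        high_risk_cells=hr,
        gain_over=best_m,
    )


def or_gss(table: PairTable, high_risk_cells) -> tuple[float, bool]:
    """Odds ratio of the high-risk cell set vs the rest.

    OR = (pi_{1,HR} * pi_{0,LR}) / (pi_{0,HR} * pi_{1,LR}) with pi the
    within-phenotype proportions.  Returns (value, infinite_flag).
    """
    hr = sorted(high_risk_cells)
    if not hr:
        raise ValueError("high-risk set is empty")
    occupied = {v + 1 for v in range(9) if table.counts[:, v].sum() > 0}
    if occupied and occupied.issubset(set(hr)):
        raise ValueError("high-risk set covers all occupied cells")
    idx = [v - 1 for v in hr]
    pi1_hr = table.counts[1, idx].sum() / table.n_cases
    pi0_hr = table.counts[0, idx].sum() / table.n_controls
    pi1_lr, pi0_lr = 1 - pi1_hr, 1 - pi0_hr
    if pi0_hr == 0 or pi1_lr == 0:
        return inf, True
    return float((pi1_hr * pi0_lr) / (pi0_hr * pi1_lr)), False


def bonferroni_threshold(n_snps: int, alpha: float = 0.05) -> float:
    """Family-wise threshold alpha / C(n_snps, 2)."""
    if n_snps < 2:
        raise ValueError("need at least 2 SNPs")
    return alpha / comb(n_snps, 2)


def n_pairs(n_snps: int) -> int:
    """Number of distinct unordered SNP pairs evaluated by a full scan."""
    return comb(n_snps, 2)


# ---------------------------------------------------------------------------
# vectorized scan engine
# ---------------------------------------------------------------------------


def _bulk_gss(case_cnt: np.ndarray, ctrl_cnt: np.ndarray):
    """Vectorized pair statistic over a (P, 9) block of tables.

    Returns (log_p, hr_bitmask, gain_over) arrays.  Identical results to
    the per-table :func:`gss_statistic` loop.
    """
    P = case_cnt.shape[0]
    n1 = case_cnt.sum(axis=1).astype(float)
    n0 = ctrl_cnt.sum(axis=1).astype(float)
    if (n1 == 0).any() or (n0 == 0).any():
        raise ValueError("both phenotype classes must be non-empty for every pair")

    key = _odds_key(case_cnt, ctrl_cnt)
    order = np.argsort(-key, axis=1, kind="stable")
    rows = np.arange(P)[:, None]
    key_s = key[rows, order]
    end = np.empty((P, 9), dtype=bool)
    end[:, :-1] = key_s[:, :-1] != key_s[:, 1:]
    end[:, -1] = True
    tp = np.cumsum(case_cnt[rows, order], axis=1).astype(float)
    fp = np.cumsum(ctrl_cnt[rows, order], axis=1).astype(float)
    fpr_q = fp / n0[:, None]
    bitmask = np.cumsum(np.left_shift(1, order), axis=1)

    eps1 = (0.5 / n1)[:, None]
    eps0 = (0.5 / n0)[:, None]
    g_per_m = np.empty((2, P, 9))
    for mi, axis in ((0, 2), (1, 1)):
        mc = case_cnt.reshape(P, 3, 3).sum(axis=axis).astype(float)
        md = ctrl_cnt.reshape(P, 3, 3).sum(axis=axis).astype(float)
        mkey = _odds_key(mc, md)
        morder = np.argsort(-mkey, axis=1, kind="stable")
        # hull knots (anchored at 0); mid-tie prefixes lie on the hull
        xp = np.concatenate(
            [np.zeros((P, 1)), np.cumsum(md[rows, morder], axis=1) / n0[:, None]], axis=1
        )
        yp = np.concatenate(
            [np.zeros((P, 1)), np.cumsum(mc[rows, morder], axis=1) / n1[:, None]], axis=1
        )
        # per-row searchsorted: rightmost knot with xp <= fpr_q
        idx = (xp[:, None, :] <= fpr_q[:, :, None]).sum(axis=2) - 1
        idx = np.clip(idx, 0, 3)
        at_end = idx >= 3
        idx_lo = np.minimum(idx, 2)
        x0 = np.take_along_axis(xp, idx_lo, axis=1)
        x1 = np.take_along_axis(xp, idx_lo + 1, axis=1)
        y0 = np.take_along_axis(yp, idx_lo, axis=1)
        y1 = np.take_along_axis(yp, idx_lo + 1, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = np.where(x1 > x0, (fpr_q - x0) / np.where(x1 > x0, x1 - x0, 1.0), 0.0)
        ps = np.where(at_end, yp[:, -1:], y0 + t * (y1 - y0))
        ps = np.clip(ps, eps1, 1 - eps1)
        pf = np.clip(fpr_q, eps0, 1 - eps0)
        g = log_binom_ge(tp, n1[:, None], ps) + log_binom_le(fp, n0[:, None], pf)
        g_per_m[mi] = np.where(end, g, np.inf)

    g_min = g_per_m.min(axis=2)  # (2, P)
    arg_q = g_per_m.argmin(axis=2)  # (2, P)
    gain_mi = g_min.argmax(axis=0)  # (P,)
    log_p = np.clip(g_min.max(axis=0), _LOG_P_FLOOR, 0.0)
    q_star = arg_q[gain_mi, np.arange(P)]
    hr_bits = bitmask[np.arange(P), q_star].astype(np.int64)
    gain = np.where(gain_mi == 0, "A", "B")
    return log_p, hr_bits, gain


def _pair_count_tables(study: GenotypeStudy):
    """All C(M,2) pair tables at once via genotype-indicator products."""
    n, m = study.genotypes.shape
    geno = study.genotypes
    out = {}
    for label, mask in (("ctrl", study.phenotype == 0), ("case", study.phenotype == 1)):
        g = geno[mask]
        ind = [np.asarray(g == a, dtype=np.float32) for a in (0, 1, 2)]
        cnt = np.empty((m, m, 9), dtype=np.int64)
        for a in range(3):
            for b in range(3):
                cnt[:, :, 3 * a + b] = np.rint(ind[a].T @ ind[b]).astype(np.int64)
        out[label] = cnt
    iu, ju = np.triu_indices(m, k=1)
    return iu, ju, out["case"][iu, ju], out["ctrl"][iu, ju]


def scan_pvalues(study: GenotypeStudy, chunk: int = 65536):
    """Raw scan over all pairs; returns (idx_a, idx_b, log10_p, hr_bits).

    Deterministic pair order (index lexicographic); the engine evaluates
    genotype-indicator blocks and must match the naive per-pair loop.
    """
    if study.n_snps < 2:
        raise ValueError("need at least 2 SNPs to scan")
    iu, ju, case_cnt, ctrl_cnt = _pair_count_tables(study)
    P = len(iu)
    log_p = np.empty(P)
    hr_bits = np.empty(P, dtype=np.int64)
    for s in range(0, P, chunk):
        e = min(s + chunk, P)
        lp, hb, _ = _bulk_gss(case_cnt[s:e], ctrl_cnt[s:e])
        log_p[s:e] = lp
        hr_bits[s:e] = hb
        logger.info("scanned %d / %d pairs", e, P)
    return iu, ju, log_p / log(10), hr_bits


def exhaustive_scan(
    study: GenotypeStudy,
    alpha: float = 0.05,
    report_threshold: float = 1e-6,
):
    """Evaluate all pairs; yield :class:`GssResult` below the threshold."""
    iu, ju, log10_p, hr_bits = scan_pvalues(study)
    snps = study.snp_meta["snp"].to_numpy()
    keep = log10_p <= np.log10(report_threshold)
    for a, b, lp, hb in zip(iu[keep], ju[keep], log10_p[keep], hr_bits[keep]):
        hr = frozenset(v + 1 for v in range(9) if hb >> v & 1)
        table = pair_contingency(study, int(a), int(b))
        try:
            orv, orinf = or_gss(table, hr)
        except ValueError:
            orv, orinf = None, False
        yield GssResult(
            pair=(snps[a], snps[b]),
            p_raw=float(10.0 ** max(lp, -300)),
            log10_p_raw=float(lp),
            high_risk_cells=hr,
            gain_over=gss_statistic(table).gain_over,
            or_gss=orv,
            or_infinite=orinf,
        )


def permuted_scan_pvalues(study: GenotypeStudy, seed: int, n_permutations: int = 1):
    """Pooled log10 p-values from full scans with permuted labels."""
    rng = np.random.default_rng(seed)
    pools = []
    for _ in range(n_permutations):
        perm = rng.permutation(study.n_samples)
        shuffled = GenotypeStudy(
            genotypes=study.genotypes,
            phenotype=study.phenotype[perm],
            snp_meta=study.snp_meta,
            sample_ids=study.sample_ids,
        )
        pools.append(scan_pvalues(shuffled)[2])
    return np.concatenate(pools)


# ---------------------------------------------------------------------------
# permutation calibration
# ---------------------------------------------------------------------------


def calibrate_pvalues(observed, null_pool, include_observed: bool = False):
    """Map observed p-values through the permuted-scan quantile map.

    The map is fitted on the -log10 scale from the pooled permuted p-value
    distribution to Uniform(0,1), is non-decreasing, and extrapolates
    linearly in -log10 beyond the deepest null quantile.  Accepts either
    p-values or log10 p-values (non-positive input is treated as log10 p).
    With ``include_observed`` the observed scan joins the pool (the identity
    permutation), which stabilizes the map's central quantiles.
    """
    observed = np.asarray(observed, dtype=float)
    null_pool = np.asarray(null_pool, dtype=float)
    if null_pool.size == 0:
        raise ValueError("empty null pool")
    if include_observed:
        null_pool = np.concatenate([null_pool, observed])
    x_obs = -observed if (observed <= 0).all() else -np.log10(observed)
    x_null = -null_pool if (null_pool <= 0).all() else -np.log10(null_pool)

    xs = np.sort(x_null)
    n = len(xs)
    ys = -np.log10((n - np.arange(n)) / (n + 1.0))
    # anchor at p = 1 and deduplicate for interpolation
    xs = np.concatenate([[0.0], xs])
    ys = np.concatenate([[0.0], ys])
    ys = np.maximum.accumulate(ys)

    y_obs = np.interp(x_obs, xs, ys)
    beyond = x_obs > xs[-1]
    if beyond.any():
        k = max(10, n // 20)
        tail_x, tail_y = xs[-k:], ys[-k:]
        denom = ((tail_x - tail_x.mean()) ** 2).sum()
        slope = (
            ((tail_x - tail_x.mean()) * (tail_y - tail_y.mean())).sum() / denom
            if denom > 0
            else 1.0
        )
        slope = max(slope, 1e-6)
        y_obs[beyond] = ys[-1] + slope * (x_obs[beyond] - xs[-1])
    return np.clip(10.0 ** (-y_obs), 1e-300, 1.0)


def genomic_lambda(p_values) -> float:
    """Genomic-control inflation: median chi2(1) quantile ratio."""
    p = np.asarray(p_values, dtype=float)
    return float(chi2.isf(np.median(p), df=1) / chi2.isf(0.5, df=1))
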