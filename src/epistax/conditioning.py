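"""Conditional independence testing of interaction pairs.

Tests whether a candidate pair carries case-control signal beyond known
risk-haplotype dosages, principal components, and strong marginal SNPs,
using likelihood-ratio tests on nested logistic regressions, with Fisher
meta-analysis across cohorts and BH-FDR thresholding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from scipy.stats import chi2

from epistax.cohort import MISSING, GenotypeStudy, ld_thin_indices


@dataclass
class HaplotypeDosageMatrix:
    """Samples x alleles dosage matrix emulating imputed risk haplotypes."""

    dosages: np.ndarray
    allele_names: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if ((self.dosages < 0) | (self.dosages > 2)).any():
            raise ValueError("dosages must lie in [0, 2]")
        if len(set(self.allele_names)) != self.dosages.shape[1]:
            raise ValueError("allele names must be unique and match columns")


@dataclass
class ConditionalTestResult:
    pair: tuple | None
    lrt_stat: float
    df: int
    p: float
    conditioning_set: str


@dataclass
class LogisticFit:
    beta: np.ndarray
    loglik: float
    converged: bool
    separated: bool
    kept_columns: np.ndarray


def _independent_columns(X: np.ndarray, basis: np.ndarray | None = None, tol: float = 1e-8):
    """Greedy earliest-first selection of linearly independent columns."""
    n = X.shape[0]
    q_list = [] if basis is None else [basis[:, i] for i in range(basis.shape[1])]
    keep = []
    for j in range(X.shape[1]):
        v = X[:, j].astype(float)
        norm0 = np.linalg.norm(v)
        if norm0 == 0:
            continue
        for q in q_list:
            v = v - (q @ v) * q
        if np.linalg.norm(v) > tol * max(norm0, 1.0):
            q_list.append(v / np.linalg.norm(v))
            keep.append(j)
    return np.array(keep, dtype=int)


def logistic_mle(
    y: np.ndarray,
    X: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-10,
    separation_penalty: float = 1e-4,
) -> LogisticFit:
    """IRLS maximum-likelihood logistic fit.

    Aliased columns are dropped deterministically (earliest independent
    columns kept, coefficients of dropped columns set to 0).  On detected
    separation the model is refit with a tiny quadratic penalty on the
    slopes and flagged; constant columns are exempt from the penalty.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    kept = _independent_columns(X)
    Xk = X[:, kept]

    def irls(pen: float):
        const = np.ptp(Xk, axis=0) == 0
        pen_vec = np.where(const, 0.0, pen)
        beta = np.zeros(Xk.shape[1])
        converged = False
        for _ in range(max_iter):
            eta = np.clip(Xk @ beta, -35, 35)
            mu = expit(eta)
            w = np.clip(mu * (1 - mu), 1e-12, None)
            grad = Xk.T @ (y - mu) - pen_vec * beta
            H = (Xk * w[:, None]).T @ Xk + np.diag(pen_vec + 1e-12)
            step = np.linalg.solve(H, grad)
            beta = beta + step
            if np.max(np.abs(step)) < tol:
                converged = True
                break
        eta = np.clip(Xk @ beta, -35, 35)
        mu = expit(eta)
        ll = float(y @ np.log(np.clip(mu, 1e-300, None)) + (1 - y) @ np.log(np.clip(1 - mu, 1e-300, None)))
        return beta, ll, converged

    beta, ll, converged = irls(0.0)
    separated = bool(np.max(np.abs(beta)) > 25) or not converged
    if separated:
        beta, ll, converged = irls(separation_penalty)
    full_beta = np.zeros(X.shape[1])
    full_beta[kept] = beta
    return LogisticFit(
        beta=full_beta, loglik=ll, converged=converged, separated=separated, kept_columns=kept
    )


def likelihood_ratio_test(y, X_null, X_added, pair=None, label="") -> ConditionalTestResult:
    """LRT of nested logistic fits; df counts non-aliased added columns."""
    X_full = np.column_stack([X_null, X_added])
    fit0 = logistic_mle(y, X_null)
    fit1 = logistic_mle(y, X_full)
    base_kept = _independent_columns(X_null)
    q = np.linalg.qr(X_null[:, base_kept])[0] if len(base_kept) else None
    added_kept = _independent_columns(X_added, basis=q)
    df = len(added_kept)
    stat = max(0.0, 2.0 * (fit1.loglik - fit0.loglik))
    p = float(chi2.sf(stat, df)) if df > 0 else 1.0
    return ConditionalTestResult(pair=pair, lrt_stat=stat, df=df, p=p, conditioning_set=label)


# ---------------------------------------------------------------------------
# covariate builders
# ---------------------------------------------------------------------------


def compute_pcs(study: GenotypeStudy, k: int = 5, thin_r2: float = 0.2) -> np.ndarray:
    """Top-k principal components of the standardized, LD-thinned genotypes.

    Sign convention: the largest-magnitude loading of each component is
    positive.  Scores are orthogonal.
    """
    if study.n_samples < k + 1:
        raise ValueError("need at least k+1 samples")
    snps = ld_thin_indices(study, r2_max=thin_r2)
    geno = study.genotypes[:, snps].astype(float)
    geno[geno == MISSING] = np.nan
    mean = np.nanmean(geno, axis=0)
    geno = np.where(np.isnan(geno), mean, geno)
    std = geno.std(axis=0)
    ok = std > 0
    z = (geno[:, ok] - mean[ok]) / std[ok]
    if z.shape[1] == 0:
        raise ValueError("no polymorphic SNPs for PCA")
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    if (s[:k] <= 1e-10).any() or k > len(s):
        raise ValueError("requested components exceed the matrix rank")
    scores = u[:, :k] * s[:k]
    for j in range(k):
        if vt[j, np.argmax(np.abs(vt[j]))] < 0:
            scores[:, j] = -scores[:, j]
    return scores


def encode_vip_indicators(
    g_a: np.ndarray,
    g_b: np.ndarray,
    controls: np.ndarray,
    rare_freq: float = 0.01,
) -> np.ndarray:
    """Encode a pair's 9 genotype cells as up to 8 indicators.

    The reference cell is the most frequent cell among controls; samples
    with a missing genotype get all-zero rows.  Cells below ``rare_freq``
    within-class frequency in BOTH cases and controls are folded into the
    reference (the rare-cell heuristic; near-empty indicator columns make
    the LRT anti-conservative).
    """
    controls = np.asarray(controls, dtype=bool)
    ok = (g_a != MISSING) & (g_b != MISSING)
    cell = np.where(ok, 3 * g_a.astype(int) + g_b, -1)
    ctrl_counts = np.bincount(cell[controls & ok], minlength=10)[:9]
    case_counts = np.bincount(cell[~controls & ok], minlength=10)[:9]
    ctrl_freq = ctrl_counts / max(ctrl_counts.sum(), 1)
    case_freq = case_counts / max(case_counts.sum(), 1)
    ref = int(np.argmax(ctrl_counts))
    keep = [
        c
        for c in range(9)
        if c != ref and (ctrl_freq[c] >= rare_freq or case_freq[c] >= rare_freq)
    ]
    out = np.zeros((len(g_a), len(keep)))
    for j, c in enumerate(keep):
        out[:, j] = cell == c
    return out


def encode_snp_indicators(g: np.ndarray) -> np.ndarray:
    """2 binary indicators (het, hom-minor) for one SNP; 0/0 when missing."""
    return np.column_stack([(g == 1).astype(float), (g == 2).astype(float)])


def hla_independence_lrt(
    y: np.ndarray,
    vip_indicators: np.ndarray,
    hap: HaplotypeDosageMatrix | None,
    pcs: np.ndarray | None = None,
    pair=None,
) -> ConditionalTestResult:
    """Does the pair add fit beyond risk-haplotype dosages (and PCs)?"""
    parts = [np.ones((len(y), 1))]
    if pcs is not None:
        parts.append(pcs)
    if hap is not None:
        parts.append(hap.dosages)
    X_null = np.column_stack(parts)
    return likelihood_ratio_test(y, X_null, vip_indicators, pair=pair, label="hap+pcs")


def conditional_interaction_lrt(
    y: np.ndarray,
    g_a: np.ndarray,
    g_b: np.ndarray,
    controls: np.ndarray,
    hap: HaplotypeDosageMatrix | None = None,
    pcs: np.ndarray | None = None,
    top_snps: np.ndarray | None = None,
    pair=None,
) -> ConditionalTestResult:
    """Log-odds-scale interaction test conditional on marginal effects.

    Null model: marginal SNPs (2 indicators each) plus the conditioning
    set; full model adds the 8 pair-cell indicators.  Unlike the
    discrimination-gain scan this detects interaction only on the log-odds
    scale.
    """
    parts = [np.ones((len(y), 1))]
    if pcs is not None:
        parts.append(pcs)
    if hap is not None:
        parts.append(hap.dosages)
    if top_snps is not None:
        parts.append(top_snps)
    parts.append(encode_snp_indicators(g_a))
    parts.append(encode_snp_indicators(g_b))
    X_null = np.column_stack(parts)
    X_added = encode_vip_indicators(g_a, g_b, controls)
    return likelihood_ratio_test(y, X_null, X_added, pair=pair, label="margins+hap+pcs+topsnps")


# ---------------------------------------------------------------------------
# meta-analysis, FDR, dosage quality
# ---------------------------------------------------------------------------


def fisher_meta(p_values) -> tuple[float, int, float]:
    """Fisher's method: X2 = -2 sum ln p ~ chi2 with 2k df."""
    p = np.asarray(p_values, dtype=float)
    if p.size < 1:
        raise ValueError("need at least one p-value")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]; floor zeros upstream")
    x2 = float(-2.0 * np.log(p).sum())
    df = 2 * p.size
    return x2, df, float(chi2.sf(x2, df))


def bh_fdr(p_values, q: float = 0.05) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up; returns (rejection mask, p cutoff)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    thresh = q * (np.arange(1, m + 1)) / m
    passing = np.flatnonzero(p[order] <= thresh)
    mask = np.zeros(m, dtype=bool)
    if passing.size == 0:
        return mask, 0.0
    k = passing[-1]
    mask[order[: k + 1]] = True
    return mask, float(p[order[k]])


def info_metric(dosages: np.ndarray, controls: np.ndarray) -> float:
    """Imputation quality: Var(x) / (2 p (1 - p)), both in controls only."""
    x = np.asarray(dosages, dtype=float)[np.asarray(controls, dtype=bool)]
    if x.size < 2:
        raise ValueError("need at least 2 control samples")
    p = x.mean() / 2.0
    if p <= 0 or p >= 1:
        return 0.0
    return float(x.var() / (2.0 * p * (1.0 - p)))


# ---------------------------------------------------------------------------
# null-calibration simulation
# ---------------------------------------------------------------------------


def null_interaction_qq(
    study: GenotypeStudy,
    n_pairs: int = 100_000,
    seed: int = 0,
    strong_p_max: float = 1e-10,
):
    """Interaction-test calibration under the null, with/without strong loci.

    Scenario "strong_random" pairs a locus with a strong univariate effect
    with a genotype-permuted null locus; "random_random" pairs two permuted
    null loci.  Returns a dict with per-scenario p-value arrays and
    genomic-control lambdas.
    """
    rng = np.random.default_rng(seed)
    y = study.phenotype.astype(float)
    controls = study.phenotype == 0
    geno = study.genotypes

    chi_p = np.ones(study.n_snps)
    for j in range(study.n_snps):
        g = geno[:, j]
        ok = g != MISSING
        tab = np.zeros((2, 3))
        for i in (0, 1):
            tab[i] = np.bincount(g[ok & (study.phenotype == i)], minlength=3)
        tab = tab[:, tab.sum(axis=0) > 0]
        if tab.shape[1] < 2:
            continue
        e = np.outer(tab.sum(axis=1), tab.sum(axis=0)) / tab.sum()
        stat = ((tab - e) ** 2 / e).sum()
        chi_p[j] = chi2.sf(stat, (tab.shape[1] - 1))
    strong = np.flatnonzero(chi_p < strong_p_max)

    def permuted(j):
        return geno[rng.permutation(study.n_samples), j]

    out = {}
    for name in ("strong_random", "random_random"):
        if name == "strong_random" and strong.size == 0:
            out[name] = {"p": np.array([]), "lambda": np.nan}
            continue
        ps = np.empty(n_pairs)
        for t in range(n_pairs):
            if name == "strong_random":
                ga = geno[:, rng.choice(strong)]
                gb = permuted(rng.integers(study.n_snps))
            else:
                ga = permuted(rng.integers(study.n_snps))
                gb = permuted(rng.integers(study.n_snps))
            res = conditional_interaction_lrt(y, ga, gb, controls)
            ps[t] = res.p
        med = np.median(ps)
        lam = float(chi2.isf(med, 1) / chi2.isf(0.5, 1))
        out[name] = {"p": ps, "lambda": lam}
    return out
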