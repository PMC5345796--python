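"""Penalized predictive models over single-SNP dosages and pair indicators.

The predictor minimizes the L1-penalized squared hinge loss

    (1/2N) sum_i max(0, 1 - y_i (x_i' b + b0))^2 + lambda * sum_j |b_j|

by cyclic coordinate descent with soft thresholding.  Model quality is
summarized by the Mann-Whitney AUC, compared between models with DeLong's
test, and converted to liability-scale variance explained via the normal
liability-threshold mapping at a given population prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm, rankdata

from epistax.cohort import MISSING, GenotypeStudy


@dataclass
class SparseLinearModel:
    beta: np.ndarray
    beta0: float
    lam: float
    feature_names: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return X @ self.beta + self.beta0

    @property
    def n_active(self) -> int:
        return int(np.count_nonzero(self.beta))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"feature": self.feature_names, "weight": self.beta})


@dataclass
class PredictionEval:
    auc: float
    variance_explained_liability: float
    prevalence: float
    n_samples: int


# ---------------------------------------------------------------------------
# feature encodings
# ---------------------------------------------------------------------------


def encode_pair_indicators(study: GenotypeStudy, pairs) -> tuple[np.ndarray, list[str]]:
    """9 one-hot columns per pair; all-zero where either genotype is missing.

    Cell index is 3*g_a + g_b + 1, consistent with the scan tables, so the
    encoding is identical across cohorts sharing allele orientation.
    """
    snp_idx = {s: i for i, s in enumerate(study.snp_meta["snp"])}
    cols, names = [], []
    for a, b in pairs:
        ia = snp_idx.get(a) if not isinstance(a, (int, np.integer)) else int(a)
        ib = snp_idx.get(b) if not isinstance(b, (int, np.integer)) else int(b)
        if ia is None or ib is None:
            raise KeyError(f"unknown SNP id in pair ({a}, {b})")
        ga, gb = study.genotypes[:, ia], study.genotypes[:, ib]
        ok = (ga != MISSING) & (gb != MISSING)
        cell = 3 * ga.astype(int) + gb + 1
        block = np.zeros((study.n_samples, 9), dtype=np.float32)
        for v in range(1, 10):
            block[:, v - 1] = ok & (cell == v)
        cols.append(block)
        names.extend(f"{a}:{b}:cell{v}" for v in range(1, 10))
    X = np.concatenate(cols, axis=1) if cols else np.zeros((study.n_samples, 0), np.float32)
    return X, names


def encode_snp_dosages(study: GenotypeStudy) -> tuple[np.ndarray, list[str]]:
    """Minor-allele dosage {0,1,2} per SNP; missing encoded as 0."""
    X = study.genotypes.astype(np.float32)
    X[X == MISSING] = 0.0
    return X, list(study.snp_meta["snp"])


# ---------------------------------------------------------------------------
# L1 squared-hinge solver
# ---------------------------------------------------------------------------


def _objective(X, y, beta, beta0, lam) -> float:
    r = 1.0 - y * (X @ beta + beta0)
    return float(0.5 * np.mean(np.maximum(r, 0.0) ** 2) + lam * np.abs(beta).sum())


def _optimal_intercept(y: np.ndarray) -> float:
    # 1-d minimization of the squared hinge at beta = 0
    lo, hi = -2.0, 2.0
    for _ in range(100):
        mid = (lo + hi) / 2
        r = 1.0 - y * mid
        g = -np.mean(np.where(r > 0, r, 0.0) * y)
        if g > 0:
            hi = mid
        else:
            lo = mid
    return (lo + hi) / 2


def lambda_max(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty at which the all-zero slope vector is optimal."""
    b0 = _optimal_intercept(np.asarray(y, dtype=float))
    r = 1.0 - y * b0
    active = r > 0
    grad = -(X.T @ (np.where(active, r, 0.0) * y)) / len(y)
    return float(np.max(np.abs(grad)))


def fit_l1_squared_hinge(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    tol: float = 1e-6,
    max_sweeps: int = 10_000,
    warm: tuple[np.ndarray, float] | None = None,
    feature_names: list[str] | None = None,
) -> SparseLinearModel:
    """Cyclic coordinate descent on the L1-penalized squared hinge.

    Uses the per-coordinate curvature bound mean(x_j^2), so each update is
    a majorize-minimize step and the objective never increases.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if not np.isfinite(X).all():
        raise ValueError("non-finite entries in X")
    if set(np.unique(y)) - {-1.0, 1.0}:
        raise ValueError("y must be coded +1 / -1")
    n, p = X.shape
    h = (X**2).mean(axis=0)
    beta, beta0 = (warm[0].copy(), warm[1]) if warm is not None else (np.zeros(p), 0.0)
    f = X @ beta + beta0
    for _ in range(max_sweeps):
        max_delta = 0.0
        # intercept (unpenalized, curvature bound 1)
        r = 1.0 - y * f
        g0 = -np.mean(np.where(r > 0, r, 0.0) * y)
        beta0_new = beta0 - g0
        f += beta0_new - beta0
        max_delta = abs(beta0_new - beta0)
        beta0 = beta0_new
        for j in range(p):
            if h[j] == 0:
                continue
            r = 1.0 - y * f
            gj = -np.mean(np.where(r > 0, r, 0.0) * y * X[:, j])
            z = beta[j] - gj / h[j]
            bj = np.sign(z) * max(abs(z) - lam / h[j], 0.0)
            if bj != beta[j]:
                f += (bj - beta[j]) * X[:, j]
                max_delta = max(max_delta, abs(bj - beta[j]))
                beta[j] = bj
        if max_delta < tol:
            break
    names = feature_names if feature_names is not None else [f"x{j}" for j in range(p)]
    return SparseLinearModel(beta=beta, beta0=float(beta0), lam=lam, feature_names=names)


def cv_select(
    X: np.ndarray,
    y: np.ndarray,
    n_lambdas: int = 100,
    folds: int = 10,
    reps: int = 10,
    seed: int = 0,
    feature_names: list[str] | None = None,
) -> tuple[SparseLinearModel, pd.DataFrame]:
    """Pick the penalty maximizing mean held-out AUC, then refit on all data.

    The grid is log-spaced over [1e-4 * lambda_max, lambda_max]; folds are
    stratified by class and seeded.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    lam_hi = lambda_max(X, y)
    lams = np.geomspace(lam_hi, 1e-4 * lam_hi, n_lambdas)
    rng = np.random.default_rng(seed)
    aucs = np.zeros((reps * folds, n_lambdas))
    row = 0
    for _ in range(reps):
        fold_of = np.empty(len(y), dtype=int)
        for cls in (-1.0, 1.0):
            idx = np.flatnonzero(y == cls)
            rng.shuffle(idx)
            fold_of[idx] = np.arange(len(idx)) % folds
        for k in range(folds):
            test = fold_of == k
            if len(np.unique(y[test])) < 2 or len(np.unique(y[~test])) < 2:
                raise ValueError("a fold contains a single class")
            Xtr, ytr = X[~test], y[~test]
            warm = (np.zeros(X.shape[1]), 0.0)
            for li, lam in enumerate(lams):
                model = fit_l1_squared_hinge(Xtr, ytr, lam, warm=warm)
                warm = (model.beta, model.beta0)
                scores = model.decision_function(X[test])
                aucs[row, li] = auc(scores, (y[test] > 0).astype(int))
            row += 1
    mean_auc = aucs.mean(axis=0)
    best = int(np.argmax(mean_auc))
    final = fit_l1_squared_hinge(X, y, lams[best], feature_names=feature_names)
    final.meta.update({"folds": folds, "reps": reps, "seed": seed, "cv_auc": float(mean_auc[best])})
    curve = pd.DataFrame({"lam": lams, "mean_auc": mean_auc})
    return final, curve


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


def auc(scores, labels) -> float:
    """Mann-Whitney AUC; ties credited 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n1 = labels.sum()
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes required")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _placements(scores, labels):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    allr = rankdata(np.concatenate([pos, neg]))
    v10 = (allr[:m] - rankdata(pos)) / n
    v01 = 1.0 - (allr[m:] - rankdata(neg)) / m
    return v10, v01


def delong_test(scores1, scores2, labels) -> tuple[float, float]:
    """Two-sided DeLong comparison of paired AUCs; returns (delta, p)."""
    labels = np.asarray(labels).astype(int)
    s1 = np.asarray(scores1, dtype=float)
    s2 = np.asarray(scores2, dtype=float)
    a1, a2 = auc(s1, labels), auc(s2, labels)
    v10 = np.column_stack([_placements(s1, labels)[0], _placements(s2, labels)[0]])
    v01 = np.column_stack([_placements(s1, labels)[1], _placements(s2, labels)[1]])
    m, n = v10.shape[0], v01.shape[0]
    s10 = np.cov(v10.T) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(v01.T) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    delta = a1 - a2
    if var <= 0:
        return float(delta), 1.0
    z = delta / np.sqrt(var)
    return float(delta), float(2 * norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# liability-scale variance from AUC
# ---------------------------------------------------------------------------


def auc_from_liability(h2: float, prevalence: float) -> float:
    """AUC implied by liability-scale variance h2 at the given prevalence."""
    if not 0 <= h2 < 1:
        raise ValueError("h2 must lie in [0, 1)")
    if h2 == 0:
        return 0.5
    t = norm.isf(prevalence)
    z = norm.pdf(t)
    i = z / prevalence
    i2 = -z / (1 - prevalence)
    num = h2 * (i - i2)
    den = np.sqrt(h2 * (1 - h2 * i * (i - t)) + h2 * (1 - h2 * i2 * (i2 - t)))
    return float(norm.cdf(num / den))


def liability_variance_from_auc(auc_value: float, prevalence: float, tol: float = 1e-10) -> float:
    """Invert the liability-threshold AUC mapping numerically."""
    if not 0 < prevalence < 1:
        raise ValueError("prevalence must lie in (0, 1)")
    if auc_value < 0.5:
        raise ValueError("AUC below 0.5 has no liability interpretation")
    if auc_value == 0.5:
        return 0.0
    hi = 1.0 - 1e-12
    if auc_value >= auc_from_liability(hi, prevalence):
        return hi
    return float(brentq(lambda h2: auc_from_liability(h2, prevalence) - auc_value, 0.0, hi, xtol=tol))


def evaluate(scores, labels, prevalence: float = 0.01) -> PredictionEval:
    a = auc(scores, labels)
    h2 = liability_variance_from_auc(max(a, 0.5), prevalence)
    return PredictionEval(
        auc=a,
        variance_explained_liability=h2,
        prevalence=prevalence,
        n_samples=len(labels),
    )
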