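"""Synthetic case-control cohorts with LD-block haplotype structure,
multi-allelic risk-haplotype effects, and planted two-locus models.

Haplotypes are mosaics of founder haplotypes: each block carries a pool of
founders whose allele columns follow a Markov chain along the block, which
sets the within-block LD level.  One designated block can act as a
multi-allelic risk locus whose founder identity plays the role of an
imputed risk-haplotype allele; SNPs inside that block partially tag the
founder, which is exactly the mechanism that induces spurious pairwise
interactions without any true two-locus effect.

Disease risk is logistic: a prevalence-calibrated intercept, per-allele
log-odds for risk haplotypes, and a log-odds offset for each planted
two-locus penetrance model (so a lone planted model with no haplotype
effects reproduces its penetrance table exactly).  Cases and controls are
obtained by rejection sampling from this superpopulation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from epistax.cohort import GenotypeStudy, orient_to_minor


@dataclass
class TwoLocusModel:
    """3x3 penetrance table over genotypes of two biallelic loci."""

    penetrance: np.ndarray
    maf_a: float
    maf_b: float
    label: str | None = None

    def __post_init__(self) -> None:
        self.penetrance = np.asarray(self.penetrance, dtype=float)
        if self.penetrance.shape != (3, 3):
            raise ValueError("penetrance must be 3x3")
        if ((self.penetrance < 0) | (self.penetrance > 1)).any():
            raise ValueError("penetrance values must lie in [0, 1]")
        for maf in (self.maf_a, self.maf_b):
            if not 0 < maf < 1:
                raise ValueError("allele frequencies must lie in (0, 1)")

    def genotype_probs(self, maf: float) -> np.ndarray:
        q = 1 - maf
        return np.array([q * q, 2 * q * maf, maf * maf])

    def implied_prevalence(self) -> float:
        """Population prevalence under HWE at the model's allele freqs."""
        pa = self.genotype_probs(self.maf_a)
        pb = self.genotype_probs(self.maf_b)
        return float(pa @ self.penetrance @ pb)

    @classmethod
    def from_pattern(cls, high_cells, pen_high, pen_low, maf_a, maf_b, label=None):
        pen = np.where(np.asarray(high_cells, bool), pen_high, pen_low)
        return cls(pen, maf_a, maf_b, label=label)

    @classmethod
    def dominant_dominant(cls, pen_high, pen_low, maf_a, maf_b):
        high = np.fromfunction(lambda a, b: (a >= 1) & (b >= 1), (3, 3))
        return cls.from_pattern(high, pen_high, pen_low, maf_a, maf_b, label="DD")

    @classmethod
    def recessive_dominant(cls, pen_high, pen_low, maf_a, maf_b):
        high = np.fromfunction(lambda a, b: (a == 2) & (b >= 1), (3, 3))
        return cls.from_pattern(high, pen_high, pen_low, maf_a, maf_b, label="RD")

    @classmethod
    def threshold(cls, pen_high, pen_low, maf_a, maf_b):
        high = np.fromfunction(lambda a, b: a + b >= 2, (3, 3))
        return cls.from_pattern(high, pen_high, pen_low, maf_a, maf_b, label="T")

    @classmethod
    def xor(cls, pen_high, pen_low, maf_a, maf_b):
        high = np.fromfunction(lambda a, b: ((a >= 1) ^ (b >= 1)), (3, 3))
        return cls.from_pattern(high, pen_high, pen_low, maf_a, maf_b, label="XOR")

    @classmethod
    def null(cls, prevalence, maf_a, maf_b):
        return cls(np.full((3, 3), prevalence), maf_a, maf_b, label="null")


@dataclass
class RiskHaplotypes:
    """Multi-allelic risk locus: founder alleles of one LD block."""

    log_odds: np.ndarray
    block: int = 0

    def __post_init__(self) -> None:
        self.log_odds = np.asarray(self.log_odds, dtype=float)

    @property
    def n_alleles(self) -> int:
        return len(self.log_odds)


@dataclass
class SimulationConfig:
    n_cases: int
    n_controls: int
    seed: int
    n_blocks: int = 5
    snps_per_block: int = 10
    within_block_r2: float = 0.8
    n_founders: int = 4
    planted_models: list[TwoLocusModel] = field(default_factory=list)
    risk_haplotypes: RiskHaplotypes | None = None
    artifact_pairs: list[tuple[int, int]] = field(default_factory=list)
    #: block -> (n_founders, k) 0/1 array overriding its first k SNP columns
    founder_overrides: dict = field(default_factory=dict)
    prevalence: float = 0.01

    def __post_init__(self) -> None:
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must lie in (0, 1)")
        for name in ("n_cases", "n_controls", "n_blocks", "snps_per_block", "n_founders"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    @property
    def n_block_snps(self) -> int:
        return self.n_blocks * self.snps_per_block

    @property
    def n_snps(self) -> int:
        return self.n_block_snps + 2 * len(self.planted_models)

    def planted_loci(self, i: int) -> tuple[int, int]:
        """Indices of the two loci carrying planted model i."""
        base = self.n_block_snps + 2 * i
        return base, base + 1


class _Generator:
    """Seeded haplotype factory shared by all sampling batches."""

    def __init__(self, config: SimulationConfig, rng: np.random.Generator):
        self.cfg = config
        self.rng = rng
        r = max(min(config.within_block_r2, 1.0), 0.0)
        delta = (1.0 - np.sqrt(r)) / 2.0
        self.founders = []
        hb = config.risk_haplotypes
        for b in range(config.n_blocks):
            nf = hb.n_alleles if (hb is not None and hb.block == b) else config.n_founders
            first = rng.integers(0, 2, size=nf)
            if first.min() == first.max():  # keep the block polymorphic
                first[0] = 1 - first[0]
            cols = [first]
            for _ in range(config.snps_per_block - 1):
                flips = rng.random(nf) < delta
                cols.append(np.where(flips, 1 - cols[-1], cols[-1]))
            block = np.stack(cols, axis=1).astype(np.int8)
            if b in config.founder_overrides:
                pattern = np.asarray(config.founder_overrides[b], dtype=np.int8)
                block[:, : pattern.shape[1]] = pattern
            self.founders.append(block)
        self.planted_mafs = []
        for m in config.planted_models:
            self.planted_mafs.extend([m.maf_a, m.maf_b])

    def draw_haplotypes(self, n_hap: int):
        """Returns (haplotype matrix, founder index of the risk block)."""
        cfg = self.cfg
        cols = []
        risk_founder = None
        for b in range(cfg.n_blocks):
            nf = self.founders[b].shape[0]
            f = self.rng.integers(0, nf, size=n_hap)
            cols.append(self.founders[b][f])
            if cfg.risk_haplotypes is not None and cfg.risk_haplotypes.block == b:
                risk_founder = f
        for maf in self.planted_mafs:
            cols.append((self.rng.random((n_hap, 1)) < maf).astype(np.int8))
        hap = np.concatenate(cols, axis=1)
        if risk_founder is None:
            risk_founder = np.zeros(n_hap, dtype=int)
        return hap, risk_founder


def _linear_predictor(cfg: SimulationConfig, geno: np.ndarray, dosages: np.ndarray) -> np.ndarray:
    """Log-odds of disease; saturated penetrance cells (0 or 1) map to
    +/-inf so no intercept shift can reinterpret them."""
    base = logit(cfg.prevalence)
    eta = np.full(geno.shape[0], base)
    if cfg.risk_haplotypes is not None:
        eta += dosages @ cfg.risk_haplotypes.log_odds
    for i, model in enumerate(cfg.planted_models):
        la, lb = cfg.planted_loci(i)
        with np.errstate(divide="ignore"):
            offsets = logit(model.penetrance) - base
        eta = eta + offsets[geno[:, la], geno[:, lb]]
    if np.isnan(eta).any():
        raise ValueError("planted models assign contradictory saturated penetrances")
    return eta


def _calibrate_intercept(cfg: SimulationConfig, gen: _Generator, n_cal: int = 20000) -> float:
    """Intercept shift so the superpopulation prevalence hits the target."""
    h0, f0 = gen.draw_haplotypes(n_cal)
    h1, f1 = gen.draw_haplotypes(n_cal)
    geno = h0 + h1
    dos = _founder_dosages(cfg, f0, f1)
    eta = _linear_predictor(cfg, geno, dos)

    def mean_prev(delta):
        return float(expit(eta + delta).mean())

    lo, hi = -50.0, 50.0
    plo, phi = mean_prev(lo), mean_prev(hi)
    if not plo <= cfg.prevalence <= phi:
        raise ValueError(
            f"requested prevalence {cfg.prevalence} unattainable; achievable "
            f"range is [{plo:.4g}, {phi:.4g}] under the planted penetrances"
        )
    for _ in range(80):
        mid = (lo + hi) / 2
        if mean_prev(mid) < cfg.prevalence:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def _founder_dosages(cfg: SimulationConfig, f0, f1) -> np.ndarray:
    n_alleles = cfg.risk_haplotypes.n_alleles if cfg.risk_haplotypes is not None else 1
    dos = np.zeros((len(f0), n_alleles))
    for f in (f0, f1):
        np.add.at(dos, (np.arange(len(f)), f), 1.0)
    return dos


def _snp_meta(cfg: SimulationConfig) -> pd.DataFrame:
    rows = []
    pos = 25_600_000
    for b in range(cfg.n_blocks):
        for j in range(cfg.snps_per_block):
            rows.append((f"b{b}_s{j}", "6", pos, "A", "B"))
            pos += 5_000
    pos += 2_000_000
    for i in range(len(cfg.planted_models)):
        for tag in ("a", "b"):
            rows.append((f"pl{i}_{tag}", "6", pos, "A", "B"))
            pos += 50_000
    return pd.DataFrame(rows, columns=["snp", "chrom", "pos", "a1", "a2"])


def simulate_cohort(config: SimulationConfig) -> GenotypeStudy:
    """Simulate an ascertained case-control cohort; see module docstring."""
    study, _, _ = simulate_cohort_full(config)
    return study


def simulate_cohort_full(config: SimulationConfig):
    """Simulate and also return risk-haplotype dosages and the truth key.

    Returns (study, dosages, truth) where ``dosages`` is an
    (n_samples, n_alleles) matrix aligned with the study's samples.
    """
    rng = np.random.default_rng(config.seed)
    gen = _Generator(config, rng)
    delta = _calibrate_intercept(config, gen)

    need_cases, need_controls = config.n_cases, config.n_controls
    cases, controls = [], []
    batch = max(2048, 4 * (need_cases + need_controls))
    cap = 50 * (
        need_cases / config.prevalence + need_controls / (1 - config.prevalence)
    )
    drawn = 0
    while (
        sum(x[0].shape[0] for x in cases) < need_cases
        or sum(x[0].shape[0] for x in controls) < need_controls
    ):
        if drawn > cap:
            raise RuntimeError(
                "rejection sampling exceeded its draw budget; the requested "
                "case/control counts are unattainable at this prevalence"
            )
        h0, f0 = gen.draw_haplotypes(batch)
        h1, f1 = gen.draw_haplotypes(batch)
        drawn += batch
        geno = h0 + h1
        dos = _founder_dosages(config, f0, f1)
        prob = expit(_linear_predictor(config, geno, dos) + delta)
        disease = rng.random(batch) < prob
        cases.append((h0[disease], h1[disease], dos[disease]))
        controls.append((h0[~disease], h1[~disease], dos[~disease]))

    def take(parts, n):
        h0 = np.concatenate([p[0] for p in parts])[:n]
        h1 = np.concatenate([p[1] for p in parts])[:n]
        d = np.concatenate([p[2] for p in parts])[:n]
        return h0, h1, d

    ch0, ch1, cdos = take(cases, need_cases)
    uh0, uh1, udos = take(controls, need_controls)
    h0 = np.concatenate([ch0, uh0]).astype(np.int8)
    h1 = np.concatenate([ch1, uh1]).astype(np.int8)
    dosages = np.concatenate([cdos, udos])
    pheno = np.concatenate(
        [np.ones(need_cases, dtype=np.int8), np.zeros(need_controls, dtype=np.int8)]
    )
    sample_ids = [f"case{i:05d}" for i in range(need_cases)] + [
        f"ctrl{i:05d}" for i in range(need_controls)
    ]
    study = GenotypeStudy(
        genotypes=(h0 + h1).astype(np.int8),
        phenotype=pheno,
        snp_meta=_snp_meta(config),
        sample_ids=sample_ids,
        phase=(h0, h1),
    )
    return orient_to_minor(study), dosages, planted_truth(config)


def superpopulation_probs(config: SimulationConfig, n: int) -> np.ndarray:
    """Disease probabilities of an unascertained superpopulation sample."""
    rng = np.random.default_rng(config.seed)
    gen = _Generator(config, rng)
    delta = _calibrate_intercept(config, gen)
    h0, f0 = gen.draw_haplotypes(n)
    h1, f1 = gen.draw_haplotypes(n)
    dos = _founder_dosages(config, f0, f1)
    return expit(_linear_predictor(config, h0 + h1, dos) + delta)


def planted_truth(config: SimulationConfig):
    """Machine-readable answer key for parameter-recovery tests.

    One record per planted model (haplotype-independent by construction)
    and one per declared artifact pair (mediated by the risk haplotype).
    """
    meta = _snp_meta(config)
    snps = meta["snp"].to_numpy()
    records = []
    for i, model in enumerate(config.planted_models):
        la, lb = config.planted_loci(i)
        records.append(
            {
                "pair": (snps[la], snps[lb]),
                "loci": (la, lb),
                "model": model,
                "haplotype_independent": True,
            }
        )
    for (la, lb) in config.artifact_pairs:
        records.append(
            {
                "pair": (snps[la], snps[lb]),
                "loci": (la, lb),
                "model": None,
                "haplotype_independent": False,
            }
        )
    return records


def haplotype_artifact_config(
    n_cases: int,
    n_controls: int,
    seed: int,
    hap_log_odds: float = 1.5,
    within_block_r2: float = 0.5,
    n_blocks: int = 2,
    snps_per_block: int = 6,
    prevalence: float = 0.05,
) -> SimulationConfig:
    """Scenario where two SNPs each partially tag one strong risk haplotype.

    There is no true pair effect; any pairwise interaction found among
    block-0 SNPs is induced by the haplotype and must fail the
    haplotype-independence test.  The block's first two SNPs are forced to
    complementary half-patterns of the 8 founders, so only their joint
    haplotype (not either SNP alone) identifies the risk founder.
    """
    log_odds = np.zeros(8)
    log_odds[0] = hap_log_odds
    pattern = np.zeros((8, 2), dtype=np.int8)
    pattern[[0, 1, 2, 3], 0] = 1  # SNP 0 tags founders {0,1,2,3}
    pattern[[0, 4, 5, 6], 1] = 1  # SNP 1 tags founders {0,4,5,6}
    return SimulationConfig(
        n_cases=n_cases,
        n_controls=n_controls,
        seed=seed,
        n_blocks=n_blocks,
        snps_per_block=snps_per_block,
        within_block_r2=within_block_r2,
        risk_haplotypes=RiskHaplotypes(log_odds=log_odds, block=0),
        artifact_pairs=[(0, 1)],
        founder_overrides={0: pattern},
        prevalence=prevalence,
    )


def write_truth(records, path: str | Path) -> None:
    """Serialize a truth key as JSON (penetrances as nested lists)."""
    out = []
    for r in records:
        item = dict(r)
        if item["model"] is not None:
            m = item["model"]
            item["model"] = {
                "penetrance": m.penetrance.tolist(),
                "maf_a": m.maf_a,
                "maf_b": m.maf_b,
                "label": m.label,
            }
        item["pair"] = list(item["pair"])
        item["loci"] = list(item["loci"])
        out.append(item)
    Path(path).write_text(json.dumps(out, indent=1))
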