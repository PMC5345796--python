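"""Linkage disequilibrium between SNPs and between SNP pairs.

A SNP pair is treated as one multi-allelic locus whose 4 alleles are the
haplotypes of its two SNPs; dependence between two such loci is the
chi-squared statistic on the 4x4 joint haplotype table divided by the
number of haplotypes (Hill's Q, the multi-allelic extension of r2).
Computed on phased control haplotypes only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class HaplotypeTable:
    """k x l joint haplotype-allele counts over 2n control haplotypes."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def n_haplotypes(self) -> int:
        return int(self.counts.sum())


def _chi2_stat(counts: np.ndarray) -> float:
    """Pearson chi-squared; cells with zero expectation contribute 0."""
    total = counts.sum()
    if total == 0:
        raise ValueError("empty haplotype table")
    e = np.outer(counts.sum(axis=1), counts.sum(axis=0)) / total
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(e > 0, (counts - e) ** 2 / np.where(e > 0, e, 1.0), 0.0)
    return float(terms.sum())


def q_statistic(alleles_a: np.ndarray, alleles_b: np.ndarray, normalization: str = "none") -> float:
    """Q = chi2 / (2n) on the joint allele table of two multi-allelic loci.

    ``alleles_a``/``alleles_b`` are integer allele codes per haplotype.
    With ``normalization='df'`` the printed form is divided by
    (k - 1)(l - 1) over the observed allele counts (Hill's original
    normalization); the default is the raw chi2 / 2n form.
    """
    a = np.asarray(alleles_a)
    b = np.asarray(alleles_b)
    if a.shape != b.shape:
        raise ValueError("allele vectors must align")
    ka, kb = a.max() + 1, b.max() + 1
    counts = np.zeros((ka, kb), dtype=np.int64)
    np.add.at(counts, (a, b), 1)
    q = _chi2_stat(counts) / counts.sum()
    if normalization == "df":
        k_eff = (counts.sum(axis=1) > 0).sum()
        l_eff = (counts.sum(axis=0) > 0).sum()
        denom = max((k_eff - 1) * (l_eff - 1), 1)
        q /= denom
    elif normalization != "none":
        raise ValueError("normalization must be 'none' or 'df'")
    return q


def pairwise_ld(table: HaplotypeTable) -> tuple[float, float]:
    """(r2, |D'|) from a 2x2 haplotype count table."""
    c = table.counts
    if c.shape != (2, 2):
        raise ValueError("pairwise LD needs a 2x2 table")
    t = c.sum()
    pa, pb = c.sum(axis=1)[1] / t, c.sum(axis=0)[1] / t
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        raise ValueError("monomorphic locus")
    r2 = _chi2_stat(c) / t
    d = c[1, 1] / t - pa * pb
    if d >= 0:
        dmax = min(pa * (1 - pb), (1 - pa) * pb)
    else:
        dmax = min(pa * pb, (1 - pa) * (1 - pb))
    dprime = abs(d) / dmax if dmax > 0 else 0.0
    return float(r2), float(dprime)


def snp_r2(h_a: np.ndarray, h_b: np.ndarray) -> float:
    """r2 between two SNPs from phased 0/1 haplotype alleles."""
    counts = np.zeros((2, 2), dtype=np.int64)
    np.add.at(counts, (h_a.astype(int), h_b.astype(int)), 1)
    return pairwise_ld(HaplotypeTable(counts))[0]


def _control_haplotypes(study) -> np.ndarray:
    if study.phase is None:
        raise ValueError("phased haplotypes required")
    ctrl = study.phenotype == 0
    return np.concatenate([study.phase[0][ctrl], study.phase[1][ctrl]], axis=0)


def hills_q(
    pair_a: tuple[int, int],
    pair_b: tuple[int, int],
    haplotypes: np.ndarray,
    normalization: str = "none",
) -> float:
    """Hill's Q between two SNP pairs on phased haplotypes.

    Each pair is collapsed to a 4-allele locus (2 * allele1 + allele2);
    ``haplotypes`` is a (2n, M) 0/1 matrix of control haplotypes.
    """
    codes_a = 2 * haplotypes[:, pair_a[0]].astype(int) + haplotypes[:, pair_a[1]]
    codes_b = 2 * haplotypes[:, pair_b[0]].astype(int) + haplotypes[:, pair_b[1]]
    return q_statistic(codes_a, codes_b, normalization=normalization)


def prune_independent(
    pairs: list[tuple[int, int]],
    haplotypes: np.ndarray,
    q_max: float = 0.3,
    normalization: str = "none",
) -> list[int]:
    """Greedy reduction of ranked pairs to independent interaction signals.

    ``pairs`` must be ranked most significant first.  The best pair is
    accepted; every later pair with Q > q_max against ANY accepted pair is
    rejected.  Returns indices of accepted pairs.
    """
    accepted: list[int] = []
    for i, pair in enumerate(pairs):
        ok = True
        for j in accepted:
            if hills_q(pairs[j], pair, haplotypes, normalization=normalization) > q_max:
                ok = False
                break
        if ok:
            accepted.append(i)
    return accepted
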