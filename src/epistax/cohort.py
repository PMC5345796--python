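"""Case-control genotype cohorts: PLINK I/O and quality control.

Genotypes are stored as minor-allele counts in ``{0, 1, 2}`` with ``-1``
marking missing calls.  The minor allele is determined once, in the full
sample, so encodings remain stable across any downstream subsetting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1

_AUTOSOMES = {str(c) for c in range(1, 23)}

# PLINK bed 2-bit codes -> minor allele (A1) count; 0b01 is missing.
_BED_DECODE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_BED_ENCODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


@dataclass
class GenotypeStudy:
    """A samples x SNPs hard-call matrix with phenotype and metadata.

    Attributes
    ----------
    genotypes : (n_samples, n_snps) int8 array
        Minor-allele counts, ``-1`` = missing.
    phenotype : (n_samples,) int8 array
        1 = case, 0 = control.
    snp_meta : DataFrame with columns snp, chrom, pos, a1, a2
        ``a1`` is the counted (minor) allele.
    sample_ids : list of unique sample identifiers.
    phase : optional pair of (n_samples, n_snps) 0/1 haplotype matrices.
    """

    genotypes: np.ndarray
    phenotype: np.ndarray
    snp_meta: pd.DataFrame
    sample_ids: list[str]
    phase: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.phenotype = np.asarray(self.phenotype, dtype=np.int8)
        n, m = self.genotypes.shape
        if self.phenotype.shape != (n,):
            raise ValueError("phenotype length does not match sample count")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match sample count")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids are not unique")
        if len(self.snp_meta) != m:
            raise ValueError("snp_meta rows do not match SNP count")
        bad = ~np.isin(self.genotypes, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("genotype values outside {0,1,2,missing}")
        if not np.isin(self.phenotype, [0, 1]).all():
            raise ValueError("phenotype values outside {0,1}")
        if self.phase is not None:
            h0, h1 = self.phase
            ok = self.genotypes != MISSING
            if not np.array_equal((h0 + h1)[ok], self.genotypes[ok]):
                raise ValueError("haplotypes do not sum to genotypes")

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_cases(self) -> int:
        return int((self.phenotype == 1).sum())

    @property
    def n_controls(self) -> int:
        return int((self.phenotype == 0).sum())

    def subset(self, sample_mask=None, snp_mask=None) -> "GenotypeStudy":
        """Return a new study restricted to the masked samples/SNPs."""
        sample_mask = (
            np.ones(self.n_samples, bool) if sample_mask is None else np.asarray(sample_mask)
        )
        snp_mask = np.ones(self.n_snps, bool) if snp_mask is None else np.asarray(snp_mask)
        phase = None
        if self.phase is not None:
            phase = tuple(h[np.ix_(sample_mask, snp_mask)] for h in self.phase)
        return GenotypeStudy(
            genotypes=self.genotypes[np.ix_(sample_mask, snp_mask)],
            phenotype=self.phenotype[sample_mask],
            snp_meta=self.snp_meta.loc[snp_mask].reset_index(drop=True),
            sample_ids=[s for s, keep in zip(self.sample_ids, sample_mask) if keep],
            phase=phase,
        )


@dataclass
class QcReport:
    """Record of removed SNPs/samples with one primary reason code each."""

    removed_snps: list[tuple[str, str]] = field(default_factory=list)
    removed_samples: list[tuple[str, str]] = field(default_factory=list)
    thresholds: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# PLINK bed/bim/fam
# ---------------------------------------------------------------------------


def read_plink(path_prefix: str | Path) -> GenotypeStudy:
    """Read a PLINK bed/bim/fam triple (bed v1.00, SNP-major).

    Allele counts are re-oriented to the minor allele computed in the full
    sample; on-disk phenotypes 1/2 map to control=0/case=1.
    """
    prefix = Path(path_prefix)
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
        dtype=str,
    )
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "snp": str, "a1": str, "a2": str},
    )
    n, m = len(fam), len(bim)
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw[:3].tobytes() != b"\x6c\x1b\x01":
        raise ValueError("not a SNP-major PLINK bed v1.00 file")
    bytes_per_snp = (n + 3) // 4
    if raw.size != 3 + bytes_per_snp * m:
        raise ValueError(
            f"bed size {raw.size} inconsistent with {n} samples x {m} SNPs"
        )
    body = raw[3:].reshape(m, bytes_per_snp)
    # unpack 2-bit codes, sample order runs from the low bits of each byte
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (body[:, :, None] >> shifts[None, None, :]) & 0b11
    geno = _BED_DECODE[codes.reshape(m, -1)[:, :n]].T.copy()  # samples x snps

    pheno = np.empty(n, dtype=np.int8)
    for i, p in enumerate(fam["pheno"]):
        if p == "2":
            pheno[i] = 1
        elif p == "1":
            pheno[i] = 0
        else:
            raise ValueError(f"unsupported fam phenotype code {p!r}")

    meta = bim[["snp", "chrom", "pos", "a1", "a2"]].copy()
    study = GenotypeStudy(
        genotypes=geno,
        phenotype=pheno,
        snp_meta=meta.reset_index(drop=True),
        sample_ids=list(fam["iid"]),
    )
    return orient_to_minor(study)


def write_plink(study: GenotypeStudy, path_prefix: str | Path) -> None:
    """Write bed/bim/fam; fam phenotype uses 1=control, 2=case."""
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = study.genotypes.shape
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for sid, ph in zip(study.sample_ids, study.phenotype):
            fh.write(f"{sid} {sid} 0 0 0 {2 if ph == 1 else 1}\n")
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for _, row in study.snp_meta.iterrows():
            fh.write(f"{row.chrom}\t{row.snp}\t0\t{row.pos}\t{row.a1}\t{row.a2}\n")
    bytes_per_snp = (n + 3) // 4
    codes = np.zeros((m, bytes_per_snp * 4), dtype=np.uint8)
    enc = np.zeros(4, dtype=np.uint8)
    for g, c in _BED_ENCODE.items():
        enc[g % 4] = c  # index -1 -> 3
    codes[:, :n] = enc[study.genotypes.T % 4]
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    packed = (codes.reshape(m, bytes_per_snp, 4) << shifts).sum(axis=2).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(b"\x6c\x1b\x01")
        fh.write(packed.tobytes())


def write_phase(study: GenotypeStudy, path: str | Path) -> None:
    """Write the phased haplotypes as text, one line per haplotype."""
    if study.phase is None:
        raise ValueError("study carries no phase information")
    with open(path, "w") as fh:
        for hap_idx, hap in enumerate(study.phase):
            for i, sid in enumerate(study.sample_ids):
                alleles = " ".join(str(int(a)) for a in hap[i])
                fh.write(f"{sid} {hap_idx} {alleles}\n")


def read_phase(path: str | Path, study: GenotypeStudy) -> GenotypeStudy:
    """Attach haplotypes from a phase sidecar file to *study*."""
    h = {0: {}, 1: {}}
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            sid, idx = parts[0], int(parts[1])
            h[idx][sid] = np.array(parts[2:], dtype=np.int8)
    mats = []
    for idx in (0, 1):
        mats.append(np.stack([h[idx][sid] for sid in study.sample_ids]))
    return replace(study, phase=(mats[0], mats[1]))


def orient_to_minor(study: GenotypeStudy) -> GenotypeStudy:
    """Flip SNPs so counts refer to the minor allele in the full sample."""
    geno = study.genotypes.copy()
    meta = study.snp_meta.copy()
    obs = geno != MISSING
    with np.errstate(invalid="ignore"):
        freq = np.where(
            obs.sum(axis=0) > 0,
            np.where(geno == MISSING, 0, geno).sum(axis=0) / (2 * np.maximum(obs.sum(axis=0), 1)),
            0.0,
        )
    flip = freq > 0.5
    geno[:, flip] = np.where(
        geno[:, flip] == MISSING, MISSING, 2 - geno[:, flip]
    ).astype(np.int8)
    a1 = meta["a1"].to_numpy().copy()
    a2 = meta["a2"].to_numpy().copy()
    a1[flip], a2[flip] = a2[flip], a1[flip].copy()
    meta["a1"], meta["a2"] = a1, a2
    phase = study.phase
    if phase is not None:
        phase = tuple(np.where(flip[None, :], 1 - h, h).astype(np.int8) for h in phase)
    return replace(study, genotypes=geno, snp_meta=meta, phase=phase)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------


def hwe_exact_test(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Two-sided exact HWE p-value (Wigginton-style conditional test).

    Sums the probabilities of all heterozygote counts, conditional on the
    observed allele counts, whose probability does not exceed that of the
    observed configuration.
    """
    n = n_het + n_hom1 + n_hom2
    if n == 0:
        return 1.0
    n_rare = 2 * min(n_hom1, n_hom2) + n_het
    # feasible het counts share the parity of the rare-allele count
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    if len(hets) == 0:
        return 1.0
    # unnormalized probabilities via the standard recurrence
    probs = np.zeros(len(hets))
    mid_idx = len(hets) // 2
    probs[mid_idx] = 1.0
    for i in range(mid_idx, 0, -1):
        het = hets[i]
        hom_r = (n_rare - het) // 2
        hom_c = n - het - hom_r
        probs[i - 1] = probs[i] * het * (het - 1) / (4.0 * (hom_r + 1) * (hom_c + 1))
    for i in range(mid_idx, len(hets) - 1):
        het = hets[i]
        hom_r = (n_rare - het) // 2
        hom_c = n - het - hom_r
        probs[i + 1] = probs[i] * 4.0 * hom_r * hom_c / ((het + 2.0) * (het + 1.0))
    probs /= probs.sum()
    p_obs = probs[np.searchsorted(hets, n_het)]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# QC filters
# ---------------------------------------------------------------------------


def apply_snp_qc(
    study: GenotypeStudy,
    maf_min: float = 0.05,
    miss_max: float = 0.01,
    hwe_p_min: float = 5e-6,
) -> tuple[GenotypeStudy, QcReport]:
    """Drop non-autosomal, rare, poorly called, and HWE-deviant SNPs.

    HWE is evaluated in controls only; raises if no controls are present.
    Each removed SNP carries the first failing reason in the order
    nonautosomal, maf, missingness, hwe.
    """
    controls = study.phenotype == 0
    if not controls.any():
        raise ValueError("HWE filtering requires control samples")
    geno = study.genotypes
    obs = geno != MISSING
    n_obs = obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(geno == MISSING, 0, geno).sum(axis=0) / (2.0 * np.maximum(n_obs, 1))
    maf = np.minimum(freq, 1 - freq)
    missing_rate = 1.0 - n_obs / study.n_samples

    report = QcReport(
        thresholds={"maf_min": maf_min, "miss_max": miss_max, "hwe_p_min": hwe_p_min}
    )
    keep = np.ones(study.n_snps, dtype=bool)
    ctrl_geno = geno[controls]
    for j in range(study.n_snps):
        snp_id = study.snp_meta["snp"].iloc[j]
        if str(study.snp_meta["chrom"].iloc[j]) not in _AUTOSOMES:
            reason = "nonautosomal"
        elif maf[j] < maf_min:
            reason = "maf"
        elif missing_rate[j] > miss_max:
            reason = "missingness"
        else:
            col = ctrl_geno[:, j]
            n_hom1 = int((col == 0).sum())
            n_het = int((col == 1).sum())
            n_hom2 = int((col == 2).sum())
            if hwe_exact_test(n_het, n_hom1, n_hom2) < hwe_p_min:
                reason = "hwe"
            else:
                continue
        keep[j] = False
        report.removed_snps.append((snp_id, reason))
    return study.subset(snp_mask=keep), report


def estimate_pihat(study: GenotypeStudy, thin_r2: float | None = 0.2) -> np.ndarray:
    """Method-of-moments pairwise IBD-sharing estimates on thinned SNPs.

    Returns a symmetric (n, n) matrix; entry (j, k) is the genomic
    relationship between samples j and k, which estimates pi-hat for
    outbred pairs (duplicates approach 1, unrelated pairs 0).  Pass
    ``thin_r2=None`` to use all SNPs.
    """
    if thin_r2 is None:
        snps = np.arange(study.n_snps)
    else:
        snps = ld_thin_indices(study, r2_max=thin_r2)
    geno = study.genotypes[:, snps].astype(float)
    geno[geno == MISSING] = np.nan
    p = np.nanmean(geno, axis=0) / 2.0
    usable = (p > 0.01) & (p < 0.99)
    geno, p = geno[:, usable], p[usable]
    z = (geno - 2 * p) / np.sqrt(2 * p * (1 - p))
    z = np.nan_to_num(z)
    m = z.shape[1]
    if m == 0:
        return np.zeros((study.n_samples, study.n_samples))
    a = z @ z.T / m
    np.fill_diagonal(a, 1.0)
    return np.clip(a, 0.0, None)


def ld_thin_indices(study: GenotypeStudy, r2_max: float = 0.2, window: int = 50) -> np.ndarray:
    """Greedy windowed LD thinning; returns indices of retained SNPs."""
    if r2_max >= 1.0:
        return np.arange(study.n_snps)
    geno = study.genotypes.astype(float)
    geno[geno == MISSING] = np.nan
    kept: list[int] = []
    for j in range(study.n_snps):
        ok = True
        for k in reversed(kept):
            if j - k > window:
                break
            both = ~np.isnan(geno[:, j]) & ~np.isnan(geno[:, k])
            if both.sum() < 3:
                continue
            x, y = geno[both, j], geno[both, k]
            if x.std() == 0 or y.std() == 0:
                continue
            r = np.corrcoef(x, y)[0, 1]
            if r * r > r2_max:
                ok = False
                break
        if ok:
            kept.append(j)
    return np.array(kept, dtype=int)


def apply_sample_qc(
    study: GenotypeStudy,
    miss_max: float = 0.01,
    pihat_max: float = 0.05,
    thin_r2: float | None = 0.2,
    min_relatedness_snps: int = 200,
) -> tuple[GenotypeStudy, QcReport]:
    """Drop high-missingness samples, then one member of each related pair.

    For a pair exceeding ``pihat_max`` the member with higher missingness is
    dropped; ties broken by dropping the lexicographically larger sample_id.
    The relatedness step is skipped (with a warning) when fewer than
    ``min_relatedness_snps`` thinned SNPs are available, because the
    method-of-moments estimate is too noisy to threshold at 0.05.
    """
    if study.n_samples < 2:
        raise ValueError("sample QC requires at least 2 samples")
    report = QcReport(thresholds={"miss_max": miss_max, "pihat_max": pihat_max})
    miss = (study.genotypes == MISSING).mean(axis=1)
    keep = miss <= miss_max
    for sid, m, k in zip(study.sample_ids, miss, keep):
        if not k:
            report.removed_samples.append((sid, "missingness"))
    study2 = study.subset(sample_mask=keep)
    miss2 = (study2.genotypes == MISSING).mean(axis=1)

    n_informative = (
        study2.n_snps if thin_r2 is None else len(ld_thin_indices(study2, r2_max=thin_r2))
    )
    if n_informative < min_relatedness_snps:
        warnings.warn(
            f"only {n_informative} thinned SNPs; skipping the relatedness filter"
        )
        return study2, report
    pihat = estimate_pihat(study2, thin_r2=thin_r2)
    n = study2.n_samples
    alive = np.ones(n, dtype=bool)
    pairs = [
        (j, k)
        for j in range(n)
        for k in range(j + 1, n)
        if pihat[j, k] > pihat_max
    ]
    # resolve most-related pairs first so the choice is deterministic
    pairs.sort(key=lambda jk: -pihat[jk[0], jk[1]])
    for j, k in pairs:
        if not (alive[j] and alive[k]):
            continue
        if miss2[j] > miss2[k]:
            drop = j
        elif miss2[k] > miss2[j]:
            drop = k
        else:
            drop = j if study2.sample_ids[j] > study2.sample_ids[k] else k
        alive[drop] = False
        report.removed_samples.append((study2.sample_ids[drop], "relatedness"))
    return study2.subset(sample_mask=alive), report
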