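"""Multi-cohort orchestration: cross-cohort replication of interaction
pairs, rank-overlap curves, region tallies, and the end-to-end pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from epistax import pairscan
from epistax.cohort import GenotypeStudy, apply_sample_qc, apply_snp_qc
from epistax.ldprune import prune_independent
from epistax.simulate import SimulationConfig, simulate_cohort_full

#: conventional extended-MHC span (chromosome, start, end in bp)
DEFAULT_MHC_REGION = ("6", 25_600_000, 33_400_000)


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class CohortScan:
    """Ranked pair results of one cohort with its Bonferroni cutoff."""

    cohort_id: str
    results: pd.DataFrame  # snp_a, snp_b, chr_a, pos_a, chr_b, pos_b, p_raw, p_adjusted, ...
    bonferroni: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.results.copy()
        df["pair_key"] = [
            _pair_key(a, b) for a, b in zip(df["snp_a"], df["snp_b"])
        ]
        sort_cols = ["p_adjusted", "p_raw"]
        extra = [c for c in ("chr_a", "pos_a", "chr_b", "pos_b") if c in df.columns]
        df = df.sort_values(sort_cols + extra, kind="stable").reset_index(drop=True)
        self.results = df

    @property
    def significant(self) -> set:
        df = self.results
        return set(df.loc[df["p_adjusted"] <= self.bonferroni, "pair_key"])

    def ranking(self) -> list:
        return list(self.results["pair_key"])


def scan_cohort(
    study: GenotypeStudy,
    cohort_id: str,
    seed: int,
    alpha: float = 0.05,
    n_permutations: int = 1,
) -> CohortScan:
    """Full scan + permutation calibration for one cohort."""
    iu, ju, log10_p, _ = pairscan.scan_pvalues(study)
    null_pool = pairscan.permuted_scan_pvalues(study, seed=seed, n_permutations=n_permutations)
    p_adj = pairscan.calibrate_pvalues(log10_p, null_pool)
    meta = study.snp_meta
    df = pd.DataFrame(
        {
            "snp_a": meta["snp"].to_numpy()[iu],
            "snp_b": meta["snp"].to_numpy()[ju],
            "chr_a": meta["chrom"].to_numpy()[iu],
            "pos_a": meta["pos"].to_numpy()[iu],
            "chr_b": meta["chrom"].to_numpy()[ju],
            "pos_b": meta["pos"].to_numpy()[ju],
            "p_raw": 10.0**log10_p,
            "log10_p_raw": log10_p,
            "p_adjusted": p_adj,
        }
    )
    return CohortScan(
        cohort_id=cohort_id,
        results=df,
        bonferroni=pairscan.bonferroni_threshold(study.n_snps, alpha),
    )


def define_vips(discovery: CohortScan, others: list[CohortScan]) -> list:
    """Pairs Bonferroni-significant in discovery AND >=1 other cohort."""
    if not others:
        raise ValueError("need at least one non-discovery cohort")
    disc = discovery.significant
    replicated = set()
    for other in others:
        shared_snps = set(other.results["snp_a"]) | set(other.results["snp_b"])
        disc_snps = set(discovery.results["snp_a"]) | set(discovery.results["snp_b"])
        if not shared_snps & disc_snps:
            warnings.warn(f"disjoint SNP panels between {discovery.cohort_id} and {other.cohort_id}")
        replicated |= disc & other.significant
    order = {k: i for i, k in enumerate(discovery.ranking())}
    return sorted(replicated, key=lambda k: order.get(k, len(order)))


def overlap_curve(ranking_a: list, ranking_b: list, k_grid) -> pd.DataFrame:
    """Fraction of shared pairs among the top-k of two rankings."""
    rows = []
    max_k = min(len(ranking_a), len(ranking_b))
    for k in k_grid:
        if k > max_k:
            warnings.warn(f"k={k} exceeds ranking length; truncated to {max_k}")
            k = max_k
        top_a, top_b = set(ranking_a[:k]), set(ranking_b[:k])
        rows.append((k, len(top_a & top_b) / k if k else 0.0))
    return pd.DataFrame(rows, columns=["k", "overlap"])


def _in_region(chrom, pos, region) -> bool:
    rchrom, start, end = region
    return str(chrom) == str(rchrom) and start <= pos <= end


def region_tally(
    scans: list[CohortScan],
    replicated_keys: set,
    region=DEFAULT_MHC_REGION,
) -> pd.DataFrame:
    """Counts of (both-inside / one-inside / both-outside) x (significant,
    replicated) per cohort, plus a unique-pairs row."""
    categories = ["both_inside", "one_inside", "both_outside"]
    rows = {}
    union: dict[str, set] = {c: set() for c in categories}
    union_rep: dict[str, set] = {c: set() for c in categories}
    for scan in scans:
        df = scan.results
        sig = df[df["p_adjusted"] <= scan.bonferroni]
        counts = {c: [0, 0] for c in categories}
        for _, r in sig.iterrows():
            n_in = _in_region(r["chr_a"], r["pos_a"], region) + _in_region(
                r["chr_b"], r["pos_b"], region
            )
            cat = categories[2 - n_in]
            counts[cat][0] += 1
            union[cat].add(r["pair_key"])
            if r["pair_key"] in replicated_keys:
                counts[cat][1] += 1
                union_rep[cat].add(r["pair_key"])
        rows[scan.cohort_id] = [x for c in categories for x in counts[c]]
    rows["unique_pairs"] = [
        x for c in categories for x in (len(union[c]), len(union_rep[c]))
    ]
    cols = pd.MultiIndex.from_product([categories, ["significant", "replicated"]])
    return pd.DataFrame.from_dict(rows, orient="index").set_axis(cols, axis=1)


# ---------------------------------------------------------------------------
# end-to-end pipeline on synthetic cohorts
# ---------------------------------------------------------------------------


def run_pipeline(
    configs: dict[str, SimulationConfig],
    seed: int,
    q_max: float = 0.3,
    n_permutations: int = 1,
):
    """simulate -> qc -> scan -> replicate -> prune, for named cohorts.

    The first config is the discovery cohort.  Returns a dict with the
    per-cohort scans, the replicated pair list, and the independent-signal
    representatives after Hill's Q pruning.
    """
    scans, studies = {}, {}
    for i, (name, cfg) in enumerate(configs.items()):
        study, dosages, truth = simulate_cohort_full(cfg)
        study, _ = apply_snp_qc(study)
        study, _ = apply_sample_qc(study)
        studies[name] = (study, dosages, truth)
        scans[name] = scan_cohort(study, name, seed=seed + i, n_permutations=n_permutations)
    names = list(configs)
    discovery = scans[names[0]]
    vips = define_vips(discovery, [scans[n] for n in names[1:]])

    disc_study = studies[names[0]][0]
    snp_idx = {s: i for i, s in enumerate(disc_study.snp_meta["snp"])}
    pair_indices = [(snp_idx[a], snp_idx[b]) for a, b in vips if a in snp_idx and b in snp_idx]
    ctrl = disc_study.phenotype == 0
    haps = np.concatenate([disc_study.phase[0][ctrl], disc_study.phase[1][ctrl]], axis=0)
    accepted = prune_independent(pair_indices, haps, q_max=q_max)
    return {
        "scans": scans,
        "studies": studies,
        "vips": vips,
        "independent_signals": [vips[i] for i in accepted],
    }
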