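"""Replication of candidate loci in an independent cohort.

The replication cohort contributes per-pool univariate GWAS results (one
record per SNP x trait x time interval x pool: effect size, standard error,
sample size, effect allele).  Pools are combined by fixed-effect
inverse-variance-weighted (IVW) meta-analysis; each phenotype's time
intervals are then tested jointly with the same Z-based multivariate
statistic used in discovery, with V0 re-estimated from the replication
cohort's own Z-scores.  Intervals whose univariate sample size is not
above ``min_n`` are dropped (the chi-square df shrinks accordingly).  A
locus replicates when it passes the Bonferroni threshold
alpha / (n_candidate_SNPs x n_multivariate_traits) for at least one
phenotype, and — for significant loci — when the productivity-increasing
allele agrees with discovery after allele alignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .manova import manova_log10p, manova_scores, validate_corr
from .sumstats import align_alleles, is_strand_ambiguous

logger = logging.getLogger(__name__)

POOL_RECORD_COLUMNS = ("rsid", "trait", "interval", "pool", "beta", "se", "n",
                       "eff_allele")

MIN_N_DEFAULT = 20  # interval kept only if its sample size is strictly above


def ivw_meta(betas: np.ndarray, ses: np.ndarray) -> tuple[float, float, float]:
    """Fixed-effect inverse-variance-weighted meta-analysis.

    Weights w = 1/SE^2; beta_meta = sum(w * beta) / sum(w);
    SE_meta = 1 / sqrt(sum(w)); Z_meta = beta_meta / SE_meta.
    """
    betas = np.atleast_1d(np.asarray(betas, dtype=float))
    ses = np.atleast_1d(np.asarray(ses, dtype=float))
    if betas.shape != ses.shape or betas.size < 1:
        raise ValueError("betas and ses must be equal-length, non-empty")
    if np.any(ses <= 0):
        raise ValueError("standard errors must be positive")
    w = 1.0 / ses**2
    beta_meta = float(np.sum(w * betas) / np.sum(w))
    se_meta = float(1.0 / np.sqrt(np.sum(w)))
    return beta_meta, se_meta, beta_meta / se_meta


def meta_analyze_pools(records: pd.DataFrame) -> pd.DataFrame:
    """IVW-combine per-pool GWAS records per (rsid, trait, interval).

    Effect frames are aligned to the first pool's effect allele: a record
    whose effect allele is the other allele of the pair has its beta sign
    flipped (biallelic SNPs).  Sample sizes add across pools.
    """
    missing = [c for c in POOL_RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise ConfigError(f"pool GWAS records missing columns: {missing}")
    if (records["se"] <= 0).any():
        raise ValueError("pool records contain non-positive standard errors")
    rows = []
    for (rsid, trait, interval), grp in records.groupby(
        ["rsid", "trait", "interval"], sort=True
    ):
        ea0 = str(grp["eff_allele"].iloc[0])
        sign = np.where(grp["eff_allele"].astype(str) == ea0, 1.0, -1.0)
        beta, se, zval = ivw_meta(
            grp["beta"].to_numpy(float) * sign, grp["se"].to_numpy(float)
        )
        rows.append(
            {"rsid": rsid, "trait": trait, "interval": interval, "beta": beta,
             "se": se, "z": zval, "n": float(grp["n"].sum()), "eff_allele": ea0}
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ReplicationTest:
    """One phenotype's multivariate test over its retained time intervals."""

    phenotype: str
    intervals: tuple[str, ...]
    dropped: tuple[str, ...]

    @property
    def df(self) -> int:
        return len(self.intervals)


def replication_threshold(n_snps: int, n_multivariate: int,
                          alpha: float = 0.05) -> float:
    """Bonferroni threshold alpha / (n_candidate_SNPs x n_multivariate_traits)."""
    if n_snps < 1 or n_multivariate < 1:
        raise ValueError("counts must be >= 1")
    return alpha / (n_snps * n_multivariate)


def multivariate_replication(
    z_by_interval: pd.DataFrame,
    v0_rep: pd.DataFrame,
    n_by_interval: Mapping[str, float],
    phenotype: str,
    min_n: float = MIN_N_DEFAULT,
) -> pd.DataFrame:
    """Joint test of one phenotype's time intervals for each candidate SNP.

    ``z_by_interval`` is SNPs x interval-traits (meta-analysed Z);
    ``v0_rep`` the interval-correlation matrix estimated from the
    replication cohort's own Z-scores; ``n_by_interval`` the univariate
    sample sizes.  Intervals with n <= ``min_n`` are dropped and the test
    df shrinks accordingly; if every interval is dropped the phenotype is
    skipped with a warning (empty result).
    """
    kept = [c for c in z_by_interval.columns if n_by_interval[c] > min_n]
    dropped = [c for c in z_by_interval.columns if c not in kept]
    if dropped:
        logger.info("phenotype %s: intervals dropped for n <= %g: %s",
                    phenotype, min_n, dropped)
    if not kept:
        logger.warning("phenotype %s skipped: all intervals have n <= %g",
                       phenotype, min_n)
        return pd.DataFrame(
            columns=["rsid", "phenotype", "t2", "df", "pvalue", "log10p"]
        )
    v0 = validate_corr(v0_rep.loc[kept, kept]) if len(kept) > 1 else pd.DataFrame(
        [[1.0]], index=kept, columns=kept
    )
    t2 = manova_scores(z_by_interval.loc[:, kept].to_numpy(float), v0)
    log10p = manova_log10p(t2, len(kept))
    return pd.DataFrame(
        {
            "rsid": list(z_by_interval.index),
            "phenotype": phenotype,
            "t2": t2,
            "df": len(kept),
            "pvalue": 10.0 ** np.asarray(log10p),
            "log10p": log10p,
        }
    )


def replicate(
    meta: pd.DataFrame,
    v0_by_phenotype: Mapping[str, pd.DataFrame],
    alpha: float = 0.05,
    min_n: float = MIN_N_DEFAULT,
) -> pd.DataFrame:
    """Run the full replication stage on meta-analysed records.

    ``meta`` is the output of :func:`meta_analyze_pools` restricted to the
    candidate SNPs (one row per SNP x trait x interval).  Each phenotype in
    ``meta['trait']`` is tested jointly across its intervals; ``passed``
    flags p below alpha / (n_SNPs x n_phenotypes).
    """
    phenos = sorted(meta["trait"].unique())
    snps = sorted(meta["rsid"].unique())
    frames = []
    for pheno in phenos:
        sub = meta.loc[meta["trait"] == pheno]
        z_wide = sub.pivot(index="rsid", columns="interval", values="z")
        n_by_interval = sub.groupby("interval")["n"].min().to_dict()
        if pheno not in v0_by_phenotype:
            raise ConfigError(f"no V0 supplied for phenotype {pheno!r}")
        frames.append(
            multivariate_replication(
                z_wide, v0_by_phenotype[pheno], n_by_interval, pheno, min_n
            )
        )
    result = pd.concat(frames, ignore_index=True)
    if len(result):
        thr = replication_threshold(len(snps), len(phenos), alpha)
        result["passed"] = result["pvalue"] < thr
        result.attrs["threshold"] = thr
    return result


def direction_consistency(
    discovery_alleles: Sequence[str],
    discovery_z: float,
    replication_alleles: Sequence[str],
    replication_z: float,
) -> bool | None:
    """Does the trait-increasing allele agree between cohorts?

    The replication effect is first expressed in the discovery allele frame
    (sign flip if reference and effect alleles are swapped).  Returns None
    (indeterminate) for strand-ambiguous SNPs (A/T, C/G), whose frames
    cannot be reconciled from summary data across cohorts.
    """
    if is_strand_ambiguous(discovery_alleles) or is_strand_ambiguous(
        replication_alleles
    ):
        return None
    aligned = align_alleles(
        np.array([replication_z], dtype=float), replication_alleles,
        discovery_alleles,
    )
    if not aligned.alignable:
        raise ValueError(
            f"alleles {tuple(replication_alleles)} cannot be aligned to "
            f"{tuple(discovery_alleles)}"
        )
    return bool(np.sign(aligned.z[0]) == np.sign(discovery_z))


def filter_candidates(
    rsids: Sequence[str],
    maf: Mapping[str, float],
    callrate: Mapping[str, float],
    min_maf: float = 0.01,
    min_callrate: float = 0.95,
) -> tuple[list[str], pd.DataFrame]:
    """Pre-replication genotype QC gates: MAF > 1% and call rate > 95%.

    Returns the kept rsids and a table of exclusions with reasons.
    """
    kept, excluded = [], []
    for rsid in rsids:
        m, c = float(maf[rsid]), float(callrate[rsid])
        if not (0 <= m <= 0.5) or not (0 <= c <= 1):
            raise ValueError(f"{rsid}: MAF must be in [0, 0.5], call rate in [0, 1]")
        if m <= min_maf:
            excluded.append({"rsid": rsid, "reason": "MAF", "value": m})
        elif c <= min_callrate:
            excluded.append({"rsid": rsid, "reason": "call rate", "value": c})
        else:
            kept.append(rsid)
    return kept, pd.DataFrame(excluded, columns=["rsid", "reason", "value"])
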