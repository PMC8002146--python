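"""Synthetic genotype/phenotype/summary-statistic generation and oracles.

Every analysis stage in this package consumes GWAS summary statistics; this
module generates synthetic inputs with the statistical structure those
stages assume, so the whole pipeline is testable without any external data:

* diploid genotypes drawn Binomial(2, MAF) independently per SNP (no LD —
  Z-profile LD checks instead use duplicated or shared causal signals);
* multivariate phenotypes ``Y = G_causal B + E`` with correlated residuals
  and standardized traits, so effects are in trait-SD units;
* the univariate ordinary-least-squares scans (optionally with covariates)
  such data produce, giving per-SNP per-trait (beta, SE, Z);
* a direct null generator drawing Z rows i.i.d. MVN(0, V0), the exact null
  of the summary-statistic multivariate test; and
* an individual-level MANOVA oracle (likelihood-ratio statistic from
  residual cross-product matrices) that is computationally independent of
  the Z-based path and serves as its ground truth in tests.

All generators are reproducible bit-for-bit given a seed.

The default study scenario mirrors the shape of a large carcass-trait
meta-analysis at desk scale: 2,000 individuals, 50,000 SNPs, 18 traits
grouped 9/6/3 into mass-, fat- and muscle-related multivariate traits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .manova import validate_corr
from .sumstats import TraitGroup, ZMatrix

DEFAULT_SCENARIO = {
    "n_individuals": 2000,
    "n_snps": 50000,
    "n_traits": 18,
    "group_sizes": (9, 6, 3),
    "maf_range": (0.05, 0.5),
}


@dataclass
class SimTruth:
    """Ground truth of one simulation scenario.

    ``sigma`` is the true phenotypic (residual) correlation matrix;
    ``effect_matrix`` holds per-causal-SNP, per-trait effects in trait-SD
    units (rows align with ``causal_snps``).
    """

    sigma: np.ndarray
    causal_snps: np.ndarray
    effect_matrix: np.ndarray
    mafs: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.sigma = np.asarray(self.sigma, dtype=float)
        validate_corr(pd.DataFrame(self.sigma))
        self.causal_snps = np.asarray(self.causal_snps, dtype=int)
        self.effect_matrix = np.atleast_2d(np.asarray(self.effect_matrix, float))
        self.mafs = np.asarray(self.mafs, dtype=float)
        if np.any((self.mafs <= 0) | (self.mafs > 0.5)):
            raise ValueError("MAFs must lie in (0, 0.5]")
        if self.effect_matrix.shape[0] != self.causal_snps.size:
            raise ValueError("one effect row per causal SNP required")


def equicorrelated(n_traits: int, r: float) -> np.ndarray:
    """Correlation matrix with constant off-diagonal r."""
    sigma = np.full((n_traits, n_traits), float(r))
    np.fill_diagonal(sigma, 1.0)
    return sigma


def simulate_genotypes(
    n_individuals: int,
    n_snps: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int | np.random.Generator = 0,
    mafs: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw a 0/1/2 genotype matrix with per-SNP MAFs.

    Entries are Binomial(2, MAF_s), independent across SNPs and
    individuals (no linkage disequilibrium).  Returns (G, mafs).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if mafs is None:
        lo, hi = maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        mafs = rng.uniform(lo, hi, size=n_snps)
    else:
        mafs = np.asarray(mafs, dtype=float)
    g = rng.binomial(2, mafs[None, :], size=(n_individuals, n_snps)).astype(np.int8)
    return g, mafs


def simulate_phenotypes(
    g: np.ndarray,
    truth: SimTruth,
    standardize: bool = True,
) -> np.ndarray:
    """Phenotypes Y = G_causal B + E, residuals MVN(0, sigma), traits in SD units."""
    rng = np.random.default_rng(truth.seed)
    n, _ = g.shape
    n_traits = truth.sigma.shape[0]
    chol = np.linalg.cholesky(truth.sigma)  # raises if sigma is not PD
    e = rng.standard_normal((n, n_traits)) @ chol.T
    y = e
    if truth.causal_snps.size:
        gc = g[:, truth.causal_snps].astype(float)
        y = gc @ truth.effect_matrix + e
    if standardize:
        y = (y - y.mean(axis=0)) / y.std(axis=0, ddof=1)
    return y


def univariate_gwas(
    g: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Per-SNP, per-trait ordinary least squares with optional covariates.

    Covariates (and an intercept) are projected out of both genotype and
    phenotype; the per-SNP slope, its standard error (residual df
    n - 2 - n_covariates) and Z = beta/SE follow from the residualized
    simple regression.  SNPs whose residualized genotype is (numerically)
    constant — monomorphic or collinear with a covariate — get NaN results.

    Returns arrays of shape (n_snps, n_traits) under keys beta, se, z.
    """
    g = np.asarray(g, dtype=float)
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if y.shape[0] != g.shape[0]:
        raise ValueError("G and Y must have the same number of individuals")
    n = g.shape[0]
    x = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), np.asarray(covariates, dtype=float)]
    )
    n_cov = x.shape[1] - 1
    if n <= n_cov + 2:
        raise ValueError("need n > number of covariates + 2")
    q, _ = np.linalg.qr(x)
    gr = g - q @ (q.T @ g)
    yr = y - q @ (q.T @ y)
    gss = np.einsum("ij,ij->j", gr, gr)
    degenerate = gss <= n * 1e-12
    gss_safe = np.where(degenerate, 1.0, gss)
    beta = (gr.T @ yr) / gss_safe[:, None]
    dof = n - 2 - n_cov
    rss = np.einsum("ij,ij->j", yr, yr)[None, :] - beta**2 * gss_safe[:, None]
    se = np.sqrt(np.clip(rss, 0, None) / dof / gss_safe[:, None])
    with np.errstate(divide="ignore", invalid="ignore"):
        z = beta / se
    beta[degenerate] = np.nan
    se[degenerate] = np.nan
    z[degenerate] = np.nan
    return {"beta": beta, "se": se, "z": z}


def simulate_null_z(
    n_snps: int,
    v0: pd.DataFrame | np.ndarray,
    seed: int | np.random.Generator = 0,
    trait_names: list[str] | None = None,
) -> ZMatrix:
    """Draw null summary statistics: Z rows i.i.d. MVN(0, V0).

    This is the exact sampling distribution of per-trait Z-scores at SNPs
    with no association, when the traits have phenotypic correlation V0.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    v0df = v0 if isinstance(v0, pd.DataFrame) else pd.DataFrame(np.asarray(v0, float))
    validate_corr(v0df)
    a = v0df.to_numpy(float)
    chol = np.linalg.cholesky(a + 1e-12 * np.eye(len(a)))
    z = rng.standard_normal((n_snps, len(a))) @ chol.T
    traits = trait_names or [str(c) for c in v0df.columns]
    index = pd.Index([f"snp{i}" for i in range(n_snps)], name="rsid")
    return ZMatrix(pd.DataFrame(z, index=index, columns=traits))


def manova_oracle(
    g: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
) -> float:
    """Individual-level multivariate association p-value for one SNP.

    Likelihood-ratio test comparing the multivariate regression of the
    trait matrix on covariates with and without the genotype dosage,
    computed from residual cross-product determinants:
    LR = n * ln(det(E0) / det(E1)), asymptotically chi-square with
    df = number of traits.  Entirely independent of the Z-score path —
    no standard errors, no V0 — hence usable as its ground truth.
    """
    g = np.asarray(g, dtype=float).reshape(-1, 1)
    y = np.atleast_2d(np.asarray(y, dtype=float))
    n, n_traits = y.shape
    x0 = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), np.asarray(covariates, dtype=float)]
    )
    x1 = np.column_stack([x0, g])
    if n <= x1.shape[1] + n_traits:
        raise ValueError("too few individuals for the multivariate test")

    def residual_crossprod(x: np.ndarray) -> np.ndarray:
        q, r = np.linalg.qr(x)
        resid = y - q @ (q.T @ y)
        return resid.T @ resid

    e0 = residual_crossprod(x0)
    e1 = residual_crossprod(x1)
    sign1, logdet1 = np.linalg.slogdet(e1)
    sign0, logdet0 = np.linalg.slogdet(e0)
    if sign1 <= 0 or sign0 <= 0:
        raise np.linalg.LinAlgError("singular residual cross-product matrix")
    lr = n * (logdet0 - logdet1)
    return float(np.exp(stats.chi2.logsf(lr, n_traits)))


def simulate_study(
    n_individuals: int = DEFAULT_SCENARIO["n_individuals"],
    n_snps: int = DEFAULT_SCENARIO["n_snps"],
    group_sizes: tuple[int, ...] = DEFAULT_SCENARIO["group_sizes"],
    group_names: tuple[str, ...] = ("MMass", "MFat", "MMeat"),
    residual_corr: float = 0.5,
    n_causal: int = 20,
    effect_sd: float = 0.15,
    maf_range: tuple[float, float] = DEFAULT_SCENARIO["maf_range"],
    seed: int = 0,
) -> tuple[pd.DataFrame, ZMatrix, list[TraitGroup], SimTruth]:
    """End-to-end scenario: genotypes -> phenotypes -> univariate scans.

    Causal SNPs are pleiotropic within a randomly chosen trait group (their
    effect is shared by every trait of that group), emulating loci that
    move a whole family of related measurements.  Returns a SNP map, the
    ZMatrix of OLS Z-scores, the trait groups, and the ground truth.
    """
    rng = np.random.default_rng(seed)
    n_traits = sum(group_sizes)
    traits = []
    groups = []
    start = 0
    for name, size in zip(group_names, group_sizes):
        members = [f"{name}_t{i}" for i in range(size)]
        traits.extend(members)
        groups.append(TraitGroup(name, members))
        start += size

    g, mafs = simulate_genotypes(n_individuals, n_snps, maf_range, rng)
    causal = rng.choice(n_snps, size=n_causal, replace=False) if n_causal else np.array([], int)
    effects = np.zeros((n_causal, n_traits))
    offsets = np.cumsum((0,) + tuple(group_sizes))
    for row in range(n_causal):
        gi = rng.integers(len(group_sizes))
        effects[row, offsets[gi]:offsets[gi + 1]] = effect_sd * rng.choice([-1, 1])
    truth = SimTruth(
        sigma=equicorrelated(n_traits, residual_corr),
        causal_snps=causal,
        effect_matrix=effects,
        mafs=mafs,
        seed=int(rng.integers(2**31 - 1)),
    )
    y = simulate_phenotypes(g, truth)
    scan = univariate_gwas(g, y)

    alleles = rng.choice(list("ACGT"), size=(n_snps, 2))
    same = alleles[:, 0] == alleles[:, 1]
    alleles[same, 1] = np.where(alleles[same, 0] == "A", "G", "A")
    snp_map = pd.DataFrame(
        {
            "rsid": [f"rs{i:07d}" for i in range(n_snps)],
            "chrom": (np.arange(n_snps) % 26 + 1).astype(str),
            "pos": (np.arange(n_snps) // 26 + 1) * 10_000,
            "ref_allele": alleles[:, 0],
            "eff_allele": alleles[:, 1],
        }
    )
    z = ZMatrix(
        pd.DataFrame(
            scan["z"], index=pd.Index(snp_map["rsid"], name="rsid"), columns=traits
        ),
        n_per_trait={t: n_individuals for t in traits},
    )
    return snp_map, z, groups, truth
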