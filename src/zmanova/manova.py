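"""Multivariate association testing from GWAS Z-scores.

For a SNP with Z-score vector ``z`` over a group of traits, the test
statistic is the quadratic form

    T^2 = z' V0^{-1} z

where ``V0`` is the matrix of phenotypic correlations among the traits.
Under no association the per-trait Z-scores are jointly multivariate normal
with covariance ``V0``, so T^2 follows a chi-square distribution with
degrees of freedom equal to the group size.  ``V0`` itself is estimable
directly from summary data as the Pearson correlation of the Z-score
columns across SNPs: the overwhelming majority of genome-wide SNPs are
(nearly) null, and for null SNPs the correlation of Z equals the
phenotypic correlation.

P-values are computed in log space (``chi2.logsf``) so that statistics far
in the tail (T^2 of several hundred) survive without underflow; the linear
p-value is clipped at 1e-300 in text output and always accompanied by
log10(p).
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .exceptions import ConfigError, IllConditionedError
from .sumstats import TraitGroup, ZMatrix

logger = logging.getLogger(__name__)

_LN10 = np.log(10.0)

#: Smallest p-value written to text output; log10p carries the precision.
P_FLOOR = 1e-300


def validate_corr(v0: pd.DataFrame, tol: float = 1e-12) -> pd.DataFrame:
    """Validate a correlation matrix: symmetric, unit diagonal, PSD, |r|<=1."""
    a = v0.to_numpy(float)
    if a.shape[0] != a.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(a, a.T, atol=tol):
        raise ValueError("correlation matrix is not symmetric")
    if not np.allclose(np.diag(a), 1.0, atol=tol):
        raise ValueError("correlation matrix diagonal must be 1")
    if np.any(np.abs(a) > 1 + 1e-8):
        raise ValueError("correlations must lie in [-1, 1]")
    eigmin = np.linalg.eigvalsh(a).min()
    if eigmin < -1e-10:
        raise ValueError(f"correlation matrix is not PSD (min eigenvalue {eigmin:g})")
    return v0


def estimate_v0(
    z: ZMatrix | pd.DataFrame,
    traits: Sequence[str] | None = None,
    null_filter: float | None = None,
) -> pd.DataFrame:
    """Estimate the phenotypic correlation matrix V0 from Z-scores.

    Pearson correlation across SNPs between each pair of trait Z columns.
    By default all SNPs contribute.  If ``null_filter`` is given, only SNPs
    whose maximum |Z| over the selected traits is below that cap contribute
    — an optional guard against strong association signals inflating the
    correlation estimate.

    Raises
    ------
    ValueError
        For fewer than 3 SNPs, fewer than 2 traits, or a zero-variance
        trait column (named in the message).
    """
    zdf = z.z if isinstance(z, ZMatrix) else pd.DataFrame(z)
    if traits is not None:
        zdf = zdf.loc[:, list(traits)]
    if zdf.shape[1] < 2:
        raise ValueError("V0 estimation needs at least 2 traits")
    if null_filter is not None:
        zdf = zdf.loc[zdf.abs().max(axis=1) < float(null_filter)]
    if zdf.shape[0] < 3:
        raise ValueError("V0 estimation needs at least 3 SNPs (after any null filter)")
    sd = zdf.to_numpy(float).std(axis=0)
    dead = [t for t, s in zip(zdf.columns, sd) if s == 0]
    if dead:
        raise ValueError(f"zero-variance Z column(s): {dead}")
    v0 = np.corrcoef(zdf.to_numpy(float), rowvar=False)
    np.fill_diagonal(v0, 1.0)
    out = pd.DataFrame(v0, index=zdf.columns, columns=zdf.columns)
    return validate_corr(out)


def shrink_v0(v0: pd.DataFrame, eps: float = 0.01) -> pd.DataFrame:
    """Ridge shrinkage toward the identity: (1 - eps) V0 + eps I."""
    a = (1.0 - eps) * v0.to_numpy(float) + eps * np.eye(len(v0))
    return pd.DataFrame(a, index=v0.index, columns=v0.columns)


def _check_condition(v0: np.ndarray, max_condition: float) -> None:
    cond = np.linalg.cond(v0)
    if not np.isfinite(cond) or cond > max_condition:
        raise IllConditionedError(
            f"V0 condition number {cond:.3g} exceeds {max_condition:.3g}; "
            "near-collinear traits make the quadratic form unstable — drop a "
            "redundant trait or enable ridge shrinkage (shrink=True)"
        )


def manova_score(
    z_vec: np.ndarray,
    v0: pd.DataFrame | np.ndarray,
    max_condition: float = 1e8,
) -> float:
    """The multivariate score T^2 = z' V0^{-1} z for one SNP."""
    z_vec = np.asarray(z_vec, dtype=float)
    a = v0.to_numpy(float) if isinstance(v0, pd.DataFrame) else np.asarray(v0, float)
    if z_vec.shape[0] != a.shape[0]:
        raise ValueError("z vector length must equal the V0 dimension")
    _check_condition(a, max_condition)
    return float(z_vec @ np.linalg.solve(a, z_vec))


def manova_scores(
    z: np.ndarray,
    v0: pd.DataFrame | np.ndarray,
    max_condition: float = 1e8,
) -> np.ndarray:
    """Vectorised T^2 for a SNPs-by-traits Z block (Cholesky whitening)."""
    z = np.asarray(z, dtype=float)
    a = v0.to_numpy(float) if isinstance(v0, pd.DataFrame) else np.asarray(v0, float)
    _check_condition(a, max_condition)
    try:
        chol = np.linalg.cholesky(a)
    except np.linalg.LinAlgError as err:
        raise IllConditionedError(f"V0 is not positive definite: {err}") from err
    white = np.linalg.solve(chol, z.T)
    return np.einsum("ij,ij->j", white, white)


def _chi2_logsf(t2: np.ndarray, df: int) -> np.ndarray:
    """Natural-log chi-square survival function, finite for any finite T^2.

    scipy's logsf itself returns -inf once ln p drops below about -705;
    past that point the standard asymptotic expansion of the upper
    incomplete gamma function Gamma(a, t) ~ t^{a-1} e^{-t} sum_k
    prod_j(a-j)/t^k takes over (relative error < 1e-12 in that regime).
    """
    lg = np.asarray(stats.chi2.logsf(t2, df), dtype=float)
    bad = np.isneginf(lg) & np.isfinite(t2)
    if np.any(bad):
        a = df / 2.0
        t = np.atleast_1d(np.asarray(t2, dtype=float))[np.atleast_1d(bad)] / 2.0
        series = np.ones_like(t)
        term = np.ones_like(t)
        for k in range(1, 1 + max(1, int(np.ceil(a)))):
            term *= (a - k) / t
            series += term
        tail = (a - 1) * np.log(t) - t - special.gammaln(a) + np.log(series)
        if lg.ndim == 0:
            lg = tail[0]
        else:
            lg[bad] = tail
    return lg


def manova_pvalue(t2, df: int):
    """Upper-tail chi-square probability of T^2 at the given df."""
    t2 = np.asarray(t2, dtype=float)
    if np.any(t2 < 0):
        raise ValueError("T^2 must be non-negative")
    if df < 1:
        raise ValueError("df must be >= 1")
    with np.errstate(under="ignore"):
        p = np.exp(_chi2_logsf(t2, df))
    return float(p) if p.ndim == 0 else p


def manova_log10p(t2, df: int):
    """log10 of the upper-tail p — safe far beyond float underflow."""
    lg = _chi2_logsf(np.asarray(t2, dtype=float), df) / _LN10
    return float(lg) if lg.ndim == 0 else lg


def bonferroni_threshold(n_snp: int, n_groups: int, alpha: float = 0.05) -> float:
    """Study-wide significance threshold alpha / (n_snp * n_groups)."""
    if n_snp < 1 or n_groups < 1:
        raise ValueError("n_snp and n_groups must be >= 1")
    return alpha / (n_snp * n_groups)


def inflation_factor(pvalues: np.ndarray, df: int) -> float:
    """Genomic inflation factor lambda from a p-value vector.

    P-values are mapped back to chi-square quantiles at ``df`` degrees of
    freedom; lambda is the ratio of their median to the median of the
    chi-square(df) distribution.  Lambda ~ 1 indicates a calibrated test.
    For multivariate traits the group's df is used (a convention choice;
    lambda is reported together with its df).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if df < 1:
        raise ValueError("df must be >= 1")
    observed = stats.chi2.isf(p, df)
    return float(np.median(observed) / stats.chi2.median(df))


def run_mvgwas(
    z: ZMatrix,
    groups: Sequence[TraitGroup],
    snp_map: pd.DataFrame | None = None,
    null_filter: float | None = None,
    shrink: bool = False,
    shrink_eps: float = 0.01,
    v0_full: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Run the multivariate scan: one test per SNP per trait group.

    For each group, V0 is the correlation of that group's Z columns (the
    submatrix of the full-trait correlation matrix — identical to
    re-estimating on the group's columns, which is what is done here unless
    a precomputed ``v0_full`` is supplied).  The per-group genomic inflation
    factor is logged and stored in ``result.attrs["lambda"]``.

    Returns a long-format DataFrame: rsid, group, t2, df, pvalue, log10p
    (plus chrom/pos when a SNP map is given).
    """
    frames = []
    lambdas: dict[str, float] = {}
    v0_by_group: dict[str, pd.DataFrame] = {}
    for group in groups:
        group.validate_against(z)
        if group.df == 1:
            v0 = pd.DataFrame(
                [[1.0]], index=list(group.members), columns=list(group.members)
            )
        elif v0_full is not None:
            v0 = v0_full.loc[list(group.members), list(group.members)]
        else:
            v0 = estimate_v0(z, traits=group.members, null_filter=null_filter)
        if shrink:
            v0 = shrink_v0(v0, shrink_eps)
        zg = z.z.loc[:, list(group.members)].to_numpy(float)
        t2 = manova_scores(zg, v0)
        log10p = manova_log10p(t2, group.df)
        pvalue = np.maximum(np.exp(log10p * _LN10), 0.0)
        frames.append(
            pd.DataFrame(
                {
                    "rsid": z.snps,
                    "group": group.name,
                    "t2": t2,
                    "df": group.df,
                    "pvalue": pvalue,
                    "log10p": log10p,
                }
            )
        )
        lam = inflation_factor(np.clip(pvalue, P_FLOOR, 1.0), group.df)
        lambdas[group.name] = lam
        v0_by_group[group.name] = v0
        logger.info(
            "group %s: df=%d, lambda=%.4f (lambda computed at the group df)",
            group.name, group.df, lam,
        )
    result = pd.concat(frames, ignore_index=True)
    if snp_map is not None:
        coords = snp_map.set_index("rsid")[["chrom", "pos"]]
        result.insert(1, "chrom", coords.loc[result["rsid"], "chrom"].to_numpy())
        result.insert(2, "pos", coords.loc[result["rsid"], "pos"].to_numpy())
    result.attrs["lambda"] = lambdas
    result.attrs["v0"] = v0_by_group
    return result


def results_for_output(results: pd.DataFrame) -> pd.DataFrame:
    """Clip p-values for text output; log10p retains the full precision."""
    out = results.copy()
    out["pvalue"] = np.clip(out["pvalue"].to_numpy(float), P_FLOOR, 1.0)
    return out
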