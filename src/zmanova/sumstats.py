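"""Reading, harmonising and quality-filtering GWAS summary statistics.

The central objects are a *SNP map* (a :class:`pandas.DataFrame` with one row
per SNP: rsid, chromosome, 1-based position, reference allele, effect allele)
and a :class:`ZMatrix` (SNPs x traits Z-scores, where Z = beta / SE).  All
downstream stages — the multivariate association test, locus clumping, the
locus-effect network and replication — operate on these two containers.

Coordinates are 1-based inclusive throughout the package; conversion to
0-based half-open happens only at the BED export boundary
(:func:`zmanova.loci.loci_to_bed`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError, HarmonizationError

logger = logging.getLogger(__name__)

#: Columns every SNP map carries, in canonical order.
SNP_MAP_COLUMNS = ("rsid", "chrom", "pos", "ref_allele", "eff_allele")

#: Allele pairs that are identical to their reverse complement; their strand
#: cannot be resolved from summary data alone.
STRAND_AMBIGUOUS_PAIRS = (frozenset({"A", "T"}), frozenset({"C", "G"}))


def chrom_sort_key(chrom: str) -> tuple[int, str]:
    """Sort key placing numeric chromosome labels first, in numeric order."""
    s = str(chrom)
    try:
        return (0, f"{int(s):04d}")
    except ValueError:
        return (1, s)


def validate_snp_map(snp_map: pd.DataFrame) -> pd.DataFrame:
    """Check SNP-map invariants; return the frame with canonical columns.

    Invariants: unique rsid, positions >= 1, reference allele differs from
    the effect allele.
    """
    missing = [c for c in SNP_MAP_COLUMNS if c not in snp_map.columns]
    if missing:
        raise ConfigError(f"SNP map is missing columns: {missing}")
    if snp_map["rsid"].duplicated().any():
        dupes = snp_map.loc[snp_map["rsid"].duplicated(), "rsid"].head(3).tolist()
        raise ConfigError(f"SNP map has duplicated rsids, e.g. {dupes}")
    if (snp_map["pos"] < 1).any():
        raise ConfigError("SNP map has positions < 1 (coordinates are 1-based)")
    same = snp_map["ref_allele"].astype(str) == snp_map["eff_allele"].astype(str)
    if same.any():
        raise ConfigError(
            f"{int(same.sum())} SNPs have identical reference and effect alleles"
        )
    return snp_map.loc[:, list(SNP_MAP_COLUMNS)]


def sort_snp_map(snp_map: pd.DataFrame) -> pd.DataFrame:
    """Sort a SNP map by (chromosome, position) with numeric-aware labels."""
    key = snp_map["chrom"].map(chrom_sort_key)
    order = sorted(range(len(snp_map)), key=lambda i: (key.iat[i], snp_map["pos"].iat[i]))
    return snp_map.iloc[order].reset_index(drop=True)


@dataclass
class ZMatrix:
    """SNPs x traits matrix of GWAS Z-scores.

    Parameters
    ----------
    z
        DataFrame indexed by rsid with one column per trait.  Values are
        unitless Z-scores (effect size divided by its standard error).
    n_per_trait
        Optional per-trait sample sizes, used by the replication stage's
        sample-size filter and by variance-explained calculations.
    """

    z: pd.DataFrame
    n_per_trait: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.z.columns.duplicated().any():
            raise ConfigError("ZMatrix trait names must be unique")
        self.z = self.z.astype(float)

    @property
    def traits(self) -> list[str]:
        return list(self.z.columns)

    @property
    def snps(self) -> list[str]:
        return list(self.z.index)

    @property
    def n_snps(self) -> int:
        return self.z.shape[0]

    def select_traits(self, traits: Sequence[str]) -> "ZMatrix":
        missing = [t for t in traits if t not in self.z.columns]
        if missing:
            raise KeyError(f"traits not in ZMatrix: {missing}")
        n = None
        if self.n_per_trait is not None:
            n = {t: self.n_per_trait[t] for t in traits if t in self.n_per_trait}
        return ZMatrix(self.z.loc[:, list(traits)], n)

    def select_snps(self, rsids: Sequence[str]) -> "ZMatrix":
        return ZMatrix(self.z.loc[list(rsids)], self.n_per_trait)


@dataclass(frozen=True)
class TraitGroup:
    """A named subset of traits analysed jointly as one multivariate trait.

    The group size is the number of degrees of freedom of the chi-square
    reference distribution of the multivariate score (e.g. 9 for a
    mass-related group, 6 for fat, 3 for muscle).
    """

    name: str
    members: tuple[str, ...]

    def __init__(self, name: str, members: Iterable[str]):
        object.__setattr__(self, "name", str(name))
        object.__setattr__(self, "members", tuple(members))
        if self.df < 1:
            raise ConfigError(f"trait group {name!r} is empty")

    @property
    def df(self) -> int:
        return len(self.members)

    def validate_against(self, z: ZMatrix) -> None:
        missing = [t for t in self.members if t not in z.z.columns]
        if missing:
            raise ConfigError(f"group {self.name!r} has unknown traits: {missing}")


# ---------------------------------------------------------------------------
# Reading


def _require(format_spec: Mapping, key: str):
    if key not in format_spec:
        raise ConfigError(f"column mapping is missing the {key!r} entry")
    return format_spec[key]


def read_sumstats(
    path: str | Path,
    format_spec: Mapping,
    sep: str | None = None,
) -> tuple[pd.DataFrame, ZMatrix]:
    """Read a summary-statistics table into a (SNP map, ZMatrix) pair.

    ``format_spec`` maps canonical names to the file's column names:
    ``rsid``, ``chrom``, ``pos``, ``ref_allele``, ``eff_allele`` (strings)
    and either ``z`` (a ``{trait: column}`` mapping) or both ``beta`` and
    ``se`` (same shape), from which Z = beta / SE is formed.  An optional
    ``n`` mapping gives per-trait sample sizes.

    The delimiter is sniffed unless ``sep`` is given explicitly; the column
    mapping is always explicit to avoid silently misreading a dialect.

    Rows with non-finite Z in any trait are dropped with a logged count;
    rows with SE = 0 (when deriving Z) are likewise dropped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")

    for key in ("rsid", "chrom", "pos", "ref_allele", "eff_allele"):
        col = _require(format_spec, key)
        if col not in df.columns:
            raise ConfigError(f"column {col!r} (mapped from {key!r}) not in {path.name}")

    if "z" in format_spec:
        trait_cols = dict(format_spec["z"])
        missing = [c for c in trait_cols.values() if c not in df.columns]
        if missing:
            raise ConfigError(f"Z columns absent from {path.name}: {missing}")
        zvals = df[[trait_cols[t] for t in trait_cols]].to_numpy(float)
        traits = list(trait_cols)
    elif "beta" in format_spec and "se" in format_spec:
        beta_cols = dict(format_spec["beta"])
        se_cols = dict(format_spec["se"])
        if set(beta_cols) != set(se_cols):
            raise ConfigError("beta and se mappings must cover the same traits")
        traits = list(beta_cols)
        missing = [
            c for c in [*beta_cols.values(), *se_cols.values()] if c not in df.columns
        ]
        if missing:
            raise ConfigError(f"beta/se columns absent from {path.name}: {missing}")
        beta = df[[beta_cols[t] for t in traits]].to_numpy(float)
        se = df[[se_cols[t] for t in traits]].to_numpy(float)
        zero_se = (se == 0).any(axis=1)
        if zero_se.any():
            logger.warning(
                "%d rows dropped: zero standard error when deriving Z", zero_se.sum()
            )
            df, beta, se = df.loc[~zero_se], beta[~zero_se], se[~zero_se]
        zvals = beta / se
    else:
        raise ConfigError("format_spec needs either 'z' or both 'beta' and 'se'")

    finite = np.isfinite(zvals).all(axis=1)
    if not finite.all():
        logger.info("%d rows dropped: non-finite Z-scores", (~finite).sum())
        df, zvals = df.loc[finite], zvals[finite]

    snp_map = pd.DataFrame(
        {
            "rsid": df[format_spec["rsid"]].astype(str).to_numpy(),
            "chrom": df[format_spec["chrom"]].astype(str).to_numpy(),
            "pos": df[format_spec["pos"]].astype(int).to_numpy(),
            "ref_allele": df[format_spec["ref_allele"]].astype(str).to_numpy(),
            "eff_allele": df[format_spec["eff_allele"]].astype(str).to_numpy(),
        }
    )
    snp_map = validate_snp_map(snp_map)

    n_per_trait = None
    if "n" in format_spec:
        n_spec = format_spec["n"]
        if isinstance(n_spec, Mapping):
            n_per_trait = {
                t: float(df[c].median()) if c in df.columns else float(c)
                for t, c in n_spec.items()
            }

    zmat = ZMatrix(
        pd.DataFrame(zvals, index=pd.Index(snp_map["rsid"], name="rsid"), columns=traits),
        n_per_trait,
    )
    return snp_map, zmat


# ---------------------------------------------------------------------------
# Harmonisation


def harmonize(
    sumstats_map: pd.DataFrame,
    reference_map: pd.DataFrame,
    z: ZMatrix,
) -> tuple[pd.DataFrame, ZMatrix]:
    """Retain SNPs consistent with a reference map; sort by (chrom, pos).

    A SNP is kept iff its rsid exists in the reference AND its (chromosome,
    position) agree with the reference entry — i.e. SNPs with mismatches in
    chromosome position or rs number are excluded.  Z values are never
    altered here; only rows are dropped and reordered.
    """
    sumstats_map = validate_snp_map(sumstats_map)
    reference_map = validate_snp_map(reference_map)

    ref = reference_map.set_index("rsid")
    in_ref = sumstats_map["rsid"].isin(ref.index)
    candidate = sumstats_map.loc[in_ref]
    ref_rows = ref.loc[candidate["rsid"]]
    agree = (
        (candidate["chrom"].to_numpy() == ref_rows["chrom"].to_numpy())
        & (candidate["pos"].to_numpy() == ref_rows["pos"].to_numpy())
    )
    kept = candidate.loc[agree]
    n_in, n_kept = len(sumstats_map), len(kept)
    logger.info(
        "harmonize: %d of %d SNPs retained (%d not in reference, %d coordinate mismatches)",
        n_kept, n_in, int((~in_ref).sum()), int((~agree).sum()),
    )
    if n_kept == 0:
        raise HarmonizationError(
            "no SNP survived harmonization — summary statistics and reference "
            "map share no consistent rsids (wrong genome build?)"
        )
    kept = sort_snp_map(kept)
    return kept, z.select_snps(kept["rsid"].tolist())


# ---------------------------------------------------------------------------
# Allele alignment


@dataclass(frozen=True)
class AlleleAlignment:
    """Outcome of aligning one SNP's effect frame onto a target frame.

    ``status`` is one of ``"match"`` (frames identical, Z unchanged),
    ``"swap"`` (reference and effect alleles exchanged, all Z signs
    flipped) or ``"incompatible"`` (allele sets differ; ``z`` is None and
    the SNP should be treated as non-alignable).  ``strand_ambiguous``
    marks A/T and C/G pairs, whose strand cannot be resolved from summary
    data; such SNPs are kept within a single cohort but excluded from
    cross-cohort direction-consistency checks.
    """

    z: np.ndarray | None
    status: str
    strand_ambiguous: bool = False

    @property
    def alignable(self) -> bool:
        return self.status in ("match", "swap")


def is_strand_ambiguous(alleles: Sequence[str]) -> bool:
    """True for allele pairs identical to their reverse complement (A/T, C/G)."""
    return frozenset(str(a).upper() for a in alleles) in STRAND_AMBIGUOUS_PAIRS


def align_alleles(
    z_row: np.ndarray,
    sumstats_alleles: Sequence[str],
    target_alleles: Sequence[str],
) -> AlleleAlignment:
    """Express a Z vector in the target (reference, effect) allele frame.

    If the pairs match, Z is returned unchanged; if reference and effect are
    swapped relative to the target, every Z sign is flipped (an involution);
    if the allele sets are incompatible the SNP is flagged non-alignable.
    """
    ra, ea = (str(a).upper() for a in sumstats_alleles)
    tra, tea = (str(a).upper() for a in target_alleles)
    if ra == ea or tra == tea:
        raise ConfigError("allele pairs must contain two distinct alleles")
    z_row = np.asarray(z_row, dtype=float)
    ambiguous = is_strand_ambiguous((ra, ea))
    if (ra, ea) == (tra, tea):
        return AlleleAlignment(z_row.copy(), "match", ambiguous)
    if (ra, ea) == (tea, tra):
        return AlleleAlignment(-z_row, "swap", ambiguous)
    return AlleleAlignment(None, "incompatible", ambiguous)


# ---------------------------------------------------------------------------
# Writing


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write any tabular artifact as TSV (the package's output dialect)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def write_sumstats(
    snp_map: pd.DataFrame, z: ZMatrix, path: str | Path
) -> Path:
    """Write a (SNP map, ZMatrix) pair in the dialect read_sumstats reads."""
    out = snp_map.reset_index(drop=True).copy()
    zdf = z.z.reset_index(drop=True)
    for trait in zdf.columns:
        out[f"z_{trait}"] = zdf[trait].to_numpy()
    return write_table(out, path)


def default_format_spec(traits: Sequence[str]) -> dict:
    """Column mapping matching :func:`write_sumstats` output."""
    return {
        "rsid": "rsid",
        "chrom": "chrom",
        "pos": "pos",
        "ref_allele": "ref_allele",
        "eff_allele": "eff_allele",
        "z": {t: f"z_{t}" for t in traits},
    }
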