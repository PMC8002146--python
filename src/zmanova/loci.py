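"""Locus definition: lead-SNP clumping, LD-block merging, novelty, variance.

A *locus* is the +/-500 kb region around a lead SNP (the most significantly
associated SNP not yet assigned to another locus).  Because only summary
statistics are available, linkage disequilibrium between two SNPs is proxied
by the squared Pearson correlation of their Z-score profiles across all
traits: SNPs in strong LD tag the same signal and therefore show near-
proportional Z vectors.

Loci falling in one LD block are merged — either automatically (overlapping
windows, or lead-SNP Z-profile r^2 above a cutoff) or through explicitly
configured merge regions reproducing decisions that would otherwise be made
by eye on regional association plots.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigError
from .sumstats import ZMatrix, chrom_sort_key, write_table

logger = logging.getLogger(__name__)

WINDOW_KB_DEFAULT = 500
LD_MERGE_R2_DEFAULT = 0.7


@dataclass
class Locus:
    """One associated locus: a lead SNP with its window and members."""

    lead_snp: str
    chrom: str
    pos: int
    group: str
    pvalue: float
    log10p: float
    window_start: int
    window_end: int
    member_snps: list[str]
    merged_from: list[str] = field(default_factory=list)
    groups: tuple[str, ...] = ()
    novel: bool | None = None
    var_explained_pct: float | None = None

    def __post_init__(self) -> None:
        if not (self.window_start <= self.pos <= self.window_end):
            raise ValueError("lead position must lie inside the locus window")
        if not self.groups:
            self.groups = (self.group,)


@dataclass(frozen=True)
class MergeRegion:
    """A genomic interval (1-based inclusive) whose loci are merged into one."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ConfigError(f"merge region start > end on chrom {self.chrom}")

    def contains(self, chrom: str, pos: int) -> bool:
        return str(chrom) == str(self.chrom) and self.start <= pos <= self.end


def ld_r2_z(z_i: np.ndarray, z_j: np.ndarray) -> float:
    """LD proxy: squared Pearson correlation of two SNPs' Z profiles.

    Returns NaN (with a warning) if either profile has zero variance, where
    the correlation is undefined.
    """
    z_i = np.asarray(z_i, dtype=float)
    z_j = np.asarray(z_j, dtype=float)
    if z_i.shape != z_j.shape or z_i.size < 3:
        raise ValueError("Z profiles must have equal length >= 3")
    if z_i.std() == 0 or z_j.std() == 0:
        warnings.warn("zero-variance Z profile: LD r^2 undefined", stacklevel=2)
        return float("nan")
    r = np.corrcoef(z_i, z_j)[0, 1]
    return float(r * r)


def _sort_significant(sig: pd.DataFrame) -> pd.DataFrame:
    # deterministic tie-break for equal p: smaller chromosome, then position
    key = pd.DataFrame(
        {
            "p": sig["pvalue"].to_numpy(float),
            "c": sig["chrom"].map(chrom_sort_key),
            "pos": sig["pos"].to_numpy(int),
        }
    )
    order = key.sort_values(["p", "c", "pos"], kind="mergesort").index
    return sig.loc[order]


def clump(
    results: pd.DataFrame,
    snp_map: pd.DataFrame,
    threshold: float,
    window_kb: float = WINDOW_KB_DEFAULT,
) -> list[Locus]:
    """Greedy lead-SNP clumping, run independently per trait group.

    Repeatedly take the unassigned SNP with the smallest p-value below
    ``threshold``, open a +/-``window_kb`` window around it on its
    chromosome, and assign every unassigned below-threshold SNP inside the
    window to that locus.  Ties in p are broken by (chromosome, position),
    making the procedure deterministic.
    """
    window = int(round(window_kb * 1000))
    df = results
    if "chrom" not in df.columns or "pos" not in df.columns:
        coords = snp_map.set_index("rsid")[["chrom", "pos"]]
        df = df.copy()
        df["chrom"] = coords.loc[df["rsid"], "chrom"].to_numpy()
        df["pos"] = coords.loc[df["rsid"], "pos"].to_numpy()

    loci: list[Locus] = []
    for group_name, gdf in df.groupby("group", sort=True):
        sig = _sort_significant(gdf.loc[gdf["pvalue"] < threshold])
        assigned = np.zeros(len(sig), dtype=bool)
        chroms = sig["chrom"].astype(str).to_numpy()
        positions = sig["pos"].to_numpy(int)
        for i in range(len(sig)):
            if assigned[i]:
                continue
            lead = sig.iloc[i]
            in_window = (
                (~assigned)
                & (chroms == str(lead["chrom"]))
                & (np.abs(positions - int(lead["pos"])) <= window)
            )
            members = sig.loc[in_window, "rsid"].tolist()
            assigned |= in_window
            loci.append(
                Locus(
                    lead_snp=str(lead["rsid"]),
                    chrom=str(lead["chrom"]),
                    pos=int(lead["pos"]),
                    group=str(group_name),
                    pvalue=float(lead["pvalue"]),
                    log10p=float(lead.get("log10p", np.log10(max(lead["pvalue"], 1e-300)))),
                    window_start=max(1, int(lead["pos"]) - window),
                    window_end=int(lead["pos"]) + window,
                    member_snps=members,
                )
            )
    loci.sort(key=_locus_sort_key)
    return loci


def _locus_sort_key(locus: Locus):
    return (chrom_sort_key(locus.chrom), locus.pos, locus.group)


def _canonical_regions(
    merge_regions: Iterable[MergeRegion | Mapping | Sequence] | None,
) -> list[MergeRegion]:
    out = []
    for r in merge_regions or ():
        if isinstance(r, MergeRegion):
            out.append(r)
        elif isinstance(r, Mapping):
            out.append(MergeRegion(str(r["chrom"]), int(r["start"]), int(r["end"])))
        else:
            chrom, start, end = r
            out.append(MergeRegion(str(chrom), int(start), int(end)))
    return out


def _should_merge(
    a: Locus,
    b: Locus,
    z: ZMatrix | None,
    regions: list[MergeRegion],
    ld_merge_r2: float | None,
) -> bool:
    if a.chrom != b.chrom:
        return False
    if a.window_start <= b.window_end and b.window_start <= a.window_end:
        return True
    if any(r.contains(a.chrom, a.pos) and r.contains(b.chrom, b.pos) for r in regions):
        return True
    if ld_merge_r2 is not None and z is not None:
        r2 = ld_r2_z(z.z.loc[a.lead_snp].to_numpy(), z.z.loc[b.lead_snp].to_numpy())
        if np.isfinite(r2) and r2 >= ld_merge_r2:
            return True
    return False


def _merge_component(component: list[Locus]) -> Locus:
    component = sorted(component, key=lambda l: (l.pvalue, _locus_sort_key(l)))
    lead = component[0]
    members = sorted({m for l in component for m in l.member_snps})
    history = sorted(
        {h for l in component for h in (l.merged_from or [l.lead_snp])}
    )
    groups = tuple(sorted({g for l in component for g in l.groups}))
    return Locus(
        lead_snp=lead.lead_snp,
        chrom=lead.chrom,
        pos=lead.pos,
        group=lead.group,
        pvalue=lead.pvalue,
        log10p=lead.log10p,
        window_start=min(l.window_start for l in component),
        window_end=max(l.window_end for l in component),
        member_snps=members,
        merged_from=history if len(history) > 1 else [],
        groups=groups,
    )


def merge_loci(
    loci: Sequence[Locus],
    z: ZMatrix | None = None,
    merge_regions: Iterable[MergeRegion | Mapping | Sequence] | None = None,
    ld_merge_r2: float | None = LD_MERGE_R2_DEFAULT,
) -> list[Locus]:
    """Merge loci lying in one LD block into a single locus.

    Two loci (on the same chromosome) are connected when (a) their windows
    overlap, (b) their lead SNPs' Z-profile r^2 reaches ``ld_merge_r2``, or
    (c) both leads fall inside one configured merge region.  Connected
    components are collapsed, keeping the overall-minimal-p lead, the union
    span as the window, the union of members, and the pre-merge lead rsids
    in ``merged_from``.  The procedure iterates to a fixed point, so it is
    idempotent and independent of input order.
    """
    regions = _canonical_regions(merge_regions)
    current = sorted(loci, key=_locus_sort_key)
    if z is None and ld_merge_r2 is not None:
        ld_merge_r2 = None
    while True:
        n = len(current)
        parent = list(range(n))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                if find(i) != find(j) and _should_merge(
                    current[i], current[j], z, regions, ld_merge_r2
                ):
                    parent[find(j)] = find(i)
        components: dict[int, list[Locus]] = {}
        for i in range(n):
            components.setdefault(find(i), []).append(current[i])
        merged = sorted(
            (_merge_component(c) for c in components.values()), key=_locus_sort_key
        )
        if len(merged) == n:
            return merged
        current = merged


def annotate_novelty(
    loci: Sequence[Locus], known: pd.DataFrame
) -> list[Locus]:
    """Flag each locus as novel unless it overlaps a known SNP or gene.

    ``known`` uses the 4-column schema ``name, chrom, start, end`` (1-based
    inclusive; a point entry has start == end; ``name`` may be an rsid or a
    gene symbol).  A locus is NOT novel iff some known entry's interval
    intersects the locus window on the same chromosome, or the entry's name
    matches a member rsid.
    """
    required = {"name", "chrom", "start", "end"}
    if not required.issubset(known.columns):
        raise ConfigError(f"known-loci table needs columns {sorted(required)}")
    out = []
    names = set(known["name"].astype(str))
    for locus in loci:
        same_chrom = known.loc[known["chrom"].astype(str) == locus.chrom]
        overlap = (
            (same_chrom["start"].to_numpy(int) <= locus.window_end)
            & (same_chrom["end"].to_numpy(int) >= locus.window_start)
        ).any()
        hit = bool(overlap) or bool(names & set(locus.member_snps))
        out.append(replace(locus, novel=not hit))
    return out


def variance_explained(p_min_univariate: float, n: float) -> float:
    """Percent trait variance explained by a lead SNP, from its best
    univariate p-value: chi-square(1) upper-tail quantile at p, divided by
    the sample size, times 100."""
    p = float(p_min_univariate)
    if not (0 < p <= 1):
        raise ValueError("p must lie in (0, 1] (p = 0 implies infinite variance)")
    if n < 1:
        raise ValueError("sample size must be >= 1")
    return float(stats.chi2.isf(p, df=1) / n * 100.0)


def min_univariate_pvalue(z: ZMatrix, rsid: str) -> float:
    """Smallest two-sided normal p over a SNP's univariate Z-scores."""
    zmax = float(np.abs(z.z.loc[rsid].to_numpy(float)).max())
    return float(2.0 * stats.norm.sf(zmax))


# ---------------------------------------------------------------------------
# Tabular export


def loci_to_frame(loci: Sequence[Locus]) -> pd.DataFrame:
    rows = []
    for l in loci:
        rows.append(
            {
                "lead_snp": l.lead_snp,
                "chrom": l.chrom,
                "pos": l.pos,
                "group": l.group,
                "groups": ",".join(l.groups),
                "pvalue": max(l.pvalue, 1e-300),
                "log10p": l.log10p,
                "window_start": l.window_start,
                "window_end": l.window_end,
                "n_members": len(l.member_snps),
                "member_snps": ",".join(l.member_snps),
                "merged_from": ",".join(l.merged_from),
                "novel": l.novel,
                "var_explained_pct": l.var_explained_pct,
            }
        )
    return pd.DataFrame(rows)


def write_loci(loci: Sequence[Locus], path: str | Path) -> Path:
    return write_table(loci_to_frame(loci), path)


def loci_to_bed(loci: Sequence[Locus], path: str | Path) -> Path:
    """BED export; the only place 1-based inclusive becomes 0-based half-open."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for l in loci:
            fh.write(
                f"{l.chrom}\t{l.window_start - 1}\t{l.window_end}\t"
                f"{l.lead_snp}\t0\t.\n"
            )
    return path
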