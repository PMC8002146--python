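"""End-to-end pipeline: harmonize -> multivariate scan -> loci -> network.

Configuration is a YAML file validated into :class:`PipelineConfig`
(unknown keys are rejected so typos fail loudly).  The pipeline writes all
tabular artifacts as TSV (loci also as BED) plus Manhattan/QQ/heatmap
figures, and logs retained/excluded counts and per-group inflation factors.
Two runs with identical config and inputs produce byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import loci as loci_mod
from . import manova, network, sumstats
from .exceptions import ConfigError
from .loci import Locus
from .sumstats import TraitGroup, ZMatrix

logger = logging.getLogger(__name__)

#: Merge regions for the three large LD blocks on the sheep Oar_v3.1
#: assembly known to carry strong carcass-trait signals (chr6 22-42 Mb,
#: chr11 24.5-28 Mb, chr18 62-67 Mb).
DEFAULT_MERGE_REGIONS = (
    {"chrom": "6", "start": 22_000_000, "end": 42_000_000},
    {"chrom": "11", "start": 24_500_000, "end": 28_000_000},
    {"chrom": "18", "start": 62_000_000, "end": 67_000_000},
)


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see the YAML example in the README)."""

    sumstats: str
    columns: dict
    trait_groups: dict[str, list[str]]
    output_dir: str
    reference_map: str | None = None
    known_loci: str | None = None
    n_samples: float | None = None
    alpha: float = 0.05
    window_kb: float = 500.0
    merge_regions: list = field(default_factory=lambda: list(DEFAULT_MERGE_REGIONS))
    ld_merge_r2: float | None = 0.7
    null_filter: float | None = None
    shrink_v0: bool = False
    cap_log10p: float | None = None
    seed: int = 0
    locus_labels: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        missing = [k for k in ("sumstats", "columns", "trait_groups", "output_dir")
                   if k not in raw]
        if missing:
            raise ConfigError(f"config is missing required keys: {missing}")
        return cls(**raw)

    def groups(self) -> list[TraitGroup]:
        return [TraitGroup(name, members) for name, members in self.trait_groups.items()]


def run_pipeline(config: PipelineConfig, make_plots: bool = True) -> dict[str, Any]:
    """Execute the full discovery pipeline; returns the result bundle.

    Stages: read + harmonize summary statistics, multivariate scan per
    trait group, Bonferroni threshold, clumping, LD-block merging, novelty
    annotation, variance explained, locus-effect network.  Stage failures
    abort with the stage name and cause.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _add_file_log(out_dir / "run.log")

    stage = "read summary statistics"
    try:
        snp_map, z = sumstats.read_sumstats(config.sumstats, config.columns)
        if config.reference_map is not None:
            stage = "harmonize"
            ref = pd.read_csv(config.reference_map, sep=None, engine="python")
            ref = sumstats.validate_snp_map(ref)
            snp_map, z = sumstats.harmonize(snp_map, ref, z)

        stage = "multivariate scan"
        groups = self_check_groups(config, z)
        results = manova.run_mvgwas(
            z, groups, snp_map,
            null_filter=config.null_filter, shrink=config.shrink_v0,
        )
        threshold = manova.bonferroni_threshold(z.n_snps, len(groups), config.alpha)
        logger.info("significance threshold: %.4g (%d SNPs x %d groups)",
                    threshold, z.n_snps, len(groups))

        stage = "clump"
        found = loci_mod.clump(results, snp_map, threshold, config.window_kb)
        stage = "merge loci"
        merged = loci_mod.merge_loci(
            found, z, config.merge_regions, config.ld_merge_r2
        )
        logger.info("%d loci before merging, %d after", len(found), len(merged))

        stage = "novelty"
        if config.known_loci is not None:
            known = pd.read_csv(config.known_loci, sep=None, engine="python")
            merged = loci_mod.annotate_novelty(merged, known)
            logger.info("%d of %d loci novel",
                        sum(bool(l.novel) for l in merged), len(merged))

        stage = "variance explained"
        if config.n_samples is not None:
            for locus in merged:
                locus.var_explained_pct = loci_mod.variance_explained(
                    loci_mod.min_univariate_pvalue(z, locus.lead_snp),
                    config.n_samples,
                )

        stage = "network"
        net = None
        if len(merged) >= 2:
            lead_z = z.z.loc[[l.lead_snp for l in merged]]
            labels = [config.locus_labels.get(l.lead_snp, l.lead_snp) for l in merged]
            net = network.network_edges(lead_z, config.alpha, labels=labels)

        stage = "write outputs"
        sumstats.write_table(
            manova.results_for_output(results), out_dir / "results.tsv"
        )
        loci_mod.write_loci(merged, out_dir / "loci.tsv")
        loci_mod.loci_to_bed(merged, out_dir / "loci.bed")
        if net is not None:
            network.write_edges(net, out_dir / "network_edges.tsv")

        if make_plots:
            stage = "figures"
            from . import plots
            plots.manhattan(results, out_dir / "manhattan.png",
                            threshold=threshold, cap_log10p=config.cap_log10p)
            plots.qq(results, out_dir / "qq.png")
            if net is not None:
                plots.network_heatmap(net, out_dir / "network_heatmap.png")
                plots.network_graph(net, out_dir / "network_graph.png")
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    return {
        "snp_map": snp_map,
        "z": z,
        "results": results,
        "threshold": threshold,
        "loci": merged,
        "network": net,
        "lambda": results.attrs.get("lambda", {}),
        "output_dir": out_dir,
    }


def self_check_groups(config: PipelineConfig, z: ZMatrix) -> list[TraitGroup]:
    groups = config.groups()
    for g in groups:
        g.validate_against(z)
    return groups


def regional_plot_data(
    locus: Locus,
    z: ZMatrix,
    results: pd.DataFrame,
    gene_annotation: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Data behind a regional association plot for one locus.

    Returns a per-SNP table (rsid, pos, log10p for the locus's group, LD
    r^2 to the lead via the Z-profile proxy) for SNPs inside the locus
    window, and a gene table (GFF3 genes intersecting the window, 1-based
    inclusive interval logic; empty with a warning when no annotation is
    given).
    """
    sub = results.loc[
        (results["group"] == locus.group)
        & (results["chrom"].astype(str) == locus.chrom)
        & (results["pos"].between(locus.window_start, locus.window_end))
    ].copy()
    lead_profile = z.z.loc[locus.lead_snp].to_numpy(float)
    sub["ld_r2"] = [
        loci_mod.ld_r2_z(z.z.loc[rsid].to_numpy(float), lead_profile)
        for rsid in sub["rsid"]
    ]
    snp_table = sub[["rsid", "pos", "log10p", "ld_r2"]].reset_index(drop=True)

    if gene_annotation is None:
        logger.warning("no gene annotation supplied: regional plot gene track empty")
        genes = pd.DataFrame(columns=["gene", "start", "end"])
    else:
        genes = _genes_in_window(
            gene_annotation, locus.chrom, locus.window_start, locus.window_end
        )
    return snp_table, genes


def _genes_in_window(gff_path, chrom: str, start: int, end: int) -> pd.DataFrame:
    import gffutils

    db = gffutils.create_db(
        str(gff_path), ":memory:", merge_strategy="create_unique",
        keep_order=True,
    )
    rows = []
    for feat in db.region(seqid=str(chrom), start=start, end=end,
                          featuretype="gene", completely_within=False):
        name = feat.attributes.get("Name", feat.attributes.get("ID", [feat.id]))[0]
        rows.append({"gene": name, "start": feat.start, "end": feat.end})
    return pd.DataFrame(rows, columns=["gene", "start", "end"])


def _add_file_log(path: Path) -> None:
    root = logging.getLogger("zmanova")
    if not any(
        isinstance(h, logging.FileHandler)
        and getattr(h, "baseFilename", None) == str(path)
        for h in root.handlers
    ):
        handler = logging.FileHandler(path, mode="w")
        handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
        root.addHandler(handler)
        root.setLevel(logging.INFO)
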