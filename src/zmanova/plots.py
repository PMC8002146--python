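"""Figures: Manhattan, QQ, network heatmap and graph, regional plots.

All functions write a file and return its path; nothing is shown
interactively.  Figures are illustrative — every number they encode is
also available in the TSV outputs, which are the reproducible artifacts.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy import stats

from .network import LocusNetwork
from .sumstats import chrom_sort_key


def manhattan(
    results: pd.DataFrame,
    path: str | Path,
    threshold: float | None = None,
    cap_log10p: float | None = None,
) -> Path:
    """Manhattan plot of the per-SNP minimum p across trait groups.

    ``cap_log10p`` (e.g. 14) omits SNPs stronger than 10^-cap, the usual
    convention when a handful of huge signals would flatten the rest.
    """
    best = results.loc[results.groupby("rsid")["log10p"].idxmin()]
    best = best.sort_values(
        ["chrom", "pos"], key=lambda s: s.map(chrom_sort_key) if s.name == "chrom" else s
    )
    y = -best["log10p"].to_numpy(float)
    if cap_log10p is not None:
        keep = y < cap_log10p
        best, y = best.loc[keep], y[keep]
    fig, ax = plt.subplots(figsize=(10, 3.2))
    offset = 0.0
    ticks, labels = [], []
    for i, (chrom, cdf) in enumerate(
        best.groupby("chrom", sort=True, observed=True)
    ):
        x = offset + (cdf["pos"].to_numpy(float) - cdf["pos"].min())
        ax.scatter(x, -cdf["log10p"].to_numpy(float), s=4,
                   color="C0" if i % 2 == 0 else "C1", rasterized=True)
        ticks.append(x.mean())
        labels.append(str(chrom))
        offset = x.max() + (cdf["pos"].max() - cdf["pos"].min()) * 0.02 + 1.0
    if threshold is not None:
        ax.axhline(-np.log10(threshold), color="red", lw=0.8, ls="--")
    ax.set_xticks(ticks, labels, fontsize=6)
    ax.set_xlabel("chromosome")
    ax.set_ylabel(r"$-\log_{10} p$ (min over groups)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def qq(results: pd.DataFrame, path: str | Path,
       genomic_control: bool = False) -> Path:
    """QQ plot per trait group, with the inflation factor annotated.

    Deviation is reported, never corrected, unless ``genomic_control`` is
    set — in which case observed statistics are divided by lambda before
    plotting.
    """
    from .manova import P_FLOOR, inflation_factor

    fig, ax = plt.subplots(figsize=(4, 4))
    for group, gdf in results.groupby("group", sort=True):
        p = np.clip(gdf["pvalue"].to_numpy(float), P_FLOOR, 1.0)
        df = int(gdf["df"].iloc[0])
        lam = inflation_factor(p, df)
        obs = np.sort(-gdf["log10p"].to_numpy(float))[::-1]
        if genomic_control:
            chi = stats.chi2.isf(p, df) / lam
            obs = np.sort(-stats.chi2.logsf(chi, df) / np.log(10))[::-1]
        n = len(obs)
        expected = -np.log10((np.arange(1, n + 1) - 0.5) / n)
        ax.plot(expected, obs, ".", ms=2,
                label=f"{group} (df={df}, $\\lambda$={lam:.3f})")
    lim = ax.get_xlim()[1]
    ax.plot([0, lim], [0, lim], "k-", lw=0.8)
    ax.set_xlabel(r"expected $-\log_{10} p$")
    ax.set_ylabel(r"observed $-\log_{10} p$")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def network_heatmap(network: LocusNetwork, path: str | Path) -> Path:
    """Heatmap of Spearman correlations in cluster order; edges starred."""
    order = network.cluster_order
    rho = network.rho.loc[order, order]
    pv = network.pvalues.loc[order, order]
    k = len(order)
    fig, ax = plt.subplots(figsize=(0.55 * k + 2, 0.55 * k + 2))
    im = ax.imshow(rho.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    for i in range(k):
        for j in range(k):
            if i != j and pv.iat[i, j] <= network.threshold:
                ax.text(j, i, "*", ha="center", va="center", fontsize=9)
    ax.set_xticks(range(k), order, rotation=90, fontsize=7)
    ax.set_yticks(range(k), order, fontsize=7)
    fig.colorbar(im, ax=ax, shrink=0.8, label="Spearman $\\rho$")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def network_graph(network: LocusNetwork, path: str | Path) -> Path:
    """Graph of significant locus-effect correlations (edge width = rho^2)."""
    import networkx as nx

    g = network.to_networkx()
    g.remove_nodes_from([n for n in list(g) if g.degree[n] == 0])
    fig, ax = plt.subplots(figsize=(5, 5))
    if len(g):
        pos = nx.spring_layout(g, seed=0)
        widths = [4 * g.edges[e]["weight"] for e in g.edges]
        nx.draw_networkx(g, pos, ax=ax, node_color="#a6cee3", width=widths,
                         font_size=8)
    ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def regional(
    snp_table: pd.DataFrame,
    genes: pd.DataFrame,
    path: str | Path,
    title: str = "",
) -> Path:
    """Regional association plot: -log10 p coloured by LD r^2 to the lead,
    with a gene track underneath."""
    fig, (ax, gax) = plt.subplots(
        2, 1, figsize=(6, 4), sharex=True, height_ratios=[4, 1]
    )
    sc = ax.scatter(snp_table["pos"] / 1e6, -snp_table["log10p"],
                    c=snp_table["ld_r2"], cmap="viridis", vmin=0, vmax=1, s=12)
    fig.colorbar(sc, ax=ax, label=r"LD $r^2$ to lead (Z-profile)")
    ax.set_ylabel(r"$-\log_{10} p$")
    ax.set_title(title)
    for i, row in genes.iterrows():
        gax.plot([row["start"] / 1e6, row["end"] / 1e6], [i % 3, i % 3], lw=3)
        gax.text(row["start"] / 1e6, i % 3 + 0.15, str(row["gene"]), fontsize=6)
    gax.set_yticks([])
    gax.set_xlabel("position (Mb)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
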