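"""Locus-effect correlation network and clustering.

Loci that are functionally connected — acting through one pathway or gene
network — tend to show a similar pattern of association across many traits.
This module quantifies that similarity as Spearman's rank correlation
between the lead SNPs' Z-score profiles over the trait panel, draws an edge
wherever the correlation survives a Bonferroni correction over all
k(k-1)/2 pairs, and orders the loci by Ward hierarchical clustering on
1 - |rho| distances.  Signs are irrelevant throughout: the direction of a
GWAS effect depends on the arbitrary choice of reference allele, so the
edge test is two-sided and distances use |rho| (edge weights are rho^2).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from .sumstats import write_table


def spearman_effect_corr(
    z_i: np.ndarray,
    z_j: np.ndarray,
    method: str = "t",
    n_perm: int = 10000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Spearman correlation of two loci's Z profiles, with a two-sided p.

    Ties receive average ranks.  ``method="t"`` (default) uses the
    t-approximation with m - 2 degrees of freedom, ample for trait panels
    of a few dozen; ``method="permutation"`` computes an exact-style p from
    ``n_perm`` seeded permutations for small panels.
    """
    z_i = np.asarray(z_i, dtype=float)
    z_j = np.asarray(z_j, dtype=float)
    if z_i.shape != z_j.shape or z_i.size < 5:
        raise ValueError("Z profiles must have equal length >= 5")
    if np.std(z_i) == 0 or np.std(z_j) == 0:
        warnings.warn("constant Z profile: Spearman rho undefined", stacklevel=2)
        return float("nan"), float("nan")
    rho, pvalue = stats.spearmanr(z_i, z_j)
    if method == "permutation":
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            r, _ = stats.spearmanr(z_i, rng.permutation(z_j))
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
        pvalue = (count + 1) / (n_perm + 1)
    elif method != "t":
        raise ValueError(f"unknown method {method!r}")
    return float(rho), float(pvalue)


def pairwise_bonferroni(k: int, alpha: float = 0.05) -> float:
    """Edge significance threshold alpha / (k(k-1)/2) for k nodes."""
    if k < 2:
        raise ValueError("need at least 2 nodes")
    return alpha / (k * (k - 1) / 2)


@dataclass
class LocusNetwork:
    """Pairwise Spearman structure among lead SNPs.

    ``nodes`` may carry prioritized gene names instead of rsids; labels are
    cosmetic and never enter any computation.
    """

    nodes: list[str]
    rho: pd.DataFrame
    pvalues: pd.DataFrame
    threshold: float
    edges: pd.DataFrame
    linkage: np.ndarray
    cluster_order: list[str]

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for row in self.edges.itertuples(index=False):
            g.add_edge(row.node_a, row.node_b, rho=row.rho, weight=row.rho2,
                       pvalue=row.pvalue)
        return g


def network_edges(
    lead_z: pd.DataFrame,
    alpha: float = 0.05,
    labels: Sequence[str] | None = None,
    method: str = "t",
    seed: int | None = None,
) -> LocusNetwork:
    """Build the locus-effect network from a loci-by-traits Z matrix.

    An edge joins two loci when the two-sided p of their Spearman rho is at
    or below alpha corrected for all k(k-1)/2 pairs.  The correlation sign
    is kept in ``rho`` but each edge is weighted by rho^2.
    """
    k = lead_z.shape[0]
    nodes = list(labels) if labels is not None else [str(i) for i in lead_z.index]
    if len(nodes) != k:
        raise ValueError("labels length must match the number of loci")
    threshold = pairwise_bonferroni(k, alpha)
    rho = np.eye(k)
    pmat = np.zeros((k, k))
    z = lead_z.to_numpy(float)
    edges = []
    for i, j in itertools.combinations(range(k), 2):
        r, p = spearman_effect_corr(z[i], z[j], method=method, seed=seed)
        rho[i, j] = rho[j, i] = r
        pmat[i, j] = pmat[j, i] = p
        if np.isfinite(p) and p <= threshold:
            edges.append(
                {"node_a": nodes[i], "node_b": nodes[j], "rho": r, "rho2": r * r,
                 "pvalue": p}
            )
    rho_df = pd.DataFrame(rho, index=nodes, columns=nodes)
    p_df = pd.DataFrame(pmat, index=nodes, columns=nodes)
    order, lk = cluster_loci(rho_df)
    return LocusNetwork(
        nodes=nodes,
        rho=rho_df,
        pvalues=p_df,
        threshold=threshold,
        edges=pd.DataFrame(edges, columns=["node_a", "node_b", "rho", "rho2", "pvalue"]),
        linkage=lk,
        cluster_order=order,
    )


def cluster_loci(rho: pd.DataFrame) -> tuple[list[str], np.ndarray]:
    """Ward hierarchical clustering of loci on 1 - |rho| distances.

    Returns the dendrogram leaf order (node names) and the scipy linkage
    matrix.  Merge order is deterministic: scipy breaks ties by the lowest
    pair index.
    """
    a = rho.to_numpy(float)
    if a.shape[0] != a.shape[1] or not np.allclose(a, a.T, atol=1e-10, equal_nan=True):
        raise ValueError("rho must be a symmetric square matrix")
    if a.shape[0] < 2:
        return list(rho.index), np.empty((0, 4))
    d = 1.0 - np.abs(a)
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, None)
    lk = linkage(squareform(d, checks=False), method="ward")
    order = [rho.index[i] for i in leaves_list(lk)]
    return order, lk


def write_edges(network: LocusNetwork, path: str | Path) -> Path:
    """Edge-list TSV: node_a, node_b, rho, rho^2, p."""
    return write_table(network.edges, path)
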