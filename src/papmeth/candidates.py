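"""Candidate marker selection: intersection, clustering, top-10% picks.

Genes called highly differentially methylated in every dataset are clustered
by their tissue methylation profiles (complete-linkage agglomerative
clustering on Euclidean distance, tree cut at k = 4) and the most strongly
hypermethylated genes of each cluster are flagged for wet-lab verification:
the top 10% (ceiling) of clusters larger than five genes, every gene of
smaller clusters.  Literature-novelty triage is deliberately left to the
analyst; the table carries within-cluster ranks so any final shortlist rule
can be applied on top.
"""

from __future__ import annotations

from math import ceil
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

__all__ = [
    "intersect_gene_sets",
    "cluster_genes",
    "select_top_candidates",
    "plot_cluster_heatmap",
]


def intersect_gene_sets(*sets: Iterable[str]) -> list[str]:
    """Sorted list of genes present in every input collection."""
    if len(sets) < 2:
        raise ValueError("need at least two gene sets")
    out = set(sets[0])
    for s in sets[1:]:
        out &= set(s)
    return sorted(out)


def cluster_genes(
    profiles: pd.DataFrame,
    k: int = 4,
    standardize: bool = False,
) -> pd.Series:
    """Cluster gene methylation profiles (rows) into exactly k groups.

    Complete linkage on Euclidean distance; missing entries are imputed by
    the gene's median across samples.  Genes are processed in lexicographic
    id order so equal-distance merges resolve deterministically, and cluster
    labels 1..k are canonicalized by each cluster's smallest gene id.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > profiles.shape[0]:
        raise ValueError(f"k={k} exceeds the {profiles.shape[0]} available genes")
    prof = profiles.sort_index()
    x = prof.to_numpy(dtype=float)
    if np.isnan(x).any():
        med = np.nanmedian(x, axis=1, keepdims=True)
        x = np.where(np.isnan(x), np.broadcast_to(med, x.shape), x)
        if np.isnan(x).any():
            raise ValueError("genes with all-missing profiles cannot be clustered")
    if standardize:
        sd = x.std(axis=1, keepdims=True)
        x = (x - x.mean(axis=1, keepdims=True)) / np.where(sd == 0, 1.0, sd)
    raw = fcluster(linkage(x, method="complete", metric="euclidean"), t=k,
                   criterion="maxclust")
    # canonical numbering: cluster containing the smallest gene id becomes 1
    order = {}
    for gene, lab in zip(prof.index, raw):
        order.setdefault(lab, gene)
    relabel = {
        lab: i + 1
        for i, (lab, _) in enumerate(sorted(order.items(), key=lambda kv: kv[1]))
    }
    return pd.Series([relabel[lab] for lab in raw], index=prof.index, name="cluster")


def select_top_candidates(
    clusters: pd.Series,
    hdm_levels: Mapping[str, float] | pd.Series,
    fraction: float = 0.10,
    min_cluster_to_apply: int = 5,
) -> pd.DataFrame:
    """Mark the top-``fraction`` genes of each cluster by HDM level.

    Clusters with more than ``min_cluster_to_apply`` genes keep
    ``ceil(fraction * size)`` genes; smaller clusters keep all their genes.
    Ties in HDM level break by gene id.  Returns a table with columns
    ``cluster, hdm_level, rank, selected`` indexed by gene.
    """
    hdm = pd.Series(hdm_levels)
    missing = clusters.index.difference(hdm.index)
    if len(missing):
        raise ValueError(f"no hdm_level for genes: {sorted(missing)[:5]}...")
    out = pd.DataFrame({"cluster": clusters, "hdm_level": hdm.reindex(clusters.index)})
    # stable sort over lexicographic gene order => ties in hdm_level break by id
    out = out.sort_index(kind="mergesort").sort_values(
        ["cluster", "hdm_level"], ascending=[True, False], kind="mergesort"
    )
    out["rank"] = out.groupby("cluster").cumcount() + 1
    sizes = out.groupby("cluster")["rank"].transform("size")
    quota = np.where(
        sizes > min_cluster_to_apply,
        np.ceil(fraction * sizes).astype(int),
        sizes,
    )
    out["selected"] = out["rank"] <= quota
    return out


def plot_cluster_heatmap(profiles: pd.DataFrame, clusters: pd.Series, path: str) -> None:
    """Cluster-ordered genes x samples heatmap (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = clusters.sort_values(kind="mergesort").index
    fig, ax = plt.subplots(figsize=(8, max(3, 0.08 * len(order))))
    im = ax.imshow(profiles.loc[order], aspect="auto", cmap="RdBu_r", vmin=0, vmax=1)
    ax.set_xlabel("samples")
    ax.set_ylabel("genes (cluster-ordered)")
    fig.colorbar(im, ax=ax, label="methylation level")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
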