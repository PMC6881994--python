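"""Promoter-window methylation from MBD-capture sequencing read coordinates.

Methylation of a gene is summarized as the density of uniquely mapped read
starts inside a window spanning the transcription start site (default
TSS +/- 1000 bp, i.e. a 2000-bp promoter window), normalized to each
sample's total mapped reads.  Because those raw per-sample fractions live on
a ~1e-6 scale, levels are rescaled per gene (min-max to [0, 1] by default)
before the highly-differentially-methylated (HDM) thresholds are applied.

All coordinates are 0-based, half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .diffmeth import differential_table

SEX_CHROMOSOMES = frozenset({"chrX", "chrY", "X", "Y"})

__all__ = [
    "SEX_CHROMOSOMES",
    "WindowMethylation",
    "make_tss_windows",
    "quantify_windows",
    "scale_levels",
    "call_hdm_genes",
]


@dataclass
class WindowMethylation:
    """Gene x sample methylation levels with their normalization mode."""

    levels: pd.DataFrame  # genes x samples
    total_reads: pd.Series  # per sample
    mode: str  # "raw" | "per_gene_minmax" | "rank" | "none"


def make_tss_windows(
    annotation: pd.DataFrame,
    upstream: int = 1000,
    downstream: int = 1000,
    exclude_sex: bool = True,
    nm_only: bool = True,
) -> pd.DataFrame:
    """TSS-centered windows from a gene annotation table.

    ``annotation`` needs columns ``gene_id, chrom, tss, strand`` and may carry
    an ``accession`` column (RefSeq-style); when present and ``nm_only``,
    genes whose accession does not start with ``NM_`` (i.e. non-coding
    NR-type records) are dropped.  For a + strand gene the window is
    ``[tss - upstream, tss + downstream)``; for - strand the roles of up- and
    downstream flip, which for a symmetric span yields the same interval.
    Windows that would extend below zero are clamped with a warning.
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("upstream and downstream must be >= 0")
    ann = annotation.copy()
    if exclude_sex:
        ann = ann[~ann["chrom"].isin(SEX_CHROMOSOMES)]
    if nm_only and "accession" in ann.columns:
        ann = ann[ann["accession"].astype(str).str.startswith("NM_")]
    plus = ann["strand"] == "+"
    start = np.where(plus, ann["tss"] - upstream, ann["tss"] - downstream)
    end = np.where(plus, ann["tss"] + downstream, ann["tss"] + upstream)
    if (start < 0).any():
        warnings.warn("windows extending below position 0 were clamped", stacklevel=2)
        start = np.maximum(start, 0)
    out = pd.DataFrame(
        {
            "gene_id": ann["gene_id"].to_numpy(),
            "chrom": ann["chrom"].to_numpy(),
            "strand": ann["strand"].to_numpy(),
            "start": start.astype(np.int64),
            "end": end.astype(np.int64),
        }
    )
    return out.reset_index(drop=True)


def _count_in_windows(reads: pd.DataFrame, windows: pd.DataFrame) -> np.ndarray:
    """Read-start counts per window; a start at ``end`` is excluded (half-open)."""
    counts = np.zeros(len(windows), dtype=np.int64)
    by_chrom = {
        chrom: np.sort(grp["start"].to_numpy())
        for chrom, grp in reads.groupby("chrom", observed=True)
    }
    for chrom, widx in windows.groupby("chrom").groups.items():
        pos = by_chrom.get(chrom)
        if pos is None or pos.size == 0:
            continue
        w = windows.loc[widx]
        counts[windows.index.get_indexer(widx)] = np.searchsorted(
            pos, w["end"].to_numpy()
        ) - np.searchsorted(pos, w["start"].to_numpy())
    return counts


def quantify_windows(
    reads: Mapping[str, pd.DataFrame],
    windows: pd.DataFrame,
    total_reads: Mapping[str, int] | pd.Series | None = None,
) -> WindowMethylation:
    """Per-gene, per-sample read-start fraction inside each TSS window.

    ``reads`` maps sample id to a BED-like frame with ``chrom, start``
    columns (read 5' coordinates).  ``total_reads`` defaults to the number
    of rows per sample; samples with zero total reads are excluded with a
    warning.
    """
    windows = windows.reset_index(drop=True)
    cols = {}
    totals = {}
    for sample, df in reads.items():
        total = int(total_reads[sample]) if total_reads is not None else len(df)
        if total <= 0:
            warnings.warn(f"sample {sample!r} has no mapped reads; excluded", stacklevel=2)
            continue
        cols[sample] = _count_in_windows(df, windows) / total
        totals[sample] = total
    levels = pd.DataFrame(cols, index=windows["gene_id"].to_numpy())
    levels.index.name = "gene_id"
    return WindowMethylation(
        levels=levels, total_reads=pd.Series(totals, name="total_reads"), mode="raw"
    )


def scale_levels(wm: WindowMethylation, method: str = "per_gene_minmax") -> WindowMethylation:
    """Rescale raw read fractions so a [0, 1]-scale HDM threshold applies.

    ``per_gene_minmax`` maps each gene's values across samples onto [0, 1]
    (a constant gene maps to all zeros); ``rank`` maps to (rank - 0.5)/n;
    ``none`` passes through.
    """
    if wm.mode != "raw":
        raise ValueError("scale_levels expects raw-mode input")
    x = wm.levels
    if method == "per_gene_minmax":
        lo = x.min(axis=1)
        span = x.max(axis=1) - lo
        span = span.replace(0.0, np.nan)
        scaled = x.sub(lo, axis=0).div(span, axis=0).fillna(0.0)
    elif method == "rank":
        scaled = (x.rank(axis=1) - 0.5) / x.shape[1]
    elif method == "none":
        scaled = x.copy()
        method = "none"
    else:
        raise ValueError(f"unknown scaling method {method!r}")
    return WindowMethylation(levels=scaled, total_reads=wm.total_reads, mode=method)


def call_hdm_genes(
    wm: WindowMethylation,
    labels,
    p_max: float = 0.01,
    hdm_min: float = 0.2,
    auc_min: float = 0.85,
) -> pd.DataFrame:
    """Tissue-stage HDM gene calls (defaults: p < 0.01, level > 0.2, AUC > 0.85)."""
    return differential_table(
        wm.levels, labels, delta_min=hdm_min, p_max=p_max, auc_min=auc_min
    )
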