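"""450K-style bead-array stages: probe QC, HDM probes, promoter aggregation.

Two comparison designs are supported:

* individual case/control samples (public consortium tissue stage): per-probe
  median beta difference, Mann-Whitney p and AUC with thresholds
  delta > 0.15, p < 0.05, AUC > 0.75, then genes with >= 3 passing promoter
  probes;
* pooled scrapings (few equal-mass 5-specimen DNA pools per group): per-probe
  mean-of-pools beta difference with threshold delta > 0.015 and the same
  >= 3 promoter-probe rule, without a hypothesis test (too few pools).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .diffmeth import differential_table
from .mbdseq import SEX_CHROMOSOMES

__all__ = [
    "qc_filter_probes",
    "call_hdm_probes",
    "aggregate_promoter",
    "call_pooled_hdm",
]


def qc_filter_probes(
    manifest: pd.DataFrame,
    betas: pd.DataFrame,
    detection_p: pd.DataFrame | None = None,
    max_detection_p: float = 0.01,
    detection_rule: str = "any",
    snp_exclude: bool = True,
    snp_min_count: int = 1,
    nm_only: bool = True,
    drop_sex: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Probe-level quality control.

    Removes probes whose detection p exceeds ``max_detection_p`` in any
    sample (``detection_rule="any"``; ``"all"`` requires failure everywhere),
    probes carrying ``n_snp >= snp_min_count`` annotated SNPs when
    ``snp_exclude`` (SNPs under the probe distort beta; exclusion is the
    standard QC reading and is configurable), probes whose closest gene is
    non-coding (accession not ``NM_``-type) and probes on sex chromosomes.
    Returns the filtered ``(manifest, betas)``; an empty result warns rather
    than raises.
    """
    if manifest["probe_id"].duplicated().any():
        raise ValueError("probe ids must be unique")
    keep = manifest.set_index("probe_id")
    mask = pd.Series(True, index=keep.index)
    if detection_p is not None:
        dp = detection_p.reindex(mask.index)
        failed = dp.gt(max_detection_p)
        if detection_rule == "any":
            mask &= ~failed.any(axis=1)
        elif detection_rule == "all":
            mask &= ~failed.all(axis=1)
        else:
            raise ValueError("detection_rule must be 'any' or 'all'")
    if snp_exclude and "n_snp" in keep.columns:
        mask &= keep["n_snp"].fillna(0) < snp_min_count
    if nm_only and "accession" in keep.columns:
        mask &= keep["accession"].astype(str).str.startswith("NM_")
    if drop_sex:
        mask &= ~keep["chrom"].isin(SEX_CHROMOSOMES)
    kept_ids = mask.index[mask]
    if len(kept_ids) == 0:
        warnings.warn("all probes removed by QC", stacklevel=2)
    out_manifest = manifest[manifest["probe_id"].isin(kept_ids)].reset_index(drop=True)
    out_betas = betas.loc[betas.index.intersection(kept_ids)]
    return out_manifest, out_betas


def call_hdm_probes(
    betas: pd.DataFrame,
    labels,
    delta_min: float = 0.15,
    p_max: float = 0.05,
    auc_min: float = 0.75,
    level_stat: str = "median",
) -> pd.DataFrame:
    """Per-probe HDM calls for an individual-sample beta matrix."""
    return differential_table(
        betas, labels, delta_min=delta_min, p_max=p_max, auc_min=auc_min,
        level_stat=level_stat,
    )


def aggregate_promoter(
    probe_results: pd.DataFrame,
    manifest: pd.DataFrame,
    min_probes: int = 3,
) -> list[str]:
    """Genes with at least ``min_probes`` passing probes in their promoter.

    Only probes annotated ``in_promoter`` count; the gene is the manifest's
    ``closest_gene``.  Returns a sorted gene list.
    """
    ann = manifest.set_index("probe_id")
    passed = probe_results.index[probe_results["passed"]]
    ann = ann.loc[ann.index.intersection(passed)]
    ann = ann[ann["in_promoter"].astype(bool)]
    counts = ann.groupby("closest_gene").size()
    return sorted(counts.index[counts >= min_probes])


def call_pooled_hdm(
    pooled_betas: pd.DataFrame,
    pool_labels,
    manifest: pd.DataFrame,
    delta_min: float = 0.015,
    min_probes: int = 3,
) -> list[str]:
    """Pooled-scraping HDM genes: mean-of-case-pools minus mean-of-control-pools.

    A probe passes when that difference exceeds ``delta_min``; a gene is
    called when >= ``min_probes`` of its promoter probes pass.  No p value is
    computed: with 2-3 pools per group a rank test is meaningless.
    """
    y = np.asarray(pool_labels, dtype=bool)
    if not y.any() or y.all():
        raise ValueError("need at least one pool per group")
    mat = pooled_betas.to_numpy(dtype=float)
    delta = np.nanmean(mat[:, y], axis=1) - np.nanmean(mat[:, ~y], axis=1)
    res = pd.DataFrame(
        {"hdm_level": delta, "passed": delta > delta_min}, index=pooled_betas.index
    )
    return aggregate_promoter(res, manifest, min_probes=min_probes)
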