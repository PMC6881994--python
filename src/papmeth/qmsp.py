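"""Quantitative methylation-specific PCR (qMSP) readouts.

Methylation of a target gene is read out as
``delta_cp = Cp(gene assay) - Cp(COL2A1 reference assay)``; COL2A1 is
methylation-independent, so the difference normalizes for DNA input.  Lower
delta_cp means more methylated template.  A reference Cp above 36 cycles
indicates absent template DNA and invalidates the measurement; an undetected
target with a valid reference is right-censored at a configurable delta_cp
ceiling so rank statistics keep their ordering.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

MAX_REF_CP = 36.0
CENSOR_CEILING = 12.0

__all__ = [
    "MAX_REF_CP",
    "CENSOR_CEILING",
    "compute_delta_cp",
    "delta_cp_table",
    "aggregate_duplicates",
    "verify_candidate_pools",
    "pick_per_cluster",
]


def compute_delta_cp(
    cp_gene: float | None,
    cp_ref: float | None,
    max_ref_cp: float = MAX_REF_CP,
    censor_ceiling: float = CENSOR_CEILING,
) -> tuple[float, bool, bool]:
    """One measurement -> ``(delta_cp, valid, censored)``.

    ``None``/NaN marks an undetected assay.  An invalid or absent reference
    (Cp > ``max_ref_cp``) voids the record; an undetected target with a valid
    reference is censored at ``censor_ceiling`` cycles.
    """
    ref_missing = cp_ref is None or not np.isfinite(cp_ref)
    gene_missing = cp_gene is None or not np.isfinite(cp_gene)
    if ref_missing or cp_ref > max_ref_cp:
        return (np.nan, False, False)
    if gene_missing:
        return (float(censor_ceiling), True, True)
    return (float(cp_gene - cp_ref), True, False)


def delta_cp_table(
    records: pd.DataFrame,
    max_ref_cp: float = MAX_REF_CP,
    censor_ceiling: float = CENSOR_CEILING,
) -> pd.DataFrame:
    """Vectorized :func:`compute_delta_cp` over a long-format qMSP table.

    ``records`` needs ``cp_gene`` and ``cp_ref`` columns; all other columns
    (sample_id, gene, replicate, group, pool_id, ...) are passed through.
    Adds ``delta_cp, valid, censored``.
    """
    out = records.copy()
    cp_gene = pd.to_numeric(out["cp_gene"], errors="coerce")
    cp_ref = pd.to_numeric(out["cp_ref"], errors="coerce")
    valid_ref = cp_ref.notna() & (cp_ref <= max_ref_cp)
    censored = valid_ref & cp_gene.isna()
    delta = cp_gene - cp_ref
    delta[censored] = censor_ceiling
    delta[~valid_ref] = np.nan
    out["delta_cp"] = delta
    out["valid"] = valid_ref
    out["censored"] = censored
    return out


def aggregate_duplicates(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse technical replicates to one record per (sample_id, gene).

    The aggregate is the mean delta_cp over valid replicates; a pair with no
    valid replicate stays in the table as invalid.
    """
    def _agg(g: pd.DataFrame) -> pd.Series:
        ok = g[g["valid"]]
        if len(ok):
            return pd.Series(
                {
                    "delta_cp": ok["delta_cp"].mean(),
                    "valid": True,
                    "censored": bool(ok["censored"].any()),
                    "n_replicates": len(g),
                }
            )
        return pd.Series(
            {"delta_cp": np.nan, "valid": False, "censored": False, "n_replicates": len(g)}
        )

    keys = ["sample_id", "gene"]
    carry = [
        c
        for c in records.columns
        if c not in keys + ["delta_cp", "valid", "censored", "cp_gene", "cp_ref", "replicate"]
    ]
    agg = records.groupby(keys, sort=True).apply(_agg, include_groups=False).reset_index()
    if carry:
        first = records.groupby(keys, sort=True)[carry].first().reset_index()
        agg = agg.merge(first, on=keys)
    agg["valid"] = agg["valid"].astype(bool)
    agg["censored"] = agg["censored"].astype(bool)
    agg["n_replicates"] = agg["n_replicates"].astype(int)
    return agg


def verify_candidate_pools(
    tissue_case_pools,
    tissue_control_pools,
    scraping_case_pools,
    scraping_control_pools,
    normal_reference: str = "min",
) -> tuple[bool, dict]:
    """Pooled-DNA verification gate for one candidate gene.

    The gene passes when (a) at least one disease tissue pool shows a
    delta_cp strictly below the normal tissue pools, and (b) every disease
    scraping pool is strictly below the normal scraping pools.  "Below the
    normal pools" compares against their minimum by default (the strictest
    reading) or their mean (``normal_reference="mean"``).  Returns
    ``(passed, detail)`` with per-pool comparisons for auditing.
    """
    ref = {"min": np.min, "mean": np.mean}.get(normal_reference)
    if ref is None:
        raise ValueError("normal_reference must be 'min' or 'mean'")
    groups = {
        "tissue_case": np.asarray(tissue_case_pools, dtype=float),
        "tissue_control": np.asarray(tissue_control_pools, dtype=float),
        "scraping_case": np.asarray(scraping_case_pools, dtype=float),
        "scraping_control": np.asarray(scraping_control_pools, dtype=float),
    }
    for name, arr in groups.items():
        if arr.size == 0:
            raise ValueError(f"missing pool group: {name}")
    tissue_ref = float(ref(groups["tissue_control"]))
    scraping_ref = float(ref(groups["scraping_control"]))
    tissue_below = groups["tissue_case"] < tissue_ref
    scraping_below = groups["scraping_case"] < scraping_ref
    tissue_ok = bool(tissue_below.any())
    scraping_ok = bool(scraping_below.all())
    detail = {
        "tissue_reference": tissue_ref,
        "scraping_reference": scraping_ref,
        "tissue_pools_below": tissue_below.tolist(),
        "scraping_pools_below": scraping_below.tolist(),
        "tissue_criterion": tissue_ok,
        "scraping_criterion": scraping_ok,
    }
    return tissue_ok and scraping_ok, detail


def pick_per_cluster(
    candidates: pd.DataFrame,
    max_per_cluster: int = 2,
) -> list[str]:
    """Final panel: per cluster, the verified genes with the widest pooled gap.

    ``candidates`` needs columns ``gene, cluster, gap`` where ``gap`` is the
    normal-minus-disease pooled delta_cp difference (bigger = stronger
    methylation contrast).  Keeps up to ``max_per_cluster`` genes per
    cluster, ranked by gap descending with ties broken by gene id.
    """
    df = candidates.sort_values(
        ["cluster", "gap", "gene"], ascending=[True, False, True], kind="mergesort"
    )
    kept = df.groupby("cluster").head(max_per_cluster)
    return kept["gene"].tolist()
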