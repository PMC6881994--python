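"""Orchestration: discovery, pooled verification, validation, scoring.

Discovery runs the three HDM stages (tissue sequencing, individual-sample
arrays, pooled-scraping arrays), intersects the gene sets, clusters the
intersection on the tissue profiles and marks top candidates.  Validation
fits and freezes the risk model on the training cohort before the testing
cohort is touched — the train/test separation is structural (two inputs,
two phases), so no testing value can leak into a training-derived quantity.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import beadarray, candidates, mbdseq, qmsp, riskscore, rocstats

__all__ = [
    "PipelineConfig",
    "DiscoveryResult",
    "ValidationResult",
    "run_discovery",
    "run_verification",
    "run_validation",
]


@dataclass
class PipelineConfig:
    """Every stage threshold, with the study defaults."""

    # tissue stage
    tss_upstream: int = 1000
    tss_downstream: int = 1000
    exclude_sex: bool = True
    nm_only: bool = True
    scaling: str = "per_gene_minmax"
    tissue_p_max: float = 0.01
    tissue_hdm_min: float = 0.2
    tissue_auc_min: float = 0.85
    # individual-sample array stage
    max_detection_p: float = 0.01
    detection_rule: str = "any"
    snp_exclude: bool = True
    snp_min_count: int = 1
    array_delta_min: float = 0.15
    array_p_max: float = 0.05
    array_auc_min: float = 0.75
    array_level_stat: str = "median"
    min_promoter_probes: int = 3
    # pooled-scraping stage
    pooled_delta_min: float = 0.015
    pooled_min_probes: int = 3
    # selection
    n_clusters: int = 4
    top_fraction: float = 0.10
    min_cluster_to_apply: int = 5
    # verification
    normal_reference: str = "min"
    max_per_cluster: int = 2
    # validation
    single_gene_auc_gate: float = 0.7
    cv_folds: int = 10
    cv_replications: int = 200
    cv_aggregation: str = "mean"
    ridge: float = 1e-6
    n_boot: int = 200
    max_ref_cp: float = 36.0
    censor_ceiling: float = 12.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


@dataclass
class DiscoveryResult:
    tissue_results: pd.DataFrame
    tissue_genes: list[str]
    array_genes: list[str]
    pooled_genes: list[str]
    intersection: list[str]
    clusters: pd.Series
    candidate_table: pd.DataFrame


def run_discovery(
    config: PipelineConfig,
    tissue_reads: dict[str, pd.DataFrame],
    tissue_annotation: pd.DataFrame,
    tissue_labels,
    array_manifest: pd.DataFrame,
    array_betas: pd.DataFrame,
    array_detection_p: pd.DataFrame | None,
    array_labels,
    pooled_manifest: pd.DataFrame,
    pooled_betas: pd.DataFrame,
    pool_labels,
    tissue_totals=None,
) -> DiscoveryResult:
    """Three HDM stages -> intersection -> clustering -> candidate table."""
    # tissue sequencing stage
    windows = mbdseq.make_tss_windows(
        tissue_annotation,
        upstream=config.tss_upstream,
        downstream=config.tss_downstream,
        exclude_sex=config.exclude_sex,
        nm_only=config.nm_only,
    )
    wm_raw = mbdseq.quantify_windows(tissue_reads, windows, tissue_totals)
    wm = mbdseq.scale_levels(wm_raw, method=config.scaling)
    labels_arr = np.asarray(tissue_labels, dtype=bool)
    tissue_results = mbdseq.call_hdm_genes(
        wm,
        labels_arr,
        p_max=config.tissue_p_max,
        hdm_min=config.tissue_hdm_min,
        auc_min=config.tissue_auc_min,
    )
    tissue_genes = sorted(tissue_results.index[tissue_results["passed"]])

    # individual-sample array stage
    man_f, betas_f = beadarray.qc_filter_probes(
        array_manifest,
        array_betas,
        array_detection_p,
        max_detection_p=config.max_detection_p,
        detection_rule=config.detection_rule,
        snp_exclude=config.snp_exclude,
        snp_min_count=config.snp_min_count,
        nm_only=config.nm_only,
        drop_sex=config.exclude_sex,
    )
    probe_results = beadarray.call_hdm_probes(
        betas_f,
        np.asarray(array_labels, dtype=bool),
        delta_min=config.array_delta_min,
        p_max=config.array_p_max,
        auc_min=config.array_auc_min,
        level_stat=config.array_level_stat,
    )
    array_genes = beadarray.aggregate_promoter(
        probe_results, man_f, min_probes=config.min_promoter_probes
    )

    # pooled-scraping stage
    pman_f, pbetas_f = beadarray.qc_filter_probes(
        pooled_manifest,
        pooled_betas,
        None,
        snp_exclude=config.snp_exclude,
        snp_min_count=config.snp_min_count,
        nm_only=config.nm_only,
        drop_sex=config.exclude_sex,
    )
    pooled_genes = beadarray.call_pooled_hdm(
        pbetas_f,
        np.asarray(pool_labels, dtype=bool),
        pman_f,
        delta_min=config.pooled_delta_min,
        min_probes=config.pooled_min_probes,
    )

    intersection = candidates.intersect_gene_sets(tissue_genes, array_genes, pooled_genes)
    if len(intersection) == 0:
        warnings.warn("empty intersection: no candidate genes", stacklevel=2)
        empty = pd.DataFrame(columns=["cluster", "hdm_level", "rank", "selected"])
        return DiscoveryResult(
            tissue_results, tissue_genes, array_genes, pooled_genes, [],
            pd.Series(dtype=int), empty,
        )
    k = min(config.n_clusters, len(intersection))
    clusters = candidates.cluster_genes(wm.levels.loc[intersection], k=k)
    table = candidates.select_top_candidates(
        clusters,
        tissue_results["hdm_level"],
        fraction=config.top_fraction,
        min_cluster_to_apply=config.min_cluster_to_apply,
    )
    return DiscoveryResult(
        tissue_results=tissue_results,
        tissue_genes=tissue_genes,
        array_genes=array_genes,
        pooled_genes=pooled_genes,
        intersection=intersection,
        clusters=clusters,
        candidate_table=table,
    )


def run_verification(
    config: PipelineConfig,
    pool_dcp: pd.DataFrame,
    clusters: pd.Series | None = None,
) -> pd.DataFrame:
    """Apply the pooled-DNA gate per gene; rank survivors within clusters.

    ``pool_dcp`` is long format with columns
    ``gene, specimen_type (tissue|scraping), pool_id, group, delta_cp``.
    Returns a per-gene table with pass flags, the normal-minus-disease pooled
    gap and (when clusters are given) the final per-cluster panel picks.
    """
    rows = []
    for gene, g in pool_dcp.groupby("gene"):
        t = g[g["specimen_type"] == "tissue"]
        s = g[g["specimen_type"] == "scraping"]
        passed, detail = qmsp.verify_candidate_pools(
            t.loc[t["group"] == "case", "delta_cp"],
            t.loc[t["group"] == "control", "delta_cp"],
            s.loc[s["group"] == "case", "delta_cp"],
            s.loc[s["group"] == "control", "delta_cp"],
            normal_reference=config.normal_reference,
        )
        gap = float(
            s.loc[s["group"] == "control", "delta_cp"].mean()
            - s.loc[s["group"] == "case", "delta_cp"].mean()
        )
        rows.append({"gene": gene, "passed": passed, "gap": gap, **{
            k: v for k, v in detail.items() if not isinstance(v, list)
        }})
    table = pd.DataFrame(rows)
    table["selected"] = False
    if clusters is not None and len(table):
        table["cluster"] = table["gene"].map(clusters)
        survivors = table[table["passed"] & table["cluster"].notna()]
        panel = qmsp.pick_per_cluster(
            survivors[["gene", "cluster", "gap"]], max_per_cluster=config.max_per_cluster
        )
        table.loc[table["gene"].isin(panel), "selected"] = True
    return table


def _dcp_wide(records: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    """Long qMSP records -> samples x genes delta_cp (replicates averaged)."""
    tab = qmsp.delta_cp_table(
        records, max_ref_cp=config.max_ref_cp, censor_ceiling=config.censor_ceiling
    )
    agg = qmsp.aggregate_duplicates(tab)
    return agg.pivot(index="sample_id", columns="gene", values="delta_cp")


@dataclass
class ValidationResult:
    per_gene: pd.DataFrame  # group medians + Mann-Whitney p (summary shape)
    roc_table: pd.DataFrame  # cutoff / sens / spec / AUC for genes and panel
    model: riskscore.RiskModel
    train_metrics: dict
    test_metrics: dict
    panel: list[str]
    excluded_genes: list[str] = field(default_factory=list)


def run_validation(
    config: PipelineConfig,
    train_records: pd.DataFrame,
    train_labels: pd.Series,
    test_records: pd.DataFrame,
    test_labels: pd.Series,
    panel: list[str],
) -> ValidationResult:
    """Training-set statistics, risk-model fit, frozen evaluation on testing.

    Single genes must clear the training AUC gate (default 0.7) to enter the
    logistic combination.  Everything training-derived (gates, coefficients,
    cutoff) is frozen before the testing records are read.
    """
    overlap = set(train_records["sample_id"]) & set(test_records["sample_id"])
    if overlap:
        raise ValueError(f"train/test sample overlap: {sorted(overlap)[:5]}")
    missing = [g for g in panel if g not in set(train_records["gene"])]
    if missing:
        raise ValueError(f"panel gene(s) absent from training records: {missing}")

    # ---- training phase (testing data untouched) ----
    train_dcp = _dcp_wide(train_records, config)
    y_train = train_labels.reindex(train_dcp.index).to_numpy(dtype=bool)

    per_gene_rows = []
    roc_rows = []
    kept = []
    for gene in panel:
        v = train_dcp[gene]
        ok = v.notna()
        case = v[ok & pd.Series(y_train, index=train_dcp.index)]
        ctrl = v[ok & ~pd.Series(y_train, index=train_dcp.index)]
        _, p = rocstats.mann_whitney_two_tailed(case, ctrl)
        roc = rocstats.roc_analysis(
            v[ok],
            pd.Series(y_train, index=train_dcp.index)[ok],
            rocstats.LOWER_IS_POSITIVE,
            n_boot=config.n_boot,
            seed=config.seed,
        )
        per_gene_rows.append(
            {
                "gene": gene,
                "set": "training",
                "n_case": len(case),
                "n_control": len(ctrl),
                "median_case": case.median(),
                "median_control": ctrl.median(),
                "p_value": p,
            }
        )
        roc_rows.append(_roc_row(gene, "training", roc))
        if roc.auc > config.single_gene_auc_gate:
            kept.append(gene)
        else:
            warnings.warn(
                f"{gene}: training AUC {roc.auc:.2f} below gate "
                f"{config.single_gene_auc_gate}; excluded from combination",
                stacklevel=2,
            )
    excluded = [g for g in panel if g not in kept]
    combo = kept if kept else panel
    complete = train_dcp[combo].notna().all(axis=1)
    model = riskscore.fit_cv_model(
        train_dcp.loc[complete, combo],
        y_train[complete.to_numpy()],
        folds=config.cv_folds,
        replications=config.cv_replications,
        seed=config.seed,
        aggregation=config.cv_aggregation,
        ridge=config.ridge,
    )
    train_metrics = riskscore.evaluate(
        model, train_dcp, pd.Series(y_train, index=train_dcp.index),
        n_boot=config.n_boot, seed=config.seed,
    )
    roc_rows.append(_roc_row("+".join(combo), "training", train_metrics["roc"],
                             cutoff=model.cutoff,
                             sens=train_metrics["sensitivity"],
                             spec=train_metrics["specificity"]))

    # ---- testing phase (model and cutoff already frozen) ----
    test_dcp = _dcp_wide(test_records, config)
    y_test = test_labels.reindex(test_dcp.index).to_numpy(dtype=bool)
    for gene in kept:
        v = test_dcp[gene]
        ok = v.notna()
        yv = pd.Series(y_test, index=test_dcp.index)[ok]
        case = v[ok][yv]
        ctrl = v[ok][~yv]
        _, p = rocstats.mann_whitney_two_tailed(case, ctrl)
        roc = rocstats.roc_analysis(
            v[ok], yv, rocstats.LOWER_IS_POSITIVE, n_boot=config.n_boot,
            seed=config.seed,
        )
        per_gene_rows.append(
            {
                "gene": gene,
                "set": "testing",
                "n_case": len(case),
                "n_control": len(ctrl),
                "median_case": case.median(),
                "median_control": ctrl.median(),
                "p_value": p,
            }
        )
        roc_rows.append(_roc_row(gene, "testing", roc))
    test_metrics = riskscore.evaluate(
        model, test_dcp, pd.Series(y_test, index=test_dcp.index),
        n_boot=config.n_boot, seed=config.seed,
    )
    roc_rows.append(_roc_row("+".join(combo), "testing", test_metrics["roc"],
                             cutoff=model.cutoff,
                             sens=test_metrics["sensitivity"],
                             spec=test_metrics["specificity"]))
    return ValidationResult(
        per_gene=pd.DataFrame(per_gene_rows),
        roc_table=pd.DataFrame(roc_rows),
        model=model,
        train_metrics=train_metrics,
        test_metrics=test_metrics,
        panel=combo,
        excluded_genes=excluded,
    )


def _roc_row(name, which, roc, cutoff=None, sens=None, spec=None):
    return {
        "gene_set": name,
        "set": which,
        "cutoff": roc.cutoff if cutoff is None else cutoff,
        "sensitivity": roc.sensitivity if sens is None else sens,
        "specificity": roc.specificity if spec is None else spec,
        "auc": roc.auc,
        "auc_lo": roc.auc_ci[0],
        "auc_hi": roc.auc_ci[1],
    }
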