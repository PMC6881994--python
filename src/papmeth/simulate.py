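"""Synthetic cohorts with known ground truth for every pipeline stage.

One latent per-sample methylation fraction per gene drives all platforms, so
a gene planted as a marker is hypermethylated in disease samples of the
tissue sequencing cohort, the individual-sample bead-array cohort, the
pooled-scraping arrays and the qMSP cohorts alike — which is what makes a
cross-dataset intersection meaningful.

Platform models (implementation choices; no distributional model is imposed
by the biology):

* tissue MBD-capture sequencing: the read-start count inside a gene's
  TSS +/- 1 kb window is Poisson with mean
  ``read_depth * window_rate * latent``; remaining reads scatter uniformly
  outside windows, so window counts stay exactly Poisson;
* bead arrays: probe beta ~ Beta centered on the latent fraction with
  precision ``beta_precision``, plus a fixed per-probe offset; equal-mass
  DNA pools average the latent fractions of their members;
* qMSP: ``Cp_gene = ref_cp_mean + baseline_gene - cp_slope * latent +
  noise`` against a reference ``Cp_ref ~ Normal(ref_cp_mean, ref_cp_sd)``,
  so delta_cp falls linearly as methylation rises (about ``cp_slope`` cycles
  per unit methylated fraction); pooling of Cp values happens on the
  ``2**-Cp`` template scale, as equal-mass DNA mixing mixes template
  quantities.

Cohort-size defaults are study-shaped: 50 vs 6 tissue, 79 vs 6 array,
3 vs 2 five-specimen scraping pools, 31+31 training and 21+21 testing qMSP
samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .riskscore import RiskModel

__all__ = [
    "SimParams",
    "SyntheticTruth",
    "TissueReadset",
    "ArrayDataset",
    "PooledArrayDataset",
    "QmspCohort",
    "TRAINING_TARGET_MEDIANS",
    "TESTING_TARGET_MEDIANS",
    "gene_universe",
    "generate_tissue_readset",
    "generate_array_dataset",
    "generate_pooled_array",
    "pool_specimens",
    "generate_qmsp_cohort",
    "generate_verification_pools",
    "generate_logistic_cohort",
]

# Calibration defaults for qMSP delta_cp scales: per-gene
# (normal median, disease median) in cycles, matching the validation
# cohorts' reported group medians.
TRAINING_TARGET_MEDIANS: dict[str, tuple[float, float]] = {
    "AMPD3": (3.8, 2.7),
    "AOX1": (2.0, 1.0),
    "MEGF11": (5.8, 4.4),
    "NRN1": (2.3, 0.1),
    "TBX15": (7.6, 5.1),
}
TESTING_TARGET_MEDIANS: dict[str, tuple[float, float]] = {
    "AMPD3": (3.6, 2.0),
    "AOX1": (2.8, 0.9),
    "NRN1": (4.2, 0.4),
    "TBX15": (7.6, 4.9),
}

_GENE_SPACING = 100_000
_WINDOW_HALF = 1_000


@dataclass
class SimParams:
    """All generator knobs with study-shaped defaults."""

    n_genes: int = 500
    n_markers: int = 10
    # tissue MBD-seq stage
    tissue_n_case: int = 50
    tissue_n_control: int = 6
    tissue_effect: float = 0.3
    read_depth: int = 100_000
    window_rate: float = 0.002  # fraction of reads per window per unit methylation
    sample_sd: float = 0.05  # specimen-level latent wobble
    # individual-sample array stage
    array_n_case: int = 79
    array_n_control: int = 6
    array_effect: float = 0.2
    probes_per_gene_min: int = 5
    probes_per_gene_extra: float = 3.0  # Poisson mean on top of the minimum
    beta_precision: float = 200.0
    probe_offset_sd: float = 0.03
    distal_probe_fraction: float = 0.2
    snp_probe_fraction: float = 0.05
    detection_fail_fraction: float = 0.01
    # pooled-scraping array stage
    scraping_case_pools: int = 3
    scraping_control_pools: int = 2
    pool_size: int = 5
    scraping_effect: float = 0.05
    # qMSP stages
    cp_slope: float = 5.0  # cycles per unit methylated fraction
    cp_noise_sd: float = 1.5  # cycles, per replicate
    ref_cp_mean: float = 27.0
    ref_cp_sd: float = 0.3
    qmsp_sample_sd: float = 0.15
    qmsp_replicates: int = 2
    qmsp_fail_fraction: float = 0.0  # fraction of samples with absent template
    train_n_per_group: int = 31
    test_n_per_group: int = 21
    # gene universe
    baseline_low: float = 0.15
    baseline_high: float = 0.45
    sex_gene_fraction: float = 0.04
    noncoding_fraction: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 1 or self.n_markers < 0 or self.n_markers > self.n_genes:
            raise ValueError("need 0 <= n_markers <= n_genes and n_genes >= 1")
        for name in (
            "tissue_n_case",
            "tissue_n_control",
            "array_n_case",
            "array_n_control",
            "scraping_case_pools",
            "scraping_control_pools",
            "pool_size",
            "train_n_per_group",
            "test_n_per_group",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("tissue_effect", "array_effect", "scraping_effect"):
            e = getattr(self, name)
            if not (0.0 <= e < 1.0):
                raise ValueError(f"{name} must be in [0, 1)")
        if self.read_depth <= 0:
            raise ValueError("read_depth must be positive")
        if self.cp_slope <= 0:
            raise ValueError("cp_slope must be positive")
        if not (0 <= self.baseline_low <= self.baseline_high <= 1):
            raise ValueError("baseline range must satisfy 0 <= low <= high <= 1")


@dataclass
class SyntheticTruth:
    """What was planted: the marker set, per-stage effects, latent fractions."""

    marker_genes: tuple[str, ...]
    effects: dict = field(default_factory=dict)
    latents: pd.DataFrame | None = None  # genes x samples for this stage


@dataclass
class TissueReadset:
    reads: dict[str, pd.DataFrame]  # sample -> BED-like (chrom, start, end)
    annotation: pd.DataFrame
    labels: pd.Series  # bool per sample
    total_reads: pd.Series
    truth: SyntheticTruth


@dataclass
class ArrayDataset:
    manifest: pd.DataFrame
    betas: pd.DataFrame  # probes x samples
    detection_p: pd.DataFrame
    labels: pd.Series
    truth: SyntheticTruth


@dataclass
class PooledArrayDataset:
    manifest: pd.DataFrame
    betas: pd.DataFrame  # probes x pools
    pool_labels: pd.Series
    pool_members: dict[str, list[str]]
    truth: SyntheticTruth


@dataclass
class QmspCohort:
    records: pd.DataFrame  # long: sample_id, gene, replicate, cp_gene, cp_ref, group
    labels: pd.Series
    covariates: pd.DataFrame
    truth: SyntheticTruth


def _rng(params: SimParams, stage: int) -> np.random.Generator:
    return np.random.default_rng([params.seed, stage])


def gene_universe(params: SimParams) -> pd.DataFrame:
    """Deterministic gene table: id, chrom, TSS, strand, accession, baseline.

    A configurable slice of genes sits on chrX and a slice carries NR-type
    (non-coding) accessions, so the annotation filters have something to do.
    Markers are drawn among autosomal coding genes.
    """
    rng = _rng(params, 0)
    n = params.n_genes
    genes = [f"G{i:05d}" for i in range(1, n + 1)]
    n_sex = int(round(params.sex_gene_fraction * n))
    n_nr = int(round(params.noncoding_fraction * n))
    chroms = np.array([f"chr{(i % 22) + 1}" for i in range(n)], dtype=object)
    sex_idx = rng.choice(n, size=n_sex, replace=False) if n_sex else np.array([], int)
    chroms[sex_idx] = "chrX"
    accession = np.array([f"NM_{i:06d}" for i in range(1, n + 1)], dtype=object)
    eligible_nr = np.setdiff1d(np.arange(n), sex_idx)
    nr_idx = rng.choice(eligible_nr, size=min(n_nr, eligible_nr.size), replace=False)
    for i in nr_idx:
        accession[i] = accession[i].replace("NM_", "NR_")
    # position genes sequentially within each chromosome
    tss = np.zeros(n, dtype=np.int64)
    counters: dict[str, int] = {}
    for i, c in enumerate(chroms):
        k = counters.get(c, 0)
        tss[i] = 50_000 + k * _GENE_SPACING
        counters[c] = k + 1
    strand = np.where(rng.random(n) < 0.5, "+", "-")
    baseline = rng.uniform(params.baseline_low, params.baseline_high, size=n)
    df = pd.DataFrame(
        {
            "gene_id": genes,
            "chrom": chroms,
            "tss": tss,
            "strand": strand,
            "accession": accession,
            "baseline": baseline,
        }
    ).set_index("gene_id", drop=False)
    marker_pool = df.index[(df["chrom"] != "chrX") & df["accession"].str.startswith("NM_")]
    markers = tuple(sorted(rng.choice(marker_pool, size=params.n_markers, replace=False)))
    df.attrs["marker_genes"] = markers
    return df


def _latents(
    genes: pd.DataFrame,
    markers: Sequence[str],
    labels: pd.Series,
    effect: float,
    sd: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    base = genes["baseline"].to_numpy()[:, None]
    is_marker = genes.index.isin(markers)[:, None]
    is_case = labels.to_numpy(dtype=bool)[None, :]
    m = base + effect * (is_marker & is_case) + rng.normal(0.0, sd, (len(genes), len(labels)))
    return pd.DataFrame(
        np.clip(m, 0.01, 0.99), index=genes.index, columns=labels.index
    )


def _sample_labels(prefix: str, n_case: int, n_control: int) -> pd.Series:
    ids = [f"{prefix}_case{i:03d}" for i in range(1, n_case + 1)] + [
        f"{prefix}_ctrl{i:03d}" for i in range(1, n_control + 1)
    ]
    return pd.Series([True] * n_case + [False] * n_control, index=ids, name="is_case")


def generate_tissue_readset(params: SimParams) -> TissueReadset:
    """Tissue MBD-seq cohort as per-sample read-start tables plus annotation."""
    genes = gene_universe(params)
    markers = genes.attrs["marker_genes"]
    rng = _rng(params, 1)
    labels = _sample_labels("T", params.tissue_n_case, params.tissue_n_control)
    lat = _latents(genes, markers, labels, params.tissue_effect, params.sample_sd, rng)

    win_start = (genes["tss"] - _WINDOW_HALF).clip(lower=0).to_numpy()
    win_end = (genes["tss"] + _WINDOW_HALF).to_numpy()
    chrom_arr = genes["chrom"].to_numpy()
    chrom_len = {c: genes.loc[genes["chrom"] == c, "tss"].max() + _GENE_SPACING
                 for c in np.unique(chrom_arr)}
    # sorted window boundaries per chromosome for background rejection
    bounds = {
        c: np.sort(
            np.concatenate(
                [win_start[chrom_arr == c], win_end[chrom_arr == c]]
            )
        )
        for c in chrom_len
    }

    chrom_names = sorted(chrom_len)
    chrom_code = {c: i for i, c in enumerate(chrom_names)}
    gene_code = np.array([chrom_code[c] for c in chrom_arr])
    reads: dict[str, pd.DataFrame] = {}
    totals = {}
    for sample in labels.index:
        lam = params.read_depth * params.window_rate * lat[sample].to_numpy()
        counts = rng.poisson(lam)
        hit = np.flatnonzero(counts)
        pos_parts = [rng.integers(win_start[g], win_end[g], size=counts[g]) for g in hit]
        code_parts = [np.full(counts[g], gene_code[g]) for g in hit]
        n_bg = max(0, params.read_depth - int(counts.sum()))
        if n_bg:
            bg_code = rng.integers(0, len(chrom_names), size=n_bg)
            bg_pos = np.empty(n_bg, dtype=np.int64)
            for ci, c in enumerate(chrom_names):
                sel = np.flatnonzero(bg_code == ci)
                if sel.size == 0:
                    continue
                draw = rng.integers(0, chrom_len[c], size=sel.size)
                for _ in range(20):  # re-draw starts landing inside a window
                    inside = (np.searchsorted(bounds[c], draw, side="right") % 2) == 1
                    if not inside.any():
                        break
                    draw[inside] = rng.integers(0, chrom_len[c], size=int(inside.sum()))
                bg_pos[sel] = draw
            code_parts.append(bg_code)
            pos_parts.append(bg_pos)
        start = np.concatenate(pos_parts) if pos_parts else np.array([], dtype=np.int64)
        codes = np.concatenate(code_parts) if code_parts else np.array([], dtype=np.int64)
        df = pd.DataFrame(
            {"chrom": pd.Categorical.from_codes(codes, categories=chrom_names),
             "start": start}
        )
        df["end"] = df["start"] + 50  # nominal read length
        reads[sample] = df
        totals[sample] = len(df)

    annotation = genes[["gene_id", "chrom", "tss", "strand", "accession"]].reset_index(
        drop=True
    )
    truth = SyntheticTruth(
        marker_genes=markers, effects={"tissue": params.tissue_effect}, latents=lat
    )
    return TissueReadset(
        reads=reads,
        annotation=annotation,
        labels=labels,
        total_reads=pd.Series(totals, name="total_reads"),
        truth=truth,
    )


def array_manifest(params: SimParams) -> pd.DataFrame:
    """The (fixed) probe manifest shared by both bead-array stages.

    Every gene gets at least ``probes_per_gene_min`` promoter probes (within
    TSS +/- 1 kb); extra probes may fall further out.  A configurable probe
    fraction carries annotated SNPs; sex-chromosome and NR-accession genes
    are present so QC has work to do.
    """
    genes = gene_universe(params)
    rng = _rng(params, 2)
    rows = []
    pid = 0
    for gene_id, g in genes.iterrows():
        k = params.probes_per_gene_min + rng.poisson(params.probes_per_gene_extra)
        for j in range(k):
            pid += 1
            if j < params.probes_per_gene_min or rng.random() >= params.distal_probe_fraction:
                offset = int(rng.integers(-_WINDOW_HALF + 1, _WINDOW_HALF))
            else:
                offset = int(rng.integers(1_500, 5_000)) * (1 if rng.random() < 0.5 else -1)
            n_snp = int(1 + rng.poisson(0.5)) if rng.random() < params.snp_probe_fraction else 0
            rows.append(
                {
                    "probe_id": f"cg{pid:08d}",
                    "chrom": g["chrom"],
                    "position": int(g["tss"] + offset),
                    "closest_gene": gene_id,
                    "dist_to_tss": offset,
                    "in_promoter": abs(offset) <= _WINDOW_HALF,
                    "n_snp": n_snp,
                    "accession": g["accession"],
                }
            )
    return pd.DataFrame(rows)


def _probe_betas(
    manifest: pd.DataFrame,
    latents: pd.DataFrame,
    precision: float,
    offset_sd: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    gidx = latents.index.get_indexer(manifest["closest_gene"])
    offsets = rng.normal(0.0, offset_sd, size=len(manifest))
    m = np.clip(latents.to_numpy()[gidx] + offsets[:, None], 0.01, 0.99)
    betas = rng.beta(m * precision, (1.0 - m) * precision)
    return pd.DataFrame(betas, index=manifest["probe_id"].to_numpy(), columns=latents.columns)


def _detection_p(
    manifest: pd.DataFrame,
    samples: Sequence[str],
    fail_fraction: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    dp = rng.uniform(1e-4, 9e-3, size=(len(manifest), len(samples)))
    fails = np.flatnonzero(rng.random(len(manifest)) < fail_fraction)
    for i in fails:
        dp[i, rng.integers(0, len(samples))] = rng.uniform(0.011, 0.5)
    return pd.DataFrame(dp, index=manifest["probe_id"].to_numpy(), columns=list(samples))


def generate_array_dataset(params: SimParams) -> ArrayDataset:
    """Individual-sample bead-array cohort (consortium-tissue shaped)."""
    genes = gene_universe(params)
    markers = genes.attrs["marker_genes"]
    manifest = array_manifest(params)
    rng = _rng(params, 3)
    labels = _sample_labels("A", params.array_n_case, params.array_n_control)
    lat = _latents(genes, markers, labels, params.array_effect, params.sample_sd, rng)
    betas = _probe_betas(manifest, lat, params.beta_precision, params.probe_offset_sd, rng)
    dp = _detection_p(manifest, labels.index, params.detection_fail_fraction, rng)
    truth = SyntheticTruth(
        marker_genes=markers, effects={"array": params.array_effect}, latents=lat
    )
    return ArrayDataset(
        manifest=manifest, betas=betas, detection_p=dp, labels=labels, truth=truth
    )


def pool_specimens(member_values: Sequence[float], mode: str) -> float:
    """Equal-quantity pooling of specimen values.

    ``mode="beta"``: pooled methylation fraction is the arithmetic mean.
    ``mode="cp"``: pooled Cp is ``-log2(mean(2**-Cp_i))`` — equal DNA masses
    mix template quantities, which live on the exponential scale.
    """
    v = np.asarray(member_values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot pool an empty specimen list")
    if mode == "beta":
        return float(v.mean())
    if mode == "cp":
        return float(-np.log2(np.mean(np.exp2(-v))))
    raise ValueError("mode must be 'beta' or 'cp'")


def generate_pooled_array(params: SimParams) -> PooledArrayDataset:
    """Pooled-scraping bead arrays: few equal-mass 5-specimen pools per group."""
    genes = gene_universe(params)
    markers = genes.attrs["marker_genes"]
    manifest = array_manifest(params)
    rng = _rng(params, 4)
    n_case_spec = params.scraping_case_pools * params.pool_size
    n_ctrl_spec = params.scraping_control_pools * params.pool_size
    spec_labels = _sample_labels("S", n_case_spec, n_ctrl_spec)
    lat = _latents(genes, markers, spec_labels, params.scraping_effect, params.sample_sd, rng)

    pool_cols = {}
    members: dict[str, list[str]] = {}
    pool_is_case = {}
    spec_ids = list(spec_labels.index)
    for p in range(params.scraping_case_pools):
        ids = spec_ids[p * params.pool_size : (p + 1) * params.pool_size]
        name = f"P_case{p + 1}"
        pool_cols[name] = lat[ids].mean(axis=1)
        members[name] = ids
        pool_is_case[name] = True
    off = n_case_spec
    for p in range(params.scraping_control_pools):
        ids = spec_ids[off + p * params.pool_size : off + (p + 1) * params.pool_size]
        name = f"P_ctrl{p + 1}"
        pool_cols[name] = lat[ids].mean(axis=1)
        members[name] = ids
        pool_is_case[name] = False
    pooled_lat = pd.DataFrame(pool_cols)
    betas = _probe_betas(
        manifest, pooled_lat, params.beta_precision, params.probe_offset_sd, rng
    )
    truth = SyntheticTruth(
        marker_genes=markers, effects={"scraping": params.scraping_effect}, latents=lat
    )
    return PooledArrayDataset(
        manifest=manifest,
        betas=betas,
        pool_labels=pd.Series(pool_is_case, name="is_case"),
        pool_members=members,
        truth=truth,
    )


def _qmsp_gene_setup(
    gene_panel: Sequence[str],
    target_medians: Mapping[str, tuple[float, float]] | None,
    cp_slope: float,
) -> pd.DataFrame:
    """Per-gene latent centers and Cp baselines hitting the target medians."""
    rows = []
    for gene in gene_panel:
        if target_medians is not None and gene in target_medians:
            t_normal, t_case = target_medians[gene]
        else:
            t_normal, t_case = 4.0, 2.5  # generic hypermethylated marker
        eff = (t_normal - t_case) / cp_slope
        m0 = float(np.clip(0.5 - eff / 2.0, 0.02, 0.98))
        m1 = float(np.clip(m0 + eff, 0.02, 0.98))
        baseline = t_normal + cp_slope * m0
        rows.append((gene, t_normal, t_case, m0, m1, baseline))
    return pd.DataFrame(
        rows,
        columns=["gene", "target_normal", "target_case", "m_normal", "m_case", "baseline"],
    ).set_index("gene")


def _covariates(labels: pd.Series, rng: np.random.Generator) -> pd.DataFrame:
    y = labels.to_numpy(dtype=bool)
    n = len(labels)
    age = np.where(y, rng.normal(52, 12, n), rng.normal(43, 13, n)).round(0)
    histology = np.where(
        y,
        rng.choice(["serous", "mucinous", "endometrioid", "clear_cell"],
                   size=n, p=[0.55, 0.15, 0.10, 0.20]),
        "none",
    )
    stage = np.where(y, rng.choice(["I", "II", "III", "IV"], size=n,
                                   p=[0.30, 0.15, 0.40, 0.15]), "none")
    grade = np.where(y, rng.choice(["G1", "G2", "G3"], size=n, p=[0.15, 0.20, 0.65]),
                     "none")
    return pd.DataFrame(
        {"age": age, "histology": histology, "stage": stage, "grade": grade},
        index=labels.index,
    )


def generate_qmsp_cohort(
    params: SimParams,
    gene_panel: Sequence[str],
    n_case: int | None = None,
    n_control: int | None = None,
    target_medians: Mapping[str, tuple[float, float]] | None = None,
    prefix: str = "Q",
    stage: int = 5,
) -> QmspCohort:
    """Individual-sample qMSP cohort in long format (with duplicate wells).

    ``target_medians`` maps gene -> (normal median, disease median) delta_cp
    in cycles; group latent centers and per-gene Cp baselines are solved so
    the generated group medians land on those targets.  A
    ``qmsp_fail_fraction`` of samples gets reference Cp > 36 on all wells
    (absent template).
    """
    if not len(gene_panel):
        raise ValueError("gene_panel must be nonempty")
    rng = _rng(params, stage)
    n_case = params.train_n_per_group if n_case is None else n_case
    n_control = params.train_n_per_group if n_control is None else n_control
    labels = _sample_labels(prefix, n_case, n_control)
    setup = _qmsp_gene_setup(gene_panel, target_medians, params.cp_slope)

    centers = np.where(
        labels.to_numpy(dtype=bool)[None, :],
        setup["m_case"].to_numpy()[:, None],
        setup["m_normal"].to_numpy()[:, None],
    )
    lat = np.clip(
        centers + rng.normal(0.0, params.qmsp_sample_sd, centers.shape), 0.0, 1.0
    )
    lat_df = pd.DataFrame(lat, index=setup.index, columns=labels.index)
    failed = rng.random(len(labels)) < params.qmsp_fail_fraction

    rows = []
    for gi, gene in enumerate(setup.index):
        for si, sample in enumerate(labels.index):
            for rep in range(1, params.qmsp_replicates + 1):
                if failed[si]:
                    cp_ref = rng.uniform(36.5, 40.0)
                else:
                    cp_ref = rng.normal(params.ref_cp_mean, params.ref_cp_sd)
                cp_gene = (
                    params.ref_cp_mean
                    + setup["baseline"].iloc[gi]
                    - params.cp_slope * lat[gi, si]
                    + rng.normal(0.0, params.cp_noise_sd)
                )
                rows.append((sample, gene, rep, cp_gene, cp_ref))
    records = pd.DataFrame(
        rows, columns=["sample_id", "gene", "replicate", "cp_gene", "cp_ref"]
    )
    records["group"] = records["sample_id"].map(
        labels.map({True: "case", False: "control"})
    )
    truth = SyntheticTruth(
        marker_genes=tuple(gene_panel),
        effects={g: float(setup.loc[g, "target_normal"] - setup.loc[g, "target_case"])
                 for g in setup.index},
        latents=lat_df,
    )
    return QmspCohort(
        records=records,
        labels=labels,
        covariates=_covariates(labels, rng),
        truth=truth,
    )


def generate_verification_pools(
    params: SimParams,
    gene_panel: Sequence[str],
    marker_genes: Sequence[str] | None = None,
    marker_effect: float = 0.8,
    baseline_fraction: float = 0.1,
    tissue_case_pools: int = 3,
    tissue_control_pools: int = 2,
    scraping_case_pools: int = 3,
    scraping_control_pools: int = 3,
    stage: int = 7,
) -> pd.DataFrame:
    """Pooled-DNA qMSP screen (duplicate wells per pool) for a candidate panel.

    Markers (default: every panel gene) are strongly methylated in disease
    specimens (latent ``baseline_fraction + marker_effect`` vs
    ``baseline_fraction``); pooling happens on the 2**-Cp template scale
    before measurement noise.  Returns a long table with columns
    ``gene, specimen_type, pool_id, group, delta_cp``.
    """
    rng = _rng(params, stage)
    markers = set(gene_panel if marker_genes is None else marker_genes)
    out = []
    plan = [
        ("tissue", True, tissue_case_pools),
        ("tissue", False, tissue_control_pools),
        ("scraping", True, scraping_case_pools),
        ("scraping", False, scraping_control_pools),
    ]
    for gene in gene_panel:
        eff = marker_effect if gene in markers else 0.0
        baseline_cycles = params.ref_cp_mean + params.cp_slope  # arbitrary gene assay offset
        for specimen_type, is_case, n_pools in plan:
            for p in range(1, n_pools + 1):
                m = np.clip(
                    baseline_fraction
                    + (eff if is_case else 0.0)
                    + rng.normal(0.0, params.qmsp_sample_sd, params.pool_size),
                    0.0,
                    1.0,
                )
                member_cp = baseline_cycles - params.cp_slope * m
                pooled_cp = pool_specimens(member_cp, mode="cp")
                reps_gene = pooled_cp + rng.normal(0.0, params.cp_noise_sd,
                                                   params.qmsp_replicates)
                reps_ref = rng.normal(params.ref_cp_mean, params.ref_cp_sd,
                                      params.qmsp_replicates)
                delta = float(np.mean(reps_gene) - np.mean(reps_ref))
                out.append(
                    (
                        gene,
                        specimen_type,
                        f"{specimen_type}_{'case' if is_case else 'ctrl'}{p}",
                        "case" if is_case else "control",
                        delta,
                    )
                )
    return pd.DataFrame(
        out, columns=["gene", "specimen_type", "pool_id", "group", "delta_cp"]
    )


def generate_logistic_cohort(
    model: RiskModel,
    n: int,
    dcp_means: Mapping[str, float],
    dcp_sd: float = 1.3,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Samples whose labels truly follow a known logistic model.

    delta_cp values are Gaussian around ``dcp_means``; the disease label is
    Bernoulli with probability ``sigmoid(eps + sum beta_i * dcp_i)``.  Used
    for coefficient-recovery checks.
    """
    rng = np.random.default_rng(seed)
    x = pd.DataFrame(
        {g: rng.normal(dcp_means[g], dcp_sd, n) for g in model.genes},
        index=[f"L{i:04d}" for i in range(1, n + 1)],
    )
    eta = model.intercept + x.to_numpy() @ model.coefficients
    p = 1.0 / (1.0 + np.exp(-eta))
    y = pd.Series(rng.random(n) < p, index=x.index, name="is_case")
    return x, y
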