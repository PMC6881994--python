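"""Ground-truth generators: determinism, calibration, analytic means."""

import numpy as np
import pandas as pd
import pytest

from papmeth import mbdseq, qmsp, simulate


class TestPoolSpecimens:
    def test_beta_mode_is_mean(self):
        assert simulate.pool_specimens([0.2, 0.4], "beta") == pytest.approx(0.3)

    def test_cp_identical_members(self):
        assert simulate.pool_specimens([30.0] * 5, "cp") == pytest.approx(30.0)

    def test_cp_template_scale_mixing(self):
        expected = -np.log2((2.0**-30 + 2.0**-32) / 2)
        got = simulate.pool_specimens([30.0, 32.0], "cp")
        assert got == pytest.approx(expected)
        assert got == pytest.approx(30.678, abs=1e-3)

    def test_cp_bounded_by_member_extremes(self, rng):
        for _ in range(100):
            v = rng.uniform(20, 36, size=rng.integers(1, 8))
            pooled = simulate.pool_specimens(v, "cp")
            assert v.min() - 1e-9 <= pooled <= v.max() + 1e-9

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            simulate.pool_specimens([], "beta")


class TestParams:
    def test_bad_depth_rejected(self):
        with pytest.raises(ValueError):
            simulate.SimParams(read_depth=0)

    def test_bad_effect_rejected(self):
        with pytest.raises(ValueError):
            simulate.SimParams(tissue_effect=1.5)

    def test_bad_group_size_rejected(self):
        with pytest.raises(ValueError):
            simulate.SimParams(tissue_n_control=0)


class TestTissueReadset:
    def test_deterministic_under_seed(self):
        p = simulate.SimParams(n_genes=20, n_markers=2, read_depth=5_000, seed=5)
        a = simulate.generate_tissue_readset(p)
        b = simulate.generate_tissue_readset(p)
        assert a.truth.marker_genes == b.truth.marker_genes
        for s in a.reads:
            pd.testing.assert_frame_equal(a.reads[s], b.reads[s])

    def test_null_effect_no_group_difference(self):
        p = simulate.SimParams(
            n_genes=30, n_markers=3, tissue_effect=0.0, read_depth=20_000, seed=2
        )
        t = simulate.generate_tissue_readset(p)
        lat = t.truth.latents
        y = t.labels.to_numpy()
        markers = list(t.truth.marker_genes)
        diff = lat.loc[markers, y].mean(axis=1) - lat.loc[markers, ~y].mean(axis=1)
        assert np.abs(diff).max() < 0.1  # only sampling noise remains

    def test_marker_window_counts_match_analytic_mean(self):
        """Monte-Carlo window counts track depth * rate * latent (Poisson)."""
        p = simulate.SimParams(
            n_genes=10, n_markers=2, read_depth=50_000, tissue_effect=0.5,
            sample_sd=0.0, seed=8,
        )
        t = simulate.generate_tissue_readset(p)
        w = mbdseq.make_tss_windows(t.annotation, exclude_sex=False, nm_only=False)
        wm = mbdseq.quantify_windows(t.reads, w)
        counts = wm.levels * t.total_reads  # back to raw counts
        lam = p.read_depth * p.window_rate * t.truth.latents.loc[wm.levels.index]
        # average over all samples x genes: relative error shrinks as 1/sqrt(N)
        rel = (counts.mean(axis=1) - lam.mean(axis=1)) / lam.mean(axis=1)
        assert np.abs(rel).max() < 0.1

    def test_marker_case_enrichment_ratio(self):
        p = simulate.SimParams(
            n_genes=10, n_markers=2, read_depth=50_000, tissue_effect=0.5,
            sample_sd=0.0, seed=9, baseline_low=0.25, baseline_high=0.25,
        )
        t = simulate.generate_tissue_readset(p)
        w = mbdseq.make_tss_windows(t.annotation, exclude_sex=False, nm_only=False)
        wm = mbdseq.quantify_windows(t.reads, w)
        y = t.labels.to_numpy()
        m = list(t.truth.marker_genes)
        ratio = wm.levels.loc[m, y].mean(axis=1) / wm.levels.loc[m, ~y].mean(axis=1)
        # latent 0.75 vs 0.25 -> threefold window enrichment
        assert ratio.to_numpy() == pytest.approx([3.0, 3.0], rel=0.1)


class TestArrayDataset:
    def test_every_gene_has_promoter_probes(self):
        p = simulate.SimParams(n_genes=25, n_markers=2, seed=4)
        man = simulate.array_manifest(p)
        per_gene = man[man["in_promoter"]].groupby("closest_gene").size()
        assert (per_gene >= p.probes_per_gene_min).all()
        assert per_gene.index.size == p.n_genes

    def test_single_gene_manifest(self):
        p = simulate.SimParams(
            n_genes=1, n_markers=0, sex_gene_fraction=0.0, noncoding_fraction=0.0, seed=1
        )
        man = simulate.array_manifest(p)
        assert set(man["closest_gene"]) == {"G00001"}

    def test_clean_dataset_qc_removes_only_sex_and_noncoding(self):
        from papmeth import beadarray

        p = simulate.SimParams(
            n_genes=50, n_markers=0, snp_probe_fraction=0.0,
            detection_fail_fraction=0.0, seed=6,
        )
        ds = simulate.generate_array_dataset(p)
        man, _ = beadarray.qc_filter_probes(ds.manifest, ds.betas, ds.detection_p)
        removed = set(ds.manifest["probe_id"]) - set(man["probe_id"])
        bad = ds.manifest[
            ds.manifest["chrom"].isin(["chrX", "chrY"])
            | ~ds.manifest["accession"].str.startswith("NM_")
        ]
        assert removed == set(bad["probe_id"])

    def test_marker_beta_shift_matches_effect(self):
        """Mean case-control probe beta difference tracks the planted effect."""
        p = simulate.SimParams(
            n_genes=10, n_markers=3, array_effect=0.2, sample_sd=0.0, seed=10,
            array_n_case=200, array_n_control=200,
        )
        ds = simulate.generate_array_dataset(p)
        y = ds.labels.to_numpy()
        marker_probes = ds.manifest.loc[
            ds.manifest["closest_gene"].isin(ds.truth.marker_genes), "probe_id"
        ]
        diff = (
            ds.betas.loc[marker_probes, ds.labels.index[y]].mean(axis=1)
            - ds.betas.loc[marker_probes, ds.labels.index[~y]].mean(axis=1)
        )
        assert diff.mean() == pytest.approx(0.2, abs=0.02)

    def test_deterministic(self):
        p = simulate.SimParams(n_genes=15, n_markers=2, seed=3)
        a = simulate.generate_array_dataset(p)
        b = simulate.generate_array_dataset(p)
        pd.testing.assert_frame_equal(a.betas, b.betas)


class TestPooledArray:
    def test_pools_average_member_latents(self):
        p = simulate.SimParams(n_genes=12, n_markers=2, seed=7)
        ds = simulate.generate_pooled_array(p)
        for pool, members in ds.pool_members.items():
            assert len(members) == p.pool_size
        assert ds.pool_labels.sum() == p.scraping_case_pools
        assert (~ds.pool_labels).sum() == p.scraping_control_pools

    def test_shares_manifest_with_array_stage(self):
        p = simulate.SimParams(n_genes=12, n_markers=2, seed=7)
        a = simulate.generate_array_dataset(p)
        b = simulate.generate_pooled_array(p)
        pd.testing.assert_frame_equal(a.manifest, b.manifest)


class TestQmspCohort:
    def test_null_noise_free_groups_identical(self):
        p = simulate.SimParams(cp_noise_sd=0.0, ref_cp_sd=0.0, qmsp_sample_sd=0.0, seed=1)
        c = simulate.generate_qmsp_cohort(
            p, ["g1"], n_case=5, n_control=5, target_medians={"g1": (4.0, 4.0)}
        )
        tab = qmsp.aggregate_duplicates(qmsp.delta_cp_table(c.records))
        assert tab["delta_cp"].std() == pytest.approx(0.0, abs=1e-12)

    def test_realized_medians_hit_targets(self):
        """Group medians land within 0.3 cycles of targets (median of 50 seeds)."""
        targets = simulate.TESTING_TARGET_MEDIANS
        errs = {g: [] for g in targets}
        for seed in range(50):
            p = simulate.SimParams(seed=seed)
            c = simulate.generate_qmsp_cohort(
                p, list(targets), n_case=21, n_control=21, target_medians=targets
            )
            tab = qmsp.aggregate_duplicates(qmsp.delta_cp_table(c.records))
            tab["is_case"] = tab["sample_id"].map(c.labels)
            med = tab.groupby(["gene", "is_case"])["delta_cp"].median()
            for g, (t_norm, t_case) in targets.items():
                errs[g].append(abs(med[(g, False)] - t_norm))
                errs[g].append(abs(med[(g, True)] - t_case))
        for g, e in errs.items():
            assert np.median(e) < 0.3, g

    def test_qc_failure_fraction_flags_expected_share(self):
        p = simulate.SimParams(qmsp_fail_fraction=0.1, seed=42)
        c = simulate.generate_qmsp_cohort(p, ["g1"], n_case=50, n_control=50)
        tab = qmsp.aggregate_duplicates(qmsp.delta_cp_table(c.records))
        n_invalid = int((~tab["valid"]).sum())
        assert 3 <= n_invalid <= 20  # ~Binomial(100, 0.1)

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            simulate.generate_qmsp_cohort(simulate.SimParams(), [])

    def test_deterministic(self):
        p = simulate.SimParams(seed=5)
        a = simulate.generate_qmsp_cohort(p, ["g1", "g2"])
        b = simulate.generate_qmsp_cohort(p, ["g1", "g2"])
        pd.testing.assert_frame_equal(a.records, b.records)


class TestLogisticCohort:
    def test_labels_follow_model_probabilities(self):
        from papmeth import riskscore

        model = riskscore.published_model()
        x, y = simulate.generate_logistic_cohort(
            model, 4000, {"AMPD3": 2.8, "NRN1": 2.3, "TBX15": 6.2}, seed=0
        )
        eta = model.intercept + x.to_numpy() @ model.coefficients
        p = 1 / (1 + np.exp(-eta))
        # calibration: observed rate in high/low probability halves
        hi = p > np.median(p)
        assert abs(y[hi].mean() - p[hi].mean()) < 0.05
        assert abs(y[~hi].mean() - p[~hi].mean()) < 0.05
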