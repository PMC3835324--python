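"""Ground-truth generator: moments, determinism, forward/inverse consistency."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ycquant.calibration import ratio_to_calcium
from ycquant.imaging import compute_ratio_stack, estimate_background, measure_rois
from ycquant.io import rois_from_labels
from ycquant.synthetic import (
    CohortConfig,
    _place_spines,
    export_truth,
    lognormal_params_from_moments,
    render_scene,
    sample_cohort,
    simulate_measurement_tables,
)

from conftest import straight_dendrite_scene


class TestCohortConfig:
    def test_defaults_mirror_study_design(self):
        cfg = CohortConfig(seed=0)
        assert (cfg.n_control_animals, cfg.n_tau_animals) == (6, 9)
        assert cfg.volumes_per_animal == 10
        assert cfg.tau_density_factor == pytest.approx(0.7)

    @pytest.mark.parametrize(
        "kw", [dict(n_control_animals=0), dict(tau_density_factor=0.0),
               dict(overload_fraction_tau=1.0), dict(control_density=-1)]
    )
    def test_invalid_config_rejected_before_sampling(self, kw):
        with pytest.raises(ValueError):
            dataclasses.replace(CohortConfig(seed=0), **kw)


class TestCalciumDistribution:
    def test_moment_matching_closed_form(self):
        mu, sigma = lognormal_params_from_moments(125.3, 101.0)
        assert np.exp(mu + sigma**2 / 2) == pytest.approx(125.3, rel=1e-12)
        var = (np.exp(sigma**2) - 1) * np.exp(2 * mu + sigma**2)
        assert np.sqrt(var) == pytest.approx(101.0, rel=1e-12)

    def test_sampled_moments_match_control_statistics(self):
        """10^4 resting-calcium draws have mean in [115, 135] nM and SD in
        [90, 112] nM, the control-like distribution the cohort assumes."""
        cfg = CohortConfig(seed=123)
        rng = np.random.default_rng(cfg.seed)
        draws = rng.lognormal(cfg.calcium_log_mean, cfg.calcium_log_sd, size=10_000)
        assert 115 <= draws.mean() <= 135
        assert 90 <= draws.std(ddof=1) <= 112


class TestDeterminism:
    def test_same_seed_identical_scenes(self):
        cfg = dataclasses.replace(CohortConfig(seed=77), n_control_animals=1,
                                  n_tau_animals=1, volumes_per_animal=1)
        a, b = sample_cohort(cfg), sample_cohort(cfg)
        assert len(a) == len(b)
        for sa, sb in zip(a, b):
            assert sa.scene_id == sb.scene_id
            for ta, tb in zip(sa.traces, sb.traces):
                assert np.array_equal(ta.polyline, tb.polyline)
            for k in sa.spines:
                assert np.array_equal(sa.spines[k], sb.spines[k])
            assert sa.true_calcium == sb.true_calcium

    def test_same_seed_identical_renders(self, small_cohort_config):
        scene = sample_cohort(small_cohort_config)[0]
        s1, l1, m1 = render_scene(scene, small_cohort_config, seed=5)
        s2, l2, m2 = render_scene(scene, small_cohort_config, seed=5)
        assert np.array_equal(s1.cfp, s2.cfp) and np.array_equal(s1.yfp, s2.yfp)
        assert np.array_equal(l1, l2)

    def test_same_seed_identical_measurement_tables(self):
        cfg = dataclasses.replace(CohortConfig(seed=3), volumes_per_animal=2)
        m1, d1 = simulate_measurement_tables(cfg)
        m2, d2 = simulate_measurement_tables(cfg)
        pd.testing.assert_frame_equal(m1, m2)
        pd.testing.assert_frame_equal(d1, d2)


class TestGenotypeSymmetry:
    def test_no_injected_effect_is_statistically_invisible(self):
        """With tau_density_factor=1 and no overload mixture, pooled genotype
        summaries are indistinguishable (two-sample tests give p > 0.05 in
        >= 90% of seeds)."""
        ok_ca, ok_de = 0, 0
        n_seeds = 30
        for s in range(n_seeds):
            cfg = dataclasses.replace(
                CohortConfig(seed=40_000 + s),
                tau_density_factor=1.0, volumes_per_animal=2, animal_density_cv=0.0,
            )
            m, d = simulate_measurement_tables(cfg)
            dend = m[m["compartment"] == "dendrite"]
            ctl = dend.loc[dend["genotype"] == "control", "mean_ratio"]
            tau = dend.loc[dend["genotype"] == "tau", "mean_ratio"]
            ok_ca += sps.mannwhitneyu(ctl, tau).pvalue > 0.05
            ok_de += sps.ttest_ind(
                d.loc[d["genotype"] == "control", "density_per_um"],
                d.loc[d["genotype"] == "tau", "density_per_um"],
            ).pvalue > 0.05
        assert ok_ca / n_seeds >= 0.9
        assert ok_de / n_seeds >= 0.9


class TestSpinePlacement:
    def test_counts_are_poisson_with_configured_rate(self):
        """Pooled spine counts over fixed-length traces pass a chi-square
        goodness-of-fit test against Poisson(rate * length)."""
        rng = np.random.default_rng(99)
        L, rate = 30.0, 0.6
        counts = np.array([len(_place_spines(rng, L, rate, 0.4)) for _ in range(600)])
        lam = rate * L
        kmax = int(sps.poisson.ppf(0.999, lam))
        edges = np.arange(0, kmax + 2)
        obs = np.histogram(counts, bins=np.append(edges, np.inf))[0]
        exp = np.diff(np.append(sps.poisson.cdf(edges - 1, lam), 1.0)) * len(counts)
        keep = exp > 1.0
        chi2 = ((obs[keep] - exp[keep]) ** 2 / exp[keep]).sum()
        p = sps.chi2.sf(chi2, keep.sum() - 1)
        assert p > 0.01

    def test_hardcore_spacing_enforced(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            pos = _place_spines(rng, 30.0, 0.6, 0.4)
            if len(pos) > 1:
                assert np.diff(np.sort(pos)).min() >= 0.4 - 1e-9


class TestForwardInverseConsistency:
    @pytest.mark.parametrize("true_calcium", [10.0, 50.0, 125.3, 500.0, 1000.0])
    def test_noiseless_render_round_trip(self, true_calcium):
        """Noiseless, PSF-free rendering followed by the measurement chain
        recovers the true concentration within 0.1% relative."""
        scene, _ = straight_dendrite_scene(0, calcium_nM=true_calcium)
        cfg = CohortConfig(seed=0)
        stack, labels, meta = render_scene(scene, cfg, seed=1, apply_psf=False, apply_noise=False)
        rs = compute_ratio_stack(stack, *cfg.background)
        out = measure_rois(rs, rois_from_labels(labels, meta))
        c = ratio_to_calcium(out["mean_ratio"].iloc[0]).concentration
        assert c == pytest.approx(true_calcium, rel=1e-3)

    def test_zero_photon_budget_gives_background_only(self):
        scene, _ = straight_dendrite_scene(3)
        cfg = dataclasses.replace(CohortConfig(seed=0), photon_budget=0.0)
        stack, labels, meta = render_scene(scene, cfg, seed=1, apply_psf=False, apply_noise=False)
        assert (stack.cfp == cfg.background[0]).all()
        b = estimate_background(stack)
        rs = compute_ratio_stack(stack, *b)
        out = measure_rois(rs, rois_from_labels(labels, meta))
        assert out["no_signal"].all()


class TestExportTruth:
    def test_row_counts(self):
        cfg = dataclasses.replace(CohortConfig(seed=13), n_control_animals=1, n_tau_animals=1,
                                  volumes_per_animal=1, rendered_dendrites_per_volume=2)
        scenes = sample_cohort(cfg)[:1]
        structures, dendrites = export_truth(scenes)
        n_spines = sum(len(v) for v in scenes[0].spines.values())
        assert len(dendrites) == 2
        assert len(structures) == 2 + n_spines

    def test_csv_round_trip(self, tmp_path):
        cfg = dataclasses.replace(CohortConfig(seed=13), n_control_animals=1, n_tau_animals=1,
                                  volumes_per_animal=1)
        structures, dendrites = export_truth(sample_cohort(cfg))
        for df, name in ((structures, "s.csv"), (dendrites, "d.csv")):
            df.to_csv(tmp_path / name, index=False)
            back = pd.read_csv(tmp_path / name)
            num = df.select_dtypes("number")
            pd.testing.assert_frame_equal(back[num.columns], num, check_dtype=False)

    def test_truth_ids_match_rendered_rois(self, small_cohort_config):
        scenes = sample_cohort(small_cohort_config)
        structures, _ = export_truth(scenes)
        _, labels, meta = render_scene(scenes[0], small_cohort_config, seed=2)
        scene_truth = structures[structures["scene_id"] == scenes[0].scene_id]
        assert set(meta["roi_id"]) == set(scene_truth["structure_id"])


class TestMeasurementTables:
    def test_scales_match_study_design(self):
        m, d = simulate_measurement_tables(CohortConfig(seed=8))
        dend = m[m["compartment"] == "dendrite"]
        spine = m[m["compartment"] == "spine"]
        assert len(dend) == 15 * 10 * 31      # ~4650 dendrites across 15 animals
        assert len(spine) == 15 * 77          # ~1155 spines
        assert d.groupby("animal_id").size().eq(8).all()

    def test_measured_ratios_track_truth(self):
        m, _ = simulate_measurement_tables(CohortConfig(seed=8))
        dend = m[m["compartment"] == "dendrite"]
        from ycquant.calibration import calcium_to_ratio

        r_true = np.array([calcium_to_ratio(c) for c in dend["true_calcium_nM"]])
        resid = dend["mean_ratio"].to_numpy() - r_true
        assert abs(resid.mean()) < 0.005
        assert resid.std() < 0.05
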