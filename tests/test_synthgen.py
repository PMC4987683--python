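"""Synthetic-cohort generator: determinism, latent recovery, geometry."""

import numpy as np
import pytest

from ebclock.kinetics import ImpulseParams, detect_onset, impulse_value
from ebclock.qpcrnorm import normalize_neg_ddct
from ebclock.synthgen import (
    CohortConfig,
    GeneSpec,
    NoiseModel,
    default_gene_panel,
    gen_cohort,
    gen_expression_panel,
    gen_impulse_series,
    gen_point_cloud_series,
    impulse_params_for_events,
    perturbation_preset,
)


class TestImpulseSeries:
    def test_zero_noise_is_exact_model_curve(self, canonical_params):
        times = np.arange(60.0, 120.0, 1.5)
        s = gen_impulse_series(canonical_params, times, NoiseModel("none"))
        np.testing.assert_allclose(s.counts, impulse_value(canonical_params, times))

    def test_gaussian_residual_sd_matches_scale(self, canonical_params):
        times = np.linspace(60.0, 120.0, 40)
        model = impulse_value(canonical_params, times)
        sds = []
        for seed in range(20):
            s = gen_impulse_series(canonical_params, times, NoiseModel("gaussian", 30.0), seed)
            sds.append(np.std(s.counts - model, ddof=1))
        assert np.mean(sds) == pytest.approx(30.0, rel=0.25)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ImpulseParams(100.0, -0.5, 0.3, 0.0, 10.0)

    def test_default_cohort_onsets_span_reported_window(self):
        # within-experiment onset distribution: crossings land roughly
        # between 70 and 95 h after seeding
        cohort = gen_cohort(CohortConfig(n_ebs=30, seed=7))
        onsets = [detect_onset(p) for p in cohort.truth["params"]]
        assert all(70.0 < o < 95.0 for o in onsets)


class TestEventCalibration:
    def test_params_hit_requested_onset_and_interval(self):
        from ebclock.kinetics import detect_peak

        p = impulse_params_for_events(83.3, 12.8, 3000.0, 0.5, 0.3)
        onset = detect_onset(p, 300.0)
        assert onset == pytest.approx(83.3, abs=1e-4)
        assert detect_peak(p) - onset == pytest.approx(12.8, abs=1e-4)

    def test_amplitude_below_threshold_rejected(self):
        with pytest.raises(ValueError):
            impulse_params_for_events(80.0, 12.0, 200.0, 0.5, 0.3)


class TestPointCloudGeometry:
    PARAMS = ImpulseParams(2000.0, 0.5, 0.3, 85.0, 100.0)

    def test_zero_signal_zero_gfp_points(self):
        p = ImpulseParams(0.0, 0.5, 0.3, 85.0, 100.0)
        frames = gen_point_cloud_series(100.0, [0, 0, 1], p, [50.0, 90.0], 0.0, rng=0)
        assert all(len(f) == 0 for f in frames)

    def test_full_amplitude_covers_whole_shell(self):
        p = ImpulseParams(3000.0, 5.0, 5.0, 0.0, 100.0)
        frames = gen_point_cloud_series(100.0, [0, 0, 1], p, [50.0], 0.0, rng=1)
        dirs = frames[0].points / np.linalg.norm(frames[0].points, axis=1, keepdims=True)
        angles = np.arccos(np.clip(dirs @ [0, 0, 1], -1, 1))
        assert angles.max() > 0.95 * np.pi  # angular extent approaches π

    def test_cap_centered_on_locus_rise_and_decline(self):
        # frames on either side of the peak with comparable N(t): both caps
        # recede toward / spread from the same original locus
        locus = np.array([1.0, 0, 0])
        p = self.PARAMS
        frames = gen_point_cloud_series(113.0, locus, p, [88.0, 104.0], 0.0, rng=2)
        for f in frames:
            centroid = f.points.mean(axis=0)
            centroid /= np.linalg.norm(centroid)
            assert np.arccos(np.clip(centroid @ locus, -1, 1)) < 0.2

    def test_cap_contiguity_no_point_outside_angular_radius(self):
        locus = np.array([0.0, 1.0, 0.0])
        p = self.PARAMS
        t = 90.0
        frames = gen_point_cloud_series(113.0, locus, p, [t], 0.0, rng=3)
        frac = impulse_value(p, t) / p.A
        alpha = np.arccos(1 - 2 * frac)
        dirs = frames[0].points / np.linalg.norm(frames[0].points, axis=1, keepdims=True)
        angles = np.arccos(np.clip(dirs @ locus, -1, 1))
        assert angles.max() <= alpha + 1e-6

    def test_clutter_strictly_outside_sphere(self):
        p = ImpulseParams(0.0, 0.5, 0.3, 85.0, 100.0)
        frames = gen_point_cloud_series(100.0, [0, 0, 1], p, [90.0], clutter_rate=40.0, rng=4)
        assert len(frames[0]) > 0
        assert np.linalg.norm(frames[0].points, axis=1).min() > 100.0

    def test_invalid_radius_rejected(self):
        with pytest.raises(ValueError):
            gen_point_cloud_series(0.0, [0, 0, 1], self.PARAMS, [90.0])


class TestExpressionPanel:
    def test_zero_noise_round_trip_recovers_linear_model(self):
        # DevA chosen so the control median of the generated level is 0:
        # the normalization's median shift then cancels exactly and the
        # recovered −ΔΔCT equals intercept + slope·DevA
        specs = [
            GeneSpec("hk1", housekeeping=True, noise_sd=0.0, ct_base=14.0),
            GeneSpec("hk2", housekeeping=True, noise_sd=0.0, ct_base=13.0),
            GeneSpec("g", intercept=-3.0, slope_devA=0.3, noise_sd=0.0),
        ]
        devA = np.array([0.0, 5.0, 10.0, 15.0, 20.0])  # median 10 → level median 0
        panel, truth = gen_expression_panel(devA, specs, rng=0)
        norm = normalize_neg_ddct(panel, ("hk1", "hk2"), "control")
        np.testing.assert_allclose(norm.neg_ddct.loc["g"], -3.0 + 0.3 * devA, atol=1e-10)
        np.testing.assert_allclose(norm.neg_ddct.loc["g"], truth.loc["g"], atol=1e-10)

    def test_noisy_round_trip_recovers_truth_record_exactly(self, rng):
        devA = rng.uniform(0, 25, size=20)
        panel, truth = gen_expression_panel(devA, default_gene_panel(), rng=rng)
        norm = normalize_neg_ddct(panel, ("Rock2", "Ywhaz"), "control")
        np.testing.assert_allclose(
            norm.neg_ddct.to_numpy(), truth.loc[norm.neg_ddct.index].to_numpy(), atol=1e-9
        )

    def test_wnt3_downregulated_under_chir(self, rng):
        devA = rng.uniform(5, 20, size=30)
        groups = ["control"] * 15 + ["chir_long"] * 15
        panel, truth = gen_expression_panel(devA, default_gene_panel(), groups, rng=rng)
        w = truth.loc["Wnt3"]
        ctrl = w.iloc[:15].median()
        chir = w.iloc[15:].median()
        assert chir < ctrl

    def test_twelve_cycle_range_is_4096_fold(self):
        from ebclock.qpcrnorm import fold_range

        specs = [
            GeneSpec("hk1", housekeeping=True, noise_sd=0.0),
            GeneSpec("hk2", housekeeping=True, noise_sd=0.0),
            GeneSpec("wide", intercept=0.0, slope_devA=1.0, noise_sd=0.0),
        ]
        devA = np.linspace(0.0, 12.0, 7)  # dialed to a 12-unit −ΔΔCT span
        panel, truth = gen_expression_panel(devA, specs, rng=0)
        assert fold_range(truth.loc["wide"]) == pytest.approx(4096.0)

    def test_duplicate_gene_names_rejected(self):
        specs = [GeneSpec("a"), GeneSpec("a")]
        with pytest.raises(ValueError, match="duplicate"):
            gen_expression_panel(np.array([1.0, 2.0]), specs)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            gen_expression_panel(np.array([]), [GeneSpec("a")])


class TestCohort:
    def test_same_seed_reproduces_identical_outputs(self):
        cfg = CohortConfig(n_ebs=6, seed=11, clutter_rate=10.0)
        a = gen_cohort(cfg, n_clouds=2)
        b = gen_cohort(cfg, n_clouds=2)
        for sa, sb in zip(a.series, b.series):
            np.testing.assert_array_equal(sa.counts, sb.counts)
        for eb in a.clouds:
            for fa, fb in zip(a.clouds[eb], b.clouds[eb]):
                np.testing.assert_array_equal(fa.points, fb.points)
        np.testing.assert_array_equal(
            a.panel.ct.to_numpy(), b.panel.ct.to_numpy()
        )
        np.testing.assert_array_equal(a.truth["onset_h"], b.truth["onset_h"])

    def test_pooled_panel_sized_cohort_has_78_columns(self):
        cohort = gen_cohort(CohortConfig(n_ebs=78, seed=3))
        assert cohort.panel.ct.shape[1] == 78

    def test_truth_onset_mean_matches_config_over_seeds(self):
        cfg_mean, cfg_sd, per_seed = 83.3, 3.7, 8
        means = []
        for seed in range(50):
            c = gen_cohort(CohortConfig(n_ebs=per_seed, seed=seed))
            means.append(c.truth["onset_h"].mean())
        grand = np.mean(means)
        sem = cfg_sd / np.sqrt(50 * per_seed)
        assert abs(grand - cfg_mean) < 3 * sem

    def test_onset_and_radius_generated_independently(self):
        c = gen_cohort(CohortConfig(n_ebs=120, seed=5))
        r = np.corrcoef(c.truth["onset_h"], c.truth["radius_um"])[0, 1]
        assert abs(r) < 0.25

    def test_amplitude_size_coupling_only_below_100um(self):
        c = gen_cohort(CohortConfig(n_ebs=150, seed=9, radius_bounds=(70.0, 176.0),
                                    radius_mean=100.0, radius_sd=25.0))
        radii, amps = c.truth["radius_um"], c.truth["amplitude"]
        small = radii < 95.0
        big = radii > 110.0
        r_small = np.corrcoef(radii[small], amps[small])[0, 1]
        r_big = np.corrcoef(radii[big], amps[big])[0, 1]
        assert r_small > 0.5 and abs(r_big) < 0.3

    def test_perturbation_presets_shift_kinetics(self):
        assert perturbation_preset("chir_long").onset_mean == 50.0
        assert perturbation_preset("bmp4").onset_mean == 50.0
        assert perturbation_preset("control").onset_mean == 70.0
        assert perturbation_preset("chir_short_early").onset_mean == 70.0

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(radius_bounds=(176.0, 81.0))
        with pytest.raises(ValueError):
            CohortConfig(t_start=100.0, t_end=60.0)
        with pytest.raises(ValueError):
            CohortConfig(perturbation="mystery")
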