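"""Generator tests: preset calibration, rendering, and score panels."""

import numpy as np
import pytest

from uromorph.synthetic import (
    PRESETS,
    AreaMixture,
    CalibrationError,
    GeneratorConfig,
    GradePreset,
    PlacementError,
    RaterNoiseModel,
    calibrate_preset,
    render_field,
    simulate_score_panel,
    tumor_median_for_mean,
)


class TestCalibration:
    @pytest.mark.parametrize("name", ["group1", "group3", "group5"])
    def test_population_statistics_match_targets(self, name):
        """Calibrated mixtures hit the preset mean/p10/p90 within 2%."""
        preset = PRESETS[name]
        cfg = calibrate_preset(preset)
        mix = cfg.area_mixture()
        assert mix.mean() == pytest.approx(preset.target_mean_area_um2, rel=0.02)
        assert mix.quantile(0.10) == pytest.approx(preset.target_p10_area_um2, rel=0.02)
        assert mix.quantile(0.90) == pytest.approx(preset.target_p90_area_um2, rel=0.02)

    def test_group1_has_near_zero_inflammatory_fraction(self):
        cfg = calibrate_preset(PRESETS["group1"])
        assert cfg.inflammatory_fraction < 0.06

    def test_group5_has_substantial_inflammatory_fraction(self):
        cfg = calibrate_preset(PRESETS["group5"])
        assert cfg.inflammatory_fraction > 0.10

    def test_group5_monte_carlo_quantiles(self):
        """Brute-force sampling (n = 10^6) of the calibrated group-5 mixture
        reproduces the targets within 2%."""
        preset = PRESETS["group5"]
        mix = calibrate_preset(preset).area_mixture()
        draws = mix.sample(np.random.default_rng(0), 1_000_000)
        assert draws.mean() == pytest.approx(preset.target_mean_area_um2, rel=0.02)
        assert np.percentile(draws, 10) == pytest.approx(
            preset.target_p10_area_um2, rel=0.02
        )
        assert np.percentile(draws, 90) == pytest.approx(
            preset.target_p90_area_um2, rel=0.02
        )

    def test_degenerate_mean_only_calibration(self):
        """With no admixture the tumor median follows from the log-normal
        mean formula directly."""
        med = tumor_median_for_mean(570.0, np.exp(0.4))
        assert med == pytest.approx(570.0 / np.exp(0.4**2 / 2.0))
        mix = AreaMixture((1.0,), (np.log(med),), (0.4,))
        assert mix.mean() == pytest.approx(570.0)

    def test_infeasible_targets_raise_named_error(self):
        bad = GradePreset("custom", 5.0, 2.0, 3000.0, hematoxylin_od_mean=0.6)
        with pytest.raises(CalibrationError, match="mean|p10|p90"):
            calibrate_preset(bad)

    def test_inverted_targets_rejected(self):
        with pytest.raises(ValueError, match="p10 < mean < p90"):
            GradePreset("broken", 100.0, 200.0, 300.0, hematoxylin_od_mean=0.6)


class TestRendering:
    def test_reproducible_bit_for_bit(self):
        cfg = GeneratorConfig(
            image_size_px=(400, 400), microns_per_pixel=0.5, n_tumor_nuclei=25,
            tumor_area_dist=(200.0, np.exp(0.3)),
        )
        rgb1, gt1 = render_field(cfg, seed=5)
        rgb2, gt2 = render_field(cfg, seed=5)
        assert np.array_equal(rgb1, rgb2)
        assert np.array_equal(gt1.label_mask, gt2.label_mask)
        assert gt1.records.equals(gt2.records)

    def test_different_seeds_differ(self):
        cfg = GeneratorConfig(
            image_size_px=(400, 400), microns_per_pixel=0.5, n_tumor_nuclei=25,
            tumor_area_dist=(200.0, np.exp(0.3)),
        )
        rgb1, _ = render_field(cfg, seed=5)
        rgb2, _ = render_field(cfg, seed=6)
        assert not np.array_equal(rgb1, rgb2)

    def test_zero_inflammatory_fraction_all_tumor(self):
        cfg = GeneratorConfig(
            image_size_px=(400, 400), microns_per_pixel=0.5, n_tumor_nuclei=20,
            tumor_area_dist=(200.0, np.exp(0.3)), inflammatory_fraction=0.0,
        )
        _, gt = render_field(cfg, seed=1)
        assert (gt.records["class"] == "tumor").all()

    def test_empty_field(self):
        cfg = GeneratorConfig(
            image_size_px=(300, 300), microns_per_pixel=0.5, n_tumor_nuclei=0,
        )
        rgb, gt = render_field(cfg, seed=1)
        assert gt.label_mask.max() == 0
        assert len(gt.records) == 0
        assert rgb.shape == (300, 300, 3)

    def test_mask_labels_consecutive_and_match_records(self, group5_field):
        _, _, gt = group5_field
        labels = np.unique(gt.label_mask)
        labels = labels[labels > 0]
        assert np.array_equal(labels, np.arange(1, len(gt.records) + 1))
        assert sorted(gt.records["label"]) == list(labels)

    def test_unplaceable_request_raises(self):
        cfg = GeneratorConfig(
            image_size_px=(120, 120), microns_per_pixel=0.5, n_tumor_nuclei=200,
            tumor_area_dist=(400.0, np.exp(0.3)),
        )
        with pytest.raises(PlacementError, match="place"):
            render_field(cfg, seed=1)

    def test_hyperchromasia_monotone_in_optical_density(self):
        """Lower hematoxylin OD renders paler nuclei (higher intensity on
        ground-truth pixels)."""
        means = []
        for od in (0.4, 0.6, 0.9):
            cfg = GeneratorConfig(
                image_size_px=(400, 400), microns_per_pixel=0.5, n_tumor_nuclei=25,
                tumor_area_dist=(200.0, np.exp(0.3)), hematoxylin_od=(od, 0.0),
                noise_sd=0.0, texture_od_sd=0.0,
            )
            rgb, gt = render_field(cfg, seed=3)
            lum = rgb.astype(float).mean(axis=2)
            means.append(lum[gt.label_mask > 0].mean())
        assert means[0] > means[1] > means[2]

    @pytest.mark.parametrize("name", ["group1", "group3", "group5"])
    def test_pooled_area_statistics_over_many_fields(self, name):
        """Pooled true areas over 50 rendered fields stay within 5% of the
        calibration targets (mean, p10, p90) for every preset."""
        preset = PRESETS[name]
        cfg = calibrate_preset(preset, n_nuclei=60)
        pooled = []
        for seed in range(1, 51):
            _, gt = render_field(cfg, seed=seed)
            pooled.append(gt.records["true_area_um2"].to_numpy())
        pooled = np.concatenate(pooled)
        assert pooled.mean() == pytest.approx(preset.target_mean_area_um2, rel=0.05)
        assert np.percentile(pooled, 10) == pytest.approx(
            preset.target_p10_area_um2, rel=0.05
        )
        assert np.percentile(pooled, 90) == pytest.approx(
            preset.target_p90_area_um2, rel=0.05
        )


class TestScorePanels:
    def test_noiseless_panel_equals_latent(self):
        latent = [1, 2, 3, 4, 5]
        scores = simulate_score_panel(latent, RaterNoiseModel.concordant(), seed=0)
        wide = scores.pivot(index="image_id", columns="rater_id", values="score")
        for col in wide.columns:
            assert wide[col].tolist() == latent

    def test_constant_bias_shifts_unclamped_scores(self):
        model = RaterNoiseModel(
            general_biases=(1.0,) * 5,
            general_offset_probs={0: 1.0},
            expert_offset_probs={0: 1.0},
        )
        latent = [1, 2, 3, 4]
        scores = simulate_score_panel(latent, model, seed=0)
        general = scores[scores["role"] == "general"]
        wide = general.pivot(index="image_id", columns="rater_id", values="score")
        for col in wide.columns:
            assert wide[col].tolist() == [2, 3, 4, 5]

    def test_clamping_keeps_scores_in_range(self):
        model = RaterNoiseModel(
            general_biases=(3.0,) * 5,
            general_offset_probs={0: 0.5, 2: 0.5},
            expert_offset_probs={0: 1.0},
        )
        scores = simulate_score_panel([4, 5, 5], model, seed=1)
        assert scores["score"].between(1, 5).all()

    def test_offset_distribution_agreement_expectation(self):
        """With offsets P(0)=0.8, P(+1)=0.15, P(+2)=0.05 against a noiseless
        expert, the closed-form expected agreement (|delta| < 2) is 95%."""
        model = RaterNoiseModel(
            general_biases=(0.0,),
            general_offset_probs={0: 0.80, 1: 0.15, 2: 0.05},
            expert_offset_probs={0: 1.0},
            n_experts=1,
        )
        latent = [3] * 2000  # away from the clamp boundaries
        scores = simulate_score_panel(latent, model, seed=42)
        rater = scores[scores["rater_id"] == "p1"]["score"].to_numpy()
        expert = scores[scores["rater_id"] == "e1"]["score"].to_numpy()
        rate = 100.0 * (np.abs(rater - expert) < 2).mean()
        assert rate == pytest.approx(95.0, abs=2.0)

    def test_invalid_latent_grades_rejected(self):
        with pytest.raises(ValueError, match="latent"):
            simulate_score_panel([0, 3], seed=0)
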