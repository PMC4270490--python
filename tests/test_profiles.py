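"""Ratio profiles: ROI geometry, normalization closed forms, cohort stats."""

import numpy as np
import pytest

from myonuc import profiles as pr
from myonuc import synthetic as sy
from myonuc.io import MultiChannelImage
from myonuc.profiles import GRID, LocalizationProfile, RawProfile


def make_profile(values):
    values = np.asarray(values, dtype=float)
    return LocalizationProfile(
        positions=GRID.copy(),
        ratio=values,
        peak=float(values.max()),
        auc=float(np.trapezoid(values, GRID)),
    )


def raw_from_curve(positions_px, values):
    positions_px = np.asarray(positions_px, dtype=float)
    return RawProfile(
        positions_px=positions_px,
        positions_um=positions_px * 0.2,
        ratio=np.asarray(values, dtype=float),
        n_pixels_per_bin=np.full(len(positions_px), 11),
    )


class TestSelectROI:
    def test_roi_length_matches_end_to_outline_distance(self, control_scene):
        fiber, nuclei, *_ = control_scene
        from myonuc.positioning import end_to_nucleus_distance

        d_norm, nid = end_to_nucleus_distance(fiber, nuclei, "dorsal")
        roi = pr.select_profile_roi(fiber, nuclei, "dorsal", width_um=2.0)
        assert roi.nucleus_id == nid
        expected_px = d_norm * fiber.length_um / fiber.um_per_pixel
        assert roi.length_px == pytest.approx(expected_px, abs=1.0)

    def test_identical_pixel_set_across_channels(self, control_scene):
        fiber, nuclei, image, _ = control_scene
        roi = pr.select_profile_roi(fiber, nuclei, "dorsal", width_um=2.0)
        pts_a = roi.sample_points()
        pts_b = roi.sample_points()
        assert np.array_equal(pts_a, pts_b)
        same = MultiChannelImage(
            {"target": image["reference"], "reference": image["reference"]},
            image.um_per_pixel,
        )
        flat = pr.compute_ratio_profile(same, roi)
        assert np.allclose(flat.ratio, 100.0)

    def test_roi_always_inside_mask(self, presets):
        for seed in range(50):
            fiber = sy.make_fiber(40.0, 6.0, 0.2, 0.0, seed=seed)
            nuclei = sy.place_nuclei(fiber, presets["control"], seed=seed)
            roi = pr.select_profile_roi(fiber, nuclei, "dorsal", width_um=2.0)
            pts = roi.sample_points().reshape(-1, 2)
            xi = np.rint(pts[:, 0]).astype(int)
            yi = np.rint(pts[:, 1]).astype(int)
            assert fiber.mask[yi, xi].all()


class TestRatioProfile:
    def test_identical_channels_give_flat_100(self, control_scene):
        fiber, nuclei, image, _ = control_scene
        roi = pr.select_profile_roi(fiber, nuclei, "dorsal")
        same = MultiChannelImage(
            {"target": image["reference"], "reference": image["reference"]},
            image.um_per_pixel,
        )
        assert np.allclose(pr.compute_ratio_profile(same, roi).ratio, 100.0)

    def test_doubled_target_gives_flat_200(self, control_scene):
        fiber, nuclei, image, _ = control_scene
        roi = pr.select_profile_roi(fiber, nuclei, "dorsal")
        doubled = MultiChannelImage(
            {"target": 2.0 * image["reference"], "reference": image["reference"]},
            image.um_per_pixel,
        )
        assert np.allclose(pr.compute_ratio_profile(doubled, roi).ratio, 200.0)

    def test_noiseless_profile_matches_analytic_truth(self, noiseless):
        preset = noiseless("syd_like")
        fiber = sy.make_fiber(40.0, 6.0, 0.05, 0.0, seed=11)
        nuclei = sy.place_nuclei(fiber, preset, seed=11)
        image, truth = sy.render_channels(fiber, nuclei, preset, seed=11)
        roi = pr.select_profile_roi(fiber, nuclei, "dorsal", width_um=2.0)
        prof = pr.normalize_profile(pr.compute_ratio_profile(image, roi))
        err = np.abs(prof.ratio - truth.target_profile_true).max()
        assert err < 0.02 * prof.peak

    def test_zero_reference_position_rejected(self, control_scene):
        fiber, nuclei, image, _ = control_scene
        roi = pr.select_profile_roi(fiber, nuclei, "dorsal")
        dark = MultiChannelImage(
            {"target": image["target"], "reference": np.zeros_like(image["reference"])},
            image.um_per_pixel,
        )
        with pytest.raises(ValueError, match="reference"):
            pr.compute_ratio_profile(dark, roi)

    def test_joint_channel_scaling_leaves_ratio_unchanged(self, control_scene):
        fiber, nuclei, image, _ = control_scene
        roi = pr.select_profile_roi(fiber, nuclei, "dorsal")
        base = pr.compute_ratio_profile(image, roi)
        for k in (0.5, 7.3):
            scaled = MultiChannelImage(
                {"target": k * image["target"], "reference": k * image["reference"]},
                image.um_per_pixel,
            )
            assert np.allclose(pr.compute_ratio_profile(scaled, roi).ratio, base.ratio)


class TestNormalizeProfile:
    def test_constant_profile_closed_form(self):
        raw = raw_from_curve(np.arange(21), np.full(21, 7.0))
        prof = pr.normalize_profile(raw)
        assert prof.peak == pytest.approx(7.0)
        assert prof.auc == pytest.approx(700.0)

    def test_linear_ramp_closed_form(self):
        pos = np.arange(21)
        raw = raw_from_curve(pos, 5.0 * pos / pos[-1])
        prof = pr.normalize_profile(raw)
        assert prof.auc == pytest.approx(250.0)  # 50 * c, trapezoid exact

    def test_random_smooth_curve_matches_oversampled_integral(self, rng):
        # random smooth curve: low-order Fourier series, strictly positive
        coef = rng.normal(0, 1, 4)

        def f(x_pct):
            x = x_pct / 100.0 * np.pi
            return 6.0 + sum(c * np.sin((k + 1) * x) for k, c in enumerate(coef))

        pos = np.arange(41.0)
        prof = pr.normalize_profile(raw_from_curve(pos, f(pos / pos[-1] * 100.0)))
        fine = np.linspace(0.0, 100.0, 40001)
        oracle = np.trapezoid(f(fine), fine)
        assert prof.auc == pytest.approx(oracle, rel=0.01)

    def test_too_short_span_rejected(self):
        with pytest.raises(ValueError, match="short"):
            pr.normalize_profile(raw_from_curve([0, 1, 2], [1.0, 1.0, 1.0]))

    def test_peak_auc_consistency(self, rng):
        for _ in range(20):
            vals = rng.random(101) * 50.0
            prof = make_profile(vals)
            assert prof.peak >= prof.auc / 100.0 >= vals.min() - 1e-9


class TestFixedBox:
    def test_constant_ratio_auc_is_length_times_c(self, noiseless):
        # mid-fiber nuclei leave ample room for a fixed box toward the end
        preset = noiseless("syd_like")
        fiber = sy.make_fiber(40.0, 6.0, 0.2, 0.0, seed=4)
        nuclei = sy.place_nuclei(fiber, preset, seed=4)
        image, _ = sy.render_channels(fiber, nuclei, preset, seed=4)
        same = MultiChannelImage(
            {"target": 3.0 * image["reference"], "reference": image["reference"]},
            image.um_per_pixel,
        )
        raw = pr.fixed_box_profile(same, fiber, nuclei, "dorsal", box_dims_um=(2.0, 2.5))
        assert np.allclose(raw.ratio, 300.0)
        auc = np.trapezoid(raw.ratio, raw.positions_um)
        assert auc == pytest.approx(2.5 * 300.0, rel=1e-6)

    def test_nucleus_enriched_target_peaks_at_nucleus_edge(self, noiseless):
        preset = noiseless("syd_like")
        fiber = sy.make_fiber(40.0, 6.0, 0.05, 0.0, seed=3)
        nuclei = sy.place_nuclei(fiber, preset, seed=3)
        image, _ = sy.render_channels(fiber, nuclei, preset, seed=3)
        raw = pr.fixed_box_profile(image, fiber, nuclei, "dorsal", box_dims_um=(2.0, 4.0))
        # positions measured from the nucleus edge: peak within 1 µm of it
        assert raw.positions_um[np.argmax(raw.ratio)] <= 1.0

    def test_box_exceeding_fiber_rejected(self, control_scene):
        fiber, nuclei, image, _ = control_scene
        with pytest.raises(ValueError, match="exceeds"):
            pr.fixed_box_profile(image, fiber, nuclei, "dorsal", box_dims_um=(2.0, 500.0))


class TestDistalRatio:
    def test_identical_channels_give_100(self, control_scene):
        fiber, _, image, _ = control_scene
        same = MultiChannelImage(
            {"target": image["reference"], "reference": image["reference"]},
            image.um_per_pixel,
        )
        assert pr.distal_region_ratio(same, fiber) == pytest.approx(100.0)

    def test_zero_target_gives_zero(self, control_scene):
        fiber, _, image, _ = control_scene
        dark = MultiChannelImage(
            {"target": np.zeros_like(image["target"]), "reference": image["reference"]},
            image.um_per_pixel,
        )
        assert pr.distal_region_ratio(dark, fiber) == 0.0

    def test_end_enriched_target_has_elevated_distal_ratio(self, control_scene):
        fiber, _, image, _ = control_scene
        distal = pr.distal_region_ratio(image, fiber, end_label="dorsal")
        inside = fiber.mask
        whole = image["target"][inside].mean() / image["reference"][inside].mean() * 100.0
        assert distal > whole

    def test_fiber_shorter_than_depth_rejected(self, control_scene):
        fiber, _, image, _ = control_scene
        with pytest.raises(ValueError, match="depth"):
            pr.distal_region_ratio(image, fiber, depth_um=100.0)


class TestCohorts:
    def test_identical_profiles_have_zero_sd(self):
        p = make_profile(np.full(101, 4.0))
        cohort = pr.average_profiles([p, p])
        assert np.allclose(cohort.mean, 4.0)
        assert np.allclose(cohort.sd, 0.0)

    def test_two_profile_closed_form(self):
        c = 3.0
        cohort = pr.average_profiles([make_profile(np.full(101, c)),
                                      make_profile(np.full(101, 3 * c))])
        assert np.allclose(cohort.mean, 2 * c)
        assert np.allclose(cohort.sd, np.sqrt(2.0) * c)
        assert cohort.auc_mean == pytest.approx(200.0 * c)

    def test_cohort_mean_tracks_truth_curve(self, presets):
        preset = presets["control"]
        profs = []
        for seed in range(60):
            fiber = sy.make_fiber(40.0, 6.0, 0.05, 0.0, seed=seed)
            nuclei = sy.place_nuclei(fiber, preset, seed=seed)
            image, truth = sy.render_channels(fiber, nuclei, preset, seed=seed)
            roi = pr.select_profile_roi(fiber, nuclei, "dorsal", width_um=2.0)
            profs.append(pr.normalize_profile(pr.compute_ratio_profile(image, roi)))
        cohort = pr.average_profiles(profs)
        se = cohort.sd / np.sqrt(cohort.n)
        truth_curve = sy.truth_ratio_curve(preset)
        # allow the small systematic resampling bias on top of 2 SE
        tol = 2.0 * se + 0.02 * truth_curve.max()
        assert np.all(np.abs(cohort.mean - truth_curve) <= tol)

    def test_mismatched_grids_rejected(self):
        good = make_profile(np.full(101, 1.0))
        bad = LocalizationProfile(
            positions=np.linspace(0, 100, 51),
            ratio=np.full(51, 1.0),
            peak=1.0,
            auc=100.0,
        )
        with pytest.raises(ValueError, match="grid"):
            pr.average_profiles([good, bad])

    def test_single_profile_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            pr.average_profiles([make_profile(np.full(101, 1.0))])


class TestReferenceControlCheck:
    def _ref_cohort(self, level, n, rng):
        return [
            make_profile(np.full(101, level) + rng.normal(0, 3, 101))
            for _ in range(n)
        ]

    def test_equal_reference_levels_not_flagged_usually(self, rng):
        flags = 0
        for _ in range(20):
            cohorts = {
                "control": self._ref_cohort(100.0, 12, rng),
                "mutant": self._ref_cohort(100.0, 12, rng),
            }
            table = pr.reference_control_check(cohorts)
            flags += int(table.flagged.any())
        assert flags <= 3  # type-I errors only

    def test_doubled_reference_level_flagged(self, rng):
        cohorts = {
            "control": self._ref_cohort(100.0, 12, rng),
            "mutant": self._ref_cohort(200.0, 12, rng),
        }
        table = pr.reference_control_check(cohorts)
        assert bool(table.loc[table.genotype == "mutant", "flagged"].iloc[0])

    def test_single_genotype_rejected(self, rng):
        with pytest.raises(ValueError, match="2 genotypes"):
            pr.reference_control_check({"control": self._ref_cohort(100.0, 5, rng)})
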