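"""Positioning metrics against closed forms and brute-force oracles."""

import math
import warnings

import numpy as np
import pytest

from myonuc import positioning as po
from myonuc import synthetic as sy
from myonuc.geometry import Nucleus, NucleusSet, ellipse_polygon, fiber_from_mask

UPP = 0.2


def nuclei_at_fracs(fiber, fracs, radius_um=1.0, vfracs=None):
    """Place circular nuclei at given fractional axial positions."""
    axis = fiber.axis_unit_vector
    perp = np.array([-axis[1], axis[0]])
    pts = fiber.mask_points()
    center = pts.mean(axis=0)
    u = (pts - center) @ axis
    u0, u1 = u.min(), u.max()
    r_px = radius_um / fiber.um_per_pixel
    nuclei = []
    vfracs = vfracs if vfracs is not None else [0.0] * len(fracs)
    for i, (frac, vf) in enumerate(zip(fracs, vfracs)):
        cu = u0 + frac * (u1 - u0)
        c = center + cu * axis + vf * perp
        nuclei.append(
            Nucleus(
                id=i + 1,
                centroid_px=c,
                outline=ellipse_polygon(c, r_px, r_px),
                area_px=math.pi * r_px**2,
            )
        )
    return NucleusSet(nuclei)


def brute_end_distance(fiber, nuclei, end_label):
    """Oracle: exhaustive pairwise distance over contour x outline points."""
    contour = fiber.end_contours[end_label]
    best = math.inf
    for nu in nuclei:
        for cx, cy in contour:
            for ox, oy in nu.outline:
                best = min(best, math.dist((cx, cy), (ox, oy)))
    return best * fiber.um_per_pixel / fiber.length_um


def brute_nearest_neighbor(fiber, nuclei):
    """Oracle: O(n^2) centroid pair loop."""
    cents = nuclei.centroids
    out = []
    for i in range(len(cents)):
        best = math.inf
        for j in range(len(cents)):
            if i != j:
                best = min(best, math.dist(cents[i], cents[j]))
        out.append(best * fiber.um_per_pixel / fiber.length_um)
    return np.array(out)


def brute_longest_gap(fiber, nuclei):
    """Oracle: sort-and-merge the projected coverage intervals."""
    u = fiber.axial_coordinate(fiber.mask_points())
    lo, hi = u.min() - 0.5, u.max() + 0.5
    ivals = sorted(
        (max(fiber.axial_coordinate(nu.outline).min(), lo),
         min(fiber.axial_coordinate(nu.outline).max(), hi))
        for nu in nuclei
    )
    gaps, cursor = [], lo
    for a, b in ivals:
        if a > cursor:
            gaps.append(a - cursor)
        cursor = max(cursor, b)
    gaps.append(max(hi - cursor, 0.0))
    return max(gaps) * fiber.um_per_pixel / fiber.length_um


class TestEndToNucleusDistance:
    def test_centered_circle_closed_form(self, straight_fiber):
        r = 1.2
        nuclei = nuclei_at_fracs(straight_fiber, [0.5], radius_um=r)
        d, nid = po.end_to_nucleus_distance(straight_fiber, nuclei, "dorsal")
        L = straight_fiber.length_um
        assert nid == 1
        assert d == pytest.approx((0.5 * L - r) / L, abs=0.004)

    def test_touching_outline_gives_zero(self, straight_fiber):
        contour_pt = straight_fiber.end_contours["dorsal"][0]
        outline = ellipse_polygon(contour_pt + np.array([3.0, 0.0]), 3.0, 3.0)
        nuclei = NucleusSet(
            [Nucleus(id=1, centroid_px=contour_pt + 3.0, outline=outline, area_px=28.0)]
        )
        d, _ = po.end_to_nucleus_distance(straight_fiber, nuclei, "dorsal")
        assert d == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_on_random_placements(self, straight_fiber, presets):
        for seed in range(25):
            for name in ("control", "syd_like"):
                nuclei = sy.place_nuclei(straight_fiber, presets[name], seed=seed)
                for end in ("dorsal", "ventral"):
                    d, _ = po.end_to_nucleus_distance(straight_fiber, nuclei, end)
                    assert d == pytest.approx(
                        brute_end_distance(straight_fiber, nuclei, end), abs=1e-9
                    )

    def test_empty_nucleus_set_rejected(self, straight_fiber):
        with pytest.raises(ValueError, match="at least one"):
            po.end_to_nucleus_distance(straight_fiber, NucleusSet([]), "dorsal")


class TestNearestNeighbor:
    def test_evenly_spaced_closed_form(self, straight_fiber):
        fracs = np.linspace(0.1, 0.9, 5)
        nuclei = nuclei_at_fracs(straight_fiber, fracs)
        nn = po.nearest_neighbor_distances(straight_fiber, nuclei)
        u0, u1 = straight_fiber.axial_range()
        span_um = (u1 - u0) * straight_fiber.um_per_pixel
        expected = (0.8 / 4) * span_um / straight_fiber.length_um
        assert np.allclose(nn, expected, atol=1e-9)

    def test_coincident_centroids_give_zero(self, straight_fiber):
        nuclei = nuclei_at_fracs(straight_fiber, [0.5, 0.5], radius_um=0.5)
        nn = po.nearest_neighbor_distances(straight_fiber, nuclei)
        assert np.all(nn == 0.0)

    def test_matches_quadratic_oracle(self, straight_fiber, presets):
        for seed in range(25):
            nuclei = sy.place_nuclei(straight_fiber, presets["control"], seed=seed)
            nn = po.nearest_neighbor_distances(straight_fiber, nuclei)
            assert np.allclose(nn, brute_nearest_neighbor(straight_fiber, nuclei), atol=1e-12)

    def test_single_nucleus_is_undefined_not_zero(self, straight_fiber):
        nuclei = nuclei_at_fracs(straight_fiber, [0.5])
        with pytest.raises(ValueError, match="undefined"):
            po.nearest_neighbor_distances(straight_fiber, nuclei)


class TestLongestGap:
    def test_single_central_nucleus(self, straight_fiber):
        # axial extent [0.4 L, 0.6 L] -> leading/trailing gaps of 0.4 each
        u0, u1 = straight_fiber.axial_range()
        span_px = u1 - u0 + 1.0
        half_extent_um = 0.1 * span_px * UPP
        nuclei = nuclei_at_fracs(straight_fiber, [0.5], radius_um=half_extent_um)
        assert po.longest_gap(straight_fiber, nuclei) == pytest.approx(0.4, abs=0.01)

    def test_tiling_nuclei_leave_no_gap(self, straight_fiber):
        fracs = np.linspace(0.02, 0.98, 25)
        nuclei = nuclei_at_fracs(straight_fiber, fracs, radius_um=1.1)
        assert po.longest_gap(straight_fiber, nuclei) == pytest.approx(0.0, abs=0.01)

    def test_matches_interval_sweep_oracle(self, straight_fiber, presets):
        for seed in range(25):
            for name in ("control", "syd_like"):
                nuclei = sy.place_nuclei(straight_fiber, presets[name], seed=seed)
                assert po.longest_gap(straight_fiber, nuclei) == pytest.approx(
                    brute_longest_gap(straight_fiber, nuclei), abs=1e-12
                )


class TestCountsAndLength:
    def test_count_matches_generator(self, straight_fiber, control_preset):
        nuclei = sy.place_nuclei(straight_fiber, control_preset, seed=4)
        assert po.count_nuclei(nuclei) == control_preset.nucleus_placement["n_nuclei"]
        assert po.count_nuclei(NucleusSet([])) == 0

    def test_axis_aligned_length_exact(self, straight_fiber):
        assert po.muscle_length(straight_fiber) == pytest.approx(40.0, abs=1e-9)

    def test_rotated_length_within_tolerance(self):
        f = sy.make_fiber(40.0, 6.0, UPP, 33.0, seed=1)
        assert po.muscle_length(f) == pytest.approx(40.0, abs=0.3)

    def test_square_mask_warns(self):
        square = np.ones((20, 20), dtype=bool)
        with pytest.warns(UserWarning, match="elongated|width"):
            f = fiber_from_mask(square, UPP)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                po.muscle_length(f)


class TestInvariances:
    def test_pixel_size_rescaling_leaves_normalized_outputs_unchanged(
        self, straight_fiber, control_preset
    ):
        import dataclasses

        nuclei = sy.place_nuclei(straight_fiber, control_preset, seed=6)
        rescaled = dataclasses.replace(
            straight_fiber,
            um_per_pixel=UPP * 3.0,
            length_um=straight_fiber.length_um * 3.0,
        )
        for end in ("dorsal", "ventral"):
            d1, _ = po.end_to_nucleus_distance(straight_fiber, nuclei, end)
            d2, _ = po.end_to_nucleus_distance(rescaled, nuclei, end)
            assert d1 == pytest.approx(d2, rel=1e-9)
        assert np.allclose(
            po.nearest_neighbor_distances(straight_fiber, nuclei),
            po.nearest_neighbor_distances(rescaled, nuclei),
        )
        assert po.longest_gap(straight_fiber, nuclei) == pytest.approx(
            po.longest_gap(rescaled, nuclei), rel=1e-9
        )

    def test_rotation_leaves_normalized_outputs_within_two_percent(self, straight_fiber):
        fracs = [0.25, 0.4, 0.5, 0.68, 0.8]
        vfracs = [2.0, -3.0, 0.0, 3.0, -2.0]
        rotated = sy.make_fiber(40.0, 6.0, UPP, 30.0, seed=1)
        n0 = nuclei_at_fracs(straight_fiber, fracs, vfracs=vfracs)
        n1 = nuclei_at_fracs(rotated, fracs, vfracs=vfracs)
        for end in ("dorsal", "ventral"):
            d0, _ = po.end_to_nucleus_distance(straight_fiber, n0, end)
            d1, _ = po.end_to_nucleus_distance(rotated, n1, end)
            assert d1 == pytest.approx(d0, abs=0.02 * d0)
        assert po.longest_gap(rotated, n1) == pytest.approx(
            po.longest_gap(straight_fiber, n0), rel=0.02
        )
        assert np.allclose(
            po.nearest_neighbor_distances(rotated, n1),
            po.nearest_neighbor_distances(straight_fiber, n0),
            rtol=0.02,
        )


def test_position_report_tidy_table(straight_fiber, control_preset):
    nuclei = sy.place_nuclei(straight_fiber, control_preset, seed=2)
    report = po.position_report(straight_fiber, nuclei)
    df = report.to_frame("f1")
    assert set(df.columns) == {"fiber_id", "metric", "value", "normalized_by"}
    normalized = df[df.normalized_by == "muscle_length"].value
    assert ((normalized >= 0) & (normalized <= 1)).all()
    assert (df.metric == "nearest_neighbor").sum() == len(nuclei)


def test_nuclei_coordinate_csv_round_trip(tmp_path, straight_fiber):
    import pandas as pd

    from myonuc.positioning import nuclei_from_csv

    rows = [
        {"fiber_id": "f1", "nucleus_id": 1, "x_px": 30.0, "y_px": 17.0},
        {"fiber_id": "f1", "nucleus_id": 2, "x_px": 170.0, "y_px": 18.0},
    ]
    path = tmp_path / "coords.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    sets = nuclei_from_csv(path, default_radius_px=5.0)
    nn = po.nearest_neighbor_distances(straight_fiber, sets["f1"])
    expected = math.dist((30, 17), (170, 18)) * UPP / straight_fiber.length_um
    assert np.allclose(nn, expected)
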