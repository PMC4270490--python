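"""Myonuclear positioning statistics, normalized to muscle length.

The distances quantified here describe how well myonuclei are distributed
along an elongated muscle fiber: the shortest distance from either muscle
end to the nearest nucleus (the readout of cortical-pulling defects), the
distance from each nucleus to its nearest neighbour (clumping), the longest
stretch of muscle devoid of nuclei, the nucleus count, and the fiber length
itself.  All distances are divided by muscle length so fibers of different
sizes are comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .geometry import FiberGeometry, NucleusSet

__all__ = [
    "PositionReport",
    "end_to_nucleus_distance",
    "nearest_neighbor_distances",
    "longest_gap",
    "count_nuclei",
    "muscle_length",
    "position_report",
    "nuclei_from_csv",
]


def end_to_nucleus_distance(
    fiber: FiberGeometry, nuclei: NucleusSet, end_label: str
) -> tuple[float, int]:
    """Shortest end-to-nearest-nucleus distance, normalized to muscle length.

    The distance is boundary-to-boundary: the minimum Euclidean distance
    between the end contour and any nucleus outline, in µm, divided by
    ``length_um``.  Also returns the id of the nearest nucleus.
    """
    if len(nuclei) == 0:
        raise ValueError("end-to-nucleus distance needs at least one nucleus")
    contour = fiber.end_contours[end_label]
    best_d, best_id = np.inf, -1
    for nu in nuclei:
        d = cdist(contour, nu.outline).min()
        if d < best_d:
            best_d, best_id = d, nu.id
    return float(best_d * fiber.um_per_pixel / fiber.length_um), best_id


def nearest_neighbor_distances(fiber: FiberGeometry, nuclei: NucleusSet) -> np.ndarray:
    """Per-nucleus centroid-to-nearest-centroid distance / muscle length."""
    if len(nuclei) < 2:
        raise ValueError(
            "nearest-neighbor distance is undefined (not zero) for fewer than "
            "2 nuclei"
        )
    c = nuclei.centroids
    d = cdist(c, c)
    np.fill_diagonal(d, np.inf)
    return d.min(axis=1) * fiber.um_per_pixel / fiber.length_um


def longest_gap(fiber: FiberGeometry, nuclei: NucleusSet) -> float:
    """Longest nucleus-free axial stretch, normalized to muscle length.

    Nucleus outlines are projected on the long axis as covered intervals;
    the fiber ends bound the outermost gaps, so a nucleus-free muscle end
    counts as a gap.
    """
    if len(nuclei) == 0:
        raise ValueError("longest gap needs at least one nucleus")
    u0, u1 = fiber.axial_range()
    lo, hi = u0 - 0.5, u1 + 0.5  # full axial footprint of the mask
    intervals = []
    for nu in nuclei:
        u = fiber.axial_coordinate(nu.outline)
        intervals.append((max(float(u.min()), lo), min(float(u.max()), hi)))
    intervals.sort()
    merged = [list(intervals[0])]
    for a, b in intervals[1:]:
        if a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    gaps = [merged[0][0] - lo]
    for (_, b1), (a2, _) in zip(merged[:-1], merged[1:]):
        gaps.append(a2 - b1)
    gaps.append(hi - merged[-1][1])
    return float(max(gaps) * fiber.um_per_pixel / fiber.length_um)


def count_nuclei(nuclei: NucleusSet) -> int:
    """Number of labelled nuclei."""
    return len(nuclei)


def muscle_length(fiber: FiberGeometry) -> float:
    """Axial extent of the mask (pixel centers, + 1 px) in µm."""
    u0, u1 = fiber.axial_range()
    pts = fiber.mask_points()
    perp = np.array([-fiber.axis_unit_vector[1], fiber.axis_unit_vector[0]])
    width = np.ptp(pts @ perp)
    if (u1 - u0) <= width:
        warnings.warn(
            "fiber length does not exceed its width; the long axis is "
            "ill-defined for this mask",
            stacklevel=2,
        )
    return float((u1 - u0 + 1.0) * fiber.um_per_pixel)


@dataclass
class PositionReport:
    """All positioning metrics of one fiber, normalized where applicable."""

    end_distance: dict[str, float]
    nearest_end_nucleus: dict[str, int]
    nearest_neighbor: np.ndarray | None
    longest_gap: float
    n_nuclei: int
    length_um: float

    def to_frame(self, fiber_id="fiber") -> pd.DataFrame:
        """Tidy table: one row per measurement."""
        rows = []
        for end, val in self.end_distance.items():
            rows.append((fiber_id, f"end_distance_{end}", val, "muscle_length"))
        if self.nearest_neighbor is not None:
            for v in self.nearest_neighbor:
                rows.append((fiber_id, "nearest_neighbor", float(v), "muscle_length"))
        rows.append((fiber_id, "longest_gap", self.longest_gap, "muscle_length"))
        rows.append((fiber_id, "n_nuclei", float(self.n_nuclei), "none"))
        rows.append((fiber_id, "length_um", self.length_um, "none"))
        return pd.DataFrame(rows, columns=["fiber_id", "metric", "value", "normalized_by"])


def nuclei_from_csv(path, default_radius_px: float = 5.0) -> dict[str, NucleusSet]:
    """Read nucleus coordinate tables: fiber_id, nucleus_id, x_px, y_px.

    An optional ``radius_px`` column sets each nucleus's circular outline;
    without it, ``default_radius_px`` is used.  Returns one NucleusSet per
    fiber_id.
    """
    from .geometry import Nucleus, ellipse_polygon

    df = pd.read_csv(path)
    required = {"fiber_id", "nucleus_id", "x_px", "y_px"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"coordinate CSV missing columns: {sorted(missing)}")
    out = {}
    for fid, grp in df.groupby("fiber_id", sort=False):
        nuclei = []
        for _, row in grp.iterrows():
            r = float(row["radius_px"]) if "radius_px" in grp.columns else default_radius_px
            c = np.array([row.x_px, row.y_px], dtype=float)
            nuclei.append(
                Nucleus(
                    id=int(row.nucleus_id),
                    centroid_px=c,
                    outline=ellipse_polygon(c, r, r),
                    area_px=float(np.pi * r * r),
                )
            )
        out[str(fid)] = NucleusSet(sorted(nuclei, key=lambda n: n.id))
    return out


def position_report(fiber: FiberGeometry, nuclei: NucleusSet) -> PositionReport:
    """Compute every positioning metric for one fiber."""
    ends, nearest = {}, {}
    for end in ("dorsal", "ventral"):
        d, nid = end_to_nucleus_distance(fiber, nuclei, end)
        ends[end] = d
        nearest[end] = nid
    nn = nearest_neighbor_distances(fiber, nuclei) if len(nuclei) >= 2 else None
    return PositionReport(
        end_distance=ends,
        nearest_end_nucleus=nearest,
        nearest_neighbor=nn,
        longest_gap=longest_gap(fiber, nuclei),
        n_nuclei=count_nuclei(nuclei),
        length_um=muscle_length(fiber),
    )
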