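"""Protein-localization intensity profiles along the end-to-nucleus span.

The central readout: within an oriented rectangular ROI running from a
muscle end to the nearest nucleus, the target-channel intensity is divided
by the reference-channel intensity (the structural stain used as internal
control) position by position, multiplied by 100, and resampled onto a
normalized position axis where 0% is the muscle end and 100% the nucleus.
The curve's maximum is the peak intensity; the area under the curve is the
total fluorescence.  Variants: a fixed-dimension box anchored at the nucleus
(plotted against raw position), and the distal-region ratio over the last
few µm of the fiber.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.integrate import simpson
from scipy.spatial.distance import cdist

from .geometry import FiberGeometry, NucleusSet
from .io import MultiChannelImage
from . import stats as _stats

__all__ = [
    "ProfileROI",
    "RawProfile",
    "LocalizationProfile",
    "ProfileCohort",
    "select_profile_roi",
    "compute_ratio_profile",
    "compute_intensity_profile",
    "normalize_profile",
    "fixed_box_profile",
    "distal_region_ratio",
    "average_profiles",
    "reference_control_check",
]

GRID = np.linspace(0.0, 100.0, 101)
MIN_WIDTH_PX = 3


@dataclass
class ProfileROI:
    """Oriented rectangular ROI from a muscle end to the nearest nucleus.

    The ROI is defined once on geometry (selected on the reference/nuclei
    channels) and the identical pixel set is sampled in every channel.
    """

    anchor_end: np.ndarray  # (x, y) on the end contour
    anchor_nucleus: np.ndarray  # (x, y) on the nucleus outline
    direction: np.ndarray  # unit vector end -> nucleus
    length_px: float
    n_width: int  # odd number of 1-px-spaced width samples
    um_per_pixel: float
    end_label: str = ""
    nucleus_id: int = -1
    mask: np.ndarray | None = None  # fiber mask; bounds the sampled region

    @property
    def span_um(self) -> float:
        return self.length_px * self.um_per_pixel

    @property
    def width_um(self) -> float:
        return self.n_width * self.um_per_pixel

    def longitudinal_positions_px(self) -> np.ndarray:
        """1-px steps from the end anchor, always including the far endpoint."""
        pos = np.arange(0.0, self.length_px, 1.0)
        if len(pos) == 0 or pos[-1] < self.length_px - 1e-9:
            pos = np.append(pos, self.length_px)
        return pos

    def sample_points(self) -> np.ndarray:
        """(n_len, n_width, 2) array of (x, y) sample coordinates."""
        pos = self.longitudinal_positions_px()
        perp = np.array([-self.direction[1], self.direction[0]])
        offsets = np.arange(self.n_width) - (self.n_width - 1) / 2.0
        return (
            self.anchor_end[None, None, :]
            + pos[:, None, None] * self.direction[None, None, :]
            + offsets[None, :, None] * perp[None, None, :]
        )


def _closest_pair(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    d = cdist(a, b)
    ia, ib = np.unravel_index(np.argmin(d), d.shape)
    return a[ia], b[ib], float(d[ia, ib])


def _nearest_nucleus(fiber: FiberGeometry, nuclei: NucleusSet, end_label: str):
    contour = fiber.end_contours[end_label]
    best = None
    best_d = np.inf
    for nu in nuclei:
        _, _, d = _closest_pair(contour, nu.outline)
        if d < best_d:
            best, best_d = nu, d
    return best


def _points_in_mask(mask: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Nearest-pixel membership test for an array of (x, y) points."""
    ny, nx = mask.shape
    xi = np.clip(np.rint(pts[..., 0]).astype(int), 0, nx - 1)
    yi = np.clip(np.rint(pts[..., 1]).astype(int), 0, ny - 1)
    inside = mask[yi, xi]
    inside &= (pts[..., 0] > -0.5) & (pts[..., 0] < nx - 0.5)
    inside &= (pts[..., 1] > -0.5) & (pts[..., 1] < ny - 0.5)
    return inside


def select_profile_roi(
    fiber: FiberGeometry,
    nuclei: NucleusSet,
    end_label: str,
    width_um: float = 2.0,
) -> ProfileROI:
    """ROI of set width spanning the shortest end-to-nearest-nucleus segment.

    The rectangle is aligned to the end-to-nucleus direction and centered on
    the shortest segment between the end contour and the nucleus outline.
    If the requested width exits the fiber mask, it is shrunk (with a
    warning) down to a 3-px minimum, below which an error is raised.
    """
    if len(nuclei) == 0:
        raise ValueError("profile ROI needs at least one nucleus")
    nu = _nearest_nucleus(fiber, nuclei, end_label)
    contour = fiber.end_contours[end_label]
    p_end, p_nuc, dist = _closest_pair(contour, nu.outline)
    if dist < 1e-9:
        raise ValueError(
            f"nucleus {nu.id} touches the {end_label} end contour; "
            "no span to profile"
        )
    direction = (p_nuc - p_end) / dist
    n_width = max(int(round(width_um / fiber.um_per_pixel)), MIN_WIDTH_PX)
    if n_width % 2 == 0:
        n_width += 1
    while n_width >= MIN_WIDTH_PX:
        roi = ProfileROI(
            anchor_end=p_end,
            anchor_nucleus=p_nuc,
            direction=direction,
            length_px=dist,
            n_width=n_width,
            um_per_pixel=fiber.um_per_pixel,
            end_label=end_label,
            nucleus_id=nu.id,
            mask=fiber.mask,
        )
        if _points_in_mask(fiber.mask, roi.sample_points()).all():
            if n_width < int(round(width_um / fiber.um_per_pixel)):
                warnings.warn(
                    f"profile box width shrunk to {roi.width_um:.2f} µm to stay "
                    "inside the fiber mask",
                    stacklevel=2,
                )
            return roi
        n_width -= 2
    raise ValueError(
        "profile box exits the fiber mask even at the minimum width; "
        "the fiber is too narrow here"
    )


@dataclass
class RawProfile:
    """Width-averaged ratio (or intensity) versus raw longitudinal position."""

    positions_px: np.ndarray
    positions_um: np.ndarray
    ratio: np.ndarray  # (target/reference) x 100, or plain intensity
    n_pixels_per_bin: np.ndarray
    kind: str = "ratio"  # "ratio" | "intensity"


def _sample_channel(
    image: MultiChannelImage, pts: np.ndarray, channel: str, mask: np.ndarray | None
) -> np.ndarray:
    """Bilinear sampling; outside-mask pixels are filled with their nearest
    inside value first, so samples at the fiber boundary are not diluted by
    background zeros."""
    arr = image[channel]
    if mask is not None and not mask.all():
        fill_idx = ndimage.distance_transform_edt(
            ~mask, return_distances=False, return_indices=True
        )
        arr = arr[tuple(fill_idx)]
    coords = np.stack([pts[..., 1].ravel(), pts[..., 0].ravel()])  # (row, col)
    vals = ndimage.map_coordinates(arr, coords, order=1, mode="nearest")
    return vals.reshape(pts.shape[:-1])


def compute_ratio_profile(
    image: MultiChannelImage,
    roi: ProfileROI,
    target_channel: str = "target",
    reference_channel: str = "reference",
) -> RawProfile:
    """Per-position (target/reference) x 100 along the ROI.

    At each 1-px longitudinal step the target and reference are averaged
    across the box width, then divided.  Any position with nonpositive mean
    reference raises (widen the box or mask out the offending region).
    """
    pts = roi.sample_points()
    tgt = _sample_channel(image, pts, target_channel, roi.mask).mean(axis=1)
    ref = _sample_channel(image, pts, reference_channel, roi.mask).mean(axis=1)
    if np.any(ref <= 0):
        bad = int(np.argmax(ref <= 0))
        raise ValueError(
            f"mean reference intensity is zero at position {bad}; "
            "widen the box or mask out the dark region"
        )
    pos = roi.longitudinal_positions_px()
    return RawProfile(
        positions_px=pos,
        positions_um=pos * roi.um_per_pixel,
        ratio=tgt / ref * 100.0,
        n_pixels_per_bin=np.full(len(pos), roi.n_width),
        kind="ratio",
    )


def compute_intensity_profile(
    image: MultiChannelImage, roi: ProfileROI, channel: str = "reference"
) -> RawProfile:
    """Width-averaged single-channel intensity along the ROI (no ratio)."""
    pts = roi.sample_points()
    vals = _sample_channel(image, pts, channel, roi.mask).mean(axis=1)
    pos = roi.longitudinal_positions_px()
    return RawProfile(
        positions_px=pos,
        positions_um=pos * roi.um_per_pixel,
        ratio=vals,
        n_pixels_per_bin=np.full(len(pos), roi.n_width),
        kind="intensity",
    )


@dataclass
class LocalizationProfile:
    """Profile resampled to the fixed 101-point normalized position grid."""

    positions: np.ndarray  # 0..100 %
    ratio: np.ndarray
    peak: float
    auc: float
    n_pixels_per_bin: np.ndarray = field(default_factory=lambda: np.empty(0))
    kind: str = "ratio"

    def __post_init__(self) -> None:
        if np.any(self.ratio < 0):
            raise ValueError("ratio values must be nonnegative")


def normalize_profile(raw: RawProfile) -> LocalizationProfile:
    """Resample a raw profile onto [0, 100] % of the span (101 points).

    Linear interpolation; the peak is the curve maximum and the AUC the
    trapezoidal integral over the normalized axis (a constant ``c`` profile
    therefore integrates to ``100 c``).
    """
    if len(raw.positions_px) < 4:
        raise ValueError("profile span too short: need at least 4 raw positions")
    span = raw.positions_px[-1] - raw.positions_px[0]
    if span <= 0:
        raise ValueError("profile span must be positive")
    pct = (raw.positions_px - raw.positions_px[0]) / span * 100.0
    ratio = np.interp(GRID, pct, raw.ratio)
    # peak and AUC come from the raw samples (denser than the fixed grid for
    # long spans, no resampling loss for short ones); composite Simpson
    # integration avoids the trapezoid's convexity bias on steep decays while
    # remaining exact for constant and linear profiles
    return LocalizationProfile(
        positions=GRID.copy(),
        ratio=ratio,
        peak=float(raw.ratio.max()),
        auc=float(simpson(raw.ratio, x=pct)),
        n_pixels_per_bin=np.interp(GRID, pct, raw.n_pixels_per_bin),
        kind=raw.kind,
    )


def fixed_box_profile(
    image: MultiChannelImage,
    fiber: FiberGeometry,
    nuclei: NucleusSet,
    end_label: str,
    box_dims_um: tuple[float, float] = (2.0, 5.0),
    target_channel: str = "target",
    reference_channel: str = "reference",
) -> RawProfile:
    """Ratio profile in a fixed-size box anchored at the nearest nucleus.

    ``box_dims_um`` is (width, length).  The box starts at the nucleus
    outline point closest to the chosen end and extends ``length`` µm toward
    that end; positions are raw µm from the nucleus edge (no normalization).
    Raises if the box leaves the fiber mask.
    """
    width_um, length_um = box_dims_um
    nu = _nearest_nucleus(fiber, nuclei, end_label)
    contour = fiber.end_contours[end_label]
    p_end, p_nuc, dist = _closest_pair(contour, nu.outline)
    if dist < 1e-9:
        raise ValueError("nucleus touches the end; no room for a box")
    direction = (p_end - p_nuc) / dist  # from nucleus toward the end
    length_px = length_um / fiber.um_per_pixel
    n_width = max(int(round(width_um / fiber.um_per_pixel)), MIN_WIDTH_PX)
    if n_width % 2 == 0:
        n_width += 1
    roi = ProfileROI(
        anchor_end=p_nuc,
        anchor_nucleus=p_nuc + direction * length_px,
        direction=direction,
        length_px=length_px,
        n_width=n_width,
        um_per_pixel=fiber.um_per_pixel,
        end_label=end_label,
        nucleus_id=nu.id,
        mask=fiber.mask,
    )
    if not _points_in_mask(fiber.mask, roi.sample_points()).all():
        raise ValueError(
            f"fixed box ({width_um} x {length_um} µm) exceeds the fiber mask"
        )
    return compute_ratio_profile(image, roi, target_channel, reference_channel)


def distal_region_ratio(
    image: MultiChannelImage,
    fiber: FiberGeometry,
    depth_um: float = 2.0,
    end_label: str | None = None,
    target_channel: str = "target",
    reference_channel: str = "reference",
) -> float:
    """Mean target / mean reference x 100 in the distal zone of the fiber.

    The distal zone is the set of mask pixels within ``depth_um`` of the end
    contour — of one end if ``end_label`` is given, else of either end.
    """
    if fiber.length_um <= depth_um:
        raise ValueError("fiber shorter than the requested distal depth")
    pts = fiber.mask_points()
    depth_px = depth_um / fiber.um_per_pixel
    labels = [end_label] if end_label else ["dorsal", "ventral"]
    zone = np.zeros(len(pts), dtype=bool)
    u = fiber.axial_coordinate(pts)
    for lab in labels:
        cu = fiber.axial_coordinate(fiber.end_contours[lab])
        # axial prefilter: only points this close to the end cap can be in range
        near = np.abs(u - cu.mean()) <= depth_px + 2.0
        d = cdist(pts[near], fiber.end_contours[lab]).min(axis=1)
        zone[near] |= d <= depth_px
    xi = pts[zone, 0].astype(int)
    yi = pts[zone, 1].astype(int)
    ref = image[reference_channel][yi, xi]
    tgt = image[target_channel][yi, xi]
    mean_ref = float(ref.mean())
    if mean_ref <= 0:
        raise ValueError("zero mean reference intensity in the distal zone")
    return float(tgt.mean()) / mean_ref * 100.0


@dataclass
class ProfileCohort:
    """Pointwise mean curve with SD band plus cohort peak/AUC statistics.

    Cohort peak/AUC are the mean and SD of the per-profile values, not the
    peak/AUC of the mean curve.
    """

    positions: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    peaks: np.ndarray
    aucs: np.ndarray
    n: int

    @property
    def peak_mean(self) -> float:
        return float(self.peaks.mean())

    @property
    def peak_sd(self) -> float:
        return float(self.peaks.std(ddof=1))

    @property
    def auc_mean(self) -> float:
        return float(self.aucs.mean())

    @property
    def auc_sd(self) -> float:
        return float(self.aucs.std(ddof=1))


def average_profiles(profiles: list[LocalizationProfile]) -> ProfileCohort:
    """Average >= 2 profiles sharing the common normalized grid."""
    if len(profiles) < 2:
        raise ValueError("cohort averaging needs at least 2 profiles")
    grid = profiles[0].positions
    for p in profiles[1:]:
        if len(p.positions) != len(grid) or not np.allclose(p.positions, grid):
            raise ValueError(
                "profiles are on different grids; normalize_profile them first"
            )
    curves = np.array([p.ratio for p in profiles])
    return ProfileCohort(
        positions=grid.copy(),
        mean=curves.mean(axis=0),
        sd=curves.std(axis=0, ddof=1),
        peaks=np.array([p.peak for p in profiles]),
        aucs=np.array([p.auc for p in profiles]),
        n=len(profiles),
    )


def reference_control_check(
    cohorts: dict[str, list[LocalizationProfile]],
    control_label: str | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Validate the reference channel as internal control across genotypes.

    Takes cohorts of reference-channel profiles (one list per genotype),
    compares each genotype's total (AUC) against the control with the
    pairwise t-test and the omnibus one-way ANOVA across all genotypes, and
    flags genotypes whose reference totals are dual-significant — a flag
    means the reference stain is NOT a valid internal control there.
    """
    if len(cohorts) < 2:
        raise ValueError("reference control check needs at least 2 genotypes")
    labels = list(cohorts)
    control_label = control_label or labels[0]
    if control_label not in cohorts:
        raise ValueError(f"control label {control_label!r} not among cohorts")
    totals = {g: np.array([p.auc for p in profs]) for g, profs in cohorts.items()}
    p_anova = _stats.one_way_anova(list(totals.values()))
    rows = []
    for g in labels:
        if g == control_label:
            continue
        p_t = _stats.students_t(totals[control_label], totals[g])
        result = _stats.dual_significance(p_t, p_anova)
        rows.append(
            {
                "genotype": g,
                "control": control_label,
                "auc_mean": float(totals[g].mean()),
                "auc_sd": float(totals[g].std(ddof=1)),
                "n": len(totals[g]),
                "p_t": p_t,
                "p_anova": p_anova,
                "flagged": bool(result.significant_05 if alpha >= 0.05 else result.significant_01),
                "stars": result.stars,
            }
        )
    return pd.DataFrame(rows)
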