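"""Synthetic fluorescence-microscopy data with ground truth.

This module fabricates everything the measurement modules consume — fiber
images with reference/nuclei/target channels, nucleus placements, time-lapse
nucleus tracks, and larval centroid tracks — under named "genotype" presets,
so that every downstream statistic can be checked against a known truth.

The model of one fiber image:

* the fiber is an elongated (rotatable) rectangular mask;
* the reference channel (the structural stain used as internal control) is a
  constant level inside the mask, ~0 outside;
* the nuclei channel is bright ellipses at the placed nucleus positions;
* the target channel follows, over each end-to-nearest-nucleus span, an
  exponential-peak model
  ``baseline + peak_amplitude * exp(-|s - peak_position| / decay_length)``
  on the normalized span coordinate ``s`` (0 = muscle end, 1 = nucleus edge),
  blended with a spatially uniform diffuse component of equal span mean by
  ``mixture_weight_diffuse``;
* Gaussian noise (optionally with a Poisson-like signal-dependent scale) is
  applied last; the noiseless analytic ratio curve is returned as truth.

Nucleus placement: fractional axial positions are drawn from a mixture of
Gaussian clusters, then rejected-and-resampled until every elliptical
nucleus fits inside the mask without overlapping a neighbour.  Nuclei sit
near the fiber midline, as myonuclei do in these thin body-wall muscles.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .dynamics import NucleusTrack, TrackFrame
from .geometry import FiberGeometry, Nucleus, NucleusSet, ellipse_polygon
from .io import MultiChannelImage
from .locomotion import CentroidTrack

__all__ = [
    "GenotypePreset",
    "SyntheticFiberTruth",
    "DynamicsParams",
    "load_presets",
    "make_fiber",
    "place_nuclei",
    "render_channels",
    "simulate_nucleus_tracks",
    "simulate_larval_track",
    "truth_ratio_curve",
]

# default nucleus ellipse semi-axes (µm): semi-major along the fiber axis
NUCLEUS_SEMI_AXES_UM = (1.4, 1.0)
NUCLEI_CHANNEL_LEVEL = 300.0
PROFILE_GRID = np.linspace(0.0, 100.0, 101)


# --------------------------------------------------------------------------- #
# presets
# --------------------------------------------------------------------------- #
@dataclass
class GenotypePreset:
    """Parameters describing one genotype's synthetic phenotype."""

    name: str
    nucleus_placement: dict
    target_model: dict
    reference_level: float
    noise: dict = field(default_factory=lambda: {"gaussian_sd": 0.0, "poisson_like": False})

    def __post_init__(self) -> None:
        np_ = self.nucleus_placement
        tm = self.target_model
        if np_["n_nuclei"] < 1:
            raise ValueError("n_nuclei must be >= 1")
        for c in np_["cluster_centers"]:
            if not 0.0 <= c <= 1.0:
                raise ValueError("cluster centers must lie in [0, 1]")
        if np_["cluster_sd"] < 0:
            raise ValueError("cluster_sd must be >= 0")
        for key in ("baseline", "peak_amplitude", "decay_length"):
            if tm[key] < 0:
                raise ValueError(f"target_model.{key} must be >= 0")
        if not 0.0 <= tm["peak_position"] <= 1.0:
            raise ValueError("peak_position must lie in [0, 1]")
        if not 0.0 <= tm.get("mixture_weight_diffuse", 0.0) <= 1.0:
            raise ValueError("mixture_weight_diffuse must lie in [0, 1]")
        if self.reference_level <= 0:
            raise ValueError("reference_level must be positive")
        if self.noise.get("gaussian_sd", 0.0) < 0:
            raise ValueError("gaussian_sd must be >= 0")

    @classmethod
    def from_dict(cls, name: str, d: dict) -> "GenotypePreset":
        return cls(
            name=name,
            nucleus_placement=dict(d["nucleus_placement"]),
            target_model=dict(d["target_model"]),
            reference_level=float(d["reference_level"]),
            noise=dict(d.get("noise", {"gaussian_sd": 0.0, "poisson_like": False})),
        )

    def replace(self, **sections) -> "GenotypePreset":
        """Copy with shallow updates to named sections (e.g. noise={...})."""
        d = {
            "nucleus_placement": dict(self.nucleus_placement),
            "target_model": dict(self.target_model),
            "reference_level": self.reference_level,
            "noise": dict(self.noise),
        }
        for key, val in sections.items():
            if isinstance(d.get(key), dict) and isinstance(val, dict):
                d[key].update(val)
            else:
                d[key] = val
        return GenotypePreset.from_dict(self.name, d)


def load_presets(path=None) -> dict[str, GenotypePreset]:
    """Load genotype presets from a YAML file (default: the packaged presets)."""
    if path is None:
        text = resources.files("myonuc").joinpath("presets.yaml").read_text()
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    return {name: GenotypePreset.from_dict(name, d) for name, d in raw.items()}


# --------------------------------------------------------------------------- #
# fiber geometry
# --------------------------------------------------------------------------- #
def make_fiber(
    length_um: float,
    width_um: float,
    um_per_pixel: float,
    orientation_deg: float = 0.0,
    seed: int = 0,
) -> FiberGeometry:
    """Rasterize an elongated rectangular fiber mask at the given orientation.

    The reported ``length_um`` equals the long-axis extent of the mask within
    one pixel.  The dorsal end is the end with the smaller axial coordinate.
    ``seed`` is accepted for interface symmetry; the geometry is deterministic.
    """
    del seed
    if not (length_um > width_um > 0):
        raise ValueError("require length_um > width_um > 0")
    if um_per_pixel <= 0:
        raise ValueError("um_per_pixel must be positive")
    l_px = length_um / um_per_pixel
    w_px = width_um / um_per_pixel
    if w_px < 4:
        raise ValueError(
            f"degenerate size: fiber width is {w_px:.1f} px (< 4 px across); "
            "use a finer um_per_pixel or a wider fiber"
        )
    theta = np.deg2rad(orientation_deg)
    axis = np.array([np.cos(theta), np.sin(theta)])
    perp = np.array([-np.sin(theta), np.cos(theta)])
    margin = 3
    half_diag = (abs(axis[0]) * l_px + abs(perp[0]) * w_px) / 2, (
        abs(axis[1]) * l_px + abs(perp[1]) * w_px
    ) / 2
    nx = int(np.ceil(half_diag[0] * 2)) + 2 * margin
    ny = int(np.ceil(half_diag[1] * 2)) + 2 * margin
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    yy, xx = np.mgrid[0:ny, 0:nx]
    dx, dy = xx - cx, yy - cy
    u = dx * axis[0] + dy * axis[1]
    v = dx * perp[0] + dy * perp[1]
    half_l = (l_px - 1.0) / 2.0
    half_w = (w_px - 1.0) / 2.0
    mask = (np.abs(u) <= half_l + 1e-9) & (np.abs(v) <= half_w + 1e-9)
    if mask.sum() < 4:
        raise ValueError("degenerate size: mask smaller than 4 pixels")
    # orient the axis so the dorsal (low-u) end is well defined
    pts = np.column_stack(np.nonzero(mask))[:, ::-1].astype(float)  # (x, y)
    up = pts @ axis
    u0, u1 = up.min(), up.max()
    # outermost pixel layer: digitized edge pixel centers lie within this
    # band of the extreme axial coordinate
    cap = 0.5 * (abs(axis[0]) + abs(axis[1])) + 1e-6
    ends = {"dorsal": pts[up <= u0 + cap], "ventral": pts[up >= u1 - cap]}
    return FiberGeometry(
        mask=mask,
        axis_unit_vector=axis,
        end_contours=ends,
        length_um=(u1 - u0 + 1.0) * um_per_pixel,
        um_per_pixel=um_per_pixel,
    )


# --------------------------------------------------------------------------- #
# nucleus placement
# --------------------------------------------------------------------------- #
def place_nuclei(
    fiber: FiberGeometry,
    preset: GenotypePreset,
    seed: int = 0,
    semi_axes_um: tuple[float, float] = NUCLEUS_SEMI_AXES_UM,
    max_tries: int = 2000,
    end_standoff_um: float = 1.5,
) -> NucleusSet:
    """Place elliptical nuclei per the preset's cluster model.

    Fractional axial positions are drawn from the Gaussian cluster mixture;
    candidates are rejected and resampled until each nucleus lies wholly
    inside the mask and overlaps no previously placed nucleus.  Nucleus
    edges keep at least ``end_standoff_um`` from the fiber ends, as even
    end-clustered myonuclei leave a short span of cortex free.
    """
    rng = np.random.default_rng(seed)
    placement = preset.nucleus_placement
    centers = np.asarray(placement["cluster_centers"], dtype=float)
    sd = float(placement["cluster_sd"])
    n = int(placement["n_nuclei"])
    upp = fiber.um_per_pixel
    a_px = semi_axes_um[0] / upp
    b_px = semi_axes_um[1] / upp

    axis = fiber.axis_unit_vector
    perp = np.array([-axis[1], axis[0]])
    pts = fiber.mask_points()
    center_pt = pts.mean(axis=0)
    u = (pts - center_pt) @ axis
    v = (pts - center_pt) @ perp
    u0, u1 = u.min(), u.max()
    v_half = np.abs(v).max()
    angle = np.arctan2(axis[1], axis[0])

    # fractional margin so the ellipse fits axially with the end standoff
    frac_margin = (a_px + end_standoff_um / upp + 0.5) / (u1 - u0)
    v_sd = 0.3 * v_half
    v_lim = max(v_half - b_px - 0.5, 0.0)

    def _try_place_all() -> list[tuple[float, float]] | None:
        placed: list[tuple[float, float]] = []  # (u, v) of accepted centers
        for _ in range(n):
            for _ in range(max_tries):
                c = centers[rng.integers(len(centers))]
                frac = rng.normal(c, sd) if sd > 0 else c
                frac = float(np.clip(frac, frac_margin, 1.0 - frac_margin))
                cu = u0 + frac * (u1 - u0)
                cv = float(
                    np.clip(rng.normal(0.0, v_sd) if v_sd > 0 else 0.0, -v_lim, v_lim)
                )
                if cu - a_px < u0 - 0.5 or cu + a_px > u1 + 0.5:
                    continue
                # non-overlap for aligned equal ellipses (elliptic separation
                # >= 2), padded so neighbours keep a resolvable gap
                if all(
                    ((cu - pu) / a_px) ** 2 + ((cv - pv) / b_px) ** 2 >= 2.3**2
                    for pu, pv in placed
                ):
                    placed.append((cu, cv))
                    break
            else:
                return None
        return placed

    placed = None
    for _ in range(20):  # whole-set restarts avoid dead-end configurations
        placed = _try_place_all()
        if placed is not None:
            break
    if placed is None:
        raise RuntimeError(
            f"could not place {n} nuclei without overlap after repeated "
            "restarts: the cluster model is too dense for this fiber "
            "(reduce n_nuclei, cluster_sd, or nucleus size)"
        )
    nuclei: list[Nucleus] = []
    for i, (cu, cv) in enumerate(placed):
        centroid = center_pt + cu * axis + cv * perp
        outline = ellipse_polygon(centroid, a_px, b_px, angle_rad=angle)
        nuclei.append(
            Nucleus(
                id=i + 1,
                centroid_px=centroid,
                outline=outline,
                area_px=float(np.pi * a_px * b_px),
            )
        )
    nuclei.sort(key=lambda nu: fiber.axial_coordinate(nu.centroid_px)[0])
    for new_id, nu in enumerate(nuclei, start=1):
        nu.id = new_id
    return NucleusSet(nuclei)


# --------------------------------------------------------------------------- #
# channel rendering
# --------------------------------------------------------------------------- #
@dataclass
class SyntheticFiberTruth:
    """Ground truth accompanying one rendered fiber image."""

    fiber: FiberGeometry
    nuclei_true_positions: np.ndarray  # sorted fractional axial positions
    target_profile_true: np.ndarray  # analytic noiseless ratio on [0, 100]
    seed: int
    span_anchors: dict = field(default_factory=dict)  # per-end (end_pt, nucleus_pt)

    def __post_init__(self) -> None:
        self.nuclei_true_positions = np.sort(np.asarray(self.nuclei_true_positions, float))
        if np.any(self.target_profile_true < 0):
            raise ValueError("analytic truth curve must be nonnegative")


def _structured(s: np.ndarray, tm: dict) -> np.ndarray:
    return tm["baseline"] + tm["peak_amplitude"] * np.exp(
        -np.abs(s - tm["peak_position"]) / tm["decay_length"]
    )


def _diffuse_level(tm: dict) -> float:
    """Uniform level with the same span mean as the structured component."""
    lam, p = tm["decay_length"], tm["peak_position"]
    mean_exp = lam * (2.0 - np.exp(-p / lam) - np.exp(-(1.0 - p) / lam))
    return tm["baseline"] + tm["peak_amplitude"] * mean_exp


def truth_ratio_curve(preset: GenotypePreset, grid: np.ndarray = PROFILE_GRID) -> np.ndarray:
    """Noiseless (target/reference) x 100 ratio on the normalized span grid."""
    tm = preset.target_model
    w = tm.get("mixture_weight_diffuse", 0.0)
    s = np.asarray(grid, dtype=float) / 100.0
    target = (1.0 - w) * _structured(s, tm) + w * _diffuse_level(tm)
    return target / preset.reference_level * 100.0


def _closest_pair(points_a: np.ndarray, points_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Closest (a, b) pair between two point sets (brute via broadcasting)."""
    d2 = ((points_a[:, None, :] - points_b[None, :, :]) ** 2).sum(axis=2)
    ia, ib = np.unravel_index(np.argmin(d2), d2.shape)
    return points_a[ia], points_b[ib]


def render_channels(
    fiber: FiberGeometry,
    nuclei: NucleusSet,
    preset: GenotypePreset,
    seed: int = 0,
) -> tuple[MultiChannelImage, SyntheticFiberTruth]:
    """Render reference, nuclei and target channels plus the analytic truth.

    The target model is evaluated on the normalized coordinate of each
    end-to-nearest-nucleus span, with the span anchored exactly as the
    profile module anchors its ROI: at the closest pair of points between the
    end contour and the nearest nucleus outline.
    """
    if len(nuclei) == 0:
        raise ValueError("render_channels requires at least one nucleus")
    rng = np.random.default_rng(seed)
    tm = preset.target_model
    w = tm.get("mixture_weight_diffuse", 0.0)
    mask = fiber.mask
    ny, nx = mask.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    pix = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)

    reference = np.where(mask, preset.reference_level, 0.0)

    nuclei_chan = np.zeros_like(reference)
    for nu in nuclei:
        c = nu.centroid_px
        rel = pix - c
        # recover ellipse frame from the outline's principal axes
        angle = np.arctan2(fiber.axis_unit_vector[1], fiber.axis_unit_vector[0])
        ca, sa = np.cos(angle), np.sin(angle)
        eu = rel[:, 0] * ca + rel[:, 1] * sa
        ev = -rel[:, 0] * sa + rel[:, 1] * ca
        a = np.max(np.abs((nu.outline - c) @ np.array([ca, sa])))
        b = np.max(np.abs((nu.outline - c) @ np.array([-sa, ca])))
        inside = (eu / a) ** 2 + (ev / b) ** 2 <= 1.0
        nuclei_chan.ravel()[inside] = NUCLEI_CHANNEL_LEVEL

    structured = np.where(mask, tm["baseline"], 0.0).astype(float)
    anchors = {}
    for end_label in ("dorsal", "ventral"):
        contour = fiber.end_contours[end_label]
        # nearest nucleus to this end by boundary distance
        best, best_d = None, np.inf
        for nu in nuclei:
            d2 = ((contour[:, None, :] - nu.outline[None, :, :]) ** 2).sum(axis=2)
            d = np.sqrt(d2.min())
            if d < best_d:
                best, best_d = nu, d
        p_end, p_nuc = _closest_pair(contour, best.outline)
        span_vec = p_nuc - p_end
        span_len = np.linalg.norm(span_vec)
        anchors[end_label] = (p_end.copy(), p_nuc.copy(), best.id)
        if span_len < 1e-9:
            continue  # nucleus touches the end: no span to paint
        direction = span_vec / span_len
        s = ((pix - p_end) @ direction) / span_len
        # continuation beyond the span keeps the field smooth at the anchors:
        # constant behind the end cap (s < 0), the model itself on [0, 1], a
        # plateau across the nucleus body, then the same exponential decay
        # beyond it — no discontinuity and no two-sided cusp at the anchors
        a_px = float(np.max(np.abs((best.outline - best.centroid_px) @ direction)))
        d_nuc = 2.0 * a_px / span_len
        inside = mask.ravel()
        si = s[inside]
        s_adj = np.where(
            si < 0.0,
            0.0,
            np.where(si <= 1.0, si, np.where(si <= 1.0 + d_nuc, 1.0, si - d_nuc)),
        )
        vals = _structured(s_adj, tm)
        flat = structured.ravel()
        flat[inside] = np.maximum(flat[inside], vals)

    target = np.where(mask, (1.0 - w) * structured + w * _diffuse_level(tm), 0.0)

    sd = float(preset.noise.get("gaussian_sd", 0.0))
    channels = {"reference": reference, "nuclei": nuclei_chan, "target": target}
    if sd > 0:
        for name, chan in channels.items():
            if preset.noise.get("poisson_like", False):
                scale = sd * np.sqrt(np.maximum(chan, 0.0) / preset.reference_level + 0.25)
            else:
                scale = sd
            channels[name] = np.clip(chan + rng.normal(0.0, 1.0, chan.shape) * scale, 0.0, None)

    image = MultiChannelImage(channels=channels, um_per_pixel=fiber.um_per_pixel)
    truth = SyntheticFiberTruth(
        fiber=fiber,
        nuclei_true_positions=fiber.fractional_position(nuclei.centroids),
        target_profile_true=truth_ratio_curve(preset),
        seed=seed,
        span_anchors=anchors,
    )
    return image, truth


# --------------------------------------------------------------------------- #
# time-lapse nucleus tracks
# --------------------------------------------------------------------------- #
@dataclass
class DynamicsParams:
    """Kinematic parameters for simulated nucleus translocation."""

    speed_um_per_min: float = 0.3
    shape_change_rate_per_hr: float = 4.0
    direction_flip_rate_per_hr: float = 0.2
    ar_elongated: float = 1.8
    ar_spherical: float = 1.1

    def __post_init__(self) -> None:
        if self.speed_um_per_min < 0:
            raise ValueError("speed must be >= 0")
        if self.shape_change_rate_per_hr < 0 or self.direction_flip_rate_per_hr < 0:
            raise ValueError("event rates must be >= 0")
        if not self.ar_elongated >= self.ar_spherical >= 1.0:
            raise ValueError("require ar_elongated >= ar_spherical >= 1")


def _poisson_event_times(rng, rate_per_hr: float, duration_s: float) -> np.ndarray:
    if rate_per_hr <= 0:
        return np.empty(0)
    times = []
    t = 0.0
    rate_per_s = rate_per_hr / 3600.0
    while True:
        t += rng.exponential(1.0 / rate_per_s)
        if t >= duration_s:
            return np.array(times)
        times.append(t)


def simulate_nucleus_tracks(
    n_nuclei: int,
    duration_min: float,
    frame_interval_s: float,
    dynamics: DynamicsParams | dict | None = None,
    seed: int = 0,
    um_per_pixel: float = 0.2,
    equivalent_radius_um: float = 1.1,
) -> list[NucleusTrack]:
    """Simulate translocating nuclei alternating spherical/elongated shapes.

    Shape toggles and direction reversals are independent Poisson processes;
    the centroid advances along the movement axis (image +y) at constant
    speed with the current sign.  Outlines are ellipses of constant area
    realizing the current aspect ratio.
    """
    if dynamics is None:
        dynamics = DynamicsParams()
    elif isinstance(dynamics, dict):
        dynamics = DynamicsParams(**dynamics)
    if duration_min < 20:
        raise ValueError(
            "duration_min must be >= 20 (rate estimates need at least 20 min)"
        )
    max_rate = max(dynamics.shape_change_rate_per_hr, dynamics.direction_flip_rate_per_hr)
    if max_rate > 0 and frame_interval_s >= 3600.0 / max_rate:
        raise ValueError(
            f"undersampling: frame interval {frame_interval_s} s is not shorter "
            f"than the expected state dwell time {3600.0 / max_rate:.0f} s"
        )
    rng = np.random.default_rng(seed)
    duration_s = duration_min * 60.0
    t_frames = np.arange(0.0, duration_s + 1e-9, frame_interval_s)
    r_px = equivalent_radius_um / um_per_pixel
    tracks = []
    for _ in range(n_nuclei):
        shape_times = _poisson_event_times(rng, dynamics.shape_change_rate_per_hr, duration_s)
        flip_times = _poisson_event_times(rng, dynamics.direction_flip_rate_per_hr, duration_s)
        state0 = int(rng.integers(2))  # 0 spherical, 1 elongated
        sign0 = 1 if rng.random() < 0.5 else -1
        x0 = 50.0 + rng.normal(0.0, 2.0)
        y0 = 100.0 + rng.normal(0.0, 10.0)

        # piecewise-constant sign integrated to a position
        def position(t: float) -> float:
            knots = np.concatenate([[0.0], flip_times, [t]])
            knots = knots[knots <= t]
            disp = 0.0
            sgn = sign0
            for a, b in zip(knots[:-1], knots[1:]):
                disp += sgn * (b - a)
                sgn = -sgn
            return disp

        frames = []
        for t in t_frames:
            n_shape = int(np.searchsorted(shape_times, t, side="right"))
            state = (state0 + n_shape) % 2
            ar = dynamics.ar_elongated if state == 1 else dynamics.ar_spherical
            disp_um = position(t) * dynamics.speed_um_per_min / 60.0
            cy = y0 + disp_um / um_per_pixel
            a = r_px * np.sqrt(ar)
            b = r_px / np.sqrt(ar)
            outline = ellipse_polygon(np.array([x0, cy]), a, b, angle_rad=np.pi / 2)
            frames.append(TrackFrame(t_s=float(t), centroid_px=np.array([x0, cy]), outline=outline))
        tracks.append(
            NucleusTrack(frames=frames, um_per_pixel=um_per_pixel, duration_min=duration_min)
        )
    return tracks


# --------------------------------------------------------------------------- #
# larval tracks
# --------------------------------------------------------------------------- #
def simulate_larval_track(
    mean_speed_um_s: float,
    heading_noise: float,
    duration_s: float,
    frame_interval_s: float,
    seed: int = 0,
    stimulus_point: tuple[float, float] = (50_000.0, 0.0),
) -> CentroidTrack:
    """Correlated random walk toward a fixed stimulus point.

    The larva advances ``mean_speed_um_s * frame_interval_s`` per step along a
    heading equal to the bearing to the stimulus plus AR(1) angular noise of
    stationary SD ``heading_noise`` (radians).  With zero noise the path is a
    straight line and the path-length velocity equals ``mean_speed_um_s``
    exactly.
    """
    if mean_speed_um_s < 0:
        raise ValueError("mean speed must be >= 0")
    rng = np.random.default_rng(seed)
    n_steps = int(np.floor(duration_s / frame_interval_s))
    t = np.arange(n_steps + 1) * frame_interval_s
    xy = np.zeros((n_steps + 1, 2))
    stim = np.asarray(stimulus_point, dtype=float)
    rho = 0.7
    noise = 0.0
    path_len = 0.0
    for i in range(n_steps):
        bearing = np.arctan2(*(stim - xy[i])[::-1])
        if heading_noise > 0:
            noise = rho * noise + np.sqrt(1 - rho**2) * rng.normal(0.0, heading_noise)
        heading = bearing + noise
        step = mean_speed_um_s * frame_interval_s
        xy[i + 1] = xy[i] + step * np.array([np.cos(heading), np.sin(heading)])
        path_len += step
    return CentroidTrack(
        t_s=t, x_um=xy[:, 0], y_um=xy[:, 1], stimulus_point=stim, path_length_true_um=path_len
    )
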