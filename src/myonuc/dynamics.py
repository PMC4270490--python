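"""Time-lapse nuclear translocation metrics.

Quantifies the behaviour of individual myonuclei followed over 20–60 min:
the extremes of the outline aspect ratio, the number of spherical/elongated
shape transitions per hour (counted with a hysteresis classifier so that
noise cannot inflate the event count), the percentage of nuclei that reverse
their direction of travel, and space-time kymograph montages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "TrackFrame",
    "NucleusTrack",
    "Kymograph",
    "aspect_ratio",
    "aspect_extremes",
    "count_shape_changes",
    "direction_change_fraction",
    "build_kymograph",
    "dynamics_report",
    "write_tracks_csv",
    "read_tracks_csv",
]


@dataclass
class TrackFrame:
    """One time point of a tracked nucleus."""

    t_s: float
    centroid_px: np.ndarray
    outline: np.ndarray


@dataclass
class NucleusTrack:
    """Time series of one nucleus's centroid and outline."""

    frames: list[TrackFrame]
    um_per_pixel: float
    duration_min: float

    def __post_init__(self) -> None:
        if self.um_per_pixel <= 0:
            raise ValueError("um_per_pixel must be positive")
        t = np.array([f.t_s for f in self.frames])
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("frame timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def times_s(self) -> np.ndarray:
        return np.array([f.t_s for f in self.frames])

    @property
    def centroids_px(self) -> np.ndarray:
        return np.array([f.centroid_px for f in self.frames])

    def aspect_ratios(self) -> np.ndarray:
        return np.array([aspect_ratio(f.outline) for f in self.frames])

    @property
    def duration_hr(self) -> float:
        t = self.times_s
        return float((t[-1] - t[0]) / 3600.0)


def _polygon_cov(outline: np.ndarray) -> np.ndarray:
    """Area-weighted covariance (second central moments) of a simple polygon."""
    p = np.asarray(outline, dtype=float)
    x, y = p[:, 0], p[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cr = x * yn - xn * y
    a = np.sum(cr) / 2.0
    if abs(a) < 1e-9:
        raise ValueError("degenerate polygon: zero area")
    cx = np.sum((x + xn) * cr) / (6.0 * a)
    cy = np.sum((y + yn) * cr) / (6.0 * a)
    ixx = np.sum((x * x + x * xn + xn * xn) * cr) / 12.0
    iyy = np.sum((y * y + y * yn + yn * yn) * cr) / 12.0
    ixy = np.sum((x * yn + 2 * x * y + 2 * xn * yn + xn * y) * cr) / 24.0
    cov = np.array([[ixx / a - cx * cx, ixy / a - cx * cy],
                    [ixy / a - cx * cy, iyy / a - cy * cy]])
    return cov


def aspect_ratio(outline: np.ndarray) -> float:
    """Major/minor axis ratio of the outline's inertia-equivalent ellipse.

    Computed from the closed-form second moments of the polygonal region;
    exact (up to discretization of the outline) and invariant to rotation,
    translation and uniform scaling.  Always >= 1.
    """
    cov = _polygon_cov(outline)
    evals = np.linalg.eigvalsh(cov)
    if evals[0] <= 0:
        raise ValueError("degenerate polygon: collapsed along one axis")
    return float(np.sqrt(evals[1] / evals[0]))


def aspect_extremes(track: NucleusTrack) -> tuple[float, float]:
    """(ar_max, ar_min) over the frames of one track; needs >= 5 frames."""
    if len(track) < 5:
        raise ValueError("aspect extremes need at least 5 frames")
    ars = track.aspect_ratios()
    return float(ars.max()), float(ars.min())


def count_shape_changes(
    track: NucleusTrack,
    enter_elongated: float = 1.4,
    exit_elongated: float = 1.2,
) -> float:
    """Shape-change events per hour, via a two-state hysteresis classifier.

    The nucleus becomes "elongated" when its aspect ratio crosses
    ``enter_elongated`` upward, and "spherical" when it crosses
    ``exit_elongated`` downward; each state transition is one event.
    Hysteresis makes the count invariant to temporal oversampling.
    """
    if enter_elongated <= exit_elongated:
        raise ValueError("enter_elongated must exceed exit_elongated")
    dur_hr = track.duration_hr
    if dur_hr * 60.0 < 20.0 - 1e-9:
        raise ValueError("shape-change rate needs a track of at least 20 min")
    ars = track.aspect_ratios()
    mid = (enter_elongated + exit_elongated) / 2.0
    state = 1 if ars[0] >= mid else 0
    events = 0
    for ar in ars[1:]:
        if state == 0 and ar >= enter_elongated:
            state, events = 1, events + 1
        elif state == 1 and ar <= exit_elongated:
            state, events = 0, events + 1
    return events / dur_hr


def _axial_positions_um(track: NucleusTrack, axis) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    return track.centroids_px @ axis * track.um_per_pixel


def direction_change_fraction(
    tracks: list[NucleusTrack],
    window_frames: int = 10,
    min_disp_um: float = 0.5,
    axis=(0.0, 1.0),
) -> float:
    """Percentage of nuclei that reverse travel direction, per hour.

    Motion is assessed along ``axis`` over a sliding window of
    ``window_frames``; a window only counts as motion when its net
    displacement exceeds ``min_disp_um``.  A track "changed direction" if the
    motion sign flips at least once; each track's indicator is divided by its
    duration in hours before averaging, and the mean is reported x 100.
    """
    if not tracks:
        raise ValueError("need at least one track")
    values = []
    any_motion = False
    for track in tracks:
        if track.duration_hr * 60.0 < 20.0 - 1e-9:
            raise ValueError("direction analysis needs tracks of at least 20 min")
        u = _axial_positions_um(track, axis)
        if len(u) <= window_frames:
            raise ValueError("track shorter than the sliding window")
        disp = u[window_frames:] - u[:-window_frames]
        signs = np.sign(disp[np.abs(disp) > min_disp_um])
        if len(signs):
            any_motion = True
        changed = bool(len(signs) and np.any(np.diff(signs) != 0))
        values.append(changed / track.duration_hr)
    if not any_motion:
        warnings.warn(
            "no track exceeded the minimum displacement; all stationary",
            stacklevel=2,
        )
        return 0.0
    return 100.0 * float(np.mean(values))


@dataclass
class Kymograph:
    """Space-time montage: rows ordered by time, columns along the axis."""

    data: np.ndarray
    positions_px: np.ndarray
    t_s: np.ndarray
    out_of_bounds: bool


def build_kymograph(
    track: NucleusTrack,
    movie: np.ndarray,
    strip_width_px: int = 5,
) -> Kymograph:
    """Extract the intensity strip along the movement axis for each frame.

    ``movie`` is a ``(n_frames, H, W)`` array aligned to the track frames.
    Each row of the montage is the width-averaged intensity along the
    movement axis through the track's mean centroid; rows are ordered by
    time, and the position axis is flipped so the net motion points toward
    lower column indices ("upward" when the montage is displayed with the
    position axis vertical).  Samples falling outside the image are padded
    with zeros and flagged.
    """
    movie = np.asarray(movie, dtype=float)
    if movie.ndim != 3 or movie.shape[0] == 0:
        raise ValueError("movie must be a non-empty (frames, H, W) array")
    if movie.shape[0] != len(track):
        raise ValueError(
            f"movie has {movie.shape[0]} frames but track has {len(track)}"
        )
    cents = track.centroids_px
    net = cents[-1] - cents[0]
    norm = np.linalg.norm(net)
    axis = net / norm if norm > 1e-9 else np.array([0.0, 1.0])
    perp = np.array([-axis[1], axis[0]])
    center = cents.mean(axis=0)
    u = (cents - center) @ axis
    pad = 15.0
    pos = np.arange(np.floor(u.min() - pad), np.ceil(u.max() + pad) + 1.0)
    offsets = np.arange(strip_width_px) - (strip_width_px - 1) / 2.0

    h, w = movie.shape[1:]
    rows = []
    oob = False
    for k in range(movie.shape[0]):
        pts = (
            center[None, None, :]
            + pos[:, None, None] * axis[None, None, :]
            + offsets[None, :, None] * perp[None, None, :]
        )  # (n_pos, n_off, 2) as (x, y)
        coords = np.stack([pts[..., 1].ravel(), pts[..., 0].ravel()])  # (row, col)
        if (
            coords[0].min() < 0 or coords[0].max() > h - 1
            or coords[1].min() < 0 or coords[1].max() > w - 1
        ):
            oob = True
        vals = ndimage.map_coordinates(movie[k], coords, order=1, cval=0.0)
        rows.append(vals.reshape(len(pos), len(offsets)).mean(axis=1))
    kymo = np.array(rows)
    if (cents[-1] - cents[0]) @ axis > 0:
        kymo = kymo[:, ::-1]
        pos = pos[::-1]
    return Kymograph(data=kymo, positions_px=pos, t_s=track.times_s, out_of_bounds=oob)


def write_tracks_csv(tracks: list[NucleusTrack], path) -> None:
    """Write tracks as CSV: track_id, frame, t_s, x_px, y_px, outline_wkt."""
    from shapely.geometry import Polygon

    rows = []
    for tid, track in enumerate(tracks):
        for fi, frame in enumerate(track.frames):
            rows.append(
                {
                    "track_id": tid,
                    "frame": fi,
                    "t_s": frame.t_s,
                    "x_px": frame.centroid_px[0],
                    "y_px": frame.centroid_px[1],
                    "outline_wkt": Polygon(frame.outline).wkt,
                    "um_per_pixel": track.um_per_pixel,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_tracks_csv(path, um_per_pixel: float | None = None) -> list[NucleusTrack]:
    """Read tracks from CSV (track_id, frame, t_s, x_px, y_px, outline_wkt)."""
    from shapely import wkt as shapely_wkt

    df = pd.read_csv(path)
    required = {"track_id", "frame", "t_s", "x_px", "y_px", "outline_wkt"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"track CSV missing columns: {sorted(missing)}")
    tracks = []
    for _, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("frame")
        upp = um_per_pixel
        if upp is None:
            upp = float(grp["um_per_pixel"].iloc[0]) if "um_per_pixel" in grp else 1.0
        frames = []
        for _, row in grp.iterrows():
            poly = shapely_wkt.loads(row.outline_wkt)
            outline = np.asarray(poly.exterior.coords)[:-1]  # drop closing vertex
            frames.append(
                TrackFrame(
                    t_s=float(row.t_s),
                    centroid_px=np.array([row.x_px, row.y_px], dtype=float),
                    outline=outline,
                )
            )
        duration_min = (frames[-1].t_s - frames[0].t_s) / 60.0
        tracks.append(
            NucleusTrack(frames=frames, um_per_pixel=upp, duration_min=duration_min)
        )
    return tracks


def dynamics_report(
    tracks: list[NucleusTrack],
    enter_elongated: float = 1.4,
    exit_elongated: float = 1.2,
    window_frames: int = 10,
    min_disp_um: float = 0.5,
    axis=(0.0, 1.0),
) -> tuple[pd.DataFrame, dict]:
    """Per-track table and cohort summary of the dynamics metrics."""
    records = []
    for i, track in enumerate(tracks):
        ar_max, ar_min = aspect_extremes(track)
        u = _axial_positions_um(track, axis)
        disp = u[window_frames:] - u[:-window_frames]
        signs = np.sign(disp[np.abs(disp) > min_disp_um])
        changed = bool(len(signs) and np.any(np.diff(signs) != 0))
        records.append(
            {
                "track_id": i,
                "ar_max": ar_max,
                "ar_min": ar_min,
                "shape_changes_per_hr": count_shape_changes(
                    track, enter_elongated, exit_elongated
                ),
                "changed_direction": changed,
                "duration_hr": track.duration_hr,
            }
        )
    df = pd.DataFrame.from_records(records)
    cohort = {
        "ar_max_mean": float(df.ar_max.mean()),
        "ar_max_sd": float(df.ar_max.std(ddof=1)) if len(df) > 1 else np.nan,
        "ar_min_mean": float(df.ar_min.mean()),
        "ar_min_sd": float(df.ar_min.std(ddof=1)) if len(df) > 1 else np.nan,
        "shape_changes_per_hr_mean": float(df.shape_changes_per_hr.mean()),
        "shape_changes_per_hr_sd": (
            float(df.shape_changes_per_hr.std(ddof=1)) if len(df) > 1 else np.nan
        ),
        "pct_direction_changers_per_hr": 100.0
        * float((df.changed_direction / df.duration_hr).mean()),
        "n_tracks": len(df),
    }
    return df, cohort
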