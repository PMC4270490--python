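"""Larval crawling velocity and developmental viability rates.

Velocity is the total crawled path length divided by elapsed time, matching
stimulus-approach tracking assays; a net-displacement variant is available
by flag.  Viability is the fraction of starting embryos reaching each later
stage (hatching, pupation, eclosion), expressed as a percentage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CentroidTrack",
    "ViabilityCounts",
    "average_velocity",
    "viability_rates",
    "load_tracks_csv",
]


@dataclass
class CentroidTrack:
    """Timestamped centroid positions of one tracked larva (µm)."""

    t_s: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray
    stimulus_point: np.ndarray | None = None
    path_length_true_um: float | None = None

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.x_um = np.asarray(self.x_um, dtype=float)
        self.y_um = np.asarray(self.y_um, dtype=float)
        if not (len(self.t_s) == len(self.x_um) == len(self.y_um)):
            raise ValueError("t_s, x_um, y_um must have equal length")
        if len(self.t_s) > 1 and not np.all(np.diff(self.t_s) > 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def xy(self) -> np.ndarray:
        return np.column_stack([self.x_um, self.y_um])


def average_velocity(track: CentroidTrack, mode: str = "path") -> float:
    """Average crawl velocity in µm/s.

    ``mode="path"`` (default): total path length (sum of inter-sample
    Euclidean steps) over elapsed time.  ``mode="net"``: straight-line
    start-to-end displacement over elapsed time; always <= the path value.
    """
    if len(track.t_s) < 2:
        raise ValueError("velocity needs at least 2 samples")
    elapsed = track.t_s[-1] - track.t_s[0]
    if elapsed <= 0:
        raise ValueError("zero elapsed time")
    if mode == "path":
        dist = float(np.sum(np.linalg.norm(np.diff(track.xy, axis=0), axis=1)))
    elif mode == "net":
        dist = float(np.linalg.norm(track.xy[-1] - track.xy[0]))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return dist / elapsed


@dataclass
class ViabilityCounts:
    """Stage counts from one viability assay (per genotype)."""

    n_embryos: int
    n_L1: int
    n_pupae: int
    n_adults: int

    def __post_init__(self) -> None:
        counts = [self.n_embryos, self.n_L1, self.n_pupae, self.n_adults]
        if any(c < 0 for c in counts):
            raise ValueError("stage counts must be nonnegative")
        if not (self.n_embryos >= self.n_L1 >= self.n_pupae >= self.n_adults):
            raise ValueError(
                "stage counts must be nonincreasing "
                "(embryos >= L1 >= pupae >= adults); check the bookkeeping"
            )


def viability_rates(counts: ViabilityCounts) -> dict[str, float]:
    """Stage survival normalized to the starting embryo count, in percent."""
    if counts.n_embryos <= 0:
        raise ValueError("need a positive number of starting embryos")
    base = counts.n_embryos
    return {
        "pct_hatch": 100.0 * counts.n_L1 / base,
        "pct_pupation": 100.0 * counts.n_pupae / base,
        "pct_eclosion": 100.0 * counts.n_adults / base,
    }


def load_tracks_csv(path) -> dict[str, CentroidTrack]:
    """Read larval tracks from CSV with columns larva_id, t_s, x_um, y_um."""
    df = pd.read_csv(path)
    required = {"larva_id", "t_s", "x_um", "y_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"track CSV missing columns: {sorted(missing)}")
    out = {}
    for larva_id, grp in df.groupby("larva_id"):
        grp = grp.sort_values("t_s")
        out[str(larva_id)] = CentroidTrack(
            t_s=grp.t_s.to_numpy(), x_um=grp.x_um.to_numpy(), y_um=grp.y_um.to_numpy()
        )
    return out
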