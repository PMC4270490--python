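"""Core geometric containers for muscle fibers and myonuclei.

Coordinate convention used throughout the package: 0-based, pixel-centered,
row-major arrays with y increasing downward.  Points are stored as ``(x, y)``
pairs where ``x`` is the column index and ``y`` the row index; physical
distances are obtained by multiplying pixel distances by ``um_per_pixel``.

A :class:`FiberGeometry` describes one elongated muscle fiber: its binary
mask, the unit vector of its long axis, the pixel sets forming its two end
contours (labelled ``dorsal`` and ``ventral``) and its physical length.  The
"dorsal" end is, by convention, the end with the smaller axial coordinate; a
flipped assignment can be requested where the anatomical orientation of a
user image differs.

A :class:`NucleusSet` collects the myonuclei of a single fiber, each with a
centroid, a polygonal outline and an area.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FiberGeometry",
    "Nucleus",
    "NucleusSet",
    "ellipse_polygon",
    "polygon_area",
    "polygon_centroid",
    "fiber_from_mask",
    "END_LABELS",
]

END_LABELS = ("dorsal", "ventral")


def ellipse_polygon(
    center: np.ndarray,
    semi_major: float,
    semi_minor: float,
    angle_rad: float = 0.0,
    n_vertices: int = 64,
) -> np.ndarray:
    """Vertices of an ellipse as an ``(n, 2)`` array of ``(x, y)`` points.

    ``semi_major`` lies along ``angle_rad`` (measured from +x toward +y).
    """
    if semi_major <= 0 or semi_minor <= 0:
        raise ValueError("ellipse semi-axes must be positive")
    t = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    x = semi_major * np.cos(t)
    y = semi_minor * np.sin(t)
    pts = np.column_stack([c * x - s * y, s * x + c * y])
    return pts + np.asarray(center, dtype=float)


def polygon_area(outline: np.ndarray) -> float:
    """Unsigned area of a simple polygon (shoelace formula)."""
    p = np.asarray(outline, dtype=float)
    x, y = p[:, 0], p[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    return float(abs(np.sum(x * yn - xn * y)) / 2.0)


def polygon_centroid(outline: np.ndarray) -> np.ndarray:
    """Area centroid of a simple polygon."""
    p = np.asarray(outline, dtype=float)
    x, y = p[:, 0], p[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = np.sum(cross) / 2.0
    if abs(a) < 1e-12:
        return p.mean(axis=0)
    cx = np.sum((x + xn) * cross) / (6.0 * a)
    cy = np.sum((y + yn) * cross) / (6.0 * a)
    return np.array([cx, cy])


@dataclass
class Nucleus:
    """One myonucleus: integer label, centroid, polygonal outline, area."""

    id: int
    centroid_px: np.ndarray
    outline: np.ndarray  # (n, 2) polygon vertices, pixel units
    area_px: float

    def __post_init__(self) -> None:
        self.centroid_px = np.asarray(self.centroid_px, dtype=float)
        self.outline = np.asarray(self.outline, dtype=float)
        if self.area_px <= 0:
            raise ValueError(f"nucleus {self.id}: area must be positive")
        if self.outline.ndim != 2 or self.outline.shape[1] != 2 or len(self.outline) < 3:
            raise ValueError(f"nucleus {self.id}: outline must be an (n>=3, 2) polygon")


@dataclass
class NucleusSet:
    """The labelled myonuclei of a single fiber."""

    nuclei: list[Nucleus] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.nuclei)

    def __iter__(self):
        return iter(self.nuclei)

    def __getitem__(self, i: int) -> Nucleus:
        return self.nuclei[i]

    @property
    def centroids(self) -> np.ndarray:
        """(n, 2) array of centroid (x, y) coordinates in pixels."""
        if not self.nuclei:
            return np.empty((0, 2))
        return np.array([n.centroid_px for n in self.nuclei])


@dataclass
class FiberGeometry:
    """Elongated muscle fiber: mask, long axis, end contours, length.

    Parameters
    ----------
    mask
        Binary 2D array, True inside the fiber.
    axis_unit_vector
        Unit ``(x, y)`` direction of the long axis, oriented so that the
        dorsal end has the smaller axial coordinate.
    end_contours
        ``{"dorsal": (n, 2), "ventral": (m, 2)}`` pixel-center coordinates of
        the two end caps.
    length_um
        Extent of the mask projected on the axis, plus one pixel, in µm.
    um_per_pixel
        Physical calibration.
    """

    mask: np.ndarray
    axis_unit_vector: np.ndarray
    end_contours: dict[str, np.ndarray]
    length_um: float
    um_per_pixel: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.axis_unit_vector = np.asarray(self.axis_unit_vector, dtype=float)
        nrm = np.linalg.norm(self.axis_unit_vector)
        if not np.isfinite(nrm) or nrm == 0:
            raise ValueError("axis vector must be nonzero")
        self.axis_unit_vector = self.axis_unit_vector / nrm
        if self.length_um <= 0:
            raise ValueError("fiber length must be positive")
        if self.um_per_pixel <= 0:
            raise ValueError("um_per_pixel must be positive")
        missing = [k for k in END_LABELS if k not in self.end_contours]
        if missing:
            raise ValueError(f"missing end contours: {missing}")

    # -- axial coordinate helpers -------------------------------------------------
    def mask_points(self) -> np.ndarray:
        """(n, 2) pixel-center (x, y) coordinates of all mask pixels."""
        rr, cc = np.nonzero(self.mask)
        return np.column_stack([cc, rr]).astype(float)

    def axial_coordinate(self, points: np.ndarray) -> np.ndarray:
        """Project points onto the long axis (pixel units, arbitrary origin)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.axis_unit_vector

    def axial_range(self) -> tuple[float, float]:
        """(min, max) axial coordinate over mask pixel centers."""
        u = self.axial_coordinate(self.mask_points())
        return float(u.min()), float(u.max())

    def fractional_position(self, points: np.ndarray) -> np.ndarray:
        """Axial position rescaled to [0, 1]: 0 = dorsal end, 1 = ventral end."""
        u0, u1 = self.axial_range()
        u = self.axial_coordinate(points)
        return (u - u0) / (u1 - u0)

    def end_anchor(self, end_label: str) -> np.ndarray:
        """Representative point of an end: contour pixel closest to the axis line
        through the mask centroid (i.e. the middle of the end cap)."""
        contour = self.end_contours[end_label]
        center = self.mask_points().mean(axis=0)
        d = contour - center
        perp = d - np.outer(d @ self.axis_unit_vector, self.axis_unit_vector)
        return contour[int(np.argmin(np.einsum("ij,ij->i", perp, perp)))]


def fiber_from_mask(
    mask: np.ndarray,
    um_per_pixel: float,
    end_cap_px: float | None = None,
    flip_dorsal: bool = False,
) -> FiberGeometry:
    """Derive a :class:`FiberGeometry` from a binary mask.

    The long axis is the first principal component of the mask pixel-center
    coordinates; end contours are the mask pixels within ``end_cap_px`` of
    either axial extreme (default: the outermost digitized pixel layer for
    the estimated orientation, plus a quarter pixel of slack for ragged
    masks).  ``flip_dorsal`` swaps the dorsal/ventral labels for images whose
    anatomical orientation is reversed.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 4:
        raise ValueError("mask is degenerate (fewer than 4 pixels)")
    rr, cc = np.nonzero(mask)
    pts = np.column_stack([cc, rr]).astype(float)
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered / len(pts)
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, int(np.argmax(evals))]
    if axis[0] < 0 or (axis[0] == 0 and axis[1] < 0):
        axis = -axis  # deterministic sign
    u = pts @ axis
    u0, u1 = u.min(), u.max()
    if end_cap_px is None:
        end_cap_px = 0.5 * (abs(axis[0]) + abs(axis[1])) + 0.25
    low = pts[u <= u0 + end_cap_px]
    high = pts[u >= u1 - end_cap_px]
    if flip_dorsal:
        low, high = high, low
        axis = -axis
    ends = {"dorsal": low, "ventral": high}
    length_um = (u1 - u0 + 1.0) * um_per_pixel
    width = np.ptp(centered @ evecs[:, int(np.argmin(evals))])
    if (u1 - u0) <= width:
        warnings.warn(
            "mask is not elongated: axial extent <= transverse extent; "
            "axis direction may be unstable",
            stacklevel=2,
        )
    return FiberGeometry(
        mask=mask,
        axis_unit_vector=axis,
        end_contours=ends,
        length_um=length_um,
        um_per_pixel=um_per_pixel,
    )
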