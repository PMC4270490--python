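"""Image and table I/O: multi-channel TIFF, projections, segmentation.

Images are multi-page TIFFs, one page per channel, with the channel names and
the µm-per-pixel calibration stored as JSON in the image description.  Masks
travel either as single-page label TIFFs or as polygon CSVs; measurement
tables are strict CSV (comma separator, header row, UTF-8).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import tifffile
from skimage import measure
from skimage.filters import threshold_otsu

from .geometry import FiberGeometry, Nucleus, NucleusSet, fiber_from_mask

__all__ = [
    "MultiChannelImage",
    "SegmentationInput",
    "read_image",
    "write_image",
    "max_project",
    "load_segmentation",
    "segmentation_to_geometry",
    "read_polygon_csv",
    "write_polygon_csv",
]

logger = logging.getLogger(__name__)

DEFAULT_ROLES = ("reference", "nuclei", "target")


@dataclass
class MultiChannelImage:
    """Named 2D intensity channels sharing a pixel grid and calibration."""

    channels: dict[str, np.ndarray]
    um_per_pixel: float = 1.0

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("image must have at least one channel")
        if self.um_per_pixel <= 0:
            raise ValueError("um_per_pixel must be positive")
        shapes = {np.asarray(a).shape for a in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels differ in shape: {shapes}")
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    @property
    def shape(self) -> tuple[int, ...]:
        return next(iter(self.channels.values())).shape

    def __getitem__(self, name: str) -> np.ndarray:
        return self.channels[name]


def write_image(path, image: MultiChannelImage) -> None:
    """Write one page per channel; names and calibration go in the description."""
    meta = {"channel_names": image.channel_names, "um_per_pixel": image.um_per_pixel}
    data = np.stack([image.channels[n] for n in image.channel_names]).astype(np.float32)
    tifffile.imwrite(
        path, data, description=json.dumps(meta), photometric="minisblack"
    )


def read_image(path, channel_map: dict | None = None) -> MultiChannelImage:
    """Read a multi-page TIFF into a :class:`MultiChannelImage`.

    ``channel_map`` maps either 1-based page numbers or stored channel names
    to role names (e.g. ``{1: "reference", 2: "nuclei", 3: "target"}``).
    Without a map, stored channel names (or ``channel_0`` ...) are kept.
    Missing calibration metadata falls back to 1.0 µm/px with a warning.
    """
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        desc = tif.pages[0].description
    if arr.ndim == 2:
        arr = arr[None]
    meta: dict = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    um_per_pixel = meta.get("um_per_pixel")
    if um_per_pixel is None:
        warnings.warn(
            f"{path}: no µm/px calibration found, assuming 1.0 µm/px", stacklevel=2
        )
        logger.warning("%s: missing calibration, defaulting to 1.0 um/px", path)
        um_per_pixel = 1.0
    stored = meta.get("channel_names") or [f"channel_{i}" for i in range(len(arr))]
    channels = {name: arr[i] for i, name in enumerate(stored)}
    if channel_map:
        remapped = {}
        for key, role in channel_map.items():
            if isinstance(key, int):
                if not 1 <= key <= len(arr):
                    raise ValueError(
                        f"channel_map page {key} out of range; file has pages "
                        f"1..{len(arr)} with names {stored}"
                    )
                remapped[role] = arr[key - 1]
            else:
                if key not in channels:
                    raise ValueError(
                        f"channel {key!r} not in file; available: {stored}"
                    )
                remapped[role] = channels[key]
        channels = remapped
    return MultiChannelImage(channels=channels, um_per_pixel=float(um_per_pixel))


def max_project(stack) -> MultiChannelImage:
    """Maximum-intensity projection over Z, per channel.

    Accepts a dict of 3D ``(z, y, x)`` arrays (or 2D arrays, returned
    unchanged) or a :class:`MultiChannelImage` whose channels are stacks.
    """
    if isinstance(stack, MultiChannelImage):
        chans, upp = stack.channels, stack.um_per_pixel
    elif isinstance(stack, dict):
        chans, upp = stack, 1.0
    else:
        raise TypeError("stack must be a MultiChannelImage or a dict of arrays")
    out = {}
    for name, arr in chans.items():
        arr = np.asarray(arr, dtype=float)
        if arr.ndim == 2:
            out[name] = arr  # single slice: unchanged
        elif arr.ndim == 3:
            out[name] = arr.max(axis=0)
        else:
            raise ValueError(f"channel {name!r}: expected 2D or 3D, got {arr.ndim}D")
    return MultiChannelImage(channels=out, um_per_pixel=upp)


class SegmentationInput:
    """Fiber mask plus labelled nuclei, either user-provided or derived."""

    def __init__(self, fiber_mask, nucleus_labels, source: str = "derived"):
        self.fiber_mask = np.asarray(fiber_mask, dtype=bool)
        self.nucleus_labels = np.asarray(nucleus_labels)
        self.source = source
        if not self.fiber_mask.any():
            raise ValueError("fiber mask is empty")
        outside = self.nucleus_labels[~self.fiber_mask]
        n_out = int(np.count_nonzero(outside))
        n_tot = int(np.count_nonzero(self.nucleus_labels))
        if n_tot and n_out:
            frac = n_out / n_tot
            if frac <= 0.05:
                warnings.warn(
                    f"{frac:.1%} of nucleus pixels protrude beyond the fiber mask",
                    stacklevel=3,
                )
            else:
                raise ValueError(
                    f"{frac:.1%} of nucleus pixels lie outside the fiber mask"
                )


def load_segmentation(
    source,
    method: str = "threshold_otsu_on_reference_and_nuclei",
    min_nucleus_area_px: int = 12,
    fiber_mask=None,
    nucleus_labels=None,
) -> SegmentationInput:
    """Obtain a segmentation, either passed through or by Otsu thresholding.

    ``method="provided_masks"`` returns the given ``fiber_mask`` and
    ``nucleus_labels`` untouched (this is the reference route, standing in for
    manual outlining).  The automatic route thresholds the reference channel
    (fiber = largest connected above-threshold component) and the nuclei
    channel (nuclei = above-threshold components of at least
    ``min_nucleus_area_px`` pixels).
    """
    if method == "provided_masks":
        if fiber_mask is None or nucleus_labels is None:
            raise ValueError("provided_masks requires fiber_mask and nucleus_labels")
        return SegmentationInput(fiber_mask, nucleus_labels, source="provided")
    if method != "threshold_otsu_on_reference_and_nuclei":
        raise ValueError(f"unknown segmentation method {method!r}")

    image = source if isinstance(source, MultiChannelImage) else read_image(source)
    ref = image["reference"]
    nuc = image["nuclei"]
    if not np.any(ref > 0):
        raise ValueError("reference channel is empty; cannot derive a fiber mask")
    fiber = ref > threshold_otsu(ref)
    if not fiber.any():
        raise ValueError("Otsu threshold produced an empty fiber mask")
    lbl = measure.label(fiber)
    largest = np.argmax(np.bincount(lbl.ravel())[1:]) + 1
    fiber = lbl == largest

    if np.any(nuc > 0):
        nuc_bin = nuc > threshold_otsu(nuc)
    else:
        nuc_bin = np.zeros_like(fiber)
    labels = measure.label(nuc_bin, connectivity=1)
    for region in measure.regionprops(labels):
        if region.area < min_nucleus_area_px:
            labels[labels == region.label] = 0
    labels = measure.label(labels > 0)  # relabel consecutively
    return SegmentationInput(fiber, labels, source="derived")


def write_polygon_csv(path, polygons: dict) -> None:
    """Write outlines as strict CSV: fiber_id, vertex_index, x_px, y_px."""
    import csv

    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["fiber_id", "vertex_index", "x_px", "y_px"])
        for fid, poly in polygons.items():
            for i, (x, y) in enumerate(np.asarray(poly, dtype=float)):
                writer.writerow([fid, i, x, y])


def read_polygon_csv(path) -> dict:
    """Read outlines from CSV (fiber_id, vertex_index, x_px, y_px)."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"fiber_id", "vertex_index", "x_px", "y_px"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"polygon CSV missing columns: {sorted(missing)}")
    out = {}
    for fid, grp in df.groupby("fiber_id", sort=False):
        grp = grp.sort_values("vertex_index")
        out[fid] = grp[["x_px", "y_px"]].to_numpy(dtype=float)
    return out


def segmentation_to_geometry(
    seg: SegmentationInput, um_per_pixel: float
) -> tuple[FiberGeometry, NucleusSet]:
    """Turn a segmentation into the geometric containers the metrics consume."""
    fiber = fiber_from_mask(seg.fiber_mask, um_per_pixel)
    nuclei = []
    for region in measure.regionprops(seg.nucleus_labels):
        contours = measure.find_contours(seg.nucleus_labels == region.label, 0.5)
        outline_rc = max(contours, key=len)
        outline = outline_rc[:, ::-1]  # (row, col) -> (x, y)
        cy, cx = region.centroid
        nuclei.append(
            Nucleus(
                id=int(region.label),
                centroid_px=np.array([cx, cy]),
                outline=outline,
                area_px=float(region.area),
            )
        )
    nuclei.sort(key=lambda n: n.id)
    return fiber, NucleusSet(nuclei)
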