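"""Reading, writing and cropping binary vessel masks.

Conventions used throughout the package:

* masks are 2-D boolean arrays, row-major, row 0 at the top;
* coordinates are 0-based ``(row, column)`` = ``(y, x)``;
* an ROI window of side ``s`` centred at ``c`` spans the half-open interval
  ``[c - s//2, c - s//2 + s)`` on each axis;
* a pixel belongs to a circular ROI iff the Euclidean distance from its
  centre to the window centre is at most ``(s - 1) / 2``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .errors import BoundsError, ManifestValidationError, MaskFormatError, SchemaError

logger = logging.getLogger(__name__)

#: ITU-R 601 luminance weights used to collapse RGB-encoded binary masks.
_LUMA = np.array([0.299, 0.587, 0.114])

ROI_LABELS = ("optic_disc", "macula", "whole", "custom")
DEFAULT_GROUPS = ("H", "G", "DR")

MANIFEST_COLUMNS = ("image", "mask", "group", "od_x", "od_y", "mac_x", "mac_y")


@dataclass
class BinaryMask:
    """A binary vessel raster: ``True`` = vessel foreground."""

    pixels: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        pixels = np.asarray(self.pixels)
        if pixels.ndim != 2:
            raise MaskFormatError(f"mask must be 2-D, got shape {pixels.shape}")
        if pixels.size == 0:
            raise MaskFormatError("mask has zero area")
        self.pixels = pixels.astype(bool)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def foreground_count(self) -> int:
        return int(self.pixels.sum())


@dataclass(frozen=True)
class RoiSpec:
    """A named region of interest addressing a sub-window of a mask.

    ``size`` is the side length for squares and the diameter for circles,
    in pixels.
    """

    label: str
    centre_x: int
    centre_y: int
    shape: str = "square"
    size: int = 1000

    def __post_init__(self) -> None:
        if self.label not in ROI_LABELS:
            raise ValueError(f"label must be one of {ROI_LABELS}, got {self.label!r}")
        if self.shape not in ("square", "circle"):
            raise ValueError(f"shape must be 'square' or 'circle', got {self.shape!r}")
        if self.size < 2:
            raise ValueError(f"ROI size must be >= 2 px, got {self.size}")


@dataclass(frozen=True)
class ManifestRecord:
    image: str
    mask: str
    group: str
    optic_disc: RoiSpec
    macula: RoiSpec


@dataclass
class DatasetManifest:
    """An ordered collection of (image, mask, group, ROI centres) records."""

    records: list[ManifestRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def group_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for rec in self.records:
            counts[rec.group] = counts.get(rec.group, 0) + 1
        return counts


def read_mask(path: str | Path, threshold: int = 127, name: str | None = None) -> BinaryMask:
    """Read a raster file as a binary mask.

    Multi-channel images are collapsed by ITU-R 601 luminance before
    thresholding; pixels strictly greater than ``threshold`` become
    foreground.
    """
    path = Path(path)
    with Image.open(path) as img:
        arr = np.asarray(img)
    if arr.ndim == 3:
        arr = arr[..., :3] @ _LUMA
    if arr.ndim != 2 or arr.size == 0:
        raise MaskFormatError(f"{path} decodes to unusable shape {arr.shape}")
    return BinaryMask(arr > threshold, name=name if name is not None else path.stem)


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a mask as an 8-bit single-channel raster (0 / 255)."""
    img = Image.fromarray(mask.pixels.astype(np.uint8) * 255, mode="L")
    img.save(Path(path))


def circle_membership(size: int) -> np.ndarray:
    """Boolean stencil of the inscribed circle of a ``size``-px window.

    A pixel is inside iff its centre lies within ``(size - 1) / 2`` of the
    window centre ``((size-1)/2, (size-1)/2)`` — deterministic and
    antialias-free.
    """
    c = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    return (yy - c) ** 2 + (xx - c) ** 2 <= c**2


def crop_roi(mask: BinaryMask, roi: RoiSpec, clamp: bool = False) -> BinaryMask:
    """Extract a square or circular ROI as a ``size`` × ``size`` mask.

    For circular ROIs, pixels outside the inscribed circle are forced to
    background; they still belong to the output window (the "black corners"
    of a circular crop).

    With ``clamp=False`` an ROI window leaving the image raises
    :class:`BoundsError`; with ``clamp=True`` the window is shifted inside
    bounds and the shift is logged.
    """
    size = roi.size
    h, w = mask.height, mask.width
    if not (0 <= roi.centre_y < h and 0 <= roi.centre_x < w):
        raise BoundsError(
            f"ROI centre ({roi.centre_y}, {roi.centre_x}) outside image {h}x{w}"
        )
    if size > h or size > w:
        raise BoundsError(f"ROI size {size} exceeds image {h}x{w}")
    r0 = roi.centre_y - size // 2
    c0 = roi.centre_x - size // 2
    if r0 < 0 or c0 < 0 or r0 + size > h or c0 + size > w:
        if not clamp:
            raise BoundsError(
                f"ROI window [{r0}:{r0 + size}, {c0}:{c0 + size}] exceeds image "
                f"{h}x{w}; pass clamp=True to shift it inside"
            )
        r0c = min(max(r0, 0), h - size)
        c0c = min(max(c0, 0), w - size)
        logger.warning(
            "ROI %s clamped from (%d, %d) to (%d, %d)", roi.label, r0, c0, r0c, c0c
        )
        r0, c0 = r0c, c0c
    window = mask.pixels[r0 : r0 + size, c0 : c0 + size].copy()
    if roi.shape == "circle":
        window &= circle_membership(size)
    return BinaryMask(window, name=f"{mask.name}:{roi.label}" if mask.name else roi.label)


def read_manifest(
    path: str | Path,
    groups: Sequence[str] = DEFAULT_GROUPS,
    roi_shape: str = "square",
    roi_size: int = 1000,
) -> DatasetManifest:
    """Read a dataset manifest CSV.

    Expected header: ``image,mask,group,od_x,od_y,mac_x,mac_y``. ROI specs
    are built with the given shape and size (defaults: square, 1000 px).
    """
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"manifest {path} missing columns: {missing}")
    allowed = set(groups)
    records: list[ManifestRecord] = []
    seen_paths: set[str] = set()
    for idx, row in df.iterrows():
        if row["group"] not in allowed:
            raise ManifestValidationError(
                f"row {idx}: unknown group {row['group']!r} (allowed: {sorted(allowed)})"
            )
        for col in ("image", "mask"):
            p = str(row[col])
            if p in seen_paths:
                raise ManifestValidationError(f"row {idx}: duplicate path {p!r}")
        seen_paths.update({str(row["image"]), str(row["mask"])})
        records.append(
            ManifestRecord(
                image=str(row["image"]),
                mask=str(row["mask"]),
                group=str(row["group"]),
                optic_disc=RoiSpec(
                    "optic_disc", int(row["od_x"]), int(row["od_y"]), roi_shape, roi_size
                ),
                macula=RoiSpec(
                    "macula", int(row["mac_x"]), int(row["mac_y"]), roi_shape, roi_size
                ),
            )
        )
    return DatasetManifest(records)


def write_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    rows = [
        {
            "image": rec.image,
            "mask": rec.mask,
            "group": rec.group,
            "od_x": rec.optic_disc.centre_x,
            "od_y": rec.optic_disc.centre_y,
            "mac_x": rec.macula.centre_x,
            "mac_y": rec.macula.centre_y,
        }
        for rec in manifest.records
    ]
    pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS)).to_csv(path, index=False)
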