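"""Image containers, coordinate conventions and raster I/O.

Conventions used throughout the package:

* pixels are indexed ``(row, col)`` with the origin at the top-left;
* a :class:`PixelPoint` is ``(col, row)`` (x before y, like image viewers);
* physical coordinates are ``(x, y)`` in micrometres of *pixel centres*,
  0-based: ``x = col * resolution``, ``y = row * resolution``;
* all stage outputs preserve the dimensions of the input image.

The physical resolution (µm per pixel) is always supplied explicitly via
configuration or function argument — it is never inferred silently from
image metadata, because every size class downstream is physical.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Tuple

import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = [
    "GrayImage",
    "FilterGeometry",
    "load_image",
    "save_image",
    "apply_circular_mask",
    "phys_coords",
    "pixel_coords",
]

PixelPoint = Tuple[int, int]  # (col, row)
PhysPoint = Tuple[float, float]  # (x, y) in µm


@dataclass
class GrayImage:
    """A 2-D grayscale raster with a physical resolution.

    Parameters
    ----------
    pixels
        2-D array of non-negative finite intensities, row-major,
        origin top-left.  Stored as ``float64`` internally; integer
        inputs are preserved losslessly.
    resolution_um_per_px
        Physical edge length of one pixel in micrometres (> 0).
    bit_depth
        Bit depth of the source data (8 or 16 for typical dark-field
        exports); informational tag only.
    """

    pixels: np.ndarray
    resolution_um_per_px: float
    bit_depth: int = 8

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2-D raster, got shape {self.pixels.shape}")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image must be at least 1x1")
        if not (self.resolution_um_per_px > 0):
            raise ValueError("resolution must be > 0 µm/px")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("intensities must be finite")
        if np.any(self.pixels < 0):
            raise ValueError("intensities must be >= 0")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray) -> "GrayImage":
        """New image sharing resolution/depth but with different pixel data."""
        return GrayImage(pixels, self.resolution_um_per_px, self.bit_depth)


@dataclass
class FilterGeometry:
    """Geometry of the circular filter membrane within an image.

    ``center_px`` is the disc centre as a ``(col, row)`` pixel coordinate;
    ``diameter_um`` the physical filter diameter (e.g. 20 mm = 20000 µm).
    """

    center_px: Tuple[float, float]
    diameter_um: float
    usable_disc: bool = True

    def __post_init__(self) -> None:
        if not (self.diameter_um > 0):
            raise ValueError("filter diameter must be > 0")

    @property
    def radius_um(self) -> float:
        return self.diameter_um / 2.0

    def radius_px(self, resolution_um_per_px: float) -> float:
        return self.radius_um / resolution_um_per_px


def load_image(path: str | Path, resolution_um_per_px: float, bit_depth: int | None = None) -> GrayImage:
    """Read a single-channel TIFF or PNG into a :class:`GrayImage`.

    Integer depths round-trip losslessly.  Multi-channel images are
    accepted only when all channels are identical (a grayscale image
    saved as RGB); genuinely coloured input is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3:
        if arr.shape[2] in (3, 4):
            rgb = arr[..., :3]
            if not (np.array_equal(rgb[..., 0], rgb[..., 1]) and np.array_equal(rgb[..., 0], rgb[..., 2])):
                raise ValueError(f"{path}: multi-channel image without a grayscale conversion rule")
            arr = rgb[..., 0]
        else:
            raise ValueError(f"{path}: unsupported channel layout {arr.shape}")
    if bit_depth is None:
        bit_depth = int(arr.dtype.itemsize * 8) if arr.dtype.kind in "ui" else 8
    return GrayImage(arr, resolution_um_per_px, bit_depth)


def save_image(img: GrayImage, path: str | Path) -> None:
    """Write the raster as 8/16-bit TIFF or PNG depending on extension."""
    path = Path(path)
    dtype = np.uint16 if img.bit_depth > 8 else np.uint8
    data = np.clip(np.rint(img.pixels), 0, np.iinfo(dtype).max).astype(dtype)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, data)
    else:
        iio.imwrite(path, data)


def apply_circular_mask(img: GrayImage, geom: FilterGeometry) -> GrayImage:
    """Zero out everything outside the filter disc (e.g. the filter holder).

    The disc must fit entirely inside the image; dimensions are preserved
    and masking is idempotent.
    """
    r_px = geom.radius_px(img.resolution_um_per_px)
    cx, cy = geom.center_px
    if cx - r_px < -0.5 or cy - r_px < -0.5 or cx + r_px > img.width - 0.5 or cy + r_px > img.height - 0.5:
        raise ValueError("filter disc exceeds image bounds")
    rows = np.arange(img.height)[:, None]
    cols = np.arange(img.width)[None, :]
    inside = (cols - cx) ** 2 + (rows - cy) ** 2 <= r_px**2
    return img.with_pixels(np.where(inside, img.pixels, 0.0))


def phys_coords(pt: PixelPoint, img: GrayImage) -> PhysPoint:
    """Physical (x, y) µm of a pixel centre; ``(col, row) * resolution``."""
    col, row = pt
    if not (0 <= col < img.width and 0 <= row < img.height):
        raise ValueError(f"pixel point {pt} outside image bounds {img.width}x{img.height}")
    res = img.resolution_um_per_px
    return (col * res, row * res)


def pixel_coords(pt: PhysPoint, img: GrayImage) -> PixelPoint:
    """Nearest pixel centre to a physical (x, y) µm coordinate."""
    x, y = pt
    res = img.resolution_um_per_px
    col = int(round(x / res))
    row = int(round(y / res))
    if not (0 <= col < img.width and 0 <= row < img.height):
        raise ValueError(f"physical point {pt} outside image bounds")
    return (col, row)
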