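"""Binarisation and contour extraction for bright objects on dark background.

The detector runs a local-mean adaptive threshold twice — once with a
large block size (243 px, prevents fragmentation of large dim objects)
and once with a small one (91 px, catches small fragments without
merging neighbours) — with offset C = -6, i.e. a pixel is foreground iff
its intensity strictly exceeds the local mean + 6.  The two binary maps
are combined by pixelwise union and contours extracted once from the
union, which makes twofold counting impossible by construction.  Only
outermost contours are kept (enclosed contours are interior structure of
the same object, so component holes are filled).

Detected objects are then gated: pixel area >= 13 (below that a contour
carries too few pixels for shape classification), and minimum/maximum
Feret diameter inside the configured physical size range.

For window-based acquisition an unbiased counting frame (ISO 13322-1
style) smaller than the field of view decides which objects a window is
allowed to count: objects are kept when they intersect the frame without
touching its exclusion edges (right, bottom) or the FOV border, so that
tiling a plane with frames counts every object exactly once.

Block sizes are fixed in pixels of the constant-resolution image export
and are not rescaled with magnification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .raster_core import FilterGeometry, GrayImage
from .shape_morphology import ShapeFeatures, boundary_polygon, feret_diameters

__all__ = [
    "DetectionParams",
    "Contour",
    "DetectedObject",
    "adaptive_binarize",
    "dual_pass_detect",
    "filter_contours",
    "apply_counting_frame",
    "detect_objects",
]


@dataclass
class DetectionParams:
    """Thresholding and gating parameters (defaults are the validated set)."""

    blocksize_run1: int = 243
    blocksize_run2: int = 91
    c_offset: float = -6.0
    min_area_px: int = 13
    min_feret_um: float = 1.0
    max_feret_um: float = 1000.0
    drop_border_objects: bool = True

    def __post_init__(self) -> None:
        for b in (self.blocksize_run1, self.blocksize_run2):
            if b < 3 or b % 2 == 0:
                raise ValueError("blocksizes must be odd and >= 3")
        if self.min_area_px < 1:
            raise ValueError("min_area_px must be >= 1")
        if not (self.min_feret_um < self.max_feret_um):
            raise ValueError("min_feret_um must be < max_feret_um")


@dataclass
class Contour:
    """A connected foreground component: filled local mask + boundary polygon."""

    bbox: Tuple[int, int, int, int]  # (rmin, cmin, rmax, cmax), half-open
    mask: np.ndarray  # local boolean, holes filled
    polygon: np.ndarray  # (N, 2) global (row, col) boundary

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    def touches_border(self, shape: Tuple[int, int]) -> bool:
        rmin, cmin, rmax, cmax = self.bbox
        return rmin == 0 or cmin == 0 or rmax == shape[0] or cmax == shape[1]


@dataclass
class DetectedObject:
    """A detected fragment with its derived morphology."""

    id: int
    bbox: Tuple[int, int, int, int]
    mask: np.ndarray  # local boolean within bbox
    polygon: np.ndarray  # (N, 2) global (row, col)
    area_px: int
    area_um2: float
    feret_min_um: float
    feret_max_um: float
    features: Optional[ShapeFeatures] = None
    shape_class: Optional[str] = None  # 'particle' | 'fiber'
    fiber_prob: Optional[float] = None
    fiber_length_um: Optional[float] = None
    measurement_point_px: Optional[Tuple[int, int]] = None  # global (col, row)
    parent_id: Optional[int] = None
    provenance: str = "detect"

    @property
    def centroid_px(self) -> Tuple[float, float]:
        rr, cc = np.nonzero(self.mask)
        return (float(cc.mean() + self.bbox[1]), float(rr.mean() + self.bbox[0]))

    def extent_um(self, resolution: float) -> Tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of pixel centres, µm."""
        rmin, cmin, rmax, cmax = self.bbox
        return (cmin * resolution, rmin * resolution, (cmax - 1) * resolution, (rmax - 1) * resolution)


def adaptive_binarize(img: GrayImage, blocksize: int, c_offset: float) -> np.ndarray:
    """Local-mean adaptive threshold: foreground iff I > mean(blocksize) - C.

    The local mean is taken over a blocksize x blocksize neighbourhood
    with reflected borders.  The inequality is strict, so ties (e.g. a
    uniform image with C = 0) are background.
    """
    if blocksize < 3 or blocksize % 2 == 0:
        raise ValueError("blocksize must be odd and >= 3")
    local_mean = ndimage.uniform_filter(img.pixels, size=blocksize, mode="reflect")
    return img.pixels > (local_mean - c_offset)


def _extract_components(binary: np.ndarray) -> List[Contour]:
    """Outermost contours of an 8-connected binary map, holes filled."""
    filled = ndimage.binary_fill_holes(binary)
    labels, _n = ndimage.label(filled, structure=np.ones((3, 3)))
    contours: List[Contour] = []
    for lab, sl in enumerate(ndimage.find_objects(labels), start=1):
        if sl is None:
            continue
        mask = labels[sl] == lab
        rmin, cmin = sl[0].start, sl[1].start
        poly = boundary_polygon(mask) + np.array([rmin, cmin], dtype=float)
        contours.append(Contour(bbox=(rmin, cmin, sl[0].stop, sl[1].stop), mask=mask, polygon=poly))
    return contours


def dual_pass_detect(img: GrayImage, params: DetectionParams) -> List[Contour]:
    """Two adaptive-threshold passes, pixelwise union, one contour extraction.

    Returns outermost contours only; because contours come from a single
    union map, no two of them overlap or nest.
    """
    b1 = adaptive_binarize(img, params.blocksize_run1, params.c_offset)
    b2 = adaptive_binarize(img, params.blocksize_run2, params.c_offset)
    return _extract_components(b1 | b2)


def filter_contours(
    contours: Sequence[Contour],
    img: GrayImage,
    params: DetectionParams,
    geometry: FilterGeometry | None = None,
) -> List[DetectedObject]:
    """Area and Feret gating; stable ids in reading order.

    Drops contours with pixel area below ``min_area_px`` (13 by default:
    the smallest retained area is exactly 13 px) and objects whose
    minimum Feret falls below / maximum Feret exceeds the physical gate.
    Objects touching the image border are discarded when
    ``drop_border_objects`` is set (partial objects have undefined
    morphology); with a filter ``geometry``, objects must lie fully
    inside the filter disc.
    """
    res = img.resolution_um_per_px
    kept = []
    for ct in contours:
        if ct.area_px < params.min_area_px:
            continue
        if params.drop_border_objects and ct.touches_border(img.shape):
            continue
        if geometry is not None and not _inside_disc(ct, geometry, res):
            continue
        d_min, d_max = feret_diameters(ct.mask, res)
        if d_min < params.min_feret_um or d_max > params.max_feret_um:
            continue
        kept.append((ct, d_min, d_max))
    kept.sort(key=lambda t: (t[0].bbox[0], t[0].bbox[1]))
    objects = []
    for i, (ct, d_min, d_max) in enumerate(kept):
        objects.append(
            DetectedObject(
                id=i,
                bbox=ct.bbox,
                mask=ct.mask,
                polygon=ct.polygon,
                area_px=ct.area_px,
                area_um2=ct.area_px * res**2,
                feret_min_um=d_min,
                feret_max_um=d_max,
            )
        )
    return objects


def _inside_disc(ct: Contour, geom: FilterGeometry, resolution: float) -> bool:
    cx, cy = geom.center_px
    r_px = geom.radius_px(resolution)
    rr, cc = np.nonzero(ct.mask)
    rr = rr + ct.bbox[0]
    cc = cc + ct.bbox[1]
    return bool(np.all((cc - cx) ** 2 + (rr - cy) ** 2 <= r_px**2))


def apply_counting_frame(
    objects: Sequence[DetectedObject],
    frame_um: Tuple[float, float, float, float],
    fov_shape: Tuple[int, int],
    resolution: float,
) -> List[DetectedObject]:
    """Unbiased counting-frame rule for window acquisition.

    ``frame_um`` is (x0, y0, x1, y1) strictly inside the field of view.
    Objects wholly inside the frame, or crossing only the inclusion
    edges (left, top), are kept; objects touching the exclusion edges
    (right, bottom) or the FOV border are dropped.  Tiling a plane with
    such frames counts each object exactly once.
    """
    x0, y0, x1, y1 = frame_um
    fov_w = (fov_shape[1] - 1) * resolution
    fov_h = (fov_shape[0] - 1) * resolution
    if not (0 < x0 < x1 < fov_w and 0 < y0 < y1 < fov_h):
        raise ValueError("counting frame must lie strictly inside the field of view")
    kept = []
    for obj in objects:
        rmin, cmin, rmax, cmax = obj.bbox
        if rmin == 0 or cmin == 0 or rmax == fov_shape[0] or cmax == fov_shape[1]:
            continue  # touches FOV border
        oxmin, oymin, oxmax, oymax = obj.extent_um(resolution)
        intersects = oxmax >= x0 and oxmin < x1 and oymax >= y0 and oymin < y1
        if intersects and oxmax < x1 and oymax < y1:
            kept.append(obj)
    return kept


def detect_objects(
    img: GrayImage,
    params: DetectionParams | None = None,
    geometry: FilterGeometry | None = None,
    frame_um: Tuple[float, float, float, float] | None = None,
) -> List[DetectedObject]:
    """Convenience wrapper: dual-pass detection, gating, optional frame."""
    if params is None:
        params = DetectionParams()
    contours = dual_pass_detect(img, params)
    objects = filter_contours(contours, img, params, geometry=geometry)
    if frame_um is not None:
        objects = apply_counting_frame(objects, frame_um, img.shape, img.resolution_um_per_px)
    return objects
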