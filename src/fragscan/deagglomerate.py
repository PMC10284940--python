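"""Adaptive de-agglomeration of touching particles.

Plain watershed splitting is prone to over-fragmentation, particularly
on fibers.  The adaptive variant restricts it to objects that plausibly
are agglomerates: non-fibrous objects with a distinctly concave outline.
The convexity (solidity, feature f4) threshold separating singular
particles from agglomerates is calibrated once with a 1-D Otsu on the
convexity distribution of a representative image; objects *below* the
threshold (the concave side) become candidates.

A candidate's masked grayscale patch is eroded (3x3, once) and
multiplied by the Euclidean distance transform of its mask; connected
regional maxima of that product map above a height fraction of its
maximum seed a marker-based watershed constrained to the parent mask.
A split is accepted only when it yields at least two children of at
least the detection minimum area (13 px); otherwise the parent stands.
Accepted children replace the parent in the size-classification output
while the all-particles output retains the parent row.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import ndimage
from skimage.morphology import local_maxima
from skimage.segmentation import watershed

from .detect import DetectedObject
from .raster_core import GrayImage
from .shape_morphology import boundary_polygon, feret_diameters, measurement_point, shape_features

__all__ = [
    "DeaggParams",
    "SplitRecord",
    "otsu_threshold_1d",
    "calibrate_convexity_threshold",
    "split_agglomerate",
    "deagglomerate_all",
]


@dataclass
class DeaggParams:
    convexity_threshold: Union[float, str] = "auto"  # value in (0,1) or "auto"
    marker_height_fraction: float = 0.5
    min_child_area_px: int = 13
    marker_smooth_sigma: float = 1.5  # px; merges texture-induced twin maxima
    invert_selection: bool = False  # select the convex side instead (diagnostic)

    def __post_init__(self) -> None:
        if isinstance(self.convexity_threshold, float) and not (0.0 < self.convexity_threshold < 1.0):
            raise ValueError("convexity threshold must lie in (0, 1)")
        if not (0.0 < self.marker_height_fraction < 1.0):
            raise ValueError("marker_height_fraction must lie in (0, 1)")


@dataclass
class SplitRecord:
    parent_id: int
    child_ids: List[int]
    accepted: bool


def otsu_threshold_1d(values: Sequence[float]) -> float:
    """Exact Otsu threshold on a 1-D sample.

    Maximizes the between-class variance over all midpoints between
    consecutive sorted distinct values (no histogram binning).  Raises
    when fewer than two distinct values exist.
    """
    v = np.sort(np.asarray(values, dtype=float))
    if v.size < 2 or v[0] == v[-1]:
        raise ValueError("need at least two distinct values")
    n = v.size
    csum = np.cumsum(v)
    total = csum[-1]
    k = np.arange(1, n)  # split: first k values below, rest above
    mu0 = csum[:-1] / k
    mu1 = (total - csum[:-1]) / (n - k)
    between = k * (n - k) * (mu0 - mu1) ** 2
    valid = v[1:] > v[:-1]  # only splits between distinct values
    between = np.where(valid, between, -np.inf)
    k_best = int(np.argmax(between)) + 1
    return float((v[k_best - 1] + v[k_best]) / 2.0)


def calibrate_convexity_threshold(
    convexities: Sequence[float],
    labels: Optional[Sequence[str]] = None,
) -> float:
    """Otsu split of a convexity (f4) distribution.

    ``labels`` ('single'/'agglomerate'), when given, are used only to
    validate the side assignment: agglomerates are expected below the
    threshold.  A warning-level mismatch raises, as it indicates the
    distribution is not bimodal in the expected orientation.
    """
    thr = otsu_threshold_1d(convexities)
    if labels is not None:
        conv = np.asarray(convexities, dtype=float)
        lab = np.asarray(labels)
        agg_below = np.mean(conv[lab == "agglomerate"] < thr) if np.any(lab == "agglomerate") else 1.0
        single_above = np.mean(conv[lab == "single"] >= thr) if np.any(lab == "single") else 1.0
        if agg_below < 0.5 or single_above < 0.5:
            raise ValueError(
                f"convexity threshold {thr:.3f} does not separate the labelled groups "
                f"(agglomerate-below={agg_below:.2f}, single-above={single_above:.2f})"
            )
    return thr


def split_agglomerate(
    obj: DetectedObject,
    img: GrayImage,
    params: DeaggParams,
    next_id: int = 0,
) -> List[DetectedObject]:
    """Watershed split of one candidate; children may number fewer than 2.

    Children are full objects (morphology, features, measurement point)
    carrying a parent link; those below ``min_child_area_px`` are
    discarded.  The caller decides acceptance (>= 2 children).
    """
    rmin, cmin, rmax, cmax = obj.bbox
    patch = img.pixels[rmin:rmax, cmin:cmax]
    mask = obj.mask
    eroded = ndimage.grey_erosion(np.where(mask, patch, 0.0), size=(3, 3))
    edt = ndimage.distance_transform_edt(mask)
    product = eroded * edt
    peak = product.max()
    if peak <= 0:
        return []
    # markers: regional maxima of the (lightly smoothed) product map, kept
    # when they reach the height fraction of the global peak.  Both guards
    # fight over-fragmentation, the known failure mode of plain watershed:
    # smoothing merges texture-induced twin maxima inside one grain, the
    # height gate drops shallow spurious maxima.
    smoothed = (
        ndimage.gaussian_filter(product, params.marker_smooth_sigma)
        if params.marker_smooth_sigma > 0
        else product
    )
    speak = smoothed.max()
    maxima = local_maxima(smoothed, connectivity=2) & mask
    labeled_max, n_max = ndimage.label(maxima, structure=np.ones((3, 3)))
    if n_max < 1:
        return []
    heights = ndimage.maximum(smoothed, labeled_max, index=np.arange(1, n_max + 1))
    keep_labels = np.nonzero(heights >= params.marker_height_fraction * speak)[0] + 1
    if keep_labels.size < 2:
        return []
    markers = np.where(np.isin(labeled_max, keep_labels), labeled_max, 0)
    markers, n_markers = ndimage.label(markers > 0, structure=np.ones((3, 3)))
    segmented = watershed(-product, markers=markers, mask=mask)
    children: List[DetectedObject] = []
    res = img.resolution_um_per_px
    for lab in range(1, n_markers + 1):
        child_mask_full = segmented == lab
        if child_mask_full.sum() < params.min_child_area_px:
            continue
        sl = ndimage.find_objects(child_mask_full.astype(np.int8))[0]
        child_mask = child_mask_full[sl]
        c_rmin = rmin + sl[0].start
        c_cmin = cmin + sl[1].start
        poly = boundary_polygon(child_mask) + np.array([c_rmin, c_cmin], dtype=float)
        d_min, d_max = feret_diameters(child_mask, res)
        child = DetectedObject(
            id=next_id + len(children),
            bbox=(c_rmin, c_cmin, c_rmin + child_mask.shape[0], c_cmin + child_mask.shape[1]),
            mask=child_mask,
            polygon=poly,
            area_px=int(child_mask.sum()),
            area_um2=float(child_mask.sum()) * res**2,
            feret_min_um=d_min,
            feret_max_um=d_max,
            parent_id=obj.id,
            provenance="deagglomerate",
        )
        child.features = shape_features(child_mask, res)
        child.shape_class = "particle"
        child_patch = img.pixels[child.bbox[0] : child.bbox[2], child.bbox[1] : child.bbox[3]]
        mcol, mrow = measurement_point(child_mask, child_patch)
        child.measurement_point_px = (child.bbox[1] + mcol, child.bbox[0] + mrow)
        children.append(child)
    return children


def deagglomerate_all(
    objects: Sequence[DetectedObject],
    img: GrayImage,
    params: DeaggParams,
) -> Tuple[List[DetectedObject], List[SplitRecord]]:
    """Split every selected candidate; fibers are never candidates.

    Candidates are non-fiber objects whose convexity (f4) lies below the
    threshold (Otsu-calibrated on the current scene when the threshold is
    ``"auto"``).  Returns the object list with accepted children appended
    (parents retained, children linked via ``parent_id``) plus one
    :class:`SplitRecord` per attempted candidate.
    """
    objects = list(objects)
    non_fiber = [o for o in objects if o.shape_class != "fiber" and o.features is not None]
    if isinstance(params.convexity_threshold, str):
        if params.convexity_threshold != "auto":
            raise ValueError("convexity_threshold must be a float or 'auto'")
        convexities = [o.features.f4 for o in non_fiber]
        try:
            threshold = otsu_threshold_1d(convexities)
        except ValueError:
            return objects, []
    else:
        threshold = params.convexity_threshold
    if params.invert_selection:
        candidates = [o for o in non_fiber if o.features.f4 >= threshold]
    else:
        candidates = [o for o in non_fiber if o.features.f4 < threshold]
    records: List[SplitRecord] = []
    out = objects
    next_id = max((o.id for o in objects), default=-1) + 1
    for obj in candidates:
        children = split_agglomerate(obj, img, params, next_id=next_id)
        accepted = len(children) >= 2
        if accepted:
            out = out + children
            next_id += len(children)
            records.append(SplitRecord(obj.id, [c.id for c in children], True))
        else:
            records.append(SplitRecord(obj.id, [], False))
    return out, records
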