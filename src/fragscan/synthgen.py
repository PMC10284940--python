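"""Seeded synthetic dark-field scenes with ground truth.

Emulates micrographs of gold-coated track-etched membranes: a dark base
with a jittered lattice of faint pore disks, Gaussian sensor noise and a
smooth illumination gradient, plus bright sample objects — ellipsoidal
particles, constant-width smoothly curved fibers, and agglomerates
(clusters of overlapping blobs).  Object edges get a 1-px Gaussian
falloff so that threshold-boundary behaviour is exercised realistically.
Placement is either completely spatially random (CSR) or clustered via a
parent-offspring (Neyman-Scott type) process, which produces the
between-window overdispersion that distinguishes bootstrap-estimable
from between-campaign variance.

Everything is deterministic under the scene seed.  The generator also
produces synthetic spectral-identification tables (material labels plus
hit-quality indices) and a labelled single-object set for training the
fiber classifier; a :class:`VirtualFilter` serves whole-filter scenes
window by window for subsampling campaigns.

What this does *not* emulate: physically accurate dark-field optics
(diffraction rings, glare of highly reflective particles), focus drift,
or stitching artefacts of real exports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .fiber_classify import LabeledContourSet
from .raster_core import FilterGeometry, GrayImage
from .report import IdentificationRecord
from .shape_morphology import shape_features

__all__ = [
    "SceneSpec",
    "PlantedObject",
    "GroundTruth",
    "generate_background",
    "generate_scene",
    "generate_id_table",
    "generate_labeled_set",
    "VirtualFilter",
]

PLASTIC_MATERIALS = ("PS", "PET", "PLA")


@dataclass
class SceneSpec:
    """Scene parameters; defaults emulate the high-magnification regime.

    The default resolution of 0.25 µm/px makes a 1 µm fragment span
    about 13 px of area, matching the minimum-pixel-count rationale of
    the detection gate; the default canvas is a 120 µm field of view.
    """

    shape_px: Tuple[int, int] = (480, 480)
    resolution_um_per_px: float = 0.25
    # background
    background_level: float = 12.0
    pore_spacing_um: float = 2.5
    pore_radius_um: float = 0.4
    pore_contrast: float = 8.0
    noise_sd: float = 2.0
    gradient_amplitude: float = 6.0
    # objects
    n_particles: int = 30
    particle_diameter_um: Tuple[float, float] = (2.0, 8.0)
    particle_aspect: Tuple[float, float] = (1.0, 2.0)
    particle_intensity: Tuple[float, float] = (120.0, 220.0)
    n_fibers: int = 3
    fiber_length_um: Tuple[float, float] = (20.0, 60.0)
    fiber_width_um: Tuple[float, float] = (1.5, 3.0)
    fiber_curvature: float = 0.10  # heading jitter, rad per px step
    n_agglomerates: int = 0
    agglomerate_cluster_size: Tuple[int, int] = (3, 6)
    agglomerate_overlap: float = 0.3  # centre offset = (1 - overlap) * mean radius
    # placement
    placement: str = "csr"  # 'csr' | 'clustered'
    cluster_radius_um: float = 20.0
    mean_cluster_size: float = 5.0
    margin_px: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.placement not in ("csr", "clustered"):
            raise ValueError("placement must be 'csr' or 'clustered'")
        for lo, hi in (self.particle_diameter_um, self.fiber_length_um, self.fiber_width_um):
            if not (0 < lo <= hi):
                raise ValueError("size ranges must be positive and ordered")


@dataclass
class PlantedObject:
    """Ground-truth record for one planted object."""

    kind: str  # 'particle' | 'fiber' | 'agglomerate'
    bbox: Tuple[int, int, int, int]
    mask: np.ndarray  # local boolean, pre-blur
    center_px: Tuple[float, float]  # (col, row)
    size_um: float  # diameter for particles, curve length for fibers
    cluster_id: int = -1
    n_members: int = 1  # constituent blobs for agglomerates

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())


@dataclass
class GroundTruth:
    objects: List[PlantedObject]
    spec: SceneSpec

    @property
    def counts(self) -> dict:
        out: dict = {}
        for o in self.objects:
            out[o.kind] = out.get(o.kind, 0) + 1
        return out


# ---------------------------------------------------------------------------
# background
# ---------------------------------------------------------------------------

def generate_background(spec: SceneSpec, rng: np.random.Generator | None = None) -> GrayImage:
    """Dark base + jittered pore lattice + illumination gradient + noise."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    H, W = spec.shape_px
    img = np.full((H, W), spec.background_level, dtype=np.float64)
    res = spec.resolution_um_per_px
    spacing = spec.pore_spacing_um / res
    r_pore = spec.pore_radius_um / res
    if spec.pore_contrast > 0 and r_pore > 0:
        stamp = _disk_stamp(r_pore)
        sh, sw = stamp.shape
        ny = int(H / spacing) + 2
        nx = int(W / spacing) + 2
        jitter = rng.uniform(-0.3, 0.3, size=(ny, nx, 2)) * spacing
        for i in range(ny):
            for j in range(nx):
                cy = i * spacing + jitter[i, j, 0]
                cx = j * spacing + jitter[i, j, 1]
                _add_stamp(img, stamp * spec.pore_contrast, cy, cx)
    if spec.gradient_amplitude > 0:
        theta = rng.uniform(0, 2 * math.pi)
        yy, xx = np.mgrid[0:H, 0:W]
        ramp = (xx * math.cos(theta) + yy * math.sin(theta)) / max(H, W)
        ramp = (ramp - ramp.min()) / max(float(np.ptp(ramp)), 1e-12)
        img += spec.gradient_amplitude * ramp
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=(H, W))
    return GrayImage(np.clip(img, 0, None), res)


def _disk_stamp(radius: float) -> np.ndarray:
    r = max(int(math.ceil(radius)), 1)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (yy**2 + xx**2 <= radius**2).astype(np.float64)


def _add_stamp(img: np.ndarray, stamp: np.ndarray, cy: float, cx: float) -> None:
    sh, sw = stamp.shape
    r0 = int(round(cy)) - sh // 2
    c0 = int(round(cx)) - sw // 2
    r1, c1 = r0 + sh, c0 + sw
    H, W = img.shape
    sr0, sc0 = max(0, -r0), max(0, -c0)
    sr1, sc1 = sh - max(0, r1 - H), sw - max(0, c1 - W)
    if sr0 >= sr1 or sc0 >= sc1:
        return
    img[max(r0, 0) : min(r1, H), max(c0, 0) : min(c1, W)] += stamp[sr0:sr1, sc0:sc1]


# ---------------------------------------------------------------------------
# object rasterisation (integer-lattice, platform independent)
# ---------------------------------------------------------------------------

def _raster_ellipse(rng: np.random.Generator, diam_px: float, aspect: float) -> np.ndarray:
    a = diam_px / 2.0
    b = a / aspect
    theta = rng.uniform(0, math.pi)
    r = int(math.ceil(a)) + 1
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    ct, st = math.cos(theta), math.sin(theta)
    u = xx * ct + yy * st
    v = -xx * st + yy * ct
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _raster_blob(rng: np.random.Generator, diam_px: float) -> np.ndarray:
    """Irregular particle: radially perturbed disk."""
    a = diam_px / 2.0
    n_harm = 4
    amps = rng.uniform(0.0, 0.35, size=n_harm) * a
    phases = rng.uniform(0, 2 * math.pi, size=n_harm)
    r = int(math.ceil(a * 1.5)) + 1
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    ang = np.arctan2(yy, xx)
    radius = a + sum(amps[k] * np.cos((k + 2) * ang + phases[k]) for k in range(n_harm))
    radius = np.clip(radius, a * 0.3, None)
    return np.hypot(yy, xx) <= radius


def _raster_fiber(
    rng: np.random.Generator, length_px: float, width_px: float, curvature: float
) -> Tuple[np.ndarray, float]:
    """Constant-width smooth random curve; returns (mask, arc length px)."""
    n_steps = max(int(round(length_px)), 3)
    theta = rng.uniform(0, 2 * math.pi)
    pos = np.zeros((n_steps, 2))
    for i in range(1, n_steps):
        theta += rng.normal(0.0, curvature)
        pos[i] = pos[i - 1] + (math.cos(theta), math.sin(theta))
    pos -= pos.min(axis=0)
    half_w = width_px / 2.0
    pad = int(math.ceil(half_w)) + 2
    H = int(math.ceil(pos[:, 1].max())) + 2 * pad + 1
    W = int(math.ceil(pos[:, 0].max())) + 2 * pad + 1
    mask = np.zeros((H, W), dtype=bool)
    stamp = _disk_stamp(half_w).astype(bool)
    for x, y in pos:
        _or_stamp(mask, stamp, y + pad, x + pad)
    return mask, float(n_steps - 1)


def _or_stamp(mask: np.ndarray, stamp: np.ndarray, cy: float, cx: float) -> None:
    sh, sw = stamp.shape
    r0 = int(round(cy)) - sh // 2
    c0 = int(round(cx)) - sw // 2
    H, W = mask.shape
    r1, c1 = r0 + sh, c0 + sw
    sr0, sc0 = max(0, -r0), max(0, -c0)
    sr1, sc1 = sh - max(0, r1 - H), sw - max(0, c1 - W)
    if sr0 >= sr1 or sc0 >= sc1:
        return
    mask[max(r0, 0) : min(r1, H), max(c0, 0) : min(c1, W)] |= stamp[sr0:sr1, sc0:sc1]


def _raster_agglomerate(
    rng: np.random.Generator, spec: SceneSpec
) -> Tuple[np.ndarray, int, float]:
    """Cluster of overlapping ellipses; returns (mask, n members, extent µm)."""
    res = spec.resolution_um_per_px
    k = int(rng.integers(spec.agglomerate_cluster_size[0], spec.agglomerate_cluster_size[1] + 1))
    diams = rng.uniform(*spec.particle_diameter_um, size=k) / res
    mean_r = float(np.mean(diams)) / 2.0
    step = max((1.0 - spec.agglomerate_overlap) * 2 * mean_r, 1.0)
    size = int(math.ceil(step * k + diams.max())) + 4
    mask = np.zeros((size, size), dtype=bool)
    cy = cx = size / 2.0
    for d in diams:
        blob = _raster_ellipse(rng, d, rng.uniform(1.0, 1.5))
        _or_stamp(mask, blob, cy, cx)
        ang = rng.uniform(0, 2 * math.pi)
        cy += step * math.sin(ang)
        cx += step * math.cos(ang)
        cy = min(max(cy, diams.max()), size - diams.max())
        cx = min(max(cx, diams.max()), size - diams.max())
    # keep the largest connected component (steps may disconnect)
    labels, n = ndimage.label(mask, structure=np.ones((3, 3)))
    if n > 1:
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    extent_um = max(mask.shape) * res
    return mask, k, extent_um


# ---------------------------------------------------------------------------
# placement + scene assembly
# ---------------------------------------------------------------------------

def _draw_positions(rng: np.random.Generator, n: int, spec: SceneSpec) -> Tuple[np.ndarray, np.ndarray]:
    """(n, 2) float (row, col) positions + cluster ids."""
    H, W = spec.shape_px
    m = spec.margin_px
    if spec.placement == "csr" or n == 0:
        pos = rng.uniform([m, m], [H - m, W - m], size=(n, 2))
        return pos, np.full(n, -1, dtype=int)
    # Neyman-Scott: parents CSR, offspring Gaussian around parents
    sigma = spec.cluster_radius_um / spec.resolution_um_per_px
    n_parents = max(int(round(n / spec.mean_cluster_size)), 1)
    parents = rng.uniform([m, m], [H - m, W - m], size=(n_parents, 2))
    which = rng.integers(0, n_parents, size=n)
    pos = parents[which] + rng.normal(0, sigma, size=(n, 2))
    pos = np.clip(pos, [m, m], [H - m, W - m])
    return pos, which


def generate_scene(spec: SceneSpec) -> Tuple[GrayImage, GroundTruth]:
    """Render a full scene and its ground truth.

    Object layers are rendered from integer-lattice masks, given soft
    edges with a 1-px Gaussian falloff and added to the background; the
    ground-truth masks are the pre-blur rasters.
    """
    rng = np.random.default_rng(spec.seed)
    background = generate_background(spec, rng=rng)
    H, W = spec.shape_px
    res = spec.resolution_um_per_px
    layer = np.zeros((H, W), dtype=np.float64)
    objects: List[PlantedObject] = []

    n_total = spec.n_particles + spec.n_fibers + spec.n_agglomerates
    positions, cluster_ids = _draw_positions(rng, n_total, spec)
    cursor = 0

    for _ in range(spec.n_particles):
        d_um = rng.uniform(*spec.particle_diameter_um)
        aspect = rng.uniform(*spec.particle_aspect)
        mask = (
            _raster_ellipse(rng, d_um / res, aspect)
            if rng.random() < 0.5
            else _raster_blob(rng, d_um / res)
        )
        objects.append(_plant(layer, mask, positions[cursor], rng, spec, "particle", d_um, cluster_ids[cursor]))
        cursor += 1
    for _ in range(spec.n_fibers):
        L_um = rng.uniform(*spec.fiber_length_um)
        w_um = rng.uniform(*spec.fiber_width_um)
        mask, arc_px = _raster_fiber(rng, L_um / res, w_um / res, spec.fiber_curvature)
        objects.append(_plant(layer, mask, positions[cursor], rng, spec, "fiber", arc_px * res, cluster_ids[cursor]))
        cursor += 1
    for _ in range(spec.n_agglomerates):
        mask, k, extent_um = _raster_agglomerate(rng, spec)
        obj = _plant(layer, mask, positions[cursor], rng, spec, "agglomerate", extent_um, cluster_ids[cursor])
        obj.n_members = k
        objects.append(obj)
        cursor += 1

    soft = ndimage.gaussian_filter(layer, sigma=1.0)
    pixels = np.clip(background.pixels + soft, 0, None)
    return GrayImage(pixels, res), GroundTruth(objects=[o for o in objects if o is not None], spec=spec)


def _plant(
    layer: np.ndarray,
    mask: np.ndarray,
    pos: np.ndarray,
    rng: np.random.Generator,
    spec: SceneSpec,
    kind: str,
    size_um: float,
    cluster_id: int,
) -> PlantedObject:
    intensity = rng.uniform(*spec.particle_intensity)
    H, W = layer.shape
    sh, sw = mask.shape
    r0 = int(round(pos[0])) - sh // 2
    c0 = int(round(pos[1])) - sw // 2
    r0 = min(max(r0, 0), max(H - sh, 0))
    c0 = min(max(c0, 0), max(W - sw, 0))
    mask = mask[: H - r0, : W - c0]
    region = layer[r0 : r0 + mask.shape[0], c0 : c0 + mask.shape[1]]
    np.maximum(region, np.where(mask, intensity, 0.0), out=region)
    return PlantedObject(
        kind=kind,
        bbox=(r0, c0, r0 + mask.shape[0], c0 + mask.shape[1]),
        mask=mask.copy(),
        center_px=(c0 + mask.shape[1] / 2.0, r0 + mask.shape[0] / 2.0),
        size_um=size_um,
        cluster_id=int(cluster_id),
    )


# ---------------------------------------------------------------------------
# identification tables
# ---------------------------------------------------------------------------

def generate_id_table(
    spots_um: Sequence[Tuple[float, float]],
    plastic_ratio: float,
    seed: int = 0,
    hqi_plastic: Tuple[float, float] = (0.75, 0.15),
    hqi_other: Tuple[float, float] = (0.30, 0.10),
) -> List[IdentificationRecord]:
    """Synthetic spectral-identification output for measured spots.

    Each spot gets a material drawn with probability ``plastic_ratio``
    from the plastic set (else 'mineral') and a hit-quality index from a
    clipped normal per class; sub-0.45 indices exercise the unassigned
    path downstream.
    """
    rng = np.random.default_rng(seed)
    records = []
    for x, y in spots_um:
        if rng.random() < plastic_ratio:
            material = PLASTIC_MATERIALS[int(rng.integers(len(PLASTIC_MATERIALS)))]
            hqi = float(np.clip(rng.normal(*hqi_plastic), 0.0, 1.0))
        else:
            material = "mineral"
            hqi = float(np.clip(rng.normal(*hqi_other), 0.0, 1.0))
        records.append(IdentificationRecord(x_um=float(x), y_um=float(y), material=material, hqi=hqi))
    return records


# ---------------------------------------------------------------------------
# labelled set for the fiber classifier
# ---------------------------------------------------------------------------

def generate_labeled_set(
    n_fibers: int = 500,
    n_particles: int = 1500,
    resolution_um_per_px: float = 0.25,
    seed: int = 7,
) -> LabeledContourSet:
    """Features of rendered single objects: fibers vs particles.

    Fibers are rasterized random smooth curves spanning straight to
    strongly curved; particles are ellipses, irregular blobs and small
    agglomerate-like clusters.  Features are measured by the same
    morphology code used in the detection pipeline.
    """
    rng = np.random.default_rng(seed)
    res = resolution_um_per_px
    feats, labels = [], []
    spec = SceneSpec(resolution_um_per_px=res, seed=seed)
    for _ in range(n_fibers):
        L = rng.uniform(15.0, 80.0) / res
        w = rng.uniform(1.0, 3.0) / res
        curv = rng.uniform(0.0, 0.25)
        mask, _ = _raster_fiber(rng, L, w, curv)
        feats.append(shape_features(mask, res).as_array())
        labels.append("fiber")
    for i in range(n_particles):
        d = rng.uniform(1.5, 12.0) / res
        u = rng.random()
        if u < 0.4:
            mask = _raster_ellipse(rng, d, rng.uniform(1.0, 3.0))
        elif u < 0.8:
            mask = _raster_blob(rng, d)
        else:
            mask, _, _ = _raster_agglomerate(rng, spec)
        feats.append(shape_features(mask, res).as_array())
        labels.append("particle")
    return LabeledContourSet(np.array(feats), np.array(labels), provenance=f"synthetic seed={seed}")


# ---------------------------------------------------------------------------
# virtual filter for subsampling campaigns
# ---------------------------------------------------------------------------

@dataclass
class VirtualFilter:
    """A whole-filter synthetic scene served window by window.

    Object centres for the entire filter disc are drawn once (CSR or
    clustered) at construction; ``fov_image`` renders the field of view
    around any window centre, so overlapping windows see consistent
    content.  ``true_total`` is the planted object count — the estimand
    of a subsampling campaign.
    """

    geometry: FilterGeometry
    mean_per_window_area: float  # expected objects per window-area unit (see density)
    window_area_um2: float
    fov_side_um: float = 120.0
    resolution_um_per_px: float = 0.5
    # smallest planted diameter kept comfortably above the 13-px area gate
    # at the default simulation resolution
    particle_diameter_um: Tuple[float, float] = (2.5, 5.0)
    intensity: Tuple[float, float] = (140.0, 220.0)
    placement: str = "csr"
    cluster_radius_um: float = 40.0
    mean_cluster_size: float = 8.0
    # optical condition drift: Gaussian defocus applied to the rendered FOV.
    # Campaign repeats with different values emulate altered measurement
    # conditions between otherwise identical measurements.
    defocus_sigma: float = 0.0
    seed: int = 0
    background: SceneSpec = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        rng = np.random.default_rng(self.seed)
        R = self.geometry.radius_um
        area = math.pi * R**2
        density = self.mean_per_window_area / self.window_area_um2
        n = rng.poisson(density * area)
        if self.placement == "csr":
            pts = _uniform_disc(rng, n, R)
            self._cluster = np.full(n, -1)
        elif self.placement == "clustered":
            n_par = max(int(round(n / self.mean_cluster_size)), 1)
            parents = _uniform_disc(rng, n_par, R)
            which = rng.integers(0, n_par, size=n)
            pts = parents[which] + rng.normal(0, self.cluster_radius_um, size=(n, 2))
            r = np.hypot(pts[:, 0], pts[:, 1])
            keep = r <= R
            pts = pts[keep]
            self._cluster = which[keep]
        else:
            raise ValueError("placement must be 'csr' or 'clustered'")
        self.centers_um = pts
        self.diameters_um = rng.uniform(*self.particle_diameter_um, size=len(pts))
        self.intensities = rng.uniform(*self.intensity, size=len(pts))
        self.angles = rng.uniform(0, math.pi, size=len(pts))
        self.aspects = rng.uniform(1.0, 1.6, size=len(pts))
        if self.background is None:
            self.background = SceneSpec(
                shape_px=self._fov_shape(),
                resolution_um_per_px=self.resolution_um_per_px,
                n_particles=0,
                n_fibers=0,
            )

    def _fov_shape(self) -> Tuple[int, int]:
        n = int(round(self.fov_side_um / self.resolution_um_per_px))
        return (n, n)

    @property
    def true_total(self) -> int:
        return len(self.centers_um)

    def fov_image(self, center_um: Tuple[float, float]) -> GrayImage:
        """Render the field of view centred on a window position."""
        cx, cy = center_um
        res = self.resolution_um_per_px
        H, W = self._fov_shape()
        x0 = cx - self.fov_side_um / 2.0
        y0 = cy - self.fov_side_um / 2.0
        # deterministic per-window background: seed derived from the centre
        key = (self.seed, int(round(cx * 1000)) & 0x7FFFFFFF, int(round(cy * 1000)) & 0x7FFFFFFF)
        bg_rng = np.random.default_rng(key)
        bg = generate_background(self.background, rng=bg_rng)
        layer = np.zeros((H, W), dtype=np.float64)
        margin = self.particle_diameter_um[1]
        near = (
            (self.centers_um[:, 0] >= x0 - margin)
            & (self.centers_um[:, 0] <= x0 + self.fov_side_um + margin)
            & (self.centers_um[:, 1] >= y0 - margin)
            & (self.centers_um[:, 1] <= y0 + self.fov_side_um + margin)
        )
        for i in np.nonzero(near)[0]:
            d_px = self.diameters_um[i] / res
            mask = _ellipse_at_angle(d_px, self.aspects[i], self.angles[i])
            row = (self.centers_um[i, 1] - y0) / res
            col = (self.centers_um[i, 0] - x0) / res
            stamp = np.where(mask, self.intensities[i], 0.0)
            _max_stamp(layer, stamp, row, col)
        soft = ndimage.gaussian_filter(layer, sigma=1.0)
        pixels = np.clip(bg.pixels + soft, 0, None)
        if self.defocus_sigma > 0:
            pixels = ndimage.gaussian_filter(pixels, self.defocus_sigma)
        return GrayImage(pixels, res)


def _uniform_disc(rng: np.random.Generator, n: int, R: float) -> np.ndarray:
    r = R * np.sqrt(rng.random(n))
    th = rng.uniform(0, 2 * math.pi, n)
    return np.stack([r * np.cos(th), r * np.sin(th)], axis=1)


def _ellipse_at_angle(diam_px: float, aspect: float, theta: float) -> np.ndarray:
    a = diam_px / 2.0
    b = a / aspect
    r = int(math.ceil(a)) + 1
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    ct, st = math.cos(theta), math.sin(theta)
    u = xx * ct + yy * st
    v = -xx * st + yy * ct
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _max_stamp(img: np.ndarray, stamp: np.ndarray, cy: float, cx: float) -> None:
    sh, sw = stamp.shape
    r0 = int(round(cy)) - sh // 2
    c0 = int(round(cx)) - sw // 2
    H, W = img.shape
    r1, c1 = r0 + sh, c0 + sw
    sr0, sc0 = max(0, -r0), max(0, -c0)
    sr1, sc1 = sh - max(0, r1 - H), sw - max(0, c1 - W)
    if sr0 >= sr1 or sc0 >= sc1:
        return
    region = img[max(r0, 0) : min(r1, H), max(c0, 0) : min(c1, W)]
    np.maximum(region, stamp[sr0:sr1, sc0:sc1], out=region)
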