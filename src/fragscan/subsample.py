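"""Subsampling regimes: random sampling (RS) and random window subsampling (RWS).

RS is used with full-filter imaging: when the number of detected objects
exceeds the intended measurement sample length (7000 by default, derived
from representativeness considerations at 90% confidence), a uniform
sample without replacement of exactly that size is drawn.

RWS is designed for high magnification, where imaging the whole filter
is impossible and stage-positioning error accumulates: square windows
(70 µm inside a 120 µm field of view by default) are placed uniformly at
random over the filter disc, each window is imaged, processed and
counted, and the total count on the filter is extrapolated by the area
proportion

    N_hat = (A_filter / (n * A_window)) * sum(counts).

After every tenth window (the CI cadence) a percentile bootstrap
confidence interval of the extrapolated total is computed from the
per-window counts (B = 1000 resamples, 90% nominal level) and the
campaign stops as soon as the relative half-width undercuts the stop
threshold — or earlier on the window / measured-fragment caps.  All
randomness flows from a single campaign seed, so a campaign is exactly
replayable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

from .detect import DetectedObject
from .raster_core import FilterGeometry, GrayImage

__all__ = [
    "RsParams",
    "RwsParams",
    "Campaign",
    "random_subsample",
    "place_windows",
    "extrapolate_total",
    "bootstrap_ci",
    "run_campaign",
]


@dataclass
class RsParams:
    sample_cap: int = 7000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_cap < 1:
            raise ValueError("sample_cap must be >= 1")


@dataclass
class RwsParams:
    window_side_um: float = 70.0
    fov_side_um: float = 120.0
    n_windows_max: int = 100
    ci_cadence: int = 10
    ci_level: float = 0.90
    n_bootstrap: int = 1000
    rel_error_stop: Optional[float] = None
    max_measured_fragments: Optional[int] = None
    max_time_s: Optional[float] = None
    seed: int = 0
    allow_overlap: bool = True

    def __post_init__(self) -> None:
        if not (self.window_side_um < self.fov_side_um):
            raise ValueError("window must be smaller than the field of view")
        if not (0.0 < self.ci_level < 1.0):
            raise ValueError("ci_level must lie in (0, 1)")
        if self.ci_cadence < 1:
            raise ValueError("ci_cadence must be >= 1")
        if self.n_windows_max < 1:
            raise ValueError("n_windows_max must be >= 1")

    @property
    def window_area_um2(self) -> float:
        return self.window_side_um**2


@dataclass
class Campaign:
    """State and history of one RWS measurement campaign."""

    geometry: FilterGeometry
    params: RwsParams
    window_centers_um: List[Tuple[float, float]] = field(default_factory=list)
    window_counts: List[int] = field(default_factory=list)
    window_fiber_counts: List[int] = field(default_factory=list)
    objects_per_window: List[List[DetectedObject]] = field(default_factory=list)
    ci_history: List[Tuple[int, float, float, float]] = field(default_factory=list)
    stop_reason: Optional[str] = None

    @property
    def n_windows(self) -> int:
        return len(self.window_counts)

    @property
    def final_estimate(self) -> float:
        return extrapolate_total(self.window_counts, self.geometry, self.params)

    @property
    def final_ci(self) -> Optional[Tuple[float, float, float]]:
        if not self.ci_history:
            return None
        n, low, high, point = self.ci_history[-1]
        return (low, high, point)


def random_subsample(objects: Sequence[DetectedObject], params: RsParams) -> List[DetectedObject]:
    """Uniform sample without replacement of at most ``sample_cap`` objects."""
    objects = list(objects)
    if len(objects) <= params.sample_cap:
        return objects
    rng = np.random.default_rng(params.seed)
    idx = rng.choice(len(objects), size=params.sample_cap, replace=False)
    return [objects[i] for i in sorted(idx)]


def place_windows(
    geom: FilterGeometry,
    params: RwsParams,
    n: int,
    rng: np.random.Generator | None = None,
) -> List[Tuple[float, float]]:
    """Draw n window centres uniformly over the admissible region.

    A centre is admissible when the square window lies fully inside the
    filter disc (checked on the farthest window corner; rejection
    sampling from the disc's bounding square).  Overlaps between windows
    are permitted.  Centres are physical (x, y) µm relative to the disc
    centre's physical position.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    half = params.window_side_um / 2.0
    R = geom.radius_um
    if params.window_side_um > geom.diameter_um:
        raise ValueError("window larger than the filter disc")
    if math.hypot(half, half) > R:
        raise ValueError("window does not fit inside the filter disc")
    centers: List[Tuple[float, float]] = []
    max_center_r2 = (R - math.hypot(half, half)) ** 2  # quick-accept radius
    budget = 100000 * max(n, 1)
    while len(centers) < n and budget > 0:
        m = min(4 * (n - len(centers)) + 16, 65536)
        budget -= m
        xy = rng.uniform(-R, R, size=(m, 2))
        dx = np.abs(xy[:, 0]) + half
        dy = np.abs(xy[:, 1]) + half
        ok = dx**2 + dy**2 <= R**2
        for x, y in xy[ok]:
            if len(centers) < n:
                if not params.allow_overlap and any(
                    abs(x - cx) < params.window_side_um and abs(y - cy) < params.window_side_um for cx, cy in centers
                ):
                    continue
                centers.append((float(x), float(y)))
    if len(centers) < n:
        raise RuntimeError("window placement rejection budget exceeded")
    return centers


def extrapolate_total(
    counts: Sequence[float],
    geom: FilterGeometry,
    params: RwsParams,
) -> float:
    """Area-proportion extrapolation of window counts to the whole filter."""
    counts = np.asarray(counts, dtype=float)
    if counts.size == 0:
        raise ValueError("need at least one window")
    filter_area = math.pi * geom.radius_um**2
    factor = filter_area / (counts.size * params.window_area_um2)
    return float(factor * counts.sum())


def bootstrap_ci(
    window_counts: Sequence[float],
    geom: FilterGeometry,
    params: RwsParams,
    rng: np.random.Generator | None = None,
) -> Tuple[float, float, float]:
    """Percentile bootstrap interval of the extrapolated total.

    Returns ``(low, high, point)``.  The window-count list is resampled
    with replacement B times; the interval is taken from the percentile
    quantiles of the extrapolated statistic at the nominal level.  With
    identical counts the interval has zero width.
    """
    counts = np.asarray(window_counts, dtype=float)
    if counts.size < 2:
        raise ValueError("need at least two windows for a bootstrap interval")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    point = extrapolate_total(counts, geom, params)
    filter_area = math.pi * geom.radius_um**2
    factor = filter_area / (counts.size * params.window_area_um2)
    idx = rng.integers(0, counts.size, size=(params.n_bootstrap, counts.size))
    totals = factor * counts[idx].sum(axis=1)
    alpha = 1.0 - params.ci_level
    low, high = np.quantile(totals, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(low), float(high), float(point)


def run_campaign(
    scene_source: Callable[[Tuple[float, float]], GrayImage],
    geom: FilterGeometry,
    params: RwsParams,
    process_window: Callable[[GrayImage], List[DetectedObject]],
    keep_objects: bool = True,
) -> Campaign:
    """Run the RWS measurement loop until a stopping criterion fires.

    ``scene_source`` maps a window centre (x, y µm, disc-centred) to the
    field-of-view image; ``process_window`` runs the per-window pipeline
    (preprocess, detect, counting frame, classify, de-agglomerate) and
    returns the accepted objects whose count enters the estimator.

    Criteria precedence: the fragment and window caps are checked every
    window; the uncertainty threshold only at the CI cadence.
    """
    import time as _time

    t_start = _time.monotonic()
    rng = np.random.default_rng(params.seed)
    centers = place_windows(geom, params, params.n_windows_max, rng=rng)
    campaign = Campaign(geometry=geom, params=params)
    measured = 0
    for i, center in enumerate(centers):
        fov = scene_source(center)
        objects = process_window(fov)
        campaign.window_centers_um.append(center)
        campaign.window_counts.append(len(objects))
        campaign.window_fiber_counts.append(
            sum(1 for o in objects if getattr(o, "shape_class", None) == "fiber")
        )
        if keep_objects:
            campaign.objects_per_window.append(objects)
        measured += len(objects)
        n = campaign.n_windows
        if params.max_measured_fragments is not None and measured >= params.max_measured_fragments:
            campaign.stop_reason = "max fragments"
            break
        if params.max_time_s is not None and _time.monotonic() - t_start >= params.max_time_s:
            campaign.stop_reason = "max time"
            break
        if n % params.ci_cadence == 0 and n >= 2:
            low, high, point = bootstrap_ci(campaign.window_counts, geom, params, rng=rng)
            campaign.ci_history.append((n, low, high, point))
            if params.rel_error_stop is not None and point > 0:
                rel_half_width = (high - low) / 2.0 / point
                if rel_half_width <= params.rel_error_stop:
                    campaign.stop_reason = "uncertainty undercut"
                    break
        if n >= params.n_windows_max:
            campaign.stop_reason = "max windows"
            break
    if campaign.stop_reason is None:
        campaign.stop_reason = "max windows"
    if not campaign.ci_history and campaign.n_windows >= 2:
        low, high, point = bootstrap_ci(campaign.window_counts, geom, params, rng=rng)
        campaign.ci_history.append((campaign.n_windows, low, high, point))
    return campaign
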