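"""End-to-end orchestration of the two analysis branches.

RS (random sampling, full-filter imaging): circular mask → preprocess →
detect → morphology/classification → de-agglomeration → random
subsample of objects for measurement → merge with identification table →
size classification and outputs.

RWS (random window subsampling): loop of window placement → field-of-view
acquisition → preprocess → detect → counting frame → classification →
de-agglomeration → count accumulation, with bootstrap confidence
intervals at a fixed cadence and early stopping, followed by
area-proportion extrapolation and the same reporting.

Everything is driven by a single :class:`RunConfig` (YAML-loadable);
every output directory receives the exact configuration and seeds needed
to replay the run.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import yaml

from . import __version__
from .deagglomerate import DeaggParams, deagglomerate_all
from .detect import DetectedObject, DetectionParams, detect_objects
from .fiber_classify import ClassifierModel, load_model, predict_shape_class
from .preprocess import PreprocessParams, preprocess
from .raster_core import FilterGeometry, GrayImage, load_image
from .report import (
    DEFAULT_SIZE_BINS_UM,
    IdentificationRecord,
    make_overlay,
    merge_by_spot,
    size_classify,
    write_outputs,
)
from .shape_morphology import measurement_point, shape_features, skeleton_stats
from .subsample import Campaign, RsParams, RwsParams, random_subsample, run_campaign

logger = logging.getLogger("fragscan")

__all__ = ["RunConfig", "characterize_objects", "WindowPipeline", "run_rs", "run_rws", "run"]


@dataclass
class RunConfig:
    """All parameter blocks of a run plus the master seed."""

    mode: str = "rs"  # 'rs' | 'rws'
    image_path: Optional[str] = None
    resolution_um_per_px: float = 0.873
    filter_diameter_mm: float = 20.0
    filter_center_px: Optional[Tuple[float, float]] = None
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    detection: DetectionParams = field(default_factory=DetectionParams)
    deagglomeration: DeaggParams = field(default_factory=DeaggParams)
    rs: RsParams = field(default_factory=RsParams)
    rws: RwsParams = field(default_factory=RwsParams)
    size_bins_um: Tuple[float, ...] = DEFAULT_SIZE_BINS_UM
    model_path: Optional[str] = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in ("rs", "rws"):
            raise ValueError("mode must be 'rs' or 'rws'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        for key, sub in (
            ("preprocess", PreprocessParams),
            ("detection", DetectionParams),
            ("deagglomeration", DeaggParams),
            ("rs", RsParams),
            ("rws", RwsParams),
        ):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = sub(**kwargs[key])
        if "size_bins_um" in kwargs:
            kwargs["size_bins_um"] = tuple(kwargs["size_bins_um"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["version"] = __version__
        return out


def characterize_objects(
    objects: Sequence[DetectedObject],
    img: GrayImage,
    model: Optional[ClassifierModel],
    f6_mode: str = "width",
) -> List[DetectedObject]:
    """Shape features, class, fiber length and measurement point per object."""
    res = img.resolution_um_per_px
    for obj in objects:
        skel = skeleton_stats(obj.mask, res)
        obj.features = shape_features(obj.mask, res, skel=skel, f6_mode=f6_mode)
        if model is not None:
            obj.shape_class, obj.fiber_prob = predict_shape_class(obj.features, model)
        else:
            obj.shape_class = "particle"
            obj.fiber_prob = 0.0
        if obj.shape_class == "fiber":
            obj.fiber_length_um = skel.longest_path_um if skel.valid else obj.feret_max_um
        rmin, cmin, rmax, cmax = obj.bbox
        patch = img.pixels[rmin:rmax, cmin:cmax]
        mcol, mrow = measurement_point(obj.mask, patch)
        obj.measurement_point_px = (cmin + mcol, rmin + mrow)
    return list(objects)


@dataclass
class WindowPipeline:
    """The per-window processing chain used inside an RWS campaign."""

    preprocess_params: PreprocessParams = field(default_factory=PreprocessParams)
    detection_params: DetectionParams = field(default_factory=DetectionParams)
    deagg_params: DeaggParams = field(default_factory=DeaggParams)
    window_side_um: float = 70.0
    fov_side_um: float = 120.0
    model: Optional[ClassifierModel] = None
    enable_deagglomeration: bool = True

    def frame_um(self) -> Tuple[float, float, float, float]:
        off = (self.fov_side_um - self.window_side_um) / 2.0
        return (off, off, off + self.window_side_um, off + self.window_side_um)

    def __call__(self, fov: GrayImage) -> List[DetectedObject]:
        pre = preprocess(fov, self.preprocess_params)
        objects = detect_objects(pre, self.detection_params, frame_um=self.frame_um())
        objects = characterize_objects(objects, pre, self.model)
        if self.enable_deagglomeration and objects:
            objects, splits = deagglomerate_all(objects, pre, self.deagg_params)
            accepted = {s.parent_id for s in splits if s.accepted}
            objects = [o for o in objects if o.id not in accepted]
        return objects


def run_rs(
    config: RunConfig,
    out_dir: str | Path,
    img: Optional[GrayImage] = None,
    records: Sequence[IdentificationRecord] = (),
    model: Optional[ClassifierModel] = None,
) -> dict:
    """Full-filter branch; returns a summary dict and writes artefacts."""
    _setup_logging(config.log_level)
    if img is None:
        if config.image_path is None:
            raise ValueError("RS mode needs an image (path or in-memory)")
        img = load_image(config.image_path, config.resolution_um_per_px)
    if model is None and config.model_path:
        model = load_model(config.model_path)
    geometry = None
    if config.filter_center_px is not None:
        geometry = FilterGeometry(tuple(config.filter_center_px), config.filter_diameter_mm * 1000.0)
        from .raster_core import apply_circular_mask

        img = apply_circular_mask(img, geometry)
    logger.info("RS: preprocessing %dx%d image", img.height, img.width)
    pre = preprocess(img, config.preprocess)
    objects = detect_objects(pre, config.detection, geometry=geometry)
    logger.info("RS: %d objects detected", len(objects))
    objects = characterize_objects(objects, pre, model)
    objects, splits = deagglomerate_all(objects, pre, config.deagglomeration)
    measured = random_subsample(objects, config.rs)
    measured_ids = {o.id for o in measured}
    merged = merge_by_spot(objects, list(records), img.resolution_um_per_px)
    size_table = size_classify(merged, splits, config.size_bins_um)
    overlay = make_overlay(pre, objects)
    meta = {"config": _plain(config.to_dict()), "n_objects": len(objects), "n_measured": len(measured)}
    paths = write_outputs(out_dir, merged, size_table, overlay=overlay, metadata=meta)
    import pandas as pd

    pd.DataFrame(
        [
            {"parent_id": s.parent_id, "child_ids": ";".join(map(str, s.child_ids)), "accepted": s.accepted}
            for s in splits
        ],
        columns=["parent_id", "child_ids", "accepted"],
    ).to_csv(Path(out_dir) / "splits.csv", index=False)
    return {
        "objects": objects,
        "splits": splits,
        "measured_ids": measured_ids,
        "merged": merged,
        "size_table": size_table,
        "paths": paths,
    }


def run_rws(
    config: RunConfig,
    out_dir: str | Path,
    scene_source,
    model: Optional[ClassifierModel] = None,
) -> Campaign:
    """Window-loop branch; ``scene_source`` maps window centre → FOV image."""
    _setup_logging(config.log_level)
    if model is None and config.model_path:
        model = load_model(config.model_path)
    geometry = FilterGeometry((0.0, 0.0), config.filter_diameter_mm * 1000.0)
    pipeline = WindowPipeline(
        preprocess_params=config.preprocess,
        detection_params=config.detection,
        deagg_params=config.deagglomeration,
        window_side_um=config.rws.window_side_um,
        fov_side_um=config.rws.fov_side_um,
        model=model,
    )
    campaign = run_campaign(scene_source, geometry, config.rws, pipeline)
    logger.info(
        "RWS: %d windows, stop=%s, estimate=%.1f",
        campaign.n_windows,
        campaign.stop_reason,
        campaign.final_estimate,
    )
    _write_campaign(Path(out_dir), campaign, config)
    return campaign


def _write_campaign(out_dir: Path, campaign: Campaign, config: RunConfig) -> None:
    import pandas as pd

    out_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "x_um": [c[0] for c in campaign.window_centers_um],
            "y_um": [c[1] for c in campaign.window_centers_um],
            "count": campaign.window_counts,
            "fiber_count": campaign.window_fiber_counts,
        }
    ).to_csv(out_dir / "windows.csv", index=False)
    pd.DataFrame(campaign.ci_history, columns=["n_windows", "ci_low", "ci_high", "estimate"]).to_csv(
        out_dir / "ci_history.csv", index=False
    )
    pd.DataFrame(
        [{"estimate": campaign.final_estimate, "stop_reason": campaign.stop_reason, "n_windows": campaign.n_windows}]
    ).to_csv(out_dir / "final_estimate.csv", index=False)
    (out_dir / "run_metadata.yaml").write_text(yaml.safe_dump(_plain(config.to_dict()), sort_keys=True))


def _plain(obj):
    """YAML-safe copy (tuples → lists, numpy scalars → python)."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def run(config: RunConfig, out_dir: str | Path, **kwargs) -> object:
    """Dispatch on the configured mode."""
    if config.mode == "rs":
        return run_rs(config, out_dir, **kwargs)
    return run_rws(config, out_dir, **kwargs)


def default_fiber_model(seed: int = 42) -> ClassifierModel:
    """Train the shipped-default classifier from the synthetic labelled set.

    The model is generated (seeded, hence reproducible) rather than
    distributed as a file; training takes a few seconds.  Production
    use should retrain on expert-labelled contours via the CLI.
    """
    from .fiber_classify import train_classifier
    from .synthgen import generate_labeled_set

    return train_classifier(generate_labeled_set(seed=7), seed=seed)


def _setup_logging(level: str) -> None:
    if not logging.getLogger().handlers:
        logging.basicConfig(level=getattr(logging, level.upper(), logging.INFO), format="%(asctime)s %(name)s %(levelname)s %(message)s")
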