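"""Result merging, material assignment, size classification and output files.

Detection output (one row per object, with its measurement-spot
coordinate) is merged with the tabular output of spectral database
matching (one record per measured spot: best material label and
hit-quality index).  A material is assigned when the HQI is at least
0.45 (inclusive); below that the spot is "unassigned" and counts as
non-plastic by default.

Size classification bins objects by *minimum* Feret diameter.  Accepted
de-agglomeration children replace their parents in the size table while
the all-particles listing keeps the parent rows.  Extrapolation is
regime specific: under RS, material proportions among the measured
subset of each size class scale to all detected objects of that class;
under RWS a single area-proportion factor scales window counts to the
filter.

Outputs: ``final_result_all_particles.csv``,
``final_result_size_classification.csv``, a contour overlay PNG
(particles green, fibers red, de-agglomeration children cyan) and a
run-metadata YAML.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml
from scipy.spatial import cKDTree

from .deagglomerate import SplitRecord
from .detect import DetectedObject
from .raster_core import GrayImage

__all__ = [
    "IdentificationRecord",
    "SizeClassTable",
    "DEFAULT_SIZE_BINS_UM",
    "assign_material",
    "merge_by_spot",
    "size_classify",
    "make_overlay",
    "write_outputs",
]

DEFAULT_SIZE_BINS_UM = (1.0, 5.0, 10.0, 20.0, 50.0, 100.0, 500.0, 1000.0)
HQI_THRESHOLD_DEFAULT = 0.45
UNASSIGNED = "unassigned"
NOT_MEASURED = "not measured"


@dataclass
class IdentificationRecord:
    """One measured spot: coordinates (µm), best material, HQI in [0, 1]."""

    x_um: float
    y_um: float
    material: str
    hqi: float
    second_material: Optional[str] = None
    second_hqi: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.hqi <= 1.0):
            raise ValueError("HQI must lie in [0, 1]")
        if not (np.isfinite(self.x_um) and np.isfinite(self.y_um)):
            raise ValueError("spot coordinates must be finite")


@dataclass
class SizeClassTable:
    """Per-bin, per-material observed and extrapolated counts."""

    bin_edges_um: Tuple[float, ...]
    table: pd.DataFrame  # columns: bin_low, bin_high, material, observed, extrapolated


def assign_material(record: IdentificationRecord, threshold: float = HQI_THRESHOLD_DEFAULT) -> str:
    """Best label iff HQI >= threshold (inclusive), else 'unassigned'."""
    return record.material if record.hqi >= threshold else UNASSIGNED


def merge_by_spot(
    objects: Sequence[DetectedObject],
    records: Sequence[IdentificationRecord],
    resolution_um_per_px: float,
    tol_um: float = 1.0,
    hqi_threshold: float = HQI_THRESHOLD_DEFAULT,
) -> pd.DataFrame:
    """One-to-one join of objects to identification records by spot distance.

    Greedy nearest-neighbour within ``tol_um`` (candidate pairs sorted by
    distance; ties broken by object id, then record coordinates, so the
    join is invariant under permutation of the record list).  Unmatched
    objects are flagged 'not measured'; unmatched records appear as
    orphan rows with ``object_id = -1``.
    """
    coords = []
    for r in records:
        coords.append((r.x_um, r.y_um))
    if len(set(coords)) < len(coords):
        raise ValueError("duplicate exact-coordinate identification records")
    rows = [_object_row(o, resolution_um_per_px) for o in objects]
    df = pd.DataFrame(rows) if rows else pd.DataFrame(columns=_OBJECT_COLUMNS)
    df["material"] = NOT_MEASURED
    df["hqi"] = np.nan
    if records and rows:
        spots = df[["spot_x_um", "spot_y_um"]].to_numpy(dtype=float)
        rec_xy = np.asarray(coords, dtype=float)
        tree = cKDTree(rec_xy)
        pairs = []
        for oi, (x, y) in enumerate(spots):
            if np.isnan(x):
                continue
            for ri in tree.query_ball_point([x, y], tol_um):
                d = float(np.hypot(x - rec_xy[ri, 0], y - rec_xy[ri, 1]))
                pairs.append((d, int(df.iloc[oi]["id"]), rec_xy[ri, 0], rec_xy[ri, 1], oi, ri))
        pairs.sort()
        used_obj, used_rec = set(), set()
        for d, _oid, _rx, _ry, oi, ri in pairs:
            if oi in used_obj or ri in used_rec:
                continue
            used_obj.add(oi)
            used_rec.add(ri)
            rec = records[ri]
            df.loc[df.index[oi], "material"] = assign_material(rec, hqi_threshold)
            df.loc[df.index[oi], "hqi"] = rec.hqi
        orphan_rows = []
        for ri, rec in enumerate(records):
            if ri not in used_rec:
                orphan_rows.append(
                    {c: np.nan for c in df.columns}
                    | {"id": -1, "material": assign_material(rec, hqi_threshold), "hqi": rec.hqi, "orphan": True}
                )
        df["orphan"] = False
        if orphan_rows:
            df = pd.concat([df, pd.DataFrame(orphan_rows)], ignore_index=True)
    else:
        df["orphan"] = False
        if records and not rows:
            df = pd.DataFrame(
                [
                    {c: np.nan for c in df.columns}
                    | {"id": -1, "material": assign_material(r, hqi_threshold), "hqi": r.hqi, "orphan": True}
                    for r in records
                ]
            )
    return df


_OBJECT_COLUMNS = [
    "id",
    "x_um",
    "y_um",
    "spot_x_um",
    "spot_y_um",
    "area_um2",
    "area_px",
    "feret_min_um",
    "feret_max_um",
    "f1",
    "f2",
    "f3",
    "f4",
    "f5",
    "f6",
    "shape_class",
    "fiber_length_um",
    "parent_id",
]


def _object_row(o: DetectedObject, res: float) -> dict:
    cx, cy = o.centroid_px
    spot = o.measurement_point_px
    f = o.features
    return {
        "id": o.id,
        "x_um": cx * res,
        "y_um": cy * res,
        "spot_x_um": spot[0] * res if spot else np.nan,
        "spot_y_um": spot[1] * res if spot else np.nan,
        "area_um2": o.area_um2,
        "area_px": o.area_px,
        "feret_min_um": o.feret_min_um,
        "feret_max_um": o.feret_max_um,
        "f1": f.f1 if f else np.nan,
        "f2": f.f2 if f else np.nan,
        "f3": f.f3 if f else np.nan,
        "f4": f.f4 if f else np.nan,
        "f5": f.f5 if f else np.nan,
        "f6": f.f6 if f else np.nan,
        "shape_class": o.shape_class or "",
        "fiber_length_um": o.fiber_length_um if o.fiber_length_um is not None else np.nan,
        "parent_id": o.parent_id if o.parent_id is not None else -1,
    }


def size_classify(
    merged: pd.DataFrame,
    splits: Sequence[SplitRecord] = (),
    bin_edges_um: Sequence[float] = DEFAULT_SIZE_BINS_UM,
    rws_factor: Optional[float] = None,
    count_unassigned_as: str = UNASSIGNED,
) -> SizeClassTable:
    """Bin objects by minimum Feret into half-open [low, high) classes.

    Parents of accepted splits are dropped (their children are rows of
    their own); orphan records are excluded.  Extrapolation: with
    ``rws_factor`` every observed count is scaled by the area-proportion
    factor; otherwise (RS) the material mix of the measured subset in
    each bin is scaled to all detected objects of that bin.  Objects
    outside all bins land in an 'overflow' row.
    """
    edges = list(bin_edges_um)
    if sorted(edges) != edges or len(edges) < 2:
        raise ValueError("bin edges must be ascending and >= 2")
    accepted_parents = {s.parent_id for s in splits if s.accepted}
    df = merged[(merged.get("orphan", False) != True) & (merged["id"] >= 0)].copy()  # noqa: E712
    df = df[~df["id"].isin(accepted_parents)]
    rows = []
    bins = list(zip(edges[:-1], edges[1:])) + [(edges[-1], np.inf)]
    for low, high in bins:
        sel = df[(df["feret_min_um"] >= low) & (df["feret_min_um"] < high)]
        n_detected = len(sel)
        if n_detected == 0:
            continue
        measured = sel[sel["material"] != NOT_MEASURED]
        mats = sorted(measured["material"].unique()) if len(measured) else []
        if rws_factor is not None:
            for mat in mats:
                obs = int((measured["material"] == mat).sum())
                rows.append(_bin_row(low, high, mat, obs, obs * rws_factor))
            n_unmeasured = n_detected - len(measured)
            if n_unmeasured:
                rows.append(_bin_row(low, high, NOT_MEASURED, n_unmeasured, n_unmeasured * rws_factor))
        else:
            n_measured = len(measured)
            for mat in mats:
                obs = int((measured["material"] == mat).sum())
                extrap = obs * (n_detected / n_measured) if n_measured else 0.0
                # binomial error of the measured-subset proportion scaled to
                # the class — the smallest possible error of RS, ignoring
                # any spatial variability
                p = obs / n_measured if n_measured else 0.0
                err = n_detected * float(np.sqrt(p * (1 - p) / n_measured)) if n_measured else 0.0
                rows.append(_bin_row(low, high, mat, obs, extrap, err))
            if not mats:
                rows.append(_bin_row(low, high, NOT_MEASURED, n_detected, float(n_detected)))
    table = pd.DataFrame(
        rows, columns=["bin_low_um", "bin_high_um", "material", "observed", "extrapolated", "sampling_error"]
    )
    return SizeClassTable(bin_edges_um=tuple(edges), table=table)


def _bin_row(
    low: float, high: float, material: str, observed: int, extrapolated: float, error: float = 0.0
) -> dict:
    return {
        "bin_low_um": low,
        "bin_high_um": high if np.isfinite(high) else -1.0,
        "material": material,
        "observed": observed,
        "extrapolated": float(extrapolated),
        "sampling_error": float(error),
    }


_CLASS_COLORS = {"particle": (0, 200, 0), "fiber": (230, 40, 40), "child": (0, 210, 210)}


def make_overlay(img: GrayImage, objects: Sequence[DetectedObject]) -> np.ndarray:
    """RGB uint8 copy of the image with contours coloured by class."""
    base = img.pixels
    vmax = max(base.max(), 1.0)
    gray = np.clip(base / vmax * 255.0, 0, 255).astype(np.uint8)
    rgb = np.stack([gray] * 3, axis=-1)
    for o in objects:
        color = _CLASS_COLORS["child"] if o.parent_id is not None else _CLASS_COLORS.get(o.shape_class or "particle", (255, 255, 0))
        rr = np.clip(np.round(o.polygon[:, 0]).astype(int), 0, img.height - 1)
        cc = np.clip(np.round(o.polygon[:, 1]).astype(int), 0, img.width - 1)
        rgb[rr, cc] = color
    return rgb


def write_outputs(
    out_dir: str | Path,
    merged: pd.DataFrame,
    size_table: SizeClassTable,
    overlay: Optional[np.ndarray] = None,
    metadata: Optional[dict] = None,
) -> Dict[str, Path]:
    """Write the CSV/overlay/metadata artefact set; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    all_particles = out_dir / "final_result_all_particles.csv"
    cols = [c for c in _OBJECT_COLUMNS if c in merged.columns] + ["material", "hqi", "orphan"]
    merged.to_csv(all_particles, index=False, columns=[c for c in cols if c in merged.columns])
    paths["all_particles"] = all_particles
    size_csv = out_dir / "final_result_size_classification.csv"
    size_table.table.to_csv(size_csv, index=False)
    paths["size_classification"] = size_csv
    if overlay is not None:
        overlay_path = out_dir / "overlay.png"
        iio.imwrite(overlay_path, overlay)
        paths["overlay"] = overlay_path
    meta_path = out_dir / "run_metadata.yaml"
    meta_path.write_text(yaml.safe_dump(metadata or {}, sort_keys=True))
    paths["metadata"] = meta_path
    return paths
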