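"""Excess-green segmentation of top-view plate images.

Plants are recovered per well by thresholding the excess-green index
2G − R − B, cleaning the foreground with a morphological opening, and
assigning to each well the largest connected component whose centroid
falls inside the well disc.  The per-plant pixel count is the area
measurement; channel statistics are averaged per pixel over the final
plant mask (required for a well-defined per-plant GLI).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from skimage import measure, morphology

from .simulate import PlateLayout, PlateScene
from .traits import PlantTimeSeries, gli

logger = logging.getLogger(__name__)

__all__ = [
    "SegmentationError",
    "WellMeasurement",
    "excess_green",
    "segment_plants",
    "extract_time_series",
]


class SegmentationError(ValueError):
    """Invalid input to the segmentation stage."""


@dataclass(frozen=True)
class WellMeasurement:
    """Per-well plant measurement at one timepoint.

    ``area_px`` is the plant pixel count (0 when no plant is detected);
    channel means and the pixel-averaged GLI are NaN for empty wells.
    """

    well_index: int
    time: float
    area_px: int
    mean_r: float = float("nan")
    mean_g: float = float("nan")
    mean_b: float = float("nan")
    mean_gli: float = float("nan")


def excess_green(image: np.ndarray) -> np.ndarray:
    """Per-pixel excess-green index 2G − R − B (signed, in [−510, 510])."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise SegmentationError(f"expected an H x W x 3 image, got shape {image.shape}")
    img = image.astype(float)
    return 2.0 * img[..., 1] - img[..., 0] - img[..., 2]


def segment_plants(
    scene: PlateScene | np.ndarray,
    layout: PlateLayout | None = None,
    *,
    threshold: float = 40.0,
    min_object_px: int = 20,
    opening_radius: int = 1,
    time: float | None = None,
) -> tuple[np.ndarray, list[WellMeasurement]]:
    """Segment every well of a plate image.

    Pixels with excess green above ``threshold`` are candidate
    foreground.  A binary opening (disc footprint of radius
    ``opening_radius``) acts as a speck filter: connected components
    with no surviving pixel are discarded, the rest keep their raw
    thresholded extent so areas are not eroded.  Each well is then
    assigned its largest remaining component with centroid inside the
    well disc and at least ``min_object_px`` pixels.  Returns the
    per-well label mask (uint16; 0 background, k+1 for well k) and one
    :class:`WellMeasurement` per well.
    """
    if isinstance(scene, PlateScene):
        image = scene.image
        layout = layout or scene.layout
        if time is None:
            time = scene.time
    else:
        image = np.asarray(scene)
        if time is None:
            time = 0.0
    if layout is None:
        raise SegmentationError("a plate layout is required")
    if not (0 < threshold < 510):
        raise SegmentationError("threshold must be in (0, 510)")
    if image.shape[:2] != tuple(layout.image_shape):
        raise SegmentationError("image shape does not match layout")

    exg = excess_green(image)
    fg = exg > threshold
    comp_labels, n_comp = measure.label(fg, connectivity=2, return_num=True)
    if opening_radius > 0 and n_comp:
        # opening as a speck filter by reconstruction: components with no
        # pixel surviving the opening are discarded, the rest keep their
        # raw thresholded boundaries (area is not eroded)
        seed = morphology.opening(fg, morphology.disk(opening_radius))
        survivors = np.unique(comp_labels[seed])
        survivors = set(survivors[survivors > 0].tolist())
    else:
        survivors = None

    out_mask = np.zeros(image.shape[:2], dtype=np.uint16)
    measurements: list[WellMeasurement] = []
    rad = layout.well_diameter_px / 2.0

    props = measure.regionprops(comp_labels) if n_comp else []
    if survivors is not None:
        props = [p for p in props if p.label in survivors]
    centroids = np.array([p.centroid for p in props]) if props else np.empty((0, 2))
    areas = np.array([p.area for p in props]) if props else np.empty((0,))

    img_f = image.astype(float)
    for k, (cx, cy) in enumerate(layout.well_centers):
        chosen = None
        if len(props):
            d = np.hypot(centroids[:, 1] - cx, centroids[:, 0] - cy)
            ok = (d <= rad) & (areas >= min_object_px)
            if ok.any():
                chosen = props[int(np.flatnonzero(ok)[np.argmax(areas[ok])])]
        if chosen is None:
            measurements.append(WellMeasurement(well_index=k, time=time, area_px=0))
            continue
        ys, xs = chosen.coords[:, 0], chosen.coords[:, 1]
        if np.any(np.hypot(xs - cx, ys - cy) > rad):
            logger.warning(
                "well %d: component extends beyond its well disc; "
                "assigned by centroid", k,
            )
        out_mask[ys, xs] = k + 1
        r = img_f[ys, xs, 0]
        g = img_f[ys, xs, 1]
        b = img_f[ys, xs, 2]
        pix_gli = gli(r, g, b)
        n_excluded = int(np.isnan(pix_gli).sum())
        if n_excluded:
            logger.debug("well %d: %d black pixels excluded from GLI", k, n_excluded)
        measurements.append(
            WellMeasurement(
                well_index=k,
                time=time,
                area_px=int(chosen.area),
                mean_r=float(r.mean()),
                mean_g=float(g.mean()),
                mean_b=float(b.mean()),
                mean_gli=float(np.nanmean(pix_gli)) if np.isfinite(pix_gli).any() else float("nan"),
            )
        )
    return out_mask, measurements


def extract_time_series(
    scenes: Sequence[PlateScene],
    mapping: Mapping[int, tuple[str, str, float, str]],
    *,
    threshold: float = 40.0,
    min_object_px: int = 20,
    opening_radius: int = 1,
) -> list[PlantTimeSeries]:
    """Assemble per-plant time series from a sequence of plate scenes.

    ``mapping`` assigns each well index a
    (plant_id, treatment, concentration, condition) tuple.  Scenes may
    be passed in any order; they are sorted by acquisition time, and
    duplicate times are an error.  Wells absent from ``mapping`` are
    skipped.
    """
    if not scenes:
        return []
    scenes = sorted(scenes, key=lambda s: s.time)
    times = np.array([s.time for s in scenes])
    if np.any(np.diff(times) == 0):
        raise SegmentationError("duplicate scene times")
    layout = scenes[0].layout
    for s in scenes[1:]:
        if s.layout.n_wells != layout.n_wells:
            raise SegmentationError("scenes must share one plate layout")

    per_well: dict[int, list[WellMeasurement]] = {k: [] for k in mapping}
    for scene in scenes:
        _, ms = segment_plants(
            scene,
            threshold=threshold,
            min_object_px=min_object_px,
            opening_radius=opening_radius,
        )
        for m in ms:
            if m.well_index in per_well:
                per_well[m.well_index].append(m)

    out = []
    for well, (plant_id, treatment, conc, condition) in mapping.items():
        ms = per_well[well]
        out.append(
            PlantTimeSeries(
                plant_id=plant_id,
                treatment=treatment,
                concentration=float(conc),
                condition=condition,
                times=times,
                areas=np.array([m.area_px for m in ms], dtype=float),
                mean_r=np.array([m.mean_r for m in ms]),
                mean_g=np.array([m.mean_g for m in ms]),
                mean_b=np.array([m.mean_b for m in ms]),
                gli_series=np.array([m.mean_gli for m in ms]),
            )
        )
    return out
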