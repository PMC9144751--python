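"""Per-plant growth and colour traits from rosette area time series.

A plant imaged from the top is summarised by five traits over the
experiment:

* **GC-slope** — ordinary least-squares slope of projected rosette area
  (px) versus time (days), the linear trend of the growth curve.
* **AUC** — area under the growth curve, a cumulative growth summary in
  px·day (trapezoidal rule over real time).
* **RGR** — relative growth rate, ``(ln s2 − ln s1)/(t2 − t1)`` per day,
  using the first and last observed sizes.
* **FG** — final rosette size, the area at the last timepoint.
* **GLI** — green leaf index, ``(2G − R − B)/(2G + R + B)``, a greenness
  score in [−1, 1] averaged over the plant mask at the final timepoint.

These are the inputs to the biostimulant characterisation index (see
:mod:`phenoprime.pbci`).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PlantTimeSeries",
    "TraitVector",
    "TraitError",
    "DegenerateSeriesError",
    "auc",
    "rgr",
    "gc_slope",
    "gli",
    "compute_traits",
    "compute_trait_table",
    "TRAIT_NAMES",
]

TRAIT_NAMES = ("gc_slope", "auc", "rgr", "fg", "gli")


class TraitError(ValueError):
    """Invalid input to a trait computation."""


class DegenerateSeriesError(TraitError):
    """Series too short or otherwise unusable for any trait."""


@dataclass
class PlantTimeSeries:
    """One plant's area and colour trajectory over the imaging timepoints.

    Parameters
    ----------
    plant_id : str
        Unique identifier of the plant (one well of the plate).
    treatment : str
        Priming compound, ``"control"`` for unprimed seeds.
    concentration : float
        Priming concentration in mM (0 for control).
    condition : str
        Growth condition label (``optimal`` / ``osmotic`` / ``salt``).
    times : array of float
        Days since transfer, strictly increasing.
    areas : array of float
        Projected rosette area in pixels, one per timepoint, ≥ 0.
    mean_r, mean_g, mean_b : array of float, optional
        Mean channel intensities over the plant mask per timepoint
        (NaN where the plant was not detected).
    gli_series : array of float, optional
        Per-timepoint mean of per-pixel GLI over the mask.  When absent,
        GLI falls back to the GLI of the channel means.
    """

    plant_id: str
    treatment: str
    concentration: float
    condition: str
    times: np.ndarray
    areas: np.ndarray
    mean_r: np.ndarray | None = None
    mean_g: np.ndarray | None = None
    mean_b: np.ndarray | None = None
    gli_series: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.areas = np.asarray(self.areas, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.areas.shape:
            raise TraitError("times and areas must be 1-D arrays of equal length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise TraitError("times must be strictly increasing")
        if self.times.size and self.times[0] < 0:
            raise TraitError("times must be nonnegative")
        if not np.all(np.isfinite(self.areas)) or np.any(self.areas < 0):
            raise TraitError("areas must be finite and nonnegative")
        for name in ("mean_r", "mean_g", "mean_b", "gli_series"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != self.times.shape:
                    raise TraitError(f"{name} must match times in length")
                setattr(self, name, v)

    def __len__(self) -> int:
        return self.times.size

    @property
    def gli_values(self) -> np.ndarray | None:
        """Per-timepoint GLI; mask-pixel average if available, else GLI of channel means."""
        if self.gli_series is not None:
            return self.gli_series
        if self.mean_r is not None and self.mean_g is not None and self.mean_b is not None:
            return gli(self.mean_r, self.mean_g, self.mean_b)
        return None


@dataclass(frozen=True)
class TraitVector:
    """The five per-plant phenotyping traits.

    ``flags`` names traits that could not be computed for this plant
    (value NaN); the plant is flagged, never silently dropped.
    """

    gc_slope: float
    auc: float
    rgr: float
    fg: float
    gli: float
    flags: tuple[str, ...] = field(default_factory=tuple)

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in TRAIT_NAMES}


def _times_areas(series, areas) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(series, PlantTimeSeries):
        return series.times, series.areas
    return np.asarray(series, dtype=float), np.asarray(areas, dtype=float)


def auc(series, areas=None, *, mode: str = "trapezoid") -> float:
    """Area under the growth curve.

    In ``trapezoid`` mode (default) this is the trapezoidal rule over
    real time, Σ (sᵢ + sᵢ₋₁)/2 · (tᵢ − tᵢ₋₁), in px·day.  ``literal``
    mode evaluates Σ (sᵢ − sᵢ₋₁)/2 instead, which telescopes to
    (sₙ − s₀)/2 (px); it is retained for comparability with reports that
    define AUC by that difference form, but it discards the trajectory
    and is not recommended.
    """
    t, a = _times_areas(series, areas)
    if t.size < 2:
        raise DegenerateSeriesError("AUC needs at least 2 timepoints")
    if np.any(np.diff(t) <= 0):
        raise TraitError("times must be strictly increasing")
    if mode == "trapezoid":
        return float(np.trapezoid(a, t))
    if mode == "literal":
        return float((a[-1] - a[0]) / 2.0)
    raise TraitError(f"unknown AUC mode {mode!r}")


def rgr(series, areas=None) -> float:
    """Relative growth rate (ln s₂ − ln s₁)/(t₂ − t₁) per day.

    s₁/s₂ are the first/last observed areas.  Nonpositive endpoints make
    the log undefined and raise :class:`TraitError` (the caller flags
    the plant as degenerate).
    """
    t, a = _times_areas(series, areas)
    if t.size < 2:
        raise DegenerateSeriesError("RGR needs at least 2 timepoints")
    s1, s2 = a[0], a[-1]
    if s1 <= 0 or s2 <= 0:
        raise TraitError("RGR undefined: nonpositive endpoint area")
    return float((np.log(s2) - np.log(s1)) / (t[-1] - t[0]))


def gc_slope(series, areas=None) -> float:
    """OLS slope of area versus time (px/day)."""
    t, a = _times_areas(series, areas)
    if t.size < 2:
        raise DegenerateSeriesError("GC-slope needs at least 2 timepoints")
    if np.ptp(t) == 0:
        raise TraitError("GC-slope undefined: all times equal")
    tc = t - t.mean()
    return float(np.dot(tc, a - a.mean()) / np.dot(tc, tc))


def gli(R, G, B):
    """Green leaf index (2G − R − B)/(2G + R + B), elementwise.

    Accepts scalars or arrays of channel intensities in [0, 255].
    Pixels with zero denominator (pure black) yield NaN and are expected
    to be excluded from any mask average by the caller.
    """
    R = np.asarray(R, dtype=float)
    G = np.asarray(G, dtype=float)
    B = np.asarray(B, dtype=float)
    num = 2.0 * G - R - B
    den = 2.0 * G + R + B
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den != 0, num / np.where(den != 0, den, 1.0), np.nan)
    if out.ndim == 0:
        return float(out)
    return out


def compute_traits(series: PlantTimeSeries, *, auc_mode: str = "trapezoid") -> TraitVector:
    """Assemble the five traits for one plant.

    Per-trait failures (e.g. RGR on a plant whose first or last area is
    zero) set that trait to NaN and record its name in ``flags``; the
    other traits are still computed.
    """
    if len(series) < 2:
        raise DegenerateSeriesError(
            f"plant {series.plant_id}: need at least 2 timepoints, got {len(series)}"
        )
    flags: list[str] = []

    slope = gc_slope(series)
    auc_value = auc(series, mode=auc_mode)
    try:
        rgr_value = rgr(series)
    except TraitError:
        logger.warning("plant %s: RGR undefined (nonpositive endpoint area)", series.plant_id)
        rgr_value = float("nan")
        flags.append("rgr")
    fg = float(series.areas[-1])

    gli_values = series.gli_values
    if gli_values is None or not np.isfinite(gli_values[-1]):
        gli_value = float("nan")
        flags.append("gli")
    else:
        gli_value = float(gli_values[-1])

    return TraitVector(slope, auc_value, rgr_value, fg, gli_value, tuple(flags))


def compute_trait_table(
    series_collection: Iterable[PlantTimeSeries], *, auc_mode: str = "trapezoid"
) -> pd.DataFrame:
    """Trait table for a collection of plants.

    Returns one row per plant with identifying metadata
    (plant_id, treatment, concentration, condition), the five trait
    columns, and a ``flags`` column listing degenerate traits.
    """
    rows = []
    for s in series_collection:
        tv = compute_traits(s, auc_mode=auc_mode)
        row = {
            "plant_id": s.plant_id,
            "treatment": s.treatment,
            "concentration": s.concentration,
            "condition": s.condition,
        }
        row.update(tv.as_dict())
        row["flags"] = ";".join(tv.flags)
        rows.append(row)
    return pd.DataFrame(rows)
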