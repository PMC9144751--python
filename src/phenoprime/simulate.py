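"""Synthetic plate experiments: growth trajectories, plate images, metabolites.

No imaging data accompany the assay this package analyses, so this
module generates inputs with the statistical structure the analysis
assumes, making every downstream stage testable end to end:

* :func:`simulate_growth` draws per-plant rosette-area trajectories
  from a logistic growth law with stress acting on the carrying
  capacity, priming treatments multiplying rate/capacity/greenness, and
  multiplicative lognormal measurement noise.
* :func:`render_plate` paints each plant as a lobed green blob of an
  exact requested pixel count inside its well, with a pixel-perfect
  ground-truth label mask, so segmentation accuracy can be scored.
* :func:`simulate_metabolites` draws a sample × metabolite
  concentration table with group-mean log-fold-change effects and
  lognormal replicate noise.

Default design: 48 plants per treatment×condition, 14 timepoints
(twice daily over 7 days), three growth conditions (optimal, 100 mM
mannitol osmotic stress, 100 mM NaCl salt stress), and seven seed
treatments (unprimed control; DAP, Orn and Put each at 0.1 and 1 mM).
The default stress multipliers on final size (0.30 osmotic, 0.22 salt)
reproduce the 70% / 78% rosette-size reductions typical of this assay.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import METABOLITE_CLASSES, MetaboliteTable
from .traits import PlantTimeSeries

logger = logging.getLogger(__name__)

__all__ = [
    "ScenarioError",
    "TreatmentEffect",
    "GrowthScenario",
    "PlateLayout",
    "PlateScene",
    "logistic_area",
    "simulate_growth",
    "series_to_frame",
    "frame_to_series",
    "make_grid_layout",
    "render_plate",
    "simulate_metabolites",
    "default_metabolite_panel",
    "default_metabolite_effects",
    "DEFAULT_TREATMENTS",
    "DEFAULT_CONDITIONS",
    "default_timepoints",
]


class ScenarioError(ValueError):
    """A scenario or layout violates one of its invariants."""


DEFAULT_CONDITIONS = ("optimal", "osmotic", "salt")

#: (compound, concentration in mM); control = unprimed seeds.
DEFAULT_TREATMENTS = (
    ("control", 0.0),
    ("DAP", 0.1),
    ("DAP", 1.0),
    ("Orn", 0.1),
    ("Orn", 1.0),
    ("Put", 0.1),
    ("Put", 1.0),
)


def default_timepoints() -> np.ndarray:
    """Fourteen imaging times in days: twice daily (10:00 and 16:00) for 7 days."""
    return np.array([d + o for d in range(7) for o in (0.0, 0.25)])


@dataclass(frozen=True)
class TreatmentEffect:
    """Multipliers a priming treatment applies under one condition.

    ``r`` scales the intrinsic growth rate, ``K`` the carrying capacity
    (final size), ``greenness`` the mean GLI.  All must be positive; 1.0
    is no effect.
    """

    r: float = 1.0
    K: float = 1.0
    greenness: float = 1.0


NEUTRAL_EFFECT = TreatmentEffect()

#: Default treatment effects, emulating the qualitative outcome of a
#: polyamine seed-priming screen: little or mildly negative effect under
#: optimal growth, alleviation under salt (strongest for 1 mM DAP),
#: mixed effects under osmotic stress, growth inhibition by 1 mM Orn.
DEFAULT_TREATMENT_EFFECTS: dict[tuple[tuple[str, float], str], TreatmentEffect] = {
    (("DAP", 0.1), "optimal"): TreatmentEffect(r=1.04, K=1.0, greenness=1.03),
    (("DAP", 1.0), "optimal"): TreatmentEffect(K=0.95),
    (("Orn", 0.1), "optimal"): TreatmentEffect(K=0.96),
    (("Orn", 1.0), "optimal"): TreatmentEffect(r=0.95, K=0.88),
    (("Put", 0.1), "optimal"): TreatmentEffect(K=0.97),
    (("Put", 1.0), "optimal"): TreatmentEffect(K=0.96),
    (("DAP", 0.1), "osmotic"): TreatmentEffect(K=0.92, greenness=0.97),
    (("DAP", 1.0), "osmotic"): TreatmentEffect(r=1.08, K=1.20, greenness=1.05),
    (("Orn", 0.1), "osmotic"): TreatmentEffect(r=1.06, K=1.18, greenness=1.04),
    (("Orn", 1.0), "osmotic"): TreatmentEffect(r=0.94, K=0.85, greenness=0.96),
    (("Put", 0.1), "osmotic"): TreatmentEffect(K=1.06, greenness=1.02),
    (("Put", 1.0), "osmotic"): TreatmentEffect(K=1.08, greenness=1.02),
    (("DAP", 0.1), "salt"): TreatmentEffect(K=1.05, greenness=1.02),
    (("DAP", 1.0), "salt"): TreatmentEffect(r=1.10, K=1.30, greenness=1.08),
    (("Orn", 0.1), "salt"): TreatmentEffect(K=1.12, greenness=1.03),
    (("Orn", 1.0), "salt"): TreatmentEffect(r=0.92, K=0.82, greenness=1.04),
    (("Put", 0.1), "salt"): TreatmentEffect(r=1.04, K=1.15, greenness=1.04),
    (("Put", 1.0), "salt"): TreatmentEffect(r=1.05, K=1.18, greenness=1.05),
}


@dataclass
class GrowthScenario:
    """Design and generative parameters of a simulated plate experiment.

    Growth is logistic, ``A(t) = K'/(1 + ((K'−A0)/A0) e^{−r' t})``, with
    the effective capacity ``K' = K · stress_K_multiplier[condition] ·
    effect.K`` and rate ``r' = r · effect.r``.  Observed areas are the
    noiseless expectation times i.i.d. lognormal noise with unit mean
    and coefficient of variation ``noise_cv``.  Each plant's greenness
    (mean GLI) is drawn once around the treatment×condition greenness
    parameter with s.d. ``gli_sd``.
    """

    n_plants_per_group: int = 48
    timepoints: np.ndarray = field(default_factory=default_timepoints)
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    treatments: tuple[tuple[str, float], ...] = DEFAULT_TREATMENTS
    A0: float = 40.0
    K: float = 1000.0
    r: float = 1.4
    stress_K_multiplier: Mapping[str, float] = field(
        default_factory=lambda: {"optimal": 1.0, "osmotic": 0.30, "salt": 0.22}
    )
    treatment_effects: Mapping[tuple[tuple[str, float], str], TreatmentEffect] = field(
        default_factory=lambda: dict(DEFAULT_TREATMENT_EFFECTS)
    )
    base_greenness: float = 0.40
    stress_greenness_multiplier: Mapping[str, float] = field(
        default_factory=lambda: {"optimal": 1.0, "osmotic": 0.90, "salt": 0.85}
    )
    gli_sd: float = 0.02
    noise_cv: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.validate()

    def validate(self) -> None:
        t = self.timepoints
        if t.size < 1 or np.any(t < 0):
            raise ScenarioError("timepoints must be nonnegative")
        if np.any(np.diff(t) <= 0):
            raise ScenarioError("timepoints must be strictly increasing")
        if self.n_plants_per_group < 1:
            raise ScenarioError("n_plants_per_group must be >= 1")
        if not self.A0 > 0:
            raise ScenarioError("A0 must be > 0")
        if self.K < self.A0:
            raise ScenarioError("K must be >= A0")
        if not self.r > 0:
            raise ScenarioError("r must be > 0")
        for cond in self.conditions:
            m = self.stress_K_multiplier.get(cond, 1.0)
            if not (0 < m <= 1):
                raise ScenarioError(
                    f"stress_K_multiplier[{cond!r}] must be in (0, 1], got {m}"
                )
        for key, eff in self.treatment_effects.items():
            if min(eff.r, eff.K, eff.greenness) <= 0:
                raise ScenarioError(f"treatment effect multipliers must be > 0: {key}")
        if self.noise_cv < 0:
            raise ScenarioError("noise_cv must be >= 0")

    def effect(self, treatment: tuple[str, float], condition: str) -> TreatmentEffect:
        return self.treatment_effects.get((tuple(treatment), condition), NEUTRAL_EFFECT)


def logistic_area(t, A0: float, K: float, r: float):
    """Logistic growth law ``K/(1 + ((K−A0)/A0) e^{−r t})``."""
    t = np.asarray(t, dtype=float)
    return K / (1.0 + ((K - A0) / A0) * np.exp(-r * t))


def _greenness_to_rgb(g: float, G: float = 150.0) -> tuple[float, float, float]:
    """Channel means (R, G, B) whose GLI equals ``g`` with R = B."""
    x = G * (1.0 - g) / (1.0 + g)
    return x, G, x


def simulate_growth(scenario: GrowthScenario) -> list[PlantTimeSeries]:
    """Draw one area/greenness trajectory per plant of the scenario.

    Returns one :class:`~phenoprime.traits.PlantTimeSeries` per plant
    per treatment×condition, fully reproducible for a fixed
    ``scenario.seed``.
    """
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    t = scenario.timepoints
    cv = scenario.noise_cv
    sigma = np.sqrt(np.log1p(cv**2)) if cv > 0 else 0.0
    out: list[PlantTimeSeries] = []
    for condition in scenario.conditions:
        stress_m = scenario.stress_K_multiplier.get(condition, 1.0)
        green_m = scenario.stress_greenness_multiplier.get(condition, 1.0)
        for compound, conc in scenario.treatments:
            eff = scenario.effect((compound, conc), condition)
            K_eff = scenario.K * stress_m * eff.K
            r_eff = scenario.r * eff.r
            A0 = min(scenario.A0, K_eff)  # keep K' >= A0 under strong stress
            expectation = logistic_area(t, A0, K_eff, r_eff)
            g_mean = scenario.base_greenness * green_m * eff.greenness
            for i in range(scenario.n_plants_per_group):
                if sigma > 0:
                    noise = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=t.size)
                else:
                    noise = 1.0
                areas = expectation * noise
                g = float(np.clip(rng.normal(g_mean, scenario.gli_sd), -0.95, 0.95))
                mr, mg, mb = _greenness_to_rgb(g)
                const = np.full(t.size, 1.0)
                out.append(
                    PlantTimeSeries(
                        plant_id=f"{compound}-{conc:g}-{condition}-{i:03d}",
                        treatment=compound,
                        concentration=conc,
                        condition=condition,
                        times=t.copy(),
                        areas=areas,
                        mean_r=mr * const,
                        mean_g=mg * const,
                        mean_b=mb * const,
                    )
                )
    return out


TRAJECTORY_COLUMNS = [
    "plant_id",
    "treatment",
    "concentration",
    "condition",
    "time_days",
    "area_px",
    "mean_R",
    "mean_G",
    "mean_B",
]


def series_to_frame(series: Iterable[PlantTimeSeries]) -> pd.DataFrame:
    """Long-format trajectory table (one row per plant per timepoint)."""
    parts = []
    for s in series:
        n = len(s)
        nan = np.full(n, np.nan)
        parts.append(
            pd.DataFrame(
                {
                    "plant_id": s.plant_id,
                    "treatment": s.treatment,
                    "concentration": s.concentration,
                    "condition": s.condition,
                    "time_days": s.times,
                    "area_px": s.areas,
                    "mean_R": s.mean_r if s.mean_r is not None else nan,
                    "mean_G": s.mean_g if s.mean_g is not None else nan,
                    "mean_B": s.mean_b if s.mean_b is not None else nan,
                }
            )
        )
    if not parts:
        return pd.DataFrame(columns=TRAJECTORY_COLUMNS)
    return pd.concat(parts, ignore_index=True)


def frame_to_series(frame: pd.DataFrame) -> list[PlantTimeSeries]:
    """Rebuild :class:`PlantTimeSeries` objects from a long-format table."""
    missing = [c for c in TRAJECTORY_COLUMNS[:6] if c not in frame.columns]
    if missing:
        raise ScenarioError(f"trajectory table is missing columns: {missing}")
    out = []
    for pid, g in frame.groupby("plant_id", sort=False):
        g = g.sort_values("time_days")
        has_rgb = {"mean_R", "mean_G", "mean_B"} <= set(g.columns)
        out.append(
            PlantTimeSeries(
                plant_id=str(pid),
                treatment=str(g["treatment"].iloc[0]),
                concentration=float(g["concentration"].iloc[0]),
                condition=str(g["condition"].iloc[0]),
                times=g["time_days"].to_numpy(),
                areas=g["area_px"].to_numpy(),
                mean_r=g["mean_R"].to_numpy() if has_rgb else None,
                mean_g=g["mean_G"].to_numpy() if has_rgb else None,
                mean_b=g["mean_B"].to_numpy() if has_rgb else None,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Plate layout and rendering
# ---------------------------------------------------------------------------

@dataclass
class PlateLayout:
    """Geometry of a multi-well plate in image coordinates."""

    n_rows: int
    n_cols: int
    well_centers: np.ndarray  # (n, 2) as (x, y) pixel coordinates
    well_diameter_px: float
    image_shape: tuple[int, int]  # (height, width)
    mm_per_px: float = 0.1

    def __post_init__(self) -> None:
        self.well_centers = np.asarray(self.well_centers, dtype=float)
        self.validate()

    def validate(self) -> None:
        n = self.n_rows * self.n_cols
        if self.well_centers.shape != (n, 2):
            raise ScenarioError(
                f"expected {n} well centers for {self.n_rows}x{self.n_cols}, "
                f"got {self.well_centers.shape}"
            )
        h, w = self.image_shape
        x, y = self.well_centers[:, 0], self.well_centers[:, 1]
        rad = self.well_diameter_px / 2.0
        if np.any(x - rad < 0) or np.any(x + rad > w) or np.any(y - rad < 0) or np.any(y + rad > h):
            raise ScenarioError("well discs must lie inside the image bounds")
        if n > 1:
            d = np.sqrt(((self.well_centers[:, None] - self.well_centers[None]) ** 2).sum(-1))
            np.fill_diagonal(d, np.inf)
            if d.min() <= self.well_diameter_px:
                raise ScenarioError("wells overlap: center distance <= well diameter")

    @property
    def n_wells(self) -> int:
        return self.n_rows * self.n_cols

    def to_dict(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "n_cols": self.n_cols,
            "well_centers": self.well_centers.tolist(),
            "well_diameter_px": self.well_diameter_px,
            "image_shape": list(self.image_shape),
            "mm_per_px": self.mm_per_px,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PlateLayout":
        return cls(
            n_rows=int(d["n_rows"]),
            n_cols=int(d["n_cols"]),
            well_centers=np.asarray(d["well_centers"], dtype=float),
            well_diameter_px=float(d["well_diameter_px"]),
            image_shape=tuple(int(v) for v in d["image_shape"]),
            mm_per_px=float(d.get("mm_per_px", 0.1)),
        )


@dataclass
class PlateScene:
    """A plate image, its layout, and (for synthetic scenes) the
    ground-truth label mask (0 = background, k+1 = plant in well k)."""

    image: np.ndarray  # H x W x 3 uint8
    layout: PlateLayout
    truth_mask: np.ndarray | None = None
    time: float = 0.0

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ScenarioError("image must be H x W x 3")
        if self.image.shape[:2] != tuple(self.layout.image_shape):
            raise ScenarioError("image shape does not match layout.image_shape")
        if self.truth_mask is not None:
            self.truth_mask = np.asarray(self.truth_mask)
            if self.truth_mask.shape != self.image.shape[:2]:
                raise ScenarioError("truth_mask shape must match image")
            if self.truth_mask.max(initial=0) > self.layout.n_wells:
                raise ScenarioError("truth_mask labels exceed number of wells")


def make_grid_layout(
    n_rows: int = 6,
    n_cols: int = 8,
    *,
    well_diameter_px: float = 64.0,
    pitch_px: float | None = None,
    margin_px: float = 12.0,
    mm_per_px: float = 10.4 / 64.0,
) -> PlateLayout:
    """Regular grid layout (default 6×8 = 48 wells).

    The default scale maps the well diameter (10.4 mm) to 64 px.
    """
    if pitch_px is None:
        pitch_px = well_diameter_px + 2 * margin_px / 2
    rad = well_diameter_px / 2.0
    xs = margin_px + rad + pitch_px * np.arange(n_cols)
    ys = margin_px + rad + pitch_px * np.arange(n_rows)
    centers = np.array([(x, y) for y in ys for x in xs])
    w = int(np.ceil(xs[-1] + rad + margin_px))
    h = int(np.ceil(ys[-1] + rad + margin_px))
    return PlateLayout(
        n_rows=n_rows,
        n_cols=n_cols,
        well_centers=centers,
        well_diameter_px=well_diameter_px,
        image_shape=(h, w),
        mm_per_px=mm_per_px,
    )


def render_plate(
    entries: Sequence[tuple[int, float, float]],
    layout: PlateLayout,
    *,
    seed: int = 0,
    time: float = 0.0,
    background_rgb: tuple[int, int, int] = (205, 205, 200),
    pixel_noise_sd: float = 2.0,
) -> PlateScene:
    """Render plants as lobed green blobs on a non-green plate background.

    ``entries`` are (well_index, area_px, greenness) triples, at most
    one per well.  Each plant is drawn as a connected, star-shaped blob
    of exactly ``round(area_px)`` pixels inside its well disc, coloured
    so the mean per-pixel GLI over the blob equals the requested
    greenness (within a small pixel-noise jitter).  The returned scene
    carries a pixel-exact ground-truth label mask.
    """
    layout.validate()
    rng = np.random.default_rng(seed)
    h, w = layout.image_shape
    img = np.empty((h, w, 3), dtype=float)
    img[..., 0] = background_rgb[0]
    img[..., 1] = background_rgb[1]
    img[..., 2] = background_rgb[2]
    img += rng.normal(0.0, pixel_noise_sd, size=img.shape)
    mask = np.zeros((h, w), dtype=np.uint16)

    seen: set[int] = set()
    rad = layout.well_diameter_px / 2.0
    # subtle well rim so plates look like plates (stays achromatic)
    yy0, xx0 = np.mgrid[0:h, 0:w]
    for cx, cy in layout.well_centers:
        ring = np.abs(np.hypot(xx0 - cx, yy0 - cy) - rad) < 1.0
        img[ring] -= 25.0

    for well_index, area, greenness in entries:
        if well_index in seen:
            raise ScenarioError(f"well {well_index} listed twice")
        seen.add(well_index)
        if not (0 <= well_index < layout.n_wells):
            raise ScenarioError(f"well index {well_index} out of range")
        if area < 0:
            raise ScenarioError("requested area must be >= 0")
        n_px = int(round(area))
        if n_px == 0:
            continue
        cx, cy = layout.well_centers[well_index]
        x0, x1 = int(np.floor(cx - rad)) - 1, int(np.ceil(cx + rad)) + 2
        y0, y1 = int(np.floor(cy - rad)) - 1, int(np.ceil(cy + rad)) + 2
        yy, xx = np.mgrid[y0:y1, x0:x1]
        in_disc = np.hypot(xx - cx, yy - cy) <= rad
        avail = int(in_disc.sum())
        if n_px > avail:
            raise ScenarioError(
                f"requested area {n_px} px exceeds well disc area {avail} px"
            )
        # lobed star-shaped blob around a jittered centre
        jx = cx + rng.uniform(-0.08, 0.08) * rad
        jy = cy + rng.uniform(-0.08, 0.08) * rad
        n_lobes = int(rng.integers(4, 9))
        amp = rng.uniform(0.12, 0.25)
        phase = rng.uniform(0, 2 * np.pi)
        phase2 = rng.uniform(0, 2 * np.pi)
        dx, dy = xx - jx, yy - jy
        theta = np.arctan2(dy, dx)
        f = 1.0 + amp * np.cos(n_lobes * theta + phase) + (amp / 3.0) * np.cos(
            (2 * n_lobes) * theta + phase2
        )
        key = np.hypot(dx, dy) / np.maximum(f, 0.3)
        key = np.where(in_disc, key, np.inf)
        flat = np.argsort(key, axis=None, kind="stable")[:n_px]
        sel_y, sel_x = np.unravel_index(flat, key.shape)
        sel_y = sel_y + y0
        sel_x = sel_x + x0
        mask[sel_y, sel_x] = well_index + 1
        r_val, g_val, b_val = _greenness_to_rgb(greenness)
        jitter = rng.normal(0.0, pixel_noise_sd, size=(n_px, 3))
        img[sel_y, sel_x, 0] = r_val + jitter[:, 0]
        img[sel_y, sel_x, 1] = g_val + jitter[:, 1]
        img[sel_y, sel_x, 2] = b_val + jitter[:, 2]

    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return PlateScene(image=img, layout=layout, truth_mask=mask, time=time)


# ---------------------------------------------------------------------------
# Metabolite simulation
# ---------------------------------------------------------------------------

#: name -> (class, baseline concentration in nmol/g DW-equivalent units)
DEFAULT_METABOLITE_PANEL: dict[str, tuple[str, float]] = {
    "Pro": ("free amino acid", 120.0),
    "Asp": ("free amino acid", 90.0),
    "Gln": ("free amino acid", 85.0),
    "Glu": ("free amino acid", 60.0),
    "GABA": ("free amino acid", 25.0),
    "AcOrn": ("free amino acid", 8.0),
    "Orn": ("free amino acid", 5.0),
    "Cit": ("free amino acid", 4.0),
    "Arg": ("free amino acid", 12.0),
    "Ser": ("free amino acid", 30.0),
    "Met": ("free amino acid", 3.0),
    "Cis": ("free amino acid", 0.5),
    "Put_total": ("total polyamine", 40.0),
    "DAP_total": ("total polyamine", 10.0),
    "Cad_total": ("total polyamine", 6.0),
    "Spd_total": ("total polyamine", 30.0),
    "ThSpm_total": ("total polyamine", 5.0),
    "Spm_total": ("total polyamine", 8.0),
    "Agm_total": ("total polyamine", 28.0),
    "Put_free": ("free polyamine", 20.0),
    "DAP_free": ("free polyamine", 4.0),
    "Spd_free": ("free polyamine", 15.0),
    "Spm_free": ("free polyamine", 3.0),
    "Agm_free": ("free polyamine", 12.0),
    "NorSpd_free": ("free polyamine", 2.0),
}


def default_metabolite_panel() -> tuple[list[str], pd.Series, np.ndarray]:
    """Names, class labels and baselines of the default metabolite panel."""
    names = list(DEFAULT_METABOLITE_PANEL)
    classes = pd.Series({n: c for n, (c, _) in DEFAULT_METABOLITE_PANEL.items()})
    baselines = np.array([b for _, b in DEFAULT_METABOLITE_PANEL.values()])
    return names, classes, baselines


def default_metabolite_effects(
    groups: Sequence[tuple[str, float, str]], metabolites: Sequence[str]
) -> np.ndarray:
    """Group-mean ln-fold-change matrix emulating the screen's signature.

    Primed plants accumulate N-acetylornithine (except 1 mM Put under
    optimal and 0.1 mM Put under salt); stress raises Pro and GABA; the
    best alleviators also raise total polyamine conjugates; 1 mM Orn
    lowers Pro/GABA under salt.
    """
    ln2 = np.log(2.0)
    eff = np.zeros((len(groups), len(metabolites)))
    midx = {m: j for j, m in enumerate(metabolites)}

    def add(i, name, value):
        if name in midx:
            eff[i, midx[name]] += value

    for i, (treat, conc, cond) in enumerate(groups):
        primed = treat != "control"
        if cond in ("osmotic", "salt"):
            add(i, "Pro", 1.2 * ln2)
            add(i, "GABA", 0.6 * ln2)
            add(i, "AcOrn", 0.5 * ln2)
        if primed and not (
            (treat == "Put" and conc == 1.0 and cond == "optimal")
            or (treat == "Put" and conc == 0.1 and cond == "salt")
        ):
            add(i, "AcOrn", ln2)
        if primed and cond == "optimal":
            add(i, "ThSpm_total", 0.8 * ln2)
            add(i, "Spm_total", 0.6 * ln2)
        if treat == "DAP" and conc == 1.0:
            add(i, "DAP_total", 1.5 * ln2)
            add(i, "DAP_free", ln2)
            if cond in ("osmotic", "salt"):
                add(i, "Put_total", 0.8 * ln2)
                add(i, "Spd_total", 0.6 * ln2)
        if treat == "Put":
            add(i, "Put_total", ln2)
            add(i, "Put_free", 0.7 * ln2)
        if treat == "Orn":
            add(i, "Orn", 0.8 * ln2)
            if conc == 1.0 and cond == "salt":
                add(i, "Pro", -0.8 * ln2)
                add(i, "GABA", -0.6 * ln2)
                add(i, "NorSpd_free", 0.8 * ln2)
    return eff


def simulate_metabolites(
    groups: Sequence[tuple[str, float, str]],
    n_per_group: int = 4,
    metabolites: Sequence[str] | None = None,
    classes: pd.Series | Mapping[str, str] | None = None,
    effects: np.ndarray | None = None,
    baselines: np.ndarray | float | None = None,
    noise_sd: float = 0.2,
    seed: int = 0,
) -> MetaboliteTable:
    """Draw a sample × metabolite concentration table.

    Concentrations are ``baseline · exp(effect) · exp(N(0, noise_sd²))``
    with ``effects`` a (n_groups × n_metabolites) matrix of natural-log
    fold changes; ``groups`` are (treatment, concentration, condition)
    triples and each contributes ``n_per_group`` biological replicates
    (default 4).  Reproducible for a fixed seed.
    """
    if n_per_group < 2:
        raise ScenarioError("n_per_group must be >= 2")
    if noise_sd < 0:
        raise ScenarioError("noise_sd must be >= 0")
    if metabolites is None:
        metabolites, default_classes, default_baselines = default_metabolite_panel()
        if classes is None:
            classes = default_classes
        if baselines is None:
            baselines = default_baselines
    if classes is None:
        raise ScenarioError("classes must be given for a custom metabolite list")
    classes = pd.Series(classes)
    n_groups, n_mets = len(groups), len(metabolites)
    if effects is None:
        effects = np.zeros((n_groups, n_mets))
    effects = np.asarray(effects, dtype=float)
    if effects.shape != (n_groups, n_mets):
        raise ScenarioError(
            f"effects must be ({n_groups}, {n_mets}), got {effects.shape}"
        )
    if not np.all(np.isfinite(effects)):
        raise ScenarioError("effects must be finite")
    if baselines is None:
        baselines = 1.0
    baselines = np.broadcast_to(np.asarray(baselines, dtype=float), (n_mets,))
    if np.any(baselines <= 0):
        raise ScenarioError("baselines must be > 0")

    rng = np.random.default_rng(seed)
    rows, meta_rows, ids = [], [], []
    for gi, (treat, conc, cond) in enumerate(groups):
        mean = baselines * np.exp(effects[gi])
        for ri in range(n_per_group):
            noise = (
                np.exp(rng.normal(0.0, noise_sd, size=n_mets)) if noise_sd > 0 else 1.0
            )
            rows.append(mean * noise)
            ids.append(f"{treat}-{conc:g}-{cond}-rep{ri + 1}")
            meta_rows.append(
                {"treatment": treat, "concentration": conc, "condition": cond}
            )
    values = pd.DataFrame(rows, index=pd.Index(ids, name="sample_id"), columns=metabolites)
    meta = pd.DataFrame(meta_rows, index=values.index)
    return MetaboliteTable(values=values, meta=meta, classes=classes)
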