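"""Plant Biostimulant Characterization Index (PBCI).

A treatment×condition group is scored against the unprimed control of
the same growth condition by the sum over the five phenotyping traits
(GC-slope, AUC, RGR, FG, GLI) of log2(mean_treatment / mean_control).
A positive sum marks a growth promoter under optimal conditions or a
stress alleviator under stress; a negative sum marks a stress inductor.

Ratios of group means are used (plants are unpaired across groups).
Traits whose group mean is nonpositive have no principled log ratio:
the component is dropped from the sum, counted, and flagged on the
record rather than clamped.  A bootstrap over plants provides an
optional confidence interval and sign-stability fraction (an addition
of this package; the index itself carries no uncertainty).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .traits import TRAIT_NAMES, TraitVector

logger = logging.getLogger(__name__)

__all__ = [
    "PBCIError",
    "PBCIRecord",
    "BootstrapResult",
    "trait_log2_ratios",
    "pbci_score",
    "classify",
    "bootstrap_pbci",
    "score_all",
    "parallel_coordinates_table",
    "CONDITIONS",
]

CONDITIONS = ("optimal", "osmotic", "salt")


class PBCIError(ValueError):
    """Invalid input to a PBCI computation."""


@dataclass(frozen=True)
class BootstrapResult:
    ci_low: float | None
    ci_high: float | None
    sign_stability: float
    n_undefined: int
    n_boot: int


@dataclass
class PBCIRecord:
    """PBCI of one treatment×condition versus its control.

    ``ratios`` maps each trait to its log2 ratio (NaN when undefined);
    ``pbci`` is the sum of the defined ratios, ``missing`` the traits
    excluded from that sum.
    """

    treatment: str
    concentration: float
    condition: str
    ratios: dict[str, float]
    pbci: float
    label: str
    missing: tuple[str, ...] = ()
    bootstrap: BootstrapResult | None = None


def _trait_matrix(group) -> pd.DataFrame:
    """Coerce a group of TraitVectors or a trait DataFrame to an
    (n_plants × 5) frame with the canonical trait columns."""
    if isinstance(group, pd.DataFrame):
        missing = [t for t in TRAIT_NAMES if t not in group.columns]
        if missing:
            raise PBCIError(f"trait table missing columns: {missing}")
        return group[list(TRAIT_NAMES)].astype(float)
    rows = []
    for tv in group:
        if not isinstance(tv, TraitVector):
            raise PBCIError("expected TraitVector instances or a trait DataFrame")
        rows.append(tv.as_dict())
    if not rows:
        raise PBCIError("empty trait group")
    return pd.DataFrame(rows)


def trait_log2_ratios(treatment_traits, control_traits) -> dict[str, float]:
    """Per-trait log2(mean treatment / mean control).

    Means are over per-plant trait values, NaN-flagged plants excluded
    per trait.  A nonpositive group mean leaves that trait's ratio NaN
    (undefined) with a warning.
    """
    mt = _trait_matrix(treatment_traits).mean(skipna=True)
    mc = _trait_matrix(control_traits).mean(skipna=True)
    out: dict[str, float] = {}
    for trait in TRAIT_NAMES:
        a, b = mt[trait], mc[trait]
        if not (np.isfinite(a) and np.isfinite(b)) or a <= 0 or b <= 0:
            logger.warning(
                "trait %s: log2 ratio undefined (means %.4g / %.4g)", trait, a, b
            )
            out[trait] = float("nan")
        else:
            out[trait] = float(np.log2(a / b))
    return out


def pbci_score(ratios) -> tuple[float, int]:
    """Sum of the defined log2 trait ratios.

    Accepts the dict from :func:`trait_log2_ratios` or a plain sequence.
    Returns ``(pbci, n_missing)``; raises if every ratio is undefined.
    """
    vals = np.asarray(
        list(ratios.values()) if isinstance(ratios, dict) else list(ratios),
        dtype=float,
    )
    if vals.size == 0 or np.all(np.isnan(vals)):
        raise PBCIError("all trait ratios undefined; PBCI cannot be computed")
    n_missing = int(np.isnan(vals).sum())
    return float(np.nansum(vals)), n_missing


def classify(pbci_value: float, condition: str) -> str:
    """Sign rule: positive = promoter (optimal) / alleviator (stress);
    negative = inductor; exactly zero = neutral."""
    if condition not in CONDITIONS:
        raise PBCIError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")
    if not np.isfinite(pbci_value):
        raise PBCIError("PBCI must be finite to classify")
    if pbci_value > 0:
        return "promoter" if condition == "optimal" else "alleviator"
    if pbci_value < 0:
        return "inductor"
    return "neutral"


def bootstrap_pbci(
    treatment_traits,
    control_traits,
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> BootstrapResult:
    """Percentile bootstrap CI of the PBCI, resampling plants within groups.

    ``sign_stability`` is the fraction of replicates sharing the point
    estimate's sign (for a point estimate of exactly 0, the larger of
    the positive and negative replicate fractions, ≈0.5 under the
    null).  The CI is reported unavailable when over half the
    replicates have no defined ratio at all.
    """
    mt = _trait_matrix(treatment_traits).to_numpy()
    mc = _trait_matrix(control_traits).to_numpy()
    if len(mt) < 3 or len(mc) < 3:
        raise PBCIError("bootstrap needs >= 3 plants per group")
    if n_boot < 100:
        raise PBCIError("n_boot must be >= 100")
    rng = np.random.default_rng(seed)

    def score(a: np.ndarray, b: np.ndarray) -> float:
        ma = np.nanmean(a, axis=0)
        mb = np.nanmean(b, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where((ma > 0) & (mb > 0), np.log2(ma / mb), np.nan)
        if np.all(np.isnan(r)):
            return float("nan")
        return float(np.nansum(r))

    point = score(mt, mc)
    reps = np.empty(n_boot)
    for i in range(n_boot):
        reps[i] = score(
            mt[rng.integers(0, len(mt), len(mt))],
            mc[rng.integers(0, len(mc), len(mc))],
        )
    n_undef = int(np.isnan(reps).sum())
    ok = reps[~np.isnan(reps)]
    if n_undef > n_boot / 2:
        logger.warning("bootstrap CI unavailable: %d/%d undefined replicates", n_undef, n_boot)
        ci_low = ci_high = None
    else:
        ci_low, ci_high = (
            float(np.percentile(ok, 100 * alpha / 2)),
            float(np.percentile(ok, 100 * (1 - alpha / 2))),
        )
    frac_pos = float(np.mean(ok > 0)) if ok.size else 0.0
    frac_neg = float(np.mean(ok < 0)) if ok.size else 0.0
    if point > 0:
        stability = frac_pos
    elif point < 0:
        stability = frac_neg
    else:
        stability = max(frac_pos, frac_neg)
    return BootstrapResult(ci_low, ci_high, stability, n_undef, n_boot)


def score_all(
    trait_table: pd.DataFrame,
    *,
    control: str = "control",
    n_boot: int = 0,
    seed: int = 0,
) -> list[PBCIRecord]:
    """Score every treatment×condition of a trait table against its control.

    The control group is scored against itself (PBCI exactly 0,
    ``neutral``), so a full factorial design yields
    n_treatments × n_conditions records.  Set ``n_boot`` > 0 to attach
    bootstrap CIs.
    """
    records = []
    for condition in pd.unique(trait_table["condition"]):
        sub = trait_table[trait_table["condition"] == condition]
        ctrl = sub[sub["treatment"] == control]
        if ctrl.empty:
            raise PBCIError(f"no control group in condition {condition!r}")
        for (treatment, conc), g in sub.groupby(
            ["treatment", "concentration"], sort=True
        ):
            ratios = trait_log2_ratios(g, ctrl)
            value, _ = pbci_score(ratios)
            missing = tuple(t for t, v in ratios.items() if np.isnan(v))
            boot = None
            if n_boot > 0 and treatment != control:
                boot = bootstrap_pbci(g, ctrl, n_boot=n_boot, seed=seed)
            records.append(
                PBCIRecord(
                    treatment=treatment,
                    concentration=float(conc),
                    condition=condition,
                    ratios=ratios,
                    pbci=value,
                    label=classify(value, condition),
                    missing=missing,
                    bootstrap=boot,
                )
            )
    return records


def records_to_frame(records: Iterable[PBCIRecord]) -> pd.DataFrame:
    """One row per record: metadata, the five ratios, PBCI, label, CI."""
    rows = []
    for r in records:
        row = {
            "treatment": r.treatment,
            "concentration": r.concentration,
            "condition": r.condition,
        }
        row.update({f"log2_{t}": r.ratios[t] for t in TRAIT_NAMES})
        row["pbci"] = r.pbci
        row["label"] = r.label
        row["n_missing"] = len(r.missing)
        if r.bootstrap is not None:
            row["ci_low"] = r.bootstrap.ci_low
            row["ci_high"] = r.bootstrap.ci_high
            row["sign_stability"] = r.bootstrap.sign_stability
        rows.append(row)
    return pd.DataFrame(rows)


def parallel_coordinates_table(records: Iterable[PBCIRecord]) -> pd.DataFrame:
    """Tidy (treatment, condition, trait, log2_ratio) table for the
    parallel-coordinates trait plot, with the PBCI and its class label
    on every row.  Undefined ratios contribute no row; ``n_missing``
    carries the count."""
    rows = []
    for r in records:
        for trait in TRAIT_NAMES:
            v = r.ratios[trait]
            if np.isnan(v):
                continue
            rows.append(
                {
                    "treatment": r.treatment,
                    "concentration": r.concentration,
                    "condition": r.condition,
                    "trait": trait,
                    "log2_ratio": v,
                    "pbci": r.pbci,
                    "label": r.label,
                    "n_missing": len(r.missing),
                }
            )
    cols = [
        "treatment", "concentration", "condition", "trait",
        "log2_ratio", "pbci", "label", "n_missing",
    ]
    return pd.DataFrame(rows, columns=cols)
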