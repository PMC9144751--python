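"""End-to-end orchestration: simulate/ingest → traits → PBCI → statistics.

``run_pipeline`` executes the full screen analysis and writes every
result table, a JSON run manifest, and a human-readable PBCI report.
One global seed fans out to per-stage child seeds through
``numpy.random.SeedSequence``, so identical config + seed gives
byte-identical outputs and each stage is independently reproducible.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io import read_trajectory_csv, write_metabolite_csv, write_table
from .pbci import records_to_frame, parallel_coordinates_table, score_all
from .segmentation import extract_time_series
from .simulate import (
    GrowthScenario,
    default_metabolite_effects,
    default_metabolite_panel,
    frame_to_series,
    series_to_frame,
    simulate_growth,
    simulate_metabolites,
)
from .stats import (
    heatmap_matrix,
    kruskal_auc,
    metabolite_anova,
    pca_metabolites,
    pearson_matrix,
)
from .traits import compute_trait_table

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one run.

    ``mode`` is ``"simulate"`` (trajectories are generated from
    ``scenario``) or ``"ingest"`` (a trajectory CSV at
    ``trajectories_path`` is analysed).  ``seed`` governs every source
    of randomness through per-stage child seeds.
    """

    mode: str = "simulate"
    scenario: GrowthScenario = field(default_factory=GrowthScenario)
    trajectories_path: str | None = None
    metabolites_path: str | None = None
    metabolite_classes_path: str | None = None
    auc_mode: str = "trapezoid"
    alpha: float = 0.05
    posthoc: str = "tukey"
    pca_group_means: bool = True
    n_boot: int = 0
    metabolite_noise_sd: float = 0.2
    metabolite_n_per_group: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "ingest"):
            raise PipelineError(f"unknown mode {self.mode!r}")
        if not (0 < self.alpha < 1):
            raise PipelineError("alpha must be in (0, 1)")
        if not isinstance(self.seed, (int, np.integer)):
            raise PipelineError("seed must be an integer")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        sc = d["scenario"]
        sc["timepoints"] = list(map(float, sc["timepoints"]))
        sc["stress_K_multiplier"] = dict(sc["stress_K_multiplier"])
        sc["stress_greenness_multiplier"] = dict(sc["stress_greenness_multiplier"])
        sc["treatments"] = [list(t) for t in sc["treatments"]]
        sc["conditions"] = list(sc["conditions"])
        sc["treatment_effects"] = {
            f"{k[0][0]}|{k[0][1]:g}|{k[1]}": list(dataclasses.astuple(v))
            if dataclasses.is_dataclass(v) else list(v)
            for k, v in self.scenario.treatment_effects.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        from .simulate import TreatmentEffect

        d = dict(d)
        sc = dict(d.pop("scenario", {}))
        if sc:
            if "treatments" in sc:
                sc["treatments"] = tuple((c, float(m)) for c, m in sc["treatments"])
            if "conditions" in sc:
                sc["conditions"] = tuple(sc["conditions"])
            if "timepoints" in sc:
                sc["timepoints"] = np.asarray(sc["timepoints"], dtype=float)
            eff = {}
            for key, vals in sc.pop("treatment_effects", {}).items():
                compound, conc, cond = key.split("|")
                eff[((compound, float(conc)), cond)] = TreatmentEffect(*vals)
            sc["treatment_effects"] = eff
            d["scenario"] = GrowthScenario(**sc)
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _stage_seeds(seed: int) -> dict[str, int]:
    names = ("growth", "metabolites", "bootstrap", "render")
    states = np.random.SeedSequence(seed).generate_state(len(names))
    return {n: int(s % (2**31)) for n, s in zip(names, states)}


def _report_text(pbci_frame: pd.DataFrame) -> str:
    lines = ["# PBCI report", ""]
    for condition in pd.unique(pbci_frame["condition"]):
        sub = pbci_frame[pbci_frame["condition"] == condition]
        lines.append(f"## Condition: {condition}")
        lines.append("")
        lines.append("| treatment | concentration (mM) | PBCI | class |")
        lines.append("|---|---|---|---|")
        for _, r in sub.iterrows():
            lines.append(
                f"| {r['treatment']} | {r['concentration']:g} | "
                f"{r['pbci']:+.3f} | {r['label']} |"
            )
        lines.append("")
    return "\n".join(lines)


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict[str, Path]:
    """Run the full analysis and write all outputs under ``outdir``.

    Returns a mapping of output names to paths.  On stage failure a
    ``FAILED`` marker naming the stage is written next to any partial
    outputs and :class:`PipelineError` is raised.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    paths: dict[str, Path] = {}
    stage = "setup"
    try:
        stage = "simulate" if config.mode == "simulate" else "ingest"
        if config.mode == "simulate":
            scenario = dataclasses.replace(config.scenario, seed=seeds["growth"])
            series = simulate_growth(scenario)
        else:
            if not config.trajectories_path:
                raise PipelineError("ingest mode needs trajectories_path")
            p = Path(config.trajectories_path)
            if not p.exists():
                raise PipelineError(f"trajectory file not found: {p}")
            series = frame_to_series(read_trajectory_csv(p))
        paths["trajectories"] = write_table(
            series_to_frame(series), outdir / "trajectories.csv"
        )

        stage = "traits"
        trait_table = compute_trait_table(series, auc_mode=config.auc_mode)
        paths["traits"] = write_table(trait_table, outdir / "traits.csv")

        stage = "pbci"
        records = score_all(
            trait_table, n_boot=config.n_boot, seed=seeds["bootstrap"]
        )
        pbci_frame = records_to_frame(records)
        paths["pbci"] = write_table(pbci_frame, outdir / "pbci.csv")
        paths["parallel_coordinates"] = write_table(
            parallel_coordinates_table(records), outdir / "parallel_coordinates.csv"
        )

        stage = "stats:kruskal"
        kw = pd.concat(
            [
                kruskal_auc(trait_table, cond, alpha=config.alpha)
                for cond in pd.unique(trait_table["condition"])
            ],
            ignore_index=True,
        )
        paths["kruskal_auc"] = write_table(kw, outdir / "kruskal_auc.csv")

        stage = "stats:metabolites"
        if config.mode == "simulate":
            groups = [
                (t, c, cond)
                for cond in config.scenario.conditions
                for t, c in config.scenario.treatments
            ]
            names, classes, baselines = default_metabolite_panel()
            mtable = simulate_metabolites(
                groups,
                n_per_group=config.metabolite_n_per_group,
                metabolites=names,
                classes=classes,
                effects=default_metabolite_effects(groups, names),
                baselines=baselines,
                noise_sd=config.metabolite_noise_sd,
                seed=seeds["metabolites"],
            )
        else:
            if not config.metabolites_path:
                mtable = None
            else:
                from .io import read_metabolite_csv

                mtable = read_metabolite_csv(
                    config.metabolites_path, config.metabolite_classes_path
                )
        if mtable is not None:
            write_metabolite_csv(
                mtable, outdir / "metabolites.csv", outdir / "metabolite_classes.csv"
            )
            paths["metabolites"] = outdir / "metabolites.csv"
            anova = metabolite_anova(
                mtable, posthoc=config.posthoc, alpha=config.alpha
            )
            paths["anova"] = write_table(anova.anova, outdir / "anova.csv")
            if anova.posthoc is not None:
                paths["posthoc"] = write_table(anova.posthoc, outdir / "posthoc.csv")

            stage = "stats:pca"
            pca = pca_metabolites(mtable, group_means=config.pca_group_means)
            paths["pca_scores"] = write_table(
                pca.scores.reset_index(names="sample"), outdir / "pca_scores.csv"
            )
            paths["pca_loadings"] = write_table(
                pca.loadings.reset_index(names="variable"), outdir / "pca_loadings.csv"
            )
            paths["pca_variance"] = write_table(
                pd.DataFrame(
                    {
                        "component": [f"PC{i+1}" for i in range(len(pca.variance_explained))],
                        "variance_fraction": pca.variance_explained,
                    }
                ),
                outdir / "pca_variance.csv",
            )

            stage = "stats:pearson"
            corr = pearson_matrix(mtable.log_values())
            paths["correlation_r"] = write_table(
                corr.r.reset_index(names="variable"), outdir / "correlation_r.csv"
            )
            paths["correlation_p"] = write_table(
                corr.p.reset_index(names="variable"), outdir / "correlation_p.csv"
            )

            stage = "stats:heatmap"
            hm = heatmap_matrix(mtable, anova)
            hm_out = hm.values.copy()
            hm_out.insert(0, "class", hm.classes.values)
            paths["heatmap"] = write_table(
                hm_out.reset_index(names="metabolite"), outdir / "heatmap.csv"
            )

        stage = "report"
        report = _report_text(pbci_frame)
        report_path = outdir / "report.md"
        report_path.write_text(report)
        paths["report"] = report_path

        manifest = {
            "package": "phenoprime",
            "version": __version__,
            "config": config.to_dict(),
            "stage_seeds": seeds,
            "versions": {
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
            "outputs": {k: str(v.name) for k, v in paths.items()},
            "n_plants": int(trait_table.shape[0]),
            "n_pbci_rows": int(pbci_frame.shape[0]),
        }
        manifest_path = outdir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        paths["manifest"] = manifest_path
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    return paths
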