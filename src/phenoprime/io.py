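"""File formats: long-format CSV tables, PNG scenes, JSON configs.

All tables are UTF-8 CSV with '.' decimals and explicit schemas; label
masks round-trip losslessly as 16-bit PNG; layouts and configs as JSON.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from PIL import Image

from .simulate import PlateLayout, PlateScene
from .stats import MetaboliteTable

__all__ = [
    "SchemaError",
    "TRAIT_COLUMNS",
    "read_table",
    "write_table",
    "read_trait_csv",
    "read_trajectory_csv",
    "save_scene",
    "load_scene",
    "write_metabolite_csv",
    "read_metabolite_csv",
]


class SchemaError(ValueError):
    """A table lacks required columns."""


TRAIT_COLUMNS = [
    "plant_id", "treatment", "concentration", "condition",
    "gc_slope", "auc", "rgr", "fg", "gli",
]
TRAJECTORY_REQUIRED = [
    "plant_id", "treatment", "concentration", "condition", "time_days", "area_px",
]


def _check_columns(df: pd.DataFrame, required: Iterable[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required columns: {missing}")


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def read_table(path: str | Path, required: Iterable[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path)
    if required is not None:
        _check_columns(df, required, str(path))
    return df


def read_trait_csv(path: str | Path) -> pd.DataFrame:
    return read_table(path, TRAIT_COLUMNS)


def read_trajectory_csv(path: str | Path) -> pd.DataFrame:
    return read_table(path, TRAJECTORY_REQUIRED)


def save_scene(scene: PlateScene, stem: str | Path) -> dict[str, Path]:
    """Write a scene as ``<stem>.png`` (RGB image), ``<stem>.mask.png``
    (16-bit label mask, if present) and ``<stem>.layout.json``."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    paths = {}
    img_path = stem.with_suffix(".png")
    Image.fromarray(scene.image, mode="RGB").save(img_path)
    paths["image"] = img_path
    if scene.truth_mask is not None:
        mask_path = stem.parent / (stem.name + ".mask.png")
        Image.fromarray(scene.truth_mask.astype(np.uint16)).save(mask_path)
        paths["mask"] = mask_path
    layout_path = stem.parent / (stem.name + ".layout.json")
    layout_path.write_text(
        json.dumps({"layout": scene.layout.to_dict(), "time": scene.time}, indent=2)
    )
    paths["layout"] = layout_path
    return paths


def load_scene(stem: str | Path) -> PlateScene:
    """Load a scene written by :func:`save_scene`."""
    stem = Path(stem)
    layout_path = stem.parent / (stem.name + ".layout.json")
    if not layout_path.exists():
        raise FileNotFoundError(f"missing layout file: {layout_path}")
    meta = json.loads(layout_path.read_text())
    image = np.asarray(Image.open(stem.with_suffix(".png")).convert("RGB"))
    mask_path = stem.parent / (stem.name + ".mask.png")
    mask = None
    if mask_path.exists():
        mask = np.asarray(Image.open(mask_path)).astype(np.uint16)
    return PlateScene(
        image=image,
        layout=PlateLayout.from_dict(meta["layout"]),
        truth_mask=mask,
        time=float(meta.get("time", 0.0)),
    )


def write_metabolite_csv(table: MetaboliteTable, values_path, classes_path) -> None:
    """Write concentrations (+ design columns) and the metabolite-class map."""
    values_path, classes_path = Path(values_path), Path(classes_path)
    values_path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.concat([table.meta, table.values], axis=1)
    df.to_csv(values_path, index_label="sample_id")
    table.classes.rename("class").to_csv(classes_path, index_label="metabolite")


def read_metabolite_csv(values_path, classes_path) -> MetaboliteTable:
    df = pd.read_csv(values_path, index_col="sample_id")
    _check_columns(df, ["treatment", "concentration", "condition"], str(values_path))
    meta = df[["treatment", "concentration", "condition"]]
    values = df.drop(columns=["treatment", "concentration", "condition"])
    classes = pd.read_csv(classes_path, index_col="metabolite")["class"]
    return MetaboliteTable(values=values, meta=meta, classes=classes)
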