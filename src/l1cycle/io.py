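"""Serialization: CSV tables, 16-bit TIFF channels, YAML sidecar configs.

Every generated artifact is written together with a YAML sidecar
capturing the generating parameters and seed, so that any output can be
reproduced bit-for-bit from its sidecar alone.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile
import yaml

from .datatypes import CellField, FACSTable, ImageBundle, PeptideTable

__all__ = [
    "write_cell_field",
    "read_cell_field",
    "write_facs_table",
    "read_facs_table",
    "write_image_bundle",
    "read_image_bundle",
    "write_peptide_table",
    "read_peptide_table",
    "write_sidecar",
    "write_json",
]


def write_sidecar(path: Path, params: dict) -> Path:
    """Write the YAML parameter/seed sidecar next to an output file."""
    side = Path(str(path) + ".config.yaml")
    with open(side, "w") as fh:
        yaml.safe_dump(params, fh, sort_keys=True)
    return side


def write_json(path, obj) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_default)


def write_cell_field(field: CellField, path, params: Optional[dict] = None) -> None:
    path = Path(path)
    df = field.cells.copy()
    for col in ("x", "y"):
        df[col] = df[col].round(3)
    df.to_csv(path, index=False)
    meta = {"width": field.width, "height": field.height}
    if params:
        meta.update(params)
    write_sidecar(path, meta)


def read_cell_field(path, width: Optional[float] = None,
                    height: Optional[float] = None) -> CellField:
    path = Path(path)
    df = pd.read_csv(path)
    if "pair_id" not in df.columns:
        df["pair_id"] = pd.NA
    df["pair_id"] = pd.array(df["pair_id"], dtype="Int64")
    df["nuclear_positive"] = df["nuclear_positive"].astype(bool)
    side = Path(str(path) + ".config.yaml")
    if (width is None or height is None) and side.exists():
        with open(side) as fh:
            meta = yaml.safe_load(fh)
        width = width if width is not None else meta.get("width")
        height = height if height is not None else meta.get("height")
    if width is None:
        width = float(df["x"].max()) if len(df) else 0.0
    if height is None:
        height = float(df["y"].max()) if len(df) else 0.0
    return CellField(df, float(width), float(height))


def write_facs_table(facs: FACSTable, path, params: Optional[dict] = None) -> None:
    path = Path(path)
    facs.events.to_csv(path, index=False)
    if params is not None:
        write_sidecar(path, params)


def read_facs_table(path) -> FACSTable:
    df = pd.read_csv(path)
    if "true_event_time" in df.columns:
        df["true_event_time"] = pd.array(df["true_event_time"], dtype="Float64")
    return FACSTable(df)


def write_image_bundle(bundle: ImageBundle, prefix,
                       params: Optional[dict] = None) -> dict:
    """Write 16-bit TIFF per channel plus a CSV truth table.

    Returns the mapping of written paths.
    """
    prefix = Path(prefix)
    paths = {
        "nuclear": prefix.with_name(prefix.name + "_nuclear.tif"),
        "marker": prefix.with_name(prefix.name + "_marker.tif"),
        "truth": prefix.with_name(prefix.name + "_truth.csv"),
    }
    for key, chan in (("nuclear", bundle.nuclear_channel),
                      ("marker", bundle.marker_channel)):
        arr = np.clip(np.round(np.asarray(chan)), 0, 65535).astype(np.uint16)
        tifffile.imwrite(paths[key], arr)
    bundle.truth.to_csv(paths["truth"], index=False)
    meta = {"pixel_size": bundle.pixel_size}
    if params:
        meta.update(params)
    write_sidecar(paths["truth"], meta)
    return {k: str(v) for k, v in paths.items()}


def read_image_bundle(prefix) -> ImageBundle:
    prefix = Path(prefix)
    nuclear = tifffile.imread(prefix.with_name(prefix.name + "_nuclear.tif")).astype(float)
    marker = tifffile.imread(prefix.with_name(prefix.name + "_marker.tif")).astype(float)
    truth = pd.read_csv(prefix.with_name(prefix.name + "_truth.csv"))
    side = Path(str(prefix.with_name(prefix.name + "_truth.csv")) + ".config.yaml")
    pixel_size = 1.0
    if side.exists():
        with open(side) as fh:
            pixel_size = float(yaml.safe_load(fh).get("pixel_size", 1.0))
    return ImageBundle(nuclear, marker, pixel_size, truth)


def write_peptide_table(table: PeptideTable, path,
                        params: Optional[dict] = None) -> None:
    table.rows.to_csv(path, sep="\t", index=False)
    if params is not None:
        write_sidecar(Path(path), params)


def read_peptide_table(path) -> PeptideTable:
    """Read a peptide-count CSV/TSV; missing count cells become zeros."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    for col in ("V5_1", "V5_2", "IgG_1", "IgG_2"):
        if col not in df.columns:
            df[col] = 0
        df[col] = pd.to_numeric(df[col], errors="coerce").fillna(0).astype(int)
    return PeptideTable(df)
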