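"""Readers and writers for cell tables, typing schemas, masks and run metadata.

Cell tables are delimited text (CSV/TSV) with a header; masks are
single-channel TIFF or PNG rasters (any nonzero value is foreground);
schemas and run configs are YAML.  All coordinates are microns.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import REQUIRED_COLUMNS, CellTable, CompartmentMaskSet, RunConfig, TypingSchema
from .errors import MaskError, SchemaError

logger = logging.getLogger("cytoplex")


def _delimiter_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if path.suffix.lower() in (".tsv", ".txt") else ","


def read_cell_table(path: str | Path, marker_columns: Sequence[str] | None = None,
                    delimiter: str | None = None) -> CellTable:
    """Read a delimited per-cell table.

    ``marker_columns`` names the intensity columns; when omitted, every
    column other than the required ones and ``area`` is treated as a marker.
    Raises :class:`SchemaError` for a missing column and
    :class:`ValidationError` (with the row index) for negative or non-finite
    values.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter_for(path, delimiter),
                     float_precision="round_trip")
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"cell table {path.name!r} lacks required column {col!r}")
    if marker_columns is None:
        marker_columns = [c for c in df.columns
                          if c not in REQUIRED_COLUMNS and c != "area"]
    else:
        for m in marker_columns:
            if m not in df.columns:
                raise SchemaError(f"cell table {path.name!r} lacks marker column {m!r}")
    df["cell_id"] = df["cell_id"].astype(str)
    df["image_id"] = df["image_id"].astype(str)
    return CellTable(df.reset_index(drop=True), tuple(marker_columns))


def write_cell_table(table: CellTable, path: str | Path,
                     delimiter: str | None = None) -> None:
    path = Path(path)
    cols = [c for c in REQUIRED_COLUMNS] + (["area"] if "area" in table.df else [])
    cols += list(table.markers)
    table.df[cols].to_csv(path, sep=_delimiter_for(path, delimiter), index=False)


def read_typing_schema(path: str | Path) -> TypingSchema:
    """Read a YAML typing configuration (markers, lineages, subtypes,
    reference markers, population criteria, perturbation)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping) or "markers" not in data:
        raise SchemaError(f"{Path(path).name!r} is not a typing schema (no 'markers')")
    return TypingSchema.from_dict(data)


def write_typing_schema(schema: TypingSchema, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(schema.to_dict(), fh, sort_keys=False)


def read_run_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)


def _read_raster(path: Path) -> np.ndarray:
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        arr = tifffile.imread(path)
    else:
        from PIL import Image
        arr = np.asarray(Image.open(path))
    arr = np.squeeze(arr)
    if arr.ndim != 2:
        raise MaskError(f"mask {path.name!r} is not single-channel (shape {arr.shape})")
    return (arr != 0).astype(np.uint8)


def read_masks(paths: Mapping[str, Mapping[str, str | Path]],
               microns_per_pixel: float) -> CompartmentMaskSet:
    """Read binary compartment masks.

    ``paths`` maps image id to ``{compartment name: raster path}``.  Any
    nonzero pixel is foreground; rasters of one image must share a shape.
    """
    masks = {img: {name: _read_raster(Path(p)) for name, p in comps.items()}
             for img, comps in paths.items()}
    return CompartmentMaskSet(masks, microns_per_pixel)


def write_masks(maskset: CompartmentMaskSet, out_dir: str | Path) -> list[Path]:
    import tifffile
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for img, comps in maskset.masks.items():
        for name, arr in comps.items():
            p = out_dir / f"{img}_{name}.tif"
            tifffile.imwrite(p, (arr * 255).astype(np.uint8))
            written.append(p)
    return written


def write_run_metadata(path: str | Path, *, command: str, config: RunConfig,
                       inputs: Mapping[str, str] | None = None,
                       outputs: Sequence[str] = (),
                       timings: Mapping[str, float] | None = None,
                       warnings: Sequence[str] = ()) -> None:
    """Write the run-metadata sidecar (seed, config hash, version, artefacts).

    Written even on partial failure so a run is always accounted for."""
    meta = {
        "command": command,
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.hash(),
        "config": config.to_dict(),
        "inputs": dict(inputs or {}),
        "outputs": list(map(str, outputs)),
        "timings_s": {k: round(v, 3) for k, v in (timings or {}).items()},
        "warnings": list(warnings),
        "written_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=2)
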