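"""File I/O: CSV tables, TIFF images, and plate-layout YAML."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .scoring import ScreenLayout

__all__ = [
    "write_table",
    "read_table",
    "write_tiff",
    "read_tiff",
    "read_layout_yaml",
    "write_layout_yaml",
]


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    """CSV writer preserving full float precision (repr round-trip)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=index, float_format="%.17g")


def read_table(path, index_col=0) -> pd.DataFrame:
    try:
        return pd.read_csv(path, index_col=index_col, float_precision="round_trip")
    except pd.errors.ParserError as e:
        raise ValueError(f"malformed CSV {path}: {e}") from e


def write_tiff(path, image: np.ndarray) -> None:
    """Write a 2-D image or a (pages, H, W) stack as (multi-page) TIFF."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, image)


def read_tiff(path) -> np.ndarray:
    try:
        return tifffile.imread(path)
    except (tifffile.TiffFileError, FileNotFoundError) as e:
        raise ValueError(f"cannot read TIFF {path}: {e}") from e


def read_layout_yaml(path) -> ScreenLayout:
    """Load and validate a plate-layout YAML.

    Expected structure::

        wells:
          A03: {condition: mock, plate: P1, column: 3, is_mock: true}
          A04: {condition: siDOCK5, plate: P1, column: 4}
    """
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    except yaml.YAMLError as e:
        raise ValueError(f"malformed layout YAML {path}: {e}") from e
    if not isinstance(raw, dict) or "wells" not in raw:
        raise ValueError("layout YAML must contain a top-level 'wells' mapping")
    rows = []
    for well_id, entry in raw["wells"].items():
        entry = dict(entry or {})
        unknown = set(entry) - {"condition", "plate", "column", "is_mock"}
        if unknown:
            raise ValueError(f"well {well_id!r}: unknown layout keys {sorted(unknown)}")
        rows.append(
            {
                "well_id": well_id,
                "condition": entry.get("condition", ""),
                "plate": entry.get("plate", "P1"),
                "column": int(entry.get("column", 0)),
                "is_mock": bool(entry.get("is_mock", False)),
            }
        )
    return ScreenLayout(wells=pd.DataFrame(rows).set_index("well_id"))


def write_layout_yaml(layout: ScreenLayout, path) -> None:
    wells = {
        well_id: {
            "condition": row["condition"],
            "plate": row["plate"],
            "column": int(row["column"]),
            "is_mock": bool(row["is_mock"]),
        }
        for well_id, row in layout.wells.iterrows()
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump({"wells": wells}, fh, sort_keys=True)
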