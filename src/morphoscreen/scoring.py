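"""Screen-level aggregation: wells, plate normalization, Z-scores, hits.

Single-cell classifications and nuclear:ring marker ratios are summarised
per well (shape fractions over classified non-normal cells, median log10
ratio, normal fraction), optionally plate-normalized by subtracting the
per-plate median of mock wells, then converted to Z-scores against the
pooled mock wells of the screen:

    Z = (value - mean_mock) / sd_mock

Each condition's quantitative morphological signature (QMS) is the mean of
its replicate wells' Z-scores per metric.  Hits: |Z| >= 1.5 on the YAP/TAZ
ratio (sign gives direction), and normal-fraction Z <= -1 for shape hits.
Wells on the density-gradient columns (1, 2, 23, 24) are excluded
throughout, as are wells below a minimum cell count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SHAPE_CLASSES",
    "ScreenLayout",
    "summarize_wells",
    "zscore_vs_mock",
    "assemble_qms",
    "call_hits",
]

SHAPE_CLASSES = ("spindly", "large_round", "triangular", "fan", "small_round")
DENSITY_COLUMNS = (1, 2, 23, 24)
YAP_Z_THRESHOLD = 1.5
NORMAL_Z_THRESHOLD = -1.0
MIN_CELLS_PER_WELL = 50

_METRICS = [f"frac_{s}" for s in SHAPE_CLASSES] + ["median_ratio", "normal_fraction"]


@dataclass
class ScreenLayout:
    """Well -> condition map with mock flags and plate/column assignment."""

    wells: pd.DataFrame  # index well_id; condition, plate, column, is_mock

    def __post_init__(self) -> None:
        required = {"condition", "plate", "column", "is_mock"}
        missing = required - set(self.wells.columns)
        if missing:
            raise ValueError(f"layout missing columns {sorted(missing)}")
        if self.wells.index.has_duplicates:
            raise ValueError("duplicate well ids in layout")
        if not self.wells["is_mock"].any():
            raise ValueError("layout contains no mock wells")

    @property
    def mock_wells(self) -> pd.Index:
        return self.wells.index[self.wells["is_mock"]]


def summarize_wells(
    cells: pd.DataFrame,
    layout: ScreenLayout,
    min_cells: int = MIN_CELLS_PER_WELL,
) -> pd.DataFrame:
    """Aggregate a single-cell table to per-well summaries.

    ``cells`` needs columns well_id, shape_class (one of SHAPE_CLASSES or
    "normal"), and ratio (log10 nuclear:ring, NaN allowed).  Shape
    fractions are over classified non-normal cells; the normal fraction is
    over all cells.  Wells on density columns or under ``min_cells`` are
    flagged excluded.
    """
    unknown = set(cells["well_id"]) - set(layout.wells.index)
    if unknown:
        raise ValueError(f"cells reference unknown wells: {sorted(unknown)[:5]}")
    rows = []
    for well_id, grp in cells.groupby("well_id", sort=True):
        info = layout.wells.loc[well_id]
        n = len(grp)
        shaped = grp[grp["shape_class"] != "normal"]
        fracs = {
            f"frac_{s}": (np.mean(shaped["shape_class"] == s) if len(shaped) else np.nan)
            for s in SHAPE_CLASSES
        }
        rows.append(
            {
                "well_id": well_id,
                "condition": info["condition"],
                "plate": info["plate"],
                "column": int(info["column"]),
                "is_mock": bool(info["is_mock"]),
                "n_cells": n,
                **fracs,
                "median_ratio": float(np.nanmedian(grp["ratio"])) if grp["ratio"].notna().any() else np.nan,
                "normal_fraction": float(np.mean(grp["shape_class"] == "normal")),
                "excluded": int(info["column"]) in DENSITY_COLUMNS or n < min_cells,
            }
        )
    return pd.DataFrame(rows).set_index("well_id")


def _plate_normalize(wells: pd.DataFrame, metrics: list[str]) -> pd.DataFrame:
    """Subtract the per-plate median of (non-excluded) mock wells."""
    out = wells.copy()
    for plate, grp in wells.groupby("plate"):
        mocks = grp[grp["is_mock"] & ~grp["excluded"]]
        if mocks.empty:
            raise ValueError(f"plate {plate!r} has no usable mock wells")
        med = mocks[metrics].median()
        out.loc[grp.index, metrics] = grp[metrics] - med
    return out


def zscore_vs_mock(
    wells: pd.DataFrame,
    metrics: list[str] | None = None,
    plate_normalize: bool = True,
    min_mock_wells: int = 8,
) -> pd.DataFrame:
    """Per-well Z-scores against the pooled mock wells of the screen.

    Excluded wells never contribute to the mock statistics but still
    receive Z-scores (flagged by the carried-over ``excluded`` column).
    """
    metrics = metrics or [m for m in _METRICS if m in wells.columns]
    usable_mock = wells[wells["is_mock"] & ~wells["excluded"]]
    if len(usable_mock) < min_mock_wells:
        raise ValueError(
            f"only {len(usable_mock)} usable mock wells; need >= {min_mock_wells}"
        )
    if plate_normalize:
        wells = _plate_normalize(wells, metrics)
        usable_mock = wells.loc[usable_mock.index]
    z = wells.copy()
    for m in metrics:
        mu = usable_mock[m].mean()
        sd = usable_mock[m].std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"mock standard deviation is zero for metric {m!r}")
        z[m] = (wells[m] - mu) / sd
    return z


def assemble_qms(zscores: pd.DataFrame, metrics: list[str] | None = None) -> pd.DataFrame:
    """Condition-level QMS = mean of replicate-well Z-scores per metric."""
    metrics = metrics or [m for m in _METRICS if m in zscores.columns]
    usable = zscores[~zscores["excluded"]]
    if usable.empty:
        raise ValueError("no non-excluded wells")
    qms = usable.groupby("condition")[metrics].mean()
    qms["n_replicates"] = usable.groupby("condition").size()
    return qms


def call_hits(
    z: pd.DataFrame,
    yap_threshold: float = YAP_Z_THRESHOLD,
    normal_threshold: float = NORMAL_Z_THRESHOLD,
    ratio_metric: str = "median_ratio",
    normal_metric: str = "normal_fraction",
) -> pd.DataFrame:
    """Flag hits from a Z-score table (per well or per condition).

    yap_high: Z >= +threshold; yap_low: Z <= -threshold (both inclusive);
    shape_hit: normal-fraction Z <= normal_threshold.  Excluded wells are
    never flagged.
    """
    out = z.copy()
    excluded = out["excluded"] if "excluded" in out.columns else pd.Series(False, index=out.index)
    out["yap_high"] = (out[ratio_metric] >= yap_threshold) & ~excluded
    out["yap_low"] = (out[ratio_metric] <= -yap_threshold) & ~excluded
    if normal_metric in out.columns:
        out["shape_hit"] = (out[normal_metric] <= normal_threshold) & ~excluded
    return out
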