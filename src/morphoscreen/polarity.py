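"""Wound-healing polarity readouts: Golgi orientation and migration rate.

The Golgi angle is measured between the nucleus-to-Golgi vector and the
wound line, with the convention that 90 deg means the Golgi faces the wound
(front-rear polarity established) and 0/180 deg mean the Golgi lies parallel
to the wound.  Cells whose Golgi sits on the far side of the nucleus from
the wound are excluded: only cells with their Golgi within the wound-facing
half-plane are scored.

Angles are summarised as frequencies over the bin centres
0, 30, 60, 90, 120, 150, 180 deg (nearest centre, ties to the lower bin).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["GolgiAngleRecord", "golgi_angle", "score_golgi_table", "bin_angles", "migration_rate"]

ANGLE_BIN_CENTRES = (0, 30, 60, 90, 120, 150, 180)


@dataclass
class GolgiAngleRecord:
    cell_id: str
    nucleus: tuple[float, float]
    golgi: tuple[float, float]
    angle_deg: float | None  # None when Golgi == nucleus or off wound side
    wound_side: bool


def _wound_frame(wound_line, inward_normal):
    """Unit tangent/normal pair for the wound; tangent sign fixed so the
    (t, n) frame is right-handed, making 30 vs 150 deg assignments
    deterministic."""
    p0, p1 = (np.asarray(p, dtype=float) for p in wound_line)
    t = p1 - p0
    norm = np.linalg.norm(t)
    if norm == 0.0:
        raise ValueError("degenerate wound line")
    t = t / norm
    n = np.asarray(inward_normal, dtype=float)
    n = n - t * (n @ t)  # enforce orthogonality to the wound
    n_norm = np.linalg.norm(n)
    if n_norm == 0.0:
        raise ValueError("inward normal parallel to wound line")
    n = n / n_norm
    if t[0] * n[1] - t[1] * n[0] < 0:
        t = -t
    return t, n


def golgi_angle(nucleus, golgi, wound_line, inward_normal) -> tuple[float | None, bool]:
    """Angle (deg) of the nucleus->Golgi vector relative to the wound.

    Returns ``(theta, wound_side)``.  ``theta`` is ``None`` when the Golgi
    coincides with the nucleus centroid or the cell is flagged off the
    wound side (v . n < 0); otherwise theta in [0, 180] with 90 deg meaning
    the Golgi points along the inward wound normal.
    """
    t, n = _wound_frame(wound_line, inward_normal)
    v = np.asarray(golgi, dtype=float) - np.asarray(nucleus, dtype=float)
    vn = np.linalg.norm(v)
    if vn == 0.0:
        return None, False
    if v @ n < 0:
        return None, False
    cos_t = np.clip((v @ t) / vn, -1.0, 1.0)
    return float(np.degrees(np.arccos(cos_t))), True


def score_golgi_table(table: pd.DataFrame, wound_line, inward_normal) -> pd.DataFrame:
    """Score every cell of a nucleus/Golgi coordinate table.

    ``table`` needs columns nucleus_x, nucleus_y, golgi_x, golgi_y and an
    optional cell_id.  Returns the table with ``angle_deg`` (NaN when
    excluded) and ``wound_side`` columns appended.
    """
    angles = np.full(len(table), np.nan)
    side = np.zeros(len(table), dtype=bool)
    for i, row in enumerate(table.itertuples(index=False)):
        theta, ws = golgi_angle(
            (row.nucleus_x, row.nucleus_y), (row.golgi_x, row.golgi_y), wound_line, inward_normal
        )
        side[i] = ws
        if theta is not None:
            angles[i] = theta
    out = table.copy()
    out["angle_deg"] = angles
    out["wound_side"] = side
    return out


def bin_angles(angles_deg) -> pd.DataFrame:
    """Frequency table over the 30-degree bin centres.

    Each angle goes to the nearest centre; exact midpoints (15, 45, ...)
    go to the lower bin.  Percentages are over the included (finite) angles.
    """
    a = np.asarray(angles_deg, dtype=float)
    a = a[np.isfinite(a)]
    centres = np.asarray(ANGLE_BIN_CENTRES, dtype=float)
    counts = np.zeros(len(centres), dtype=int)
    if a.size:
        # nearest centre with midpoint ties resolved downward:
        # bin k covers (30k - 15, 30k + 15]
        idx = np.ceil((a - 15.0) / 30.0).astype(int)
        idx = np.clip(idx, 0, len(centres) - 1)
        counts = np.bincount(idx, minlength=len(centres))
    pct = 100.0 * counts / a.size if a.size else np.zeros(len(centres))
    return pd.DataFrame({"bin_deg": ANGLE_BIN_CENTRES, "count": counts, "percent": pct})


def migration_rate(times_h, front_positions_um) -> float:
    """Wound-edge migration rate (um/hour) by least-squares slope.

    ``front_positions_um`` is the mean displacement of the wound edge at
    each time point; times must be strictly increasing with >= 3 points.
    The fitted slope is invariant to the choice of time origin.
    """
    t = np.asarray(times_h, dtype=float)
    y = np.asarray(front_positions_um, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 time points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time points must be strictly increasing")
    slope = np.polynomial.polynomial.polyfit(t, y, 1)[1]
    return float(slope)
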