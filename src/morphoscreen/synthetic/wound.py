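"""Synthetic wound-healing assays: Golgi/nucleus coordinates and wound front.

The wound is a vertical line; the monolayer sits on its left and the
inward wound normal points +x.  A fraction ``polarity_bias`` of cells has
its Golgi placed exactly on the wound normal from the nucleus (true angle
90 deg); the remainder draw a true angle uniformly in [0, 180] deg within
the wound-facing half-plane.  The wound front recedes at a configurable
speed with optional measurement noise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def generate_wound_assay(
    n_cells: int,
    polarity_bias: float,
    seed: int = 0,
    wound_x: float = 1500.0,
    field_height: float = 1000.0,
    golgi_distance_px: float = 12.0,
    front_speed_um_h: float = 20.0,
    n_hours: float = 10.0,
    dt_h: float = 0.5,
    front_noise_sd_um: float = 0.0,
):
    """Generate one wound assay with known per-cell Golgi angles.

    Returns
    -------
    cells : DataFrame with cell_id, nucleus_x/y, golgi_x/y, true_angle_deg
    wound_line : ((x, y0), (x, y1)) endpoints of the wound
    inward_normal : (1, 0)
    front : DataFrame with time_h, displacement_um (ground-truth slope =
        ``front_speed_um_h``)
    """
    if not 0.0 <= polarity_bias <= 1.0:
        raise ValueError("polarity_bias must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    polar = rng.random(n_cells) < polarity_bias
    angles = np.where(polar, 90.0, rng.uniform(0.0, 180.0, size=n_cells))
    nx = rng.uniform(100.0, wound_x - 100.0, size=n_cells)
    ny = rng.uniform(0.0, field_height, size=n_cells)
    # right-handed (tangent, inward-normal) frame: tangent = -y, normal = +x;
    # angle theta from the tangent, 90 deg = straight toward the wound
    rad = np.radians(angles)
    gx = nx + golgi_distance_px * np.sin(rad)
    gy = ny - golgi_distance_px * np.cos(rad)
    cells = pd.DataFrame(
        {
            "cell_id": [f"c{i:05d}" for i in range(n_cells)],
            "nucleus_x": nx,
            "nucleus_y": ny,
            "golgi_x": gx,
            "golgi_y": gy,
            "true_angle_deg": angles,
        }
    )
    times = np.arange(0.0, n_hours + 1e-9, dt_h)
    disp = front_speed_um_h * times
    if front_noise_sd_um > 0:
        disp = disp + rng.normal(0.0, front_noise_sd_um, size=times.size)
    front = pd.DataFrame({"time_h": times, "displacement_um": disp})
    wound_line = ((wound_x, 0.0), (wound_x, field_height))
    return cells, wound_line, (1.0, 0.0), front
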