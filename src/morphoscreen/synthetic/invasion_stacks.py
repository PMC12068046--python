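"""Synthetic 3D invasion z-stacks.

Renders Gaussian nuclear + GFP blobs at each plane matching requested
per-plane counts (plane 0 = plate bottom, planes 30 um apart).  A
configurable fraction of low-intensity decoy blobs exercises the
dual-intensity counting filter.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

_NUC_AMP = 200.0
_GFP_AMP = 160.0
_BLOB_SIGMA = 3.0
_READ_NOISE_SD = 1.0


def _paint_blob(img: np.ndarray, cy: float, cx: float, amp: float, sigma: float) -> None:
    h, w = img.shape
    half = int(4 * sigma)
    y0, y1 = max(0, int(cy) - half), min(h, int(cy) + half + 1)
    x0, x1 = max(0, int(cx) - half), min(w, int(cx) + half + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    img[y0:y1, x0:x1] += amp * np.exp(-(((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2)))


def generate_invasion_stack(
    counts_per_plane,
    seed: int = 0,
    image_size: int = 320,
    decoy_fraction: float = 0.0,
    decoy_intensity: float = 0.1,
    plane_spacing_um: float = 30.0,
):
    """Render an invasion stack with known per-plane cell counts.

    Returns
    -------
    nuclear_stack, gfp_stack : float arrays (planes, H, W)
    truth : DataFrame with plane, depth_um, row, col, is_decoy
    """
    counts = np.asarray(counts_per_plane, dtype=int)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    rng = np.random.default_rng(seed)
    n_planes = counts.size
    nuc = np.zeros((n_planes, image_size, image_size))
    gfp = np.zeros_like(nuc)
    records = []
    for z in range(n_planes):
        n_real = counts[z]
        n_decoy = int(round(decoy_fraction * n_real))
        total = n_real + n_decoy
        if total == 0:
            continue
        grid = int(np.ceil(np.sqrt(total)))
        pitch = image_size / grid
        if pitch < 8 * _BLOB_SIGMA:
            raise ValueError("image too small for requested blob count")
        slots = rng.permutation(grid * grid)[:total]
        flags = np.array([False] * n_real + [True] * n_decoy)
        rng.shuffle(flags)
        for k, slot in enumerate(slots):
            i, j = divmod(int(slot), grid)
            cy = (i + 0.5) * pitch + rng.uniform(-2.0, 2.0)
            cx = (j + 0.5) * pitch + rng.uniform(-2.0, 2.0)
            scale = decoy_intensity if flags[k] else 1.0
            _paint_blob(nuc[z], cy, cx, _NUC_AMP * scale, _BLOB_SIGMA)
            _paint_blob(gfp[z], cy, cx, _GFP_AMP * scale, _BLOB_SIGMA)
            records.append(
                {
                    "plane": z,
                    "depth_um": z * plane_spacing_um,
                    "row": cy,
                    "col": cx,
                    "is_decoy": bool(flags[k]),
                }
            )
    nuc += rng.normal(0.0, _READ_NOISE_SD, nuc.shape)
    gfp += rng.normal(0.0, _READ_NOISE_SD, gfp.shape)
    return np.clip(nuc, 0, None), np.clip(gfp, 0, None), pd.DataFrame(records)
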