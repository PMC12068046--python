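"""Synthetic focal-adhesion time-lapse movies.

Each adhesion is a small fixed-position ellipse whose mean intensity
follows exponential assembly then exponential disassembly:

    I(t) = I0 * exp(k_a * (t - t_birth))          birth <= t <= peak
    I(t) = I_peak * exp(-k_d * (t - t_peak))      peak  <= t <= death

Noise is multiplicative log-normal per frame (``noise_sd`` is the standard
deviation of ln-intensity; 0.1 corresponds to SNR ~ 10), plus Gaussian
camera read noise on the rendered pixels.  Ground truth stores exact phase
boundaries and rates for every track.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skimage.draw import ellipse as draw_ellipse

_READ_NOISE_SD = 2.0
_I0 = 40.0  # intensity at birth, well above the detection floor


def generate_fa_movie(
    n_tracks: int,
    k_a: float,
    k_d: float,
    frame_interval_min: float = 3.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_frames: int = 40,
    image_size: int = 512,
    axial_ratio: float = 1.6,
    adhesion_radius_px: float = 4.0,
    read_noise_sd: float = _READ_NOISE_SD,
):
    """Render a movie of ``n_tracks`` non-interacting adhesions.

    Parameters
    ----------
    k_a, k_d
        Assembly and disassembly rates (1/min), both > 0 (``k_d = 0`` is
        allowed and freezes the intensity at its peak).
    noise_sd
        Per-frame sd of ln-intensity (multiplicative noise); 0 gives an
        exactly exponential trace.

    Returns
    -------
    movie : uint16 array (n_frames, H, W)
    truth : DataFrame with track_id, row, col, birth_frame, peak_frame,
        death_frame, k_a, k_d, plus the per-frame true mean intensities in
        ``intensity_trace`` (list column).
    """
    if k_a <= 0 or k_d < 0:
        raise ValueError("require k_a > 0 and k_d >= 0")
    if n_frames < 5:
        raise ValueError("need at least 5 frames")
    rng = np.random.default_rng(seed)

    grid = int(np.ceil(np.sqrt(n_tracks)))
    pitch = image_size / grid
    if pitch < 6 * adhesion_radius_px:
        raise ValueError("image too small for requested track count")

    movie = np.zeros((n_frames, image_size, image_size), dtype=float)
    records = []
    order = rng.permutation(grid * grid)[:n_tracks]
    for tid, k in enumerate(order):
        i, j = divmod(int(k), grid)
        cy = (i + 0.5) * pitch + rng.uniform(-1.0, 1.0)
        cx = (j + 0.5) * pitch + rng.uniform(-1.0, 1.0)
        birth = int(rng.integers(0, max(1, n_frames // 5)))
        a_len = int(rng.integers(8, 14))  # frames of growth
        d_len = int(rng.integers(8, 14))
        peak = min(birth + a_len, n_frames - 2)
        death = min(peak + d_len, n_frames - 1)
        theta = rng.uniform(0.0, np.pi)
        ry = adhesion_radius_px * np.sqrt(axial_ratio)
        rx = adhesion_radius_px / np.sqrt(axial_ratio)
        rr, cc = draw_ellipse(cy, cx, ry, rx, shape=(image_size, image_size), rotation=theta)

        trace = np.zeros(n_frames)
        for t in range(birth, death + 1):
            minutes = (t - birth) * frame_interval_min
            if t <= peak:
                val = _I0 * np.exp(k_a * minutes)
            else:
                peak_minutes = (peak - birth) * frame_interval_min
                val = _I0 * np.exp(k_a * peak_minutes) * np.exp(
                    -k_d * (minutes - peak_minutes)
                )
            obs = val * np.exp(rng.normal(0.0, noise_sd)) if noise_sd > 0 else val
            movie[t, rr, cc] += obs
            trace[t] = obs
        records.append(
            {
                "track_id": tid,
                "row": cy,
                "col": cx,
                "birth_frame": birth,
                "peak_frame": peak,
                "death_frame": death,
                "k_a": k_a,
                "k_d": k_d,
                "intensity_trace": trace,
            }
        )
    if read_noise_sd > 0:
        movie += rng.normal(0.0, read_noise_sd, movie.shape)
    movie = np.clip(np.round(movie), 0, 65535).astype(np.uint16)
    return movie, pd.DataFrame(records)
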