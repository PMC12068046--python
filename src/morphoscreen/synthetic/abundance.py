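"""Synthetic protein abundance tables with spiked log2 fold changes."""

from __future__ import annotations

import numpy as np
import pandas as pd


def generate_abundance_table(
    n_proteins: int,
    n_spiked: int,
    delta_log2: float,
    n_reps: int = 3,
    noise_sd: float = 0.2,
    seed: int = 0,
    cell_line: str = "LM2",
    base_log2_mean: float = 20.0,
    base_log2_sd: float = 2.0,
):
    """Log-normal abundance table, mock vs perturbed, with spiked proteins.

    The first ``n_spiked`` proteins get ``delta_log2`` added to their
    perturbed-sample log2 abundances; ``noise_sd`` is the per-measurement
    log2 noise.  ``delta_log2 = 0`` makes the ground-truth differential
    set empty.

    Returns
    -------
    table : DataFrame proteins x samples (positive abundances)
    meta : DataFrame indexed by sample with cell_line / condition / replicate
    truth : DataFrame with protein, spiked (bool), delta_log2
    """
    if n_spiked > n_proteins:
        raise ValueError("n_spiked cannot exceed n_proteins")
    rng = np.random.default_rng(seed)
    proteins = [f"P{i:05d}" for i in range(n_proteins)]
    base = rng.normal(base_log2_mean, base_log2_sd, size=n_proteins)
    spiked = np.zeros(n_proteins, dtype=bool)
    spiked[:n_spiked] = delta_log2 != 0.0

    cols, meta_rows = [], []
    data = np.empty((n_proteins, 2 * n_reps))
    for k in range(2 * n_reps):
        condition = "mock" if k < n_reps else "perturbed"
        rep = k % n_reps + 1
        name = f"{cell_line}_{condition}_{rep}"
        log2 = base + (rng.normal(0.0, noise_sd, size=n_proteins) if noise_sd > 0 else 0.0)
        if condition == "perturbed":
            log2 = log2 + np.where(spiked, delta_log2, 0.0)
        data[:, k] = 2.0**log2
        cols.append(name)
        meta_rows.append({"sample": name, "cell_line": cell_line, "condition": condition, "replicate": rep})
    table = pd.DataFrame(data, index=proteins, columns=cols)
    meta = pd.DataFrame(meta_rows).set_index("sample")
    truth = pd.DataFrame(
        {"protein": proteins, "spiked": spiked, "delta_log2": np.where(spiked, delta_log2, 0.0)}
    ).set_index("protein")
    return table, meta, truth
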