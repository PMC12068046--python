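"""Table-level synthetic screens for hit-calling and Z-score studies.

These builders produce single-cell tables and layouts directly (no image
rendering); they emulate the statistical structure of a screen at the
scale of hundreds of wells, which is what the screen-scoring statistics
actually see.

Mock (reagent-only control) wells carry slightly more well-to-well
variability than siRNA wells: they are spread across the whole plate and
absorb residual positional and handling effects.  The default gives mock
wells an extra per-well ratio offset of sqrt(2)x the sampling error of
the well median (total mock sd ~ 1.7x a test well's), matching the
overdispersion such controls show in practice.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..scoring import ScreenLayout
from .plate import DEFAULT_RATIO_BASELINES, WellSpec, simulate_cell_table

MOCK_MIXTURE = (0.10, 0.05, 0.55, 0.05, 0.25)


def median_sampling_se(
    n_cells: int,
    ratio_noise_sd: float = 0.10,
    mixture=MOCK_MIXTURE,
    n_sim: int = 4000,
) -> float:
    """Sampling sd of a well's median ratio under the default generator.

    The per-cell ratio is a mixture over shape classes (class baselines +
    Gaussian noise), so the median's sampling error is wider than the
    single-Gaussian 1.2533*sd/sqrt(n); estimate it by Monte Carlo with a
    fixed internal seed.
    """
    rng = np.random.default_rng(987654321)
    baselines = np.array([DEFAULT_RATIO_BASELINES[c] for c in
                          ("spindly", "large_round", "triangular", "fan", "small_round")])
    cls = rng.choice(5, size=(n_sim, n_cells), p=np.asarray(mixture))
    vals = baselines[cls] + rng.normal(0.0, ratio_noise_sd, size=(n_sim, n_cells))
    return float(np.median(vals, axis=1).std(ddof=1))


def mock_ratio_sd(
    n_cells: int, ratio_noise_sd: float = 0.10, mock_extra_factor: float = 1.4142135623730951
) -> float:
    """Predicted sd of mock-well median ratios: sampling error plus the
    extra mock well-level offset in quadrature."""
    se = median_sampling_se(n_cells, ratio_noise_sd)
    return float(se * np.sqrt(1.0 + mock_extra_factor**2))


def build_hit_screen(
    n_mock: int = 60,
    n_hit: int = 250,
    n_null: int = 250,
    n_cells: int = 200,
    hit_shift_mock_sd: float = 3.0,
    ratio_noise_sd: float = 0.10,
    mock_extra_factor: float = 1.4142135623730951,
    normal_fraction: float = 0.5,
    seed: int = 0,
):
    """A screen of mock, ratio-shifted ("hit") and unshifted null wells.

    Hit wells have their nuclear:ring ratio shifted down by
    ``hit_shift_mock_sd`` mock-well standard deviations (default 3, a
    robust hit); null wells are statistically identical to siRNA wells
    with no effect.  Returns (cells, layout, truth) where truth flags the
    true hit wells.
    """
    sd_mock = mock_ratio_sd(n_cells, ratio_noise_sd, mock_extra_factor)
    extra = mock_extra_factor * median_sampling_se(n_cells, ratio_noise_sd)
    wells: list[WellSpec] = []
    for i in range(n_mock):
        wells.append(
            WellSpec(
                well_id=f"mock{i:03d}", condition="mock", shape_mixture=MOCK_MIXTURE,
                column=3 + i % 20, is_mock=True, normal_fraction=normal_fraction,
                well_noise_sd=extra,
            )
        )
    for i in range(n_hit):
        wells.append(
            WellSpec(
                well_id=f"hit{i:03d}", condition=f"siHIT{i:03d}", shape_mixture=MOCK_MIXTURE,
                ratio_shift=-hit_shift_mock_sd * sd_mock, column=3 + i % 20,
                normal_fraction=normal_fraction,
            )
        )
    for i in range(n_null):
        wells.append(
            WellSpec(
                well_id=f"null{i:03d}", condition=f"siNULL{i:03d}", shape_mixture=MOCK_MIXTURE,
                column=3 + i % 20, normal_fraction=normal_fraction,
            )
        )
    cells = simulate_cell_table(wells, n_cells_per_well=n_cells,
                                ratio_noise_sd=ratio_noise_sd, seed=seed)
    layout = ScreenLayout(
        wells=pd.DataFrame(
            [
                {"well_id": w.well_id, "condition": w.condition, "plate": w.plate,
                 "column": w.column, "is_mock": w.is_mock}
                for w in wells
            ]
        ).set_index("well_id")
    )
    truth = pd.DataFrame(
        {
            "well_id": [w.well_id for w in wells],
            "true_hit": [w.ratio_shift <= -hit_shift_mock_sd * sd_mock + 1e-12 and w.ratio_shift < 0 for w in wells],
        }
    ).set_index("well_id")
    return cells, layout, truth


def build_mock_screen(
    n_mock: int = 40,
    n_cells: int = 200,
    ratio_noise_sd: float = 0.10,
    normal_fraction: float = 0.5,
    seed: int = 0,
):
    """Mock-only screen for Z-score standardization checks."""
    wells = [
        WellSpec(
            well_id=f"mock{i:03d}", condition="mock", shape_mixture=MOCK_MIXTURE,
            column=3 + i % 20, is_mock=True, normal_fraction=normal_fraction,
        )
        for i in range(n_mock)
    ]
    cells = simulate_cell_table(wells, n_cells_per_well=n_cells,
                                ratio_noise_sd=ratio_noise_sd, seed=seed)
    layout = ScreenLayout(
        wells=pd.DataFrame(
            [
                {"well_id": w.well_id, "condition": w.condition, "plate": w.plate,
                 "column": w.column, "is_mock": w.is_mock}
                for w in wells
            ]
        ).set_index("well_id")
    )
    return cells, layout
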