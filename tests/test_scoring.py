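"""Well summaries, mock-referenced Z-scores, QMS assembly, hit calling."""

import numpy as np
import pandas as pd
import pytest

from morphoscreen.scoring import (
    SHAPE_CLASSES,
    ScreenLayout,
    assemble_qms,
    call_hits,
    summarize_wells,
    zscore_vs_mock,
)
from morphoscreen.synthetic.screen import build_hit_screen, build_mock_screen


def simple_layout(well_ids, mock_ids=(), columns=None, plates=None):
    return ScreenLayout(
        wells=pd.DataFrame(
            {
                "condition": [f"c_{w}" if w not in mock_ids else "mock" for w in well_ids],
                "plate": plates or ["P1"] * len(well_ids),
                "column": columns or [5] * len(well_ids),
                "is_mock": [w in mock_ids for w in well_ids],
            },
            index=pd.Index(well_ids, name="well_id"),
        )
    )


class TestSummarizeWells:
    def test_pure_triangular_fractions(self):
        cells = pd.DataFrame(
            {"well_id": ["A"] * 60, "shape_class": ["triangular"] * 60, "ratio": [0.3] * 60}
        )
        wells = summarize_wells(cells, simple_layout(["A", "M"], mock_ids={"M"}))
        fracs = wells.loc["A", [f"frac_{s}" for s in SHAPE_CLASSES]].to_numpy(dtype=float)
        np.testing.assert_allclose(fracs, [0, 0, 1, 0, 0])

    def test_fractions_sum_to_one(self):
        cells, layout = build_mock_screen(n_mock=10, n_cells=80, seed=1)
        wells = summarize_wells(cells, layout)
        frac_cols = [f"frac_{s}" for s in SHAPE_CLASSES]
        np.testing.assert_allclose(wells[frac_cols].sum(axis=1), 1.0, atol=1e-9)

    def test_unknown_well_rejected(self):
        cells = pd.DataFrame({"well_id": ["ZZ"], "shape_class": ["fan"], "ratio": [0.1]})
        with pytest.raises(ValueError, match="unknown wells"):
            summarize_wells(cells, simple_layout(["A", "M"], mock_ids={"M"}))

    def test_density_columns_excluded(self):
        cells = pd.DataFrame(
            {
                "well_id": ["A"] * 60 + ["B"] * 60,
                "shape_class": ["fan"] * 120,
                "ratio": [0.1] * 120,
            }
        )
        layout = simple_layout(["A", "B", "M"], mock_ids={"M"}, columns=[1, 5, 5])
        wells = summarize_wells(cells, layout)
        assert bool(wells.loc["A", "excluded"]) and not bool(wells.loc["B", "excluded"])

    def test_low_cell_count_excluded(self):
        cells = pd.DataFrame(
            {"well_id": ["A"] * 10, "shape_class": ["fan"] * 10, "ratio": [0.1] * 10}
        )
        wells = summarize_wells(cells, simple_layout(["A", "M"], mock_ids={"M"}), min_cells=50)
        assert bool(wells.loc["A", "excluded"])

    def test_normal_fraction_over_all_cells(self):
        cells = pd.DataFrame(
            {
                "well_id": ["A"] * 100,
                "shape_class": ["normal"] * 30 + ["spindly"] * 70,
                "ratio": [0.2] * 100,
            }
        )
        wells = summarize_wells(cells, simple_layout(["A", "M"], mock_ids={"M"}))
        assert wells.loc["A", "normal_fraction"] == pytest.approx(0.3)
        assert wells.loc["A", "frac_spindly"] == pytest.approx(1.0)


class TestZScores:
    def test_mock_z_standardized(self):
        cells, layout = build_mock_screen(n_mock=40, seed=2)
        z = zscore_vs_mock(summarize_wells(cells, layout))
        metrics = [f"frac_{s}" for s in SHAPE_CLASSES] + ["median_ratio", "normal_fraction"]
        for m in metrics:
            vals = z.loc[z["is_mock"], m]
            assert -0.1 < vals.mean() < 0.1
            assert 0.9 < vals.std() < 1.1

    def test_exact_arithmetic(self):
        cells, layout = build_mock_screen(n_mock=12, seed=3)
        wells = summarize_wells(cells, layout)
        z = zscore_vs_mock(wells, metrics=["median_ratio"], plate_normalize=False)
        mocks = wells[wells.is_mock & ~wells.excluded]["median_ratio"]
        expected = (wells["median_ratio"] - mocks.mean()) / mocks.std(ddof=1)
        np.testing.assert_allclose(z["median_ratio"], expected, atol=1e-12)

    def test_zero_mock_sd_names_metric(self):
        cells = pd.DataFrame(
            {
                "well_id": np.repeat([f"m{i}" for i in range(10)], 60),
                "shape_class": ["triangular"] * 600,
                "ratio": [0.3] * 600,
            }
        )
        layout = simple_layout([f"m{i}" for i in range(10)], mock_ids={f"m{i}" for i in range(10)})
        wells = summarize_wells(cells, layout)
        with pytest.raises(ValueError, match="median_ratio"):
            zscore_vs_mock(wells, metrics=["median_ratio"])

    def test_too_few_mock_wells_rejected(self):
        cells, layout = build_mock_screen(n_mock=4, seed=4)
        with pytest.raises(ValueError, match="mock wells"):
            zscore_vs_mock(summarize_wells(cells, layout))

    def test_affine_rescaling_leaves_z_invariant(self):
        cells, layout = build_mock_screen(n_mock=20, seed=5)
        wells = summarize_wells(cells, layout)
        z1 = zscore_vs_mock(wells, metrics=["median_ratio"], plate_normalize=False)
        scaled = wells.copy()
        scaled["median_ratio"] = 3.0 * scaled["median_ratio"] + 11.0
        z2 = zscore_vs_mock(scaled, metrics=["median_ratio"], plate_normalize=False)
        np.testing.assert_allclose(z1["median_ratio"], z2["median_ratio"], atol=1e-9)


class TestQMS:
    def test_single_replicate_equals_well_z(self):
        cells, layout = build_mock_screen(n_mock=10, seed=6)
        z = zscore_vs_mock(summarize_wells(cells, layout))
        qms = assemble_qms(z)
        # every condition here is "mock" with 10 replicates
        assert qms.loc["mock", "n_replicates"] == 10

    def test_replicate_mean(self):
        z = pd.DataFrame(
            {
                "condition": ["g", "g"],
                "median_ratio": [1.0, 3.0],
                "excluded": [False, False],
            },
            index=["w1", "w2"],
        )
        qms = assemble_qms(z, metrics=["median_ratio"])
        assert qms.loc["g", "median_ratio"] == pytest.approx(2.0)

    def test_well_order_invariance(self):
        z = pd.DataFrame(
            {
                "condition": ["g", "h", "g"],
                "median_ratio": [1.0, 5.0, 3.0],
                "excluded": [False] * 3,
            },
            index=["w1", "w2", "w3"],
        )
        q1 = assemble_qms(z, metrics=["median_ratio"])
        q2 = assemble_qms(z.iloc[::-1], metrics=["median_ratio"])
        pd.testing.assert_frame_equal(q1, q2)

    def test_excluded_wells_dropped(self):
        z = pd.DataFrame(
            {
                "condition": ["g", "g"],
                "median_ratio": [1.0, 99.0],
                "excluded": [False, True],
            },
            index=["w1", "w2"],
        )
        qms = assemble_qms(z, metrics=["median_ratio"])
        assert qms.loc["g", "median_ratio"] == pytest.approx(1.0)


class TestCallHits:
    def test_printed_dock5_wells(self):
        # four replicate wells of one siRNA with published per-well Z-scores
        z = pd.DataFrame(
            {
                "condition": ["siDOCK5"] * 4,
                "median_ratio": [-1.73, -2.33, -2.77, -0.79],
                "excluded": [False] * 4,
            },
            index=[f"w{i}" for i in range(4)],
        )
        hits = call_hits(z)
        assert hits["yap_low"].tolist() == [True, True, True, False]
        assert not hits["yap_high"].any()

    def test_no_hits_at_zero(self):
        z = pd.DataFrame(
            {"condition": ["a"], "median_ratio": [0.0], "normal_fraction": [0.0],
             "excluded": [False]},
            index=["w"],
        )
        hits = call_hits(z)
        assert not hits[["yap_low", "yap_high", "shape_hit"]].any().any()

    def test_boundary_inclusive(self):
        z = pd.DataFrame(
            {"condition": ["a", "b"], "median_ratio": [1.5, -1.5],
             "normal_fraction": [-1.0, 0.0], "excluded": [False, False]},
            index=["w1", "w2"],
        )
        hits = call_hits(z)
        assert bool(hits.loc["w1", "yap_high"]) and bool(hits.loc["w2", "yap_low"])
        assert bool(hits.loc["w1", "shape_hit"])

    def test_excluded_wells_never_flagged(self):
        z = pd.DataFrame(
            {"condition": ["a"], "median_ratio": [-9.0], "excluded": [True]},
            index=["w"],
        )
        assert not call_hits(z)["yap_low"].any()


class TestEndToEndHitCalling:
    def test_sensitivity_and_fpr_on_simulated_screen(self):
        cells, layout, truth = build_hit_screen(seed=11)
        hits = call_hits(zscore_vs_mock(summarize_wells(cells, layout))).join(truth)
        sens = hits.loc[hits["true_hit"], "yap_low"].mean()
        fpr = hits.loc[~hits["true_hit"] & ~hits["is_mock"], "yap_low"].mean()
        assert sens >= 0.9
        assert fpr <= 0.05
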