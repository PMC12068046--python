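"""Differential-abundance statistics: scaling, ratios, permutation FDR."""

import numpy as np
import pandas as pd
import pytest

from morphoscreen.proteomics import (
    log2_ratio,
    permutation_fdr_ttest,
    scale_within_cellline,
    select_significant,
)
from morphoscreen.synthetic.abundance import generate_abundance_table


@pytest.fixture
def small_table():
    return generate_abundance_table(200, 20, 1.0, n_reps=3, noise_sd=0.2, seed=1)


class TestScaling:
    def test_sample_medians_zeroed(self, small_table):
        table, meta, _ = small_table
        scaled = scale_within_cellline(table, meta)
        protein_centred = scaled.sub(scaled.mean(axis=1), axis=0)
        # per-protein centring holds exactly
        assert np.allclose(scaled.mean(axis=1), 0.0, atol=1e-12)

    def test_multiplying_one_sample_changes_nothing(self, small_table):
        table, meta, _ = small_table
        bumped = table.copy()
        bumped.iloc[:, 0] = bumped.iloc[:, 0] * 4.0
        s1 = scale_within_cellline(table, meta)
        s2 = scale_within_cellline(bumped, meta)
        pd.testing.assert_frame_equal(s1, s2)

    def test_single_sample_cellline_rejected(self, small_table):
        table, meta, _ = small_table
        meta2 = meta.copy()
        meta2.loc[meta2.index[0], "cell_line"] = "LONER"
        with pytest.raises(ValueError, match="single sample"):
            scale_within_cellline(table, meta2)

    def test_nonpositive_abundance_rejected(self, small_table):
        table, meta, _ = small_table
        bad = table.copy()
        bad.iloc[0, 0] = 0.0
        with pytest.raises(ValueError, match="positive"):
            scale_within_cellline(bad, meta)


class TestLog2Ratio:
    def test_doubling_gives_one(self):
        table, meta, _ = generate_abundance_table(50, 50, 1.0, n_reps=3, noise_sd=0.0, seed=2)
        ratios = log2_ratio(table, meta)
        assert np.allclose(ratios, 1.0, atol=1e-9)

    def test_equal_groups_zero(self):
        table, meta, _ = generate_abundance_table(50, 0, 0.0, n_reps=3, noise_sd=0.0, seed=3)
        assert np.allclose(log2_ratio(table, meta), 0.0, atol=1e-9)

    def test_negative_spike_recovered_noiseless(self):
        table, meta, truth = generate_abundance_table(60, 10, -0.8, n_reps=3, noise_sd=0.0, seed=4)
        ratios = log2_ratio(table, meta)
        assert np.allclose(ratios[truth["spiked"]], -0.8, atol=1e-9)

    def test_missing_condition_rejected(self):
        table, meta, _ = generate_abundance_table(10, 0, 0.0, seed=5)
        only_mock = meta[meta.condition == "mock"]
        with pytest.raises(ValueError):
            log2_ratio(table[only_mock.index], only_mock)


class TestPermutationFDR:
    def test_row_order_invariance(self, small_table):
        table, meta, _ = small_table
        r1 = permutation_fdr_ttest(table, meta, seed=7)
        shuffled = table.sample(frac=1, random_state=0)
        r2 = permutation_fdr_ttest(shuffled, meta, seed=7)
        pd.testing.assert_frame_equal(r1.table.sort_index(), r2.table.sort_index())

    def test_relabel_equivariance(self, small_table):
        table, meta, _ = small_table
        flipped = meta.copy()
        flipped["condition"] = flipped["condition"].map(
            {"mock": "perturbed", "perturbed": "mock"}
        )
        r = permutation_fdr_ttest(table, meta, seed=7)
        rf = permutation_fdr_ttest(table, flipped, seed=7)
        np.testing.assert_allclose(r.table["log2_ratio"], -rf.table["log2_ratio"], atol=1e-12)
        up1, down1 = select_significant(r)
        up2, down2 = select_significant(rf)
        assert up1 == down2 and down1 == up2

    def test_q_monotone_in_abs_t(self, small_table):
        table, meta, _ = small_table
        r = permutation_fdr_ttest(table, meta, seed=8)
        ordered = r.table.reindex(r.table["t"].abs().sort_values(ascending=False).index)
        q = ordered["q_value"].to_numpy()
        assert np.all(np.diff(q) >= -1e-12)

    def test_exhaustive_permutations_used_for_small_groups(self, small_table):
        table, meta, _ = small_table
        r = permutation_fdr_ttest(table, meta, n_perm=1000, seed=9)
        assert r.n_perm_used == 20  # C(6,3) distinct perturbed-masks

    def test_too_few_replicates_rejected(self):
        table, meta, _ = generate_abundance_table(20, 0, 0.0, n_reps=1, seed=10)
        with pytest.raises(ValueError):
            permutation_fdr_ttest(table, meta, seed=0)

    def test_spiked_proteins_recovered(self):
        table, meta, truth = generate_abundance_table(500, 25, 1.0, n_reps=3, noise_sd=0.2, seed=11)
        r = permutation_fdr_ttest(table, meta, seed=11)
        sens = r.table.loc[truth["spiked"], "significant"].mean()
        fpr = r.table.loc[~truth["spiked"], "significant"].mean()
        assert sens >= 0.8 and fpr <= 0.02

    def test_bh_method_also_flags_spikes(self):
        table, meta, truth = generate_abundance_table(300, 15, 1.5, n_reps=4, noise_sd=0.2, seed=12)
        r = permutation_fdr_ttest(table, meta, seed=12, method="bh")
        assert r.table.loc[truth["spiked"], "significant"].mean() >= 0.8


class TestSelectSignificant:
    def test_boundary_log2_excluded(self):
        res = permutation_fdr_ttest(
            *generate_abundance_table(50, 0, 0.0, seed=13)[:2], seed=13
        )
        res.table.loc[:, "log2_ratio"] = 0.5
        res.table.loc[:, "q_value"] = 0.0
        up, down = select_significant(res)
        assert up == [] and down == []

    def test_down_set_sign_logic(self):
        # CTGF-like protein: clear down-regulation passes the cut
        res = permutation_fdr_ttest(
            *generate_abundance_table(50, 0, 0.0, seed=14)[:2], seed=14
        )
        res.table.loc[res.table.index[0], "log2_ratio"] = -0.78
        res.table.loc[res.table.index[0], "q_value"] = 0.01
        up, down = select_significant(res)
        assert res.table.index[0] in down and res.table.index[0] not in up

    def test_empty_results_empty_sets(self):
        res = permutation_fdr_ttest(
            *generate_abundance_table(30, 0, 0.0, seed=15)[:2], seed=15
        )
        res.table = res.table.iloc[:0]
        up, down = select_significant(res)
        assert up == [] and down == []
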