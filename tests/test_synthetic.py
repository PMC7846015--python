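"""Synthetic-data generator: determinism, ground-truth fidelity, mosaicism."""

import numpy as np
import pandas as pd
import pytest

import enhancerdose as ed
from enhancerdose.curves import HillParams, encode_log_dose, eval_monophasic
from enhancerdose.synthetic import (
    SCORE_COLUMNS,
    ImageStackSpec,
    simulate_image_stack,
    simulate_insitu,
)


class TestSimulateExperiment:
    def test_deterministic_given_seed(self, small_config):
        a_emb, a_cells, _ = ed.simulate_experiment(small_config, seed=3)
        b_emb, b_cells, _ = ed.simulate_experiment(small_config, seed=3)
        assert a_emb.to_csv(index=False) == b_emb.to_csv(index=False)
        assert a_cells.to_csv(index=False) == b_cells.to_csv(index=False)

    def test_every_embryo_has_forty_cells(self, small_experiment):
        _, cells, _ = small_experiment
        counts = cells.groupby("embryo_id")["cell_index"].size()
        assert (counts == 40).all()

    def test_noise_free_dmso_cells_hit_model_value_exactly(self):
        truth = HillParams(A=1.0, B=-2.0, C=-1.0, D=0.0)
        cfg = ed.SynthConfig(
            reporters=("Distal",),
            true_params={"Distal": ed.ReporterTruth("monophasic", truth)},
            on_intensity_shape=0.0,
            batch_efficiency_sd=0.0,
            p_on_baseline=1.0,
            intensity_scale=1.0,
            n_batches=1,
            embryos_per_batch_per_dose=2,
        )
        _, cells, _ = ed.simulate_experiment(cfg, seed=0)
        doses = np.asarray(cfg.doses)
        x = encode_log_dose(doses, doses == 0)
        expected = eval_monophasic(x[0], truth)
        dmso = cells[cells["vehicle"]]
        assert (dmso["roi_mean"] == expected).all()

    def test_dmso_on_fraction_converges_to_baseline(self, study_experiment):
        _, cells, truth = study_experiment
        merged = cells.merge(truth.cells, on=["embryo_id", "cell_index"])
        frac = merged[merged["vehicle"]]["true_on"].mean()
        n = merged["vehicle"].sum()
        se = np.sqrt(0.7 * 0.3 / n)
        assert abs(frac - 0.7) < 4 * se

    def test_on_intensity_tracks_true_curve(self):
        # >=500 ON cells per dose, batch effects off: dose-wise mean ON
        # intensity matches the configured curve within 3 standard errors
        truth = HillParams(A=0.9, B=-1.43, C=-1.1, D=0.05)
        cfg = ed.SynthConfig(
            reporters=("Distal",),
            true_params={"Distal": ed.ReporterTruth("monophasic", truth)},
            batch_efficiency_sd=0.0,
            embryos_per_batch_per_dose=10,
            n_batches=3,
        )
        _, cells, gt = ed.simulate_experiment(cfg, seed=21)
        merged = cells.merge(gt.cells, on=["embryo_id", "cell_index"])
        on = merged[merged["true_on"]]
        doses = np.asarray(cfg.doses)
        x = encode_log_dose(doses, doses == 0)
        mean_factor = np.exp(cfg.on_intensity_shape**2 / 2)  # lognormal median->mean
        for dose, xi in zip(doses, x):
            grp = on[on["dose_um"] == dose]["roi_mean"]
            assert len(grp) >= 500
            expected = cfg.intensity_scale * eval_monophasic(xi, truth) * mean_factor
            se = grp.std() / np.sqrt(len(grp))
            assert abs(grp.mean() - expected) < 3 * se

    def test_mode_distribution_is_bimodal_with_clean_off_ceiling(self, study_experiment):
        _, cells, truth = study_experiment
        merged = cells.merge(truth.cells, on=["embryo_id", "cell_index"])
        off_modes = merged.loc[~merged["true_on"], "roi_mode"]
        on_modes = merged.loc[merged["true_on"], "roi_mode"]
        assert off_modes.max() <= 10
        assert on_modes.min() >= 11

    def test_roi_statistic_ordering(self, small_experiment):
        _, cells, _ = small_experiment
        assert (cells["roi_min"] <= cells["roi_median"]).all()
        assert (cells["roi_median"] <= cells["roi_max"]).all()
        assert cells["roi_mode"].between(0, 4095).all()

    def test_sev_equals_cell_totals_without_ectopic(self, small_experiment):
        embryos, cells, _ = small_experiment
        totals = cells.groupby("embryo_id")["roi_total"].sum()
        joined = embryos.set_index("embryo_id")["sev"]
        np.testing.assert_allclose(joined, totals[joined.index])

    def test_ectopic_term_inflates_sev_only(self):
        cfg = ed.SynthConfig(reporters=("Distal",), n_batches=1,
                             embryos_per_batch_per_dose=2, ectopic_fraction=0.2)
        embryos, cells, _ = ed.simulate_experiment(cfg, seed=4)
        totals = cells.groupby("embryo_id")["roi_total"].sum()
        joined = embryos.set_index("embryo_id")["sev"]
        assert (joined >= totals[joined.index] - 1e-9).all()
        assert (joined > totals[joined.index]).any()

    @pytest.mark.parametrize(
        "patch",
        [
            {"doses": ()},
            {"doses": (0.1, 0.2)},  # no DMSO level
            {"reporters": ("Mystery",)},
            {"p_on_baseline": 1.5},
            {"n_notochord_cells": 0},
        ],
    )
    def test_invalid_configs_rejected(self, patch):
        with pytest.raises(ValueError):
            ed.simulate_experiment(ed.SynthConfig(**patch))


class TestSimulateInsitu:
    def test_scores_in_codomain(self, small_config):
        scores = simulate_insitu(small_config, seed=1)
        assert set(np.unique(scores[list(SCORE_COLUMNS)])) <= {0, 1, 2, 3}

    def test_saturating_limit_all_threes(self):
        cfg = ed.SynthConfig(
            insitu_noise_sd=0.0,
            founder_offsets={p: 0.0 for p in ("A8.5", "A8.6", "A8.13", "A8.14", "B8.6")},
        )
        scores = simulate_insitu(cfg, seed=0)
        dmso = scores[scores["vehicle"]]
        assert (dmso[list(SCORE_COLUMNS)].to_numpy() == 3).all()

    def test_medial_offset_raises_medial_scores_at_ec50(self):
        cfg = ed.SynthConfig(
            founder_offsets={"A8.5": 0.3, "A8.6": 0.3, "A8.13": 0.0,
                             "A8.14": 0.0, "B8.6": 0.0},
            insitu_doses=(0.0, 10 ** ed.SynthConfig().insitu_ec50_log10),
            insitu_embryos_per_dose=400,
        )
        scores = simulate_insitu(cfg, seed=2)
        at_ec50 = scores[~scores["vehicle"]]
        medial = at_ec50[["A8.5_L", "A8.5_R", "A8.6_L", "A8.6_R"]].to_numpy().mean()
        lateral = at_ec50[["A8.13_L", "A8.13_R", "A8.14_L", "A8.14_R"]].to_numpy().mean()
        assert medial > lateral

    def test_missing_founder_offset_rejected(self):
        cfg = ed.SynthConfig(founder_offsets={"A8.5": 0.0})
        with pytest.raises(ValueError, match="founder"):
            simulate_insitu(cfg)


class TestSimulateImageStack:
    def test_zero_blobs_zero_noise_gives_flat_background(self):
        spec = ImageStackSpec(n_blobs=0, noise_sd=0.0, background=17.0, centers=[], signals=[])
        stack, truth = simulate_image_stack(ed.SynthConfig(), spec, seed=0)
        assert (stack.reporter == 17).all()
        assert truth.total_signal == 0.0

    def test_single_blob_integrated_signal_preserved(self):
        spec = ImageStackSpec(
            noise_sd=0.0, background=0.0, centers=[(6, 48, 64)], signals=[5.0e4]
        )
        stack, truth = simulate_image_stack(ed.SynthConfig(), spec, seed=0)
        total = float(stack.reporter.sum())
        # rounding to integer gray values is the only loss
        assert total == pytest.approx(5.0e4, rel=0.01)
        assert truth.total_signal == 5.0e4

    def test_twelve_bit_ceiling_clips(self):
        spec = ImageStackSpec(
            noise_sd=0.0, background=0.0, centers=[(6, 48, 64)], signals=[1.0e9]
        )
        stack, _ = simulate_image_stack(ed.SynthConfig(), spec, seed=0)
        assert stack.reporter.max() == 4095

    def test_out_of_bounds_center_rejected(self):
        spec = ImageStackSpec(centers=[(100, 0, 0)], signals=[1.0])
        with pytest.raises(ValueError, match="bounds"):
            simulate_image_stack(ed.SynthConfig(), spec, seed=0)
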