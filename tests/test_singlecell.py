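"""ON/OFF classification and matched-control bootstrap statistics."""

import numpy as np
import pandas as pd
import pytest

import enhancerdose as ed
from enhancerdose.singlecell import (
    bootstrap_cell_statistic,
    bootstrap_on_ratio,
    classify_on_off,
    filter_complete_embryos,
    format_exceedance_p,
    log_pseudocount,
    normalize_cell_means,
    pairwise_dose_pvalue,
)


class TestClassifyOnOff:
    def test_boundary_values(self):
        assert classify_on_off(10) is False  # mode 10 is OFF
        assert classify_on_off(11) is True
        assert classify_on_off(0) is False

    def test_matches_brute_force_over_full_gray_range(self):
        modes = np.arange(0, 4096)
        expected = np.array([m > 10 for m in modes])  # independent scan
        np.testing.assert_array_equal(classify_on_off(modes), expected)

    def test_non_integer_mode_rejected(self):
        with pytest.raises(ValueError):
            classify_on_off(np.array([3.5]))


class TestCompleteEmbryoFilter:
    def test_incomplete_embryos_excluded_and_counted(self, small_experiment):
        _, cells, _ = small_experiment
        clipped = cells[
            ~((cells["embryo_id"] == cells["embryo_id"].iloc[0]) & (cells["cell_index"] > 39))
        ]
        kept, n_excluded = filter_complete_embryos(clipped)
        assert n_excluded == 1
        assert cells["embryo_id"].iloc[0] not in set(kept["embryo_id"])


class TestNormalizeCellMeans:
    def test_batch_rescale_invariance(self, small_experiment):
        # one batch rescaled: batch-relative scores unchanged; normalized
        # means move only by a per-reporter common factor
        _, cells, _ = small_experiment
        base = normalize_cell_means(cells)
        scaled = cells.copy()
        mask = scaled["batch_id"] == "batch1"
        scaled.loc[mask, "roi_mean"] *= 3.7
        out = normalize_cell_means(scaled)
        for rep in out["reporter"].unique():
            ratio = (
                out.loc[out["reporter"] == rep, "norm_mean"].to_numpy()
                / base.loc[base["reporter"] == rep, "norm_mean"].to_numpy()
            )
            np.testing.assert_allclose(ratio, ratio[0])

    def test_pseudocount_log_of_zero(self):
        assert log_pseudocount(0.0) == 0.0
        assert log_pseudocount(9.0) == pytest.approx(1.0)

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            log_pseudocount([-1.0])


def _cell_frame(on_flags, batches, values=None):
    n = len(on_flags)
    return pd.DataFrame(
        {
            "batch_id": batches,
            "on": np.asarray(on_flags, bool),
            "norm_mean": np.ones(n) if values is None else np.asarray(values, float),
        }
    )


class TestOnRatioBootstrap:
    def test_identical_on_fractions_give_unit_ratio(self):
        flags = [True] * 30 + [False] * 10
        treated = _cell_frame(flags, ["b1"] * 40)
        dmso = _cell_frame(flags, ["b1"] * 40)
        boot = bootstrap_on_ratio(treated, dmso, n_boot=100, seed=0)
        lo, hi = boot.ci()
        assert lo <= 1.0 <= hi

    def test_all_on_everywhere_degenerate_unit_ratio(self):
        treated = _cell_frame([True] * 40, ["b1"] * 40)
        dmso = _cell_frame([True] * 40, ["b1"] * 40)
        boot = bootstrap_on_ratio(treated, dmso, n_boot=50, seed=0)
        assert boot.ci() == (1.0, 1.0)
        assert boot.p_vs_1 == 1.0

    def test_half_on_fraction_gives_half_ratio(self, rng):
        n = 4000
        treated = _cell_frame(rng.random(n) < 0.3, ["b1"] * n)
        dmso = _cell_frame(rng.random(n) < 0.6, ["b1"] * n)
        boot = bootstrap_on_ratio(treated, dmso, n_boot=300, seed=1)
        assert boot.median == pytest.approx(0.5, abs=0.05)
        assert boot.p_vs_1 < 1e-10

    def test_zero_dmso_replicates_dropped_and_counted(self, rng):
        treated = _cell_frame([True] * 20, ["b1"] * 20)
        dmso = _cell_frame([True] + [False] * 19, ["b1"] * 20)
        boot = bootstrap_on_ratio(treated, dmso, n_boot=200, seed=2)
        assert boot.n_dropped > 0
        assert boot.ratios.size == boot.n_boot - boot.n_dropped

    def test_batch_relabeling_preserves_distribution_in_law(self, rng):
        n = 600
        batches = np.repeat(["b1", "b2", "b3"], n // 3)
        treated = _cell_frame(rng.random(n) < 0.4, batches)
        dmso = _cell_frame(rng.random(n) < 0.7, batches)
        a = bootstrap_on_ratio(treated, dmso, n_boot=500, seed=3)
        relabel = {"b1": "c2", "b2": "c3", "b3": "c1"}
        b = bootstrap_on_ratio(
            treated.assign(batch_id=treated["batch_id"].map(relabel)),
            dmso.assign(batch_id=dmso["batch_id"].map(relabel)),
            n_boot=500,
            seed=4,
        )
        assert a.median == pytest.approx(b.median, abs=0.03)
        assert np.allclose(a.ci(), b.ci(), atol=0.06)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_on_ratio(_cell_frame([], []), _cell_frame([True], ["b1"]))


class TestCellStatisticBootstrap:
    def test_constant_values_constant_statistic(self):
        cells = _cell_frame([True] * 30, ["b1"] * 30, values=[2.5] * 30)
        for stat in ("mean", "p90"):
            boot = bootstrap_cell_statistic(cells, stat, n_boot=50, seed=0)
            assert boot.ci() == (2.5, 2.5)

    def test_p90_linear_interpolation_reference(self):
        # direct percentile check on 1..1000 without resampling noise
        assert np.percentile(np.arange(1, 1001), 90) == pytest.approx(900.1)

    def test_seed_reproducible(self, rng):
        cells = _cell_frame(
            rng.random(100) < 0.6, ["b1"] * 50 + ["b2"] * 50, values=rng.lognormal(0, 1, 100)
        )
        a = bootstrap_cell_statistic(cells, "p90", n_boot=100, seed=5)
        b = bootstrap_cell_statistic(cells, "p90", n_boot=100, seed=5)
        np.testing.assert_array_equal(a.values, b.values)

    def test_empty_on_subset_rejected(self):
        cells = _cell_frame([False] * 10, ["b1"] * 10)
        with pytest.raises(ValueError, match="empty"):
            bootstrap_cell_statistic(cells, "mean", subset="on")


class TestPairwiseDosePvalue:
    def test_no_exceedance_reports_below_resolution(self):
        hi = np.zeros(1000)
        lo = np.ones(1000)
        p = pairwise_dose_pvalue(hi, lo)
        assert p == 0.0
        assert format_exceedance_p(p, 1000) == "< 0.001"

    def test_exchangeable_distributions_near_half(self, rng):
        a = rng.normal(0, 1, 2000)
        b = rng.normal(0, 1, 2000)
        assert pairwise_dose_pvalue(a, b) == pytest.approx(0.5, abs=0.05)

    def test_count_arithmetic(self):
        hi = np.array([1.0] * 250 + [0.0] * 750)
        lo = np.full(1000, 0.5)
        assert pairwise_dose_pvalue(hi, lo) == 0.25

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pairwise_dose_pvalue(np.ones(5), np.ones(6))


class TestSwitchVsFade:
    """The two extreme single-cell mechanisms of bulk expression loss are
    distinguishable from the module's outputs (cf. the generator's
    separately tunable ON-fraction and intensity dose responses)."""

    @staticmethod
    def _run(mode, dose=0.2):
        # EC50 of the varying response sits at 0.2 uM in both modes
        flat = ed.ReporterTruth("monophasic", ed.HillParams(0.3, -1e-9, 0.0, 0.3))
        falling = ed.ReporterTruth(
            "monophasic", ed.HillParams(0.3, -1.5, np.log10(0.2), 0.02)
        )
        on_hill = {"Distal": ed.OnResponse(ec50_log10=np.log10(0.2), hill=-1.5)}
        cfg = ed.SynthConfig(
            reporters=("Distal",),
            doses=(0.0, 0.2, 1.0),
            true_params={"Distal": flat if mode == "switch" else falling},
            on_response=on_hill if mode == "switch" else {},
            batch_efficiency_sd=0.0,
        )
        _, cells, _ = ed.simulate_experiment(cfg, seed=31)
        cells = cells.assign(on=classify_on_off(cells["roi_mode"].to_numpy()))
        cells = normalize_cell_means(cells, reference_reporter=None)
        dmso = cells[cells["vehicle"]]
        treated = cells[cells["dose_um"] == dose]
        ratio = bootstrap_on_ratio(treated, dmso, n_boot=300, seed=1)
        on_mean_dmso = bootstrap_cell_statistic(dmso, "mean", "on", 300, seed=2)
        on_mean_treated = bootstrap_cell_statistic(treated, "mean", "on", 300, seed=3)
        return ratio, on_mean_dmso, on_mean_treated

    def test_pure_switch_drops_on_fraction_not_intensity(self):
        ratio, dmso_stat, treated_stat = self._run("switch")
        assert ratio.ci()[1] < 1.0  # ON fraction clearly reduced
        # ON-cell intensity unchanged: bootstrap CIs overlap
        assert treated_stat.ci()[1] >= dmso_stat.ci()[0]
        assert treated_stat.ci()[0] <= dmso_stat.ci()[1]

    def test_pure_fade_drops_intensity_not_on_fraction(self):
        ratio, dmso_stat, treated_stat = self._run("fade")
        lo, hi = ratio.ci()
        assert lo <= 1.0 <= hi  # ON fraction unchanged
        assert treated_stat.ci()[1] < dmso_stat.ci()[0]  # intensity clearly down
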