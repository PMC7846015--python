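"""Monte-Carlo validation studies of the analysis chain.

Each study repeatedly simulates an experiment with the synthetic
generator, runs the corresponding analysis exactly as a user would, and
summarizes how well the analysis recovers the generator's ground truth:
parameter recovery and bootstrap-CI coverage for the Hill fits, AIC model
selection rates, matched ON-ratio CI coverage, and switch-vs-fade
discrimination.  They are used by the test suite and by the acceptance
script; repetition counts are arguments so callers choose their
precision/time trade-off.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .curves import HillParams, encode_log_dose
from .doseresponse import DoseResponseModel, compare_models_aic
from .normalize import normalize_embryos
from .singlecell import (
    bootstrap_cell_statistic,
    bootstrap_on_ratio,
    classify_on_off,
    normalize_cell_means,
)
from .synthetic import OnResponse, ReporterTruth, SynthConfig, simulate_experiment

__all__ = [
    "parameter_recovery_study",
    "model_selection_study",
    "on_ratio_coverage_study",
    "switch_fade_study",
]


def _study_config(reporter: str = "Distal") -> SynthConfig:
    """Default-design experiment restricted to one reporter."""
    base = SynthConfig()
    return base.replace(reporters=(reporter,))


@dataclass
class RecoveryStudy:
    abs_err_log_ec50: np.ndarray
    covered_ec50: np.ndarray
    covered_hill: np.ndarray

    @property
    def mae_log_ec50(self) -> float:
        return float(np.median(self.abs_err_log_ec50))

    @property
    def coverage_ec50(self) -> float:
        return float(np.mean(self.covered_ec50))

    @property
    def coverage_hill(self) -> float:
        return float(np.mean(self.covered_hill))


def parameter_recovery_study(
    n_rep: int = 200,
    n_boot: int = 250,
    seed: int = 0,
    bootstrap_method: str = "residual",
) -> RecoveryStudy:
    """Fit monophasic curves to repeated synthetic experiments.

    Each repetition simulates the full study design for the Distal
    reporter (its configured truth: EC50 0.0686 uM, Hill -1.43),
    normalizes, fits, and residual-bootstraps.  Records the absolute
    error of the fitted log10-EC50 and whether the 95% percentile CIs
    cover the true log10-EC50 and Hill coefficient.  Normalization
    rescales the response axis but leaves EC50 and Hill untouched, so
    truth is well-defined for both.
    """
    truth: HillParams = SynthConfig().true_params["Distal"].params
    errs = np.empty(n_rep)
    cov_c = np.empty(n_rep, dtype=bool)
    cov_b = np.empty(n_rep, dtype=bool)
    for rep in range(n_rep):
        cfg = _study_config("Distal")
        embryos, _, _ = simulate_experiment(cfg, seed=seed + rep)
        norm = normalize_embryos(embryos, reference_reporter="Distal")
        res = DoseResponseModel.from_dataframe(norm).fit()
        boot = res.bootstrap(n_boot=n_boot, seed=seed + rep, method=bootstrap_method)
        errs[rep] = abs(res.params[2] - truth.C)
        lo, hi = np.percentile(boot.estimates["C"], [2.5, 97.5])
        cov_c[rep] = lo <= truth.C <= hi
        lo, hi = np.percentile(boot.estimates["B"], [2.5, 97.5])
        cov_b[rep] = lo <= truth.B <= hi
    return RecoveryStudy(errs, cov_c, cov_b)


@dataclass
class SelectionStudy:
    picked_monophasic: np.ndarray  # generating class monophasic
    picked_biphasic: np.ndarray  # generating class biphasic
    best_rel_likelihood_always_one: bool

    @property
    def rate_monophasic(self) -> float:
        return float(np.mean(self.picked_monophasic))

    @property
    def rate_biphasic(self) -> float:
        return float(np.mean(self.picked_biphasic))


def model_selection_study(n_rep: int = 200, seed: int = 0) -> SelectionStudy:
    """AIC selection between linear/monophasic/biphasic on known truth.

    Monophasic data use the Distal truth; biphasic data use the
    FullLength truth, whose two phases sit >1 log unit apart with
    distinct plateaus.  Records how often the generating class wins and
    verifies the best model's relative likelihood is exactly 1.
    """
    picks = {"monophasic": np.empty(n_rep, dtype=bool), "biphasic": np.empty(n_rep, dtype=bool)}
    rel_ok = True
    for gen_kind, reporter in (("monophasic", "Distal"), ("biphasic", "FullLength")):
        for rep in range(n_rep):
            cfg = _study_config(reporter)
            embryos, _, _ = simulate_experiment(cfg, seed=seed + 10_000 + rep)
            norm = normalize_embryos(embryos, reference_reporter=reporter)
            fits = [
                DoseResponseModel.from_dataframe(norm, kind=k).fit()
                for k in ("linear", "monophasic", "biphasic")
            ]
            table = compare_models_aic(fits)
            picks[gen_kind][rep] = table["aic"].idxmin() == gen_kind
            rel_ok &= table["rel_likelihood"].max() == 1.0
    return SelectionStudy(picks["monophasic"], picks["biphasic"], rel_ok)


def _switch_config(r_true: float, dose: float, hill: float = -2.0) -> SynthConfig:
    """Pure-switch design whose true ON ratio at ``dose`` is exactly ``r_true``.

    Inverting the ON-fraction Hill: phase(x) = r at x = log10(dose) gives
    ``C_on = x + log10(1/r - 1) / B``.
    """
    x = np.log10(dose)
    c_on = x + np.log10(1.0 / r_true - 1.0) / hill
    flat = ReporterTruth("monophasic", HillParams(0.3, -1e-9, 0.0, 0.3))
    return SynthConfig(
        reporters=("Distal",),
        doses=(0.0, dose),
        true_params={"Distal": flat},
        on_response={"Distal": OnResponse(ec50_log10=c_on, hill=hill)},
        batch_efficiency_sd=0.0,
    )


def on_ratio_coverage_study(
    r_true: float, n_rep: int = 300, n_boot: int = 300, seed: int = 0, dose: float = 0.34
) -> float:
    """Coverage of the matched ON-ratio bootstrap CI at a known true ratio."""
    cfg = _switch_config(r_true, dose)
    hits = 0
    for rep in range(n_rep):
        _, cells, _ = simulate_experiment(cfg, seed=seed + rep)
        cells = cells.assign(on=classify_on_off(cells["roi_mode"].to_numpy()))
        treated = cells[~cells["vehicle"]]
        dmso = cells[cells["vehicle"]]
        boot = bootstrap_on_ratio(treated, dmso, n_boot=n_boot, seed=seed + rep)
        lo, hi = boot.ci()
        hits += lo <= r_true <= hi
    return hits / n_rep


@dataclass
class SwitchFadeResult:
    on_ratio_ci: tuple
    on_mean_dmso_ci: tuple
    on_mean_treated_ci: tuple

    @property
    def on_fraction_reduced(self) -> bool:
        return self.on_ratio_ci[1] < 1.0

    @property
    def on_fraction_unchanged(self) -> bool:
        return self.on_ratio_ci[0] <= 1.0 <= self.on_ratio_ci[1]

    @property
    def intensity_unchanged(self) -> bool:
        return (
            self.on_mean_treated_ci[1] >= self.on_mean_dmso_ci[0]
            and self.on_mean_treated_ci[0] <= self.on_mean_dmso_ci[1]
        )

    @property
    def intensity_reduced(self) -> bool:
        return self.on_mean_treated_ci[1] < self.on_mean_dmso_ci[0]


def switch_fade_study(
    mode: str, seed: int = 31, n_boot: int = 300, dose: float = 0.2
) -> SwitchFadeResult:
    """One seeded pure-switch or pure-fade experiment, analyzed at the EC50.

    In switch mode the ON fraction halves at the EC50 dose while ON-cell
    intensity is dose-independent; in fade mode the ON-cell intensity
    halves while mosaicism is dose-independent.
    """
    if mode not in ("switch", "fade"):
        raise ValueError("mode must be 'switch' or 'fade'")
    if mode == "switch":
        cfg = _switch_config(0.5, dose, hill=-1.5)
        cfg = cfg.replace(doses=(0.0, dose, 5.0 * dose))
    else:
        falling = ReporterTruth(
            "monophasic", HillParams(0.3, -1.5, float(np.log10(dose)), 0.02)
        )
        cfg = SynthConfig(
            reporters=("Distal",),
            doses=(0.0, dose, 5.0 * dose),
            true_params={"Distal": falling},
            batch_efficiency_sd=0.0,
        )
    _, cells, _ = simulate_experiment(cfg, seed=seed)
    cells = cells.assign(on=classify_on_off(cells["roi_mode"].to_numpy()))
    cells = normalize_cell_means(cells, reference_reporter=None)
    dmso = cells[cells["vehicle"]]
    treated = cells[cells["dose_um"] == dose]
    ratio = bootstrap_on_ratio(treated, dmso, n_boot=n_boot, seed=seed + 1)
    dmso_stat = bootstrap_cell_statistic(dmso, "mean", "on", n_boot=n_boot, seed=seed + 2)
    treated_stat = bootstrap_cell_statistic(treated, "mean", "on", n_boot=n_boot, seed=seed + 3)
    return SwitchFadeResult(ratio.ci(), dmso_stat.ci(), treated_stat.ci())
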