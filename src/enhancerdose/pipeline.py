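"""End-to-end orchestration: simulate (or load) tables, then run every
analysis stage with recorded seeds and a reproducible manifest.

Stage order: synthgen (optional) -> imagequant (optional) -> normalize ->
doseresponse -> singlecell -> insitu.  Each stage writes CSV/JSON outputs
into the run directory; the manifest records the configuration, per-stage
seeds, input hashes and per-stage summaries, so a rerun from the same
manifest reproduces all outputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import doseresponse as dr
from . import insitu as insitu_mod
from . import normalize as norm
from . import singlecell as sc
from .synthetic import SCORE_COLUMNS, SynthConfig, simulate_experiment, simulate_insitu

__all__ = ["RunConfig", "run_pipeline", "validate_inputs"]

STAGES = ("synthgen", "imagequant", "normalize", "doseresponse", "singlecell", "insitu")


@dataclass
class RunConfig:
    """Configuration for one pipeline run."""

    stages: tuple = ("synthgen", "normalize", "doseresponse", "singlecell", "insitu")
    seed: int = 0
    n_boot: int = 1000
    embryos_csv: str | None = None  # used instead of synthgen when given
    cells_csv: str | None = None
    scores_csv: str | None = None
    synth: SynthConfig = field(default_factory=SynthConfig)

    def validate(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stages: {unknown}")
        if "synthgen" not in self.stages:
            for stage, path in (
                ("normalize", self.embryos_csv),
                ("singlecell", self.cells_csv),
                ("insitu", self.scores_csv),
            ):
                if stage in self.stages and path is None:
                    raise ValueError(f"stage {stage!r} enabled but no input table given")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        synth = SynthConfig(**raw.pop("synth", {}))
        cfg = cls(synth=synth, **{k: tuple(v) if k == "stages" else v for k, v in raw.items()})
        cfg.validate()
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_seed(base: int, stage: str) -> int:
    h = hashlib.sha256(f"{base}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def validate_inputs(
    embryos: pd.DataFrame | None = None,
    cells: pd.DataFrame | None = None,
    scores: pd.DataFrame | None = None,
    n_cells: int = 40,
) -> pd.DataFrame:
    """Check input tables against the analysis contracts.

    Hard violations make a stage impossible (batch without DMSO controls,
    negative SEV, scores outside 0..3); soft violations only exclude rows
    (embryos without a complete cell complement are dropped from
    cell-level analyses).  Returns a table of violations; empty when clean.
    """
    rows = []
    if embryos is not None:
        veh = embryos["vehicle"].astype(bool)
        have_dmso = set(
            map(tuple, embryos.loc[veh, ["batch_id", "reporter"]].drop_duplicates().to_numpy())
        )
        for key in map(tuple, embryos[["batch_id", "reporter"]].drop_duplicates().to_numpy()):
            if key not in have_dmso:
                rows.append(("hard", "batch_without_dmso", f"{key[0]}/{key[1]}"))
        neg = embryos[embryos["sev"] < 0]
        for eid in neg["embryo_id"]:
            rows.append(("hard", "negative_sev", str(eid)))
    if cells is not None:
        counts = cells.groupby("embryo_id", observed=True)["cell_index"].size()
        for eid, c in counts[counts != n_cells].items():
            rows.append(("soft", "incomplete_embryo", f"{eid}: {c}/{n_cells} cells"))
    if scores is not None:
        cols = [c for c in SCORE_COLUMNS if c in scores.columns]
        vals = scores[cols].to_numpy()
        bad = ~np.isin(vals, [0, 1, 2, 3])
        for i in np.unique(np.nonzero(bad)[0]):
            rows.append(("hard", "score_out_of_range", str(scores.iloc[i]["embryo_id"])))
    return pd.DataFrame(rows, columns=["severity", "kind", "detail"])


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute the configured stages; returns (and writes) the manifest."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "n_boot": config.n_boot,
        "stages": list(config.stages),
        "stage_seeds": {s: _stage_seed(config.seed, s) for s in config.stages},
        "inputs": {},
        "summaries": {},
    }

    embryos = cells = scores = None
    try:
        if "synthgen" in config.stages:
            sd = manifest["stage_seeds"]["synthgen"]
            embryos, cells, truth = simulate_experiment(config.synth, seed=sd)
            scores = simulate_insitu(config.synth, seed=sd + 1)
            embryos.to_csv(outdir / "embryos.csv", index=False)
            cells.to_csv(outdir / "cells.csv", index=False)
            scores.to_csv(outdir / "insitu_scores.csv", index=False)
            truth.embryos.to_csv(outdir / "truth_embryos.csv", index=False)
            manifest["summaries"]["synthgen"] = {
                "n_embryos": len(embryos),
                "n_cells": len(cells),
                "n_insitu_embryos": len(scores),
            }
        else:
            if config.embryos_csv:
                embryos = pd.read_csv(config.embryos_csv)
                manifest["inputs"]["embryos_csv"] = _sha256(Path(config.embryos_csv))
            if config.cells_csv:
                cells = pd.read_csv(config.cells_csv)
                manifest["inputs"]["cells_csv"] = _sha256(Path(config.cells_csv))
            if config.scores_csv:
                scores = pd.read_csv(config.scores_csv)
                manifest["inputs"]["scores_csv"] = _sha256(Path(config.scores_csv))

        if "normalize" in config.stages:
            _run_normalize(config, embryos, outdir, manifest)
        if "doseresponse" in config.stages:
            _run_doseresponse(config, outdir, manifest)
        if "singlecell" in config.stages:
            _run_singlecell(config, cells, outdir, manifest)
        if "insitu" in config.stages:
            _run_insitu(config, scores, outdir, manifest)
    except Exception as exc:
        # partial outputs stay on disk for debugging; name the failing stage
        raise RuntimeError(f"pipeline failed in stage context: {exc}") from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest


def _run_normalize(config, embryos, outdir, manifest):
    if embryos is None:
        raise ValueError("normalize stage requires an embryo table")
    normalized = norm.normalize_embryos(embryos)
    normalized.to_csv(outdir / "normalized_embryos.csv", index=False)
    boot = norm.bootstrap_dmso_expression(
        normalized, n_boot=config.n_boot, seed=manifest["stage_seeds"]["normalize"]
    )
    boot.to_csv(outdir / "dmso_bootstrap.csv", index=False)
    summary = {
        col: {
            "mean": float(boot[col].mean()),
            "ci": list(norm.percentile_ci(boot[col])),
        }
        for col in boot.columns
    }
    if {"FullLength", "ProximalPlusDistal"} <= set(boot.columns):
        summary["p_fulllength_vs_sum"] = norm.compare_dmso_means(
            boot["FullLength"], boot["ProximalPlusDistal"]
        )
    if {"Proximal", "Distal"} <= set(boot.columns):
        summary["p_proximal_vs_distal"] = norm.compare_dmso_means(
            boot["Proximal"], boot["Distal"]
        )
    manifest["summaries"]["normalize"] = summary


def _run_doseresponse(config, outdir, manifest):
    normalized = pd.read_csv(outdir / "normalized_embryos.csv")
    seed = manifest["stage_seeds"]["doseresponse"]
    out = {}
    for i, (rep, grp) in enumerate(normalized.groupby("reporter", observed=True, sort=True)):
        fits = [
            dr.DoseResponseModel.from_dataframe(grp, kind=k).fit()
            for k in ("linear", "monophasic", "biphasic")
        ]
        table = dr.compare_models_aic(fits)
        best_kind = table["rel_likelihood"].idxmax()
        mono = fits[1]
        boot = mono.bootstrap(n_boot=config.n_boot, seed=seed + i)
        boot.estimates.to_csv(outdir / f"bootstrap_{rep}.csv", index=False)
        out[rep] = {
            "aic_table": table.reset_index().to_dict(orient="records"),
            "preferred_model": str(best_kind),
            "monophasic_params": dict(zip(mono.param_names, map(float, mono.params))),
            "bootstrap_medians": {k: float(v) for k, v in boot.medians.items()},
            "ec50_um_median": float(10 ** boot.medians["C"]),
            "n_failed_bootstrap": boot.n_failed,
        }
    with open(outdir / "doseresponse.json", "w") as fh:
        json.dump(out, fh, indent=2)
    manifest["summaries"]["doseresponse"] = {
        rep: {"ec50_um_median": v["ec50_um_median"], "preferred_model": v["preferred_model"]}
        for rep, v in out.items()
    }


def _run_singlecell(config, cells, outdir, manifest):
    if cells is None:
        raise ValueError("singlecell stage requires a cell table")
    seed = manifest["stage_seeds"]["singlecell"]
    cells, n_excluded = sc.filter_complete_embryos(cells, config.synth.n_notochord_cells)
    cells = cells.assign(on=sc.classify_on_off(cells["roi_mode"].to_numpy()))
    cells = sc.normalize_cell_means(cells)
    cells.to_csv(outdir / "cells_classified.csv", index=False)
    out = {"n_incomplete_embryos_excluded": n_excluded, "reporters": {}}
    for rep, grp in cells.groupby("reporter", observed=True, sort=True):
        dmso = grp[grp["vehicle"].astype(bool)]
        per_dose = {}
        for dose, treated in grp[~grp["vehicle"].astype(bool)].groupby("dose_um", sort=True):
            ratio = sc.bootstrap_on_ratio(treated, dmso, n_boot=config.n_boot, seed=seed)
            stat = sc.bootstrap_cell_statistic(
                treated, "mean", "all", n_boot=config.n_boot, seed=seed + 1
            )
            per_dose[str(dose)] = {
                "on_ratio_median": ratio.median,
                "on_ratio_ci": list(ratio.ci()),
                "on_ratio_p_vs_1": ratio.p_vs_1,
                "mean_expr_median": stat.median,
                "mean_expr_ci": list(stat.ci()),
            }
        out["reporters"][rep] = per_dose
    with open(outdir / "singlecell.json", "w") as fh:
        json.dump(out, fh, indent=2)
    manifest["summaries"]["singlecell"] = {"n_incomplete_embryos_excluded": n_excluded}


def _run_insitu(config, scores, outdir, manifest):
    if scores is None:
        raise ValueError("insitu stage requires a score matrix")
    seed = manifest["stage_seeds"]["insitu"]
    _, per_dose = insitu_mod.rescale_to_dmso(scores)
    per_dose.to_csv(outdir / "insitu_dose_curve.csv")
    classes = insitu_mod.group_by_cell_class(scores)
    classes.to_csv(outdir / "insitu_cell_classes.csv", index=False)
    ordered = insitu_mod.heatmap_order(scores)
    ordered.to_csv(outdir / "insitu_heatmap_ordered.csv", index=False)
    shuffled = insitu_mod.shuffle_positions(ordered, seed=seed)
    shuffled.to_csv(outdir / "insitu_heatmap_shuffled.csv", index=False)
    manifest["summaries"]["insitu"] = {
        "n_embryos": len(scores),
        "n_nonuniform": len(ordered),
    }
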