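"""Batch normalization of whole-embryo reporter measurements.

Transgene electroporation efficiency varies between batches, so raw summed
enhancer values (SEV) are not comparable across electroporations.  The
normalization chain is:

1. ``norm_score`` — each embryo's SEV divided by the mean SEV of the DMSO
   vehicle controls from the *same electroporation batch and reporter*.
2. ``nssev`` — the normalized score multiplied by the grand mean SEV of
   all DMSO controls for that reporter across batches (restores the
   reporter's natural scale; NSSEV = normalized scaled SEV).
3. ``expr`` — NSSEV expressed as a fraction of the reference reporter's
   (default the full-length construct's) grand DMSO mean NSSEV, so the
   reference reporter's DMSO mean is exactly 1.

Grand DMSO means are unweighted means over embryos.  Bootstrap utilities
resample DMSO expression stratified by batch, preserving each batch's
original count by default (``equal_per_batch=True`` draws the same number
from every batch instead).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "REPORTERS",
    "normalize_embryos",
    "bootstrap_dmso_expression",
    "compare_dmso_means",
    "percentile_ci",
]

REPORTERS = ("Proximal", "Distal", "FullLength")

#: canonical embryo-table columns
EMBRYO_COLUMNS = ("embryo_id", "reporter", "dose_um", "vehicle", "batch_id", "sev")


def _check_columns(df: pd.DataFrame, needed) -> None:
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"table is missing columns: {missing}")


def normalize_embryos(
    embryos: pd.DataFrame,
    reference_reporter: str | None = "FullLength",
    value_col: str = "sev",
) -> pd.DataFrame:
    """Add ``norm_score``, ``nssev`` and ``expr`` columns to an embryo table.

    Raises if any (batch, reporter) group with measurements lacks DMSO
    controls, or if a DMSO mean is zero — both make the batch
    uninterpretable rather than merely noisy.

    ``reference_reporter=None`` skips the final rescaling (``expr`` equals
    ``nssev``); otherwise the reference reporter must have DMSO embryos.
    """
    _check_columns(embryos, ("reporter", "batch_id", "vehicle", value_col))
    df = embryos.copy()
    veh = df["vehicle"].astype(bool)

    batch_means = (
        df[veh].groupby(["batch_id", "reporter"], observed=True)[value_col].mean()
    )
    keys = pd.MultiIndex.from_frame(df[["batch_id", "reporter"]])
    have = keys.isin(batch_means.index)
    if not have.all():
        bad = sorted({tuple(k) for k in keys[~have]})
        raise ValueError(f"batches without DMSO controls: {bad}")
    means = batch_means.loc[keys].to_numpy()
    if np.any(means == 0):
        bad = sorted({tuple(k) for k, m in zip(keys, means) if m == 0})
        raise ValueError(f"zero DMSO mean SEV in: {bad}")
    df["norm_score"] = df[value_col].to_numpy() / means

    grand = df[veh].groupby("reporter", observed=True)[value_col].mean()
    df["nssev"] = df["norm_score"] * grand.loc[df["reporter"]].to_numpy()

    if reference_reporter is None:
        df["expr"] = df["nssev"]
        return df
    ref = df[veh & (df["reporter"] == reference_reporter)]
    if ref.empty:
        raise ValueError(
            f"reference reporter {reference_reporter!r} has no DMSO embryos"
        )
    df["expr"] = df["nssev"] / ref["nssev"].mean()
    return df


def _stratified_mean_replicates(
    values_by_batch: list[np.ndarray],
    n_boot: int,
    rng: np.random.Generator,
    equal_per_batch: bool,
) -> np.ndarray:
    """Bootstrap means resampled within each batch."""
    sizes = [v.size for v in values_by_batch]
    if equal_per_batch:
        per = max(1, round(sum(sizes) / len(sizes)))
        sizes = [per] * len(values_by_batch)
    total = sum(sizes)
    means = np.zeros(n_boot)
    for v, m in zip(values_by_batch, sizes):
        idx = rng.integers(0, v.size, size=(n_boot, m))
        means += v[idx].sum(axis=1)
    return means / total


def bootstrap_dmso_expression(
    embryos: pd.DataFrame,
    n_boot: int = 1000,
    seed=None,
    equal_per_batch: bool = False,
    value_col: str = "expr",
) -> pd.DataFrame:
    """Bootstrap distributions of mean DMSO expression per reporter.

    Returns a DataFrame with one column per reporter present plus, when
    both single-enhancer reporters are present, a ``ProximalPlusDistal``
    column whose replicate i is the sum of the Proximal and Distal
    replicate means — the additivity reference for the full-length
    construct.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    _check_columns(embryos, ("reporter", "batch_id", "vehicle", value_col))
    rng = np.random.default_rng(seed)
    dmso = embryos[embryos["vehicle"].astype(bool)]
    out = {}
    for rep, grp in dmso.groupby("reporter", observed=True, sort=True):
        if len(grp) < 2:
            raise ValueError(f"need >= 2 DMSO embryos for reporter {rep!r}")
        by_batch = [
            g[value_col].to_numpy(dtype=float)
            for _, g in grp.groupby("batch_id", observed=True, sort=True)
        ]
        out[rep] = _stratified_mean_replicates(by_batch, n_boot, rng, equal_per_batch)
    result = pd.DataFrame(out)
    if {"Proximal", "Distal"} <= set(result.columns):
        result["ProximalPlusDistal"] = result["Proximal"] + result["Distal"]
    return result


def compare_dmso_means(dist_a, dist_b) -> float:
    """Two-sided independent-samples t-test between two bootstrap distributions.

    Welch's correction is used (no equal-variance assumption).  Two
    zero-variance inputs are degenerate: returns 1.0 for equal means, else
    ~0, with a warning.
    """
    a = np.asarray(dist_a, dtype=float)
    b = np.asarray(dist_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 values per distribution")
    if np.var(a) == 0 and np.var(b) == 0:
        warnings.warn("both distributions are constant; t-test degenerate", RuntimeWarning)
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def percentile_ci(values, level: float = 95.0) -> tuple[float, float]:
    """Percentile confidence interval (2.5th/97.5th at the default level)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty input")
    lo = (100.0 - level) / 2.0
    low, high = np.percentile(v, [lo, 100.0 - lo])
    return float(low), float(high)
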