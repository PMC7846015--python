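"""Single-cell ON/OFF classification and matched-control bootstrap statistics.

Electroporated transgene expression is mosaic: even vehicle-control
embryos contain notochord cells with no reporter signal.  Cells are
classified OFF when the modal gray value of their nuclear ROI is at or
below a threshold (default 10), exploiting the bimodal distribution of
ROI modes; everything else is ON.

Because the ON fraction is very sensitive to batch-to-batch
electroporation efficiency, dose effects on the ON fraction are expressed
as a *ratio* against matched DMSO controls: each bootstrap replicate
resamples treated cells stratified by electroporation batch and draws an
equally sized DMSO sample from the same batches, so efficiency differences
cancel within every replicate.

Mean and 90th-percentile expression are bootstrapped stratified by batch
(each batch contributes exactly its observed number of cells), separately
for ALL cells and for ON cells only — the two views needed to tell a
"switch" (fewer expressing cells) from a "fade" (dimmer expressing cells)
response.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .normalize import normalize_embryos, percentile_ci

__all__ = [
    "classify_on_off",
    "filter_complete_embryos",
    "normalize_cell_means",
    "log_pseudocount",
    "bootstrap_on_ratio",
    "bootstrap_cell_statistic",
    "pairwise_dose_pvalue",
    "format_exceedance_p",
    "OnRatioBootstrap",
    "CellStatBootstrap",
]

ON_MODE_THRESHOLD = 10


def classify_on_off(roi_mode, threshold: int = ON_MODE_THRESHOLD):
    """True where the cell is ON; OFF iff ``roi_mode <= threshold``.

    Modal gray values are integers by construction; non-integer input is
    rejected rather than rounded.
    """
    arr = np.asarray(roi_mode)
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.all(np.equal(np.mod(arr, 1), 0)):
            raise ValueError("roi_mode must be integer gray values")
        arr = arr.astype(int)
    if np.any(arr < 0):
        raise ValueError("roi_mode must be >= 0")
    on = arr > threshold
    return bool(on) if np.isscalar(roi_mode) else on


def filter_complete_embryos(
    cells: pd.DataFrame, n_cells: int = 40
) -> tuple[pd.DataFrame, int]:
    """Keep only embryos with all ``n_cells`` notochord cells measured.

    Returns the filtered table and the number of excluded embryos.
    """
    counts = cells.groupby("embryo_id", observed=True)["cell_index"].size()
    complete = counts.index[counts == n_cells]
    excluded = int(len(counts) - len(complete))
    return cells[cells["embryo_id"].isin(complete)].copy(), excluded


def normalize_cell_means(
    cells: pd.DataFrame, reference_reporter: str | None = "FullLength"
) -> pd.DataFrame:
    """Normalize per-cell ROI means with the whole-embryo scheme.

    The same chain as embryo normalization is applied to ``roi_mean``
    (batch-DMSO mean division, rescaling by the grand DMSO mean, fraction
    of the reference reporter's DMSO mean); the result lands in
    ``norm_mean``.
    """
    out = normalize_embryos(cells, reference_reporter=reference_reporter, value_col="roi_mean")
    out = out.rename(columns={"expr": "norm_mean"})
    return out.drop(columns=["norm_score", "nssev"])


def log_pseudocount(values, base: float = 10.0) -> np.ndarray:
    """Log transform with a pseudocount of 1, so zero maps to zero."""
    v = np.asarray(values, dtype=float)
    if np.any(v < 0):
        raise ValueError("values must be >= 0 before log transform")
    return np.log(v + 1.0) / np.log(base)


def _batch_groups(df: pd.DataFrame, col: str) -> dict[str, np.ndarray]:
    return {
        b: g[col].to_numpy()
        for b, g in df.groupby("batch_id", observed=True, sort=True)
    }


@dataclass
class OnRatioBootstrap:
    """Bootstrap distribution of the matched ON-fraction ratio (treated / DMSO)."""

    ratios: np.ndarray
    n_boot: int
    n_dropped: int  # replicates with a zero DMSO ON fraction

    @property
    def median(self) -> float:
        return float(np.median(self.ratios))

    def ci(self, level: float = 95.0) -> tuple[float, float]:
        return percentile_ci(self.ratios, level)

    @property
    def p_vs_1(self) -> float:
        """One-sample t-test of the bootstrap distribution against ratio 1."""
        if np.var(self.ratios) == 0:
            return 1.0 if np.all(self.ratios == 1.0) else 0.0
        return float(stats.ttest_1samp(self.ratios, 1.0).pvalue)


def bootstrap_on_ratio(
    treated: pd.DataFrame,
    dmso: pd.DataFrame,
    n_boot: int = 1000,
    seed=None,
    on_col: str = "on",
) -> OnRatioBootstrap:
    """Matched-control bootstrap of the ON-fraction ratio.

    Replicate i resamples treated cells within each batch (preserving the
    batch's cell count) and an *equally sized* DMSO sample from the same
    batch, then computes ``ON fraction(treated*) / ON fraction(DMSO*)``.
    Replicates whose DMSO ON fraction is zero leave the ratio undefined;
    they are dropped and counted.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if treated.empty or dmso.empty:
        raise ValueError("treated and DMSO groups must be nonempty")
    rng = np.random.default_rng(seed)
    t_groups = _batch_groups(treated, on_col)
    d_groups = _batch_groups(dmso, on_col)
    missing = [b for b in t_groups if b not in d_groups]
    if missing:
        raise ValueError(f"no DMSO cells for batches: {missing}")

    n_total = sum(v.size for v in t_groups.values())
    t_on = np.zeros(n_boot)
    d_on = np.zeros(n_boot)
    for b, tv in t_groups.items():
        dv = d_groups[b]
        t_on += tv[rng.integers(0, tv.size, size=(n_boot, tv.size))].sum(axis=1)
        d_on += dv[rng.integers(0, dv.size, size=(n_boot, tv.size))].sum(axis=1)
    keep = d_on > 0
    ratios = (t_on[keep] / n_total) / (d_on[keep] / n_total)
    if ratios.size == 0:
        raise RuntimeError("all replicates had a zero DMSO ON fraction")
    return OnRatioBootstrap(ratios=ratios, n_boot=n_boot, n_dropped=int((~keep).sum()))


@dataclass
class CellStatBootstrap:
    """Bootstrap distribution of a summary statistic of cell expression."""

    values: np.ndarray
    statistic: str
    subset: str
    n_boot: int

    @property
    def median(self) -> float:
        return float(np.median(self.values))

    def ci(self, level: float = 95.0) -> tuple[float, float]:
        return percentile_ci(self.values, level)


def bootstrap_cell_statistic(
    cells: pd.DataFrame,
    statistic: str = "mean",
    subset: str = "all",
    n_boot: int = 1000,
    seed=None,
    value_col: str = "norm_mean",
    on_col: str = "on",
) -> CellStatBootstrap:
    """Stratified bootstrap of the mean or 90th percentile of cell expression.

    ``subset="on"`` restricts to ON cells (requires an ``on`` column);
    each replicate resamples within every electroporation batch with its
    observed cell count.
    """
    if statistic not in ("mean", "p90"):
        raise ValueError("statistic must be 'mean' or 'p90'")
    if subset not in ("all", "on"):
        raise ValueError("subset must be 'all' or 'on'")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    df = cells
    if subset == "on":
        df = df[df[on_col].astype(bool)]
    if df.empty:
        raise ValueError(f"subset {subset!r} is empty")
    rng = np.random.default_rng(seed)
    groups = _batch_groups(df, value_col)
    samples = [
        v[rng.integers(0, v.size, size=(n_boot, v.size))] for v in groups.values()
    ]
    pooled = np.concatenate(samples, axis=1)
    if statistic == "mean":
        vals = pooled.mean(axis=1)
    else:
        vals = np.percentile(pooled, 90, axis=1)
    return CellStatBootstrap(values=vals, statistic=statistic, subset=subset, n_boot=n_boot)


def pairwise_dose_pvalue(boot_high, boot_low, two_sided: bool = False) -> float:
    """Exceedance p-value from matched bootstrap replicates.

    ``p = #{i : high_i > low_i} / n``: the fraction of replicate pairs in
    which expression at the higher dose exceeded the lower dose.  Zero
    exceedances should be reported as ``< 1/n`` (see
    :func:`format_exceedance_p`).  ``two_sided=True`` doubles the smaller
    tail.
    """
    hi = np.asarray(boot_high, dtype=float)
    lo = np.asarray(boot_low, dtype=float)
    if hi.shape != lo.shape:
        raise ValueError("bootstrap distributions must be matched (equal length)")
    p = float(np.mean(hi > lo))
    if two_sided:
        p = min(1.0, 2.0 * min(p, 1.0 - p))
    return p


def format_exceedance_p(p: float, n_boot: int) -> str:
    """Human-readable exceedance p, reporting 0 as '< 1/n_boot'."""
    if p <= 0:
        return f"< {1.0 / n_boot:g}"
    return f"{p:g}"
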