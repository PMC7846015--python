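"""Analysis of semi-quantitative in situ hybridization scores.

Input is a score matrix: one row per embryo (with dose and batch), ten
columns for the notochord founder blastomeres (left/right pairs of A8.5,
A8.6, A8.13, A8.14, B8.6), integer scores 0 (no expression) to 3 (robust
expression).

Provided analyses: rescaling per-embryo mean scores so the DMSO group
mean is 1 (comparable to normalized reporter expression), grouping
founder cells into medial / lateral / secondary classes, one-way ANOVA +
Tukey HSD across cell pairs within a dose, and heatmap utilities —
ordering embryos by mean score with uniform rows removed, and per-embryo
positional shuffling as the randomized control.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import FOUNDER_PAIRS, SCORE_COLUMNS

__all__ = [
    "CELL_CLASSES",
    "rescale_to_dmso",
    "group_by_cell_class",
    "test_cell_pairs",
    "heatmap_order",
    "shuffle_positions",
]

#: founder pairs by anatomical class (medial primary cells sit nearest the midline)
CELL_CLASSES = {
    "medial": ("A8.5", "A8.6"),
    "lateral": ("A8.13", "A8.14"),
    "secondary": ("B8.6",),
}


def _score_cols(df: pd.DataFrame) -> list[str]:
    cols = [c for c in SCORE_COLUMNS if c in df.columns]
    if len(cols) != len(SCORE_COLUMNS):
        missing = sorted(set(SCORE_COLUMNS) - set(cols))
        raise ValueError(f"score matrix missing columns: {missing}")
    return cols


def _mean_ci(values: np.ndarray, level: float = 95.0) -> tuple[float, float, float]:
    """Normal-approximation CI of the mean."""
    m = float(np.mean(values))
    if values.size < 2:
        return m, m, m
    z = stats.norm.ppf(0.5 + level / 200.0)
    half = z * np.std(values, ddof=1) / np.sqrt(values.size)
    return m, m - half, m + half


def rescale_to_dmso(
    scores: pd.DataFrame, dose_col: str = "dose_um", vehicle_col: str = "vehicle"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scale per-embryo mean scores so the DMSO group mean is exactly 1.

    Returns ``(per_embryo, per_dose)``: the input with a ``scaled_mean``
    column added, and a per-dose summary (mean with 95% normal CI).
    """
    cols = _score_cols(scores)
    df = scores.copy()
    emb_mean = df[cols].mean(axis=1)
    dmso = emb_mean[df[vehicle_col].astype(bool)]
    if dmso.empty:
        raise ValueError("no DMSO embryos in score matrix")
    ref = dmso.mean()
    if ref == 0:
        raise ValueError("DMSO mean score is zero; cannot rescale")
    df["scaled_mean"] = emb_mean / ref
    rows = []
    for dose, grp in df.groupby(dose_col, sort=True):
        m, lo, hi = _mean_ci(grp["scaled_mean"].to_numpy())
        rows.append((dose, m, lo, hi, len(grp)))
    summary = pd.DataFrame(rows, columns=[dose_col, "mean", "ci_low", "ci_high", "n"])
    return df, summary.set_index(dose_col)


def group_by_cell_class(
    scores: pd.DataFrame, dose_col: str = "dose_um"
) -> pd.DataFrame:
    """Mean score per dose per cell class (medial / lateral / secondary).

    Class means are computed per embryo first (4, 4 and 2 cells per class
    respectively), then summarized with a 95% normal CI across embryos.
    """
    _score_cols(scores)
    rows = []
    for cls, pairs in CELL_CLASSES.items():
        cols = [f"{p}_{s}" for p in pairs for s in ("L", "R")]
        per_embryo = scores[cols].mean(axis=1)
        for dose, grp in per_embryo.groupby(scores[dose_col], sort=True):
            m, lo, hi = _mean_ci(grp.to_numpy())
            rows.append((dose, cls, m, lo, hi, len(grp)))
    return pd.DataFrame(
        rows, columns=[dose_col, "cell_class", "mean", "ci_low", "ci_high", "n"]
    )


def test_cell_pairs(scores_at_dose: pd.DataFrame) -> dict:
    """One-way ANOVA + Tukey HSD across the five founder cell pairs.

    Left and right members of each pair are pooled (their mean per embryo
    is the observation).  Returns ``{"anova_F", "anova_p", "tukey"}``
    where ``tukey`` is a 10-row table of pairwise comparisons.
    """
    _score_cols(scores_at_dose)
    if len(scores_at_dose) < 2:
        raise ValueError("need >= 2 embryos")
    pooled = {
        p: scores_at_dose[[f"{p}_L", f"{p}_R"]].mean(axis=1).to_numpy()
        for p in FOUNDER_PAIRS
    }
    values = np.concatenate(list(pooled.values()))
    if np.ptp(values) == 0:
        # all scores identical: nothing to test
        tukey = pd.DataFrame(
            [
                (a, b, 0.0, 1.0, False)
                for a, b in itertools.combinations(FOUNDER_PAIRS, 2)
            ],
            columns=["group1", "group2", "meandiff", "p_adj", "reject"],
        )
        return {"anova_F": 0.0, "anova_p": 1.0, "tukey": tukey}
    if any(np.ptp(v) == 0 for v in pooled.values()):
        warnings.warn(
            "a cell pair has zero score variance; ANOVA assumptions are strained",
            RuntimeWarning,
        )
    F, p = stats.f_oneway(*pooled.values())

    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    groups = np.repeat(list(pooled.keys()), [v.size for v in pooled.values()])
    res = pairwise_tukeyhsd(values, groups)
    pairs = list(itertools.combinations(res.groupsunique, 2))
    tukey = pd.DataFrame(
        {
            "group1": [a for a, _ in pairs],
            "group2": [b for _, b in pairs],
            "meandiff": res.meandiffs,
            "p_adj": res.pvalues,
            "reject": res.reject,
        }
    )
    return {"anova_F": float(F), "anova_p": float(p), "tukey": tukey}


def heatmap_order(scores: pd.DataFrame) -> pd.DataFrame:
    """Order embryos from highest to lowest mean score for heatmap display.

    Embryos with uniform scores across all ten cells (including all-zero
    rows) carry no spatial information and are removed.  Ties keep input
    order (stable sort).  Idempotent.
    """
    cols = _score_cols(scores)
    varying = scores[cols].nunique(axis=1) > 1
    kept = scores[varying]
    if kept.empty:
        warnings.warn("all embryos have uniform scores; nothing to order", RuntimeWarning)
        return kept.copy()
    means = kept[cols].mean(axis=1).to_numpy()
    order = np.argsort(-means, kind="stable")
    return kept.iloc[order].copy()


def shuffle_positions(scores: pd.DataFrame, seed=None) -> pd.DataFrame:
    """Randomize cell positions within each embryo (without replacement).

    Each row's ten scores are independently, uniformly permuted; row
    multisets are preserved exactly.  This is the spatial null model for
    the ordered heatmaps.
    """
    cols = _score_cols(scores)
    rng = np.random.default_rng(seed)
    out = scores.copy()
    vals = out[cols].to_numpy()
    for i in range(vals.shape[0]):
        vals[i] = vals[i][rng.permutation(len(cols))]
    out[cols] = vals
    return out
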