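"""Dose-response model fitting, residual bootstrap, and AIC model selection.

The central objects follow the ``Model -> fit() -> Results`` pattern:

>>> model = DoseResponseModel(x, y, kind="monophasic")
>>> res = model.fit()
>>> boot = res.bootstrap(n_boot=1000, seed=7)
>>> print(boot.summary())

``DoseResponseModel`` holds the data (log10-dose ``x`` and normalized
expression ``y``) and the model kind; ``fit`` runs bounded nonlinear least
squares; the results object carries parameters, residuals, RSS, AIC and a
``bootstrap`` method implementing the residual bootstrap: fitted-model
residuals are resampled with replacement, added back onto the fitted
curve, and each pseudo-dataset is refit.  Replicates whose refit fails
(non-convergence, non-finite parameters, or shape parameters pinned at a
bound) are dropped and counted rather than silently kept.

EC50s are summarized in log10 space (median and percentile CI of ``C``)
and back-transformed for reporting on the concentration scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .curves import (
    BiphasicParams,
    HillParams,
    LinearParams,
    encode_log_dose,
    eval_biphasic,
    eval_linear,
    eval_monophasic,
)

__all__ = [
    "DoseResponseModel",
    "DoseResponseResults",
    "ResidualBootstrap",
    "fit_model",
    "bootstrap_residual_fits",
    "compare_models_aic",
    "compare_param_distributions",
    "aic_least_squares",
]

_PARAM_NAMES = {
    "linear": ["m", "b"],
    "monophasic": ["A", "B", "C", "D"],
    "biphasic": ["A", "B", "C", "D", "E", "F", "G"],
}
_PARAM_CLS = {"linear": LinearParams, "monophasic": HillParams, "biphasic": BiphasicParams}
_EVAL = {"linear": eval_linear, "monophasic": eval_monophasic, "biphasic": eval_biphasic}

# Hill coefficients are kept strictly negative (falling response); this is
# the open edge of the [-30, 0) bound from the fitting contract.
_B_UPPER = -1e-6


def aic_least_squares(rss: float, n: int, k: int) -> float:
    """Least-squares AIC, ``n*ln(RSS/n) + 2k``.

    Shared additive constants are omitted; only AIC *differences* between
    models fit to the same data are meaningful.  ``RSS == 0`` returns
    ``-inf`` with a warning (a perfect fit dominates any comparison).
    """
    if rss <= 0:
        warnings.warn("RSS is zero; AIC is -inf (perfect fit)", RuntimeWarning, stacklevel=2)
        return -np.inf
    return n * np.log(rss / n) + 2 * k


class DoseResponseModel:
    """Dose-response curve model on a log10-dose axis.

    Parameters
    ----------
    x : array-like
        log10 dose values (vehicle already coded; see
        :func:`enhancerdose.curves.encode_log_dose`).
    y : array-like
        Normalized expression values.
    kind : {"linear", "monophasic", "biphasic"}
    """

    def __init__(self, x, y, kind: str = "monophasic"):
        if kind not in _PARAM_NAMES:
            raise ValueError(f"unknown model kind {kind!r}")
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.ndim != 1 or x.shape != y.shape:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValueError("x and y must be finite")
        self.x = x
        self.y = y
        self.kind = kind
        self.k = len(_PARAM_NAMES[kind])
        if x.size <= self.k:
            raise ValueError(
                f"need more than {self.k} points to fit a {kind} model, got {x.size}"
            )

    # ------------------------------------------------------------------
    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        kind: str = "monophasic",
        response: str = "expr",
        dose: str = "dose_um",
        vehicle: str = "vehicle",
    ) -> "DoseResponseModel":
        """Build a model from a tidy table of (dose, vehicle flag, response)."""
        flags = data[vehicle].to_numpy(dtype=bool) if vehicle in data else None
        x = encode_log_dose(data[dose].to_numpy(dtype=float), flags)
        return cls(x, data[response].to_numpy(dtype=float), kind=kind)

    # ------------------------------------------------------------------
    def default_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Minimally restrictive box bounds for the optimizer.

        Plateaus in ``[0, 2*max(y)]``; Hill coefficients in ``[-30, 0)``;
        log10-EC50s within one log unit of the observed dose range.
        """
        ymax = float(self.y.max())
        top = max(2.0 * ymax, 1e-6)
        xlo, xhi = float(self.x.min()) - 1.0, float(self.x.max()) + 1.0
        if self.kind == "linear":
            return (np.array([-np.inf, -np.inf]), np.array([np.inf, np.inf]))
        if self.kind == "monophasic":
            lo = np.array([0.0, -30.0, xlo, 0.0])
            hi = np.array([top, _B_UPPER, xhi, top])
            return lo, hi
        lo = np.array([0.0, -30.0, xlo, 0.0, -30.0, xlo, 0.0])
        hi = np.array([top, _B_UPPER, xhi, top, _B_UPPER, xhi, top])
        return lo, hi

    def default_start(self) -> np.ndarray:
        """Crude starting values from the data.

        Top plateau from the mean response at the lowest dose, bottom from
        the highest dose, EC50 at the x nearest the half-range crossing,
        Hill coefficient -1.
        """
        x, y = self.x, self.y
        if self.kind == "linear":
            m, b = np.polyfit(x, y, 1)
            return np.array([m, b])
        a0 = float(y[x == x.min()].mean())
        d0 = float(y[x == x.max()].mean())
        half = 0.5 * (a0 + d0)
        # mean y per distinct x, pick the x whose mean is closest to half-range
        ux = np.unique(x)
        uy = np.array([y[x == v].mean() for v in ux])
        c0 = float(ux[np.argmin(np.abs(uy - half))])
        if self.kind == "monophasic":
            return np.array([a0, -1.0, c0, d0])
        # biphasic: split the transition into two phases one log unit apart
        mid = 0.5 * (a0 + d0)
        return np.array([a0, -1.0, c0 - 0.5, mid, -1.0, c0 + 0.5, d0])

    # ------------------------------------------------------------------
    def _pack(self, params: np.ndarray) -> np.ndarray:
        """External -> internal parameters (biphasic F becomes C + dF >= 0)."""
        if self.kind != "biphasic":
            return np.array(params, dtype=float)
        p = np.array(params, dtype=float)
        p[5] = max(p[5] - p[2], 0.0)
        return p

    def _unpack(self, theta: np.ndarray) -> np.ndarray:
        if self.kind != "biphasic":
            return np.array(theta, dtype=float)
        p = np.array(theta, dtype=float)
        p[5] = p[2] + p[5]
        return p

    def _resid_fn(self, y):
        ev = _EVAL[self.kind]
        unpack = self._unpack

        def fun(theta):
            return ev(self.x, unpack(theta)) - y

        return fun

    def fit(self, start=None, bounds=None, max_nfev: int | None = None) -> "DoseResponseResults":
        """Fit by bounded nonlinear least squares (linear: exact lstsq).

        Non-convergence is reported through ``converged`` on the results
        object rather than raised, so bootstrap loops can drop-and-count.
        """
        return self._fit(self.y, start=start, bounds=bounds, max_nfev=max_nfev)

    def _fit(self, y, start=None, bounds=None, max_nfev=None) -> "DoseResponseResults":
        if self.kind == "linear":
            coef = np.polyfit(self.x, y, 1)
            fitted = eval_linear(self.x, coef)
            return DoseResponseResults(self, np.asarray(coef, float), y, fitted, True, False)
        lo, hi = self.default_bounds() if bounds is None else bounds
        theta0 = self._pack(self.default_start() if start is None else np.asarray(start, float))
        if self.kind == "biphasic":
            # internal dF >= 0 enforces the phase order C <= F
            lo = lo.copy()
            hi = hi.copy()
            lo[5] = 0.0
            hi[5] = float(self.x.max() - self.x.min()) + 2.0
        theta0 = np.clip(theta0, lo + 1e-9, hi - 1e-9)
        sol = optimize.least_squares(
            self._resid_fn(y), theta0, bounds=(lo, hi), method="trf", max_nfev=max_nfev
        )
        params = self._unpack(sol.x)
        fitted = _EVAL[self.kind](self.x, params)
        at_bound = self._shape_params_at_bound(sol.x, lo, hi)
        return DoseResponseResults(self, params, y, fitted, bool(sol.success), at_bound)

    def _shape_params_at_bound(self, theta, lo, hi, tol=1e-6) -> bool:
        """True when a Hill coefficient or EC50 is pinned at a box bound.

        Plateaus at 0 are legitimate (responses bottom out at zero), so
        only the shape parameters are checked.
        """
        if self.kind == "linear":
            return False
        idx = [1, 2] if self.kind == "monophasic" else [1, 2, 4, 5]
        for i in idx:
            span = hi[i] - lo[i]
            if not np.isfinite(span):
                continue
            if theta[i] - lo[i] < tol * span or hi[i] - theta[i] < tol * span:
                # B at its open upper edge (-1e-6) means a flat, unidentified slope;
                # B at -30 or C at the range edge means the transition was not located.
                return True
        return False


@dataclass
class DoseResponseResults:
    """Fit of one dose-response model: parameters, residuals, RSS, AIC."""

    model: DoseResponseModel
    params: np.ndarray
    y: np.ndarray
    fittedvalues: np.ndarray
    converged: bool
    param_at_bound: bool
    messages: list = field(default_factory=list)

    def __post_init__(self):
        self.resid = self.y - self.fittedvalues
        self.rss = float(np.sum(self.resid**2))
        self.nobs = int(self.y.size)
        self.k = self.model.k
        self.kind = self.model.kind
        self.param_names = list(_PARAM_NAMES[self.kind])
        if self.kind == "monophasic":
            A, _, _, D = self.params
            scale = max(abs(A), abs(D), 1e-12)
            if abs(A - D) < 1e-6 * scale:
                self.messages.append(
                    "plateaus coincide (A ~= D): slope and EC50 are unidentifiable"
                )

    # ------------------------------------------------------------------
    @property
    def params_named(self):
        """Parameters as their typed container (HillParams etc.)."""
        return _PARAM_CLS[self.kind](*self.params)

    @property
    def aic(self) -> float:
        return aic_least_squares(self.rss, self.nobs, self.k)

    @property
    def ok(self) -> bool:
        """Converged with finite parameters and no shape parameter at a bound."""
        return self.converged and np.all(np.isfinite(self.params)) and not self.param_at_bound

    def predict(self, x) -> np.ndarray:
        return _EVAL[self.kind](x, self.params)

    # ------------------------------------------------------------------
    def bootstrap(
        self, n_boot: int = 1000, seed=None, method: str = "residual"
    ) -> "ResidualBootstrap":
        """Residual bootstrap of the fitted curve.

        Replicate ``i`` resamples the fit residuals with replacement,
        forms ``y* = fitted + resid*`` and refits (warm-started from the
        initial estimates).  Failed refits are dropped and counted.

        ``method="wild"`` keeps each residual at its own observation and
        flips signs at random (Rademacher weights) instead of pooling
        them.  Pooled i.i.d. resampling — the default, and the classical
        recipe — assumes exchangeable residuals; under strongly
        heteroskedastic noise its confidence intervals can undercover,
        and the wild variant is the robust alternative.
        """
        if n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if method not in ("residual", "wild"):
            raise ValueError("method must be 'residual' or 'wild'")
        if not self.converged:
            raise ValueError("initial fit did not converge; cannot bootstrap")
        rng = np.random.default_rng(seed)
        n = self.nobs
        out = np.empty((n_boot, self.k))
        ok = np.zeros(n_boot, dtype=bool)
        for i in range(n_boot):
            if method == "wild":
                rstar = self.resid * rng.choice([-1.0, 1.0], size=n)
            else:
                rstar = rng.choice(self.resid, size=n, replace=True)
            ystar = self.fittedvalues + rstar
            try:
                res = self.model._fit(ystar, start=self.params)
            except Exception:  # pragma: no cover - optimizer hard failure
                continue
            if res.ok:
                out[i] = res.params
                ok[i] = True
        if not ok.any():
            raise RuntimeError("all bootstrap replicates failed to fit")
        est = pd.DataFrame(out[ok], columns=self.param_names)
        return ResidualBootstrap(self, est, n_boot=n_boot, n_failed=int(n_boot - ok.sum()))

    # ------------------------------------------------------------------
    def summary(self) -> str:
        lines = [
            f"Dose-response fit: {self.kind}",
            f"  n = {self.nobs}, k = {self.k}, RSS = {self.rss:.6g}, AIC = {self.aic:.4g}",
            f"  converged = {self.converged}",
        ]
        for name, val in zip(self.param_names, self.params):
            lines.append(f"  {name:>2} = {val: .6g}")
        if self.kind == "monophasic":
            lines.append(f"  EC50 = {10 ** self.params[2]:.4g} uM")
        if self.kind == "biphasic":
            lines.append(
                f"  EC50 (phases) = {10 ** self.params[2]:.4g}, {10 ** self.params[5]:.4g} uM"
            )
        for msg in self.messages:
            lines.append(f"  warning: {msg}")
        return "\n".join(lines)


@dataclass
class ResidualBootstrap:
    """Parameter distributions from residual-bootstrap refits."""

    results: DoseResponseResults
    estimates: pd.DataFrame
    n_boot: int
    n_failed: int

    @property
    def medians(self) -> pd.Series:
        return self.estimates.median()

    def ci(self, level: float = 95.0) -> pd.DataFrame:
        lo = (100.0 - level) / 2.0
        q = self.estimates.quantile([lo / 100.0, 1 - lo / 100.0])
        q.index = ["ci_low", "ci_high"]
        return q.T

    def param_distribution(self, name: str) -> np.ndarray:
        return self.estimates[name].to_numpy()

    def summary_frame(self, level: float = 95.0) -> pd.DataFrame:
        """Median and percentile CI per parameter.

        EC50s are summarized in log space (on C / F) and back-transformed,
        so the EC50 rows are ``10**`` of the log-space median and CI ends.
        """
        frame = self.ci(level)
        frame.insert(0, "median", self.medians)
        extra = {}
        if "C" in frame.index:
            name = "EC50" if self.results.kind == "monophasic" else "EC50_first"
            extra[name] = 10.0 ** frame.loc["C"]
        if "F" in frame.index:
            extra["EC50_second"] = 10.0 ** frame.loc["F"]
        if extra:
            frame = pd.concat([frame, pd.DataFrame(extra).T])
        return frame

    def summary(self, level: float = 95.0) -> str:
        head = (
            f"Residual bootstrap ({self.results.kind}): "
            f"{self.n_boot} replicates, {self.n_failed} failed and dropped"
        )
        return head + "\n" + self.summary_frame(level).to_string(float_format="%.5g")


# ----------------------------------------------------------------------
# functional wrappers
# ----------------------------------------------------------------------

def fit_model(x, y, kind: str = "monophasic", bounds=None, start=None) -> DoseResponseResults:
    """Fit a single dose-response model; see :class:`DoseResponseModel`."""
    return DoseResponseModel(x, y, kind=kind).fit(start=start, bounds=bounds)


def bootstrap_residual_fits(
    x, y, kind: str = "monophasic", n_boot: int = 1000, seed=None
) -> ResidualBootstrap:
    """Fit then residual-bootstrap in one call."""
    return fit_model(x, y, kind=kind).bootstrap(n_boot=n_boot, seed=seed)


def compare_models_aic(fits: list[DoseResponseResults]) -> pd.DataFrame:
    """AIC comparison table for fits of different models to the same data.

    Relative likelihood of model i is ``exp((AIC_min - AIC_i) / 2)``; the
    best model scores exactly 1.
    """
    if not fits:
        raise ValueError("no fits to compare")
    ref = fits[0]
    for f in fits[1:]:
        if not (np.array_equal(f.model.x, ref.model.x) and np.array_equal(f.y, ref.y)):
            raise ValueError("all fits must be on identical data")
    aics = np.array([f.aic for f in fits])
    amin = aics.min()
    rel = np.exp((amin - aics) / 2.0)
    return pd.DataFrame(
        {
            "kind": [f.kind for f in fits],
            "k": [f.k for f in fits],
            "rss": [f.rss for f in fits],
            "aic": aics,
            "delta_aic": aics - amin,
            "rel_likelihood": rel,
        }
    ).set_index("kind")


def compare_param_distributions(boot_a, boot_b) -> float:
    """Two-sided Wilcoxon rank-sum p-value between two bootstrap parameter arrays."""
    a = np.asarray(boot_a, dtype=float)
    b = np.asarray(boot_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty parameter distribution")
    return float(stats.ranksums(a, b).pvalue)
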