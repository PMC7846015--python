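"""Dose-response curve equations and log-dose encoding.

Three response models are used throughout the package, all on a log10-dose
axis ``x``:

* linear:      ``y = m*x + b``
* monophasic:  four-parameter logistic (Hill),
               ``y = (A - D) / (1 + 10**((C - x) * B)) + D``
* biphasic:    sum of two logistic transitions sharing a middle plateau,
               ``y = (A - D) / (1 + 10**((C - x) * B))
                   + (D - G) / (1 + 10**((F - x) * E)) + G``

``A`` is the top plateau, ``D`` the bottom (monophasic) or middle (biphasic)
plateau, ``G`` the biphasic bottom plateau.  ``B``/``E`` are Hill
coefficients (negative for responses that fall with dose) and ``C``/``F``
are EC50s expressed in log10 concentration units, so ``EC50 = 10**C``.

At ``x == C`` the monophasic curve is exactly ``(A + D) / 2`` — the
half-maximal-response definition of the EC50.

Evaluation is overflow-safe: the logistic terms are computed with
:func:`scipy.special.expit` so arbitrarily large ``|(C - x) * B|`` never
raises.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
from scipy.special import expit

__all__ = [
    "LinearParams",
    "HillParams",
    "BiphasicParams",
    "encode_log_dose",
    "eval_linear",
    "eval_monophasic",
    "eval_biphasic",
]

_LN10 = np.log(10.0)


@dataclass(frozen=True)
class LinearParams:
    """Slope/intercept pair for the linear model."""

    m: float
    b: float


@dataclass(frozen=True)
class HillParams:
    """Four-parameter logistic: top A, Hill coefficient B, log10-EC50 C, bottom D."""

    A: float
    B: float
    C: float
    D: float

    @property
    def ec50(self) -> float:
        """EC50 on the linear concentration scale (``10**C``)."""
        return float(10.0 ** self.C)


@dataclass(frozen=True)
class BiphasicParams:
    """Double logistic: plateaus A (top), D (middle), G (bottom).

    (B, C) are Hill coefficient and log10-EC50 of the first (low-dose)
    transition, (E, F) of the second.  Phase order C <= F is enforced at
    fit time, not here.
    """

    A: float
    B: float
    C: float
    D: float
    E: float
    F: float
    G: float

    @property
    def ec50_first(self) -> float:
        return float(10.0 ** self.C)

    @property
    def ec50_second(self) -> float:
        return float(10.0 ** self.F)


def _as_array(params) -> np.ndarray:
    if isinstance(params, (LinearParams, HillParams, BiphasicParams)):
        return np.array([getattr(params, f.name) for f in fields(params)], dtype=float)
    return np.asarray(params, dtype=float)


def encode_log_dose(doses, vehicle=None) -> np.ndarray:
    """Map micromolar doses to the log10-dose axis used for fitting.

    Treated doses become ``log10(dose)``.  Vehicle (DMSO) observations have
    no defined log dose, so they are coded two log10 units below the lowest
    treated dose — far enough below the dose range to sit on the top
    plateau without producing a log-of-zero.

    Parameters
    ----------
    doses : array-like of float
        Concentrations in uM.  A zero dose is treated as vehicle.
    vehicle : array-like of bool, optional
        Explicit vehicle flags.  Defaults to ``doses == 0``.

    Returns
    -------
    numpy.ndarray of float
    """
    doses = np.asarray(doses, dtype=float)
    if vehicle is None:
        vehicle = doses == 0
    vehicle = np.asarray(vehicle, dtype=bool)
    if vehicle.shape != doses.shape:
        raise ValueError("vehicle flags must match doses in shape")
    treated = doses[~vehicle]
    if treated.size == 0:
        raise ValueError("at least one non-vehicle dose is required")
    if np.any(treated <= 0):
        raise ValueError("treated doses must be strictly positive")
    x = np.empty_like(doses)
    x[~vehicle] = np.log10(treated)
    x[vehicle] = np.log10(treated.min()) - 2.0
    return x


def eval_linear(x, params) -> np.ndarray:
    """Evaluate ``y = m*x + b``."""
    m, b = _as_array(params)
    return m * np.asarray(x, dtype=float) + b


def eval_monophasic(x, params) -> np.ndarray:
    """Evaluate the four-parameter logistic at log10-dose ``x``."""
    A, B, C, D = _as_array(params)
    x = np.asarray(x, dtype=float)
    # (A-D)/(1 + 10**((C-x)*B)) == (A-D)*expit((x-C)*B*ln10)
    return D + (A - D) * expit((x - C) * B * _LN10)


def eval_biphasic(x, params) -> np.ndarray:
    """Evaluate the double-logistic (biphasic) curve at log10-dose ``x``."""
    A, B, C, D, E, F, G = _as_array(params)
    x = np.asarray(x, dtype=float)
    return (
        G
        + (D - G) * expit((x - F) * E * _LN10)
        + (A - D) * expit((x - C) * B * _LN10)
    )
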