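"""Closed-form integrated transients of the signal deviations.

IT, JT, KT are the running time integrals of i, j, k; they enter the
assembled population curves linearly.  Each closed form is paired with an
adaptive-quadrature oracle in the test suite.

The JT/KT forms are written in phase-amplitude style,

    JT(t) =  theta1 e^{r2 V0 t} cos(r3 V0 t - r4 V0 - theta2) - theta1 cos(r4 V0 + theta2)
    KT(t) = -theta1 e^{r2 V0 t} sin(r3 V0 t - r4 V0 - theta2) - theta1 sin(r4 V0 + theta2)

with theta1 = r1/sqrt(r2^2+r3^2) and theta2 = atan2(r3, r2).  This form is
continuous and cancellation-free at r2 = 0 (the denominator is the full
hypotenuse, never the growth rate alone), so no special-cased pure-trig
antiderivative is required in that limit.
"""

from __future__ import annotations

import math
from typing import Callable

import numpy as np
from scipy.integrate import quad

from .parameters import DegenerateParameterError

__all__ = [
    "transient_IT",
    "transient_JT",
    "transient_KT",
    "quadrature_oracle",
]


def transient_IT(
    t, A: float, zeta2: float, *, allow_zero_rate: bool = False
):
    """Integral of the IFN-gamma deviation: (A/zeta2)(1 - e^{-zeta2 t}).

    Monotone in t for A > 0 and saturates at A/zeta2.  With
    ``allow_zero_rate`` the zeta2 -> 0 limit ``A*t`` is returned instead of
    raising.
    """
    t = np.asarray(t, dtype=float)
    if zeta2 <= 0.0:
        if allow_zero_rate and zeta2 == 0.0:
            return A * t
        raise DegenerateParameterError(f"zeta2 must be positive, got {zeta2!r}")
    return (A / zeta2) * (1.0 - np.exp(-zeta2 * t))


def _theta_phase(theta1, theta2, r2, r3, r4, V0, t):
    osc_phase = r3 * V0 * t - r4 * V0 - theta2
    const_phase = r4 * V0 + theta2
    growth = np.exp(r2 * V0 * t)
    return osc_phase, const_phase, growth


def transient_JT(t, theta1: float, theta2: float, r2: float, r3: float, r4: float, V0: float):
    """Integral of j(s) = r1 V0 e^{r2 V0 s} cos(r3 V0 s - r4 V0) from 0 to t."""
    if r2 == 0.0 and r3 == 0.0:
        raise DegenerateParameterError("transient_JT requires r2^2 + r3^2 > 0")
    t = np.asarray(t, dtype=float)
    osc, const, growth = _theta_phase(theta1, theta2, r2, r3, r4, V0, t)
    return theta1 * growth * np.cos(osc) - theta1 * math.cos(const)


def transient_KT(t, theta1: float, theta2: float, r2: float, r3: float, r4: float, V0: float):
    """Integral of k(s) = -r1 V0 e^{r2 V0 s} sin(r3 V0 s - r4 V0) from 0 to t."""
    if r2 == 0.0 and r3 == 0.0:
        raise DegenerateParameterError("transient_KT requires r2^2 + r3^2 > 0")
    t = np.asarray(t, dtype=float)
    osc, const, growth = _theta_phase(theta1, theta2, r2, r3, r4, V0, t)
    return -theta1 * growth * np.sin(osc) - theta1 * math.sin(const)


def quadrature_oracle(
    f: Callable[[float], float], t: float, *, tol: float = 1e-10
) -> float:
    """Adaptive quadrature of ``f`` on [0, t] with error estimate <= tol.

    Diagnostic oracle for the closed-form transients; propagates a failure
    if the requested accuracy cannot be certified.
    """
    value, err = quad(f, 0.0, t, epsabs=tol * 1e-2, epsrel=tol * 1e-2, limit=400)
    if err > tol:
        raise RuntimeError(
            f"quadrature error estimate {err:.3e} exceeds tolerance {tol:.1e}"
        )
    return value
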