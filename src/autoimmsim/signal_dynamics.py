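"""Linearized signal dynamics: eigenanalysis and closed-form trajectories.

The signal deviations (i, j, k) obey a linear system x' = Phi x where Phi is
the Jacobian of the signal-interaction functions G1..G3 at the operating
point.  Because an increase in J or K does not feed back into IFN-gamma
production (G2i = G3i = 0), the spectrum splits into G1i plus the
eigenvalues of the lower-right 2x2 (j, k) block.  When that block takes the
rotation-plus-growth form with equal diagonal alpha and opposite
off-diagonal +/-beta, the eigenvalues are alpha +/- i*beta and the signals
oscillate with envelope R e^{alpha t}:

    i(t) =  A  e^{-zeta2 t}
    j(t) =  R  e^{alpha t} cos(beta t - delta)
    k(t) = -R  e^{alpha t} sin(beta t - delta)

with the dose-proportional parameters R = r1 V0, alpha = r2 V0,
beta = r3 V0, delta = r4 V0 and zeta2 = r6 V0.

Note on conventions: the matrix generating this (j, k) pair is
[[alpha, beta], [-beta, alpha]] (j' = alpha j + beta k,
k' = -beta j + alpha k).  The trajectory formulas are canonical here --
they feed the health model -- so the internal Jacobian convention follows
them, and :func:`classify_oscillation` accepts either sign arrangement of
the off-diagonal pair as exactly oscillatory.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy.integrate import solve_ivp

from .parameters import SplitParameters, DoseScaling, DegenerateParameterError

__all__ = [
    "JacobianPhi",
    "OscillatorySolution",
    "OscillationRegime",
    "EigenReport",
    "SolverFailure",
    "eigen_analysis",
    "classify_oscillation",
    "signal_trajectories",
    "oscillation_jacobian",
    "ode_oracle",
]


class SolverFailure(RuntimeError):
    """The numerical integrator failed to meet its tolerances."""


@dataclass(frozen=True)
class JacobianPhi:
    """Partials of the signal-interaction functions G1..G3 at the operating
    point (superscript V0 in the model: the linearization depends on dose).

    Assumed sign pattern: ``[[+,+,0],[0,+,-],[0,+,+]]`` -- IFN-gamma is
    self-amplifying and J-driven but K-blind; J and K mutually interact with
    J promoting both and K inhibiting J while promoting itself.
    """

    G1i: float
    G1j: float
    G1k: float
    G2i: float
    G2j: float
    G2k: float
    G3i: float
    G3j: float
    G3k: float

    def as_matrix(self) -> np.ndarray:
        return np.array(
            [
                [self.G1i, self.G1j, self.G1k],
                [self.G2i, self.G2j, self.G2k],
                [self.G3i, self.G3j, self.G3k],
            ]
        )

    def jk_block(self) -> np.ndarray:
        return np.array([[self.G2j, self.G2k], [self.G3j, self.G3k]])

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "JacobianPhi":
        return cls(**d)


@dataclass(frozen=True)
class OscillatorySolution:
    """Phase-amplitude description of the closed-form signal deviations."""

    A: float
    R: float
    alpha: float
    beta: float
    delta: float
    zeta2: float


class OscillationRegime(enum.Enum):
    OSCILLATORY_GROWING = "oscillatory_growing"
    OSCILLATORY_DAMPED = "oscillatory_damped"
    NON_OSCILLATORY = "non_oscillatory"


@dataclass(frozen=True)
class EigenReport:
    """Spectrum of Phi via the block-triangular shortcut."""

    lambda1: complex
    block_eigenvalues: tuple[complex, complex]

    @property
    def eigenvalues(self) -> tuple[complex, complex, complex]:
        return (self.lambda1,) + self.block_eigenvalues

    def to_dict(self) -> dict:
        return {
            "lambda1": [self.lambda1.real, self.lambda1.imag],
            "block": [[z.real, z.imag] for z in self.block_eigenvalues],
        }


def eigen_analysis(phi: JacobianPhi) -> EigenReport:
    """Eigenvalues of Phi.

    The i-column has zeros below G1i, so one eigenvalue is G1i exactly and
    the remaining two are the eigenvalues of the (j, k) block, computed from
    its characteristic polynomial lambda^2 - tr*lambda + det.
    """
    tr = phi.G2j + phi.G3k
    det = phi.G2j * phi.G3k - phi.G2k * phi.G3j
    disc = tr * tr - 4.0 * det
    if disc >= 0.0:
        root = math.sqrt(disc)
        pair = (complex((tr + root) / 2.0), complex((tr - root) / 2.0))
    else:
        root = math.sqrt(-disc)
        pair = (complex(tr / 2.0, root / 2.0), complex(tr / 2.0, -root / 2.0))
    return EigenReport(lambda1=complex(phi.G1i), block_eigenvalues=pair)


def classify_oscillation(
    block: np.ndarray, tol: float = 1e-9
) -> tuple[OscillationRegime, bool]:
    """Classify the (j, k) block by its discriminant and trace.

    Returns the regime together with an exact-condition flag: true when the
    block has equal diagonal entries and opposite off-diagonal entries
    (either sign arrangement) within ``tol``, i.e. eigenvalues are exactly
    alpha +/- i*beta.
    """
    block = np.asarray(block, dtype=float)
    a, b = block[0, 0], block[0, 1]
    c, d = block[1, 0], block[1, 1]
    tr = a + d
    det = a * d - b * c
    disc = tr * tr - 4.0 * det
    exact = abs(a - d) <= tol and abs(b + c) <= tol and abs(b) > tol
    if disc < 0.0:
        regime = (
            OscillationRegime.OSCILLATORY_GROWING
            if tr > 0.0
            else OscillationRegime.OSCILLATORY_DAMPED
        )
    else:
        regime = OscillationRegime.NON_OSCILLATORY
    return regime, exact


def closed_form_solution(
    sp: SplitParameters, ds: DoseScaling, *, H1i: float | None = None
) -> OscillatorySolution:
    """Bundle the per-dose phase-amplitude parameters for dose ``sp.V0``."""
    V0 = sp.V0
    if ds.A is not None:
        A = ds.A
    elif H1i is not None:
        A = ds.amplitude_A(V0, H1i)
    else:
        A = ds.r5 * V0  # bare magnitude if no coupling constant is supplied
    return OscillatorySolution(
        A=A,
        R=ds.R(V0),
        alpha=ds.alpha(V0),
        beta=ds.beta(V0),
        delta=ds.delta(V0),
        zeta2=ds.zeta2(V0),
    )


def signal_trajectories(
    t_grid: np.ndarray,
    sp: SplitParameters,
    ds: DoseScaling,
    *,
    H1i: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Closed-form deviations (i, j, k) on ``t_grid`` for dose ``sp.V0``.

    ``t_grid`` must be sorted and nonnegative.  At t = 0 the pair satisfies
    j(0) = R cos(delta), k(0) = R sin(delta); when the dose-scaling
    constants are calibrated to the split (r1 = sqrt(q1^2 + (1-p0)^2),
    r4 V0 = atan((1-p0)/q1)) these equal J0 and K0.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or (t.size and (np.any(np.diff(t) < 0) or t[0] < 0)):
        raise ValueError("t_grid must be a sorted, nonnegative 1-D array")
    sol = closed_form_solution(sp, ds, H1i=H1i)
    phase = sol.beta * t - sol.delta
    envelope = sol.R * np.exp(sol.alpha * t)
    i = sol.A * np.exp(-sol.zeta2 * t)
    j = envelope * np.cos(phase)
    k = -envelope * np.sin(phase)
    return i, j, k


def oscillation_jacobian(
    sp: SplitParameters, ds: DoseScaling
) -> np.ndarray:
    """3x3 generator of the closed-form solution at dose ``sp.V0``.

    The i-deviation decays at rate zeta2 and the (j, k) pair rotates and
    grows: [[-zeta2, 0, 0], [0, alpha, beta], [0, -beta, alpha]].
    """
    V0 = sp.V0
    a, b, z2 = ds.alpha(V0), ds.beta(V0), ds.zeta2(V0)
    return np.array([[-z2, 0.0, 0.0], [0.0, a, b], [0.0, -b, a]])


def ode_oracle(
    jacobian: np.ndarray,
    initial: np.ndarray,
    t_grid: np.ndarray,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> np.ndarray:
    """High-accuracy numerical solution of x' = M x (diagnostic oracle).

    Integrates with an 8th-order explicit Runge-Kutta scheme at tight
    tolerances; used in tests and diagnostics as an independent check of the
    closed forms, never as the production path.

    Returns an array of shape ``(len(t_grid), len(initial))``.
    """
    M = np.asarray(jacobian, dtype=float)
    y0 = np.asarray(initial, dtype=float)
    t = np.asarray(t_grid, dtype=float)
    if not np.all(np.isfinite(M)):
        raise ValueError("jacobian entries must be finite")
    if t.size == 0:
        return np.empty((0, y0.size))
    sol = solve_ivp(
        lambda _t, y: M @ y,
        (t[0], t[-1]) if t[-1] > t[0] else (t[0], t[0] + 1e-12),
        y0,
        t_eval=t,
        method="DOP853",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise SolverFailure(f"ODE oracle failed: {sol.message}")
    return sol.y.T
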