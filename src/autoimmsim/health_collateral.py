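"""Population curves: collateral damage, altered populations, and health.

Assembles C(t), M(t), N(t) from the integrated signal transients and forms
H(t) = T - C - M - N, implements the reduced closed forms for H and C,
decomposes health into monotone decay terms plus the oscillatory push-pull
term Delta(t), and runs dose sweeps summarizing how minimal health,
collateral extremes and health rebound vary with trigger dose.

The reduced health form is

    H(t) = T - Lambda V0 - r5 V0 (1 - e^{-r6 V0 t})
           - s1 e^{r2 V0 t} cos(r3 V0 t - r4 V0 - theta2 + theta3)
           + s1 cos(r4 V0 + theta2 - theta3)

with the consistent constant-phase convention (the sign of theta2 in the
constant term is the one forced by the assembled form; the historical
variant with cos(r4 V0 - theta2 - theta3) is available behind
``paper_literal=True`` and demonstrably breaks H(V0=0) = T).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .parameters import (
    SplitParameters,
    JacobianPsi,
    DoseScaling,
    ReducedConstants,
    derive_reduced_constants,
)
from .transients import transient_IT, transient_JT, transient_KT

__all__ = [
    "PopulationCurves",
    "DoseSummary",
    "assemble_populations",
    "health_reduced",
    "collateral_reduced",
    "pushpull_decomposition",
    "dose_sweep",
    "count_interior_extrema",
    "has_rebound",
]


@dataclass(frozen=True)
class PopulationCurves:
    """Time-indexed H, C, M, N trajectories for a single dose."""

    t: np.ndarray
    H: np.ndarray
    C: np.ndarray
    M: np.ndarray
    N: np.ndarray
    V0: float

    @property
    def total(self) -> np.ndarray:
        return self.H + self.C + self.M + self.N


@dataclass(frozen=True)
class DoseSummary:
    """Per-dose summary of a health/collateral simulation."""

    V0: float
    min_health_pct: float
    max_collateral: float
    min_collateral: float
    n_health_extrema: int
    rebound: bool


def _check_grid(t_grid: np.ndarray) -> np.ndarray:
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("t_grid must be a nonempty 1-D array")
    if t[0] < 0 or np.any(np.diff(t) < 0):
        raise ValueError("t_grid must be sorted and nonnegative")
    return t


def _transients(t, sp, ds, psi):
    V0 = sp.V0
    if V0 == 0.0:
        # zero dose: every deviation vanishes identically
        z = np.zeros_like(np.asarray(t, dtype=float))
        return z, z.copy(), z.copy()
    rr = math.hypot(ds.r2, ds.r3)
    theta1 = ds.r1 / rr
    theta2 = math.atan2(ds.r3, ds.r2)
    A = ds.amplitude_A(V0, psi.H1i)
    zeta2 = ds.zeta2(V0)
    IT = transient_IT(t, A, zeta2)
    JT = transient_JT(t, theta1, theta2, ds.r2, ds.r3, ds.r4, V0)
    KT = transient_KT(t, theta1, theta2, ds.r2, ds.r3, ds.r4, V0)
    return IT, JT, KT


def assemble_populations(
    t_grid: np.ndarray,
    sp: SplitParameters,
    psi: JacobianPsi,
    ds: DoseScaling,
    T: float,
) -> PopulationCurves:
    """Assemble C, M, N from the transients and form H = T - C - M - N.

    At t = 0 the transients vanish, giving C(0) = Lambda1 V0 and
    H(0) = T - Lambda V0 exactly.  H(0) < 0 (dose overwhelming the host) is
    reported in the curves, not raised: the linear model carries no
    positivity guarantee.
    """
    t = _check_grid(t_grid)
    V0 = sp.V0
    IT, JT, KT = _transients(t, sp, ds, psi)
    j_base = sp.q1 * V0
    k_base = (1.0 - sp.p0) * V0
    C = psi.H1i * IT + psi.H1j * (j_base + JT) + psi.H1k * (k_base + KT)
    M = sp.p2 * sp.p0 * V0 + psi.H2j * (j_base + JT) + psi.H2k * (k_base + KT)
    N = sp.p1 * sp.p0 * V0 + psi.H3j * (j_base + JT) + psi.H3k * (k_base + KT)
    H = T - C - M - N
    return PopulationCurves(t=t, H=H, C=C, M=M, N=N, V0=V0)


def health_reduced(
    t_grid: np.ndarray,
    sp: SplitParameters,
    ds: DoseScaling,
    constants: ReducedConstants,
    *,
    paper_literal: bool = False,
) -> np.ndarray:
    """Reduced closed-form health curve.

    Equals the assembled H pointwise (to ~1e-10 relative) when the
    IFN-gamma amplitude takes its default coupled value and the consistent
    theta3 convention is in force.  ``paper_literal=True`` switches the
    constant push-pull phase to the historical cos(r4 V0 - theta2 - theta3)
    variant, which breaks both the assembly identity and H(V0=0) = T; it is
    retained as a documented negative control.
    """
    t = _check_grid(t_grid)
    V0 = sp.V0
    c = constants
    osc_phase = ds.r3 * V0 * t - ds.r4 * V0 - c.theta2 + c.theta3
    if paper_literal:
        const_phase = ds.r4 * V0 - c.theta2 - c.theta3
    else:
        const_phase = ds.r4 * V0 + c.theta2 - c.theta3
    decay = ds.r5 * V0 * (1.0 - np.exp(-ds.r6 * V0 * t))
    return (
        c.T
        - c.lam * V0
        - decay
        - c.s1 * np.exp(ds.r2 * V0 * t) * np.cos(osc_phase)
        + c.s1 * math.cos(const_phase)
    )


def collateral_reduced(
    t_grid: np.ndarray,
    sp: SplitParameters,
    ds: DoseScaling,
    constants: ReducedConstants,
) -> np.ndarray:
    """Reduced closed-form collateral damage curve; C(0) = Lambda1 V0 exactly."""
    t = _check_grid(t_grid)
    V0 = sp.V0
    c = constants
    osc_phase = ds.r3 * V0 * t - ds.r4 * V0 - c.theta2 + c.phi
    const_phase = ds.r4 * V0 + c.theta2 - c.phi
    return (
        c.lam1 * V0
        + ds.r5 * V0 * (1.0 - np.exp(-ds.r6 * V0 * t))
        + c.s2 * np.exp(ds.r2 * V0 * t) * np.cos(osc_phase)
        - c.s2 * math.cos(const_phase)
    )


def pushpull_decomposition(
    t_grid: np.ndarray,
    sp: SplitParameters,
    ds: DoseScaling,
    constants: ReducedConstants,
) -> dict:
    """Split health into monotone decay terms and the oscillatory Delta(t).

    decay(t)  = -Lambda V0 - r5 V0 (1 - e^{-r6 V0 t})
    Delta(t)  = -s1 e^{r2 V0 t} cos(osc phase) + s1 cos(const phase)

    so that H = T + decay + Delta identically.  The out-of-phase gain
    ``gain(t) = s1 * (cos(const) - e^{r2 V0 t} cos(osc))`` equals Delta and
    quantifies the possible health rebound at each time: it approaches
    ~2 s1 e^{r2 V0 t} when the two cosines are out of phase by about pi.
    """
    t = _check_grid(t_grid)
    V0 = sp.V0
    c = constants
    osc_phase = ds.r3 * V0 * t - ds.r4 * V0 - c.theta2 + c.theta3
    const_phase = ds.r4 * V0 + c.theta2 - c.theta3
    decay = -c.lam * V0 - ds.r5 * V0 * (1.0 - np.exp(-ds.r6 * V0 * t))
    delta = -c.s1 * np.exp(ds.r2 * V0 * t) * np.cos(osc_phase) + c.s1 * math.cos(
        const_phase
    )
    xi = math.cos(const_phase) - np.exp(ds.r2 * V0 * t) * np.cos(osc_phase)
    return {"decay": decay, "delta": delta, "gain": c.s1 * xi}


def count_interior_extrema(y: np.ndarray, tol: float) -> int:
    """Count interior local extrema with a plateau-tolerant comparator.

    Differences with magnitude <= tol are treated as flat; a plateau
    between opposite-signed slopes counts as a single extremum.
    """
    d = np.diff(np.asarray(y, dtype=float))
    signs = np.where(d > tol, 1, np.where(d < -tol, -1, 0))
    signs = signs[signs != 0]
    if signs.size < 2:
        return 0
    return int(np.count_nonzero(np.diff(signs) != 0))


def has_rebound(H: np.ndarray, T: float, rebound_frac: float, tol: float) -> bool:
    """True when H has an interior local minimum followed by a rise > rebound_frac*T."""
    H = np.asarray(H, dtype=float)
    n = H.size
    if n < 3:
        return False
    d = np.diff(H)
    signs = np.where(d > tol, 1, np.where(d < -tol, -1, 0))
    falling = False
    for idx in range(n - 1):
        s = signs[idx]
        if s == -1:
            falling = True
        elif s == 1 and falling:
            # local minimum at ~idx; check the subsequent recovery height
            if np.max(H[idx:]) - H[idx] > rebound_frac * T:
                return True
            falling = False
    return False


def dose_sweep(
    V0_grid: np.ndarray,
    t_grid: np.ndarray,
    sp: SplitParameters,
    psi: JacobianPsi,
    ds: DoseScaling,
    T: float,
    *,
    rebound_frac: float = 0.01,
    window: tuple[float, float] | None = None,
) -> list[DoseSummary]:
    """Per-dose summaries of the assembled curves over a dose grid.

    ``min_health_pct`` is 100 * min_t H / T floored at 0 (the linear model
    can cross zero); collateral extremes are taken over the post-transient
    ``window`` (a (t_lo, t_hi) pair; default the full horizon);
    ``rebound`` marks a health local minimum followed by a recovery
    exceeding ``rebound_frac * T``.
    """
    V0_grid = np.atleast_1d(np.asarray(V0_grid, dtype=float))
    t = _check_grid(t_grid)
    if V0_grid.size == 0:
        raise ValueError("V0_grid must be nonempty")
    if window is None:
        mask = np.ones_like(t, dtype=bool)
    else:
        mask = (t >= window[0]) & (t <= window[1])
        if not mask.any():
            raise ValueError("post-transient window selects no grid points")
    tol = 1e-9 * T
    out: list[DoseSummary] = []
    for v in V0_grid:
        curves = assemble_populations(t, replace(sp, V0=float(v)), psi, ds, T)
        Cw = curves.C[mask]
        out.append(
            DoseSummary(
                V0=float(v),
                min_health_pct=max(0.0, 100.0 * float(np.min(curves.H)) / T),
                max_collateral=float(np.max(Cw)),
                min_collateral=float(np.min(Cw)),
                n_health_extrema=count_interior_extrema(curves.H, tol),
                rebound=has_rebound(curves.H, T, rebound_frac, tol),
            )
        )
    return out
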