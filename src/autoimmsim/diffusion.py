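"""Buffered 1-D reaction-diffusion model of trigger transport.

Free trigger ``u(t, x)`` diffuses along a one-dimensional host while being
reversibly bound into two cell populations with occupancy fractions
``C_M`` and ``C_N`` (capacities ``B_M``, ``B_N``, rates ``k+``/``k-``):

    u_t   = kM- C_M - kM+ (B_M - C_M) u + kN- C_N - kN+ (B_N - C_N) u + D0 u_xx
    C_M,t = -kM- C_M + kM+ (B_M - C_M) u + DM C_M,xx
    C_N,t = -kN- C_N + kN+ (B_N - C_N) u + DN C_N,xx

The composite field w = u + C_M + C_N obeys a pure transport equation, and
under the rapid-equilibrium (rapid buffering) approximation with u << K
(K = k-/k+), the whole system collapses to u_t = D_hat u_xx with the
effective diffusion constant

    D_hat = (D0 + DM*gamma_M + DN*gamma_N) / (1 + gamma_M + gamma_N),

gamma = B/K, a convex combination of the three diffusivities.  A
perturbation of the bound population (C_M -> C_M + eps) shifts D_hat; both
the exact and the first-order expressions for that shift are provided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, field

import numpy as np
from scipy.integrate import solve_ivp

from .parameters import ParameterError, DegenerateParameterError
from .signal_dynamics import SolverFailure

__all__ = [
    "DiffusionConfig",
    "DiffusionField",
    "PerturbedDiffusion",
    "equilibrium_fractions",
    "linear_fractions",
    "effective_diffusion_w",
    "reduced_constant",
    "perturbed_constant",
    "fundamental_solution",
    "simulate_full",
    "simulate_reduced",
]


@dataclass(frozen=True)
class DiffusionConfig:
    """Geometry, diffusivities, kinetics and boundary fluxes.

    ``B_M``/``B_N`` are the (dimensionless) binding capacities of the two
    populations; the dissociation constants are K = k-/k+ and the buffering
    strengths gamma = B/K.  ``flux_left``/``flux_right`` give the boundary
    flux -D u_x at x = 0 and x = L (zero-flux default).
    """

    L: float
    n_x: int
    D0: float
    DM: float
    DN: float
    kM_plus: float
    kM_minus: float
    kN_plus: float
    kN_minus: float
    B_M: float
    B_N: float
    flux_left: float = 0.0
    flux_right: float = 0.0

    def __post_init__(self) -> None:
        if self.L <= 0 or self.n_x < 3:
            raise ParameterError("need L > 0 and at least 3 grid points")
        for name in ("D0", "DM", "DN", "kM_plus", "kM_minus", "kN_plus", "kN_minus"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.B_M < 0 or self.B_N < 0:
            raise ParameterError("capacities B_M, B_N must be nonnegative")

    @property
    def K_M(self) -> float:
        return self.kM_minus / self.kM_plus

    @property
    def K_N(self) -> float:
        return self.kN_minus / self.kN_plus

    @property
    def gamma_M(self) -> float:
        return self.B_M / self.K_M

    @property
    def gamma_N(self) -> float:
        return self.B_N / self.K_N

    @property
    def lam(self) -> float:
        """Buffering factor 1 + gamma_M + gamma_N relating w = lam * u."""
        return 1.0 + self.gamma_M + self.gamma_N

    @property
    def d_hat(self) -> float:
        return reduced_constant(self.gamma_M, self.gamma_N, self.D0, self.DM, self.DN)

    @property
    def x_grid(self) -> np.ndarray:
        return np.linspace(0.0, self.L, self.n_x)

    @property
    def dx(self) -> float:
        return self.L / (self.n_x - 1)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DiffusionConfig":
        return cls(**d)


@dataclass(frozen=True)
class DiffusionField:
    """Spatial snapshot of the three fields plus the composite w."""

    x: np.ndarray
    u: np.ndarray
    C_M: np.ndarray
    C_N: np.ndarray
    t: float

    @property
    def w(self) -> np.ndarray:
        return self.u + self.C_M + self.C_N

    def mass_w(self) -> float:
        """Trapezoidal integral of w over the domain."""
        return float(np.trapezoid(self.w, self.x))


@dataclass(frozen=True)
class PerturbedDiffusion:
    """Exact and first-order shifted diffusion constants."""

    d_tilde: float
    delta_exact: float
    delta_first_order: float


def equilibrium_fractions(u, B_M: float, K_M: float, B_N: float, K_N: float):
    """Rapid-equilibrium bound fractions C = B u / (K + u), saturating at B."""
    u = np.asarray(u, dtype=float)
    if np.any(u < 0):
        raise ParameterError("free trigger concentration must be nonnegative")
    return B_M * u / (K_M + u), B_N * u / (K_N + u)


def linear_fractions(u, gamma_M: float, gamma_N: float):
    """Linear-buffering fractions C = gamma * u and composite w = (1+gM+gN) u.

    Valid for u << min(K_M, K_N); u is recoverable as w / (1+gM+gN).
    """
    u = np.asarray(u, dtype=float)
    C_M = gamma_M * u
    C_N = gamma_N * u
    return C_M, C_N, (1.0 + gamma_M + gamma_N) * u


def effective_diffusion_w(dCM_dw: float, dCN_dw: float, D0: float, DM: float, DN: float) -> float:
    """Composite-field diffusion coefficient D0 + (DM-D0) dCM/dw + (DN-D0) dCN/dw."""
    return D0 + (DM - D0) * dCM_dw + (DN - D0) * dCN_dw


def reduced_constant(gamma_M: float, gamma_N: float, D0: float, DM: float, DN: float) -> float:
    """Effective free-trigger diffusivity (D0 + DM gM + DN gN)/(1 + gM + gN).

    A convex combination: always between min and max of (D0, DM, DN).
    """
    lam = 1.0 + gamma_M + gamma_N
    return (D0 + DM * gamma_M + DN * gamma_N) / lam


def perturbed_constant(
    eps: float,
    d_hat: float,
    lam: float,
    D_N: float,
    K_N: float,
    *,
    paper_literal: bool = False,
) -> PerturbedDiffusion:
    """Shift of D_hat when the M-fraction is perturbed by eps.

    Increasing C_M reduces the N-side capacity (B_N -> B_N - eps), so with
    xi = 1/K_N the buffering factor drops to lam - eps*xi and

        D_tilde = (lam * D_hat - eps * xi * D_N) / (lam - eps * xi)
        dD_exact = D_hat - D_tilde = eps * xi * (D_N - D_hat) / (lam - eps*xi)
        dD_first = eps * xi * (D_N - D_hat) / lam

    Both shifts vanish at eps = 0 and when D_N = D_hat, and their gap is
    second order in eps.  ``paper_literal`` reproduces the historical
    first-order expression without the xi factor.
    """
    xi = 1.0 / K_N
    denom = lam - eps * xi
    if denom <= 0.0:
        raise DegenerateParameterError(
            f"perturbation too large: lam - eps/K_N = {denom!r} <= 0"
        )
    d_tilde = (lam * d_hat - eps * xi * D_N) / denom
    delta_exact = eps * xi * (D_N - d_hat) / denom
    if paper_literal:
        delta_first = eps * (D_N / lam) * (1.0 - d_hat / D_N)
    else:
        delta_first = eps * xi * (D_N - d_hat) / lam
    return PerturbedDiffusion(
        d_tilde=d_tilde, delta_exact=delta_exact, delta_first_order=delta_first
    )


def fundamental_solution(t, x, D: float):
    """Free-space heat kernel (4 pi D t)^{-1/2} exp(-x^2 / (4 D t))."""
    if D <= 0.0:
        raise ParameterError(f"D must be positive, got {D!r}")
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ParameterError("fundamental solution requires t > 0")
    x = np.asarray(x, dtype=float)
    out = np.exp(-(x * x) / (4.0 * D * t)) / np.sqrt(4.0 * math.pi * D * t)
    return float(out) if out.ndim == 0 else out


# ----------------------------------------------------------------------------
# method-of-lines solvers


def _laplacian(f: np.ndarray, dx: float, D: float, flux_left: float, flux_right: float) -> np.ndarray:
    """Second-order central Laplacian with ghost-node flux boundaries.

    The boundary condition -D f_x = J is imposed via mirrored ghost nodes:
    f[-1] = f[1] + 2 dx J_left / D and symmetrically on the right.
    """
    lap = np.empty_like(f)
    lap[1:-1] = f[2:] - 2.0 * f[1:-1] + f[:-2]
    ghost_l = f[1] + 2.0 * dx * flux_left / D
    ghost_r = f[-2] - 2.0 * dx * flux_right / D
    lap[0] = ghost_l - 2.0 * f[0] + f[1]
    lap[-1] = f[-2] - 2.0 * f[-1] + ghost_r
    return lap / (dx * dx)


def _check_solution(y: np.ndarray, what: str) -> None:
    if not np.all(np.isfinite(y)) or np.max(np.abs(y)) > 1e12:
        raise SolverFailure(f"{what} solution blew up (instability detected)")


def simulate_full(
    cfg: DiffusionConfig,
    u0: np.ndarray,
    t_eval: np.ndarray,
    *,
    CM0: np.ndarray | None = None,
    CN0: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-11,
) -> list[DiffusionField]:
    """Evolve the full three-field system; returns snapshots at ``t_eval``.

    Bound fractions default to their rapid-equilibrium profiles for the
    initial free-trigger profile.  Uses stiffness-switching LSODA on an
    interleaved state vector so the Jacobian is banded (bandwidth 3); with
    zero boundary flux the total integral of w is conserved.
    """
    x = cfg.x_grid
    n = cfg.n_x
    u0 = np.asarray(u0, dtype=float)
    if u0.shape != (n,):
        raise ParameterError(f"u0 must have shape ({n},)")
    if CM0 is None or CN0 is None:
        eqM, eqN = equilibrium_fractions(u0, cfg.B_M, cfg.K_M, cfg.B_N, cfg.K_N)
        CM0 = eqM if CM0 is None else np.asarray(CM0, dtype=float)
        CN0 = eqN if CN0 is None else np.asarray(CN0, dtype=float)

    t_eval = np.asarray(t_eval, dtype=float)
    y0 = np.empty(3 * n)
    y0[0::3], y0[1::3], y0[2::3] = u0, CM0, CN0
    dx = cfg.dx

    def rhs(_t, y):
        u = y[0::3]
        cm = y[1::3]
        cn = y[2::3]
        react_M = cfg.kM_minus * cm - cfg.kM_plus * (cfg.B_M - cm) * u
        react_N = cfg.kN_minus * cn - cfg.kN_plus * (cfg.B_N - cn) * u
        du = react_M + react_N + cfg.D0 * _laplacian(
            u, dx, cfg.D0, cfg.flux_left, cfg.flux_right
        )
        dcm = -react_M + cfg.DM * _laplacian(cm, dx, cfg.DM, 0.0, 0.0)
        dcn = -react_N + cfg.DN * _laplacian(cn, dx, cfg.DN, 0.0, 0.0)
        out = np.empty_like(y)
        out[0::3], out[1::3], out[2::3] = du, dcm, dcn
        return out

    sol = solve_ivp(
        rhs,
        (t_eval[0] if t_eval[0] < 0 else 0.0, t_eval[-1]),
        y0,
        t_eval=t_eval,
        method="LSODA",
        rtol=rtol,
        atol=atol,
        lband=3,
        uband=3,
    )
    if not sol.success:
        raise SolverFailure(f"full diffusion solver failed: {sol.message}")
    _check_solution(sol.y, "full diffusion")
    snapshots = []
    for idx, t in enumerate(sol.t):
        y = sol.y[:, idx]
        snapshots.append(
            DiffusionField(x=x, u=y[0::3].copy(), C_M=y[1::3].copy(), C_N=y[2::3].copy(), t=float(t))
        )
    return snapshots


def simulate_reduced(
    cfg: DiffusionConfig,
    u0: np.ndarray,
    t_eval: np.ndarray,
    *,
    D: float | None = None,
    rtol: float = 1e-9,
    atol: float = 1e-12,
) -> np.ndarray:
    """Constant-coefficient diffusion u_t = D u_xx with the same boundaries.

    ``D`` defaults to the effective constant D_hat from the config.
    Returns an array of shape ``(len(t_eval), n_x)``.
    """
    if D is None:
        D = cfg.d_hat
    if D <= 0.0:
        raise ParameterError(f"diffusion constant must be positive, got {D!r}")
    u0 = np.asarray(u0, dtype=float)
    if u0.shape != (cfg.n_x,):
        raise ParameterError(f"u0 must have shape ({cfg.n_x},)")
    t_eval = np.asarray(t_eval, dtype=float)
    dx = cfg.dx

    def rhs(_t, u):
        return D * _laplacian(u, dx, D, cfg.flux_left, cfg.flux_right)

    sol = solve_ivp(
        rhs,
        (0.0, t_eval[-1]),
        u0,
        t_eval=t_eval,
        method="LSODA",
        rtol=rtol,
        atol=atol,
        lband=1,
        uband=1,
    )
    if not sol.success:
        raise SolverFailure(f"reduced diffusion solver failed: {sol.message}")
    _check_solution(sol.y, "reduced diffusion")
    return sol.y.T
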