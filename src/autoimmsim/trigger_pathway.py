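"""Micro-level second-messenger trigger pathway.

An extracellular trigger T0 crosses a port into the cell, creating an
induced trigger T1; a fraction ``r`` of T1 stays free in the cytosol, a
fraction ``s`` of that binds a nuclear enzyme, and the resulting protein
drives a bounded change in expression of a fragility-related protein Q
(e.g. an MHC-1 pathway component).  Each stage is a tanh sigmoid switch
with its own gain and threshold, so the cascade output is bounded and
monotone in the trigger concentration.

The trigger also increments the fragility of an affected cell population:
a relative change eps in the underlying signal produces

    delta_T = mu (2 eps + eps^2) = mu ((1 + eps)^2 - 1)

which reduces to the first-order 2*mu*eps for small eps but grows
super-linearly (the "potentially explosive" response).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

from .parameters import ParameterError

__all__ = [
    "PathwayConfig",
    "FragilityParams",
    "PopulationPathwayParams",
    "fragility_delta",
    "sigmoid_switch",
    "port_activation",
    "enzyme_activation",
    "expression_change",
    "population_expression_change",
    "compose_pathway",
]


def _check_open_unit(name: str, value: float) -> None:
    if not (0.0 < value < 1.0):
        raise ParameterError(f"{name} must lie in (0, 1), got {value!r}")


def _check_positive(name: str, value: float) -> None:
    if value <= 0.0:
        raise ParameterError(f"{name} must be positive, got {value!r}")


@dataclass(frozen=True)
class PathwayConfig:
    """Gains, thresholds and fractions for the three-stage cascade.

    r : free fraction of the induced trigger T1, in (0, 1)
    s : fraction of free T1 binding the nuclear enzyme, in (0, 1)
    e : protein-creation efficiency (Michaelis-Menten-like), in (0, 1)
    g_p, g_e, g_Q : sigmoid gains (transition speed at threshold is 1/(2g))
    T0_base : port activation threshold concentration
    T1_nominal : nominal induced-trigger concentration
    delta_Q : maximal fractional change in Q expression, in (0, 1]
    Q_max : baseline maximal Q expression
    """

    r: float
    s: float
    e: float
    g_p: float
    g_e: float
    g_Q: float
    T0_base: float
    T1_nominal: float
    delta_Q: float
    Q_max: float

    def __post_init__(self) -> None:
        _check_open_unit("r", self.r)
        _check_open_unit("s", self.s)
        _check_open_unit("e", self.e)
        for name in ("g_p", "g_e", "g_Q", "T1_nominal", "Q_max"):
            _check_positive(name, getattr(self, name))
        if not (0.0 < self.delta_Q <= 1.0):
            raise ParameterError(f"delta_Q must lie in (0, 1], got {self.delta_Q!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PathwayConfig":
        return cls(**d)


@dataclass(frozen=True)
class FragilityParams:
    """Scale ``mu`` (either sign) and relative increment ``eps >= -1``."""

    mu: float
    eps: float

    def __post_init__(self) -> None:
        if self.eps < -1.0:
            raise ParameterError(f"eps must be >= -1, got {self.eps!r}")

    @property
    def delta(self) -> float:
        return fragility_delta(self.mu, self.eps)


@dataclass(frozen=True)
class PopulationPathwayParams:
    """Per-population expression-change parameters (M or N cells)."""

    e: float
    delta: float
    p_max: float
    g: float

    def __post_init__(self) -> None:
        _check_open_unit("e", self.e)
        _check_positive("g", self.g)
        _check_positive("p_max", self.p_max)
        if not (0.0 < self.delta <= 1.0):
            raise ParameterError(f"delta must lie in (0, 1], got {self.delta!r}")


def fragility_delta(mu, eps):
    """Fragility increment mu*(2 eps + eps^2); zero at eps = 0."""
    eps = np.asarray(eps, dtype=float)
    out = mu * (2.0 * eps + eps * eps)
    return float(out) if out.ndim == 0 else out


def sigmoid_switch(x, x0: float, g: float, scale: float = 1.0):
    """Sigmoid switch scale * 0.5 * (1 + tanh((x - x0)/g)).

    Output lies strictly in (0, scale); equals scale/2 at x = x0 with slope
    scale/(2g) there.
    """
    if g <= 0.0:
        raise ParameterError(f"sigmoid gain must be positive, got {g!r}")
    x = np.asarray(x, dtype=float)
    out = 0.5 * scale * (1.0 + np.tanh((x - x0) / g))
    return float(out) if out.ndim == 0 else out


def port_activation(T0_conc, cfg: PathwayConfig):
    """Port stage h_p in (0, r): fraction of T1 freed for a given [T0]."""
    return sigmoid_switch(T0_conc, cfg.T0_base, cfg.g_p, scale=cfg.r)


def enzyme_activation(x, cfg: PathwayConfig):
    """Enzyme stage h_e in (0, s); threshold at r*[T1]_n/2.

    ``x`` is the transported amount h_p([T0]) * [T1]_n, which ranges over
    (0, r*[T1]_n), so the half-maximum sits at the midpoint of that range.
    """
    x0 = cfg.r * cfg.T1_nominal / 2.0
    return sigmoid_switch(x, x0, cfg.g_e, scale=cfg.s)


def expression_change(P_conc, cfg: PathwayConfig):
    """Expression stage h_Q in (0, e*delta_Q*Q_max), half-maximal at P = 0.

    Translation proceeds at any protein level, so the switch point is 0 and
    the floor value h_Q(0) = (e/2) delta_Q Q_max is nonzero by design.
    """
    return sigmoid_switch(P_conc, 0.0, cfg.g_Q, scale=cfg.e * cfg.delta_Q * cfg.Q_max)


def population_expression_change(P_conc, params: PopulationPathwayParams):
    """Per-population variant h_M / h_N with its own (e, delta, max, gain)."""
    return sigmoid_switch(P_conc, 0.0, params.g, scale=params.e * params.delta * params.p_max)


def compose_pathway(
    T0_conc,
    cfg: PathwayConfig,
    *,
    subtract_baseline: bool = False,
    population: PopulationPathwayParams | None = None,
):
    """Full cascade: Delta Q_max = h_Q(h_e(h_p([T0]) [T1]_n) [T1]_n).

    Monotone nondecreasing in [T0] and bounded by e*delta_Q*Q_max (or the
    population-specific product when ``population`` is given).  With
    ``subtract_baseline`` the zero-stimulus floor h_Q(...(0)...) is removed
    so the reported change vanishes at [T0] = 0.
    """
    h_p = port_activation(T0_conc, cfg)
    h_e = enzyme_activation(h_p * cfg.T1_nominal, cfg)
    P = h_e * cfg.T1_nominal
    if population is None:
        dq = expression_change(P, cfg)
    else:
        dq = population_expression_change(P, population)
    if subtract_baseline:
        hp0 = port_activation(-np.inf, cfg)
        he0 = enzyme_activation(hp0 * cfg.T1_nominal, cfg)
        P0 = he0 * cfg.T1_nominal
        base = (
            expression_change(P0, cfg)
            if population is None
            else population_expression_change(P0, population)
        )
        dq = dq - base
    return dq
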