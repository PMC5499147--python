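"""Sign-pattern screen for autoimmune-capable signal pairs.

Given N candidate signals, an assay measures for every ordered pair
(p, q) the four relative sensitivities A1 = dj/j, A2 = dj/k, A3 = dk/j and
A4 = dk/k (treating signal p as "J" and signal q as "K").  A pair can
support undamped health oscillations when

    A1 > 0,   sign(A3) = -sign(A2),   sign(A1) = sign(A4),

the relaxed sign version of the exact rotation conditions
G2j = G3k, G3j = -G2k.  The screen also maps micro-level fragility
parameters (theta, eps) to the Jacobian block entries via
G ~ theta (2 eps + eps^2) and cross-checks the resulting oscillation
verdict against the eigenvalue classification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .trigger_pathway import fragility_delta
from .signal_dynamics import classify_oscillation, OscillationRegime

__all__ = [
    "ScreenMeasurement",
    "CandidatePair",
    "MicroGradientReport",
    "screen_pairs",
    "micro_gradient_map",
    "generate_screen_fixture",
]


@dataclass(frozen=True)
class ScreenMeasurement:
    """Pairwise sensitivity arrays; diagonals are undefined (NaN)."""

    A1: np.ndarray
    A2: np.ndarray
    A3: np.ndarray
    A4: np.ndarray

    def __post_init__(self) -> None:
        shapes = {np.asarray(a).shape for a in (self.A1, self.A2, self.A3, self.A4)}
        if len(shapes) != 1:
            raise ValueError(f"sensitivity arrays must share a shape, got {shapes}")
        shape = shapes.pop()
        if len(shape) != 2 or shape[0] != shape[1] or shape[0] < 2:
            raise ValueError(f"arrays must be square with n >= 2, got {shape}")

    @property
    def n_signals(self) -> int:
        return int(np.asarray(self.A1).shape[0])


@dataclass(frozen=True)
class CandidatePair:
    """Screen verdict for one ordered signal pair."""

    p: int
    q: int
    passes: bool
    reasons: dict = field(default_factory=dict)


@dataclass(frozen=True)
class MicroGradientReport:
    """Micro-parameter-built Jacobian block and its oscillation verdicts."""

    block: np.ndarray
    exact_growth_condition: bool     # G2j == G3k within tol
    exact_frequency_condition: bool  # G3j == -G2k within tol
    sign_verdict: bool               # relaxed: signs permit oscillation, G2j > 0
    regime: OscillationRegime


def _pair_conditions(a1: float, a2: float, a3: float, a4: float, zero_tol: float) -> dict:
    """Three screen conditions; values within zero_tol of 0 are indeterminate
    and conservatively fail."""

    def definite(v: float) -> bool:
        return abs(v) > zero_tol

    return {
        "undamped_A1_positive": a1 > zero_tol,
        "cross_signs_opposite": definite(a2) and definite(a3) and (a2 > 0) != (a3 > 0),
        "diagonal_signs_match": definite(a1) and definite(a4) and (a1 > 0) == (a4 > 0),
    }


def screen_pairs(m: ScreenMeasurement, zero_tol: float = 1e-12) -> list[CandidatePair]:
    """Evaluate every ordered pair p != q against the oscillation sign recipe.

    Output order is deterministic (row-major over ordered pairs).  Because
    the four sensitivities play asymmetric roles (which signal is "J"
    matters), both orientations of each unordered pair are screened and
    reported separately.
    """
    n = m.n_signals
    arrays = [np.asarray(a, dtype=float) for a in (m.A1, m.A2, m.A3, m.A4)]
    for a in arrays:
        off_diag = a[~np.eye(n, dtype=bool)]
        if not np.all(np.isfinite(off_diag)):
            raise ValueError("off-diagonal sensitivities must be finite")
    out: list[CandidatePair] = []
    for p in range(n):
        for q in range(n):
            if p == q:
                continue
            reasons = _pair_conditions(
                arrays[0][p, q], arrays[1][p, q], arrays[2][p, q], arrays[3][p, q], zero_tol
            )
            out.append(
                CandidatePair(p=p, q=q, passes=all(reasons.values()), reasons=reasons)
            )
    return out


def micro_gradient_map(
    theta_2j: float,
    theta_2k: float,
    theta_3j: float,
    theta_3k: float,
    eps_2j: float,
    eps_2k: float,
    eps_3j: float,
    eps_3k: float,
    tol: float = 1e-9,
) -> MicroGradientReport:
    """Build the (j, k) Jacobian block from micro fragility parameters.

    Each entry is G ~ theta (2 eps + eps^2).  Reports whether the exact
    rotation conditions hold within ``tol``, the relaxed sign verdict
    (opposite cross signs, matching diagonal signs, positive G2j for
    undamped growth), and the eigenvalue-based regime of the block.
    """
    g2j = fragility_delta(theta_2j, eps_2j)
    g2k = fragility_delta(theta_2k, eps_2k)
    g3j = fragility_delta(theta_3j, eps_3j)
    g3k = fragility_delta(theta_3k, eps_3k)
    block = np.array([[g2j, g2k], [g3j, g3k]])
    scale = max(abs(g2j), abs(g2k), abs(g3j), abs(g3k), 1.0)
    exact_growth = abs(g2j - g3k) <= tol * scale
    exact_freq = abs(g3j + g2k) <= tol * scale
    sign_verdict = (
        g2j > tol
        and abs(g3j) > tol
        and abs(g2k) > tol
        and (g3j > 0) != (g2k > 0)
        and abs(g3k) > tol
        and (g2j > 0) == (g3k > 0)
    )
    regime, _ = classify_oscillation(block, tol=tol)
    return MicroGradientReport(
        block=block,
        exact_growth_condition=exact_growth,
        exact_frequency_condition=exact_freq,
        sign_verdict=sign_verdict,
        regime=regime,
    )


def generate_screen_fixture(
    n_signals: int,
    planted_pairs: list[tuple[int, int]],
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> ScreenMeasurement:
    """Synthetic pairwise-sensitivity arrays with known passing pairs.

    Stands in for the proposed organoid-well assay: planted ordered pairs
    satisfy all three oscillation sign conditions before noise; every other
    pair is drawn to violate at least one of them.  Reproducible for a
    fixed seed.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    planted = set()
    for p, q in planted_pairs:
        if not (0 <= p < n_signals and 0 <= q < n_signals) or p == q:
            raise ValueError(f"invalid planted pair ({p}, {q}) for n={n_signals}")
        planted.add((p, q))

    shape = (n_signals, n_signals)
    A = [np.full(shape, np.nan) for _ in range(4)]

    def mag() -> float:
        return float(rng.uniform(0.5, 2.0))

    def coin() -> float:
        return 1.0 if rng.random() < 0.5 else -1.0

    for p in range(n_signals):
        for q in range(n_signals):
            if p == q:
                continue
            if (p, q) in planted:
                a1 = mag()
                a4 = mag()
                a2 = mag() * coin()
                a3 = -math.copysign(mag(), a2)
            else:
                # violate one condition at random; the rest may or may not hold
                mode = int(rng.integers(0, 3))
                if mode == 0:  # damped: A1 <= 0
                    a1 = -mag()
                    a4 = mag() * coin()
                    a2 = mag() * coin()
                    a3 = mag() * coin()
                elif mode == 1:  # cross signs equal
                    a1 = mag()
                    a4 = a1 * float(rng.uniform(0.5, 1.5))
                    a2 = mag() * coin()
                    a3 = math.copysign(mag(), a2)
                else:  # diagonal signs differ
                    a1 = mag()
                    a4 = -mag()
                    a2 = mag() * coin()
                    a3 = -math.copysign(mag(), a2)
            for arr, v in zip(A, (a1, a2, a3, a4)):
                arr[p, q] = v
    if noise_sd > 0:
        mask = ~np.eye(n_signals, dtype=bool)
        for arr in A:
            noise = rng.normal(0.0, noise_sd, size=shape)
            arr[mask] += noise[mask]
    return ScreenMeasurement(A1=A[0], A2=A[1], A3=A[2], A4=A[3])
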