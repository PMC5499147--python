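"""Model constants, initial conditions, and reduced-form constants.

A trigger dose ``V0`` (virus, bacterium, toxin) partitions a host cell
population of total size ``T`` into two altered populations ``M`` and ``N``
plus collateral-damage ``C`` and healthy ``H`` cells.  Three mediating
signals ``I`` (IFN-gamma), ``J`` and ``K`` drive the populations through a
sign-constrained Jacobian ``Psi`` of the population-response functions
H1..H3 evaluated at the pre-trigger operating point.

This module holds those constants, derives the initial state implied by the
dose split, derives the reduced constants (theta/phi phase angles, s1/s2
amplitudes, Lambda dose coefficients) shared by the closed-form health and
collateral curves, and validates the sign assumptions of the model.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict, replace
from typing import TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .signal_dynamics import JacobianPhi

__all__ = [
    "ParameterError",
    "DegenerateParameterError",
    "SplitParameters",
    "InitialState",
    "JacobianPsi",
    "DoseScaling",
    "ReducedConstants",
    "SignReport",
    "derive_initial_state",
    "derive_reduced_constants",
    "validate_sign_pattern",
    "PSI_SIGN_PATTERN",
    "PHI_SIGN_PATTERN",
]

#: relative tolerance for the p1 + p2 = 1 constraint
_P_SPLIT_RTOL = 1e-12


class ParameterError(ValueError):
    """A parameter violates its stated range or constraint."""


class DegenerateParameterError(ParameterError):
    """A required denominator or rate is zero where the formulas need it."""


def _check_fraction(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ParameterError(f"{name} must lie in [0, 1], got {value!r}")


@dataclass(frozen=True)
class SplitParameters:
    """Trigger dose and its partition into the cell populations.

    Parameters
    ----------
    V0 : float
        Initial trigger dose, nonnegative (abstract concentration units).
    p0 : float
        Fraction of the dose that enters cells, in [0, 1].  The remaining
        ``(1 - p0) V0`` stays free and sets the initial K-signal level.
    p1, p2 : float
        Split of the infected cells between population N (``p1``) and
        population M (``p2``); must satisfy p1 + p2 = 1.
    q1 : float
        Upregulation scaling: the initial J-signal level is ``q1 * V0``.
    """

    V0: float
    p0: float
    p1: float
    p2: float
    q1: float

    def __post_init__(self) -> None:
        if self.V0 < 0:
            raise ParameterError(f"V0 must be nonnegative, got {self.V0!r}")
        _check_fraction("p0", self.p0)
        _check_fraction("p1", self.p1)
        _check_fraction("p2", self.p2)
        if self.q1 <= 0:
            raise ParameterError(f"q1 must be positive, got {self.q1!r}")
        if abs(self.p1 + self.p2 - 1.0) > _P_SPLIT_RTOL:
            raise ParameterError(
                f"p1 + p2 must equal 1 (rel tol {_P_SPLIT_RTOL}); "
                f"got p1={self.p1!r}, p2={self.p2!r}"
            )

    def with_dose(self, V0: float) -> "SplitParameters":
        """Same split fractions at a different dose."""
        return replace(self, V0=V0)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SplitParameters":
        return cls(**d)


@dataclass(frozen=True)
class InitialState:
    """Cell counts and signal levels at the moment of triggering.

    C0 = 0 and I0 = 0 (no pre-existing collateral damage or IFN-gamma);
    M0 = p2*p0*V0, N0 = p1*p0*V0, J0 = q1*V0, K0 = (1-p0)*V0.
    """

    C0: float
    M0: float
    N0: float
    I0: float
    J0: float
    K0: float


@dataclass(frozen=True)
class JacobianPsi:
    """Partial derivatives of the population-response functions H1..H3.

    Entries are partials with respect to the signal deviations (i, j, k) at
    the operating point; ``H2i`` and ``H3i`` are identically zero (an
    IFN-gamma increase affects only collateral damage).  The assumed sign
    pattern is ``[[+,+,+],[0,-,+],[0,-,-]]``; use
    :func:`validate_sign_pattern` to check it (violations are reported, not
    raised, so that non-conforming regimes can still be explored).
    """

    H1i: float
    H1j: float
    H1k: float
    H2j: float
    H2k: float
    H3j: float
    H3k: float

    def as_matrix(self):
        import numpy as np

        return np.array(
            [
                [self.H1i, self.H1j, self.H1k],
                [0.0, self.H2j, self.H2k],
                [0.0, self.H3j, self.H3k],
            ]
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "JacobianPsi":
        return cls(**d)


@dataclass(frozen=True)
class DoseScaling:
    """Dose-proportionality constants for the oscillatory signal solution.

    Per dose ``V0`` the derived quantities are amplitude ``R = r1*V0``,
    growth rate ``alpha = r2*V0``, angular frequency ``beta = r3*V0``,
    phase ``delta = r4*V0``, IFN-gamma loss magnitude ``zeta1 = r5*V0`` and
    IFN-gamma decay rate ``zeta2 = r6*V0``.

    ``A`` optionally overrides the IFN-gamma deviation amplitude; when left
    ``None`` it defaults to ``r5*V0*zeta2 / H1i`` so that the integrated
    IFN-gamma term of the health model equals ``zeta1 (1 - e^{-zeta2 t})``
    exactly.
    """

    r1: float
    r2: float
    r3: float
    r4: float
    r5: float
    r6: float
    A: float | None = None

    def __post_init__(self) -> None:
        for name in ("r1", "r2", "r3", "r4", "r5", "r6"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be nonnegative")

    # per-dose derived values -------------------------------------------------
    def R(self, V0: float) -> float:
        return self.r1 * V0

    def alpha(self, V0: float) -> float:
        return self.r2 * V0

    def beta(self, V0: float) -> float:
        return self.r3 * V0

    def delta(self, V0: float) -> float:
        return self.r4 * V0

    def zeta1(self, V0: float) -> float:
        return self.r5 * V0

    def zeta2(self, V0: float) -> float:
        return self.r6 * V0

    def amplitude_A(self, V0: float, H1i: float) -> float:
        """IFN-gamma deviation amplitude; default couples to the health model."""
        if self.A is not None:
            return self.A
        if H1i == 0:
            raise DegenerateParameterError("default A requires H1i != 0")
        return self.r5 * V0 * self.zeta2(V0) / H1i

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DoseScaling":
        return cls(**d)


@dataclass(frozen=True)
class ReducedConstants:
    """Dose-independent constants entering the reduced closed forms.

    theta1 = r1 / sqrt(r2^2 + r3^2)        amplitude of the integrated transients
    theta2 = atan2(r3, r2)                 phase from the integration by parts
    theta3 = atan2(ck, cj)                 phase of the combined health cosine
    phi    = atan2(H1k, H1j)               phase of the collateral cosine
    cj, ck                                 column sums of Psi over j and k
    s1 = theta1 * sqrt(cj^2 + ck^2)        health oscillation amplitude
    s2 = theta1 * sqrt(H1j^2 + H1k^2)      collateral oscillation amplitude
    lam  = (p1+p2) p0 + cj q1 + ck (1-p0)  total initial-drop dose coefficient
    lam1 = H1j q1 + H1k (1-p0)             collateral initial dose coefficient

    The angle conventions are fixed so that cos(theta3) = cj / sqrt(cj^2+ck^2)
    (and analogously for phi); this is the unique convention under which the
    reduced health form equals the assembled one.
    """

    theta1: float
    theta2: float
    theta3: float
    phi: float
    s1: float
    s2: float
    cj: float
    ck: float
    lam: float
    lam1: float
    T: float


#: expected sign patterns ('+', '-', '0') for the two Jacobians
PSI_SIGN_PATTERN = (("+", "+", "+"), ("0", "-", "+"), ("0", "-", "-"))
PHI_SIGN_PATTERN = (("+", "+", "0"), ("0", "+", "-"), ("0", "+", "+"))

_PSI_ENTRY_NAMES = (
    ("H1i", "H1j", "H1k"),
    ("H2i", "H2j", "H2k"),
    ("H3i", "H3j", "H3k"),
)
_PHI_ENTRY_NAMES = (
    ("G1i", "G1j", "G1k"),
    ("G2i", "G2j", "G2k"),
    ("G3i", "G3j", "G3k"),
)


@dataclass(frozen=True)
class SignReport:
    """Per-entry pass/fail of the assumed sign patterns."""

    psi: dict = field(default_factory=dict)
    phi: dict = field(default_factory=dict)

    @property
    def all_pass(self) -> bool:
        return all(self.psi.values()) and all(self.phi.values())

    def violations(self) -> list[str]:
        out = [k for k, ok in self.psi.items() if not ok]
        out += [k for k, ok in self.phi.items() if not ok]
        return out


def _sign_ok(value: float, expected: str, zero_tol: float) -> bool:
    if expected == "0":
        return abs(value) <= zero_tol
    if expected == "+":
        return value > zero_tol
    return value < -zero_tol


def derive_initial_state(sp: SplitParameters) -> InitialState:
    """Initial cell counts and signal levels implied by the dose split.

    Homogeneous of degree 1 in ``V0``: doubling the dose doubles every
    nonzero field.
    """
    return InitialState(
        C0=0.0,
        M0=sp.p2 * sp.p0 * sp.V0,
        N0=sp.p1 * sp.p0 * sp.V0,
        I0=0.0,
        J0=sp.q1 * sp.V0,
        K0=(1.0 - sp.p0) * sp.V0,
    )


def derive_reduced_constants(
    sp: SplitParameters,
    psi: JacobianPsi,
    ds: DoseScaling,
    T: float,
) -> ReducedConstants:
    """Reduced constants shared by the health and collateral closed forms.

    Raises
    ------
    DegenerateParameterError
        If ``r2^2 + r3^2 = 0`` (no oscillation frequency scale), if
        ``cj = ck = 0`` (theta3 undefined), or if ``H1j = H1k = 0``
        (phi undefined).
    """
    rr = math.hypot(ds.r2, ds.r3)
    if rr == 0.0:
        raise DegenerateParameterError("theta1/theta2 require r2^2 + r3^2 > 0")
    theta1 = ds.r1 / rr
    theta2 = math.atan2(ds.r3, ds.r2)

    cj = psi.H1j + psi.H2j + psi.H3j
    ck = psi.H1k + psi.H2k + psi.H3k
    if cj == 0.0 and ck == 0.0:
        raise DegenerateParameterError("theta3 requires cj, ck not both zero")
    theta3 = math.atan2(ck, cj)

    if psi.H1j == 0.0 and psi.H1k == 0.0:
        raise DegenerateParameterError("phi requires H1j, H1k not both zero")
    phi = math.atan2(psi.H1k, psi.H1j)

    s1 = theta1 * math.hypot(cj, ck)
    s2 = theta1 * math.hypot(psi.H1j, psi.H1k)
    lam = (sp.p1 + sp.p2) * sp.p0 + cj * sp.q1 + ck * (1.0 - sp.p0)
    lam1 = psi.H1j * sp.q1 + psi.H1k * (1.0 - sp.p0)
    return ReducedConstants(
        theta1=theta1,
        theta2=theta2,
        theta3=theta3,
        phi=phi,
        s1=s1,
        s2=s2,
        cj=cj,
        ck=ck,
        lam=lam,
        lam1=lam1,
        T=T,
    )


def validate_sign_pattern(
    psi: JacobianPsi | None = None,
    phi: "JacobianPhi | None" = None,
    zero_tol: float = 0.0,
) -> SignReport:
    """Check Jacobian entries against the assumed sign patterns.

    Never raises on a violation; every entry is reported individually so a
    failing assumption (e.g. ``H2k < 0`` or a nonzero ``G1k``) can be
    localized.  Entries expected to be zero pass iff ``|value| <= zero_tol``.
    """
    psi_report: dict[str, bool] = {}
    phi_report: dict[str, bool] = {}
    if psi is not None:
        mat = psi.as_matrix()
        for r in range(3):
            for c in range(3):
                name = _PSI_ENTRY_NAMES[r][c]
                psi_report[name] = _sign_ok(
                    float(mat[r, c]), PSI_SIGN_PATTERN[r][c], zero_tol
                )
    if phi is not None:
        mat = phi.as_matrix()
        for r in range(3):
            for c in range(3):
                name = _PHI_ENTRY_NAMES[r][c]
                phi_report[name] = _sign_ok(
                    float(mat[r, c]), PHI_SIGN_PATTERN[r][c], zero_tol
                )
    return SignReport(psi=psi_report, phi=phi_report)


# ----------------------------------------------------------------------------
# structured-text (JSON) configuration round trip


def save_parameters(path, *, sp: SplitParameters, psi: JacobianPsi, ds: DoseScaling, T: float) -> None:
    """Serialize a full macro-model parameter set as JSON (lossless)."""
    payload = {
        "split": sp.to_dict(),
        "psi": psi.to_dict(),
        "dose_scaling": ds.to_dict(),
        "T": T,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def load_parameters(path) -> tuple[SplitParameters, JacobianPsi, DoseScaling, float]:
    with open(path) as fh:
        payload = json.load(fh)
    return (
        SplitParameters.from_dict(payload["split"]),
        JacobianPsi.from_dict(payload["psi"]),
        DoseScaling.from_dict(payload["dose_scaling"]),
        float(payload["T"]),
    )
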