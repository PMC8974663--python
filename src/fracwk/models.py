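"""Windkessel impedance models and dynamic-compliance elements.

Four lumped-parameter models of the aortic input impedance:

``FWK2``
    Fractional-order two-element Windkessel: peripheral resistance Rp in
    parallel with a fractional-order capacitor (constant-phase element)
    of pseudo-capacitance C_alpha and order alpha,

        Z(s) = Rp / (1 + Rp*C_alpha*s^alpha),   s = j*omega.

    alpha = 1 recovers the ideal-capacitor two-element model; smaller
    alpha blends in resistive (viscous) behavior, reflecting arterial
    wall viscoelasticity.

``WK2``
    Classical two-element Windkessel, Z = Rp/(1 + j*w*Rp*C).

``WK3``
    Three-element: characteristic impedance Zc in series with Rp || C.

``VWK``
    Viscoelastic Windkessel: Rp in parallel with a Voigt cell (series
    resistance Rd + capacitance C_vw), giving a complex frequency-
    dependent compliance.

All models reduce to a gain times a ratio of (at most one) zero over one
pole; ``TransferCoeffs`` carries that identifiable observational form.

Units: resistances mmHg*s/ml, capacitances ml/mmHg, pseudo-capacitance
ml/(mmHg*s^(1-alpha)), frequency rad/s.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

__all__ = [
    "FWK2Params",
    "WK2Params",
    "WK3Params",
    "VWKParams",
    "TransferCoeffs",
    "MODEL_TAGS",
    "impedance_fwk2",
    "impedance_classical",
    "model_impedance",
    "fwk2_modulus_phase",
    "foc_compliance",
    "voigt_compliance",
    "coeffs_from_params",
]

MODEL_TAGS = ("fwk2", "wk2", "wk3", "vwk")


def _require_positive(**kwargs):
    for name, v in kwargs.items():
        if not v > 0:
            raise ValueError(f"{name} must be > 0, got {v}")


@dataclass(frozen=True)
class FWK2Params:
    """Fractional two-element Windkessel parameters.

    Rp : peripheral resistance, mmHg*s/ml.
    C_alpha : pseudo-capacitance, ml/(mmHg*s^(1-alpha)).
    alpha : fractional differentiation order (>0; physiological range [0,1]).
    """

    Rp: float
    C_alpha: float
    alpha: float

    def __post_init__(self):
        _require_positive(Rp=self.Rp, C_alpha=self.C_alpha, alpha=self.alpha)

    @property
    def tau_alpha(self) -> float:
        """Fractional time constant Rp*C_alpha, units s^alpha."""
        return self.Rp * self.C_alpha


@dataclass(frozen=True)
class WK2Params:
    Rp: float
    C: float

    def __post_init__(self):
        _require_positive(Rp=self.Rp, C=self.C)


@dataclass(frozen=True)
class WK3Params:
    Zc: float
    Rp: float
    C: float

    def __post_init__(self):
        _require_positive(Zc=self.Zc, Rp=self.Rp, C=self.C)


@dataclass(frozen=True)
class VWKParams:
    Rp: float
    Rd: float
    C_vw: float

    def __post_init__(self):
        _require_positive(Rp=self.Rp, Rd=self.Rd, C_vw=self.C_vw)


ModelParams = Union[FWK2Params, WK2Params, WK3Params, VWKParams]


@dataclass(frozen=True)
class TransferCoeffs:
    """Identifiable observational form G*(1 + a1*s)/(1 + b1*s^alpha).

    form:
      - ``one_pole_fractional``: G/(1 + b1*s^alpha)      (FWK2; b1 = tau_alpha)
      - ``one_pole``:            G/(1 + b1*s)            (WK2;  b1 = Rp*C)
      - ``zero_pole``:           G*(1 + a1*s)/(1 + b1*s) (WK3, VWK)
    """

    G: float
    a1: float = 0.0
    b1: float = 0.0
    alpha: float = 1.0
    form: str = "one_pole"

    def __post_init__(self):
        if not self.G > 0:
            raise ValueError("gain G must be > 0")
        if self.a1 < 0 or self.b1 < 0:
            raise ValueError("coefficients must be >= 0")
        if self.form not in ("one_pole_fractional", "one_pole", "zero_pole"):
            raise ValueError(f"unknown transfer form {self.form!r}")

    def __call__(self, omega) -> np.ndarray:
        """Evaluate the transfer function at angular frequency(ies) >= 0."""
        omega = np.asarray(omega, dtype=float)
        if np.any(omega < 0):
            raise ValueError("negative frequency; use conjugate symmetry")
        if self.form == "one_pole_fractional":
            s_alpha = omega**self.alpha * np.exp(1j * self.alpha * np.pi / 2)
            out = self.G / (1.0 + self.b1 * s_alpha)
        else:
            s = 1j * omega
            out = self.G * (1.0 + self.a1 * s) / (1.0 + self.b1 * s)
        return out if out.ndim else complex(out)


def impedance_fwk2(p: FWK2Params, omega) -> complex | np.ndarray:
    """Fractional Windkessel input impedance Rp/(1 + Rp*C_alpha*(j*w)^alpha).

    ``(j*w)^alpha`` uses the principal branch ``w^alpha * exp(j*alpha*pi/2)``;
    at ``w = 0`` the impedance is exactly Rp for any alpha.
    """
    omega = np.asarray(omega, dtype=float)
    if np.any(omega < 0):
        raise ValueError("negative frequency; use conjugate symmetry")
    s_alpha = omega**p.alpha * np.exp(1j * p.alpha * np.pi / 2)
    out = p.Rp / (1.0 + p.Rp * p.C_alpha * s_alpha)
    return out if out.ndim else complex(out)


def impedance_classical(tag: str, params, omega) -> complex | np.ndarray:
    """Input impedance of a classical Windkessel variant.

    WK2: Rp/(1+j*w*Rp*C).  WK3: Zc + Rp/(1+j*w*Rp*C).
    VWK: Rp || (Rd + 1/(j*w*C_vw)); at w=0 the capacitor blocks and the
    result is Rp.
    """
    omega = np.asarray(omega, dtype=float)
    if np.any(omega < 0):
        raise ValueError("negative frequency; use conjugate symmetry")
    s = 1j * omega
    if tag == "wk2":
        out = params.Rp / (1.0 + s * params.Rp * params.C)
    elif tag == "wk3":
        out = params.Zc + params.Rp / (1.0 + s * params.Rp * params.C)
    elif tag == "vwk":
        # parallel reduction: Rp*(1 + s*Rd*C)/(1 + s*(Rp+Rd)*C)
        num = params.Rp * (1.0 + s * params.Rd * params.C_vw)
        den = 1.0 + s * (params.Rp + params.Rd) * params.C_vw
        out = num / den
    else:
        raise ValueError(f"unknown classical model tag {tag!r}")
    return out if out.ndim else complex(out)


def model_impedance(tag: str, params, omega):
    """Dispatch to the impedance function for any of the four models."""
    if tag == "fwk2":
        return impedance_fwk2(params, omega)
    return impedance_classical(tag, params, omega)


def fwk2_modulus_phase(G: float, tau_alpha: float, alpha: float, omega):
    """Closed-form modulus and phase of the fractional one-pole impedance.

        |Z| = G / sqrt((1 + w^a*tau*cos(a*pi/2))^2 + (w^a*tau*sin(a*pi/2))^2)
        arg Z = -atan2(w^a*tau*sin(a*pi/2), 1 + w^a*tau*cos(a*pi/2))

    For alpha in (0, 1] the phase lies in (-alpha*pi/2, 0].  The
    four-quadrant arctangent keeps the expression valid for alpha > 1,
    where the denominator can cross zero.
    """
    _require_positive(G=G, tau_alpha=tau_alpha, alpha=alpha)
    omega = np.asarray(omega, dtype=float)
    if np.any(omega < 0):
        raise ValueError("negative frequency")
    wa = omega**alpha * tau_alpha
    re = 1.0 + wa * np.cos(alpha * np.pi / 2)
    im = wa * np.sin(alpha * np.pi / 2)
    modulus = G / np.sqrt(re**2 + im**2)
    phase = -np.arctan2(im, re)
    if modulus.ndim:
        return modulus, phase
    return float(modulus), float(phase)


def foc_compliance(C_alpha: float, alpha: float, omega):
    """Equivalent complex capacitance of a fractional-order capacitor.

        C_F(w) = C_alpha * w^beta * [cos(beta*pi/2) + j*sin(beta*pi/2)],
        beta = alpha - 1.

    For alpha = 1 this is the real, frequency-independent C_alpha; for
    alpha < 1 the modulus decays as the power law w^(alpha-1), so w = 0
    is singular.
    """
    _require_positive(C_alpha=C_alpha, alpha=alpha)
    if alpha == 1.0:
        omega_arr = np.asarray(omega, dtype=float)
        out = np.full_like(omega_arr, C_alpha, dtype=complex)
        return out if out.ndim else complex(out)
    omega_arr = np.asarray(omega, dtype=float)
    if np.any(omega_arr <= 0):
        raise ValueError("omega must be > 0 for alpha != 1 (power-law singularity)")
    beta = alpha - 1.0
    out = C_alpha * omega_arr**beta * np.exp(1j * beta * np.pi / 2)
    return out if out.ndim else complex(out)


def voigt_compliance(C_vw: float, Rd: float, omega):
    """Complex compliance of a Voigt cell: C_vw / (1 + j*w*Rd*C_vw)."""
    _require_positive(C_vw=C_vw, Rd=Rd)
    omega = np.asarray(omega, dtype=float)
    out = C_vw / (1.0 + 1j * omega * Rd * C_vw)
    return out if out.ndim else complex(out)


def coeffs_from_params(tag: str, params: ModelParams) -> TransferCoeffs:
    """Observational coefficients (G, a1, b1, alpha) of a physical model."""
    if tag == "fwk2":
        return TransferCoeffs(
            G=params.Rp,
            b1=params.Rp * params.C_alpha,
            alpha=params.alpha,
            form="one_pole_fractional",
        )
    if tag == "wk2":
        return TransferCoeffs(G=params.Rp, b1=params.Rp * params.C, form="one_pole")
    if tag == "wk3":
        G = params.Zc + params.Rp
        b1 = params.Rp * params.C
        a1 = params.Zc * b1 / G
        return TransferCoeffs(G=G, a1=a1, b1=b1, form="zero_pole")
    if tag == "vwk":
        a1 = params.Rd * params.C_vw
        b1 = (params.Rp + params.Rd) * params.C_vw
        return TransferCoeffs(G=params.Rp, a1=a1, b1=b1, form="zero_pole")
    raise ValueError(f"unknown model tag {tag!r}")
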