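"""Harmonic-domain calibration of Windkessel models to impedance spectra.

The fitting contract follows the frequency-response identification recipe:

1.  The gain ``G`` is fixed to the DC impedance, ``G = Re Z[0] = P0/Q0``,
    and is never optimized.
2.  The remaining observational coefficients — ``(tau_alpha, alpha)`` for
    the fractional model, ``tau`` for the two-element model, ``(a1, b1)``
    for the zero-pole (three-element / viscoelastic) family — are found by
    bounded minimization of the normalized root-mean-square error

        NRMSE = sqrt( sum_{i=0..N} [ (Re Z_i - Re Zhat_i)^2
                                   + (Im Z_i - Im Zhat_i)^2 ] ) / ((N+1)*G)

    with positivity bounds (alpha unbounded above).  Note the divisor sits
    outside the radical: published magnitudes (~1e-2) depend on this, and
    an RMS-style sqrt-of-mean variant would differ by sqrt(N+1).
3.  Physical parameters are recovered from the optimal coefficients by the
    closed-form maps in :func:`params_from_coeffs`.

The goodness-of-fit suite comprises NRMSE, the per-harmonic moduli
deviation D_i [%] and its mean Deviation [%], and L2 relative errors of
moduli and phase [%].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .harmonics import ImpedanceSpectrum, _wrap_phase
from .models import MODEL_TAGS, TransferCoeffs, FWK2Params, WK2Params, WK3Params, VWKParams

__all__ = [
    "FitConfig",
    "FitResult",
    "MetricsReport",
    "NonPhysicalParameterError",
    "ConvergenceError",
    "compute_gain",
    "nrmse",
    "deviation_metrics",
    "relative_errors",
    "metrics_report",
    "fit_model",
    "params_from_coeffs",
]

#: Positivity lower bound used instead of exactly 0 to keep the pole stable.
_EPS = 1e-12


class NonPhysicalParameterError(ValueError):
    """Fitted coefficients violate a realizability inequality."""


class ConvergenceError(RuntimeError):
    """No optimizer start converged; carries the best iterate found."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


@dataclass(frozen=True)
class FitConfig:
    """Calibration settings.

    multistart counts deterministic starts (an alpha grid for the
    fractional model) plus seeded random perturbations beyond them.
    """

    N: int = 20
    multistart: int = 3
    seed: int = 0
    ftol: float = 1e-15
    gtol: float = 1e-12
    maxiter: int = 500
    unwrap_phase: bool = False
    phase_degrees: bool = False

    def __post_init__(self):
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.multistart < 1:
            raise ValueError("multistart must be >= 1")


@dataclass(frozen=True)
class MetricsReport:
    """The four scalar goodness-of-fit metrics for a (spectrum, model) pair."""

    nrmse: float
    re_moduli_pct: float
    re_phase_pct: float
    deviation_pct: float


@dataclass(frozen=True)
class FitResult:
    model: str
    coeffs: TransferCoeffs
    params: object
    metrics: MetricsReport
    D_pct: np.ndarray = field(repr=False)
    converged: bool = True
    n_starts: int = 1
    objective: float = float("nan")
    param_error: str | None = None

    def predicted(self, omegas) -> np.ndarray:
        """Model impedance at the given angular frequencies."""
        return self.coeffs(omegas)

    def to_dict(self) -> dict:
        d = {
            "model": self.model,
            "gain": self.coeffs.G,
            "a1": self.coeffs.a1,
            "b1": self.coeffs.b1,
            "alpha": self.coeffs.alpha,
            "form": self.coeffs.form,
            "nrmse": self.metrics.nrmse,
            "re_moduli_pct": self.metrics.re_moduli_pct,
            "re_phase_pct": self.metrics.re_phase_pct,
            "deviation_pct": self.metrics.deviation_pct,
            "converged": self.converged,
        }
        if self.params is not None:
            units = {
                "Rp": "mmHg*s/ml",
                "Zc": "mmHg*s/ml",
                "Rd": "mmHg*s/ml",
                "C": "ml/mmHg",
                "C_vw": "ml/mmHg",
                "C_alpha": "ml/(mmHg*s^(1-alpha))",
                "alpha": "dimensionless",
            }
            d["params"] = {
                k: {"value": v, "unit": units.get(k, "")}
                for k, v in vars(self.params).items()
            }
        if self.param_error:
            d["param_error"] = self.param_error
        return d

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def compute_gain(Z: ImpedanceSpectrum) -> float:
    """DC gain G = Re Z[0] (mean pressure over mean flow)."""
    G = float(Z.Z[0].real)
    if G <= 0:
        raise ValueError(f"non-positive DC impedance G={G}")
    return G


def nrmse(Z: ImpedanceSpectrum | np.ndarray, Zhat, G: float) -> float:
    """Gain-normalized root-sum-square complex residual over harmonics 0..N."""
    z = Z.Z if isinstance(Z, ImpedanceSpectrum) else np.asarray(Z, complex)
    zh = Zhat.Z if isinstance(Zhat, ImpedanceSpectrum) else np.asarray(Zhat, complex)
    if z.shape != zh.shape:
        raise ValueError("spectra have different harmonic counts")
    if not G > 0:
        raise ValueError("G must be > 0")
    resid = (z.real - zh.real) ** 2 + (z.imag - zh.imag) ** 2
    return float(np.sqrt(np.sum(resid)) / (len(z) * G))


def deviation_metrics(Z, Zhat) -> tuple[np.ndarray, float]:
    """Per-harmonic moduli deviation D_i [%] and its mean over i=0..N."""
    z = Z.Z if isinstance(Z, ImpedanceSpectrum) else np.asarray(Z, complex)
    zh = Zhat.Z if isinstance(Zhat, ImpedanceSpectrum) else np.asarray(Zhat, complex)
    mod = np.abs(z)
    if np.any(mod == 0):
        raise ValueError("zero impedance modulus at a retained harmonic")
    D = (np.abs(zh) - mod) / mod * 100.0
    return D, float(np.mean(D))


def relative_errors(Z, Zhat, unwrap: bool = False) -> tuple[float, float]:
    """L2 relative errors [%] of the moduli and of the phase vectors.

    Phases are wrapped principal values in radians unless ``unwrap`` is
    set, in which case ``numpy.unwrap`` is applied along the harmonic
    index before the norm.  An all-real reference spectrum has zero phase
    norm; the phase error is then reported as NaN (undefined) rather than
    raising.
    """
    z = Z.Z if isinstance(Z, ImpedanceSpectrum) else np.asarray(Z, complex)
    zh = Zhat.Z if isinstance(Zhat, ImpedanceSpectrum) else np.asarray(Zhat, complex)
    mod, modh = np.abs(z), np.abs(zh)
    denom = np.linalg.norm(mod)
    if denom == 0:
        raise ValueError("zero-norm moduli vector")
    re_mod = float(np.linalg.norm(mod - modh) / denom * 100.0)
    ph = _wrap_phase(np.angle(z))
    phh = _wrap_phase(np.angle(zh))
    if unwrap:
        ph, phh = np.unwrap(ph), np.unwrap(phh)
    ph_norm = np.linalg.norm(ph)
    if ph_norm == 0:
        return re_mod, float("nan")
    re_ph = float(np.linalg.norm(ph - phh) / ph_norm * 100.0)
    return re_mod, re_ph


def metrics_report(Z: ImpedanceSpectrum, Zhat, G: float, unwrap=False) -> MetricsReport:
    D, dev = deviation_metrics(Z, Zhat)
    re_mod, re_ph = relative_errors(Z, Zhat, unwrap=unwrap)
    return MetricsReport(
        nrmse=nrmse(Z, Zhat, G),
        re_moduli_pct=re_mod,
        re_phase_pct=re_ph,
        deviation_pct=dev,
    )


def params_from_coeffs(tag: str, coeffs: TransferCoeffs):
    """Physical parameters from optimal observational coefficients.

    FWK2: Rp=G, C_alpha=tau_alpha/G, alpha.  WK2: Rp=G, C=tau/G.
    WK3: Rp*C=b1, Zc=G*a1/b1, Rp=G-Zc, C=b1/Rp (needs a1 < b1).
    VWK: Rp=G, C_vw=(b1-a1)/G, Rd=a1/C_vw (needs b1 > a1).
    """
    G = coeffs.G
    if tag == "fwk2":
        return FWK2Params(Rp=G, C_alpha=coeffs.b1 / G, alpha=coeffs.alpha)
    if tag == "wk2":
        return WK2Params(Rp=G, C=coeffs.b1 / G)
    if tag == "wk3":
        if not coeffs.b1 > coeffs.a1:
            raise NonPhysicalParameterError(
                f"WK3 needs a1 < b1 (Zc < G); got a1={coeffs.a1}, b1={coeffs.b1}"
            )
        Zc = G * coeffs.a1 / coeffs.b1
        Rp = G - Zc
        return WK3Params(Zc=Zc, Rp=Rp, C=coeffs.b1 / Rp)
    if tag == "vwk":
        if not coeffs.b1 > coeffs.a1:
            raise NonPhysicalParameterError(
                f"VWK needs a1 < b1; got a1={coeffs.a1}, b1={coeffs.b1}"
            )
        C_vw = (coeffs.b1 - coeffs.a1) / G
        return VWKParams(Rp=G, Rd=coeffs.a1 / C_vw, C_vw=C_vw)
    raise ValueError(f"unknown model tag {tag!r}")


def _tau0_from_spectrum(Z: ImpedanceSpectrum, G: float) -> float:
    """Moment-match initial time constant from the first harmonic.

    For a one-pole model G/(1+j*w*tau): G/Z_1 = 1 + j*w0*tau, so
    tau = Im(G/Z_1)/w0.  Falls back to 1.0 s when non-positive.
    """
    if Z.N < 1 or Z.omega0 <= 0 or Z.Z[1] == 0:
        return 1.0
    tau = float(np.imag(G / Z.Z[1]) / Z.omega0)
    return tau if tau > 0 else 1.0


def _starts(tag: str, Z: ImpedanceSpectrum, G: float, cfg: FitConfig) -> list[np.ndarray]:
    tau0 = _tau0_from_spectrum(Z, G)
    if tag == "fwk2":
        base = [np.array([tau0, a0]) for a0 in (0.3, 0.5, 0.8)]
    elif tag == "wk2":
        base = [np.array([tau0]), np.array([1.0]), np.array([0.5 * tau0])]
    else:  # zero-pole family
        base = [
            np.array([0.05 * tau0, tau0]),
            np.array([0.1 * tau0, 1.5 * tau0]),
            np.array([0.01 * tau0, 0.7 * tau0]),
        ]
    starts = base[: max(cfg.multistart, 1)]
    if cfg.multistart > len(base):
        rng = np.random.default_rng(cfg.seed)
        for _ in range(cfg.multistart - len(base)):
            jitter = rng.lognormal(mean=0.0, sigma=0.5, size=base[0].size)
            starts.append(base[0] * jitter)
    return starts


def _coeffs_from_theta(tag: str, G: float, theta: np.ndarray) -> TransferCoeffs:
    if tag == "fwk2":
        return TransferCoeffs(G=G, b1=theta[0], alpha=theta[1], form="one_pole_fractional")
    if tag == "wk2":
        return TransferCoeffs(G=G, b1=theta[0], form="one_pole")
    return TransferCoeffs(G=G, a1=theta[0], b1=theta[1], form="zero_pole")


def fit_model(Z: ImpedanceSpectrum, tag: str, cfg: FitConfig | None = None) -> FitResult:
    """Calibrate one model to an empirical impedance spectrum.

    Runs a bounded local minimization of the NRMSE objective from each
    multistart point and keeps the best, then polishes with a
    derivative-free pass.  The gain is fixed to the DC impedance
    throughout.  Physical-parameter extraction failures (realizability
    violations in the zero-pole family) do not invalidate the fit; the
    result carries ``params=None`` and the error message.
    """
    if tag not in MODEL_TAGS:
        raise ValueError(f"unknown model tag {tag!r}; expected one of {MODEL_TAGS}")
    cfg = cfg or FitConfig()
    if Z.N != cfg.N:
        raise ValueError(f"spectrum has N={Z.N} but config expects N={cfg.N}")
    G = compute_gain(Z)
    omegas = Z.omegas
    z = Z.Z

    def objective(theta):
        if np.any(theta < _EPS):
            return 1e6 + float(np.sum(np.abs(np.minimum(theta - _EPS, 0))))
        coeffs = _coeffs_from_theta(tag, G, theta)
        return nrmse(z, coeffs(omegas), G)

    bounds = [( _EPS, None)] * (1 if tag == "wk2" else 2)
    best = None
    any_ok = False
    for x0 in _starts(tag, Z, G, cfg):
        res = optimize.minimize(
            objective,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": cfg.ftol, "gtol": cfg.gtol, "maxiter": cfg.maxiter},
        )
        any_ok = any_ok or res.success
        if best is None or res.fun < best.fun:
            best = res
    # derivative-free polish from the best iterate
    polish = optimize.minimize(
        objective,
        best.x,
        method="Nelder-Mead",
        options={"fatol": 1e-16, "xatol": 1e-14, "maxiter": 4000},
    )
    if polish.fun < best.fun:
        best = polish
        any_ok = any_ok or polish.success
    if not any_ok and not np.isfinite(best.fun):
        raise ConvergenceError("no start converged", best=best)

    coeffs = _coeffs_from_theta(tag, G, best.x)
    zhat = coeffs(omegas)
    metrics = metrics_report(Z, zhat, G, unwrap=cfg.unwrap_phase)
    D, _ = deviation_metrics(Z, zhat)
    params, perr = None, None
    try:
        params = params_from_coeffs(tag, coeffs)
    except NonPhysicalParameterError as e:
        perr = str(e)
    return FitResult(
        model=tag,
        coeffs=coeffs,
        params=params,
        metrics=metrics,
        D_pct=D,
        converged=any_ok,
        n_starts=cfg.multistart,
        objective=float(best.fun),
        param_error=perr,
    )
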