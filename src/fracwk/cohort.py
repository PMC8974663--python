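"""Virtual-subject generator: flow pulses and model-synthesized pressure.

Emulates the structure of an in-silico hemodynamic database built on a
3x3 grid of heart rates (53, 63, 72 beats/min) and stroke volumes
(66, 83, 100 ml), spanning cardiac outputs from about 3.5 to 7.2 l/min.
Flow is a stylized half-sine systolic ejection; pressure is synthesized
from flow through a chosen ground-truth impedance model harmonic by
harmonic (P_n = Z(j*n*w0) * Q_n), which is exact for periodic inputs —
no time-domain fractional integration is ever needed.

The generated waveforms emulate the grid structure and harmonic content
of the database, not the exact wave shapes of a 1-D arterial-network
solver (no reflected waves); parameter-recovery results on this cohort
therefore exercise the calibration machinery, not physiological realism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .waveform import Waveform, HemodynamicRecord
from .harmonics import HarmonicSeries, decompose, resynthesize, DEFAULT_N_HARMONICS
from .models import (
    MODEL_TAGS,
    FWK2Params,
    WK2Params,
    WK3Params,
    VWKParams,
    model_impedance,
)

__all__ = [
    "CohortSpec",
    "VirtualSubject",
    "generate_flow_pulse",
    "synthesize_pressure",
    "generate_cohort",
    "cohort_manifest",
]

DEFAULT_HR = (53.0, 63.0, 72.0)   # beats/min
DEFAULT_SV = (66.0, 83.0, 100.0)  # ml
DEFAULT_EJECTION_FRACTION = 0.33  # systolic ejection as a fraction of the cycle
DEFAULT_N_SAMPLES = 1024

# Ground-truth sampling ranges (uniform draws).  Rp spans typical total
# peripheral resistance; alpha spans the range reported for virtual
# subjects (printed estimates 0.33-0.52); C_alpha is set through the
# time constant tau_alpha = Rp*C_alpha in [0.5, 2] s.
DEFAULT_RANGES = {
    "Rp": (0.7, 1.5),        # mmHg*s/ml
    "alpha": (0.3, 0.6),
    "tau_alpha": (0.5, 2.0),  # s^alpha
    "Zc": (0.03, 0.09),       # mmHg*s/ml
    "Rd": (0.02, 0.08),       # mmHg*s/ml
}


@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic cohort.

    noise_sigma is the standard deviation of i.i.d. complex Gaussian
    perturbations added to each synthesized pressure harmonic, expressed
    as a fraction of the first pressure harmonic's modulus.
    """

    hr_set: tuple = DEFAULT_HR
    sv_set: tuple = DEFAULT_SV
    model: str = "fwk2"
    ranges: dict = field(default_factory=lambda: dict(DEFAULT_RANGES))
    n_harmonics: int = DEFAULT_N_HARMONICS
    n_samples: int = DEFAULT_N_SAMPLES
    ejection_fraction: float = DEFAULT_EJECTION_FRACTION
    noise_sigma: float = 0.0
    seed: int = 0
    subjects_per_cell: int = 1

    def __post_init__(self):
        if len(self.hr_set) == 0 or len(self.sv_set) == 0:
            raise ValueError("HR and SV sets must be non-empty")
        if any(h <= 0 for h in self.hr_set) or any(s <= 0 for s in self.sv_set):
            raise ValueError("HR and SV values must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.model not in MODEL_TAGS:
            raise ValueError(f"unknown ground-truth model {self.model!r}")

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        for k in ("hr_set", "sv_set"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass(frozen=True)
class VirtualSubject:
    record: HemodynamicRecord
    model: str
    params: object
    HR: float
    SV: float
    cell_id: str

    def true_impedance(self, omegas):
        return model_impedance(self.model, self.params, omegas)


def generate_flow_pulse(
    HR: float,
    SV: float,
    ejection_fraction: float = DEFAULT_EJECTION_FRACTION,
    n_samples: int = DEFAULT_N_SAMPLES,
) -> Waveform:
    """Half-sine systolic ejection pulse with exact analytic stroke volume.

    The pulse is ``q(t) = q_peak * sin(pi*t/d)`` for ``t < d`` (ejection
    duration ``d = ejection_fraction * T``) and zero in diastole;
    ``q_peak = SV*pi/(2*d)`` makes the continuous-time integral equal SV.
    """
    if not 0 < ejection_fraction < 1:
        raise ValueError("ejection fraction must lie in (0, 1)")
    if HR <= 0 or SV <= 0:
        raise ValueError("HR and SV must be positive")
    T = 60.0 / HR
    d = ejection_fraction * T
    t = np.arange(n_samples) * (T / n_samples)
    peak = SV * np.pi / (2.0 * d)
    y = np.where(t < d, peak * np.sin(np.pi * t / d), 0.0)
    return Waveform(t=t, y=y, T=T, unit="ml/s")


def synthesize_pressure(
    Qs: HarmonicSeries,
    tag: str,
    params,
    t: np.ndarray,
    noise_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
) -> Waveform:
    """Pressure waveform implied by a flow series and an impedance model.

    Each pressure harmonic is the model impedance at that harmonic times
    the flow harmonic, P(j*n*w0) = Z(j*n*w0)*Q(j*n*w0), for n = 0..N;
    the time-domain signal is the cosine-series reconstruction (periodic
    steady state, no transient).  Optional complex Gaussian noise is
    added to harmonics n >= 1 before reconstruction, with standard
    deviation ``noise_sigma * |P_1|``.
    """
    omega0 = Qs.omega0
    n = np.arange(1, Qs.N + 1)
    Zn = np.asarray(model_impedance(tag, params, n * omega0), dtype=complex)
    Z0 = complex(model_impedance(tag, params, 0.0))
    q_coeff = Qs.amp * np.exp(1j * Qs.phase)
    p_coeff = Zn * q_coeff
    p_mean = Z0.real * Qs.mean
    if noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng()
        scale = noise_sigma * np.abs(p_coeff[0]) if Qs.N >= 1 else noise_sigma
        noise = rng.normal(0.0, scale, size=p_coeff.shape) + 1j * rng.normal(
            0.0, scale, size=p_coeff.shape
        )
        p_coeff = p_coeff + noise
    Ps = HarmonicSeries(
        mean=p_mean,
        amp=np.abs(p_coeff),
        phase=np.where(np.abs(p_coeff) == 0, 0.0, np.angle(p_coeff)),
        omega0=omega0,
        N=Qs.N,
    )
    T = 2.0 * np.pi / omega0
    return Waveform(t=np.asarray(t, float), y=resynthesize(Ps, t), T=T, unit="mmHg")


def _draw_params(tag: str, ranges: dict, rng: np.random.Generator):
    u = lambda key: rng.uniform(*ranges[key])
    Rp = u("Rp")
    if tag == "fwk2":
        alpha = u("alpha")
        tau = u("tau_alpha")
        return FWK2Params(Rp=Rp, C_alpha=tau / Rp, alpha=alpha)
    tau = u("tau_alpha")
    C = tau / Rp
    if tag == "wk2":
        return WK2Params(Rp=Rp, C=C)
    if tag == "wk3":
        return WK3Params(Zc=u("Zc"), Rp=Rp, C=C)
    if tag == "vwk":
        return VWKParams(Rp=Rp, Rd=u("Rd"), C_vw=C)
    raise ValueError(tag)


def generate_cohort(spec: CohortSpec) -> list[VirtualSubject]:
    """Deterministic (seeded) synthetic cohort over the HR x SV grid."""
    rng = np.random.default_rng(spec.seed)
    subjects = []
    for hr in spec.hr_set:
        for sv in spec.sv_set:
            for k in range(spec.subjects_per_cell):
                flow = generate_flow_pulse(
                    hr, sv, spec.ejection_fraction, spec.n_samples
                )
                params = _draw_params(spec.model, spec.ranges, rng)
                Qs = decompose(flow, spec.n_harmonics)
                pressure = synthesize_pressure(
                    Qs,
                    spec.model,
                    params,
                    flow.t,
                    noise_sigma=spec.noise_sigma,
                    rng=rng,
                )
                cell = f"hr{hr:g}_sv{sv:g}"
                sid = f"{cell}_{k}"
                rec = HemodynamicRecord(
                    pressure=pressure, flow=flow, subject_id=sid
                )
                subjects.append(
                    VirtualSubject(
                        record=rec,
                        model=spec.model,
                        params=params,
                        HR=hr,
                        SV=sv,
                        cell_id=cell,
                    )
                )
    return subjects


def cohort_manifest(spec: CohortSpec, subjects: list[VirtualSubject]) -> pd.DataFrame:
    """Tabular manifest: subject_id, hr, sv, model, true params, noise, seed."""
    rows = []
    for s in subjects:
        rows.append(
            {
                "subject_id": s.record.subject_id,
                "hr": s.HR,
                "sv": s.SV,
                "model": s.model,
                "true_params_json": json.dumps(asdict(s.params)),
                "noise_sigma": spec.noise_sigma,
                "seed": spec.seed,
            }
        )
    return pd.DataFrame(rows)
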