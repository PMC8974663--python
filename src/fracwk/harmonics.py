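"""Fourier harmonic decomposition and empirical aortic input impedance.

A periodic signal sampled over one cardiac cycle is written as its mean
plus a cosine series,

    y(t) = y0 + sum_n  A_n * cos(n*w0*t + phi_n),       w0 = 2*pi/T,

and the aortic input impedance is formed harmonic by harmonic as the
complex ratio of the pressure and flow coefficients:

    Z[0] = P0/Q0,    Z[n] = (P_n/Q_n) * exp(j*(beta_n - theta_n)).

Phases are radians, wrapped to (-pi, pi].  The default harmonic count is
20, covering the frequency band of physiological interest (0 Hz to 20x
the heart rate).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .waveform import Waveform

__all__ = [
    "HarmonicSeries",
    "ImpedanceSpectrum",
    "DegenerateHarmonicError",
    "decompose",
    "resynthesize",
    "impedance_spectrum",
    "spectrum_to_frame",
]

DEFAULT_N_HARMONICS = 20

#: Flow harmonics with amplitude below this fraction of the largest flow
#: harmonic make the impedance ratio numerically meaningless.
AMPLITUDE_FLOOR = 1e-12


class DegenerateHarmonicError(ValueError):
    """A retained flow harmonic has (near-)zero amplitude."""

    def __init__(self, n: int):
        self.harmonic = n
        super().__init__(f"flow harmonic {n} has amplitude below the floor")


def _wrap_phase(phi):
    """Wrap angle(s) to the principal interval (-pi, pi]."""
    phi = np.asarray(phi, dtype=float)
    wrapped = np.angle(np.exp(1j * phi))
    # np.angle returns [-pi, pi); move -pi to +pi for the half-open convention
    wrapped = np.where(wrapped == -np.pi, np.pi, wrapped)
    return wrapped if wrapped.ndim else float(wrapped)


@dataclass(frozen=True)
class HarmonicSeries:
    """Cosine-series representation of one periodic signal.

    ``amp[k]`` and ``phase[k]`` are the amplitude and phase of harmonic
    ``k+1`` (the arrays exclude the mean, which is stored separately).
    """

    mean: float
    amp: np.ndarray
    phase: np.ndarray
    omega0: float
    N: int

    def __post_init__(self):
        amp = np.asarray(self.amp, dtype=float)
        phase = np.asarray(self.phase, dtype=float)
        object.__setattr__(self, "amp", amp)
        object.__setattr__(self, "phase", phase)
        if amp.shape != (self.N,) or phase.shape != (self.N,):
            raise ValueError("amp/phase must have shape (N,)")
        if np.any(amp < 0):
            raise ValueError("amplitudes must be non-negative")

    def coefficient(self, n: int) -> complex:
        """Complex coefficient A_n * exp(j*phi_n); n=0 returns the mean."""
        if n == 0:
            return complex(self.mean)
        return self.amp[n - 1] * np.exp(1j * self.phase[n - 1])

    @property
    def coefficients(self) -> np.ndarray:
        """Complex coefficients for harmonics 0..N (index 0 is the mean)."""
        c = np.empty(self.N + 1, dtype=complex)
        c[0] = self.mean
        c[1:] = self.amp * np.exp(1j * self.phase)
        return c


def decompose(w: Waveform, N: int = DEFAULT_N_HARMONICS) -> HarmonicSeries:
    """FFT cosine-series decomposition of one period.

    Scaled so a pure input ``A*cos(n*w0*t + phi)`` yields ``amp[n] = A`` and
    ``phase[n] = phi``.
    """
    n_samp = w.n_samples
    if N > (n_samp - 1) // 2:
        raise ValueError(
            f"N={N} exceeds Nyquist limit {(n_samp - 1) // 2} for "
            f"{n_samp} samples"
        )
    X = np.fft.rfft(w.y) / n_samp
    mean = float(X[0].real)
    coeff = 2.0 * X[1 : N + 1]
    amp = np.abs(coeff)
    phase = _wrap_phase(np.angle(coeff))
    # zero-amplitude harmonics carry an arbitrary phase; normalize to 0
    phase = np.where(amp == 0.0, 0.0, phase)
    return HarmonicSeries(mean=mean, amp=amp, phase=phase, omega0=w.omega0, N=N)


def resynthesize(h: HarmonicSeries, t: np.ndarray) -> np.ndarray:
    """Evaluate the cosine series on a time grid."""
    t = np.asarray(t, dtype=float)
    y = np.full_like(t, h.mean)
    for k in range(h.N):
        y += h.amp[k] * np.cos((k + 1) * h.omega0 * t + h.phase[k])
    return y


@dataclass(frozen=True)
class ImpedanceSpectrum:
    """Complex aortic input impedance at harmonics 0..N (mmHg*s/ml)."""

    Z: np.ndarray
    omega0: float
    N: int

    def __post_init__(self):
        Z = np.asarray(self.Z, dtype=complex)
        object.__setattr__(self, "Z", Z)
        if Z.shape != (self.N + 1,):
            raise ValueError("Z must have shape (N+1,)")

    @property
    def modulus(self) -> np.ndarray:
        return np.abs(self.Z)

    @property
    def phase(self) -> np.ndarray:
        """Phase angles in radians, wrapped to (-pi, pi]."""
        return _wrap_phase(np.angle(self.Z))

    @property
    def omegas(self) -> np.ndarray:
        """Angular frequencies n*w0 for n = 0..N."""
        return self.omega0 * np.arange(self.N + 1)


def impedance_spectrum(P: HarmonicSeries, Q: HarmonicSeries) -> ImpedanceSpectrum:
    """Empirical impedance spectrum from pressure and flow harmonic series.

    Raises
    ------
    DegenerateHarmonicError
        If any retained flow harmonic amplitude is below
        ``AMPLITUDE_FLOOR`` times the largest flow harmonic amplitude.
    """
    if P.N != Q.N:
        raise ValueError("pressure and flow series have different N")
    if not np.isclose(P.omega0, Q.omega0, rtol=1e-12):
        raise ValueError("pressure and flow series have different omega0")
    if Q.mean == 0.0:
        raise ValueError("flow mean is zero; Z(0) undefined")
    floor = AMPLITUDE_FLOOR * np.max(Q.amp) if Q.N > 0 else 0.0
    for n in range(1, Q.N + 1):
        if Q.amp[n - 1] <= floor:
            raise DegenerateHarmonicError(n)
    Z = np.empty(P.N + 1, dtype=complex)
    Z[0] = P.mean / Q.mean
    ratio = P.amp / Q.amp
    dphi = _wrap_phase(P.phase - Q.phase)
    Z[1:] = ratio * np.exp(1j * dphi)
    return ImpedanceSpectrum(Z=Z, omega0=P.omega0, N=P.N)


def spectrum_to_frame(spec: ImpedanceSpectrum) -> pd.DataFrame:
    """Tabulate a spectrum as `harmonic,freq_hz,modulus,phase_rad,real,imag`."""
    n = np.arange(spec.N + 1)
    return pd.DataFrame(
        {
            "harmonic": n,
            "freq_hz": n * spec.omega0 / (2 * np.pi),
            "modulus": spec.modulus,
            "phase_rad": spec.phase,
            "real": spec.Z.real,
            "imag": spec.Z.imag,
        }
    )
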