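"""Periodic hemodynamic waveforms: containers, CSV I/O, scalar features.

Pressure and flow are sampled on a uniform time grid covering exactly one
cardiac cycle, half-open ``[0, T)``: the sample at ``t = T`` is excluded so
that periodic means and integrals count each point once.  Internal units are
fixed: mmHg for pressure, ml/s for flow, seconds for time; cardiac output is
reported in l/min.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Waveform",
    "HemodynamicRecord",
    "WaveformFeatures",
    "GridError",
    "FormatError",
    "DataError",
    "read_record",
    "write_record",
    "extract_features",
]

CSV_COLUMNS = ("time_s", "pressure_mmHg", "flow_ml_s")

_GRID_RTOL = 1e-9


class GridError(ValueError):
    """Time grid is not uniform or not strictly increasing."""


class FormatError(ValueError):
    """File cannot be parsed as the expected CSV waveform dialect."""


class DataError(ValueError):
    """Samples are missing, non-numeric, or physiologically impossible."""


@dataclass(frozen=True)
class Waveform:
    """One period of a uniformly sampled periodic signal.

    Parameters
    ----------
    t : ndarray
        Time grid in seconds, ``t[0] = 0``, uniform spacing, covering
        ``[0, T)``.
    y : ndarray
        Samples (mmHg for pressure, ml/s for flow).
    T : float
        Heart period in seconds; ``dt = T / len(t)``.
    unit : str
        Unit label for ``y``.
    """

    t: np.ndarray
    y: np.ndarray
    T: float
    unit: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "y", y)
        if t.ndim != 1 or y.shape != t.shape:
            raise DataError("t and y must be 1-D arrays of equal length")
        if t.size < 2:
            raise DataError("waveform needs at least two samples")
        if np.any(np.isnan(y)):
            raise DataError("waveform contains NaN samples")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise GridError("time grid must be strictly increasing")
        expected = self.T / t.size
        if not np.allclose(dt, expected, rtol=_GRID_RTOL, atol=_GRID_RTOL * self.T):
            raise GridError(
                f"time grid not uniform with dt = T/n = {expected:.6g} s"
            )

    @property
    def n_samples(self) -> int:
        return self.t.size

    @property
    def dt(self) -> float:
        return self.T / self.t.size

    @property
    def omega0(self) -> float:
        """Fundamental angular frequency 2*pi/T in rad/s."""
        return 2.0 * np.pi / self.T


@dataclass(frozen=True)
class HemodynamicRecord:
    """Aortic pressure/flow pair for one subject over one cardiac cycle."""

    pressure: Waveform
    flow: Waveform
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.pressure.T != self.flow.T:
            raise DataError("pressure and flow periods differ")
        if not np.array_equal(self.pressure.t, self.flow.t):
            raise DataError("pressure and flow time grids differ")

    @property
    def T(self) -> float:
        return self.pressure.T


@dataclass(frozen=True)
class WaveformFeatures:
    """Scalar hemodynamic features of one record.

    SP/DP/PP/MBP in mmHg, SV in ml, HR in beats/min, CO in l/min.
    """

    SP: float
    DP: float
    PP: float
    MBP: float
    CO: float
    SV: float
    HR: float

    def to_dict(self) -> dict[str, float]:
        return {
            "SP": self.SP,
            "DP": self.DP,
            "PP": self.PP,
            "MBP": self.MBP,
            "CO": self.CO,
            "SV": self.SV,
            "HR": self.HR,
        }


def read_record(path, subject_id: str = "") -> HemodynamicRecord:
    """Read a one-cycle pressure/flow record from CSV.

    Expects a header row and columns ``time_s, pressure_mmHg, flow_ml_s``.
    The period is inferred as ``last t + dt`` (grid half-open at T).
    """
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError, UnicodeDecodeError) as e:
        raise FormatError(f"cannot parse CSV waveform file {path}: {e}") from e
    if df.shape[1] < 3:
        raise FormatError(
            f"expected >=3 columns (time, pressure, flow), got {df.shape[1]}"
        )
    cols = df.columns[:3]
    for c in cols:
        if not np.issubdtype(df[c].dtype, np.number):
            coerced = pd.to_numeric(df[c], errors="coerce")
            if coerced.isna().any():
                raise DataError(f"non-numeric values in column {c!r}")
            df[c] = coerced
    if df[list(cols)].isna().any().any():
        raise DataError("NaN samples in waveform file")
    t = df[cols[0]].to_numpy(dtype=float)
    if t.size < 2:
        raise DataError("need at least two samples")
    dt = np.diff(t)
    if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=_GRID_RTOL, atol=1e-12):
        raise GridError("non-uniform time grid in file")
    T = t[-1] + dt[0]
    pressure = Waveform(t=t, y=df[cols[1]].to_numpy(float), T=T, unit="mmHg")
    flow = Waveform(t=t, y=df[cols[2]].to_numpy(float), T=T, unit="ml/s")
    return HemodynamicRecord(pressure=pressure, flow=flow, subject_id=subject_id)


def write_record(record: HemodynamicRecord, path) -> None:
    """Write a record in the canonical CSV dialect (bit-stable for equal input)."""
    df = pd.DataFrame(
        {
            CSV_COLUMNS[0]: record.pressure.t,
            CSV_COLUMNS[1]: record.pressure.y,
            CSV_COLUMNS[2]: record.flow.y,
        }
    )
    df.to_csv(path, index=False, float_format="%.17g", lineterminator="\n")


def extract_features(record: HemodynamicRecord) -> WaveformFeatures:
    """Compute SP, DP, PP, MBP, SV, HR and CO from one cardiac cycle.

    MBP is the time average of pressure over the period; SV the integral of
    flow.  On the half-open periodic grid the trapezoid rule coincides with
    ``dt * sum(y)`` because the wrap-around endpoint appears once.
    """
    p = record.pressure.y
    q = record.flow.y
    if p.size == 0:
        raise DataError("empty waveform")
    T = record.T
    dt = record.pressure.dt
    sp = float(np.max(p))
    dp = float(np.min(p))
    mbp = float(np.mean(p))
    sv = float(dt * np.sum(q))  # periodic trapezoid rule
    hr = 60.0 / T
    co = sv * hr / 1000.0
    return WaveformFeatures(SP=sp, DP=dp, PP=sp - dp, MBP=mbp, CO=co, SV=sv, HR=hr)
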