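import numpy as np
import pytest

import fracwk as fw


@pytest.fixture
def flow_pulse():
    """Half-sine ejection, HR 60 / SV 100 / 33% systole, 1024 samples."""
    return fw.generate_flow_pulse(60.0, 100.0, 0.33, 1024)


@pytest.fixture
def fwk2_truth():
    return fw.FWK2Params(Rp=1.2, C_alpha=0.75, alpha=0.55)


@pytest.fixture
def fwk2_record(flow_pulse, fwk2_truth):
    """Record whose pressure is synthesized noiselessly from the FWK2 truth."""
    Qs = fw.decompose(flow_pulse, 20)
    pressure = fw.synthesize_pressure(Qs, "fwk2", fwk2_truth, flow_pulse.t)
    return fw.HemodynamicRecord(pressure=pressure, flow=flow_pulse, subject_id="fx")


def spectrum_from_model(tag, params, omega0=2 * np.pi, N=20):
    """True model spectrum at harmonics 0..N — the generator-side oracle."""
    from fracwk.harmonics import ImpedanceSpectrum
    from fracwk.models import model_impedance

    n = np.arange(N + 1)
    Z = np.asarray(model_impedance(tag, params, n * omega0), dtype=complex)
    return ImpedanceSpectrum(Z=Z, omega0=omega0, N=N)
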