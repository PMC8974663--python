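"""From waveforms to the empirical aortic input impedance spectrum.

Decomposes pressure and flow into 20 cosine harmonics and forms the
impedance harmonic by harmonic: Z[0] is mean pressure over mean flow
(the total peripheral resistance), moduli fall with frequency as the
compliant arterial tree shunts pulsatile flow, and phases are negative
(flow leads pressure) for a fractional-capacitor system.
"""

import fracwk as fw
from fracwk.harmonics import spectrum_to_frame

flow = fw.generate_flow_pulse(HR=72, SV=100)
truth = fw.FWK2Params(Rp=1.0, C_alpha=1.1, alpha=0.52)
Qs = fw.decompose(flow, 20)
pressure = fw.synthesize_pressure(Qs, "fwk2", truth, flow.t)
record = fw.HemodynamicRecord(pressure=pressure, flow=flow)

Z = fw.spectrum_from_record(record, N=20)
df = spectrum_to_frame(Z)
print(df.head(8).round(4).to_string(index=False))
print(f"\nZ[0] = {Z.Z[0].real:.4f} mmHg*s/ml = total peripheral resistance "
      f"(truth Rp = {truth.Rp}); high-harmonic phase tends to "
      f"-alpha*pi/2 = {-truth.alpha * 3.14159 / 2:.3f} rad.")
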