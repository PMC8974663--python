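# fracwk — fractional-order Windkessel models of aortic input impedance

`fracwk` is a Python library for calibrating lumped-parameter models of the
arterial tree to aortic pressure/flow data in the frequency domain. It is
aimed at cardiovascular modellers who want to quantify how well a
fractional-order Windkessel describes the aortic input impedance compared
with the classical integer-order variants, and at anyone who needs a fully
synthetic, seeded virtual cohort to exercise such a pipeline end to end.

## The models

The aortic input impedance is the harmonic-by-harmonic ratio of aortic
pressure to flow, `Z(jnω₀) = P(jnω₀)/Q(jnω₀)` with `ω₀ = 2π/T` the cardiac
fundamental. Four circuit analogues of the arterial tree are provided:

| tag   | structure | impedance |
|-------|-----------|-----------|
| `fwk2`| Rp ∥ fractional-order capacitor | `Z = Rp / (1 + Rp·Cα·(jω)^α)` |
| `wk2` | Rp ∥ ideal capacitor            | `Z = Rp / (1 + jω·Rp·C)` |
| `wk3` | Zc in series with Rp ∥ C        | `Z = Zc + Rp / (1 + jω·Rp·C)` |
| `vwk` | Rp ∥ Voigt cell (Rd + C)        | `Z = Rp(1 + jω·Rd·C) / (1 + jω(Rp+Rd)C)` |

The fractional-order capacitor (constant-phase element) has impedance
`1/(Cα·(jω)^α)`: its order `α ∈ (0, 1]` blends capacitive (elastic) and
resistive (viscous) behaviour, so `α < 1` expresses the viscoelasticity of
the arterial wall in a single parameter, while `α = 1` recovers the ideal
capacitor exactly. Its equivalent compliance is complex and
frequency-dependent, `C_F(ω) = Cα·ω^(α−1)·e^(j(α−1)π/2)`, a power law in
frequency; the Voigt cell's counterpart is `C_c(ω) = C_vw/(1 + jω·Rd·C_vw)`.

## Calibration

Each model is fitted through its identifiable transfer function
`G·(1 + a₁s)/(1 + b₁s^α)`. The gain is fixed to the DC impedance
`G = P₀/Q₀` (mean pressure over mean flow — the total peripheral
resistance) and never optimized; the remaining coefficients minimize the
gain-normalized complex residual

```
NRMSE = sqrt( Σᵢ₌₀ᴺ [ (Re Zᵢ − Re Ẑᵢ)² + (Im Zᵢ − Im Ẑᵢ)² ] ) / ((N+1)·G)
```

over harmonics 0..N (default N = 20) under positivity bounds, with the
order `α` unbounded above. Physical parameters are then recovered from the
optimal coefficients in closed form. Reported metrics: NRMSE, L2 relative
errors of moduli and phase (%), and the mean per-harmonic moduli deviation
(%). Note the NRMSE divisor sits outside the square root; an RMS-style
sqrt-of-mean definition would differ by √(N+1).

## Worked example

`python examples/fit_single_record.py` builds a half-sine flow pulse
(HR 63 beats/min, SV 83 ml), synthesizes pressure through a fractional
ground truth (Rp = 1.2, Cα = 0.75, α = 0.46), and calibrates all four
models:

```
subject: MBP=104.6 mmHg, CO=5.23 l/min, HR=63
model       NRMSE  Re_mod%   Re_ph%     Dev%
fwk2    3.766e-16    0.000    0.000   -0.000
wk2     2.892e-02   30.373  140.256  -50.395
wk3     1.335e-02    9.897   57.878   -3.427
vwk     1.335e-02    9.897   57.878   -3.427

fitted fractional order alpha = 0.4600 (truth 0.46)
```

The fractional model recovers its own truth to machine precision; the
ideal-capacitor model cannot represent the constant-phase behaviour and
pays for it in every metric; the three-element and viscoelastic models tie
exactly because they realize the same zero-pole transfer family. Other
examples: `virtual_cohort_benchmark.py` (heart-rate-group metric tables
over the 3×3 HR × SV grid), `dynamic_compliance.py` (compliance agreement
at the heart pulsation ω_h = 2π/T), `impedance_spectrum.py` (waveforms to
spectrum). The same flows are scriptable from a shell via the `fracwk`
CLI (`fracwk fit`, `fracwk simulate`, `fracwk benchmark`,
`fracwk compliance`).

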