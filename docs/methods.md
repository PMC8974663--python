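# Methods

## Scope and model family

`fracwk` treats the systemic arterial tree as a lumped electrical analogue
seen from the ascending aorta. The quantity being modelled is the aortic
input impedance: the complex ratio of pressure to flow at integer
multiples of the cardiac fundamental `ω₀ = 2π/T`. All analysis is
performed in the frequency domain under a periodic steady-state
assumption; no time-domain fractional differential equation is ever
integrated. This is exact for strictly periodic inputs, which is why the
package requires exactly one cardiac cycle per record (multi-beat
segmentation is out of scope).

The four models and their impedances are listed in the README. The
fractional two-element model replaces the ideal capacitor of the classical
two-element Windkessel with a constant-phase element, `Z_FOC =
1/(Cα·(jω)^α)`. `(jω)^α` is evaluated on the principal branch,
`ω^α·e^(jαπ/2)`; negative frequencies are never evaluated directly —
conjugate symmetry is applied at call sites. At `ω = 0` the element blocks
and every model's impedance is its total DC resistance, returned exactly
rather than through the power law.

## Data model and units

Waveforms are uniformly sampled on a half-open grid `[0, T)` with
`t[0] = 0`; the sample at `T` is excluded so periodic means and integrals
count each point once. Units are fixed internally: mmHg, ml/s, seconds;
resistances in mmHg·s/ml, compliances in ml/mmHg, pseudo-capacitance in
ml/(mmHg·s^(1−α)); cardiac output is reported in l/min. Where a
litre-based pseudo-capacitance is wanted at a reporting boundary, divide
by 1000; nothing internal depends on that convention.

Scalar features: SP/DP are the pressure extrema, MBP the time average,
SV the flow integral by the periodic trapezoid rule (identical to
`dt·Σq` on this grid), HR = 60/T, CO = SV·HR/1000.

## Harmonic analysis

Decomposition uses the FFT of the sampled cycle, rescaled to the cosine
convention `y(t) = y₀ + Σ Aₙ·cos(nω₀t + φₙ)` so that a pure cosine input
returns its own amplitude and phase. The default harmonic count is
N = 20, covering the band of physiological interest (up to 20× the heart
rate); N is configurable but bounded by Nyquist (`N ≤ (n_samples−1)/2`).
Phases are radians wrapped to (−π, π]; no unwrapping is applied by
default anywhere, including in the phase relative-error metric, because
wrapped principal values are the only convention that needs no extra rule.
An `unwrap` switch exists for sensitivity checks.

The empirical spectrum is `Z[0] = P₀/Q₀` and
`Z[n] = (Pₙ/Qₙ)·e^(j(βₙ−Θₙ))`. A retained flow harmonic with amplitude
below `1e−12 ×` the largest flow harmonic raises a degenerate-harmonic
error naming the harmonic, rather than silently dividing by a vanishing
number.

## Calibration

Fitting operates on the identifiable observational form — gain times a
ratio of at most one zero over one pole — rather than on physical
parameters, which keeps the estimation problem structurally identifiable:

- fractional one-pole: `G/(1 + τ_α·s^α)`, free θ = (τ_α, α);
- one-pole: `G/(1 + τ·s)`, free θ = (τ);
- zero-pole: `G(1 + a₁s)/(1 + b₁s)`, free θ = (a₁, b₁), shared by the
  three-element and viscoelastic models.

The gain is pinned to the measured DC impedance `G = Re Z[0]` and never
optimized. The objective is the literal NRMSE of the README — a single
code path (`fracwk.calibration.nrmse`) serves both fitting and reporting,
so the reported objective is exactly the minimized one.

Optimization: bounded L-BFGS-B from each multistart point, followed by a
Nelder-Mead polish of the best iterate (ftol 1e−15, gtol 1e−12; polish
fatol 1e−16). The lower bound on every coefficient is 1e−12 rather than
exactly 0 — a zero time constant is a degenerate pole and the tiny epsilon
keeps the objective smooth — and α has no upper bound. Deterministic
starts: τ₀ from a one-pole moment match on the first harmonic
(`τ₀ = Im(G/Z₁)/ω₀`, falling back to 1 s if non-positive), with
α₀ ∈ {0.3, 0.5, 0.8} for the fractional model; multistarts beyond the
deterministic grid are seeded lognormal jitters of the first start. The
contract is on the result (best multistart objective), not the algorithm.

Physical parameters are recovered in closed form:

- fractional: Rp = G, Cα = τ_α/G, α = α̂;
- two-element: Rp = G, C = τ/G;
- three-element: Zc = G·a₁/b₁, Rp = G − Zc, C = b₁/Rp (requires a₁ < b₁);
- viscoelastic: Rp = G, C_vw = (b₁ − a₁)/G, Rd = a₁/C_vw (requires a₁ < b₁).

A violated realizability inequality flags the extraction but keeps the
fit: the coefficients and metrics remain valid as a data-driven
description even when no positive-element circuit realizes them.

Metric conventions that were genuinely open and the choices made:

- The per-harmonic moduli deviation is averaged over i = 0..N with
  divisor N+1. Because G is pinned to Z[0], D₀ = 0 identically, so the
  alternative i = 1..N reading differs only by the divisor.
- The phase relative error uses wrapped phases in radians; degrees and
  unwrapping are available as switches but are off by default.
- An all-real reference spectrum has zero phase norm; the phase relative
  error is then NaN (undefined sentinel), not an exception.
- The closed-form fractional phase uses the four-quadrant arctangent of
  (numerator, denominator), which stays correct if α > 1 drives the
  denominator through zero.

## Synthetic cohort

The generator emulates the *structure* of an in-silico virtual-subject
database: a 3 × 3 grid of heart rates (53, 63, 72 beats/min) and stroke
volumes (66, 83, 100 ml), giving cardiac outputs from ≈3.5 to 7.2 l/min.
Flow is a half-sine systolic ejection occupying 33 % of the cycle with the
peak scaled so the analytic integral equals SV exactly; pressure is
synthesized harmonic by harmonic through a ground-truth model,
`P(jnω₀) = Z(jnω₀)·Q(jnω₀)`, and reconstructed as a cosine series —
exact for periodic signals, so noiseless cohorts are recoverable to
machine precision by construction. Optional noise adds i.i.d. complex
Gaussians to the synthesized pressure harmonics, scaled by the first
pressure harmonic's modulus. Because flow harmonics decay with frequency,
pressure-harmonic noise maps to impedance noise that grows toward high
harmonics — deliberately harsher than spectrum-level noise of the same
nominal level.

Default ground-truth sampling ranges (uniform): Rp ∈ [0.7, 1.5] mmHg·s/ml,
α ∈ [0.3, 0.6] (spanning reported virtual-subject estimates 0.33–0.52),
τ_α = Rp·Cα ∈ [0.5, 2] s, Zc ∈ [0.03, 0.09], Rd ∈ [0.02, 0.08] mmHg·s/ml.
Waveforms use 1024 samples per cycle.

What the generator does **not** emulate: reflected waves and the rich
morphology of 1-D arterial-network solutions, inter-feature correlations
of a physiological population, and measurement noise in the time domain.
Passing tests on this cohort therefore demonstrate the correctness of the
analysis/calibration machinery, not the models' fidelity to real aortic
data; metric magnitudes on real or 1-D-simulated databases will differ.

## Problem sizes

The test suite and the acceptance script size their simulations for
desk-scale reproducibility: 1000 random draws for algebraic-identity
checks, a 27-point noiseless recovery grid, 100 replicates for the noisy
α-recovery study (noise applied at spectrum level, σ = 2 % of |Z₁|, with
Z[0] kept exact since the DC gain comes from means that are far more
robust than individual harmonics), and cohorts of 9–18 subjects.

## Known limitations

- One exact period per record; no beat detection, resampling, or
  denoising.
- Phase metrics are sensitive to wrapping when true phases approach ±π;
  the default keeps principal values.
- No uncertainty quantification on fitted parameters; the multistart
  local optimizer carries no global-optimality guarantee, though the
  identifiable forms are low-dimensional and well-behaved in practice.
- The viscoelastic and three-element models are deliberately reported as
  separate columns even though their fits coincide; equality is asserted
  in tests, not assumed.
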