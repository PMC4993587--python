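# Methods

## Scope and model

kvflux quantifies three linked readouts of cerebral-artery smooth-muscle
physiology: (i) the number of functional voltage-gated K⁺ (KV) channels per
myocyte, inferred from whole-cell currents through the
Goldman–Hodgkin–Katz (GHK) constant-field framework; (ii) the voltage
dependence and kinetics of the underlying conductance (Boltzmann activation,
mono-exponential time constants); and (iii) downstream vascular function
(pressure-induced myogenic tone, laser-Doppler CBF responses, evoked-field
N1 amplitude).

### Channel counting

The chain is

    P_K = γ / [K⁺] · RT/F²                      (permeability from conductance)
    i(V) = P_K F u/(1−e⁻ᵘ) ([K⁺]ᵢ − [K⁺]ₒ e⁻ᵘ)   (GHK flux, u = zVF/RT)
    N = I / (i(V_ref) · P_o(V_ref))              (macroscopic amplitude)

with all internal computation in SI and concentrations in mol/cm³, so P_K
carries the dimension cm³/s (a per-channel volume flux). The literature
often labels this quantity "cm/s" — a per-area convention; we keep that
label as a display alias only, because only the volume-flux reading makes
the flux equation return amperes. Signs follow whole-cell practice: membrane
potential is inside-minus-outside and outward K⁺ flux is positive, so the
current is zero exactly at the Nernst potential and positive above it.

Assumptions: one permeant ion (K⁺) and a constant field across the pore; a
voltage-independent single-channel γ (measured in symmetric 140 mM K⁺,
inside-out patches); P_o known at the reference voltage only. The default
reference is the −40 mV tail voltage with P_o = 0.014 at 23 °C.

**Choice of macroscopic amplitude.** N is meaningful only if I and P_o refer
to the same voltage and the same (steady-state) gating condition. The
instantaneous tail peak reflects the activation reached during the preceding
step — using it with P_o(−40 mV) would overestimate N roughly 70-fold under
the default gating. We therefore use the *steady-state* current at the tail
voltage, estimated as the offset C of the per-sweep tail fit
I(t) = A e^(−t/τ) + C and pooled across sweeps by the median. The fit-based
estimate avoids the truncation bias a window mean would suffer when the tail
is only a few deactivation time constants long.

### Voltage-clamp analysis

* **Current density**: mean current over the last 10% of the step ("end of
  the pulse" made concrete), divided by capacitance. The window fraction is
  configurable.
* **Tail peaks**: extremum within the first 10 ms of the tail after a
  0.5 ms blanking interval (capacitive transient), after a 1 ms boxcar
  smooth so the peak is not set by a single noise sample. These windows are
  typical for KV1-family tails.
* **Boltzmann fit**: 3-parameter least squares of raw peaks to
  I_max / (1 + e^((V₀.₅−V)/k)) with k > 0 (increasing with depolarization);
  normalization is by the fitted I_max, not the largest observed point.
  A `printed_convention` flag fits the (V₀.₅+V)/k variant that appears in
  some methods sections; it is the same curve under k → −k, V₀.₅ → −V₀.₅.
* **Time constants**: A(1 − e^(−t/τ)) + C on the step segment (activation)
  and A e^(−t/τ) + C on the tail (deactivation), both after the 0.5 ms
  blank. τ is reported per step voltage; no attempt is made to collapse the
  voltage dependence into a single number.
* **No leak subtraction** is applied; the simulator can inject a linear leak
  to probe robustness of downstream estimates.

Fit machinery: `scipy.optimize.curve_fit` with parameter tolerances 1e-8 and
a 5000-evaluation cap. Starts are deterministic and derivative-free: V₀.₅
from the half-amplitude crossing, k = 10 mV, I_max = max peak; τ from the
63% rise/decay point. Failures and degenerate fits (zero amplitude, singular
covariance, τ pinned to a bound) are returned flagged, never silently
dropped and never raised.

### Vascular readouts

* Myogenic tone per pressure: (passive − active)/passive × 100, with the
  passive diameter taken from the Ca²⁺-free measurement at the same
  pressure. Missing pairs raise an incomplete-record error.
* CBF responses: traces are biological-zero corrected (flux − zero, clipped
  at 0; idempotent), then percent response = 100 (stim − rest)/rest with
  rest = mean over the 30 s before stimulation and stim = plateau mean over
  the stimulation epoch (peak optional). The baseline duration is a
  package choice; the plateau-mean statistic is the default because the
  simulated responses are sustained.
* N1 amplitude: sweeps are trial-averaged; baseline is the pre-stimulus
  mean; N1 = |minimum within 0–80 ms − baseline|, flagged not-detected when
  the trough fails to clear baseline − 2 SD(baseline).
* Group summaries are mean ± SEM with the test delegated to standard
  routines (Welch/paired t-test, one-way ANOVA, repeated-measures ANOVA);
  no bespoke statistics.

## Synthetic-data generator

The generator is the package's stand-in for recordings and defines the
conditions under which the pipeline is validated.

**Voltage clamp.** Single-gate Hodgkin–Huxley kinetics: the open fraction
relaxes mono-exponentially toward the Boltzmann steady state
n∞(V) = 1/(1 + e^((V₀.₅−V)/k)) with τ_act(V) during the step and τ_deact at
the tail; current = N·P_max·n(t)·i_GHK(V) + leak·V + white gaussian noise.
The single-gate choice makes the generative model match the fitted models
exactly; a `gate_exponent` toggle (n², same steady state, sigmoid onset)
provides deliberate kinetic misspecification for robustness checks.
P_max = P_o(ref)/n∞(V_ref) anchors the absolute open probability to the
counting convention (0.78 under the defaults, a proper probability).

Defaults (chosen once, as realistic recording conditions): N = 3120
channels, γ = 15 pS, P_o = 0.014 at −40 mV, [K⁺]ₒ/[K⁺]ᵢ = 3/140 mM, 23 °C;
protocol −80 mV holding, −70…+60 mV steps in 10-mV increments, 250 ms step,
200 ms tail at −40 mV, 10 kHz sampling; V₀.₅ = −12 mV, k = 7 mV,
τ_deact = 25 ms, τ_act(V) a symmetric bell (4–20 ms) peaking near V₀.₅;
capacitance 15 pF; noise SD 5 pA (typical whole-cell RMS at 2 kHz
filtering); no leak. Step and tail durations are package choices sized so
gating reaches steady state within each segment (≥ 8 time constants).

**Other modalities.** Pressure-diameter series: active = passive ×
(1 − tone/100) + noise, passive diameters rising 140→178 µm over 20→100
mmHg as in a posterior cerebral artery. LDF traces: flux = zero-offset +
resting × (1 + %response/100 inside stimulation epochs) + noise, default a
60 s epoch, 20% response, 10 LDFU biological zero; the response steps on
instantaneously (no hemodynamic ramp). Evoked fields: a biphasic template
(small positive deflection, then the N1 trough at 20 ms, both inside 80 ms)
scaled so the trough equals the programmed amplitude exactly, plus
independent per-sweep noise.

All generators draw from named substreams of a single integer seed
(SeedSequence keyed by seed and a CRC of the stream name), are bit-identical
for identical inputs, and attach their generating parameters under
`meta["ground_truth"]` for recovery tests.

**What the generator does not emulate** — and hence what passing recovery
tests do not demonstrate about real recordings: BK or other contaminating
conductances (recordings assume pharmacological block), channel inactivation
and rundown, capacitive/series-resistance artifacts beyond a blanking
interval, stochastic single-channel gating, correlated (filtered) noise,
hemodynamic response shapes, and vasomotion. Estimator performance on real
data therefore needs the usual external checks (stability of N across tail
durations, residual inspection of fits).

## Numerical choices

* GHK's removable singularity at V = 0 is evaluated by the series
  1 + u/2 + u²/12 for |u| < 1e-4; elsewhere `expm1` keeps the denominator
  accurate at small u.
* Channel counts are reported both raw and rounded to the nearest 10 (the
  conventional presentation); all arithmetic uses the raw value.
* Tail-fit offsets are pooled by the median across sweeps: all tails relax
  to the same steady state, and the median discounts occasional degenerate
  fits near the crossover step voltage (where the tail has no excursion and
  the fit is flagged).
* CSVs are written at %.17g and parsed with round-trip float precision, so
  write-then-read is exact.

## Statistical resolution of the Boltzmann slope

With tail peaks at the 14 protocol voltages and independent gaussian noise
of 2% of I_max, the Fisher information of the 3-parameter Boltzmann fit
bounds the slope's precision at SD(k̂) ≈ 0.4 mV for k = 7 mV (the V₀.₅
bound is ≈ 0.4 mV as well, but its practical band is ±1 mV rather than
±0.5 mV). A per-cell k estimate therefore cannot sit within ±0.5 mV of the
truth in 95% of cells at that noise level — only within roughly ±0.8 mV.
The estimator is unbiased (Monte-Carlo mean bias < 0.05 mV for both
parameters); averaging across cells tightens the group-level estimate by
√n as usual. This is a property of the design (14 points, 2% noise), not of
the fitting code.

## Known limitations

* The counting chain inherits the GHK and fixed-P_o assumptions; errors in
  γ or P_o scale N inversely and are not identifiable from whole-cell data.
* Boltzmann fits assume a single channel population; two-component
  activation would bias V₀.₅ and k.
* Tone and CBF formulas are exact arithmetic on their inputs; quality
  filtering (e.g. passive ≥ active) is the caller's responsibility upstream.
* The repeated-measures ANOVA branch requires balanced groups and delegates
  wholly to statsmodels.
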