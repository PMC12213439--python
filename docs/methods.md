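# Methods

This note documents the models, algorithms, numerical choices, and synthetic
data behind the `oscillometry` package, and what the test suite does and does
not establish.

## Arterial compliance sigmoid

The core physiological object is the sigmoidal relationship `V = f(P)`
between transmural pressure `P = Pa − Pc` (mmHg) and arterial blood volume
(mL). Its derivative, the arterial compliance curve `g(P)`, is unimodal with
its maximum `a` (mL/mmHg) at zero transmural pressure; `b` and `c` (mmHg) set
its widths over the negative and positive transmural ranges. Two forms are
implemented:

* **exp-linear** (default, used by the oscillogram models):
  `g(P) = a e^{−|P|/w}(1 + |P|/w)` with `w = b` for P < 0, `w = c` for P > 0;
* **exp**: `g(P) = a e^{−|P|/w}`, used only for the interpretable peak-position
  formulas, where its exponentials make a closed approximation possible.

The volume anchor is `f(−∞) = 0` with no extra offset; the plateau is
`2a(b + c)` (exp-linear) or `a(b + c)` (exp). Both formula branches evaluate
identically at P = 0, so the unit step's value there (taken as 1) is
observationally irrelevant; a test asserts the two branches agree exactly.
Exponent arguments are arranged to be nonpositive (`−|P|/w`), so extreme
pressures saturate analytically instead of overflowing.

## Height and area oscillogram models

`OH(Pc) = k[f(Ps − Pc) − f(Pd − Pc)]` is evaluated as an explicit
three-region piecewise expression (regions delimited by `Pc = Pd` and
`Pc = Ps`, half-open membership `[Pd, Ps)`; the expression is continuous
across the boundaries so the convention only matters at the 1e-15 level).
A test compares it against the independent route through the volume sigmoid.

The area model integrates `k f(Pa(t) − Pc)` over one beat of a triangular
pulse and subtracts the diastolic floor `T k f(Pd − Pc)`. Because the
triangle sweeps pressure linearly in time, the time integral collapses to a
pressure integral: with `F = ∫ f`,

    OA(Pc) = k T [ (F(Ps − Pc) − F(Pd − Pc)) / PP − f(Pd − Pc) ],

which is the closed form the package evaluates. The systolic rise duration
cancels exactly (rise and fall contribute `Ts/PP` and `(T − Ts)/PP` of time
per unit pressure, summing to `T/PP`). For `PP < 1e-5 (b + c)` the expression
switches to its first-order expansion `k T (PP/2) g(Pd − Pc)` because the
generic form divides an antiderivative difference by PP and loses precision.
Both models carry the single multiplicative scale `d = a·k`, which
normalization eliminates; `a` and `k` are never treated separately.

**Peak positions.** The height peak has the closed form
`PHmax = Pd + b·PP/(b + c)`, a weighted average of Ps and Pd with weights
`b/(b+c)` and `c/(b+c)` (identical in form for both compliance
parameterizations). The area peak solves the stationarity condition
`f(Pd − Pc) − f(Ps − Pc) + PP·g(Pd − Pc) = 0`, which has no closed solution;
it is found by bracketed Brent iteration on `(Pd − 5(b+c), Ps)` with the
lower end expanded by `10(b+c)` steps if the sign change is not initially
bracketed (tolerance 1e-8 mmHg). Because the condition is written with the
full piecewise `f` and `g`, it is valid even when the root falls below Pd.
For the exp form, dropping the exponentially small second term yields the
closed approximation `PAmax ≈ Pd + β ln((β + PP)/(β + γ))`, which tests show
stays within 2 mmHg of the exact root over β, γ ∈ [5, 20] mmHg,
PP ∈ [40, 80] mmHg.

## Forward simulator

`simulate_volume` maps BP and cuff-pressure waveforms to blood volume under
three system hypotheses: **elastic** (`V = f(Pa − Pc)` pointwise),
**Hammerstein** (static sigmoid, then a first-order unity-gain low-pass with
cutoff `w` rad/s), and **Wiener** (low-pass first, then the sigmoid). The
filter is discretized by the bilinear transform at the waveform's sampling
rate and its state is initialized at the first sample's steady state, so a
constant input passes through unchanged (no startup transient). The
canonical cutoff unit is rad/s; reporting converts to Hz.

`to_oscillations` high-pass filters the volume (2nd-order Butterworth,
zero-phase, default 0.5 Hz; 0 disables) and applies either a constant scale
`k` (mmHg/mL) or the variable `kv(t) = Pc(t)/Patm + 1` that accounts for
compression of the cuff's air column by the arterial pulsation
(`Patm = 760 mmHg` by default).

`boyle_cuff_pressure` implements the physical cuff-arm model: air in the
cuff obeys Boyle's law, `Va = Patm (Vp + Vc0)/(Pc + Patm)`, and the enclosed
volume `Va + Vi0 + V` loads a power-law cuff elasticity
`Pc = Ec ((Vout/Vout0)^{1/n} − 1)^n`, `Vout0 = Vi0 + Vc0`. The implicit
equation is solved per sample by bracketed Brent iteration on `[0, 10·Ec]`
followed by analytic-derivative Newton polishing; the fractional volume
excess is computed with `log1p`/`expm1` because the Ec-scaled elasticity term
would otherwise sit on an `O(Ec·eps)` round-off floor. Residuals at the
returned pressures are below 1e-9 mmHg. Differentiating the model at fixed
pumped volume gives `∂Pc/∂V = Patm (Pc/Patm + 1)² / (Vp + Vc0)` in the
`Vi0 + Vc0 ≪ Ec` regime — the basis of the constant-k and variable-kv scale
factors — and a test confirms the numeric sensitivity matches within 5%.
Default mechanics (`Vc0 = 200 mL`, `Vi0 = 800 mL`, `Ec = 1e7 mmHg`, `n = 1`)
are package choices representative of a standard adult arm cuff; `regime_ok`
flags configurations that violate the linearization assumption.

## Synthetic data

The generator replaces a restricted clinical dataset; its defaults are the
study conditions throughout the tests:

* **Cuff protocol**: 5 s linear inflation from 0 to 180 mmHg (the inflation
  segment is discarded by construction, so its exact shape is immaterial),
  linear deflation at 3 mmHg/s (clinical range 2–4 mmHg/s) to a 60 mmHg
  hold, 250 Hz sampling.
* **Triangular BP**: exact sampled realization of the per-beat
  rise-over-`Ts`, fall-over-`T − Ts` triangle; default `T = 1 s`,
  `Ts = 0.3 T` (a fixed rise fraction stands in for per-beat values measured
  from invasive waveforms), 120/80 mmHg.
* **Realistic BP surrogate**: a band-limited template (Fourier truncation of
  the skewed bump `φ²(1−φ)⁶`, default 8 harmonics) rescaled per beat so each
  beat's extrema equal Ps and Pd exactly, with optional seeded Gaussian
  beat-duration jitter. It reproduces the sharper upstroke / slower
  downstroke of an arterial pulse and keeps < 1% of AC spectral energy above
  10 Hz. It does **not** model dicrotic notches, respiratory or baroreflex
  BP variability, or arrhythmias — so passing tests demonstrate correctness
  of the pipeline under clean periodic pulses, not robustness to pathological
  rhythms or motion artifact.
* **Noise**: optional additive white Gaussian noise on the assembled
  recording (single integer seed); no drift or artifact models.

## Oscillogram construction

Over the deflation segment (located from the protocol metadata, which this
package always has for its own recordings; foreign recordings would need
segment annotation):

1. **Oscillation extraction**: 6th-order Butterworth band-pass, 0.75–5 Hz.
   All construction filters are applied forward-backward (zero phase), so
   pulse timing is preserved; the stated orders are the designed orders and
   the two passes double the effective order.
2. **Applied-pressure trend**: 4th-order Butterworth low-pass, 0.3 Hz
   (the trend extraction step is specified only as "low-pass" in the source
   algorithm; these are package choices).
3. **Pulse detection**: candidate peaks below 0.2 mmHg and valleys above
   −0.1 mmHg are rejected (thresholds are signed amplitudes of the zero-mean
   filtered signal, read as noise-rejection rules); the pulse rate PR is the
   dominant periodogram frequency in 0.75–3 Hz (physiological heart-rate
   band); a peak is kept only if at least one adjacent peak-to-peak interval
   lies in `[0.65/PR, 1.35/PR]` — this keeps the two good neighbours of a
   dropped beat while rejecting inserted or shifted beats. Retained pulses
   are delimited by their flanking retained valleys. A run with zero retained
   pulses raises an error carrying per-rule rejection counts.
4. **Per-pulse features**, relative to the chord joining the pulse feet:
   height (peak above the chord), area (trapezoid integral above the chord,
   mmHg·s), area-to-height ratio (effective width, s), and left/right area
   ratio (asymmetry). The cuff pressure attached to a pulse is the low-passed
   trend at the peak time (alternatives such as the per-beat mean differ by
   less than one deflation-rate·beat product).
5. **Assembly**: features sorted by ascending cuff pressure, smoothed by a
   5-point centered moving average with edge shrinking, tail-trimmed, and
   optionally aligned (fiducial to 0 mmHg) and normalized to unit maximum.
   The flat-tail rule (the source algorithm names the step but not the rule):
   walking outward from the maximum, the curve ends at the sample before a
   rise sustained for 3 consecutive samples, or at the first sample below
   10% of the maximum; both parameters are configurable. The order
   smooth → trim → normalize is fixed but each step is configurable.
   For inverted-U kinds, the completeness flag requires both trimmed ends to
   fall to ≤ 80% of the maximum; incomplete oscillograms are flagged, and
   fitting refuses them unless explicitly overridden.

## Fitting

Closed-form fits minimize the trapezoid-discretized integral of
`(O − Ô(b, c))²` over the trimmed range, with `b, c ∈ [0, 60]` mmHg, seeds
(11, 14) mmHg, and tolerance 1e-6; Ps and Pd are inputs, not estimated. The
optimizer is SLSQP (sequential quadratic programming) followed by a
trust-region polish (`trust-constr`) from the SLSQP iterate: SLSQP's stopping
rule is an objective-change criterion, and the polish enforces the stated
optimality (gtol) and step (xtol) tolerances directly. The numeric lower
bound on the widths is 1e-6 mmHg (the closed forms divide by b and c).
Noise-free recovery is better than 1e-3 mmHg from the standard seeds and
from random admissible seeds. NRMSE is scale-free and trapezoid-weighted;
with a 2-point uniform grid, measured (1, 1) against fitted (1, 0) gives
100·√½ ≈ 70.7%.

Simulation-based fits (`fit_simulated`) evaluate the forward simulator inside
the objective: simulate the volume at candidate `(b, c[, w])`, convert to
oscillations, compute per-beat chord-baseline features, interpolate onto the
measured cuff-pressure grid, normalize, and score with the same integral.
Viscoelastic systems add `w` with bounds `2π·[0.1, 20]` rad/s and seed
`2π·3` rad/s (near typical fitted damping). So that candidate and measured
oscillograms pass through the same measurement operator, the simulated
oscillation signal receives the same zero-phase band-pass and the feature
sequence the same 5-point smoothing as the construction pipeline, and the
fit can reuse the pipeline's detected pulse windows (`beat_windows`; by
default beats are delimited by the BP input's feet). Threshold-based pulse
gating is deliberately not re-run inside the optimizer loop: the candidate
oscillation scale is arbitrary (normalization removes `d`), so absolute
amplitude thresholds would be meaningless there. `assumption_grid` crosses
system hypothesis × BP input shape × scale factor over a set of synthetic
recordings and tabulates fitted parameters, NRMSE, and errors against ground
truth.

`nonlinearity_adjustment` divides an oscillation signal by a piecewise-linear
volume-to-pressure profile evaluated at the cuff-pressure trend — default
0.6 mmHg/mL below 60 mmHg rising linearly to 1 mmHg/mL at 100 mmHg and
constant above, describing an arm cuff whose pressure-volume relationship
becomes linear only above ~100 mmHg (below 60 mmHg the profile is held at its
low value; synthetic protocols never deflate further). On synthetic data,
multiplying oscillations by this profile skews the area-model width estimates
toward `b > c`; dividing it back restores them — the package's reproduction
of the cuff-nonlinearity mechanism.

## Problem sizes and determinism

Test and acceptance runs use one ~60 s recording per case (≈ 55 beats,
15,500 samples at 250 Hz, ≈ 30–40 retained pulses per oscillogram), 20-draw
oracle sweeps, and 20-replicate noise studies; these sizes make every
quantity stable at the asserted tolerances while keeping a full run in tens
of seconds. All stochastic elements (noise, jitter, parameter draws) flow
from single integer seeds; identical seeds give bit-identical recordings,
CSVs, and fit results.

## Known limitations

* Deflation-segment localization relies on protocol metadata rather than
  change-point detection on the pressure trend.
* The measured-vs-model agreement floor (≈ 1–4% NRMSE end-to-end) reflects
  band-pass shaping and moving-average smoothing of the construction
  pipeline; it is a property of the measurement operator, not optimizer
  error.
* BP estimation from oscillograms (inverting the models for Ps, Pd) is out
  of scope, as are arm-tissue compression mechanics, estimation of the cuff
  mechanics parameters from bench data, and artifact/arrhythmia
  classification beyond the stated gating rules.
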