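# Methods

This note documents the models, numerical choices and design decisions in
`petkin`, and states precisely what the synthetic-study generator emulates
— hence what passing tests do and do not demonstrate about real data.

## Compartment models and units

The ammonia candidate family is the nested chain obtained from the
reversible two-tissue compartment model (2TCM) with a blood-volume term by
fixing k4, k3, k2 to zero in turn:

| model | free parameters |
|---|---|
| 1TCM irreversible | K1, vB |
| 1TCM reversible | K1, k2, vB |
| 2TCM irreversible | K1, k2, k3, vB |
| 2TCM reversible | K1, k2, k3, k4, vB |

State equations: `dC1/dt = K1·Cp − (k2+k3)·C1 + k4·C2`,
`dC2/dt = k3·C1 − k4·C2`, measured signal
`C_PET = (1−vB)(C1+C2) + vB·C_wb`. The tissue term is scaled by (1−vB)
(conventional partial-volume bookkeeping; togglable through `fit_vB`).
The whole-blood curve drives the intravascular spill-in term while parent
plasma drives the compartments — the physiologically standard split.

Units: K1 and CBF in mL/100 g/min assuming 1 g/mL tissue density
(internally divided by 100 to per-mL rates), k2–k4 in 1/min, vB unitless
in [0, 0.2], times in minutes, activities in kBq/mL. Patlak slopes and
intercepts are rescaled to the same per-100 g convention.

Water CBF uses the Meyer free-diffusion model: the reversible one-tissue
structure applied to the whole-blood curve with two extra free parameters,
a delay and a monoexponential dispersion time constant τ of the arterial
curve. With τ = delay = 0 it reduces exactly to the reversible 1TCM, which
is asserted in the tests.

**Delay sign convention.** A positive delay means the blood record lags
the tissue (the usual situation with a long sampling line); the correction
*advances* the record, `C(t) → C(t + delay)`. `estimate_delay`,
`build_parent_plasma_input` and the delay parameter of the Meyer model all
share this convention, so an estimated delay can be applied directly.

## Forward computation

The impulse response of the (up to) two-tissue system is a sum of one or
two exponentials with rates `θ1,2 = ½[(k2+k3+k4) ± √((k2+k3+k4)² − 4k2k4)]`;
k3 = 0 is routed through the one-tissue branch so the nesting identity is
exact rather than a numerical limit. Exponential convolution against the
input is computed analytically for a piecewise-linear input on the blood
sampling grid (exact at the grid nodes): the per-segment update
`y_{k+1} = y_k·e^{−a·h} + increment` is an IIR recurrence, evaluated with
`scipy.signal.lfilter` on uniform grids and a sequential loop otherwise,
with series expansions of the segment kernels below `a·h < 10⁻³` for
round-off stability. Frame values are interval means of the fine-grid
curve (cumulative trapezoid interpolated to the frame edges), not midpoint
samples. Tests compare this path against an independent stiff ODE
integration (`solve_ivp`, BDF, rtol 10⁻¹⁰) to < 10⁻⁶ relative.

## Weighted fitting

Frame weights are `w_i ∝ Δ_i·e^{−λ t_i}` normalised to sum 1 — variance
taken inversely proportional to collected counts (frame duration × decay
survival), the standard PET reading of duration-and-decay weighting. The
weighted residual `√w_i·(TAC_i − model_i)` is minimised with bounded
`scipy.optimize.least_squares` (TRF, xtol = ftol = gtol = 10⁻¹⁴) over the
boxes K1 ∈ [0, 100] mL/100 g/min, k ∈ [0, 1] /min, vB ∈ [0, 0.2],
delay ∈ [−15, 15] s, τ ∈ [0, 20] s. Five deterministic multi-starts are
placed on a Latin square of the box; lowest WRSS wins, first start wins
ties, so fits are exactly reproducible. When the candidate family is
fitted together (`fit_candidate_models`), each richer model additionally
starts from the simpler model's solution, which guarantees WRSS is
non-increasing along the nesting chain. Standard errors come from the
Gauss–Newton covariance `(JᵀJ)⁻¹` scaled by the reduced chi-square
WRSS/(n−p) (pseudo-inverse when JᵀJ is singular). Non-convergence is
reported via a flag, never an exception; an all-zero TAC fits cleanly to
zero parameters.

## Model selection and identifiability

Least-squares AIC, `n·ln(WRSS/n) + 2p`, with p counting every free
parameter including vB; no small-sample correction by default (n/p ≈ 12;
AICc is available behind a flag). Non-converged candidates are excluded
and ties go to the simpler model. Fits whose WRSS falls below 10⁻²⁵ of the
weighted sum of squares of the data are floored to a common value before
the AIC comparison: below double-precision resolution two perfect fits are
indistinguishable and should compete on parameter count, which makes
selection on noise-free data well defined.

Identifiability of a rate constant is a one-sided t-test of estimate/SE on
n_frames − n_params degrees of freedom (43 for the irreversible 2TCM on
the 47-frame schedule), significant at p < 0.05. The test is implemented
directly from this definition; no closed-form "proportional error
threshold" shortcut is used.

## Patlak analysis

`y = C_t(t)/C_p(t)` against `x = ∫₀ᵗC_p/C_p(t)` by ordinary least squares
over frames with mid-time ≥ t* (default 20 min, i.e. the last ten 60 s
frames of the 30-min scan — the "late subset" reading of the fit window).
The plasma running integral uses the trapezoid rule on the 1 s plasma
grid. For irreversible systems the slope equals K1·k3/(k2+k3); for the
reversible tracer the late-time slope is small but positive, mirroring the
known nonlinearity of Patlak plots for reversible uptake.

## Repeatability statistics

Consistency ICC, single measures, two sessions:
`ICC(C,1) = (MSR − MSE)/(MSR + MSE)` from the two-way ANOVA with subjects
as rows and sessions as columns, so additive session effects are ignored.
Negative values are reported as computed, never truncated. The
significance threshold inverts `F = MSR/MSE ~ F(n−1, n−1)` at the upper α
quantile: `(F_crit − 1)/(F_crit + 1)`, giving 0.58 at n = 8, α = 0.05
(cross-checked in the tests against a 10⁵-replicate Monte-Carlo null and
against `pingouin`'s ICC(C,1) on random data). VAR and AbsVAR are the
signed and absolute pair-mean-normalised percent differences; pairs
summing to zero are excluded with a warning because the normalisation is
undefined there.

## Blood processing

The continuous detector record is cross-calibrated to the manual samples
by the median manual/continuous ratio at overlapping times and extended to
scan end (the ammonia record stops at 15 min) by a monoexponential through
the manual tail, continuing from the calibrated end value. The
plasma-over-blood ratio is the per-subject mean of manual plasma/blood
ratios (time-constant, with 1.14 as the population fallback when plasma
samples are missing). The parent fraction is a biexponential constrained
to f(0) = 1 — at injection all tracer is parent — with A ∈ [0, 1] and fast/
slow ordering α ≥ β enforced by relabelling. Delay matching automates the
visual alignment of the blood rise with a grey-matter TAC: both curves are
peak-normalised and the squared mismatch over the reference's bolus rise
(5 % of peak up to the peak) is minimised on a 1 s grid in ±60 s.
Interpolation between blood samples is linear throughout.

## Synthetic-study generator

The generator emulates the statistical structure the analysis assumes, at
the study's stated conditions:

* **Design**: n subjects (default 8) × two same-day sessions, each with a
  5-min water scan (26 frames: 1×10, 10×5, 6×10, 9×20 s) and a 30-min
  ammonia scan (47 frames: 1×10, 10×5, 6×10, 3×20, 27×60 s).
* **Arterial input**: gamma-variate bolus (onset 30 s, exponent 3, peak
  width 15 s, peak 100 kBq/mL) plus a 15 % recirculation plateau decaying
  with a 10-min half-life. The bolus shape and amplitude are generator
  choices constrained only qualitatively (rise 30–60 s post-injection).
* **Blood measurement chain**: continuous record = truth delayed by a
  per-scan transit delay (mean 6 s, sd 2 s), scaled by a detector
  cross-calibration factor (mean 0.90, sd 0.05), lightly noised (0.2 % of
  peak), stopping at 15 min for ammonia; manual samples at 4, 6, 8, 12,
  20, 30 min (ammonia) with 2 % noise.
* **Metabolites**: parent-fraction truth A = 0.65, α = 0.5 /min,
  β = 0.04 /min (below 50 % by the first 4-min sample), sampled with
  sd 0.02 noise; plasma-over-blood ~ N(1.14, 0.03).
* **Kinetic truth**: regional means and between-subject sds anchored to
  the study population (grey matter CBF 37.6 ± 4.8, K1 20.1 ± 1.5
  mL/100 g/min, k2 0.0069 ± 0.0029 /min, and four further regions);
  between-session jitter 5 % CV. Default generating model is the
  reversible 1TCM; the irreversible 2TCM (with regional k3 truths) is
  selectable. An optional mode generates K1 as a fixed extraction fraction
  times the session CBF to emulate flow-limited delivery.
* **Physiology**: baseline blood ammonia ~ N(24.5, 5.7) µmol/L, injected
  doses ~ N(841, 126) MBq (water) and N(537, 7) MBq (ammonia).
* **Frame noise**: zero-mean Gaussian with
  `sd_i = noise_scale·√(C̄/(Δ_i·e^{−λt_i}))` (noise_scale 0.05, about 2 %
  of a grey-matter TAC on the late 60 s frames), negatives clipped with a
  recorded count. Gaussian rather than Poisson is justified by
  reconstructed-ROI averaging; the variance law matches the fitting
  weights.
* **Seeding**: one master seed; every subject/session/stream draws from
  `SeedSequence((seed, subject, session, stream))`, so regeneration is
  bit-identical and adding subjects never perturbs existing ones.

**What it does not emulate** — and hence what passing tests cannot show:
image reconstruction and its correlated noise, motion, atlas/segmentation
errors, scanner dead-time, time-varying plasma-over-blood ratios,
labelled-metabolite influx into tissue, and any real physiological
coupling beyond the configured parameter distributions. Recovery and
repeatability results on synthetic data bound what the estimator chain
itself contributes; they do not certify performance on scanner data.

## Problem sizes

The test suite and acceptance script run at desk scale: studies of 1–4
subjects × 2 sessions × 5 regions for end-to-end checks, 50 noisy
replicates for model-selection recovery, 100 for K1 bias, 10⁴ for the
frame-noise variance law and 10⁵ for the ICC Monte-Carlo null. These sizes
were chosen so the distributional checks resolve the asserted tolerances
(5 % on variance ratios, 0.01 on the ICC threshold) with margin.

## Known limitations

* The Patlak K_met of a reversible tracer is scan-length dependent; it is
  reported as defined (t* = 20 min) without correction for backflux.
* Delay estimation is grid-quantised at 1 s; sub-second transit
  differences alias into the estimate.
* The extrapolated ammonia blood tail (15–30 min) assumes monoexponential
  decline through the manual samples.
* `ps_product` returns a flagged infinity when clearance reaches flow
  (extraction saturated); downstream tables must render it as undefined.
* The 7-parameter ammonia variant (delay + dispersion added to the 2TCM)
  is implemented behind `fit_delay_dispersion` but excluded from the
  default candidate set.
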