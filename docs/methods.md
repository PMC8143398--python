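# Methods

## Observer model and measurement model

Orientation is axial data with period 180°. Internally every computation
uses radians on `[0, π)`; degrees appear only at I/O boundaries. All
circular estimation uses the doubled-angle convention: orientations are
mapped to `2θ` (period 2π), fit with directional statistics, and mapped
back. Signed orientation errors live in `[−90°, +90°)`.

A participant is modelled as a generic estimator of the target orientation.
Within a sliding window centered at `c`, a von Mises distribution is fit to
the doubled response angles of the trials whose target falls in
`[c − w/2, c + w/2)` (windows wrap across 0°/180°): the mean gives the bias
`b(c) = μ − c`, and the concentration gives the variance proxy
`σ²(c) = 1/κ`. The window width is 18° for single participants
(200 trials/block) and 4° for the pooled combined participant. The
concentration is obtained from the mean resultant length by the standard
piecewise approximation refined with two Newton steps on
`A(κ) = I₁(κ)/I₀(κ)`; degenerate (zero-spread) windows are clamped at
`kappa_cap` (default 1e4) and flagged; windows with fewer than two trials
are circularly interpolated and flagged, and more than 20% missing windows
escalates to an error in strict mode.

Because the oblique effect is 90°-periodic, the default analysis folds
targets (and responses, via their error relative to the target) modulo 90°
before windowing and tiles the 90° profile back onto `[0°, 180°)`
(`enforce_period_90`, on by default).

### Variance scales

`variance = 1/κ` is reported on the doubled-angle scale, which is where
combined-participant values of order 0.2 live. The σ that enters the
Cramér–Rao bound must be on the orientation radian scale, so the pipeline
uses `σ_ori = sqrt(1/κ)/2`. These two conventions are mutually consistent:
a flat profile with variance 0.18 gives a total resource of
`π/(0.5·sqrt(0.18)) ≈ 14.8`, the magnitude the parametric `λ` takes for a
neurotypical-scale observer.

Two small systematic properties of this measurement are worth knowing.
First, fitting *responses* within a window adds the uniform target spread,
`(2w)²/12` on the doubled scale, to `1/κ`; this is negligible for the 4°
window (<1%) but deflates 18°-window totals by roughly 9%. Second, at
moderate concentrations (`κ ≈ 2–3`, typical of oblique windows at study
noise) the resultant-based `1/κ` differs from the true circular variance by
several percent. Both are inherent to the estimator definition, not bugs,
and affect simulated and real data identically.

## Fisher-information extraction

With the bound assumed tight,

    sqrt(I_F)(θ) = (1 + b′(θ)) / σ_ori(θ),

where `b′` is a circular central difference of the (already
window-smoothed) bias on the 1° grid; no additional smoothing is applied.
Noisy windows can push the numerator below zero; such values are floored at
0 and counted (`n_floored`). The total resource is the periodic rectangle
sum `∫₀^π sqrt(I_F) dθ` (exact for a full-period grid), the
efficient-coding prior is `sqrt(I_F)` normalized to integrate to 1, and the
alternative total `∫ I_F dθ` is also computed and reported separately
(`total_fi`) for comparison.

## Parametric resource-allocation model

    sqrt(I_F)(θ; λ, ω) = λ · ( ω · c·(1 − |sin 2θ|) + (1 − ω)/π ),

with `c = 1/(π − 2)` so that the mixture integrates to exactly 1 and
`∫ sqrt(I_F) dθ = λ` (the commonly quoted rounded constant 0.877 is
available as a switch; fits under the two constants differ by <0.5% in λ).
`ω = 0.5` approximates the natural-scene orientation prior; `ω = 0` is the
uniform allocation matched to the experimental stimulus distribution.

Fitting plugs the *measured* `σ_ori(θ)` into the predicted bias

    b̂(θ) = ∫₀^θ ( sqrt(I_F)(t; λ, ω) · σ_ori(t) − 1 ) dt,

computed by cumulative trapezoid anchored at `b̂(0) = 0` on the folded 90°
half-domain (σ averaged across the two half-cycles), mean-centered per
cycle, and tiled. The integrand is deliberately *not* detrended: for a
bound-attaining observer `∫(sqrt(I_F)·σ − 1) dt = 0` over a period exactly
when λ matches the measured noise level, so a wrong λ produces a
within-cycle drift of `b̂` that the least-squares objective penalizes
heavily — this is what identifies λ, while the shape of `b̂` identifies ω.
The objective `Σ(b̂ − b)²` is minimized by bounded L-BFGS-B from a
deterministic 3×3 multi-start grid (λ₀ ∈ {0.5, 1, 2} × the nonparametric
total; ω₀ ∈ {0.1, 0.5, 0.9}); `R²` is reported against the observed bias,
and non-convergence from every start is flagged rather than raised. On
noiseless self-generated data the fit recovers (λ, ω) to 1e-3/1e-4 with
R² = 1; a grid scan confirms a unique minimum.

Degenerate caveat: a perfectly unbiased, homogeneous observer (b ≡ 0) makes
the objective flat in λ (any λ with ω = 0 predicts zero bias after
centering); λ is then reported at the boundary and `converged` still True.
Real and simulated anisotropic observers never hit this.

## Synthetic observers

The encoder follows the standard efficient-coding construction: stimulus
prior `p(θ)` (the (λ, ω) mixture), cumulative map `F(θ) = ∫₀^θ p`, internal
measurement `m ~ vonMises(2π·F(θ), κ_int)` on the internal circle. The
encoder's analytic `sqrt(I_F)` is `2π·p(θ)·sqrt(κ_int)` — proportional to
the prior, as efficient coding requires.

**Internal-noise calibration.** `κ_int = (λ/2π)²`. Derivation: for a
homogeneous encoder the doubled response angle is *exactly*
`vonMises(2θ, κ_int)`, the window fit returns `κ → κ_int`, and the
extracted total is `π·2·sqrt(κ_int) = 2π·sqrt(κ_int)`; setting this equal
to λ gives the calibration. The alternative `κ_int·A(κ_int)` (the true von
Mises Fisher information) is *not* used because the pipeline's variance
convention is `1/κ`, and that calibration would inflate recovered λ by
`1/sqrt(A(κ))` (≈ +10% at κ ≈ 3).

**Decoders.** Three bound-attaining families:

- `inverse_map`: `θ̂ = F⁻¹(m/2π)` (MLE-like; F inverted on a 4096-point
  grid with two Newton refinements, |F(F⁻¹(u)) − u| < 1e-9 away from
  zero-density spans);
- `posterior_mean`: the Bayes estimator under squared *orientation* error —
  the posterior over θ on a 720-point grid, and the posterior expectation
  of θ unwrapped around the posterior's doubled-angle circular mean. The
  task loss is squared orientation error (observers match an orientation
  and are scored by RMSE), so this, rather than the bare circular mean, is
  the natural Bayesian observer; empirically it also attains the bound best
  at study-scale noise and is therefore the cohort default;
- `remapped`: a smooth monotone period-90°-preserving distortion
  `g(θ̂) = θ̂ + a·sin(4θ̂)/4` (|a| < 1) applied to the inverse-map estimate;
  any such remap trades bias against variance while leaving the bound tight
  to first order.

Optional late noise adds wrapped zero-mean Gaussian noise (degrees) after
decoding — stimulus-independent variability such as motor noise. Its
signature downstream is a *decrease* of the extracted total/λ together with
a *flattening* (smaller ω), which is what makes it distinguishable from
genuine encoding changes.

**Bound attainment is first-order.** At study-scale noise
(λ ≈ 10–15 ⇒ κ_int ≈ 2.5–5.7) the local noise-to-curvature ratio
`σ_θ·(log p)′` reaches ~0.5 at the profile flanks, so every smooth decoder
misses the bound at second order; together with the `1/κ` convention and
the 4° window's smoothing of the `|sin 2θ|` kink this compresses recovered
ω by up to ~0.05 at ω = 0.5 (λ is recovered to ~1–2%). Parameter-recovery
tests therefore bound the *median* error over replicate cohorts, and
results on real data should be read as "ω as measured by this pipeline",
the same convention in which the reference group values are expressed.

**Cohorts.** `CohortSpec` defaults describe the study conditions: 25 NT +
17 ASD observers, three 200-trial blocks (woFB, wFB1, wFB2), uniform
targets. Per-block (λ, ω) schedules are set to the combined-participant
scale and feedback effects of the study this package models:
NT (14.7, 0.50) → (15.7, 0.40) → (16.7, 0.31); ASD (11.3, 0.55) →
(11.25, 0.50) → (11.2, 0.46). Observer heterogeneity is a lognormal
multiplier on λ (sd 0.25, spanning roughly a factor 2.5 across a cohort,
the spread seen in individual fits), plus independent jitter on the
starting ω (sd 0.05). `flexibility_coupling` (default 2.0) scales each
observer's ω-learning by their relative capacity, producing the negative
capacity–flexibility regression (R² ≈ 0.3–0.6 across seeds) that the
group-level analysis is designed to detect; set it to 0 for null cohorts.
Response times, used only by the RT summaries, are lognormal with per-block
medians (NT 3.0/2.65/2.39 s; ASD 3.4/3.0/2.65 s, sd 0.4 log-units)
matching a ~0.6–0.75 s median speed-up under feedback.

What the generator deliberately does **not** emulate: sequential effects
(every trial is independent), within-block learning drift (parameters are
constant within a block unless a segmented dataset is constructed
explicitly), lapses/guesses, and any stimulus-dependent late noise. Tests
that pass on these observers therefore validate the *pipeline's*
correctness and its invariances, not the behavioral completeness of the
observer model.

## Bootstrap inference

Statistics are bootstrapped with 5,000 replicates by default. Two
resampling units are implemented: trials-with-replacement within a pooled
set (for combined-participant statistics — SEs of order 0.2–0.5 on totals
of order 14), and participants-then-trials (hierarchical, for
per-participant summaries). Two-sided p-values for a difference Δ are
`2·min(Pr(Δ* ≤ 0), Pr(Δ* ≥ 0))` with a `+1/(n+1)` correction, so p is never
reported as 0 (floor `1/(n_reps+1)`); p-values are invariant to the sign
convention of Δ. Bootstrap SEs (SD of the replicates) and 2.5/97.5
percentile intervals are both exposed. The capacity–flexibility regression
is ordinary least squares with its parametric p-value — the one analysis
not bootstrapped. Type-I calibration of the contrast test was checked by
simulation: two same-distribution groups reject at α = 0.05 at a rate
within [0.03, 0.07].

## Numerical choices and degenerate inputs

- Grid: 1° steps; windows are left-inclusive, right-exclusive.
- `kappa_cap = 1e4` bounds degenerate concentrations; capped windows are
  flagged, not dropped.
- Fit tolerances: L-BFGS-B `ftol = 1e-12`, `gtol = 1e-10`; fits are
  invariant to grid refinement (1° vs 0.5°) within 1%.
- Empty datasets, missing columns, non-numeric angles, duplicate trial
  keys, negative RTs and out-of-enum labels all raise typed errors with
  file line numbers where applicable.
- Profile and trial CSVs round-trip bit-exactly (`float_precision=
  "round_trip"` on read; scalar metadata on `#key=value` comment lines).

## Problem sizes used in validation

The validation suite runs the decoder-invariance oracle at 10⁵ trials per
decoder with the 18° window (pairwise extracted-profile discrepancies
≤ 5% RMS), parameter recovery on 20 replicate cohorts of 25 × 200 pooled
trials per condition, the late-noise counterfactual on a 30,000-trial
cohort, and bootstrap calibration with 500 replications × 500 resamples.
These sizes give Monte-Carlo error comfortably below the tolerances they
are tested against.
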