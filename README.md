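# psyfi

Fisher-information analysis of orientation-estimation psychophysics.

`psyfi` measures *sensory encoding* — how precisely a visual orientation is
represented internally — directly from trial-level estimation data
(target orientation, reported orientation), without committing to any model
of the observer's decision process. It was built for studies that compare
encoding capacity and its reallocation across groups (e.g. neurotypical vs
autistic observers) and across feedback conditions, and it ships a full
synthetic encoder–decoder observer simulator so that every stage of the
analysis can be validated against ground truth.

## The method

An observer who reports estimates `θ̂` of an orientation `θ` has a bias
`b(θ) = E[θ̂] − θ` and a standard deviation `σ(θ)`. The Cramér–Rao bound for
a biased estimator links these to the Fisher information `I_F(θ)` of the
internal representation:

    √I_F(θ) ≥ (1 + b′(θ)) / σ(θ)

Any of the standard decoders (Bayesian, maximum-likelihood, or any smooth
remap of them) attains this bound — they trade bias against variance while
keeping the right-hand side fixed — so, assuming a tight bound, the
right-hand side *is* the encoding precision, regardless of how the observer
decodes. The pipeline is:

1. **Sliding-window circular statistics** (`sliding_profile`): a von Mises
   distribution is fit on doubled angles within a window slid over the
   orientation axis (18° for single participants, 4° for the pooled
   "combined participant"), giving `b(θ)` and the variance proxy
   `σ²(θ) = 1/κ(θ)`.
2. **Nonparametric extraction** (`extract_sqrt_fi`): `√I_F(θ)` pointwise;
   its integral `∫√I_F dθ` is the **total encoding resource**, and the
   normalized profile is the observer's **efficient-coding prior** over
   orientation (under efficient coding, `√I_F ∝ p(θ)`).
3. **Parametric model** (`fit_fi_params`):
   `√I_F(θ; λ, ω) = λ·(ω·[(1−|sin 2θ|)/(π−2)] + (1−ω)/π)` — a normalized
   mixture of a cardinal-peaked density and the uniform density. `λ` is the
   total resource; `ω` the weight on the natural-scene-like cardinal
   allocation. The fit predicts the bias implied by the model and the
   *measured* variance, `b̂(θ) = ∫₀^θ (√I_F·σ − 1) dt`, and least-squares
   matches it to the observed bias (avoiding the noisy derivative `b′`).
4. **Group inference** (`bootstrap_contrast`, `flexibility_regression`,
   …): bootstrap contrasts of any statistic across groups/blocks, and the
   regression of post-feedback allocation `ω` on initial capacity `λ`.

The observer simulator (`encoder_from_params`, `simulate_cohort`) builds
efficient-coding encoders (prior → cumulative map → homogeneous internal
von Mises noise) with bound-attaining decoders (posterior-mean,
inverse-map, remapped) plus optional stimulus-independent late noise, and
whole two-group, three-block cohorts with feedback-driven `(λ, ω)`
schedules.

## Worked example

```python
from psyfi import (CohortSpec, combined_participant, fit_fi_params,
                   simulate_cohort, sliding_profile)

data = simulate_cohort(CohortSpec(rng_seed=0))   # 42 observers x 600 trials
for group in ("NT", "ASD"):
    for block in ("woFB", "wFB1", "wFB2"):
        pooled = combined_participant(data, group, block)
        fit = fit_fi_params(sliding_profile(pooled, window_deg=4.0))
        print(f"{group:4s} {block:5s} {fit.lam:7.2f} {fit.omega:.3f} {fit.r2:.3f}")
```

prints

```
NT   woFB    15.19 0.485 0.947
NT   wFB1    16.27 0.350 0.863
NT   wFB2    16.95 0.247 0.789
ASD  woFB     9.86 0.461 0.873
ASD  wFB1     9.99 0.428 0.893
ASD  wFB2     9.79 0.420 0.844
```

Read: both groups start with a cardinal-heavy allocation (`ω ≈ 0.5`,
matching natural-scene orientation statistics); with feedback under a
uniform stimulus distribution the neurotypical group gains capacity
(`λ` 15.2 → 17.0) and flattens its allocation (`ω` 0.49 → 0.25), while the
ASD group starts with ~2/3 the capacity and barely changes — the encoding
phenotype the package is designed to quantify. The `examples/` directory
walks through each capability (simulation, profiles, extraction, fits,
group inference) as short narrative scripts.

A thin CLI mirrors the library for shell use:

```bash
psyfi simulate --seed 0 --out trials.csv
psyfi profile trials.csv --group NT --block woFB --out profile.csv
psyfi fit profile.csv
psyfi group-stats trials.csv --statistic total_sqrt_fi
```

## Documentation

`docs/methods.md` describes the model, the conventions (doubled-angle
statistics, variance scales, the internal-noise calibration), what the
synthetic observers do and do not emulate, and known limitations.
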