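# dsampsize

Discrimination-based sample size calculations for multivariable prognostic
models of time-to-event data.

Most sample size guidance for prognostic survival studies (e.g. "10 events
per variable") is about the bias and coverage of individual model
coefficients. When the purpose of a model is to *predict outcome*, what
matters instead is its prognostic ability. `dsampsize` sizes studies on the
discrimination of the model as a whole, quantified by the Royston–Sauerbrei
**D statistic**: the log hazard ratio between the two equal-sized prognostic
groups obtained by splitting the model's prognostic index (PI) at its median.
For a normally distributed PI, D = κσ\* with κ = √(8/π) ≈ 1.60 and σ\* the SD
of the PI.

## The method

The calculations rest on a proportionality assumption: for a given model,

> e · var(D̂) = λ,

a model- and disease-specific structural constant (the variance of D is
inversely proportional to the number of events e, the information in a
censored sample). λ can be estimated two ways:

* **λ_s = e₁ · SE(D₁)²** from a previous study of the same model
  (a bootstrap SE is recommended; the model-based SE is biased downwards,
  increasingly so for large D);
* **λ_m = 2.66 + 1.26·D^1.9 − 1.65·(D·cens)^1.3**, an empirical
  approximation in a target D and the expected censoring proportion.

Given λ, the required number of events in the new study is

* **significance designs** (non-inferiority/superiority vs a fixed target
  D\*): e₂ = λ·(zz/δ)², with zz = z₁₋α + z₁₋β (one-sided) or
  z₁₋α/2 + z₁₋β (two-sided) and δ the margin;
* **precision designs** (CI half-width w for D): e₂ = λ·(z₁₋α/2/w)²,
  exactly a two-sided significance design at 50% power;
* **composite designs**: accept precision δ_abs *or* p·D, whichever is
  cheaper at each D; the worst case is the absolute calculation with λ_m
  evaluated at D = δ_abs/p.

Event counts are the ceiling of the unrounded value and patients =
⌈events/(1 − cens)⌉. Harrell's c-index can be converted to D via the fitted
relationship D = 5.50(c − 0.5) + 10.26(c − 0.5)³.

The package also estimates D from data (rank-based: the PI is replaced by
Blom rankits scaled by 1/κ and a Cox model fitted on that single constructed
covariate), computes bootstrap SEs, simulates exponential survival data with
known true D = βκ and exact event/censoring counts, and validates the
calculations by Monte-Carlo simulation of power, type-I error and CI
coverage.

## Worked example

A published liver-cancer staging study reported D = 1.01 (SE 0.09) for the
CLIP prognostic model from 538 patients with 502 events. To validate the
model on new data with a one-sided 5% non-inferiority test, 90% power and
margin δ = 0.25:

```sh
$ dsampsize sig --prior-events 502 --prior-se 0.09 \
    --sided 1 --power 0.9 --delta 0.25 --cens 0.07
lambda (study): 4.0662
zz: 2.926405
events (unrounded): 557.1571
events required: 558
patients required at 7% censoring: 600
```

λ_s = 502 × 0.09² = 4.07 (full precision is carried through — rounding λ to
4.1 first would give 562 events, not 558). Planning instead to *extend* the
model (no prior study of the extended model exists), with a target D = 1.3
and 10% censoring, to estimate D with a 95% CI of half-width 0.2:

```sh
$ dsampsize ci --target-d 1.3 --cens 0.1 --width 0.2
lambda (model): 4.6180
  from D = 1.3, censoring = 0.1 (10%)
zz: 1.959964
events (unrounded): 443.4917
events required: 444
patients required at 10% censoring: 494
```

Only a c-index in the literature? Convert it:

```sh
$ dsampsize convert --c 0.70
c: 0.700
D: 1.182
R2_D: 0.250
```

The same operations are available as library functions
(`lambda_from_study`, `lambda_from_model`, `events_significance`,
`events_ci`, `composite_events`, `estimate_d`, `bootstrap_se`, `c_to_d`, …),
plus `grid` for sample-size tables over ranges of D and censoring,
`composite` for the combined absolute/relative design, `simulate` for
synthetic datasets and `validate` for the Monte-Carlo harness. See
`docs/methods.md` for the underlying model and its assumptions.

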