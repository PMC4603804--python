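# Methods

## The D statistic

D measures the prognostic ability of a survival model as the log hazard ratio
between two equal-sized risk groups formed by splitting the model's prognostic
index (PI) at its median. Under the assumption that the PI is normally
distributed with SD σ\*, D = κσ\* with κ = √(8/π). D is estimated rank-based:

1. obtain the PI (given directly, or as the linear predictor of a Cox
   proportional-hazards fit on covariate columns — lifelines is used for the
   multivariable fit);
2. replace the PI values by expected standard-normal order statistics via
   Blom's approximation Φ⁻¹((i − 3/8)/(n + 1/4)); tied PI values receive the
   mean of the rankits of the positions they span, which keeps the scores
   exactly antisymmetric under sign flips;
3. scale the scores by 1/κ and fit a Cox model of the outcome on this single
   constructed covariate. The coefficient is D; its standard error is the
   default SE of D.

Because only ranks of the PI enter, D is invariant under any strictly
increasing transformation of the PI.

The internal single-covariate Cox fit is a vectorised Newton solver on the
partial likelihood with Efron tie handling (`_cox.py`). It exists because the
Monte-Carlo validation harness performs a subject-level bootstrap inside every
replicate — on the order of 2·10⁵ fits per study — and a general-purpose
survival package is orders of magnitude slower per fit at this problem size.
It is cross-checked against lifelines (coefficient and SE, with and without
ties) in the test suite. Newton iterations start at β = 0 with step-halving;
monotone-likelihood (separation) is capped at |β| = 50 with a warning.

The **default SE** comes from the observed information of this auxiliary fit.
The **bootstrap SE** resamples subjects (time, status, PI triples) with
replacement and takes the SD of D over replicates; replicates with fewer than
two events are skipped, and more than `reps` skips abort. The bootstrap SE is
the recommended input to λ_s, particularly for D ≥ 2 where model-based SEs
are known to be biased downwards. The bias of *this* package's default SE
need not equal that of other implementations; tests therefore check only that
the bootstrap SE tracks the empirical SD of D over replicate datasets, at a
generous tolerance.

## Sample size calculations

The proportionality assumption e·var(D̂) = λ (a structural constant for a
given model and case mix) turns a normal-theory two-sample calculation into
event counts:

| design | events |
|---|---|
| prior study carried (significance) | e₂ = λ_s/[(δ/zz)² − σ₁²], feasible only for δ > σ₁·zz |
| prior study carried (precision) | e₂ = λ_s/[(w/z₁₋α/2)² − σ₁²], feasible only for w > σ₁·z₁₋α/2 |
| fixed target D\* (significance) | e₂ = λ·(zz/δ)² |
| fixed target D\* (precision) | e₂ = λ·(z₁₋α/2/w)² |

with zz = z₁₋α + z₁₋β (one-sided non-inferiority) or z₁₋α/2 + z₁₋β
(two-sided superiority). The precision design coincides exactly with a
two-sided significance design at 50% power. The prior-carrying forms are of
limited practical use because of their feasibility floor; the package
implements them with the bound reported in both the result and the error.

Numerical conventions, chosen once and applied everywhere:

* normal quantiles at full double precision (scipy), never 2-dp table values
  — the ceiling step is sensitive near .5 boundaries (e.g. 443.49 → 444);
* λ is never rounded before use; display rounding is 1–2 dp only.
  (λ_s = 4.0662 gives 558 events; the displayed "4.1" would give 562);
* events = ⌈raw⌉ with a one-ulp guard so exact integers are not bumped;
* patients = ⌈events/(1 − cens)⌉.

**Composite designs.** Specifying precision as "δ_abs or p·D, whichever is
cheaper at each value of D" bounds the loss of precision in both directions
when the realised D is uncertain. The event requirement as a function of D is
the lower envelope of the absolute curve (increasing in D through λ_m) and
the relative curve (decreasing, since λ_m grows slower than (pD)²); the
envelope peaks where they cross, at D = δ_abs/p, so the worst-case sample
size is the absolute calculation with λ_m evaluated there. The achieved
margin for any other D and a fixed event count inverts the significance
formula: δ = zz·√(λ_m(D, cens)/e).

**λ_m validity.** The approximation λ_m = 2.66 + 1.26·D^1.9 − 1.65·(D·cens)^1.3
is an empirical fit; the package warns (does not fail) outside D ∈ [0.1, 3.5]
or cens > 0.9, roughly the span of values observed in published models. Note
λ_m is not monotone in D immediately above D = 0.1 when censoring is heavy
(≳0.5): the (D·cens)^1.3 term has unbounded slope at 0. This is a property of
the fitted form, not of λ itself.

**c-index conversion.** D = 5.50(c − 0.5) + 10.26(c − 0.5)³, fitted to
published paired (c, D) values; valid for c ∈ [0.5, 1]. R²_D, the
explained-variation companion of D, is (D²/κ²)/(π²/6 + D²/κ²). The published
3-dp conversion grid reproduces to within one unit in the last printed digit
(21 of 22 D values round identically; the c = 0.88 row prints 2.652 where the
full-precision polynomial gives 2.65299, presumably reflecting unrounded
coefficients on the source side).

## Synthetic data

The generator emulates the setting the calculations were derived for:
exponential survival with a single standard-normal covariate. Event times are
drawn by inverting the cumulative hazard, T_s = −log(U)·exp(−βX)/h₀ with
U ~ U(0,1) and X ~ N(0,1), so the PI βX is exactly normal and the true D of
the generating model is βκ. The baseline hazard defaults to 1: D and all the
calculations are invariant to the time scale, so h₀ is purely a unit choice.

Censoring is random and non-informative: exponential censoring times
independent of X, a record being censored when T_c < T_s. The censoring rate
is solved numerically so that P(T_c < T_s) = E_X[h_c/(h_c + h₀e^{βX})] equals
the target proportion (Gauss–Hermite quadrature, 80 nodes, plus a bracketing
root finder on log h_c).

Datasets with an *exact* number of events e and censoring proportion are
produced by oversampling: generate a pool of 2·e/(1 − cens) records, then
draw exactly e events and round(e/(1 − cens)) − e censored records without
replacement (pool doubled and redrawn on shortfall, bounded attempts). A
single seeded generator drives draws and subsampling, so every dataset is
reproducible from its seed. Non-integer e/(1 − cens) is rounded to nearest.

What the generator does *not* emulate: non-exponential baselines,
non-normal or discrete prognostic indices, informative censoring, covariate
measurement error, or model-selection optimism. Passing tests therefore show
that the calculations are internally consistent under their own assumptions,
not that real studies with misspecified models will achieve nominal power.

## Monte-Carlo validation

The harness reproduces the power/type-I and coverage experiments behind the
calculations. For study-based designs (B1/D1) it first simulates a "first
study" with e₁ events, bootstraps SE(D₁), and forms λ_s; for model-based
designs (B2/D2) it evaluates λ_m at the target D and censoring. It then
computes e₂ and, per replicate, simulates an exact-e₂-event dataset,
estimates D and its bootstrap SE, and applies a Wald test:

* one-sided non-inferiority (H₀: D\* − D₂ ≥ δ): reject when
  (D̂ − (D\* − δ))/ŝe > z₁₋α; the type-I arm generates at the null boundary
  D\* − δ, the power arm at D\*;
* two-sided: reject when |D̂ − D\*|/ŝe > z₁₋α/2; the type-I arm generates at
  D\*, the power arm at D\* − δ.

This is the unique Wald construction consistent with the zz definition of
the designs. Coverage (D1/D2) is the fraction of replicates with
|D̂ − βκ| ≤ w, which should approximate 1 − α.

Defaults are desk-scale: 500 replications and 200 bootstrap replications
(both configurable and logged); the acceptance-level checks in the test
suite run at these sizes, and binomial Monte-Carlo SEs √(p(1−p)/reps)
accompany every observed proportion. Because λ_m is an approximation, the
model-based designs carry a small systematic power error (absolute errors of
a couple of percent at 80% nominal are expected); the test bands account for
this on top of Monte-Carlo noise.

## Known limitations

* No case-mix/transportability adjustment: development and validation
  populations are assumed to share the covariate distribution.
* No events-per-variable reasoning: the calculations are silent on the number
  of candidate variables and on selection-induced optimism in D.
* No competing risks, time-dependent covariates, or non-exponential baseline
  generators.
* The prior-carrying designs are implemented for completeness but their
  feasibility floor (δ > σ₁·zz) makes them rarely usable in practice; the
  fixed-target designs are the recommended default, with the study-based λ
  reserved for validation settings with a reliable prior study.
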