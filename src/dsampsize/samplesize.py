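"""Sample size calculations for prognostic survival studies based on the D statistic.

The calculations rest on a proportionality assumption: for a given model, the
product of the number of events and the variance of the D discrimination
statistic is a structural constant, lambda = e * var(D).  lambda can be
estimated from a prior study (``lambda_from_study``) or from an empirical
approximation in a target D and the censoring proportion
(``lambda_from_model``).  Given lambda, the number of events needed to test D
against a fixed target (significance designs) or to estimate D with a given
confidence-interval half-width (precision designs) follows from normal theory.

All intermediate quantities are kept at full double precision; only displayed
values are rounded.  Event counts are the ceiling of the unrounded formula
value, and patient counts are ``ceil(events / (1 - censoring))``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import FeasibilityError, InvalidInputError

__all__ = [
    "KAPPA",
    "PriorStudy",
    "DesignSpec",
    "LambdaEstimate",
    "SampleSizeResult",
    "CompositeResult",
    "lambda_from_study",
    "lambda_from_model",
    "zz_quantile",
    "events_significance",
    "events_ci",
    "events_with_prior",
    "composite_events",
    "achieved_margin",
    "patients_from_events",
]

#: kappa = sqrt(8/pi) ~ 1.596: scaling constant linking D to the SD of the
#: prognostic index; also the true D per unit log hazard ratio of a standard
#: normal covariate.
KAPPA = math.sqrt(8.0 / math.pi)

# coefficients of the empirical model lambda_m = c0 + c1*D^1.9 + c2*(D*cens)^1.3
_LAMBDA_C0 = 2.66
_LAMBDA_C1 = 1.26
_LAMBDA_C2 = -1.65

Sidedness = Literal["one-sided", "two-sided"]

# fitted region of the lambda_m approximation; outside it we warn, not fail
_LAMBDA_D_LO, _LAMBDA_D_HI, _LAMBDA_CENS_HI = 0.1, 3.5, 0.9

_CEIL_EPS = 1e-9


def _ceil(x: float) -> int:
    """Ceiling with a one-ulp guard so exact integers are not bumped up."""
    return int(math.ceil(x - _CEIL_EPS))


def _norm_sidedness(sidedness) -> Sidedness:
    s = str(sidedness).lower()
    if s in {"1", "one", "one-sided", "one_sided"}:
        return "one-sided"
    if s in {"2", "two", "two-sided", "two_sided"}:
        return "two-sided"
    raise InvalidInputError(f"unrecognised sidedness: {sidedness!r}")


def _check_prob(name: str, value: float) -> None:
    if not (0.0 < value < 1.0):
        raise InvalidInputError(f"{name} must lie strictly in (0, 1), got {value}")


def _check_cens(value: float) -> None:
    if not (0.0 <= value < 1.0):
        raise InvalidInputError(f"censoring must lie in [0, 1), got {value}")


@dataclass(frozen=True)
class PriorStudy:
    """Results of a previous study of the same prognostic model.

    Parameters
    ----------
    events : int
        Number of observed events e1 in the prior study.
    se_d1 : float
        Standard error of the prior D estimate (a bootstrap SE is
        recommended, particularly when D >= 2, as the default model-based SE
        is biased downwards for large D).
    d1 : float, optional
        The prior D value itself; informational, not used by the lambda
        calculation.
    censoring : float, optional
        Censoring proportion in the prior study.
    """

    events: int
    se_d1: float
    d1: Optional[float] = None
    censoring: float = 0.0

    def __post_init__(self):
        if int(self.events) != self.events or self.events < 1:
            raise InvalidInputError(f"events must be a positive integer, got {self.events}")
        if not self.se_d1 > 0:
            raise InvalidInputError(f"se_d1 must be > 0, got {self.se_d1}")
        _check_cens(self.censoring)

    @property
    def sigma1_sq(self) -> float:
        return self.se_d1**2


@dataclass(frozen=True)
class DesignSpec:
    """Design parameters of the planned study.

    Exactly one of ``margin`` (significance designs, non-inferiority margin
    delta) or ``halfwidth`` (precision designs, CI half-width w) must be set
    for any single calculation.  ``power`` applies to significance designs
    only.  All probabilities are proportions, not percentages.
    """

    alpha: float = 0.05
    sidedness: str = "two-sided"
    power: Optional[float] = None
    margin: Optional[float] = None
    halfwidth: Optional[float] = None
    censoring: float = 0.0
    target_d: Optional[float] = None

    def __post_init__(self):
        _check_prob("alpha", self.alpha)
        object.__setattr__(self, "sidedness", _norm_sidedness(self.sidedness))
        if self.power is not None:
            _check_prob("power", self.power)
        if self.margin is not None and self.margin <= 0:
            raise InvalidInputError(f"margin must be > 0, got {self.margin}")
        if self.halfwidth is not None and self.halfwidth <= 0:
            raise InvalidInputError(f"halfwidth must be > 0, got {self.halfwidth}")
        _check_cens(self.censoring)
        if self.target_d is not None and self.target_d < 0:
            raise InvalidInputError(f"target_d must be >= 0, got {self.target_d}")

    def _require(self, which: str) -> float:
        if self.margin is not None and self.halfwidth is not None:
            raise InvalidInputError("set exactly one of margin and halfwidth")
        value = getattr(self, which)
        if value is None:
            raise InvalidInputError(f"this calculation requires design.{which}")
        return value


@dataclass(frozen=True)
class LambdaEstimate:
    """A value of the structural constant lambda = e * var(D), with provenance."""

    value: float
    source: Literal["study", "model"]
    d_input: Optional[float] = None
    cens_input: Optional[float] = None

    def __post_init__(self):
        if not self.value > 0:
            raise InvalidInputError(f"lambda must be > 0, got {self.value}")


@dataclass(frozen=True)
class SampleSizeResult:
    """Required events and patients, with the unrounded intermediates."""

    events: int
    patients: int
    lam: LambdaEstimate
    zz: float
    raw_events: float
    censoring: float = 0.0
    min_margin: Optional[float] = None  # feasibility bound, prior-based designs only


@dataclass(frozen=True)
class CompositeResult:
    """Maximum sample size of a combined absolute/relative precision design."""

    peak_d: float
    lambda_peak: LambdaEstimate
    events: int
    result: SampleSizeResult
    profile: pd.DataFrame = field(repr=False)


def lambda_from_study(prior: PriorStudy) -> LambdaEstimate:
    """lambda_s = e1 * SE(D1)^2, the study-based estimate of lambda.

    The returned value is unrounded; downstream sample sizes must use the
    full-precision value (rounding lambda first visibly changes event counts).
    """
    return LambdaEstimate(value=prior.events * prior.se_d1**2, source="study")


def lambda_from_model(d: float, cens: float) -> LambdaEstimate:
    """Model-based lambda from a target D and expected censoring proportion.

    Evaluates the empirical approximation
    ``lambda_m = 2.66 + 1.26 d^1.9 - 1.65 (d*cens)^1.3``.
    The fit is only supported over the range of D values seen in practice;
    a warning (not an error) is issued outside d in [0.1, 3.5] or cens > 0.9.
    """
    if d < 0:
        raise InvalidInputError(f"target D must be >= 0, got {d}")
    _check_cens(cens)
    if d < _LAMBDA_D_LO or d > _LAMBDA_D_HI or cens > _LAMBDA_CENS_HI:
        warnings.warn(
            f"lambda_m evaluated outside its fitted region (d={d}, cens={cens}); "
            "treat the result with caution",
            UserWarning,
            stacklevel=2,
        )
    value = _LAMBDA_C0 + _LAMBDA_C1 * d**1.9 + _LAMBDA_C2 * (d * cens) ** 1.3
    return LambdaEstimate(value=value, source="model", d_input=d, cens_input=cens)


def zz_quantile(alpha: float, sidedness, power: float) -> float:
    """Sum of standard-normal quantiles zz = z_{1-alpha[/2]} + z_{1-beta}."""
    _check_prob("alpha", alpha)
    _check_prob("power", power)
    side = _norm_sidedness(sidedness)
    a = alpha / 2 if side == "two-sided" else alpha
    return float(stats.norm.ppf(1 - a) + stats.norm.ppf(power))


def patients_from_events(events: int, cens: float) -> int:
    """Patients needed so that the expected number of events is reached."""
    if events < 1:
        raise InvalidInputError(f"events must be >= 1, got {events}")
    _check_cens(cens)
    return _ceil(events / (1.0 - cens))


def _package(raw: float, lam: LambdaEstimate, zz: float, cens: float,
             min_margin: Optional[float] = None) -> SampleSizeResult:
    events = max(_ceil(raw), 1)
    return SampleSizeResult(
        events=events,
        patients=patients_from_events(events, cens),
        lam=lam,
        zz=zz,
        raw_events=raw,
        censoring=cens,
        min_margin=min_margin,
    )


def events_significance(lam: LambdaEstimate, design: DesignSpec) -> SampleSizeResult:
    """Events for a significance design: e2 = lambda * (zz / delta)^2.

    One-sided designs test non-inferiority against a fixed target D* with
    margin delta; two-sided designs test superiority.
    """
    delta = design._require("margin")
    if design.power is None:
        raise InvalidInputError("significance designs require design.power")
    zz = zz_quantile(design.alpha, design.sidedness, design.power)
    raw = lam.value * (zz / delta) ** 2
    return _package(raw, lam, zz, design.censoring)


def events_ci(lam: LambdaEstimate, design: DesignSpec) -> SampleSizeResult:
    """Events so the new D has a 100(1-alpha)% CI of half-width w.

    e2 = lambda * (z_{1-alpha/2} / w)^2.  Equivalent to a two-sided
    significance design with delta = w and 50% power.
    """
    w = design._require("halfwidth")
    z = float(stats.norm.ppf(1 - design.alpha / 2))
    raw = lam.value * (z / w) ** 2
    return _package(raw, lam, z, design.censoring)


def events_with_prior(prior: PriorStudy, design: DesignSpec,
                      mode: Literal["significance", "ci"]) -> SampleSizeResult:
    """Events when the prior D's own uncertainty is carried into the design.

    e2 = lambda_s / ((delta/zz)^2 - sigma1^2) (significance), or the w/z
    analogue (ci).  Feasible only when delta > sigma1*zz (resp. w > sigma1*z);
    the bound is returned with the result and enforced with a
    :class:`FeasibilityError`.
    """
    lam = lambda_from_study(prior)
    s1sq = prior.sigma1_sq
    if mode == "significance":
        delta = design._require("margin")
        if design.power is None:
            raise InvalidInputError("significance designs require design.power")
        zz = zz_quantile(design.alpha, design.sidedness, design.power)
    elif mode == "ci":
        delta = design._require("halfwidth")
        zz = float(stats.norm.ppf(1 - design.alpha / 2))
    else:
        raise InvalidInputError(f"mode must be 'significance' or 'ci', got {mode!r}")
    bound = prior.se_d1 * zz
    if delta <= bound:
        raise FeasibilityError(
            f"margin/half-width {delta} is not attainable: must exceed "
            f"se_d1 * zz = {bound:.6g}",
            minimum=bound,
        )
    raw = lam.value / ((delta / zz) ** 2 - s1sq)
    return _package(raw, lam, zz, design.censoring, min_margin=bound)


def _lambda_model_quiet(d: float, cens: float) -> LambdaEstimate:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return lambda_from_model(d, cens)


def composite_events(delta_abs: float, p: float, design: DesignSpec,
                     mode: Literal["significance", "ci"] = "significance",
                     d_grid: Optional[np.ndarray] = None) -> CompositeResult:
    """Maximum events over a combined absolute/relative precision profile.

    The precision requirement is delta = min over the absolute value
    ``delta_abs`` and the relative value ``p * D``; per value of D the smaller
    of the two implied sample sizes is accepted.  The profile peaks where the
    curves cross, at D = delta_abs / p, and the maximum sample size is the
    absolute-margin calculation evaluated with lambda_m at that D.
    """
    if not (0.0 < p < 1.0):
        raise InvalidInputError(f"p must lie strictly in (0, 1), got {p}")
    if delta_abs <= 0:
        raise InvalidInputError(f"delta_abs must be > 0, got {delta_abs}")
    peak_d = delta_abs / p
    lam_peak = _lambda_model_quiet(peak_d, design.censoring)

    if mode == "significance":
        design_abs = replace(design, margin=delta_abs, halfwidth=None)
        calc = events_significance
    else:
        design_abs = replace(design, halfwidth=delta_abs, margin=None)
        calc = events_ci
    at_peak = calc(lam_peak, design_abs)

    if d_grid is None:
        d_grid = np.round(np.arange(0.1, 3.01, 0.05), 10)
    rows = []
    for d in np.asarray(d_grid, dtype=float):
        lam_d = _lambda_model_quiet(d, design.censoring)
        e_abs = calc(lam_d, design_abs).events
        if mode == "significance":
            design_rel = replace(design, margin=p * d, halfwidth=None)
        else:
            design_rel = replace(design, halfwidth=p * d, margin=None)
        e_rel = calc(lam_d, design_rel).events
        rows.append((d, lam_d.value, e_abs, e_rel, min(e_abs, e_rel)))
    profile = pd.DataFrame(
        rows, columns=["d", "lambda_m", "events_absolute", "events_relative",
                       "events_composite"],
    )
    return CompositeResult(
        peak_d=peak_d,
        lambda_peak=lam_peak,
        events=at_peak.events,
        result=at_peak,
        profile=profile,
    )


def achieved_margin(events: int, d: float, cens: float, alpha: float = 0.05,
                    sidedness="two-sided", power: float = 0.9) -> float:
    """Smallest detectable margin delta with a fixed number of events.

    Inverts the significance calculation: delta = zz * sqrt(lambda_m(d, cens)
    / events).  Useful for reporting the precision actually achieved if the
    realised D differs from the one the study was sized for.
    """
    if events < 1:
        raise InvalidInputError(f"events must be >= 1, got {events}")
    zz = zz_quantile(alpha, sidedness, power)
    lam = _lambda_model_quiet(d, cens)
    return float(zz * math.sqrt(lam.value / events))
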