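"""Monte-Carlo validation of the sample size calculations.

Two harnesses check, by simulation, that the event counts produced by the
significance designs deliver their nominal power and type-I error, and that
the precision designs deliver nominal CI coverage.  Calculations B1/D1 start
from a simulated "first study" whose bootstrap SE yields a study-based lambda;
B2/D2 use the model-based lambda directly.

Test statistic (Wald, consistent with the zz construction of the designs):

* one-sided non-inferiority, H0: D* - D2 >= delta — reject when
  (Dhat - (D* - delta)) / se(Dhat) > z_{1-alpha}; the type-I arm generates
  data at the null boundary D* - delta and the power arm at D*.
* two-sided superiority — reject when |Dhat - D*| / se(Dhat) > z_{1-alpha/2};
  the type-I arm generates at D* and the power arm at D* - delta.

se(Dhat) is the subject-level bootstrap SE throughout, as recommended for
lambda estimation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
from scipy import stats

from . import samplesize as ss
from .discrimination import bootstrap_se, estimate_d
from .exceptions import InvalidInputError
from .simulate import SimulationSpec, exact_event_dataset

__all__ = ["ValidationConfig", "ValidationResult", "run_significance_study",
           "run_coverage_study"]

Calculation = Literal["B1", "B2", "D1", "D2"]


@dataclass(frozen=True)
class ValidationConfig:
    """Parameters of one Monte-Carlo validation experiment."""

    calculation: Calculation
    target_d: float
    alpha: float = 0.05
    sidedness: str = "two-sided"
    power: Optional[float] = None      # B1/B2
    delta: Optional[float] = None      # B1/B2
    width: Optional[float] = None      # D1/D2
    censoring: float = 0.0
    replications: int = 500
    boot_reps: int = 200
    first_study_events: Optional[int] = None  # B1/D1
    seed: Optional[int] = None

    def __post_init__(self):
        if self.calculation not in ("B1", "B2", "D1", "D2"):
            raise InvalidInputError(f"unknown calculation {self.calculation!r}")
        if self.replications < 2:
            raise InvalidInputError("replications must be >= 2")
        if self.target_d < 0:
            raise InvalidInputError("target_d must be >= 0")
        if self.calculation in ("B1", "B2") and (self.delta is None or self.power is None):
            raise InvalidInputError("B1/B2 require delta and power")
        if self.calculation in ("D1", "D2") and self.width is None:
            raise InvalidInputError("D1/D2 require width")
        if self.calculation in ("B1", "D1") and self.first_study_events is None:
            raise InvalidInputError("B1/D1 require first_study_events")


@dataclass(frozen=True)
class ValidationResult:
    """Observed operating characteristics with binomial Monte-Carlo SEs."""

    e2_used: int
    replications: int
    lambda_used: ss.LambdaEstimate
    observed_type1: Optional[float] = None
    se_type1: Optional[float] = None
    observed_power: Optional[float] = None
    se_power: Optional[float] = None
    observed_coverage: Optional[float] = None
    se_coverage: Optional[float] = None
    n_boot: Optional[int] = None


def _prop_se(p: float, reps: int) -> float:
    return float(np.sqrt(p * (1.0 - p) / reps))


def _lambda_for(config: ValidationConfig, rng: np.random.Generator) -> ss.LambdaEstimate:
    if config.calculation in ("B2", "D2"):
        return ss.lambda_from_model(config.target_d, config.censoring)
    # B1/D1: simulate the prior study and bootstrap its SE of D
    e1 = int(config.first_study_events)
    spec = SimulationSpec(
        beta=config.target_d / ss.KAPPA,
        target_events=e1,
        target_censoring=config.censoring,
    )
    first = exact_event_dataset(spec, rng=rng)
    se1 = bootstrap_se(first, reps=config.boot_reps, rng=rng)
    return ss.lambda_from_study(ss.PriorStudy(events=e1, se_d1=se1))


def _simulate_dhat(true_d: float, e2: int, cens: float,
                   rng: np.random.Generator, boot_reps: Optional[int]):
    spec = SimulationSpec(
        beta=true_d / ss.KAPPA, target_events=e2, target_censoring=cens
    )
    data = exact_event_dataset(spec, rng=rng)
    est = estimate_d(data)
    se = bootstrap_se(data, reps=boot_reps, rng=rng) if boot_reps else est.se_default
    return est.d, se


def run_significance_study(config: ValidationConfig) -> ValidationResult:
    """Observed type-I error and power of a B1/B2 design."""
    if config.calculation not in ("B1", "B2"):
        raise InvalidInputError("run_significance_study handles B1/B2 only")
    rng = np.random.default_rng(config.seed)
    lam = _lambda_for(config, rng)
    design = ss.DesignSpec(
        alpha=config.alpha, sidedness=config.sidedness, power=config.power,
        margin=config.delta, censoring=config.censoring,
    )
    e2 = max(ss.events_significance(lam, design).events, 2)
    d_star, delta = config.target_d, config.delta
    one_sided = design.sidedness == "one-sided"
    z_crit = float(stats.norm.ppf(1 - config.alpha / (1 if one_sided else 2)))
    if one_sided:
        d_null, d_alt = d_star - delta, d_star
    else:
        d_null, d_alt = d_star, d_star - delta

    rejections = {"null": 0, "alt": 0}
    for arm, true_d in (("null", d_null), ("alt", d_alt)):
        for _ in range(config.replications):
            dhat, se = _simulate_dhat(
                true_d, e2, config.censoring, rng, config.boot_reps
            )
            if one_sided:
                reject = (dhat - (d_star - delta)) / se > z_crit
            else:
                reject = abs(dhat - d_star) / se > z_crit
            rejections[arm] += reject
    type1 = rejections["null"] / config.replications
    power = rejections["alt"] / config.replications
    return ValidationResult(
        e2_used=e2,
        replications=config.replications,
        lambda_used=lam,
        observed_type1=type1,
        se_type1=_prop_se(type1, config.replications),
        observed_power=power,
        se_power=_prop_se(power, config.replications),
        n_boot=config.boot_reps,
    )


def run_coverage_study(config: ValidationConfig) -> ValidationResult:
    """Observed CI coverage of a D1/D2 design.

    Per replicate a dataset with the required number of events is simulated at
    the target D; coverage is the fraction of replicates with
    |Dhat - beta*kappa| <= w, which should approximate 1 - alpha.
    """
    if config.calculation not in ("D1", "D2"):
        raise InvalidInputError("run_coverage_study handles D1/D2 only")
    rng = np.random.default_rng(config.seed)
    lam = _lambda_for(config, rng)
    design = ss.DesignSpec(
        alpha=config.alpha, halfwidth=config.width, censoring=config.censoring,
    )
    e2 = max(ss.events_ci(lam, design).events, 2)
    covered = 0
    for _ in range(config.replications):
        dhat, _ = _simulate_dhat(
            config.target_d, e2, config.censoring, rng, boot_reps=None
        )
        covered += abs(dhat - config.target_d) <= config.width
    coverage = covered / config.replications
    return ValidationResult(
        e2_used=e2,
        replications=config.replications,
        lambda_used=lam,
        observed_coverage=coverage,
        se_coverage=_prop_se(coverage, config.replications),
        n_boot=config.boot_reps,
    )
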