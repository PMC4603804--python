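"""Synthetic survival data with known true D, exact event counts and censoring.

Event times follow an exponential proportional-hazards model with a single
standard-normal covariate X and log hazard ratio beta, generated by inverting
the cumulative hazard: ``T_s = -log(U) exp(-beta X) / h0`` with U ~ U(0,1).
The prognostic index beta*X is then exactly normal and the true D of the
generating model is ``beta * kappa``.

Censoring is random and non-informative: censoring times are exponential with
a rate chosen (numerically) so that the probability a record is censored
matches the target proportion.  Datasets with an *exact* number of events and
censored records are obtained by oversampling and subsampling: generate a pool
of twice the required size, then draw exactly e events and round(e/(1-cens))-e
censored records from it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize

from .discrimination import SurvivalSample
from .exceptions import InvalidInputError, SimulationError
from .samplesize import KAPPA

__all__ = ["SimulationSpec", "solve_censoring_rate", "draw_survival_times",
           "exact_event_dataset"]

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(80)
_POOL_FACTOR = 2.0
_MAX_ATTEMPTS = 6


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of the generating model.

    Parameters
    ----------
    beta : float
        Log hazard ratio per unit of X ~ N(0,1); true D = beta * kappa.
    target_events : int
        Exact number of events the final dataset must contain.
    target_censoring : float
        Censoring proportion in [0, 1); exact up to integer rounding of the
        censored-record count.
    baseline_hazard : float
        Rate of the exponential baseline; D is invariant to the time scale, so
        the default of 1 is purely a choice of units.
    censoring_rate : float, optional
        Exponential rate of the censoring distribution.  When omitted it is
        solved so that P(censored) equals ``target_censoring`` before exact
        subsampling.
    seed : int, optional
        Seed for the single generator driving the whole run (draws and
        subsampling share one stream).
    """

    beta: float
    target_events: int = 100
    target_censoring: float = 0.0
    baseline_hazard: float = 1.0
    censoring_rate: Optional[float] = None
    seed: Optional[int] = None

    def __post_init__(self):
        if not np.isfinite(self.beta):
            raise InvalidInputError("beta must be finite")
        if self.baseline_hazard <= 0:
            raise InvalidInputError("baseline_hazard must be > 0")
        if int(self.target_events) != self.target_events or self.target_events < 2:
            raise InvalidInputError("target_events must be an integer >= 2")
        if not (0.0 <= self.target_censoring < 1.0):
            raise InvalidInputError("target_censoring must lie in [0, 1)")
        if self.censoring_rate is not None and self.censoring_rate <= 0:
            raise InvalidInputError("censoring_rate must be > 0")

    @property
    def true_d(self) -> float:
        return self.beta * KAPPA


def solve_censoring_rate(beta: float, target_censoring: float,
                         baseline_hazard: float = 1.0) -> float:
    """Exponential censoring rate giving the target censoring probability.

    A record is censored when T_c < T_s; marginalising over X ~ N(0,1),
    ``P(censored) = E_X[ hc / (hc + h0 exp(beta X)) ]``, evaluated by
    Gauss-Hermite quadrature and inverted with a bracketing root finder.
    The probability is increasing in hc, from 0 to 1.
    """
    if not (0.0 <= target_censoring < 1.0):
        raise InvalidInputError("target_censoring must lie in [0, 1)")
    if target_censoring == 0.0:
        return 0.0
    hx = baseline_hazard * np.exp(beta * math.sqrt(2.0) * _GH_NODES)
    weights = _GH_WEIGHTS / math.sqrt(math.pi)

    def prob_censored(log_hc: float) -> float:
        hc = math.exp(log_hc)
        return float(np.sum(weights * hc / (hc + hx))) - target_censoring

    lo, hi = -40.0, 40.0
    return math.exp(optimize.brentq(prob_censored, lo, hi, xtol=1e-12))


def _resolve_rate(spec: SimulationSpec) -> float:
    if spec.target_censoring == 0.0:
        return 0.0
    if spec.censoring_rate is not None:
        return spec.censoring_rate
    return solve_censoring_rate(spec.beta, spec.target_censoring, spec.baseline_hazard)


def draw_survival_times(spec: SimulationSpec, n: int,
                        rng: Optional[np.random.Generator] = None) -> SurvivalSample:
    """Draw n subjects from the generating model (no exact-count control).

    Returns a :class:`SurvivalSample` whose ``pi`` column is the true
    prognostic index beta*X of the generating model.
    """
    if n < 1:
        raise InvalidInputError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    x = rng.standard_normal(n)
    u = rng.uniform(size=n)
    t_event = -np.log(u) * np.exp(-spec.beta * x) / spec.baseline_hazard
    rate = _resolve_rate(spec)
    if rate > 0.0:
        t_cens = rng.exponential(scale=1.0 / rate, size=n)
        status = (t_event <= t_cens).astype(float)
        time = np.minimum(t_event, t_cens)
    else:
        status = np.ones(n)
        time = t_event
    return SurvivalSample(time=time, status=status, pi=spec.beta * x)


def exact_event_dataset(spec: SimulationSpec,
                        rng: Optional[np.random.Generator] = None) -> SurvivalSample:
    """Dataset with exactly ``target_events`` events and the target censoring.

    A pool of ``2 * target_events / (1 - cens)`` records with approximately the
    right censoring proportion is generated, then exactly e events and
    ``round(e / (1 - cens)) - e`` censored records are drawn from it without
    replacement.  If the pool is short of either kind the draw is retried with
    a doubled pool, a bounded number of times.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    e = int(spec.target_events)
    cens = spec.target_censoring
    n_total = int(round(e / (1.0 - cens)))
    n_censored = n_total - e
    factor = _POOL_FACTOR
    for _ in range(_MAX_ATTEMPTS):
        pool_n = max(int(math.ceil(factor * e / (1.0 - cens))), n_total)
        pool = draw_survival_times(spec, pool_n, rng=rng)
        ev_idx = np.flatnonzero(pool.status == 1.0)
        cs_idx = np.flatnonzero(pool.status == 0.0)
        if ev_idx.size >= e and cs_idx.size >= n_censored:
            take = np.concatenate([
                rng.choice(ev_idx, size=e, replace=False),
                rng.choice(cs_idx, size=n_censored, replace=False),
            ])
            return pool.subset(np.sort(take))
        factor *= 2.0
    raise SimulationError(
        f"could not assemble {e} events and {n_censored} censored records "
        f"after {_MAX_ATTEMPTS} attempts"
    )
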