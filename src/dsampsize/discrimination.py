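"""Estimation of the D discrimination statistic and conversions to c and R2_D.

D quantifies the prognostic separation of a survival model: it is the log
hazard ratio between the two prognostic groups obtained by splitting the
model's prognostic index (PI) at its median, and equals kappa * sigma* where
sigma* is the SD of a normally distributed PI and kappa = sqrt(8/pi).

Estimation is rank-based: the PI values are replaced by scaled expected
standard-normal order statistics (rankits, Blom's approximation), divided by
kappa, and a Cox model of the outcome on this single constructed covariate is
fitted.  Its coefficient is D and its standard error the default SE of D.
A subject-level bootstrap SE is provided as well and is preferred for large D,
where the model-based SE is biased downwards.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._cox import cox_fit_1d
from .exceptions import EstimationError, InvalidInputError
from .samplesize import KAPPA

__all__ = [
    "SurvivalSample",
    "DiscriminationEstimate",
    "rankits",
    "estimate_d",
    "bootstrap_se",
    "c_to_d",
    "d_to_r2",
    "conversion_table",
    "read_survival_data",
]


@dataclass(frozen=True)
class SurvivalSample:
    """Per-subject follow-up time, event status and prognostic index."""

    time: np.ndarray
    status: np.ndarray
    pi: np.ndarray

    def __post_init__(self):
        time = np.asarray(self.time, dtype=float)
        status = np.asarray(self.status, dtype=float)
        pi = np.asarray(self.pi, dtype=float)
        if not (time.shape == status.shape == pi.shape) or time.ndim != 1:
            raise InvalidInputError("time, status and pi must be equal-length 1-d arrays")
        if time.size == 0:
            raise InvalidInputError("empty sample")
        if not np.all(np.isfinite(time)) or not np.all(time > 0):
            raise InvalidInputError("times must be finite and strictly positive")
        if not np.all(np.isin(status, (0.0, 1.0))):
            raise InvalidInputError("status must be 0/1")
        if not np.all(np.isfinite(pi)):
            raise InvalidInputError("prognostic index contains non-finite values")
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "status", status)
        object.__setattr__(self, "pi", pi)

    @property
    def n(self) -> int:
        return self.time.size

    @property
    def n_events(self) -> int:
        return int(self.status.sum())

    def subset(self, idx: np.ndarray) -> "SurvivalSample":
        return SurvivalSample(self.time[idx], self.status[idx], self.pi[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.time, "status": self.status.astype(int), "pi": self.pi}
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, time_col: str = "time",
                       status_col: str = "status", pi_col: Optional[str] = "pi",
                       covariates: Optional[Sequence[str]] = None) -> "SurvivalSample":
        """Build a sample from a data frame.

        Either ``pi_col`` names a precomputed prognostic index, or
        ``covariates`` names model terms; in the latter case a Cox
        proportional-hazards model is fitted (lifelines) and its linear
        predictor becomes the prognostic index.
        """
        cols = [time_col, status_col] + (list(covariates) if covariates else [pi_col])
        sub = df[cols]
        if sub.isna().any().any():
            raise InvalidInputError("missing values in required columns")
        if covariates:
            from lifelines import CoxPHFitter

            fit_df = sub.rename(columns={time_col: "time", status_col: "status"})
            cph = CoxPHFitter()
            cph.fit(fit_df, duration_col="time", event_col="status")
            pi = fit_df[list(covariates)].to_numpy() @ cph.params_.to_numpy()
        else:
            pi = sub[pi_col].to_numpy()
        return cls(sub[time_col].to_numpy(), sub[status_col].to_numpy(), pi)


@dataclass(frozen=True)
class DiscriminationEstimate:
    """A D estimate with its model-based and (optionally) bootstrap SE."""

    d: float
    se_default: float
    events: int
    n: int
    se_bootstrap: Optional[float] = None
    n_boot: Optional[int] = None
    n_boot_skipped: int = 0

    @property
    def r2_d(self) -> float:
        return d_to_r2(self.d)


def rankits(pi: np.ndarray) -> np.ndarray:
    """Expected standard-normal order statistics of the PI, Blom approximation.

    Position i of n maps to ``ppf((i - 3/8) / (n + 1/4))``.  Tied PI values
    receive the mean of the rankits of the positions they span, which keeps
    the construction exactly antisymmetric under sign flips of the PI.
    """
    pi = np.asarray(pi, dtype=float)
    n = pi.size
    order = np.argsort(pi, kind="stable")
    scores_sorted = stats.norm.ppf((np.arange(1, n + 1) - 0.375) / (n + 0.25))
    pi_sorted = pi[order]
    # average scores over runs of tied values
    boundaries = np.flatnonzero(np.diff(pi_sorted) != 0) + 1
    starts = np.concatenate(([0], boundaries))
    stops = np.concatenate((boundaries, [n]))
    cums = np.concatenate(([0.0], np.cumsum(scores_sorted)))
    for a, b in zip(starts, stops):
        if b - a > 1:
            scores_sorted[a:b] = (cums[b] - cums[a]) / (b - a)
    out = np.empty(n)
    out[order] = scores_sorted
    return out


def estimate_d(sample: SurvivalSample) -> DiscriminationEstimate:
    """Estimate D and its default SE from a survival sample.

    The PI is transformed to rankits scaled by 1/kappa and used as the sole
    covariate of a Cox model; the fitted coefficient is D on the log
    hazard-ratio scale.  The estimate depends on the PI only through its
    ranks, so it is invariant under monotone increasing transformations.
    """
    if sample.n_events < 2:
        raise EstimationError("at least 2 events are required to estimate D")
    z = rankits(sample.pi) / KAPPA
    if np.ptp(z) == 0.0:
        warnings.warn(
            "prognostic index is constant: D = 0 by construction",
            UserWarning,
            stacklevel=2,
        )
        return DiscriminationEstimate(
            d=0.0, se_default=np.nan, events=sample.n_events, n=sample.n
        )
    d, se = cox_fit_1d(sample.time, sample.status, z)
    return DiscriminationEstimate(d=d, se_default=se, events=sample.n_events, n=sample.n)


def bootstrap_se(sample: SurvivalSample, reps: int = 500,
                 seed: Optional[int] = None,
                 rng: Optional[np.random.Generator] = None) -> float:
    """Bootstrap SE of D: SD of D over subject-level resamples.

    Subjects (time, status, pi triples) are resampled with replacement;
    replicates with fewer than two events are skipped, and more than half
    skipped aborts.  Deterministic for a fixed ``seed``.
    """
    if reps < 2:
        raise InvalidInputError(f"reps must be >= 2, got {reps}")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = sample.n
    values = np.empty(reps)
    kept = 0
    skipped = 0
    while kept < reps:
        idx = rng.integers(0, n, n)
        if sample.status[idx].sum() < 2:
            skipped += 1
            if skipped > reps:
                raise EstimationError(
                    "too many bootstrap replicates with fewer than 2 events"
                )
            continue
        sub = sample.subset(idx)
        values[kept] = estimate_d(sub).d
        kept += 1
    return float(np.std(values, ddof=1))


def c_to_d(c: float) -> float:
    """Convert Harrell's c-index to D via the fitted fractional polynomial.

    ``D = 5.50 (c - 0.5) + 10.26 (c - 0.5)^3``, valid for c in [0.5, 1].
    """
    c = float(c)
    if not (0.5 <= c <= 1.0):
        raise InvalidInputError(
            f"c must lie in [0.5, 1] (negative discrimination unsupported), got {c}"
        )
    u = c - 0.5
    return 5.50 * u + 10.26 * u**3


def d_to_r2(d: float) -> float:
    """Explained-variation measure R2_D corresponding to a D value.

    ``R2_D = (d^2/kappa^2) / (pi^2/6 + d^2/kappa^2)``; strictly increasing in
    |d| and bounded in [0, 1).
    """
    s2 = float(d) ** 2 / KAPPA**2
    return s2 / (math.pi**2 / 6.0 + s2)


def conversion_table(c_values: Optional[np.ndarray] = None) -> pd.DataFrame:
    """Tabulate the (c, D, R2_D) relationship over a grid of c values."""
    if c_values is None:
        c_values = np.round(np.arange(0.50, 0.9201, 0.02), 10)
    c_values = np.asarray(c_values, dtype=float)
    d = np.array([c_to_d(c) for c in c_values])
    r2 = np.array([d_to_r2(x) for x in d])
    return pd.DataFrame({"c": c_values, "d": d, "r2_d": r2})


def read_survival_data(path, time_col: str = "time", status_col: str = "status",
                       pi_col: Optional[str] = "pi",
                       covariates: Optional[Sequence[str]] = None,
                       sep: Optional[str] = None) -> SurvivalSample:
    """Read a delimited text file (CSV/TSV; delimiter sniffed if not given)."""
    df = pd.read_csv(path, sep=sep, engine="python", comment="#")
    return SurvivalSample.from_dataframe(
        df, time_col=time_col, status_col=status_col, pi_col=pi_col,
        covariates=covariates,
    )
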