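"""Reporting helpers: sample-size grids, the design decision flow, run records."""

from __future__ import annotations

import dataclasses
import json
import time as _time
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from . import samplesize as ss
from .exceptions import InvalidInputError

__all__ = ["grid_report", "decision_flow", "Recommendation", "RunRecord"]

#: Fallback target D when the user has no prior study, no literature value and
#: no c-index: the mean D across a large pool of published prognostic models.
DEFAULT_TARGET_D = 1.4


def grid_report(d_values: Sequence[float], cens_values: Sequence[float],
                design: ss.DesignSpec,
                mode: str = "ci") -> pd.DataFrame:
    """Sample sizes over a grid of target D and censoring values.

    One row per (D, cens) combination with the model-based lambda, the
    required events and the implied number of patients.  Useful when the
    likely D or censoring proportion of the planned study is uncertain.
    """
    d_values = list(d_values)
    cens_values = list(cens_values)
    if not d_values or not cens_values:
        raise InvalidInputError("grid requires at least one D and one censoring value")
    rows = []
    for cens in cens_values:
        for d in d_values:
            lam = ss.lambda_from_model(d, cens)
            design_c = dataclasses.replace(design, censoring=cens)
            if mode == "ci":
                res = ss.events_ci(lam, design_c)
            elif mode == "significance":
                res = ss.events_significance(lam, design_c)
            else:
                raise InvalidInputError(f"mode must be 'significance' or 'ci', got {mode!r}")
            rows.append((d, cens, lam.value, res.events, res.patients))
    return pd.DataFrame(rows, columns=["d", "cens", "lambda_m", "events", "patients"])


@dataclass(frozen=True)
class Recommendation:
    calculation: str
    notes: tuple[str, ...] = ()
    default_d: Optional[float] = None


def decision_flow(has_prior_study: bool, framing: str = "precision",
                  has_target_d: bool = True, has_c_index: bool = False) -> Recommendation:
    """Recommend a calculation given what the user has available.

    Model-based designs (B2/D2) are preferred by default because they allow a
    range of sample sizes over plausible D and censoring values; study-based
    designs (B1/D1) are appropriate when a reliable prior study of the same
    model exists (e.g. validation), in which case a bootstrap SE of D should
    feed lambda_s.  With no D available at all, a published c-index can be
    converted, or the literature-wide average D = 1.4 used as a last resort.
    """
    framing = framing.lower()
    if framing not in ("significance", "precision"):
        raise InvalidInputError("framing must be 'significance' or 'precision'")
    notes: list[str] = []
    default_d = None
    if has_prior_study:
        calc = "B1" if framing == "significance" else "D1"
        notes.append(
            "use a bootstrap SE of D from the prior study to form lambda_s; "
            "the default model-based SE underestimates, especially for D >= 2"
        )
    else:
        calc = "B2" if framing == "significance" else "D2"
        if not has_target_d:
            if has_c_index:
                notes.append("convert the published c-index to D with c_to_d()")
            else:
                default_d = DEFAULT_TARGET_D
                notes.append(
                    f"no target D available: falling back to D = {DEFAULT_TARGET_D}, "
                    "the mean over a large pool of published prognostic models"
                )
    return Recommendation(calculation=calc, notes=tuple(notes), default_d=default_d)


@dataclass
class RunRecord:
    """Machine-readable trace of one CLI run: inputs, intermediates, outputs."""

    command: str
    parameters: dict
    outputs: dict = field(default_factory=dict)
    lambda_value: Optional[float] = None
    lambda_source: Optional[str] = None
    intermediates: dict = field(default_factory=dict)
    seed: Optional[int] = None
    timestamp: str = field(
        default_factory=lambda: _time.strftime("%Y-%m-%dT%H:%M:%S%z")
    )

    def to_json(self, **kwargs) -> str:
        return json.dumps(dataclasses.asdict(self), default=float, **kwargs)

    def write(self, path) -> None:
        with open(path, "a") as fh:
            fh.write(self.to_json() + "\n")
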