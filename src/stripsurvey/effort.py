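"""Survey-effort calculator: transects required to reach a target CV.

The default rule solves ``cv_target = cv_observed * T_completed /
T_estimated`` for ``T_estimated`` — the linear-in-T scaling used when
the published efficiency comparison was constructed.  A conventional
``sqrt_scaling`` variant, under which the CV of a design-based mean
shrinks as 1/sqrt(T), is provided for comparison:
``T_estimated = T_completed * (cv_observed / cv_target)^2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["EffortResult", "transects_for_cv"]

_RULES = ("linear", "sqrt_scaling")


@dataclass(frozen=True)
class EffortResult:
    T_estimated: int
    T_estimated_raw: float
    cv_observed: float
    T_completed: int
    cv_target: float
    rule: str
    tie: bool = False  # raw value was an exact half


def _round_half_away(x: float) -> int:
    # snap to 9 decimals first so binary-float noise (e.g. 61.4999...99
    # for 0.41*15/0.1) cannot flip an exact half downward
    return int(math.floor(round(x, 9) + 0.5))


def transects_for_cv(
    cv_observed: float,
    T_completed: int,
    cv_target: float = 0.1,
    rule: str = "linear",
) -> EffortResult:
    """Number of transects needed to reach ``cv_target``.

    Rounded to the nearest integer with ties away from zero, minimum 1;
    exact halves are flagged in the result.
    """
    if not (cv_observed > 0):
        raise ValueError(f"cv_observed must be > 0, got {cv_observed}")
    if T_completed < 1:
        raise ValueError(f"T_completed must be >= 1, got {T_completed}")
    if not (cv_target > 0):
        raise ValueError(f"cv_target must be > 0, got {cv_target}")
    if rule not in _RULES:
        raise ValueError(f"rule must be one of {_RULES}, got {rule!r}")
    if rule == "linear":
        raw = cv_observed * T_completed / cv_target
    else:
        raw = T_completed * (cv_observed / cv_target) ** 2
    tie = math.isclose(round(raw, 9) % 1.0, 0.5, abs_tol=1e-12)
    return EffortResult(
        T_estimated=max(1, _round_half_away(raw)),
        T_estimated_raw=raw,
        cv_observed=cv_observed,
        T_completed=T_completed,
        cv_target=cv_target,
        rule=rule,
        tie=tie,
    )
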