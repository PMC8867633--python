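"""Relevance limits and the formal verbal grading of trend differences.

Statistical significance alone would privilege large indicators, so a
magnitude criterion is combined with it.  The relevance limit of an
indicator is 10% of its potential improvement, i.e. of the distance of
the reference-sample baseline prevalence from its ideal bound (100%
for a desired increase, 0% for a desired decrease), with a floor of
0.1 percentage points.

The directed trend difference Delta (sign flipped for desired-decrease
indicators so positive always means improvement) and the directed
z-score are then classified on a seven-level scale by a sequential
rule: the first fully satisfied row wins.

    strong hint :  Delta > l_rel  AND  b_l(Delta) > 0.5 l_rel
                   and  z > 1.96  AND  b_l(z) > 1
    regular hint:  Delta > l_rel  AND  b_l(Delta) > 0
                   and  z > 1.96
    weak hint   :  Delta > l_rel  and  z > 1
    otherwise   :  inconclusive

(b_l = lower 95% confidence bound.)  The z-conditions are skipped —
the trend conditions alone decide — when the between-region SD of
control trends is at most 0.001 or the Fieller interval for z is
degenerate, since the z-score is then not meaningful.  Negative
directed differences are graded by the mirrored ladder.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ValidationError
from .pooling import DifferenceEstimate, ZEstimate

GRADES = (
    "strong_positive",
    "regular_positive",
    "weak_positive",
    "inconclusive",
    "weak_negative",
    "regular_negative",
    "strong_negative",
)

#: points per grade used by the evidence summary S_hint
GRADE_POINTS = {
    "strong_positive": 5,
    "regular_positive": 3,
    "weak_positive": 1,
    "inconclusive": 0,
    "weak_negative": -1,
    "regular_negative": -3,
    "strong_negative": -5,
}

SIGMA_C_THRESHOLD = 0.001


@dataclass(frozen=True)
class RelevanceLimit:
    """Relevance limit of one indicator (percentage points)."""

    baseline_prevalence: float  # percent
    potential_improvement: float  # percent
    l_rel: float  # percentage points


def relevance_limit(pi: float, direction: str) -> RelevanceLimit:
    """10% of the potential improvement, floored at 0.1 percentage points.

    ``pi`` is the baseline prevalence in percent; for a desired
    increase the potential improvement is ``100 - pi``, for a desired
    decrease it is ``pi`` itself.
    """
    if not 0.0 <= pi <= 100.0:
        raise ValidationError("baseline prevalence must be in [0, 100] percent")
    if direction == "increase":
        potential = 100.0 - pi
    elif direction == "decrease":
        potential = pi
    else:
        raise ValidationError(
            f"relevance limit undefined for direction {direction!r}"
        )
    return RelevanceLimit(
        baseline_prevalence=pi,
        potential_improvement=potential,
        l_rel=max(0.1 * potential, 0.1),
    )


def direct(
    delta: DifferenceEstimate, zest: ZEstimate | None, direction: str
) -> tuple[DifferenceEstimate, ZEstimate | None]:
    """Directed versions of the key figures.

    For a desired increase the estimates pass through unchanged; for a
    desired decrease all signs flip and confidence bounds swap so that
    the lower bound remains the lower directed bound.  Applying the
    decrease transform twice restores the input.
    """
    if direction == "increase":
        return delta, zest
    if direction != "decrease":
        raise ValidationError(f"cannot direct estimates for direction {direction!r}")
    d = DifferenceEstimate(
        estimate=-delta.estimate,
        se=delta.se,
        ci_low=-delta.ci_high,
        ci_high=-delta.ci_low,
        p_value=delta.p_value,
    )
    if zest is None:
        return d, None
    z = ZEstimate(
        z=-zest.z,
        ci_low=None if zest.ci_high is None else -zest.ci_high,
        ci_high=None if zest.ci_low is None else -zest.ci_low,
        degenerate=zest.degenerate,
    )
    return d, z


@dataclass
class VerbalGrade:
    """Outcome of the grading rule, with an audit trail."""

    grade: str
    z_condition_applied: bool
    conditions_log: dict = field(default_factory=dict)


def _positive_ladder(
    d: float, b_l: float, z: float | None, z_bl: float | None, l_rel: float, use_z: bool
) -> tuple[str, dict]:
    """Evaluate the positive ladder sequentially; first full row wins."""
    log = {}
    rows = [
        ("strong_positive", d > l_rel and b_l > 0.5 * l_rel, z is not None and z > 1.96 and z_bl is not None and z_bl > 1.0),
        ("regular_positive", d > l_rel and b_l > 0.0, z is not None and z > 1.96),
        ("weak_positive", d > l_rel, z is not None and z > 1.0),
    ]
    for name, trend_ok, z_ok in rows:
        ok = trend_ok and (z_ok or not use_z)
        log[name] = {"trend": trend_ok, "z": z_ok if use_z else None}
        if ok:
            return name, log
    return "inconclusive", log


def grade(
    directed_delta: DifferenceEstimate,
    directed_z: ZEstimate | None,
    l_rel: float,
    sigma_C: float,
    sigma_threshold: float = SIGMA_C_THRESHOLD,
) -> VerbalGrade:
    """Apply the sequential verbal grading to directed key figures.

    The z-conditions are applied only when ``sigma_C`` exceeds the
    threshold (default 0.001) and the Fieller interval is
    non-degenerate; otherwise the trend conditions alone decide.  A
    directed difference of exactly zero is graded inconclusive.
    """
    use_z = (
        sigma_C > sigma_threshold
        and directed_z is not None
        and not directed_z.degenerate
    )
    d, b_l = directed_delta.estimate, directed_delta.ci_low
    if d > 0:
        z = directed_z.z if (use_z and directed_z is not None) else None
        z_bl = directed_z.ci_low if use_z else None
        name, log = _positive_ladder(d, b_l, z, z_bl, l_rel, use_z)
        return VerbalGrade(grade=name, z_condition_applied=use_z, conditions_log=log)
    if d < 0:
        # mirror: grade -Delta / -z on the positive ladder
        z = -directed_z.z if (use_z and directed_z is not None) else None
        z_bl = (
            -directed_z.ci_high
            if (use_z and directed_z is not None and directed_z.ci_high is not None)
            else None
        )
        name, log = _positive_ladder(-d, -directed_delta.ci_high, z, z_bl, l_rel, use_z)
        name = name.replace("positive", "negative")
        return VerbalGrade(grade=name, z_condition_applied=use_z, conditions_log=log)
    return VerbalGrade(grade="inconclusive", z_condition_applied=use_z, conditions_log={})
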