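"""Fuzzy logic heart-rate controller.

The controller reads the measured heart rate twice per second, forms the
error against a setpoint (``dHR = HR - SP``, bpm) and its slope
(``mHR = (dHR_n - dHR_{n-1}) / 0.5``, bpm/s), fuzzifies both inputs, and
combines five singleton-output rules by the center-of-area method (which,
for singleton consequents, reduces to the weighted sum
``dCout = sum_r i(r) * o(r)``).  The resulting increment, scaled by the
user gain divided by the update rate, is accumulated into the output
coefficient ``cout``.

``cout`` is calibrated elsewhere to be roughly bpm-equivalent: positive
values map to low-frequency vagal stimulation (lowers heart rate),
negative values to kilohertz-frequency block (raises heart rate by
attenuating vagal tone).  Because ``|dCout| <= 1``, the gain ``G`` is
exactly the maximum rate of change of ``cout`` in bpm per second.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

__all__ = [
    "ErrorMembershipSet",
    "SlopeMembershipSet",
    "FuzzyRule",
    "FuzzyControllerConfig",
    "ControllerState",
    "DEFAULT_RULES",
    "compute_error",
    "compute_slope",
    "fuzzify",
    "defuzzify",
    "controller_step",
]

logger = logging.getLogger(__name__)

ERROR_ZONES = ("Below", "Near", "Above")
SLOPE_ZONES = ("Decreasing", "Increasing", "Any")


class ConfigurationError(ValueError):
    """Raised when a controller configuration violates its invariants."""


def _require_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class ErrorMembershipSet:
    """Sigmoidal three-zone partition of the heart-rate error axis.

    ``Below`` is a falling sigmoid centred at ``below_midpoint`` (< 0),
    ``Above`` a rising sigmoid centred at ``above_midpoint`` (> 0), and
    ``Near`` is the complement ``max(0, 1 - Below - Above)``.  The default
    midpoints give a ~±5 bpm dead zone around the setpoint.
    """

    below_midpoint: float = -5.0  # bpm
    above_midpoint: float = 5.0  # bpm
    steepness: float = 0.8  # 1/bpm

    def __post_init__(self) -> None:
        if not (self.below_midpoint < 0.0 < self.above_midpoint):
            raise ConfigurationError(
                "error membership midpoints must satisfy "
                f"below_midpoint < 0 < above_midpoint, got "
                f"({self.below_midpoint}, {self.above_midpoint})"
            )
        if self.steepness <= 0:
            raise ConfigurationError("steepness must be > 0")

    def membership(self, err: float) -> dict[str, float]:
        k = self.steepness
        below = 1.0 / (1.0 + math.exp(min(700.0, k * (err - self.below_midpoint))))
        above = 1.0 / (1.0 + math.exp(min(700.0, -k * (err - self.above_midpoint))))
        near = 1.0 - below - above
        if near < 0.0:
            # Overlapping sigmoids (misconfigured midpoints): floor Near at 0.
            logger.warning(
                "Below + Above memberships exceed 1 at err=%.3g; Near floored at 0",
                err,
            )
            near = 0.0
        return {"Below": below, "Near": near, "Above": above}


@dataclass(frozen=True)
class SlopeMembershipSet:
    """Complementary trapezoidal pair over the error-slope axis (bpm/s)."""

    decreasing_full: float = -1.0  # bpm/s: slope at/below which Decreasing = 1
    increasing_full: float = 1.0  # bpm/s: slope at/above which Increasing = 1

    def __post_init__(self) -> None:
        if not self.decreasing_full < self.increasing_full:
            raise ConfigurationError(
                "slope breakpoints must satisfy decreasing_full < increasing_full"
            )

    def membership(self, slope: float) -> dict[str, float]:
        lo, hi = self.decreasing_full, self.increasing_full
        inc = (slope - lo) / (hi - lo)
        inc = min(1.0, max(0.0, inc))
        return {"Decreasing": 1.0 - inc, "Increasing": inc}


@dataclass(frozen=True)
class FuzzyRule:
    """One rule: (error zone, slope zone) -> singleton output in [-1, 1]."""

    error_zone: str
    slope_zone: str
    output_singleton: float

    def __post_init__(self) -> None:
        if self.error_zone not in ERROR_ZONES:
            raise ConfigurationError(f"unknown error zone {self.error_zone!r}")
        if self.slope_zone not in SLOPE_ZONES:
            raise ConfigurationError(f"unknown slope zone {self.slope_zone!r}")
        if not -1.0 <= self.output_singleton <= 1.0:
            raise ConfigurationError("output singleton must lie in [-1, 1]")


#: Default rule table.  Positive cout means stimulation, which lowers HR,
#: so a heart rate above the setpoint demands a positive increment.  The
#: slope zone selects the large (+/-1) or small (+/-0.4) step, producing
#: the characteristic four-plateau output surface; the Near rule is the
#: zero plateau.
DEFAULT_RULES: tuple[FuzzyRule, ...] = (
    FuzzyRule("Above", "Increasing", +1.0),
    FuzzyRule("Above", "Decreasing", +0.4),
    FuzzyRule("Near", "Any", 0.0),
    FuzzyRule("Below", "Decreasing", -1.0),
    FuzzyRule("Below", "Increasing", -0.4),
)


@dataclass(frozen=True)
class FuzzyControllerConfig:
    error_mfs: ErrorMembershipSet = field(default_factory=ErrorMembershipSet)
    slope_mfs: SlopeMembershipSet = field(default_factory=SlopeMembershipSet)
    rules: tuple[FuzzyRule, ...] = DEFAULT_RULES
    gain: float = 5.0  # bpm/s: maximum rate of change of cout
    update_rate: float = 2.0  # Hz
    setpoint: float = 300.0  # bpm
    cout_limits: tuple[float, float] = (-200.0, 200.0)

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ConfigurationError(f"gain must be > 0, got {self.gain}")
        if self.update_rate <= 0:
            raise ConfigurationError("update_rate must be > 0")
        if self.setpoint <= 0:
            raise ConfigurationError("setpoint must be > 0")
        lo, hi = self.cout_limits
        if not (lo < 0.0 < hi):
            raise ConfigurationError("cout_limits must bracket zero")
        if len(self.rules) != 5:
            raise ConfigurationError(
                f"exactly 5 rules are required, got {len(self.rules)}"
            )
        object.__setattr__(self, "rules", tuple(self.rules))


@dataclass(frozen=True)
class ControllerState:
    cout: float = 0.0
    prev_error: float | None = None
    n_updates: int = 0


def compute_error(hr: float, setpoint: float) -> float:
    """Heart-rate error ``dHR = HR - SP`` in bpm (positive when HR is high)."""
    hr = _require_finite("hr", hr)
    setpoint = _require_finite("setpoint", setpoint)
    if hr < 0:
        raise ValueError(f"hr must be >= 0, got {hr}")
    if setpoint <= 0:
        raise ValueError(f"setpoint must be > 0, got {setpoint}")
    return hr - setpoint


def compute_slope(err_now: float, err_prev: float, interval: float = 0.5) -> float:
    """Error slope ``mHR`` in bpm/s between two successive samples.

    At the nominal 2 Hz update rate the samples are 0.5 s apart, so the
    slope is the difference of the last two errors divided by 0.5.
    """
    err_now = _require_finite("err_now", err_now)
    err_prev = _require_finite("err_prev", err_prev)
    if interval <= 0:
        raise ValueError("interval must be > 0")
    return (err_now - err_prev) / interval


def fuzzify(
    err: float, slope: float, config: FuzzyControllerConfig
) -> dict[str, float]:
    """Membership values of the five input zones for (error, slope)."""
    err = _require_finite("err", err)
    slope = _require_finite("slope", slope)
    out = config.error_mfs.membership(err)
    out.update(config.slope_mfs.membership(slope))
    return out


def _rule_activation(rule: FuzzyRule, memberships: Mapping[str, float]) -> float:
    try:
        i = memberships[rule.error_zone]
    except KeyError as exc:
        raise ConfigurationError(f"membership map lacks zone {rule.error_zone!r}") from exc
    if rule.slope_zone != "Any":
        try:
            i *= memberships[rule.slope_zone]
        except KeyError as exc:
            raise ConfigurationError(
                f"membership map lacks zone {rule.slope_zone!r}"
            ) from exc
    return i


def defuzzify(
    memberships: Mapping[str, float], rules: Sequence[FuzzyRule] = DEFAULT_RULES
) -> float:
    """Center-of-area output for singleton consequents.

    ``dCout = sum_r i(r) * o(r)`` where ``i(r)`` is the product of the
    rule's input memberships (the error membership alone for the
    ``Near``/``Any`` rule).  The result is clamped to [-1, 1].
    """
    if len(rules) != 5:
        raise ConfigurationError(f"exactly 5 rules are required, got {len(rules)}")
    total = 0.0
    for rule in rules:
        total += _rule_activation(rule, memberships) * rule.output_singleton
    return min(1.0, max(-1.0, total))


def controller_step(
    hr: float, state: ControllerState, config: FuzzyControllerConfig
) -> tuple[float, ControllerState]:
    """One controller update: returns the new ``cout`` and successor state.

    The increment is ``(G / update_rate) * dCout``, so over one second of
    updates ``cout`` can move by at most ``G`` bpm.  On the very first
    update the slope is taken as zero (no previous error sample exists).
    """
    err = compute_error(hr, config.setpoint)
    if state.prev_error is None:
        slope = 0.0
    else:
        slope = compute_slope(err, state.prev_error, 1.0 / config.update_rate)
    memberships = fuzzify(err, slope, config)
    dcout = defuzzify(memberships, config.rules)
    lo, hi = config.cout_limits
    cout = state.cout + (config.gain / config.update_rate) * dcout
    cout = min(hi, max(lo, cout))
    new_state = replace(
        state, cout=cout, prev_error=err, n_updates=state.n_updates + 1
    )
    return cout, new_state
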