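"""ATS/ERS repeatability selection applied to an ordered maneuver sequence.

The sequential rule: after the minimum number of maneuvers, a test
qualifies if the highest and second-highest values so far differ by at
most the repeatability criterion (RC); each later maneuver is compared to
the running maximum of the values already seen.  A brute-force top-two
oracle is provided alongside; the two formulations are provably the same
stopping rule and the equivalence is guarded by property tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

__all__ = [
    "StopRule",
    "NonRepeatablePolicy",
    "ProtocolConfig",
    "ProtocolOutcome",
    "apply_ats_protocol",
    "unrestricted_result",
    "first_qualifying_maneuver_oracle",
]

DEFAULT_RC = 0.15


@dataclass(frozen=True)
class StopRule:
    """When maneuver collection stops.

    ``early()``   — stop as soon as the RC is met (the full iterative
                    protocol, up to ``max_maneuvers``).
    ``fixed(k)``  — exactly the first k maneuvers are ever seen,
                    regardless of qualification.
    ``none()``    — all supplied maneuvers are consumed; qualification
                    records whether the RC was ever met.
    """

    kind: str
    k: Optional[int] = None

    _KINDS = ("early_stop", "fixed_stop", "no_stop")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown stop rule {self.kind!r}; expected one of {self._KINDS}")
        if self.kind == "fixed_stop":
            if self.k is None or self.k < 1:
                raise ValueError("fixed_stop requires k >= 1")
        elif self.k is not None:
            raise ValueError(f"{self.kind} takes no k")

    @classmethod
    def early(cls) -> "StopRule":
        return cls("early_stop")

    @classmethod
    def fixed(cls, k: int) -> "StopRule":
        return cls("fixed_stop", k)

    @classmethod
    def none(cls) -> "StopRule":
        return cls("no_stop")


class NonRepeatablePolicy(str, Enum):
    """What a protocol reports for a test that never satisfies the RC."""

    DISCARD = "discard"  # test dropped; no value reported
    REPORT_HIGHEST = "report_highest"  # highest value seen reported anyway
    FLAG_ONLY = "flag_only"  # highest value carried, flagged unqualified


@dataclass(frozen=True)
class ProtocolConfig:
    rc: float = DEFAULT_RC
    min_maneuvers: int = 3
    max_maneuvers: int = 8
    stop_rule: StopRule = StopRule.early()
    nonrepeatable_policy: NonRepeatablePolicy = NonRepeatablePolicy.DISCARD

    def __post_init__(self) -> None:
        if not self.rc > 0:
            raise ValueError(f"rc must be positive, got {self.rc!r}")
        if not 3 <= self.min_maneuvers <= self.max_maneuvers:
            raise ValueError(
                f"need 3 <= min_maneuvers <= max_maneuvers, got "
                f"{self.min_maneuvers}..{self.max_maneuvers}"
            )
        if self.stop_rule.kind == "fixed_stop" and self.stop_rule.k < self.min_maneuvers:
            raise ValueError(
                f"fixed stop at {self.stop_rule.k} is before min_maneuvers={self.min_maneuvers}"
            )
        object.__setattr__(self, "nonrepeatable_policy", NonRepeatablePolicy(self.nonrepeatable_policy))


@dataclass(frozen=True)
class ProtocolOutcome:
    """What one protocol run reports for one test.

    ``reported_fev1`` is None for an unqualified test under the discard
    policy.  ``unrestricted_max`` is the maximum over *all* supplied
    maneuvers, seen or not.
    """

    reported_fev1: Optional[float]
    qualified: bool
    stop_maneuver: Optional[int]
    maneuvers_seen: int
    unrestricted_max: float


def unrestricted_result(maneuvers: Sequence[float]) -> float:
    """Maximum over every maneuver — the unconstrained alternative protocol."""
    values = list(maneuvers)
    if not values:
        raise ValueError("maneuver sequence is empty")
    return max(values)


def _top_two_gap(values: Sequence[float]) -> float:
    top = sorted(values, reverse=True)
    return top[0] - top[1]


def first_qualifying_maneuver_oracle(
    maneuvers: Sequence[float], rc: float, min_maneuvers: int = 3
) -> Optional[int]:
    """Brute-force oracle: smallest m >= min_maneuvers whose first-m top-two
    gap is <= rc, or None if no prefix qualifies.

    Recomputes the top-two gap from scratch at each prefix; intentionally
    independent of the sequential implementation it checks.
    """
    values = list(maneuvers)
    if len(values) < min_maneuvers:
        raise ValueError(f"need at least {min_maneuvers} maneuvers, got {len(values)}")
    for m in range(min_maneuvers, len(values) + 1):
        if _top_two_gap(values[:m]) <= rc:
            return m
    return None


def apply_ats_protocol(maneuvers: Sequence[float], config: ProtocolConfig) -> ProtocolOutcome:
    """Run the repeatability-criterion selection over an ordered sequence.

    The sequence carries up to ``max_maneuvers`` values in performance
    order; the stop rule controls how many are actually seen.  See the
    module docstring for the rule itself.
    """
    values = [float(v) for v in maneuvers][: config.max_maneuvers]
    if len(values) < config.min_maneuvers:
        raise ValueError(
            f"need at least min_maneuvers={config.min_maneuvers} values, got {len(values)}"
        )
    overall_max = max(values)

    if config.stop_rule.kind == "fixed_stop":
        visible = values[: config.stop_rule.k]
    else:
        visible = values

    # Sequential pass: min-maneuver top-two check, then new-vs-running-max.
    qualified_at: Optional[int] = None
    running_max = max(visible[: config.min_maneuvers])
    if _top_two_gap(visible[: config.min_maneuvers]) <= config.rc:
        qualified_at = config.min_maneuvers
    m = config.min_maneuvers
    while qualified_at is None and m < len(visible):
        new = visible[m]
        m += 1
        if abs(new - running_max) <= config.rc:
            qualified_at = m
        running_max = max(running_max, new)

    if config.stop_rule.kind == "early_stop" and qualified_at is not None:
        seen = qualified_at
    else:
        seen = len(visible)
    seen_max = max(visible[:seen])

    qualified = qualified_at is not None
    if qualified:
        reported: Optional[float] = seen_max
    elif config.nonrepeatable_policy is NonRepeatablePolicy.DISCARD:
        reported = None
    else:  # report_highest / flag_only both carry the highest value seen
        reported = seen_max

    return ProtocolOutcome(
        reported_fev1=reported,
        qualified=qualified,
        stop_maneuver=qualified_at,
        maneuvers_seen=seen,
        unrestricted_max=overall_max,
    )
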