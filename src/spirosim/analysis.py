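"""Cohort-level aggregation: measurement error, rejection curves, grids.

Measurement error is summarised on two bases:

* ``population`` (default) — the mean (or quantile) of the unconstrained
  maximum over *all* tests minus the mean (or quantile) of the
  protocol-reported value over *retained* tests: the horizontal gap
  between the two empirical distributions.  This is the basis on which
  the printed sensitivity results are reproducible.
* ``within_test`` — the per-test difference ``unrestricted_max -
  reported_fev1`` averaged over retained tests; nonnegative test by test.

The vectorised routines here use the top-two-gap formulation of the
repeatability rule, which is equivalent to the sequential rule in
:mod:`spirosim.protocol` (the equivalence is property-tested, not
assumed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.stats import norm

from .protocol import NonRepeatablePolicy, ProtocolConfig, StopRule
from .reference import RoundingMode, SubjectProfile, derive_sigmas
from .simulator import Cohort, SimulationConfig, simulate_cohort

__all__ = [
    "ErrorSummary",
    "RejectionCurve",
    "CdfComparison",
    "prefix_top_two_gaps",
    "first_qualifying_vector",
    "pair_failure_probability",
    "measurement_error_summary",
    "rejection_curve",
    "sensitivity_grid",
    "cdf_comparison",
]

DEFAULT_QUANTILES = (0.25, 0.50, 0.75)

#: Allowed denominators for percent measurement error.
DENOMINATOR_RULES = ("reported", "predicted", "unrestricted")

#: Allowed measurement-error bases (see module docstring).
ERROR_BASES = ("population", "within_test")


@dataclass(frozen=True)
class ErrorSummary:
    """Aggregated measurement error for one protocol configuration."""

    rc: float
    cv_t: float
    cv_m: float
    n_tests: int
    n_retained: int
    mean_error: float
    mean_error_pct: float
    error_quantiles: Mapping[float, float]
    error_basis: str = "population"

    def to_dict(self) -> dict:
        out = {
            "rc": self.rc,
            "cv_t": self.cv_t,
            "cv_m": self.cv_m,
            "n_tests": self.n_tests,
            "n_retained": self.n_retained,
            "mean_error_lsec": self.mean_error,
            "mean_error_pct": self.mean_error_pct,
            "error_basis": self.error_basis,
        }
        for p, q in self.error_quantiles.items():
            out[f"q{int(round(p * 100))}"] = q
        return out


@dataclass(frozen=True)
class RejectionCurve:
    """Fraction of tests with no repeatable pair, by maneuvers performed."""

    cv_m: float
    rc: float
    points: Mapping[int, float]

    def __post_init__(self) -> None:
        values = [self.points[m] for m in sorted(self.points)]
        if any(not 0.0 <= v <= 1.0 for v in values):
            raise ValueError("rejection fractions must lie in [0, 1]")
        if any(a < b for a, b in zip(values, values[1:])):
            raise ValueError("rejection fraction must be nonincreasing in maneuver count")


def prefix_top_two_gaps(maneuvers: np.ndarray, min_m: int = 3) -> dict[int, np.ndarray]:
    """Per-test gap between the highest and second-highest of the first m
    maneuvers, for every m from ``min_m`` to the full width."""
    maneuvers = np.asarray(maneuvers, dtype=float)
    n, k = maneuvers.shape
    if k < min_m:
        raise ValueError(f"need at least {min_m} maneuver columns, got {k}")
    gaps: dict[int, np.ndarray] = {}
    for m in range(min_m, k + 1):
        top2 = np.partition(maneuvers[:, :m], (m - 2, m - 1), axis=1)[:, -2:]
        gaps[m] = top2[:, 1] - top2[:, 0]
    return gaps


def first_qualifying_vector(maneuvers: np.ndarray, rc: float, min_m: int = 3) -> np.ndarray:
    """First maneuver count at which each test qualifies; 0 where it never does."""
    gaps = prefix_top_two_gaps(maneuvers, min_m)
    n = np.asarray(maneuvers).shape[0]
    out = np.zeros(n, dtype=np.int64)
    for m in sorted(gaps, reverse=True):
        out[gaps[m] <= rc] = m
    return out


def pair_failure_probability(rc: float, sigma_m: float) -> float:
    """P(|X1 - X2| > rc) for two i.i.d. Normal(mu, sigma_m^2) maneuvers.

    Closed form 2*(1 - Phi(rc / (sigma_m*sqrt(2)))); the probability that a
    two-maneuver test fails the repeatability criterion.
    """
    if not rc > 0:
        raise ValueError(f"rc must be positive, got {rc!r}")
    if sigma_m < 0:
        raise ValueError(f"sigma_m must be nonnegative, got {sigma_m!r}")
    if sigma_m == 0:
        return 0.0
    return float(2.0 * norm.sf(rc / (sigma_m * np.sqrt(2.0))))


def _protocol_arrays(cohort: Cohort, config: ProtocolConfig):
    """Vectorised protocol outcome: (qualified mask, reported values, unrestricted max).

    ``reported`` is NaN for unqualified tests under the discard policy.
    """
    man = cohort.maneuvers[:, : config.max_maneuvers]
    unrestricted = cohort.maneuvers.max(axis=1)
    fq = first_qualifying_vector(man, config.rc, config.min_maneuvers)

    rule = config.stop_rule
    if rule.kind == "fixed_stop":
        visible = man[:, : rule.k]
        qualified = (fq > 0) & (fq <= rule.k)
        seen_max = visible.max(axis=1)
        reported = seen_max.copy()
    elif rule.kind == "early_stop":
        qualified = fq > 0
        seen_max = man.max(axis=1)  # what an unqualified test saw: everything
        # reported value for a qualified test = max of its first fq maneuvers
        reported = seen_max.copy()
        for m in np.unique(fq[qualified]):
            mask = fq == m
            reported[mask] = man[mask, :m].max(axis=1)
    else:  # no_stop
        qualified = fq > 0
        seen_max = man.max(axis=1)
        reported = seen_max.copy()

    if config.nonrepeatable_policy is NonRepeatablePolicy.DISCARD:
        reported[~qualified] = np.nan
    else:
        reported[~qualified] = seen_max[~qualified]
    return qualified, reported, unrestricted


def measurement_error_summary(
    cohort: Cohort,
    protocol_config: ProtocolConfig,
    denominator_rule: str = "reported",
    *,
    error_basis: str = "population",
    cv_t: float = float("nan"),
    cv_m: float = float("nan"),
    predicted_fev1: Optional[float] = None,
    quantile_probs: Sequence[float] = DEFAULT_QUANTILES,
) -> ErrorSummary:
    """Mean and quantiles of FEV1 measurement error for one protocol.

    Under ``error_basis='population'`` (default) the mean error is the
    mean unconstrained maximum over all tests minus the mean reported
    value over retained tests, and each quantile is the horizontal gap
    between the two empirical distributions at that probability.  Under
    ``'within_test'`` the error is computed test by test
    (``unrestricted_max - reported_fev1``) over retained tests.

    Under the discard policy, unqualified tests carry no reported value
    and are excluded from the retained side.  Percent error follows
    ``denominator_rule``: the protocol-reported value (default), the
    predicted FEV1, or the unrestricted maximum.
    """
    if denominator_rule not in DENOMINATOR_RULES:
        raise ValueError(f"denominator_rule must be one of {DENOMINATOR_RULES}, got {denominator_rule!r}")
    if error_basis not in ERROR_BASES:
        raise ValueError(f"error_basis must be one of {ERROR_BASES}, got {error_basis!r}")
    if denominator_rule == "predicted" and predicted_fev1 is None:
        raise ValueError("denominator_rule='predicted' requires predicted_fev1")
    if len(cohort) == 0:
        raise ValueError("cohort is empty")

    qualified, reported, unrestricted = _protocol_arrays(cohort, protocol_config)
    retained = ~np.isnan(reported)
    n_retained = int(retained.sum())
    if n_retained == 0:
        raise ValueError("all tests rejected for lack of repeatability; nothing to summarise")

    probs = sorted(float(p) for p in quantile_probs)
    if error_basis == "population":
        mean_error = float(unrestricted.mean() - reported[retained].mean())
        quantiles = {
            p: float(np.quantile(unrestricted, p) - np.quantile(reported[retained], p))
            for p in probs
        }
        denominators = {
            "reported": reported[retained].mean(),
            "unrestricted": unrestricted.mean(),
            "predicted": predicted_fev1,
        }
        mean_error_pct = float(100.0 * mean_error / denominators[denominator_rule])
    else:
        error = unrestricted[retained] - reported[retained]
        mean_error = float(error.mean())
        quantiles = {p: float(np.quantile(error, p)) for p in probs}
        if denominator_rule == "reported":
            pct = 100.0 * error / reported[retained]
        elif denominator_rule == "unrestricted":
            pct = 100.0 * error / unrestricted[retained]
        else:
            pct = 100.0 * error / predicted_fev1
        mean_error_pct = float(pct.mean())

    return ErrorSummary(
        rc=protocol_config.rc,
        cv_t=cv_t,
        cv_m=cv_m,
        n_tests=len(cohort),
        n_retained=n_retained,
        mean_error=mean_error,
        mean_error_pct=mean_error_pct,
        error_quantiles=quantiles,
        error_basis=error_basis,
    )


def _make_cohort(
    subject: SubjectProfile,
    cv_t: float,
    cv_m: float,
    n_tests: int,
    n_maneuvers: int,
    seed,
    rounding_mode: RoundingMode = RoundingMode.ROUNDED_2DP,
) -> Cohort:
    variability = derive_sigmas(subject, cv_t, cv_m, rounding_mode)
    config = SimulationConfig(
        subject=subject,
        variability=variability,
        n_tests=n_tests,
        n_maneuvers=n_maneuvers,
        seed=seed,
    )
    return simulate_cohort(config)


def rejection_curve(
    cv_m: float,
    rc: float = 0.15,
    subject: Optional[SubjectProfile] = None,
    cv_t: float = 0.03,
    n_tests: int = 20_902,
    n_maneuvers_max: int = 8,
    seed=None,
    rounding_mode: RoundingMode = RoundingMode.ROUNDED_2DP,
) -> RejectionCurve:
    """Simulated probability that a test is still unresolved after m
    maneuvers (no prefix of length <= m satisfies the RC), for m = 3..max.

    At m = 3 this equals the fraction whose first-three top-two gap
    exceeds the RC; for larger m it is the survival function of the first
    qualifying maneuver, which is what an early-stopping protocol rejects
    if testing ends at m.  Nonincreasing in m by construction.
    """
    subject = subject or SubjectProfile()
    if derive_sigmas(subject, cv_t, cv_m, rounding_mode).sigma_m == 0:
        points = {m: 0.0 for m in range(3, n_maneuvers_max + 1)}
        return RejectionCurve(cv_m=cv_m, rc=rc, points=points)
    cohort = _make_cohort(subject, cv_t, cv_m, n_tests, n_maneuvers_max, seed, rounding_mode)
    fq = first_qualifying_vector(cohort.maneuvers, rc, min_m=3)
    points = {
        m: float(np.mean((fq == 0) | (fq > m))) for m in range(3, n_maneuvers_max + 1)
    }
    return RejectionCurve(cv_m=cv_m, rc=rc, points=points)


def sensitivity_grid(
    rc_values: Sequence[float],
    cv_m_values: Sequence[float],
    subject: Optional[SubjectProfile] = None,
    cv_t: float = 0.03,
    n_tests: int = 20_902,
    n_maneuvers: int = 8,
    seed=None,
    stop_rule: Optional[StopRule] = None,
    policy: NonRepeatablePolicy = NonRepeatablePolicy.DISCARD,
    denominator_rule: str = "reported",
    error_basis: str = "population",
) -> list[ErrorSummary]:
    """One :class:`ErrorSummary` per (rc, cv_m) cell.

    The default stop rule is ``fixed(3)``: the protocol sees only the first
    three maneuvers, against the unconstrained eight-maneuver maximum.
    cv_m = 0 is simulated with an intratest SD of exactly zero.  Each cv_m
    column reuses one cohort across rc values (rc only affects selection).
    """
    if len(rc_values) == 0 or len(cv_m_values) == 0:
        raise ValueError("rc_values and cv_m_values must be nonempty")
    subject = subject or SubjectProfile()
    stop_rule = stop_rule or StopRule.fixed(3)
    seed_seq = np.random.SeedSequence(seed)
    children = seed_seq.spawn(len(cv_m_values))

    summaries: list[ErrorSummary] = []
    for cv_m, child in zip(cv_m_values, children):
        cohort = _make_cohort(subject, cv_t, cv_m, n_tests, n_maneuvers, child)
        for rc in rc_values:
            config = ProtocolConfig(
                rc=rc,
                max_maneuvers=n_maneuvers,
                stop_rule=stop_rule,
                nonrepeatable_policy=policy,
            )
            summaries.append(
                measurement_error_summary(
                    cohort,
                    config,
                    denominator_rule,
                    error_basis=error_basis,
                    cv_t=cv_t,
                    cv_m=cv_m,
                    predicted_fev1=subject.predicted_fev1,
                )
            )
    return summaries


@dataclass(frozen=True)
class CdfComparison:
    """Empirical quantiles of reported FEV1 under the protocol and the
    unconstrained alternative, over the same retained tests."""

    probs: tuple[float, ...]
    protocol_quantiles: tuple[float, ...]
    unrestricted_quantiles: tuple[float, ...]

    @property
    def error_at_quantile(self) -> tuple[float, ...]:
        return tuple(
            u - p for u, p in zip(self.unrestricted_quantiles, self.protocol_quantiles)
        )


def cdf_comparison(
    cohort: Cohort,
    protocol_config: ProtocolConfig,
    probs: Sequence[float] = tuple(np.round(np.arange(0.01, 1.0, 0.01), 2)),
    unrestricted_over: str = "retained",
) -> CdfComparison:
    """Quantile functions of the protocol-reported value and the
    unconstrained maximum; the horizontal gap is error-at-quantile.

    ``unrestricted_over`` selects whether the unconstrained distribution
    is taken over the same retained tests (default; per-test dominance
    then guarantees a nonnegative gap) or over all tests (the population
    basis used by :func:`measurement_error_summary`).
    """
    if unrestricted_over not in ("retained", "all"):
        raise ValueError(f"unrestricted_over must be 'retained' or 'all', got {unrestricted_over!r}")
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    _, reported, unrestricted = _protocol_arrays(cohort, protocol_config)
    retained = ~np.isnan(reported)
    if not retained.any():
        raise ValueError("all tests rejected for lack of repeatability; nothing to summarise")
    if unrestricted_over == "retained":
        unrestricted = unrestricted[retained]
    probs = tuple(float(p) for p in probs)
    return CdfComparison(
        probs=probs,
        protocol_quantiles=tuple(float(q) for q in np.quantile(reported[retained], probs)),
        unrestricted_quantiles=tuple(float(q) for q in np.quantile(unrestricted, probs)),
    )
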