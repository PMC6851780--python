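"""Minimum detectable difference between FEV1 measurements.

Two rules are deliberately kept distinct and labelled, because they answer
different questions and are NOT interchangeable:

* ``mdd_paired_difference`` — how far apart two individual test values
  must be to infer they come from different distributions.  The sampling
  unit is a difference of two draws, whose SD is ``sqrt(2)*sigma``, so the
  threshold is ``2 * z * sqrt(2) * sigma``.
* ``mdd_percentile_separation`` — how far apart two distribution means
  must be for each draw to fall beyond the opposite distribution's tail
  percentile (post value below the pre 10th percentile and vice versa at
  the default coverage).  Threshold ``2 * z * sigma``.

At default coverage 0.80 (two-sided; 10th/90th percentiles, equivalently
two-tailed p < 0.10 or one-tailed p < 0.05 for an expected decline),
z = Phi^-1(0.90) = 1.281552.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import norm

from .reference import SubjectProfile

__all__ = [
    "MddResult",
    "combined_sigma",
    "mdd_percentile_separation",
    "mdd_paired_difference",
    "DEFAULT_COVERAGE",
]

DEFAULT_COVERAGE = 0.80


@dataclass(frozen=True)
class MddResult:
    """A minimum-detectable-difference threshold and how it was obtained."""

    threshold: float
    threshold_pct: float
    sigma_used: float
    method: str
    coverage: float

    def to_dict(self) -> dict:
        return {
            "threshold_lsec": self.threshold,
            "threshold_pct": self.threshold_pct,
            "sigma_used": self.sigma_used,
            "method": self.method,
            "coverage": self.coverage,
        }


def combined_sigma(sigma_t: float, sigma_m: float) -> float:
    """Quadrature combination sqrt(sigma_t^2 + sigma_m^2) of the inter- and
    intratest standard deviations."""
    if sigma_t < 0 or sigma_m < 0:
        raise ValueError("standard deviations must be nonnegative")
    return math.hypot(sigma_t, sigma_m)


def _z(coverage: float) -> float:
    if not 0.0 < coverage < 1.0:
        raise ValueError(f"coverage must lie strictly between 0 and 1, got {coverage!r}")
    return float(norm.ppf((1.0 + coverage) / 2.0))


def _pct(threshold: float, subject: SubjectProfile) -> float:
    return 100.0 * threshold / subject.predicted_fev1


def mdd_percentile_separation(
    sigma: float,
    coverage: float = DEFAULT_COVERAGE,
    subject: SubjectProfile | None = None,
) -> MddResult:
    """Mean separation at which two normals with common SD ``sigma`` clear
    each other's tail percentiles: ``2 * z * sigma``."""
    if sigma < 0:
        raise ValueError(f"sigma must be nonnegative, got {sigma!r}")
    subject = subject or SubjectProfile()
    threshold = 2.0 * _z(coverage) * sigma
    return MddResult(
        threshold=threshold,
        threshold_pct=_pct(threshold, subject),
        sigma_used=sigma,
        method="percentile_separation",
        coverage=coverage,
    )


def mdd_paired_difference(
    sigma_t: float,
    coverage: float = DEFAULT_COVERAGE,
    subject: SubjectProfile | None = None,
) -> MddResult:
    """Minimum difference between two individual test values:
    ``2 * z * sqrt(2) * sigma_t``."""
    if sigma_t < 0:
        raise ValueError(f"sigma_t must be nonnegative, got {sigma_t!r}")
    subject = subject or SubjectProfile()
    threshold = 2.0 * _z(coverage) * math.sqrt(2.0) * sigma_t
    return MddResult(
        threshold=threshold,
        threshold_pct=_pct(threshold, subject),
        sigma_used=sigma_t,
        method="paired_difference",
        coverage=coverage,
    )
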