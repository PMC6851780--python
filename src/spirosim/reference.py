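"""Reference equation for predicted normal FEV1 and variability parameters.

The predicted "true" FEV1 for a subject is a deterministic function of
height and age.  Intertest and intratest variability are supplied as
coefficients of variation (CVt, CVm) and converted to absolute standard
deviations on the predicted-FEV1 scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_EVEN, Decimal
from enum import Enum
from typing import Union

__all__ = [
    "DEFAULT_POPULATION_SD",
    "RoundingMode",
    "SubjectProfile",
    "VariabilityModel",
    "predict_fev1",
    "derive_sigmas",
]

# Reference-equation coefficients (adult male, FEV1 in L/sec; height in cm,
# age in years).  The age terms are both negative: predicted FEV1 declines
# monotonically with age.
_INTERCEPT = -8.240
_LOG_HEIGHT_COEF = 1.9095
_AGE_COEF = -0.0037
_AGE_SQ_COEF = -0.000033

#: Between-subject SD of FEV1 (L/sec).  Population context only: it never
#: enters the single-subject simulation.
DEFAULT_POPULATION_SD = 0.51


def predict_fev1(height_cm: float, age_yr: float) -> float:
    """Predicted normal FEV1 (L/sec) for a subject of given height and age.

    Evaluates ``exp(-8.240 + 1.9095*ln(H) - 0.0037*A - 0.000033*A^2)``.

    Parameters
    ----------
    height_cm : float
        Standing height in centimetres; must be positive.
    age_yr : float
        Age in years; must be positive.

    Returns
    -------
    float
        Predicted FEV1 in L/sec (always positive).

    Raises
    ------
    ValueError
        If height or age is not strictly positive.
    """
    if not height_cm > 0:
        raise ValueError(f"height must be positive, got {height_cm!r}")
    if not age_yr > 0:
        raise ValueError(f"age must be positive, got {age_yr!r}")
    exponent = (
        _INTERCEPT
        + _LOG_HEIGHT_COEF * math.log(height_cm)
        + _AGE_COEF * age_yr
        + _AGE_SQ_COEF * age_yr**2
    )
    return math.exp(exponent)


class RoundingMode(str, Enum):
    """How CV-derived standard deviations are carried into the simulation.

    ``ROUNDED_2DP`` rounds sigma to two decimals (half-even) before use,
    matching values that are conventionally quoted at that precision;
    ``EXACT`` keeps the full product ``cv * predicted_fev1``.
    """

    ROUNDED_2DP = "rounded_2dp"
    EXACT = "exact"


def _round_2dp(x: float) -> float:
    # Decimal(repr(x)) keeps the shortest decimal representation of the
    # float, so printed inputs like 0.3195 round the way they read.
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_EVEN))


@dataclass(frozen=True)
class SubjectProfile:
    """Demographics of the simulated subject and the predicted FEV1 they imply.

    Attributes
    ----------
    height_cm, age_yr : float
        Subject height (cm) and age (years); both strictly positive.
    population_sd : float
        Between-subject SD of FEV1 (L/sec).  Carried for documentation;
        not used by the single-subject simulation.
    """

    height_cm: float = 173.0
    age_yr: float = 59.0
    population_sd: float = DEFAULT_POPULATION_SD

    def __post_init__(self) -> None:
        # validates height/age and caches the derived mean
        object.__setattr__(self, "_predicted", predict_fev1(self.height_cm, self.age_yr))

    @property
    def predicted_fev1(self) -> float:
        """Predicted normal FEV1 (L/sec); pure function of (height, age)."""
        return self._predicted  # type: ignore[attr-defined]


@dataclass(frozen=True)
class VariabilityModel:
    """Intertest/intratest coefficients of variation and the SDs they imply.

    ``sigma_t`` and ``sigma_m`` are on the L/sec scale of the subject's
    predicted FEV1; see :func:`derive_sigmas`.
    """

    cv_t: float
    cv_m: float
    sigma_t: float
    sigma_m: float
    rounding_mode: RoundingMode = RoundingMode.ROUNDED_2DP

    def __post_init__(self) -> None:
        for name in ("cv_t", "cv_m", "sigma_t", "sigma_m"):
            value = getattr(self, name)
            if value < 0:
                raise ValueError(f"{name} must be nonnegative, got {value!r}")


def derive_sigmas(
    subject: Union[SubjectProfile, float],
    cv_t: float,
    cv_m: float,
    rounding_mode: RoundingMode = RoundingMode.ROUNDED_2DP,
) -> VariabilityModel:
    """Convert CVs to absolute standard deviations on the subject's scale.

    Parameters
    ----------
    subject : SubjectProfile or float
        The subject whose predicted FEV1 sets the scale, or that mean
        directly as a float (L/sec).
    cv_t, cv_m : float
        Intertest and intratest coefficients of variation as fractions
        (e.g. 0.03 for 3%); must be nonnegative.
    rounding_mode : RoundingMode
        Under ``ROUNDED_2DP`` each sigma is ``cv * mean`` rounded half-even
        to two decimals; under ``EXACT`` the raw product is kept.
    """
    if cv_t < 0 or cv_m < 0:
        raise ValueError(f"coefficients of variation must be nonnegative, got cv_t={cv_t!r}, cv_m={cv_m!r}")
    mean = subject.predicted_fev1 if isinstance(subject, SubjectProfile) else float(subject)
    if mean <= 0:
        raise ValueError(f"predicted FEV1 must be positive, got {mean!r}")
    rounding_mode = RoundingMode(rounding_mode)
    sigma_t = cv_t * mean
    sigma_m = cv_m * mean
    if rounding_mode is RoundingMode.ROUNDED_2DP:
        sigma_t = _round_2dp(sigma_t)
        sigma_m = _round_2dp(sigma_m)
    return VariabilityModel(
        cv_t=cv_t, cv_m=cv_m, sigma_t=sigma_t, sigma_m=sigma_m, rounding_mode=rounding_mode
    )
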