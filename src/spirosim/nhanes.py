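"""Exclusion-rate arithmetic on maneuver-count tables and CVm inference.

A maneuver-count table records, for each maneuver index m, how many
subjects in a survey performed an m-th maneuver (Nm).  Because an
(m+1)-th maneuver is performed exactly when the repeatability criterion
is still unmet after m maneuvers, the counts imply per-maneuver exclusion
rates, and those rates in turn constrain the population's intratest
coefficient of variation.

The packaged fixture reproduces a published survey count table verbatim,
including its internal inconsistencies (non-monotone counts at the low
maneuver indices and one excluded count that disagrees with the next
row's performed count); loading it raises consistency warnings rather
than errors, and rates use the printed values.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .analysis import first_qualifying_vector, pair_failure_probability
from .reference import RoundingMode, SubjectProfile, derive_sigmas
from .simulator import SimulationConfig, simulate_cohort

__all__ = [
    "ManeuverCountTable",
    "CvmInference",
    "exclusion_rates",
    "infer_cvm",
    "load_packaged_counts",
    "read_counts_csv",
    "packaged_counts_path",
]

MIN_MANEUVERS = 3


class CountConsistencyWarning(UserWarning):
    """A maneuver-count table violates its own accounting identities."""


@dataclass(frozen=True)
class ManeuverCountTable:
    """Counts of maneuvers performed plus the accepted/excluded arithmetic.

    accepted[m] = N[m] - N[m+1]; excluded[m] = N[m+1] (or a printed
    override); rates[m] = excluded[m] / N[m], computed for m >= 3 (no
    repeatability check applies before the third maneuver).
    """

    counts: Mapping[int, int]
    accepted: Mapping[int, int]
    excluded: Mapping[int, int]
    rates: Mapping[int, float]

    def rates_percent(self, decimals: int = 0) -> dict[int, float]:
        """Rates scaled to percent and rounded for presentation."""
        return {m: round(100.0 * r, decimals) for m, r in self.rates.items()}


def exclusion_rates(
    counts: Mapping[int, int],
    printed_excluded: Optional[Mapping[int, int]] = None,
) -> ManeuverCountTable:
    """Derive accepted/excluded counts and exclusion rates from Nm counts.

    Parameters
    ----------
    counts : mapping of maneuver index -> maneuvers performed
        Indices must be a contiguous range; counts nonnegative integers.
    printed_excluded : optional mapping of maneuver index -> excluded count
        Published excluded counts to use in place of the derived
        ``N[m+1]`` where they differ (a consistency warning is raised on
        any mismatch, as on non-monotone counts).
    """
    if not counts:
        raise ValueError("counts is empty")
    indices = sorted(counts)
    if indices != list(range(indices[0], indices[-1] + 1)):
        raise ValueError(f"maneuver indices must be contiguous, got {indices}")
    for m in indices:
        n = counts[m]
        if not (isinstance(n, (int, np.integer)) and n >= 0):
            raise ValueError(f"counts must be nonnegative integers; counts[{m}] = {n!r}")

    accepted: dict[int, int] = {}
    excluded: dict[int, int] = {}
    for m in indices[:-1]:
        n_next = counts[m + 1]
        if n_next > counts[m]:
            warnings.warn(
                f"maneuver {m + 1} count ({n_next}) exceeds maneuver {m} count "
                f"({counts[m]}); table is not monotone",
                CountConsistencyWarning,
                stacklevel=2,
            )
        accepted[m] = counts[m] - n_next
        excluded[m] = n_next
        if printed_excluded and m in printed_excluded and printed_excluded[m] != n_next:
            warnings.warn(
                f"printed excluded count at maneuver {m} ({printed_excluded[m]}) "
                f"disagrees with next row's performed count ({n_next}); using printed value",
                CountConsistencyWarning,
                stacklevel=2,
            )
            excluded[m] = printed_excluded[m]
            accepted[m] = counts[m] - printed_excluded[m]

    rates = {
        m: (excluded[m] / counts[m] if counts[m] else 0.0)
        for m in excluded
        if m >= MIN_MANEUVERS
    }
    return ManeuverCountTable(counts=dict(counts), accepted=accepted, excluded=excluded, rates=rates)


def packaged_counts_path() -> Path:
    """Filesystem path of the packaged survey count fixture."""
    return Path(resources.files("spirosim").joinpath("data/nhanes_maneuver_counts.csv"))


def read_counts_csv(path: Union[str, Path]) -> tuple[dict[int, int], dict[int, int]]:
    """Read a count table CSV: columns maneuver, n_performed[, excluded_printed]."""
    path = Path(path)
    counts: dict[int, int] = {}
    printed: dict[int, int] = {}
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"maneuver", "n_performed"} <= set(reader.fieldnames):
            raise ValueError(
                f"{path}: expected columns 'maneuver' and 'n_performed', got {reader.fieldnames}"
            )
        for row_number, row in enumerate(reader, start=2):
            try:
                m = int(row["maneuver"])
                counts[m] = int(row["n_performed"])
            except (TypeError, ValueError) as exc:
                raise ValueError(f"{path}: row {row_number}: {exc}") from None
            raw = (row.get("excluded_printed") or "").strip()
            if raw:
                printed[m] = int(raw)
    if not counts:
        raise ValueError(f"{path}: no data rows")
    return counts, printed


def load_packaged_counts() -> tuple[dict[int, int], dict[int, int]]:
    """The packaged survey counts and printed excluded values, as dicts."""
    return read_counts_csv(packaged_counts_path())


@dataclass(frozen=True)
class CvmInference:
    """Grid-search fit of CVm to observed per-maneuver exclusion rates.

    ``losses`` maps each candidate cv_m to its mean absolute deviation, so
    the flatness of the fit around the optimum can be assessed rather than
    only the argmin.
    """

    best_cv_m: float
    losses: Mapping[float, float]
    method: str


def _simulated_continuation_fractions(
    cv_m: float,
    rc: float,
    subject: SubjectProfile,
    maneuver_indices: Sequence[int],
    cv_t: float,
    n_tests: int,
    seed,
) -> dict[int, float]:
    """Fraction of tests needing maneuver m+1 among those that performed m,
    under early stopping — the quantity a survey count table records."""
    variability = derive_sigmas(subject, cv_t, cv_m, RoundingMode.EXACT)
    max_m = max(maneuver_indices)
    cohort = simulate_cohort(
        SimulationConfig(
            subject=subject,
            variability=variability,
            n_tests=n_tests,
            n_maneuvers=max(max_m, MIN_MANEUVERS),
            seed=seed,
        )
    )
    fq = first_qualifying_vector(cohort.maneuvers, rc, MIN_MANEUVERS)
    unresolved_after = {m: int(np.sum((fq == 0) | (fq > m))) for m in range(MIN_MANEUVERS, max_m + 1)}
    out: dict[int, float] = {}
    for m in maneuver_indices:
        at_m = n_tests if m == MIN_MANEUVERS else unresolved_after[m - 1]
        out[m] = unresolved_after[m] / at_m if at_m else 0.0
    return out


def infer_cvm(
    observed_rates: Mapping[int, float],
    rc: float = 0.15,
    subject: Optional[SubjectProfile] = None,
    cv_grid: Sequence[float] = tuple(np.round(np.arange(0.01, 0.101, 0.01), 2)),
    method: str = "analytic_pair",
    cv_t: float = 0.03,
    n_tests: int = 20_902,
    seed=None,
) -> CvmInference:
    """Best-fitting intratest CV for observed per-maneuver exclusion rates.

    For each candidate cv_m the predicted exclusion fraction is either the
    two-maneuver closed form ``pair_failure_probability(rc, cv_m * mu)``
    (method ``analytic_pair``; constant across maneuvers) or simulated
    per-maneuver continuation fractions (method ``simulated``).  The loss
    is the mean absolute deviation from the observed rates; ties go to the
    smaller candidate.
    """
    if not isinstance(observed_rates, Mapping):
        # bare sequence: rates for consecutive maneuvers starting at the minimum
        observed_rates = {MIN_MANEUVERS + i: float(r) for i, r in enumerate(observed_rates)}
    if not observed_rates:
        raise ValueError("observed_rates is empty")
    if len(cv_grid) == 0:
        raise ValueError("cv_grid is empty")
    if method not in ("analytic_pair", "simulated"):
        raise ValueError(f"method must be 'analytic_pair' or 'simulated', got {method!r}")
    subject = subject or SubjectProfile()
    mu = subject.predicted_fev1
    maneuver_indices = sorted(observed_rates)
    obs = np.array([observed_rates[m] for m in maneuver_indices], dtype=float)

    losses: dict[float, float] = {}
    seed_seq = np.random.SeedSequence(seed)
    children = seed_seq.spawn(len(cv_grid))
    for cv, child in zip(cv_grid, children):
        cv = float(cv)
        if method == "analytic_pair":
            pred = np.full_like(obs, pair_failure_probability(rc, cv * mu))
        else:
            fractions = _simulated_continuation_fractions(
                cv, rc, subject, maneuver_indices, cv_t, n_tests, child
            )
            pred = np.array([fractions[m] for m in maneuver_indices])
        losses[cv] = float(np.mean(np.abs(pred - obs)))

    best = min(losses, key=lambda cv: (losses[cv], cv))
    return CvmInference(best_cv_m=best, losses=losses, method=method)
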