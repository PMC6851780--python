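"""Seeded generation of simulated tests under the two-level normal model.

Each test draws a session mean from Normal(predicted_fev1, sigma_t^2);
its maneuvers are then drawn i.i.d. from Normal(test_mean, sigma_m^2).
Maneuvers are independent (no learning or fatigue effects) and sigma_m is
held fixed across tests by default rather than rescaled to each simulated
test mean.
"""

from __future__ import annotations

import csv
import warnings
from collections.abc import Sequence
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Optional, Union

import numpy as np

from .reference import SubjectProfile, VariabilityModel

__all__ = ["SimulationConfig", "SimulatedTest", "Cohort", "simulate_cohort", "write_cohort", "read_cohort"]

DEFAULT_N_TESTS = 20_902
DEFAULT_N_MANEUVERS = 8
_MAX_MANEUVERS = 30


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters for one simulated cohort of tests.

    ``proportional_sigma_m=True`` rescales the intratest SD to each test's
    simulated mean (``cv_m * test_mean``) instead of using the fixed
    ``sigma_m``; the fixed-SD behaviour is the default.
    """

    subject: SubjectProfile
    variability: VariabilityModel
    n_tests: int = DEFAULT_N_TESTS
    n_maneuvers: int = DEFAULT_N_MANEUVERS
    seed: Optional[int] = None
    proportional_sigma_m: bool = False

    def __post_init__(self) -> None:
        if self.n_tests < 1:
            raise ValueError(f"n_tests must be >= 1, got {self.n_tests}")
        if not 1 <= self.n_maneuvers <= _MAX_MANEUVERS:
            raise ValueError(f"n_maneuvers must be in [1, {_MAX_MANEUVERS}], got {self.n_maneuvers}")
        mean = self.subject.predicted_fev1
        if self.variability.sigma_m / mean > 0.3:
            warnings.warn(
                f"sigma_m/mean = {self.variability.sigma_m / mean:.2f} > 0.3; "
                "negative maneuver draws become non-negligible (draws are not truncated)",
                stacklevel=2,
            )


@dataclass(frozen=True)
class SimulatedTest:
    """One simulated test: its latent session mean and ordered maneuvers."""

    test_index: int
    test_mean: float
    maneuvers: tuple[float, ...]


class Cohort(Sequence):
    """A cohort of simulated tests backed by dense arrays.

    Behaves as an immutable sequence of :class:`SimulatedTest`; the raw
    arrays are exposed as ``test_means`` (n,) and ``maneuvers`` (n, k) for
    vectorised analysis.  Maneuver column order is generation order.
    """

    def __init__(self, test_means: np.ndarray, maneuvers: np.ndarray) -> None:
        test_means = np.asarray(test_means, dtype=float)
        maneuvers = np.asarray(maneuvers, dtype=float)
        if maneuvers.ndim != 2 or test_means.shape != (maneuvers.shape[0],):
            raise ValueError("test_means must be (n,) and maneuvers (n, k)")
        self.test_means = test_means
        self.maneuvers = maneuvers
        self.test_means.setflags(write=False)
        self.maneuvers.setflags(write=False)

    @property
    def n_tests(self) -> int:
        return self.maneuvers.shape[0]

    @property
    def n_maneuvers(self) -> int:
        return self.maneuvers.shape[1]

    def __len__(self) -> int:
        return self.n_tests

    def __getitem__(self, index):
        if isinstance(index, slice):
            return Cohort(self.test_means[index], self.maneuvers[index])
        i = int(index)
        if i < 0:
            i += self.n_tests
        if not 0 <= i < self.n_tests:
            raise IndexError(index)
        return SimulatedTest(
            test_index=i,
            test_mean=float(self.test_means[i]),
            maneuvers=tuple(float(v) for v in self.maneuvers[i]),
        )

    def __iter__(self) -> Iterator[SimulatedTest]:
        for i in range(self.n_tests):
            yield self[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        return (
            self.test_means.shape == other.test_means.shape
            and self.maneuvers.shape == other.maneuvers.shape
            and bool(np.array_equal(self.test_means, other.test_means))
            and bool(np.array_equal(self.maneuvers, other.maneuvers))
        )


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Draw a seeded cohort of tests under the two-level normal model.

    Draw order is fixed: all test means first, then maneuver deviations
    test-by-test, so a given seed reproduces the cohort bit-for-bit.
    Draws are not truncated at zero.
    """
    rng = np.random.default_rng(config.seed)
    mu = config.subject.predicted_fev1
    sigma_t = config.variability.sigma_t
    n, k = config.n_tests, config.n_maneuvers

    test_means = mu + sigma_t * rng.standard_normal(n)
    noise = rng.standard_normal((n, k))
    if config.proportional_sigma_m:
        sigma_m = config.variability.cv_m * test_means[:, None]
    else:
        sigma_m = config.variability.sigma_m
    maneuvers = test_means[:, None] + sigma_m * noise
    return Cohort(test_means, maneuvers)


def _header(n_maneuvers: int) -> list[str]:
    return ["test_index", "test_mean"] + [f"maneuver_{j}" for j in range(1, n_maneuvers + 1)]


def write_cohort(cohort: Cohort, path: Union[str, Path]) -> None:
    """Write a cohort to CSV with full round-trip precision (17 sig. digits)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_header(cohort.n_maneuvers))
        for test in cohort:
            writer.writerow(
                [test.test_index, format(test.test_mean, ".17g")]
                + [format(v, ".17g") for v in test.maneuvers]
            )


def read_cohort(path: Union[str, Path]) -> Cohort:
    """Read a cohort CSV written by :func:`write_cohort`.

    Raises
    ------
    ValueError
        If the header lacks the expected columns, or a row is malformed
        (the error names the offending row).
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file") from None
        if len(header) < 3 or header[:2] != ["test_index", "test_mean"]:
            raise ValueError(
                f"{path}: bad header {header!r}; expected columns "
                f"{_header(max(len(header) - 2, 1))!r}"
            )
        n_maneuvers = len(header) - 2
        expected = _header(n_maneuvers)
        if header != expected:
            raise ValueError(f"{path}: bad header {header!r}; expected columns {expected!r}")
        means, rows = [], []
        for row_number, row in enumerate(reader, start=2):
            if len(row) != len(expected):
                raise ValueError(
                    f"{path}: row {row_number} has {len(row)} fields, expected {len(expected)}"
                )
            try:
                means.append(float(row[1]))
                rows.append([float(v) for v in row[2:]])
            except ValueError as exc:
                raise ValueError(f"{path}: row {row_number}: {exc}") from None
    if not rows:
        raise ValueError(f"{path}: no data rows")
    return Cohort(np.array(means), np.array(rows))
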