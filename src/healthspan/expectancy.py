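"""Multistate life tables: state occupancy and health expectancies.

Given fitted (or true) transition intensities, the life-table step converts
them into state-occupancy probabilities over an age grid and integrates the
curves to obtain total life expectancy (TLE), cognitive-impairment-free life
expectancy (CIFLE = expected years in state 1 starting CI-free) and
cognitively impaired life expectancy (CILE), with TLE = CIFLE + CILE.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .model import IntensityParameters, _piece_probs


class GridTruncationError(ValueError):
    """Too much probability mass survives past the grid's maximum age."""


@dataclass(frozen=True)
class AgeGrid:
    """Uniform age grid for occupancy integration.

    The default step of one month keeps the trapezoidal quadrature error far
    below the reporting precision of expectancies (0.1 years).
    """

    start: float
    stop: float = 110.0
    step: float = 1.0 / 12.0

    def __post_init__(self) -> None:
        if not self.start < self.stop:
            raise ValueError("start must be below stop")
        if self.step <= 0:
            raise ValueError("step must be positive")
        n = (self.stop - self.start) / self.step
        if abs(n - round(n)) > 1e-9:
            raise ValueError("(stop - start) must be an integral number of steps")

    @property
    def n_cells(self) -> int:
        return int(round((self.stop - self.start) / self.step))

    @property
    def ages(self) -> np.ndarray:
        return self.start + self.step * np.arange(self.n_cells + 1)


@dataclass
class OccupancyCurves:
    """State-occupancy probabilities P_sr(start, u) along an age grid."""

    ages: np.ndarray
    p11: np.ndarray  # P(state 1 at u | state 1 at start)
    p12: np.ndarray  # P(state 2 at u | state 1 at start)
    p22: np.ndarray  # P(state 2 at u | state 2 at start)

    @property
    def alive_from_healthy(self) -> np.ndarray:
        return self.p11 + self.p12


def occupancy_curve(
    params: IntensityParameters,
    covariates: Mapping[str, float] | None = None,
    grid: AgeGrid | None = None,
    piece_step: float = 0.25,
) -> OccupancyCurves:
    """Propagate occupancy probabilities across the grid from the identity row.

    Each grid cell is subdivided into pieces of at most ``piece_step`` years;
    within a piece the generator is frozen at the piece midpoint (exact when
    intensities are age-constant) and rows compose by Chapman–Kolmogorov.
    """
    if grid is None:
        raise ValueError("an AgeGrid is required")
    cell = grid.step
    sub = max(1, int(np.ceil(cell / piece_step - 1e-12)))
    n_pieces = grid.n_cells * sub
    bounds = grid.start + (grid.stop - grid.start) * np.arange(n_pieces + 1) / n_pieces
    mids = 0.5 * (bounds[:-1] + bounds[1:])
    dts = np.diff(bounds)
    q12 = np.atleast_1d(params.intensity("12", mids, covariates))
    q13 = np.atleast_1d(params.intensity("13", mids, covariates))
    q23 = np.atleast_1d(params.intensity("23", mids, covariates))
    if q12.size == 1:
        q12, q13, q23 = (np.full(n_pieces, v[0]) for v in (q12, q13, q23))
    p11s, p12s, p22s = _piece_probs(q12, q13, q23, dts)

    P11 = np.empty(grid.n_cells + 1)
    P12 = np.empty(grid.n_cells + 1)
    P22 = np.empty(grid.n_cells + 1)
    r11, r12, r22 = 1.0, 0.0, 1.0
    P11[0], P12[0], P22[0] = r11, r12, r22
    k = 0
    for i in range(n_pieces):
        r12 = r11 * p12s[i] + r12 * p22s[i]
        r11 = r11 * p11s[i]
        r22 = r22 * p22s[i]
        if (i + 1) % sub == 0:
            k += 1
            P11[k], P12[k], P22[k] = r11, r12, r22
    return OccupancyCurves(ages=grid.ages, p11=P11, p12=P12, p22=P22)


@dataclass
class ExpectancyResult:
    """Health expectancies at a starting age for one covariate profile.

    ``cifle`` (= e11) and ``cile`` (= e12) are the expected years spent
    CI-free and with CI for someone CI-free at ``start_age``; ``e22`` is the
    residual expectancy of someone already impaired.  ``truncation_mass`` is
    the probability of still being alive at the grid's maximum age: expected
    years beyond it are not counted.
    """

    start_age: float
    covariates: dict = field(default_factory=dict)
    e11: float = 0.0
    e12: float = 0.0
    e22: float = 0.0
    truncation_mass: float = 0.0
    grid: AgeGrid | None = None

    @property
    def cifle(self) -> float:
        return self.e11

    @property
    def cile(self) -> float:
        return self.e12

    @property
    def tle(self) -> float:
        return self.e11 + self.e12

    @property
    def proportion_cifle(self) -> float:
        """Share of remaining life spent CI-free, in percent."""
        return 100.0 * self.e11 / self.tle if self.tle > 0 else 100.0


def expectancies(
    params: IntensityParameters,
    covariates: Mapping[str, float] | None = None,
    grid: AgeGrid | None = None,
    piece_step: float = 0.25,
    truncation_error: float = 0.05,
    truncation_warn: float = 1e-3,
) -> ExpectancyResult:
    """Integrate occupancy curves into health expectancies (trapezoidal rule)."""
    if grid is None:
        raise ValueError("an AgeGrid is required")
    curves = occupancy_curve(params, covariates, grid, piece_step=piece_step)
    mass = float(curves.p11[-1] + curves.p12[-1])
    if mass > truncation_error:
        raise GridTruncationError(
            f"probability {mass:.4f} still alive at age {grid.stop}; "
            "raise the grid's maximum age"
        )
    if mass > truncation_warn:
        warnings.warn(
            f"truncation mass {mass:.2e} at grid maximum age {grid.stop}",
            RuntimeWarning,
            stacklevel=2,
        )
    e11 = float(np.trapezoid(curves.p11, curves.ages))
    e12 = float(np.trapezoid(curves.p12, curves.ages))
    e22 = float(np.trapezoid(curves.p22, curves.ages))
    return ExpectancyResult(
        start_age=grid.start,
        covariates=dict(covariates or {}),
        e11=e11,
        e12=e12,
        e22=e22,
        truncation_mass=mass,
        grid=grid,
    )


def averaged_expectancies(
    params: IntensityParameters,
    profiles,
    grid: AgeGrid,
    profile_weights=None,
    piece_step: float = 0.25,
    **kwargs,
) -> ExpectancyResult:
    """Population-averaged expectancies over a set of covariate profiles.

    Expectancies are linear in the occupancy curves, so averaging the
    per-profile expectancy components with the given weights equals averaging
    the curves first.  ``profiles`` is an iterable of covariate mappings
    (e.g. rows of a confounder table); weights default to uniform.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("at least one profile required")
    w = np.ones(len(profiles)) if profile_weights is None else np.asarray(
        profile_weights, dtype=float
    )
    if len(w) != len(profiles) or np.any(w < 0) or w.sum() == 0:
        raise ValueError("invalid profile weights")
    w = w / w.sum()
    parts = [
        expectancies(params, prof, grid, piece_step=piece_step, **kwargs)
        for prof in profiles
    ]
    return ExpectancyResult(
        start_age=grid.start,
        covariates={"<averaged>": len(profiles)},
        e11=float(np.dot(w, [p.e11 for p in parts])),
        e12=float(np.dot(w, [p.e12 for p in parts])),
        e22=float(np.dot(w, [p.e22 for p in parts])),
        truncation_mass=float(np.dot(w, [p.truncation_mass for p in parts])),
        grid=grid,
    )
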