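"""Diffusive insect dispersal from randomized outbreak epicenters.

The movement model is an unbiased Gaussian random walk on the unbounded
plane with one step per day: per-axis daily increments are iid
N(0, (4·sqrt(D))²), so the per-axis position standard deviation after t
days is

    sigma(D, t) = 4 * sqrt(D * t)            [metres]

with D the diffusion coefficient in m²/day.  This is the unique iid-Gaussian
walk whose marginal spread follows that law.  Insects are never removed or
reflected — egress past the survey grid is possible by construction, which
the containment experiments rely on.

The closed-form helpers (:func:`sigma`, :func:`quantile_distance`,
:func:`days_to_quantile`) expose the same law analytically, using the
one-axis normal-quantile convention (e.g. z(0.95) ≈ 1.6449).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .grids import MILE_M


@dataclass(frozen=True)
class DispersalParams:
    """Movement and outbreak-location parameters.

    D is the diffusion coefficient (m²/day); outbreak epicenters are drawn
    uniformly from a square of side ``epicenter_side_m`` centred on the grid
    origin (default: one square-mile core cell).
    """

    D: float
    epicenter_side_m: float = MILE_M

    def __post_init__(self) -> None:
        if self.D < 0:
            raise ValueError(f"diffusion coefficient must be >= 0, got {self.D}")
        if self.epicenter_side_m <= 0:
            raise ValueError("epicenter_side_m must be > 0")


@dataclass
class Trajectory:
    """Daily positions of one simulated cohort.

    positions has shape (duration_days, n_insects, 2); day index 0 is the
    end of day 1.  All insects start the walk at the shared epicenter.
    """

    epicenter: np.ndarray
    positions: np.ndarray

    @property
    def duration_days(self) -> int:
        return self.positions.shape[0]

    @property
    def n_insects(self) -> int:
        return self.positions.shape[1]


def sigma(D: float, t: float) -> float:
    """Per-axis dispersal standard deviation after t days: 4·sqrt(D·t) m."""
    if D < 0 or t < 0:
        raise ValueError("D and t must be non-negative")
    return 4.0 * math.sqrt(D * t)


def quantile_distance(sigma_m: float, q: float) -> float:
    """Distance of the q-th per-axis quantile of a centred normal spread.

    Uses the one-axis convention z(q)·sigma; e.g. sigma = 1549 m gives a
    95th-percentile distance of about 2,548 m.
    """
    if not 0.0 < q < 1.0:
        raise ValueError(f"quantile must be in (0, 1), got {q}")
    return float(stats.norm.ppf(q)) * sigma_m


def days_to_quantile(D: float, distance_m: float, q: float) -> float:
    """Days until the q-th quantile of the spread reaches ``distance_m``.

    Inverts sigma = 4·sqrt(D·t) through the quantile convention:
    t = (distance / (z(q)·4))² / D.  D = 0 yields infinity.
    """
    if D < 0:
        raise ValueError("D must be >= 0")
    if distance_m <= 0:
        raise ValueError("distance_m must be > 0")
    if not 0.0 < q < 1.0:
        raise ValueError(f"quantile must be in (0, 1), got {q}")
    if D == 0:
        return math.inf
    z = float(stats.norm.ppf(q))
    return (distance_m / (4.0 * z)) ** 2 / D


def sample_epicenter(rng: np.random.Generator,
                     side_m: float = MILE_M) -> np.ndarray:
    """Uniform outbreak location within the central core square."""
    half = side_m / 2.0
    return rng.uniform(-half, half, size=2)


def simulate_trajectories(params: DispersalParams, epicenter: np.ndarray,
                          n_insects: int, duration_days: int,
                          rng: np.random.Generator) -> Trajectory:
    """Random-walk trajectories of a cohort sharing one epicenter.

    Each insect takes one Gaussian step per day with per-axis s.d.
    4·sqrt(D), independently of the others; positions are recorded at the
    end of each day.
    """
    if n_insects < 1 or duration_days < 1:
        raise ValueError("n_insects and duration_days must be >= 1")
    epicenter = np.asarray(epicenter, dtype=float)
    step_sd = 4.0 * math.sqrt(params.D)
    # scale=0 is valid (degenerate walk) and keeps the draw count identical
    # across D values, so common-random-number comparisons stay aligned
    steps = rng.normal(0.0, step_sd, size=(duration_days, n_insects, 2))
    positions = epicenter + np.cumsum(steps, axis=0)
    return Trajectory(epicenter=epicenter, positions=positions)
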