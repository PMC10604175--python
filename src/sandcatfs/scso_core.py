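"""Continuous sand cat swarm primitives.

The sand cat swarm optimizer (SCSO) mimics the hunting behaviour of sand
cats, which perceive low-frequency sound in a sensitivity band that the
algorithm decays linearly over the run: the *general sensitivity* ``rg``
starts at ``sM`` (canonically 2) and reaches exactly 0 at the final
iteration.  Two per-agent controls derive from it each iteration:

* ``R`` — a phase-control draw in ``[-rg, rg]`` deciding between
  exploitation (move toward the global best along a random angle) and
  exploration (move relative to a random peer);
* ``r`` — a per-agent sensitivity draw in ``[0, rg]`` scaling the
  exploration step.

Everything here is pure arithmetic on scalars plus seeded draws; the
binary machinery lives in :mod:`sandcatfs.binarization` and the loop in
:mod:`sandcatfs.optimizer`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ScheduleState",
    "StepControl",
    "compute_rg",
    "compute_R",
    "compute_r",
    "sample_theta",
    "exploit_update",
    "explore_update",
    "pick_candidate",
]


class InvalidScheduleError(ValueError):
    """Raised for an iteration counter outside ``0 <= t <= T`` or ``T <= 0``."""


@dataclass(frozen=True)
class ScheduleState:
    """Iteration bookkeeping for the linearly decaying sensitivity.

    Attributes
    ----------
    t : int
        Current iteration, ``0 <= t <= T``.
    T : int
        Maximum number of iterations, ``> 0``.
    sM : float
        Initial sensitivity; the canonical value is 2 (the sand cat's
        2 kHz hearing ceiling).
    """

    t: int
    T: int
    sM: float = 2.0

    @property
    def rg(self) -> float:
        """General sensitivity at iteration ``t``: ``sM * (1 - t/T)``."""
        return compute_rg(self.t, self.T, self.sM)


@dataclass(frozen=True)
class StepControl:
    """Per-agent step controls: phase value ``R``, sensitivity ``r``, angle."""

    R: float
    r: float
    theta_deg: float


def compute_rg(t: int, T: int, sM: float = 2.0) -> float:
    """General sensitivity ``rg = sM - sM * t / T``.

    Decays linearly from ``sM`` at ``t = 0`` to exactly 0 at ``t = T``.
    """
    if T <= 0 or t < 0 or t > T:
        raise InvalidScheduleError(f"invalid schedule: t={t}, T={T}")
    if sM <= 0:
        raise InvalidScheduleError(f"initial sensitivity must be positive, got {sM}")
    return sM - sM * t / T


def compute_R(rg: float, u: float) -> float:
    """Phase-control value ``R = 2 * rg * u - rg``, uniform over ``[-rg, rg]``."""
    return 2.0 * rg * u - rg


def compute_r(rg: float, u: float) -> float:
    """Per-agent sensitivity ``r = rg * u``, uniform over ``[0, rg]``."""
    return rg * u


def sample_theta(rng: np.random.Generator) -> float:
    """Draw a movement angle in degrees, uniform over ``[0, 360]``.

    The roulette-wheel selection of the angle uses equal slices, which
    degenerates to a uniform draw over the circle.
    """
    return float(rng.uniform(0.0, 360.0))


def exploit_update(
    x_ij: float,
    xbest_j: float,
    u1: float,
    u2: float,
    theta_deg: float,
    abs_distance: bool = True,
) -> float:
    """Exploitation (prey-attack) update for one coordinate.

    Computes the randomized distance to the best position,
    ``Xrand = |u1 * xbest_j - x_ij|``, then steps from the best position
    along a random angle: ``xbest_j - u2 * Xrand * cos(theta)``.

    ``abs_distance=False`` drops the magnitude bars around the distance
    term (a strict-literal variant); the default keeps the distance
    semantics of the original formulation.
    """
    xrand = u1 * xbest_j - x_ij
    if abs_distance:
        xrand = abs(xrand)
    return xbest_j - u2 * xrand * math.cos(math.radians(theta_deg))


def explore_update(x_ij: float, xcand_j: float, r: float, u: float) -> float:
    """Exploration (prey-search) update: ``r * (xcand_j - u * x_ij)``."""
    return r * (xcand_j - u * x_ij)


def pick_candidate(n_individuals: int, rng: np.random.Generator) -> int:
    """Uniform random individual index (0-based) via ``floor(N * u)``.

    The classic formulation is 1-based, ``cp = floor(N * u) + 1``; this
    returns the equivalent 0-based index.
    """
    if n_individuals < 1:
        raise ValueError("population is empty")
    # u < 1 strictly, so floor(N*u) <= N-1 always
    return int(n_individuals * rng.uniform(0.0, 1.0))
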