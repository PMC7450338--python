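"""Cuckoo-search moves: Levy-flight machinery, the adaptive update, and the
biased selective random walk (nest abandonment).

The standard cuckoo search alternates a Levy-flight random walk around the
current best nest (exploitation; heavy-tailed steps via the Mantegna scheme)
with a biased selective random walk that rebuilds a fraction ``p_a`` of nest
coordinates from the difference of two random nests (exploration).  The
adaptive variant used inside the hybrid replaces the Levy walk by a
normally-perturbed step toward/away from the global best whose magnitude is
set by the growing step-size schedule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gamma

from .core import ConfigurationError, ObjectiveSpec


@dataclass
class CuckooParams:
    """Standard cuckoo-search constants.

    p_a : discovery probability of an alien egg (fraction of coordinates
        rebuilt by abandonment); best-practice value 0.25.
    alpha0 : Levy-walk scale of the standard algorithm, 0.01.
    lam : Levy exponent, 1.5.
    """

    p_a: float = 0.25
    alpha0: float = 0.01
    lam: float = 1.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_a <= 1.0:
            raise ConfigurationError("p_a must lie in [0, 1]")
        if not 1.0 <= self.lam <= 2.0:
            raise ConfigurationError("lam must lie in [1, 2]")


def levy_scale_coefficient(lam: float) -> float:
    """Mantegna scale coefficient for Levy-stable step generation.

    ``[ Gamma(1+lam) sin(pi lam / 2) / ( Gamma((1+lam)/2) lam 2^((lam-1)/2) ) ]^(1/lam)``

    Equals 1 in the ``lam -> 1`` limit and is positive and finite on [1, 2].
    """
    if not 1.0 <= lam <= 2.0:
        raise ConfigurationError(f"Levy exponent must lie in [1, 2]; got {lam}")
    num = gamma(1.0 + lam) * np.sin(np.pi * lam / 2.0)
    den = gamma((1.0 + lam) / 2.0) * lam * 2.0 ** ((lam - 1.0) / 2.0)
    return float((num / den) ** (1.0 / lam))


def levy_step(rng: np.random.Generator, lam: float, coefficient: float) -> float:
    """One Mantegna draw: ``coefficient * eps / |phi|^(1/lam)``.

    ``eps`` and ``phi`` are independent standard normals; ``phi`` is redrawn
    in the (measure-zero) event it is exactly zero.
    """
    eps = rng.standard_normal()
    phi = rng.standard_normal()
    while phi == 0.0:
        phi = rng.standard_normal()
    return coefficient * eps / abs(phi) ** (1.0 / lam)


def lfrw_update(
    position: np.ndarray,
    best_position: np.ndarray,
    params: CuckooParams,
    problem: ObjectiveSpec,
    rng: np.random.Generator,
    coefficient: float | None = None,
) -> np.ndarray:
    """Standard-CS Levy-flight random walk around the current best nest.

    ``x + alpha0 * Levy(lam) * (x - x_best)``, one scalar Levy draw per call,
    clipped to bounds.
    """
    if coefficient is None:
        coefficient = levy_scale_coefficient(params.lam)
    step = levy_step(rng, params.lam, coefficient)
    return problem.clip(position + params.alpha0 * step * (position - best_position))


def acs_update(
    position: np.ndarray,
    gbest_position: np.ndarray,
    step: float,
    problem: ObjectiveSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Adaptive cuckoo move: ``x + randn . step . (x - x_gbest)``.

    ``randn`` is an independent standard-normal draw per dimension; the step
    magnitude comes from the growing schedule, so the move intensifies around
    the global best early in the run and diversifies late.
    """
    randn = rng.standard_normal(position.shape)
    return problem.clip(position + randn * step * (position - gbest_position))


def bsrw_abandon(
    i: int,
    positions: np.ndarray,
    p_a: float,
    problem: ObjectiveSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Biased selective random walk (nest abandonment) for agent ``i``.

    Each coordinate is, with probability ``p_a``, rebuilt as
    ``x_j + s * (x_{a,j} - x_{b,j})`` with one scalar ``s ~ U[0,1]`` per call
    and ``a != b != i`` drawn uniformly; otherwise left unchanged.
    """
    n = positions.shape[0]
    if n < 3:
        raise ConfigurationError("abandonment walk needs at least 3 agents")
    others = np.delete(np.arange(n), i)
    a, b = rng.choice(others, size=2, replace=False)
    s = rng.uniform()
    mask = rng.uniform(size=positions.shape[1]) < p_a
    candidate = positions[i] + mask * s * (positions[a] - positions[b])
    return problem.clip(candidate)
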