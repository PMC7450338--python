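"""Grey-wolf moves: prey encircling, the intensification-dedicated
fitness-based position update, and the standard-GWO baseline.

Standard GWO averages the three candidates obtained by encircling the alpha,
beta and delta leaders.  The intensification-dedicated variant instead
evaluates all three candidates and keeps the fittest, discarding the
averaging recombination; with the control parameter ``a`` capped at 1 the
encircling coefficient ``A`` stays in [-1, 1], so the move always attacks
(intensifies) rather than diverges.
"""

from __future__ import annotations

import numpy as np

from .core import BudgetExhausted, LeaderBoard, ObjectiveSpec, Population


def encircle_candidate(
    position: np.ndarray,
    leader_position: np.ndarray,
    a: float,
    problem: ObjectiveSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """One prey-encircling candidate around a leader.

    Per dimension: ``A = 2 a r1 - a``, ``C = 2 r2``,
    ``D = |C x_leader - x|``, candidate ``= x_leader - A D``; r1, r2 are
    uniform [0,1] draws per dimension, result clipped to bounds.
    """
    d = position.shape[0]
    r1 = rng.uniform(size=d)
    r2 = rng.uniform(size=d)
    A = 2.0 * a * r1 - a
    C = 2.0 * r2
    D = np.abs(C * leader_position - position)
    return problem.clip(leader_position - A * D)


def idgwo_position_update(
    population: Population,
    i: int,
    leaders: LeaderBoard,
    leader_positions: np.ndarray,
    a: float,
    problem: ObjectiveSpec,
    rng: np.random.Generator,
    elitist: bool = False,
) -> int:
    """Fitness-value-based position update of agent ``i`` (3 FEs, atomic).

    Builds three encircling candidates from the alpha, beta and delta leader
    positions (independent coefficient draws per candidate), evaluates all
    three, and replaces the agent with the lowest-fitness candidate
    unconditionally (ties keep the lowest candidate index).  With
    ``elitist=True`` the incumbent additionally survives if it beats all
    three candidates.  Returns the index (0/1/2) of the chosen candidate, or
    -1 when the elitist incumbent was kept.
    """
    if population.budget_left() < 3:
        raise BudgetExhausted("need 3 evaluations for the grey-wolf update")
    candidates = [
        encircle_candidate(population.positions[i], leader_positions[k], a, problem, rng)
        for k in range(3)
    ]
    fits = np.array([problem.evaluate(c, rng) for c in candidates])
    population.fe_count += 3
    best = int(np.argmin(fits))  # first minimum -> lowest candidate index on ties
    if elitist and population.fitness[i] <= fits[best]:
        return -1
    population.positions[i] = candidates[best]
    population.fitness[i] = fits[best]
    return best


def gwo_linear_control(iteration: int, max_iter: int) -> float:
    """Standard-GWO schedule: ``a`` decreases linearly from 2 to 0."""
    return 2.0 - 2.0 * iteration / max_iter


def gwo_update(
    position: np.ndarray,
    leader_positions: np.ndarray,
    a: float,
    problem: ObjectiveSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Standard-GWO position update: mean of the three encircling candidates."""
    candidates = [
        encircle_candidate(position, leader_positions[k], a, problem, rng) for k in range(3)
    ]
    return problem.clip(np.mean(candidates, axis=0))
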