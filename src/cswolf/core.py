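"""Population machinery shared by every optimizer in the package.

A *search agent* (a host nest in cuckoo-search terms, a wolf in grey-wolf
terms) is one candidate solution: a real position vector inside a box, plus
its cached objective value.  Everything here is orientation-fixed: fitness is
always minimized.  Evaluation accounting is explicit because the stopping
rule of the optimizers is a fitness-evaluation (FE) budget, not an iteration
count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np


class ConfigurationError(ValueError):
    """Raised for invalid optimizer or problem configuration."""


class BudgetExhausted(RuntimeError):
    """Signals that the fitness-evaluation budget does not cover the next step."""


@dataclass
class ObjectiveSpec:
    """A box-bounded minimization problem.

    Parameters
    ----------
    d : int
        Dimension of the search space.
    lower, upper : ndarray of shape (d,)
        Box bounds; ``lower < upper`` elementwise.
    func : callable ``(x, rng) -> float``
        Objective evaluated at a position.  The optional generator argument
        lets stochastic objectives (e.g. a stochastic binarization layer)
        draw reproducible randomness; deterministic objectives ignore it.
    name : str
        Human-readable label used in logs.
    """

    d: int
    lower: np.ndarray
    upper: np.ndarray
    func: Callable[[np.ndarray, Optional[np.random.Generator]], float]
    name: str = "objective"

    def __post_init__(self) -> None:
        self.lower = np.broadcast_to(np.asarray(self.lower, dtype=float), (self.d,)).copy()
        self.upper = np.broadcast_to(np.asarray(self.upper, dtype=float), (self.d,)).copy()
        if not np.all(self.lower < self.upper):
            raise ConfigurationError("lower bounds must be strictly below upper bounds")

    def clip(self, x: np.ndarray) -> np.ndarray:
        """Project a position onto the box (applied before every evaluation)."""
        return np.clip(x, self.lower, self.upper)

    def evaluate(self, x: np.ndarray, rng: Optional[np.random.Generator] = None) -> float:
        value = float(self.func(x, rng))
        if not np.isfinite(value):
            raise FloatingPointError(f"objective '{self.name}' returned non-finite value {value}")
        return value


@dataclass
class LeaderBoard:
    """Indices of the three best agents and the worst of the remainder.

    ``alpha``, ``beta``, ``delta`` are the best, second and third best agents
    (grey-wolf social hierarchy); ``worst`` is the highest-fitness agent among
    the remaining omega agents.  Ties break toward the lower agent index.
    """

    alpha: int
    beta: int
    delta: int
    worst: int


@dataclass
class Population:
    """An evaluated swarm plus its fitness-evaluation ledger."""

    positions: np.ndarray  # (n, d)
    fitness: np.ndarray  # (n,)
    fe_count: int
    fe_budget: int
    gen: int = 0

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    def budget_left(self) -> int:
        return self.fe_budget - self.fe_count

    def best_index(self) -> int:
        return int(np.argmin(self.fitness))


def initialize_population(
    problem: ObjectiveSpec,
    n: int,
    rng: np.random.Generator,
    fe_budget: int,
) -> Population:
    """Draw ``n`` agents uniformly inside the bounds and evaluate them all.

    Requires ``n >= 4`` so that the leader hierarchy (alpha, beta, delta plus
    at least one omega) is well defined.
    """
    if n < 4:
        raise ConfigurationError(
            f"population size must be >= 4 (alpha/beta/delta leaders plus an omega agent); got {n}"
        )
    positions = rng.uniform(problem.lower, problem.upper, size=(n, problem.d))
    fitness = np.array([problem.evaluate(positions[i], rng) for i in range(n)])
    return Population(positions=positions, fitness=fitness, fe_count=n, fe_budget=fe_budget)


def greedy_select(
    population: Population,
    i: int,
    candidate: np.ndarray,
    problem: ObjectiveSpec,
    rng: Optional[np.random.Generator] = None,
) -> bool:
    """Elitist replacement: keep whichever of incumbent/candidate is fitter.

    Evaluates the candidate (one FE), replaces agent ``i`` in place iff the
    candidate is strictly better; ties keep the incumbent.  Returns True if
    the candidate was accepted.

    Raises
    ------
    BudgetExhausted
        If no FE budget remains; the incumbent is left untouched.
    """
    if population.budget_left() < 1:
        raise BudgetExhausted("fitness-evaluation budget exhausted before candidate evaluation")
    cand = problem.clip(candidate)
    f_cand = problem.evaluate(cand, rng)
    population.fe_count += 1
    if f_cand < population.fitness[i]:
        population.positions[i] = cand
        population.fitness[i] = f_cand
        return True
    return False


def rank_leaders(population: Population) -> LeaderBoard:
    """Identify alpha/beta/delta (three lowest fitness) and the worst omega.

    Ties break toward the lower agent index (stable sort on fitness).
    """
    fitness = population.fitness
    if not np.all(np.isfinite(fitness)):
        raise RuntimeError("all agents must be evaluated before ranking leaders")
    order = np.argsort(fitness, kind="stable")
    alpha, beta, delta = (int(order[k]) for k in range(3))
    rest = order[3:]
    # argmax returns the first maximum, i.e. the lowest index on ties
    worst = int(rest[np.argmax(fitness[rest])])
    return LeaderBoard(alpha=alpha, beta=beta, delta=delta, worst=worst)


@dataclass
class RunResult:
    """Outcome of one optimizer run.

    ``log`` rows are ``(gen, best_fitness, mean_fitness, fe_count)`` with the
    best-so-far fitness, so the logged best is non-increasing even for moves
    that replace agents unconditionally.
    """

    best_position: np.ndarray
    best_fitness: float
    log: list = field(default_factory=list)
    fe_count: int = 0
    seed: Optional[int] = None
    n_generations: int = 0

    def log_text(self) -> str:
        """Convergence log as tab-separated rows: gen, best, mean, fe_count."""
        lines = ["gen\tbest_fitness\tmean_fitness\tfe_count"]
        for gen, best, mean, fe in self.log:
            lines.append(f"{gen}\t{best:.12g}\t{mean:.12g}\t{fe}")
        return "\n".join(lines) + "\n"
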