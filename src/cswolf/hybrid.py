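"""Main optimizer loops: the adaptive cuckoo/grey-wolf hybrid plus the
standard cuckoo-search and grey-wolf baselines.

Per generation the hybrid ranks the leaders once, then gives every agent
three moves: the adaptive cuckoo step toward/away from the global best
(1 FE, greedy-selected), the abandonment walk (1 FE, greedy-selected), and
the three-candidate grey-wolf intensification update (3 FEs, unconditional
replacement) — five fitness evaluations per agent per generation.  The
number of generations is derived from the evaluation budget,
``gen_max = floor((fe_budget - n) / (5 n))``, so the schedules sweep their
full range exactly over the run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .acs import CuckooParams, acs_update, bsrw_abandon, levy_scale_coefficient, lfrw_update
from .core import (
    BudgetExhausted,
    ConfigurationError,
    ObjectiveSpec,
    Population,
    RunResult,
    greedy_select,
    initialize_population,
    rank_leaders,
)
from .idgwo import gwo_linear_control, gwo_update, idgwo_position_update
from .schedules import ScheduleConfig, acs_step_size, gwo_control_parameter, modulation_index

#: FEs spent per agent per generation by the hybrid: 1 (cuckoo) + 1 (abandon) + 3 (wolf)
FE_PER_AGENT_HYBRID = 5


@dataclass
class HybridConfig:
    """Run configuration; defaults follow the reference protocol
    (population 30, budget 10000 evaluations, step_max = a_o = 1, p_a = 0.25)."""

    n: int = 30
    fe_budget: int = 10000
    schedule: ScheduleConfig = None  # gen_max filled in from the budget
    cuckoo: CuckooParams = field(default_factory=CuckooParams)
    seed: Optional[int] = None
    elitist_idgwo: bool = False
    step_max: float = 1.0
    a_o: float = 1.0

    def __post_init__(self) -> None:
        if self.n < 4:
            raise ConfigurationError("population size must be >= 4")
        if self.fe_budget < self.n + FE_PER_AGENT_HYBRID * self.n:
            raise ConfigurationError(
                "fe_budget must cover initialization plus at least one full generation "
                f"({self.n + FE_PER_AGENT_HYBRID * self.n} evaluations)"
            )
        if self.schedule is None:
            self.schedule = ScheduleConfig(
                step_max=self.step_max, a_o=self.a_o, gen_max=self.gen_max
            )

    @property
    def gen_max(self) -> int:
        return (self.fe_budget - self.n) // (FE_PER_AGENT_HYBRID * self.n)


def _rng_from(config: HybridConfig, rng: Optional[np.random.Generator]) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng(config.seed)


def _track_best(population: Population, best_pos, best_fit):
    i = population.best_index()
    if population.fitness[i] < best_fit:
        return population.positions[i].copy(), float(population.fitness[i])
    return best_pos, best_fit


def run_continuous(
    problem: ObjectiveSpec,
    config: HybridConfig,
    rng: Optional[np.random.Generator] = None,
) -> RunResult:
    """Run the hybrid optimizer on a continuous problem.

    Each agent's five candidate evaluations are atomic with respect to the
    budget: a generation may end mid-population, but no agent is left with a
    partially applied update.
    """
    rng = _rng_from(config, rng)
    sched = config.schedule
    gen_max = sched.gen_max
    pop = initialize_population(problem, config.n, rng, config.fe_budget)
    best_pos, best_fit = pop.positions[pop.best_index()].copy(), float(np.min(pop.fitness))
    log = [(0, best_fit, float(np.mean(pop.fitness)), pop.fe_count)]

    gen = 0
    exhausted = False
    while gen < gen_max and not exhausted:
        leaders = rank_leaders(pop)
        f_alpha = float(pop.fitness[leaders.alpha])
        f_beta = float(pop.fitness[leaders.beta])
        f_delta = float(pop.fitness[leaders.delta])
        f_worst = float(pop.fitness[leaders.worst])
        leader_positions = pop.positions[[leaders.alpha, leaders.beta, leaders.delta]].copy()
        for i in range(pop.n):
            if pop.budget_left() < FE_PER_AGENT_HYBRID:
                exhausted = True
                break
            tau = modulation_index(
                f_alpha, f_beta, f_delta, float(pop.fitness[i]), f_worst, sched.tau_clip
            )
            step = acs_step_size(gen, gen_max, tau, sched.step_max)
            a = gwo_control_parameter(gen, gen_max, tau, sched.a_o)
            # adaptive cuckoo move toward/away from the live global best
            gbest = pop.positions[leaders.alpha]
            cand = acs_update(pop.positions[i], gbest, step, problem, rng)
            greedy_select(pop, i, cand, problem, rng)
            # abandonment walk
            cand = bsrw_abandon(i, pop.positions, config.cuckoo.p_a, problem, rng)
            greedy_select(pop, i, cand, problem, rng)
            # the wolf move replaces unconditionally, so record any cuckoo
            # improvement before it can be overwritten
            best_pos, best_fit = _track_best(pop, best_pos, best_fit)
            # grey-wolf intensification (3 FEs, unconditional replacement)
            idgwo_position_update(
                pop, i, leaders, leader_positions, a, problem, rng, config.elitist_idgwo
            )
            best_pos, best_fit = _track_best(pop, best_pos, best_fit)
        gen += 1
        log.append((gen, best_fit, float(np.mean(pop.fitness)), pop.fe_count))

    return RunResult(
        best_position=best_pos,
        best_fitness=best_fit,
        log=log,
        fe_count=pop.fe_count,
        seed=config.seed,
        n_generations=gen,
    )


def run_standard_cs(
    problem: ObjectiveSpec,
    config: HybridConfig,
    rng: Optional[np.random.Generator] = None,
) -> RunResult:
    """Standard cuckoo search baseline: Levy walk + abandonment, 2 FEs per
    agent per generation, greedy selection after each walk."""
    rng = _rng_from(config, rng)
    gen_max = (config.fe_budget - config.n) // (2 * config.n)
    if gen_max < 1:
        raise ConfigurationError("fe_budget too small for one cuckoo-search generation")
    coeff = levy_scale_coefficient(config.cuckoo.lam)
    pop = initialize_population(problem, config.n, rng, config.fe_budget)
    best_pos, best_fit = pop.positions[pop.best_index()].copy(), float(np.min(pop.fitness))
    log = [(0, best_fit, float(np.mean(pop.fitness)), pop.fe_count)]

    gen = 0
    try:
        while gen < gen_max:
            best_i = pop.best_index()
            for i in range(pop.n):
                cand = lfrw_update(
                    pop.positions[i], pop.positions[best_i], config.cuckoo, problem, rng, coeff
                )
                greedy_select(pop, i, cand, problem, rng)
            for i in range(pop.n):
                cand = bsrw_abandon(i, pop.positions, config.cuckoo.p_a, problem, rng)
                greedy_select(pop, i, cand, problem, rng)
            best_pos, best_fit = _track_best(pop, best_pos, best_fit)
            gen += 1
            log.append((gen, best_fit, float(np.mean(pop.fitness)), pop.fe_count))
    except BudgetExhausted:
        pass

    return RunResult(best_pos, best_fit, log, pop.fe_count, config.seed, gen)


def run_standard_gwo(
    problem: ObjectiveSpec,
    config: HybridConfig,
    rng: Optional[np.random.Generator] = None,
) -> RunResult:
    """Standard grey-wolf baseline: averaged three-leader update, linear
    ``a`` schedule from 2 to 0, 1 FE per agent per iteration."""
    rng = _rng_from(config, rng)
    max_iter = (config.fe_budget - config.n) // config.n
    if max_iter < 1:
        raise ConfigurationError("fe_budget too small for one grey-wolf iteration")
    pop = initialize_population(problem, config.n, rng, config.fe_budget)
    best_pos, best_fit = pop.positions[pop.best_index()].copy(), float(np.min(pop.fitness))
    log = [(0, best_fit, float(np.mean(pop.fitness)), pop.fe_count)]

    it = 0
    while it < max_iter and pop.budget_left() >= pop.n:
        a = gwo_linear_control(it, max_iter)
        leaders = rank_leaders(pop)
        leader_positions = pop.positions[[leaders.alpha, leaders.beta, leaders.delta]].copy()
        for i in range(pop.n):
            cand = gwo_update(pop.positions[i], leader_positions, a, problem, rng)
            pop.positions[i] = cand
            pop.fitness[i] = problem.evaluate(cand, rng)
            pop.fe_count += 1
        best_pos, best_fit = _track_best(pop, best_pos, best_fit)
        it += 1
        log.append((it, best_fit, float(np.mean(pop.fitness)), pop.fe_count))

    return RunResult(best_pos, best_fit, log, pop.fe_count, config.seed, it)
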