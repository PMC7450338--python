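"""Adaptive per-agent schedules driving the hybrid optimizer.

The hybrid draws its adaptivity from the complete response of a DC-excited RC
circuit: the capacitor voltage rises as ``1 - b^tau`` and the current decays
as ``b^tau`` with ``b = (gen_max - gen)/gen_max``.  The rising response sets
the cuckoo-search step size (small early -> local exploitation, near
``step_max`` late -> global exploration); the decaying response sets the
grey-wolf control parameter ``a`` (large early, zero late -> pure attack).
The exponent ``tau`` is a per-agent *modulation index* measuring how close an
agent sits to the mean of the three leaders relative to the worst omega
agent, so poor agents feel the schedules at full strength while near-leader
agents barely move.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .core import ConfigurationError

#: Denominator threshold below which the population is considered degenerate
#: (all relevant fitness values equal); the modulation index then defaults to 1.
DEGENERACY_EPS = 1e-12


@dataclass
class ScheduleConfig:
    """Schedule parameters: ``step_max`` and ``a_o`` both default to 1."""

    step_max: float = 1.0
    a_o: float = 1.0
    gen_max: int = 1
    tau_clip: Tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if self.step_max <= 0:
            raise ConfigurationError("step_max must be positive")
        if self.a_o <= 0:
            raise ConfigurationError("a_o must be positive")
        if self.gen_max < 1:
            raise ConfigurationError("gen_max must be >= 1")
        if self.tau_clip[0] > self.tau_clip[1]:
            raise ConfigurationError("tau_clip must be an ordered pair")


def modulation_index(
    f_alpha: float,
    f_beta: float,
    f_delta: float,
    f_i: float,
    f_worst: float,
    clip: Tuple[float, float] = (0.0, 1.0),
) -> float:
    """Nonlinear modulation index of one agent.

    ``tau = (m - f_i) / (m - f_worst)`` with ``m`` the mean fitness of the
    three leaders.  The ratio is 1 for the worst omega agent and 0 for an
    agent sitting exactly at the leader mean; agents better than the leader
    mean would get a negative ratio, which is clamped (default to [0, 1]) so
    the downstream schedules stay within their nominal ranges.  A degenerate
    population (denominator below ``DEGENERACY_EPS``) yields tau = 1.
    """
    values = (f_alpha, f_beta, f_delta, f_i, f_worst)
    if not all(np.isfinite(v) for v in values):
        raise FloatingPointError(f"non-finite fitness in modulation_index: {values}")
    m = (f_alpha + f_beta + f_delta) / 3.0
    denom = m - f_worst
    if abs(denom) < DEGENERACY_EPS:
        tau = 1.0
    else:
        tau = (m - f_i) / denom
    return float(min(max(tau, clip[0]), clip[1]))


def _remaining_fraction(gen: int, gen_max: int) -> float:
    if not 0 <= gen <= gen_max:
        raise ConfigurationError(f"gen must lie in [0, gen_max={gen_max}]; got {gen}")
    return (gen_max - gen) / gen_max


def _pow(base: float, tau: float) -> float:
    # 0^0 := 1 so gen == gen_max with tau == 0 is well defined
    if base == 0.0 and tau == 0.0:
        return 1.0
    return base**tau


def acs_step_size(gen: int, gen_max: int, tau: float, step_max: float = 1.0) -> float:
    """Growing cuckoo-search step: ``step_max * (1 - b^tau)``, in [0, step_max]."""
    b = _remaining_fraction(gen, gen_max)
    return step_max * (1.0 - _pow(b, tau))


def gwo_control_parameter(gen: int, gen_max: int, tau: float, a_o: float = 1.0) -> float:
    """Decaying grey-wolf control parameter: ``a_o * b^tau``, in [0, a_o]."""
    b = _remaining_fraction(gen, gen_max)
    return a_o * _pow(b, tau)
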