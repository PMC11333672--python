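"""Conductance-based leaky integrate-and-fire point neurons.

Single-neuron dynamics with exponential-decay synaptic conductances and a
within-step analytic (exact linear-ODE) membrane update, plus Poisson spike
sources for background noise and the dopaminergic / stimulus drives.

The same update scheme is implemented in vectorised form by the simulation
kernel (:mod:`bgloop._kernel`); the scalar functions here are the readable
reference and are cross-checked against the kernel in the test suite.

Integration scheme
------------------
With the simulation step ``dt`` larger than the excitatory synaptic time
constant (2 ms vs 0.5 ms), forward Euler is unusable, so each step is
integrated analytically:

1. incoming synaptic weights are added to the conductances;
2. the membrane relaxes exactly toward the conductance-weighted reversal
   ``V_inf = (g_L E_L + g_ex E_ex + g_in E_in + I_e) / g_tot`` with rate
   ``g_tot / C_m``, treating each conductance as constant over the step at
   its exact step-average value ``g0 (tau/dt)(1 - exp(-dt/tau))`` (for a
   decay time much longer than the step this tends to ``g0``; for the fast
   excitatory conductance it correctly down-weights a transient that lives
   only in the first quarter of the step);
3. conductances decay by their exact exponential factors;
4. threshold / reset / refractory bookkeeping (a refractory period shorter
   than ``dt`` blocks exactly one subsequent step).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .params import NeuronParams


@dataclass(frozen=True)
class NeuronState:
    """Dynamic state of one LIF unit."""

    V_m: float
    g_ex: float = 0.0
    g_in: float = 0.0
    refractory_remaining: float = 0.0

    def validate(self, params: NeuronParams, name: str = "neuron") -> None:
        vals = (self.V_m, self.g_ex, self.g_in, self.refractory_remaining)
        if not all(math.isfinite(v) for v in vals):
            raise FloatingPointError(
                f"non-finite state in {name}: V_m={self.V_m}, "
                f"g_ex={self.g_ex}, g_in={self.g_in}"
            )
        if self.g_ex < 0 or self.g_in < 0:
            raise ValueError(f"negative conductance in {name}")


def resting_state(params: NeuronParams) -> NeuronState:
    """State at leak equilibrium with no synaptic input."""
    return NeuronState(V_m=params.E_L)


def step_neuron(
    state: NeuronState,
    params: NeuronParams,
    incoming_exc: float = 0.0,
    incoming_inh: float = 0.0,
    dt: float = 2.0,
    name: str = "neuron",
) -> tuple[NeuronState, bool]:
    """Advance one neuron by ``dt`` ms; return the new state and spike flag.

    ``incoming_exc`` / ``incoming_inh`` are the summed synaptic weights (nS)
    of spikes delivered at the start of this step.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if incoming_exc < 0 or incoming_inh < 0:
        raise ValueError("incoming synaptic weights must be non-negative")
    state.validate(params, name)

    g_ex = state.g_ex + incoming_exc
    g_in = state.g_in + incoming_inh

    spiked = False
    if state.refractory_remaining > 0.0:
        V = params.V_reset
        refr = state.refractory_remaining - dt
    else:
        ge_eff = g_ex * step_average_factor(params.tau_syn_ex, dt)
        gi_eff = g_in * step_average_factor(params.tau_syn_in, dt)
        g_tot = params.g_L + ge_eff + gi_eff
        V_inf = (
            params.g_L * params.E_L
            + ge_eff * params.E_ex
            + gi_eff * params.E_in
            + params.I_e
        ) / g_tot
        V = V_inf + (state.V_m - V_inf) * math.exp(-g_tot * dt / params.C_m)
        refr = 0.0
        if V >= params.V_th:
            spiked = True
            V = params.V_reset
            refr = params.t_ref

    new = NeuronState(
        V_m=V,
        g_ex=g_ex * math.exp(-dt / params.tau_syn_ex),
        g_in=g_in * math.exp(-dt / params.tau_syn_in),
        refractory_remaining=max(refr, 0.0),
    )
    new.validate(params, name)
    return new, spiked


def step_average_factor(tau: float, dt: float) -> float:
    """Mean of ``exp(-t/tau)`` over one step: ``(tau/dt)(1 - exp(-dt/tau))``.

    Scales a start-of-step conductance to its average over the step; tends
    to 1 for ``tau >> dt`` (a clamped conductance is its own average).
    """
    return (tau / dt) * -math.expm1(-dt / tau)


def subthreshold_fixed_point(
    params: NeuronParams, g_ex: float = 0.0, g_in: float = 0.0
) -> float:
    """Equilibrium membrane potential under clamped conductances."""
    g_tot = params.g_L + g_ex + g_in
    return (
        params.g_L * params.E_L + g_ex * params.E_ex + g_in * params.E_in
        + params.I_e
    ) / g_tot


@dataclass(frozen=True)
class PoissonSource:
    """Homogeneous Poisson spike source.

    ``rate`` is in spikes/ms; each emitted spike is delivered with
    ``weight`` nS to its targets. Disabled sources emit nothing.
    """

    rate: float
    weight: float = 1.0
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("Poisson rate must be non-negative")

    def with_rate(self, rate: float) -> "PoissonSource":
        return replace(self, rate=rate)


def poisson_draw(
    source: PoissonSource, dt: float, rng: np.random.Generator
) -> int:
    """Number of spikes emitted by ``source`` in one step of ``dt`` ms."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not source.enabled or source.rate == 0.0:
        return 0
    return int(rng.poisson(source.rate * dt))


def poisson_counts(
    rates: np.ndarray, dt: float, n_steps: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorised spike-count matrix, shape ``(n_steps, len(rates))``."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    rates = np.asarray(rates, dtype=float)
    if np.any(rates < 0):
        raise ValueError("Poisson rates must be non-negative")
    return rng.poisson(rates * dt, size=(n_steps, rates.size)).astype(np.float64)


__all__ = [
    "NeuronState", "PoissonSource", "resting_state", "step_neuron",
    "subthreshold_fixed_point", "poisson_draw", "poisson_counts",
]
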