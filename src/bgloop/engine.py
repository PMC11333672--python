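"""Simulation engine: state management and phase execution for one network.

Bridges the structural :class:`~bgloop.topology.NetworkModel` and the
compiled stepping kernel. The engine owns the dynamic state (membrane
potentials, conductances, refractory clocks), the flattened synapse lists
(with plastic weights refreshed before every trial), and the pre-drawn
Poisson inputs for stimulus, dopaminergic and background drive.

Dynamic state is reset to leak equilibrium between trials; synaptic
weights persist. All randomness flows through a single ``numpy`` generator
per network, so a trial sequence is exactly reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernel
from .params import DASchedule, TaskParams
from .plasticity import ActivationSnapshot, windowed_activation
from .topology import NetworkModel


@dataclass
class PhaseResult:
    """Raw output of one settling phase."""

    spikes: np.ndarray          # (steps_used, n_neurons) spike counts
    selected_col: int           # 0-based premotor column, or -1
    crossing_step: int          # 1-based step of the selection event, or -1
    steps_used: int


class SimulationEngine:
    """Stateful per-network simulator."""

    def __init__(self, network: NetworkModel, task: TaskParams | None = None):
        self.network = network
        self.task = task or TaskParams()
        n = network.n_neurons
        p = network.neuron_params
        self.V = np.full(n, p.E_L)
        self.g_ex = np.zeros(n)
        self.g_in = np.zeros(n)
        self.refr = np.zeros(n)
        self._prev_spikes = np.zeros(n)
        self._build_synapse_arrays()

    # -- synapse flattening ----------------------------------------------

    def _build_synapse_arrays(self) -> None:
        exc_parts, inh_parts = [], []
        self._plastic_slices: dict[str, tuple[int, int]] = {}
        offset = 0
        for g in self.network.groups.values():
            if g.sign != "exc":
                continue
            exc_parts.append(g)
            if g.plastic:
                self._plastic_slices[g.name] = (offset, offset + g.pre.size)
            offset += g.pre.size
        for g in self.network.groups.values():
            if g.sign != "inh":
                continue
            inh_parts.append(g)
            if g.plastic:  # pragma: no cover - no inhibitory plastic groups
                raise ValueError("plastic inhibitory groups unsupported")

        self.exc_pre = np.concatenate([g.pre for g in exc_parts])
        self.exc_post = np.concatenate([g.post for g in exc_parts])
        self.exc_w = np.concatenate([g.effective_weights() for g in exc_parts])
        self.inh_pre = np.concatenate([g.pre for g in inh_parts])
        self.inh_post = np.concatenate([g.post for g in inh_parts])
        self.inh_w = np.concatenate([g.effective_weights() for g in inh_parts])

    def refresh_plastic_weights(self) -> None:
        """Copy current plastic group weights into the flat synapse list."""
        for name, (a, b) in self._plastic_slices.items():
            g = self.network.groups[name]
            self.exc_w[a:b] = g.effective_weights()

    # -- state -----------------------------------------------------------

    def reset_dynamic_state(self) -> None:
        """Return membranes/conductances to rest; weights are untouched."""
        p = self.network.neuron_params
        self.V.fill(p.E_L)
        self.g_ex.fill(0.0)
        self.g_in.fill(0.0)
        self.refr.fill(0.0)
        self._prev_spikes = np.zeros(self.network.n_neurons)

    def _check_finite(self) -> None:
        bad = np.flatnonzero(~np.isfinite(self.V))
        if bad.size:
            raise FloatingPointError(
                f"non-finite membrane potential in neuron(s) {bad.tolist()}"
            )

    # -- external drive ---------------------------------------------------

    def _external_matrix(
        self,
        n_steps: int,
        active_inputs: np.ndarray,
        stimulus_rate: float,
        snc_rate: float,
        rng: np.random.Generator,
    ) -> np.ndarray:
        """Poisson inputs for one phase.

        Rows are steps. For source units (input layer, SNc) entries are
        spike counts; for LIF units they are excitatory conductance
        increments (background counts times the background weight).
        """
        net = self.network
        bg = net.background
        idx_parts, rate_parts, scale_parts = [], [], []

        if active_inputs.size and stimulus_rate > 0:
            idx_parts.append(net.layer("input").start + active_inputs)
            rate_parts.append(np.full(active_inputs.size, stimulus_rate))
            scale_parts.append(np.ones(active_inputs.size))
        if snc_rate > 0:
            snc = net.layer("snc")
            idx_parts.append(snc.indices)
            rate_parts.append(np.full(snc.size, snc_rate))
            scale_parts.append(np.ones(snc.size))
        for lname, (rate, weight) in bg.layer_drive().items():
            if rate > 0 and weight > 0:
                lay = net.layer(lname)
                idx_parts.append(lay.indices)
                rate_parts.append(np.full(lay.size, rate))
                scale_parts.append(np.full(lay.size, weight))

        ext = np.zeros((n_steps, net.n_neurons))
        if idx_parts:
            idx = np.concatenate(idx_parts)
            rates = np.concatenate(rate_parts)
            scales = np.concatenate(scale_parts)
            counts = rng.poisson(rates * self.task.dt, size=(n_steps, idx.size))
            ext[:, idx] = counts * scales
        return ext

    # -- phases ------------------------------------------------------------

    def _run(self, ext: np.ndarray, detect: bool) -> PhaseResult:
        net = self.network
        task = self.task
        p = net.neuron_params
        n_steps = ext.shape[0]
        spikes = np.zeros((n_steps, net.n_neurons))
        pmc = net.layer("pmc")
        sel, crossing, used = _kernel.run_phase(
            self.exc_pre, self.exc_post, self.exc_w,
            self.inh_pre, self.inh_post, self.inh_w,
            net.is_source, ext, self._prev_spikes,
            self.V, self.g_ex, self.g_in, self.refr,
            spikes,
            p.C_m, p.g_L, p.E_L, p.V_reset, p.V_th, p.E_ex, p.E_in,
            p.tau_syn_ex, p.tau_syn_in, p.I_e, p.t_ref, task.dt,
            detect, pmc.start, pmc.n_columns, pmc.column_size,
            int(round(task.response_window / task.dt)),
            task.response_threshold,
            int(round(task.min_time / task.dt)),
        )
        self._check_finite()
        spikes = spikes[:used]
        self._prev_spikes = spikes[-1].copy() if used else self._prev_spikes
        return PhaseResult(spikes=spikes, selected_col=int(sel),
                           crossing_step=int(crossing), steps_used=int(used))

    def run_response_phase(
        self,
        active_inputs: np.ndarray,
        da: DASchedule,
        rng: np.random.Generator,
        stimulus_rate: float | None = None,
    ) -> PhaseResult:
        """Settle under tonic dopamine until a premotor column crosses the
        activation threshold (earliest at ``min_time``) or ``max_time``."""
        n_steps = int(round(self.task.max_time / self.task.dt))
        ext = self._external_matrix(
            n_steps, active_inputs,
            self.task.stimulus_rate if stimulus_rate is None else stimulus_rate,
            da.rate_for("response"), rng,
        )
        return self._run(ext, detect=True)

    def run_feedback_phase(
        self,
        active_inputs: np.ndarray,
        correct: bool,
        da: DASchedule,
        rng: np.random.Generator,
        duration: float,
        stimulus_rate: float | None = None,
    ) -> PhaseResult:
        """Resettle for ``duration`` ms with dopamine at burst or dip."""
        n_steps = int(round(duration / self.task.dt))
        ext = self._external_matrix(
            n_steps, active_inputs,
            self.task.stimulus_rate if stimulus_rate is None else stimulus_rate,
            da.rate_for("feedback", correct), rng,
        )
        return self._run(ext, detect=False)

    # -- readout -----------------------------------------------------------

    def layer_snapshot(
        self,
        phase_result: PhaseResult,
        layer: str,
        phase: str,
        window: float,
        end_step: int | None = None,
    ) -> ActivationSnapshot:
        """Windowed activations of one layer at the end of a phase.

        ``end_step`` truncates the record first (1-based, e.g. the selection
        event), so the window ends at that step instead of the phase end.
        """
        lay = self.network.layer(layer)
        counts = phase_result.spikes[:, lay.start:lay.stop]
        if end_step is not None and end_step > 0:
            counts = counts[:end_step]
        values = windowed_activation(counts, window, self.task.dt)
        return ActivationSnapshot(layer=layer, phase=phase, values=values,
                                  window=window)

    def column_activations(
        self, phase_result: PhaseResult, layer: str, window: float
    ) -> np.ndarray:
        """Per-column mean activation of a columnar layer."""
        lay = self.network.layer(layer)
        snap = self.layer_snapshot(phase_result, layer, "response", window)
        return snap.values.reshape(lay.n_columns, lay.column_size).mean(axis=1)


def first_crossing(
    pmc_spikes: np.ndarray,
    n_columns: int,
    window_steps: int,
    threshold: float,
    min_step: int,
) -> tuple[int, int]:
    """Pure-python response readout over a recorded premotor spike array.

    Mirrors the kernel's on-line detection: from the first full window
    onward, the earliest step at which some column's windowed activation
    reaches ``threshold`` is the selection event; the column with the
    highest activation wins, ties going to the lowest column id. The
    reported step count never precedes ``min_step``. Returns
    ``(column, crossing_step, steps_used)`` with a 0-based column, or
    ``(-1, -1, n_steps)``. Used by tests as an independent check of the
    kernel.
    """
    n_steps, n_pmc = pmc_spikes.shape
    col_size = n_pmc // n_columns
    active = (pmc_spikes > 0).astype(float)
    for t in range(n_steps):
        if (t + 1) < window_steps:
            continue
        win = active[t - window_steps + 1: t + 1]
        acts = win.reshape(window_steps, n_columns, col_size).mean(axis=(0, 2))
        crossing = np.flatnonzero(acts >= threshold)
        if crossing.size:
            best = crossing[np.argmax(acts[crossing])]
            return int(best), t + 1, max(t + 1, min_step)
    return -1, -1, n_steps


__all__ = ["SimulationEngine", "PhaseResult", "first_crossing"]
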