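"""Compiled inner loop of the network simulation.

One function advances the whole network through one settling phase on the
2 ms grid: synaptic delivery with a one-step delay, analytic LIF membrane
updates (identical maths to :func:`bgloop.neurons.step_neuron`, which the
tests cross-check against this kernel), Poisson source units, and the
on-line response readout over premotor-cortex columns.

The synapse list is a COO triple (pre, post, weight); multiplicity of
parallel synapses is folded into the effective weight.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=False)
def run_phase(
    exc_pre, exc_post, exc_w,
    inh_pre, inh_post, inh_w,
    is_source,
    ext,             # (n_steps, n_neurons): spike counts for source units,
                     # background conductance increments (nS) for LIF units
    prev_spikes,     # (n_neurons,) spikes of the step before this phase
    V, g_ex, g_in, refr,          # state vectors, updated in place
    spikes,                       # (n_steps, n_neurons) output spike counts
    C_m, g_L, E_L, V_reset, V_th, E_ex, E_in,
    tau_ex, tau_in, I_e, t_ref, dt,
    detect,          # bool: run the response readout
    pmc_start, n_cols, col_size, window, thresh, min_step,
):
    """Simulate up to ``n_steps`` steps.

    Returns ``(selected_col, crossing_step, steps_used)``. ``selected_col``
    is 0-based, or -1 if no premotor column reached the activation
    threshold (or ``detect`` is false). The crossing is monitored from the
    first full window onward; ``crossing_step`` is the 1-based step at
    which the winning column first reached threshold (the selection
    event). The phase keeps running until both the crossing and
    ``min_step`` have passed, so the reported response time is never
    earlier than the minimum simulation time; ``steps_used`` is the step
    count actually simulated.
    """
    n_steps, n_neurons = spikes.shape
    dec_ex = np.exp(-dt / tau_ex)
    dec_in = np.exp(-dt / tau_in)
    # step-average factors: conductances enter the membrane equation at
    # their exact mean over the step, (tau/dt)(1 - exp(-dt/tau))
    avg_ex = (tau_ex / dt) * (1.0 - dec_ex)
    avg_in = (tau_in / dt) * (1.0 - dec_in)

    inc_ex = np.zeros(n_neurons)
    inc_in = np.zeros(n_neurons)
    prev = prev_spikes.copy()

    sel_col = -1
    sel_step = -1
    steps_used = n_steps

    for t in range(n_steps):
        for i in range(n_neurons):
            inc_ex[i] = 0.0
            inc_in[i] = 0.0
        for k in range(exc_pre.size):
            c = prev[exc_pre[k]]
            if c != 0.0:
                inc_ex[exc_post[k]] += exc_w[k] * c
        for k in range(inh_pre.size):
            c = prev[inh_pre[k]]
            if c != 0.0:
                inc_in[inh_post[k]] += inh_w[k] * c

        for i in range(n_neurons):
            if is_source[i]:
                spikes[t, i] = ext[t, i]
                continue
            ge = g_ex[i] + inc_ex[i] + ext[t, i]
            gi = g_in[i] + inc_in[i]
            if refr[i] > 0.0:
                V[i] = V_reset
                refr[i] -= dt
                if refr[i] < 0.0:
                    refr[i] = 0.0
                spikes[t, i] = 0.0
            else:
                gea = ge * avg_ex
                gia = gi * avg_in
                gt = g_L + gea + gia
                vinf = (g_L * E_L + gea * E_ex + gia * E_in + I_e) / gt
                v = vinf + (V[i] - vinf) * np.exp(-gt * dt / C_m)
                if v >= V_th:
                    spikes[t, i] = 1.0
                    V[i] = V_reset
                    refr[i] = t_ref
                else:
                    spikes[t, i] = 0.0
                    V[i] = v
            g_ex[i] = ge * dec_ex
            g_in[i] = gi * dec_in

        prev = spikes[t]

        if detect and sel_col < 0 and (t + 1) >= window:
            best = -1
            best_act = -1.0
            for c in range(n_cols):
                hits = 0
                for j in range(col_size):
                    ni = pmc_start + c * col_size + j
                    for tt in range(t - window + 1, t + 1):
                        if spikes[tt, ni] > 0.0:
                            hits += 1
                act = hits / (window * col_size)
                if act >= thresh and act > best_act:
                    best = c
                    best_act = act
            if best >= 0:
                sel_col = best
                sel_step = t + 1
        if detect and sel_col >= 0 and (t + 1) >= min_step:
            steps_used = t + 1
            break

    return sel_col, sel_step, steps_used
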