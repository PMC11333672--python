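"""Two-phase Hebbian + error-driven plasticity.

The two plastic projections learn from per-neuron activations measured in
two network settling phases: the response phase (superscript ``-``), in
which the network chooses a motor response under tonic dopamine, and the
feedback phase (``+``), in which the substantia nigra bursts after a
correct choice or falls silent after an incorrect one.

Per synapse ``i -> j`` with weight ``w`` the raw components are::

    d_hebb = y+ * (x+ - w)                      (Hebbian, feedback phase)
    d_err  = x+ y+  -  x- y-                    (error-driven, cross-phase)
    d_sberr = d_err * (1 - w)  if d_err > 0     (soft bound toward 1)
            = d_err * w        if d_err < 0     (soft bound toward 0)
    dw = eps * (k_hebb * d_hebb + (1 - k_hebb) * d_sberr)

Cortico-striatal synapses use the full mixture with the LTP rate when the
raw combined change is positive and the LTD rate when negative; the
input -> premotor-cortex projection uses the Hebbian term alone at the much
slower cortical rate. Weights are dimensionless in [0, 1] and are used
directly as conductances in nS.

Activations are the fraction of simulation steps carrying a spike inside a
60 ms window, which places them naturally in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import LearningParams


@dataclass(frozen=True)
class ActivationSnapshot:
    """Windowed per-neuron activations of one layer in one phase.

    ``phase`` is ``"response"`` (-) or ``"feedback"`` (+); ``values`` has
    one entry per neuron of the layer, each in [0, 1].
    """

    layer: str
    phase: str
    values: np.ndarray
    window: float = 60.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "values", np.asarray(self.values, dtype=np.float64)
        )
        if self.phase not in ("response", "feedback"):
            raise ValueError("phase must be 'response' or 'feedback'")
        if self.values.size and (
            self.values.min() < 0.0 or self.values.max() > 1.0
        ):
            raise ValueError("activations must lie in [0, 1]")


def windowed_activation(
    spike_counts: np.ndarray, window: float, dt: float
) -> np.ndarray:
    """Fraction of steps with at least one spike over the trailing window.

    ``spike_counts`` has shape ``(n_steps,)`` or ``(n_steps, n_neurons)``
    and covers at least the window; the activation uses the last
    ``window / dt`` steps and is clipped to [0, 1].
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    n_win = int(round(window / dt))
    if n_win < 1:
        raise ValueError("window must cover at least one simulation step")
    counts = np.asarray(spike_counts)
    if counts.shape[0] < n_win:
        raise ValueError(
            f"spike train has {counts.shape[0]} steps, window needs {n_win}"
        )
    frac = (counts[-n_win:] > 0).mean(axis=0)
    return np.clip(frac, 0.0, 1.0)


def hebbian_delta(x_plus, y_plus, w):
    """Raw Hebbian component ``y+ * (x+ - w)``; fixed point at ``w = x+``."""
    return np.multiply(y_plus, np.subtract(x_plus, w))


def error_delta(x_plus, y_plus, x_minus, y_minus):
    """Raw error-driven component ``x+ y+ - x- y-``."""
    return np.subtract(np.multiply(x_plus, y_plus), np.multiply(x_minus, y_minus))


def soft_bound(delta_err, w):
    """Scale positive changes by ``1 - w`` and negative changes by ``w``."""
    delta_err = np.asarray(delta_err, dtype=np.float64)
    w = np.asarray(w, dtype=np.float64)
    return np.where(delta_err > 0, delta_err * (1.0 - w), delta_err * w)


def combine_update(delta_hebb, delta_sberr, eps, k_hebb):
    """Additive mixture ``eps * (k_hebb d_hebb + (1 - k_hebb) d_sberr)``."""
    if np.any(np.asarray(eps) < 0):
        raise ValueError("learning rate must be non-negative")
    if np.any(np.asarray(k_hebb) < 0) or np.any(np.asarray(k_hebb) > 1):
        raise ValueError("k_hebb must lie in [0, 1]")
    return np.multiply(
        eps,
        np.add(
            np.multiply(k_hebb, delta_hebb),
            np.multiply(1.0 - np.asarray(k_hebb, dtype=float), delta_sberr),
        ),
    )


def _gather(snapshot: ActivationSnapshot, local_idx: np.ndarray) -> np.ndarray:
    return snapshot.values[local_idx]


def apply_striatal_update(
    weights: np.ndarray,
    pre_idx: np.ndarray,
    post_idx: np.ndarray,
    x_minus: ActivationSnapshot,
    x_plus: ActivationSnapshot,
    y_minus: ActivationSnapshot,
    y_plus: ActivationSnapshot,
    params: LearningParams,
) -> np.ndarray:
    """Dopamine-gated update of cortico-striatal weights.

    ``pre_idx``/``post_idx`` are per-synapse indices into the input-layer
    and striatal snapshots. The LTP rate applies where the combined raw
    change is positive and the LTD rate where it is negative; the result is
    clipped to [0, 1] (a safety net over the soft bound).
    """
    for snap, phase in ((x_minus, "response"), (x_plus, "feedback"),
                        (y_minus, "response"), (y_plus, "feedback")):
        if snap is None:
            raise ValueError("missing phase snapshot for striatal update")
        if snap.phase != phase:
            raise ValueError(
                f"snapshot tagged {snap.phase!r} passed where {phase!r} expected"
            )
    w = np.asarray(weights, dtype=np.float64)
    xm = _gather(x_minus, pre_idx)
    xp = _gather(x_plus, pre_idx)
    ym = _gather(y_minus, post_idx)
    yp = _gather(y_plus, post_idx)

    d_hebb = hebbian_delta(xp, yp, w)
    d_sberr = soft_bound(error_delta(xp, yp, xm, ym), w)
    raw = params.k_hebb * d_hebb + (1.0 - params.k_hebb) * d_sberr
    eps = np.where(raw > 0, params.eps_ltp, params.eps_ltd)
    return np.clip(w + eps * raw, 0.0, 1.0)


def apply_cortical_update(
    weights: np.ndarray,
    pre_idx: np.ndarray,
    post_idx: np.ndarray,
    x_plus: ActivationSnapshot,
    y_plus: ActivationSnapshot,
    params: LearningParams,
) -> np.ndarray:
    """Hebbian-only update of the input -> premotor-cortex projection."""
    for snap in (x_plus, y_plus):
        if snap is None:
            raise ValueError("missing feedback snapshot for cortical update")
        if snap.phase != "feedback":
            raise ValueError("cortical update uses feedback-phase snapshots")
    w = np.asarray(weights, dtype=np.float64)
    xp = _gather(x_plus, pre_idx)
    yp = _gather(y_plus, post_idx)
    return np.clip(w + params.eps_cortical * hebbian_delta(xp, yp, w), 0.0, 1.0)


__all__ = [
    "ActivationSnapshot", "windowed_activation", "hebbian_delta",
    "error_delta", "soft_bound", "combine_update",
    "apply_striatal_update", "apply_cortical_update",
]
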