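"""The four-stimulus motor task: trials, epochs, and the learning criterion.

A trial presents one of four stimuli (a block of input-layer units firing
at the stimulus rate) for the whole simulation. In the response phase the
network settles under tonic dopamine until one premotor column's windowed
activation crosses the readout threshold (no earlier than the minimum
simulation time); the crossing column is the motor response and the
crossing time the response time. The 200 ms feedback phase follows with
dopamine at burst (correct) or fully dipped (incorrect or no response),
after which the two plastic projections are updated from the response- and
feedback-phase activation snapshots. One epoch is one pass over all four
stimuli; the task counts as learned after 10 consecutive error-free epochs.

Trials are independent settles: dynamic state is reset between trials,
weights persist. A no-response trial is incorrect and triggers a dopamine
dip.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import SimulationEngine
from .params import (
    DASchedule, LearningParams, STIMULUS_BLOCKS, TaskParams,
)
from .plasticity import (
    ActivationSnapshot, apply_cortical_update, apply_striatal_update,
)
from .topology import NetworkModel

N_STIMULI = len(STIMULUS_BLOCKS)


@dataclass(frozen=True)
class Stimulus:
    """One of the four input patterns; correct response id equals ``id``."""

    id: int
    active_inputs: np.ndarray     # local indices into the input layer
    rate: float                   # drive of the active units (spikes/ms)


def encode_stimulus(stimulus_id: int, rate: float | None = None) -> Stimulus:
    """Input-layer block for a stimulus id in {1..4}.

    The 18 input units are partitioned into contiguous blocks of sizes
    5, 5, 4, 4 in index order; stimulus ``i`` activates the ``i``-th block.
    """
    if stimulus_id not in range(1, N_STIMULI + 1):
        raise ValueError(f"stimulus id must be in 1..{N_STIMULI}")
    start = sum(STIMULUS_BLOCKS[: stimulus_id - 1])
    size = STIMULUS_BLOCKS[stimulus_id - 1]
    return Stimulus(
        id=stimulus_id,
        active_inputs=np.arange(start, start + size),
        rate=TaskParams().stimulus_rate if rate is None else rate,
    )


@dataclass
class TrialResult:
    """Outcome of one trial."""

    stimulus_id: int
    response: int | None          # chosen response in {1..4}, or None
    correct: bool
    response_time: float          # ms; deadline value when no response
    snapshots: dict[str, ActivationSnapshot] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.response is not None:
            self.correct = self.response == self.stimulus_id
        else:
            self.correct = False


@dataclass
class EpochRecord:
    """One execution of the whole task (four trials)."""

    epoch: int
    trials: list[TrialResult]

    def __post_init__(self) -> None:
        if len(self.trials) != N_STIMULI:
            raise ValueError(f"an epoch holds exactly {N_STIMULI} trials")

    @property
    def error(self) -> float:
        """Fraction of incorrect trials, in {0, 0.25, 0.5, 0.75, 1}."""
        return sum(not t.correct for t in self.trials) / len(self.trials)


def has_learned(history: list[EpochRecord], n_perfect: int = 10) -> bool:
    """True iff the last ``n_perfect`` epochs were all error-free."""
    if len(history) < n_perfect:
        return False
    return all(rec.error == 0.0 for rec in history[-n_perfect:])


class TaskRunner:
    """Run trials and epochs on one network."""

    def __init__(
        self,
        network: NetworkModel,
        da: DASchedule | None = None,
        task_params: TaskParams | None = None,
        learning_params: LearningParams | None = None,
        rng: np.random.Generator | None = None,
        keep_snapshots: bool = False,
    ) -> None:
        self.network = network
        self.da = da or DASchedule()
        self.task_params = task_params or TaskParams()
        self.learning_params = learning_params or LearningParams()
        self.rng = rng if rng is not None else np.random.default_rng(network.seed)
        self.engine = SimulationEngine(network, self.task_params)
        self.keep_snapshots = keep_snapshots
        self.history: list[EpochRecord] = []

    # -- single trial -----------------------------------------------------

    def run_trial(self, stimulus: Stimulus) -> TrialResult:
        eng = self.engine
        lp = self.learning_params
        eng.reset_dynamic_state()
        eng.refresh_plastic_weights()

        resp = eng.run_response_phase(
            stimulus.active_inputs, self.da, self.rng, stimulus.rate
        )
        if resp.selected_col >= 0:
            response: int | None = resp.selected_col + 1
            response_time = resp.steps_used * self.task_params.dt
        else:
            response = None
            response_time = self.task_params.max_time
        correct = response == stimulus.id

        fb = eng.run_feedback_phase(
            stimulus.active_inputs, correct, self.da, self.rng,
            lp.feedback_duration, stimulus.rate,
        )

        snaps = self._snapshots(resp, fb)
        self._apply_learning(stimulus, snaps)

        result = TrialResult(
            stimulus_id=stimulus.id,
            response=response,
            correct=correct,
            response_time=response_time,
        )
        if self.keep_snapshots:
            result.snapshots = snaps
        return result

    def _snapshots(self, resp, fb) -> dict[str, ActivationSnapshot]:
        # Response-phase (-) activations are taken over the window ending at
        # the selection event (the first threshold crossing), i.e. the state
        # in which the response was chosen, before post-selection settling;
        # feedback-phase (+) activations over the final window of feedback.
        eng = self.engine
        lp = self.learning_params
        end = resp.crossing_step if resp.crossing_step > 0 else None
        out: dict[str, ActivationSnapshot] = {}
        for layer in ("input", "striatum_go", "striatum_nogo"):
            out[f"{layer}-"] = eng.layer_snapshot(
                resp, layer, "response", lp.striatal_window, end_step=end)
            out[f"{layer}+"] = eng.layer_snapshot(
                fb, layer, "feedback", lp.striatal_window)
        out["pmc-"] = eng.layer_snapshot(resp, "pmc", "response",
                                         lp.cortical_window, end_step=end)
        out["pmc+"] = eng.layer_snapshot(fb, "pmc", "feedback",
                                         lp.cortical_window)
        return out

    def _apply_learning(self, stimulus, snaps) -> None:
        lp = self.learning_params
        net = self.network
        input_start = net.layer("input").start
        for layer in ("striatum_go", "striatum_nogo"):
            g = net.groups[f"input->{layer}"]
            layer_start = net.layer(layer).start
            g.weight = apply_striatal_update(
                g.weight,
                g.pre - input_start,
                g.post - layer_start,
                snaps["input-"], snaps["input+"],
                snaps[f"{layer}-"], snaps[f"{layer}+"],
                lp,
            )
        g = net.groups["input->pmc"]
        pmc_start = net.layer("pmc").start
        g.weight = apply_cortical_update(
            g.weight,
            g.pre - input_start,
            g.post - pmc_start,
            snaps["input+"], snaps["pmc+"],
            lp,
        )

    # -- epochs -----------------------------------------------------------

    def run_epoch(self, order: list[int] | None = None) -> EpochRecord:
        """Run the four stimuli (default order 1..4) and record the epoch."""
        ids = order if order is not None else list(range(1, N_STIMULI + 1))
        if sorted(ids) != list(range(1, N_STIMULI + 1)):
            raise ValueError("epoch order must be a permutation of 1..4")
        trials = [
            self.run_trial(encode_stimulus(i, self.task_params.stimulus_rate))
            for i in ids
        ]
        record = EpochRecord(epoch=len(self.history) + 1, trials=trials)
        self.history.append(record)
        return record

    def run_epochs(self, n_epochs: int) -> list[EpochRecord]:
        for _ in range(n_epochs):
            self.run_epoch()
        return self.history

    @property
    def learned(self) -> bool:
        return has_learned(self.history)


__all__ = [
    "Stimulus", "TrialResult", "EpochRecord", "TaskRunner",
    "encode_stimulus", "has_learned", "N_STIMULI",
]
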