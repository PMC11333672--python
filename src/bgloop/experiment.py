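"""Batch experiments and learning-curve analysis.

Runs replicate networks per condition (healthy or lesioned), assembles
mean learning curves, segments them into early / progressing /
consolidation phases, and compares conditions with paired t-tests under
Bonferroni correction.

Phase definitions (computed on the across-network mean curve):

* early phase: from the start of training until the mean error first
  falls below chance (50%);
* progressing phase: from there until the mean error has stayed below 5%
  for 10 consecutive epochs (the fulfilment of learning);
* consolidation phase: the remainder of the run.

The mean-curve learning time is the epoch ending the progressing phase.
Independently, each network's own learning time is the epoch at which it
first completes 10 consecutive error-free epochs; the condition's average
learning time is the mean of these. The two constructs are related but not
forced to coincide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .lesion import LesionSpec, apply_lesion
from .params import DASchedule, LearningParams, TaskParams
from .task import TaskRunner
from .topology import build_network

CHANCE_ERROR = 0.50          # "below chance" threshold on the mean curve
LEARNED_ERROR = 0.05         # "learned" threshold on the mean curve
LEARNED_RUN = 10             # consecutive epochs required below threshold


@dataclass
class LearningCurve:
    """Per-epoch error fractions for each replicate network and their mean."""

    per_network: np.ndarray       # (n_networks, n_epochs)

    def __post_init__(self) -> None:
        self.per_network = np.atleast_2d(np.asarray(self.per_network, float))
        if self.per_network.size and (
            self.per_network.min() < 0 or self.per_network.max() > 1
        ):
            raise ValueError("error fractions must lie in [0, 1]")

    @property
    def n_networks(self) -> int:
        return self.per_network.shape[0]

    @property
    def n_epochs(self) -> int:
        return self.per_network.shape[1]

    @property
    def mean_error(self) -> np.ndarray:
        return self.per_network.mean(axis=0)

    @property
    def sd_error(self) -> np.ndarray:
        return self.per_network.std(axis=0, ddof=1 if self.n_networks > 1 else 0)


@dataclass(frozen=True)
class PhaseSegmentation:
    """Boundaries of the three learning phases on a mean curve (epochs)."""

    early_end: int
    progressing_end: int | None
    complete: bool

    @property
    def learning_time(self) -> int | None:
        return self.progressing_end if self.complete else None


def segment_phases(
    curve: LearningCurve | np.ndarray,
    chance: float = CHANCE_ERROR,
    learned: float = LEARNED_ERROR,
    run_length: int = LEARNED_RUN,
) -> PhaseSegmentation:
    """Segment a mean learning curve into its three phases.

    ``early_end`` is the last epoch before the mean error first drops
    below ``chance`` (0 if the curve starts below chance).
    ``progressing_end`` is the final epoch of the first run of
    ``run_length`` consecutive epochs below ``learned``; when no such run
    exists the segmentation is marked incomplete.
    """
    mean = curve.mean_error if isinstance(curve, LearningCurve) else np.asarray(curve, float)
    if mean.size == 0:
        raise ValueError("cannot segment an empty curve")

    below_chance = np.flatnonzero(mean < chance)
    early_end = int(below_chance[0]) if below_chance.size else int(mean.size)

    below = mean < learned
    progressing_end: int | None = None
    streak = 0
    for i, ok in enumerate(below):
        streak = streak + 1 if ok else 0
        if streak >= run_length:
            progressing_end = i + 1      # 1-based epoch index
            break
    return PhaseSegmentation(
        early_end=early_end,
        progressing_end=progressing_end,
        complete=progressing_end is not None,
    )


def window_error(
    curve: LearningCurve | np.ndarray, start_epoch: int, length: int = 30
) -> float:
    """Mean of the mean curve over ``length`` epochs from ``start_epoch``
    (1-based, inclusive), as a percentage."""
    mean = curve.mean_error if isinstance(curve, LearningCurve) else np.asarray(curve, float)
    if start_epoch < 1 or start_epoch + length - 1 > mean.size:
        raise ValueError(
            f"window [{start_epoch}, {start_epoch + length - 1}] outside the "
            f"{mean.size}-epoch run"
        )
    return float(mean[start_epoch - 1: start_epoch - 1 + length].mean() * 100.0)


@dataclass(frozen=True)
class PairedTestResult:
    """Two-sided paired t-test with Bonferroni adjustment."""

    t: float
    p: float
    p_adjusted: float
    n: int
    mean_diff: float
    degenerate: bool = False


def paired_test(
    sample_a: np.ndarray, sample_b: np.ndarray, n_comparisons: int = 1
) -> PairedTestResult:
    """Paired t-test on equal-length samples, adjusted over a family of
    ``n_comparisons`` tests. Zero variance of the differences is flagged as
    degenerate rather than reported as an extreme p-value."""
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length 1-d arrays")
    if a.size < 2:
        raise ValueError("paired test needs at least two pairs")
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0):
        return PairedTestResult(
            t=np.nan, p=np.nan, p_adjusted=np.nan, n=a.size,
            mean_diff=float(diff.mean()), degenerate=True,
        )
    t, p = stats.ttest_rel(a, b)
    return PairedTestResult(
        t=float(t), p=float(p),
        p_adjusted=float(min(1.0, p * n_comparisons)),
        n=a.size, mean_diff=float(diff.mean()),
    )


@dataclass
class ConditionSummary:
    """Everything measured for one condition (one lesion level)."""

    lesion: LesionSpec
    curve: LearningCurve
    segmentation: PhaseSegmentation
    learning_times: np.ndarray        # per network; total epochs if incomplete
    learning_completed: np.ndarray    # per network, bool
    response_times: np.ndarray        # per network mean, ms
    trials: pd.DataFrame              # network, epoch, trial, stimulus, ...
    base_seed: int
    n_epochs: int

    @property
    def n_networks(self) -> int:
        return self.curve.n_networks

    def window_errors(self, starts=(1, 31, 81), length: int = 30) -> dict[int, float]:
        """Mean-curve window errors (%) at the healthy phase anchors.

        Windows that do not fit inside the run are omitted (short smoke
        runs keep whatever anchors they can hold).
        """
        return {
            s: window_error(self.curve, s, length)
            for s in starts
            if s >= 1 and s + length - 1 <= self.n_epochs
        }

    def per_network_window_error(self, start: int, length: int = 30) -> np.ndarray:
        sl = slice(start - 1, start - 1 + length)
        return self.curve.per_network[:, sl].mean(axis=1) * 100.0


def response_time_summary(trials: pd.DataFrame, max_time: float = 800.0):
    """Per-network mean response time and the condition mean (ms).

    No-response trials already carry the deadline time, so the mean is a
    plain average over all trials of each network.
    """
    per_net = trials.groupby("network")["response_time"].mean()
    return per_net.to_numpy(), float(per_net.mean())


def _network_learning_time(errors: np.ndarray, run_length: int = LEARNED_RUN):
    """Epoch at which one network first completes ``run_length`` perfect
    epochs; (epochs, False) when it never does."""
    streak = 0
    for i, e in enumerate(errors):
        streak = streak + 1 if e == 0.0 else 0
        if streak >= run_length:
            return i + 1, True
    return errors.size, False


def run_condition(
    lesion: LesionSpec,
    n_networks: int = 30,
    n_epochs: int = 300,
    base_seed: int = 0,
    task_params: TaskParams | None = None,
    learning_params: LearningParams | None = None,
    da: DASchedule | None = None,
) -> ConditionSummary:
    """Train ``n_networks`` independent networks under one lesion condition.

    Network ``i`` is built and driven with seed ``base_seed + i``; the
    whole summary is reproducible from the arguments alone. Lesions with
    ``at_epoch`` onset switch the dopamine schedule between epochs; an
    ``after_training`` onset trains entirely healthy.
    """
    if n_networks < 1:
        raise ValueError("need at least one network")
    task_params = task_params or TaskParams()
    learning_params = learning_params or LearningParams()
    base_da = da or DASchedule()
    healthy_da = base_da
    lesioned_da = apply_lesion(base_da, lesion)

    errors = np.zeros((n_networks, n_epochs))
    learning_times = np.zeros(n_networks)
    completed = np.zeros(n_networks, dtype=bool)
    rows = []
    for i in range(n_networks):
        seed = base_seed + i
        net = build_network(seed=seed)
        runner = TaskRunner(
            net, da=healthy_da, task_params=task_params,
            learning_params=learning_params,
            rng=np.random.default_rng(seed),
        )
        for epoch in range(1, n_epochs + 1):
            runner.da = (
                lesioned_da if lesion.active_at_epoch(epoch, n_epochs)
                else healthy_da
            )
            record = runner.run_epoch()
            errors[i, epoch - 1] = record.error
            for k, tr in enumerate(record.trials, start=1):
                rows.append((i, epoch, k, tr.stimulus_id,
                             tr.response if tr.response is not None else -1,
                             tr.correct, tr.response_time))
        learning_times[i], completed[i] = _network_learning_time(errors[i])

    trials = pd.DataFrame(
        rows,
        columns=["network", "epoch", "trial", "stimulus", "response",
                 "correct", "response_time"],
    )
    curve = LearningCurve(errors)
    rt_per_net, _ = response_time_summary(trials, task_params.max_time)
    return ConditionSummary(
        lesion=lesion,
        curve=curve,
        segmentation=segment_phases(curve),
        learning_times=learning_times,
        learning_completed=completed,
        response_times=rt_per_net,
        trials=trials,
        base_seed=base_seed,
        n_epochs=n_epochs,
    )


def compare_conditions(
    healthy: ConditionSummary,
    lesioned: list[ConditionSummary],
    window_starts=(1, 31, 81),
    window_length: int = 30,
) -> pd.DataFrame:
    """Bonferroni-corrected paired comparisons of each lesioned condition
    against the healthy one.

    Metric families: window error at each anchor, learning time, response
    time. Within each family the Bonferroni factor is the number of
    lesioned conditions. Conditions must share replicate count and seeds
    (networks are paired by seed).
    """
    rows = []
    m = len(lesioned)
    for cond in lesioned:
        if (cond.n_networks != healthy.n_networks
                or cond.base_seed != healthy.base_seed):
            raise ValueError(
                "conditions must share n_networks and base_seed for pairing"
            )
    for cond in lesioned:
        for start in window_starts:
            if start + window_length - 1 > min(cond.n_epochs, healthy.n_epochs):
                continue
            res = paired_test(
                cond.per_network_window_error(start, window_length),
                healthy.per_network_window_error(start, window_length),
                n_comparisons=m,
            )
            rows.append(("window_error", start, cond.lesion.lesion_fraction, res))
        res = paired_test(cond.learning_times, healthy.learning_times,
                          n_comparisons=m)
        rows.append(("learning_time", None, cond.lesion.lesion_fraction, res))
        res = paired_test(cond.response_times, healthy.response_times,
                          n_comparisons=m)
        rows.append(("response_time", None, cond.lesion.lesion_fraction, res))
    return pd.DataFrame(
        [
            {
                "metric": metric,
                "window_start": start,
                "lesion": lesion,
                "t": r.t,
                "p": r.p,
                "p_adjusted": r.p_adjusted,
                "mean_diff": r.mean_diff,
                "degenerate": r.degenerate,
                "n": r.n,
            }
            for metric, start, lesion, r in rows
        ]
    )


def perturb_robustness(
    perturbation_scale: float,
    n: int,
    n_epochs: int = 60,
    base_seed: int = 0,
    task_params: TaskParams | None = None,
) -> pd.DataFrame:
    """Sensitivity of healthy learning to static-weight perturbations.

    Runs ``n`` healthy networks whose static (non-plastic) weights are
    multiplied by ``1 + u``, ``u ~ U(-scale, +scale)`` per synapse, and
    reports each run's final-stretch error and below-chance status.
    """
    rows = []
    task_params = task_params or TaskParams()
    for j in range(n):
        seed = base_seed + j
        net = build_network(seed=seed)
        rng = np.random.default_rng(seed + 10_000)
        if perturbation_scale > 0:
            for g in net.groups.values():
                if not g.plastic:
                    factor = 1.0 + rng.uniform(
                        -perturbation_scale, perturbation_scale, size=g.weight.size
                    )
                    g.weight = g.weight * factor
        runner = TaskRunner(net, task_params=task_params,
                            rng=np.random.default_rng(seed))
        runner.run_epochs(n_epochs)
        errs = np.array([rec.error for rec in runner.history])
        tail = errs[-10:]
        rows.append({
            "replicate": j,
            "scale": perturbation_scale,
            "final_error": float(tail.mean()),
            "below_chance": bool(tail.mean() < CHANCE_ERROR),
        })
    return pd.DataFrame(rows)


__all__ = [
    "LearningCurve", "PhaseSegmentation", "ConditionSummary",
    "PairedTestResult", "segment_phases", "window_error", "paired_test",
    "response_time_summary", "run_condition", "compare_conditions",
    "perturb_robustness", "CHANCE_ERROR", "LEARNED_ERROR", "LEARNED_RUN",
]
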