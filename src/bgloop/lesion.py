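"""Dopamine-depletion (substantia nigra lesion) model.

A lesion is a fractional loss of dopaminergic drive: the tonic and burst
rates of the SNc Poisson sources are scaled by ``1 - lesion_fraction``,
while the dip after negative feedback remains absolute silence. The
fraction maps onto disease stages: mild depletion (20-40%) emulates the
preclinical/prodromal window before motor symptoms, stronger depletion
(50-70%) the clinical and advanced stages. The lesion acts only on SNc
firing rates; weights, wiring and neuron counts are untouched, so a lesion
applied after training leaves everything learned in place.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .params import DASchedule

#: Stage labels for the lesion fractions examined in the experiments.
STAGE_LABELS: dict[float, str] = {
    0.0: "healthy",
    0.2: "preclinical",
    0.3: "early_prodromal",
    0.4: "prodromal",
    0.5: "clinical",
    0.7: "advanced",
}

ONSET_CHOICES = ("before_training", "at_epoch", "after_training")


@dataclass(frozen=True)
class LesionSpec:
    """Degree and onset of the dopaminergic lesion.

    ``onset`` selects when the SNc rate multiplier switches from 1 to
    ``1 - lesion_fraction``: before any training, between epochs (at the
    start of epoch ``onset_epoch``), or only after training ends. The
    switch never happens mid-trial.
    """

    lesion_fraction: float = 0.0
    onset: str = "before_training"
    onset_epoch: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.lesion_fraction <= 1.0:
            raise ValueError("lesion_fraction must lie in [0, 1]")
        if self.onset not in ONSET_CHOICES:
            raise ValueError(f"onset must be one of {ONSET_CHOICES}")
        if self.onset == "at_epoch" and (
            self.onset_epoch is None or self.onset_epoch < 1
        ):
            raise ValueError("at_epoch onset requires onset_epoch >= 1")

    @property
    def multiplier(self) -> float:
        return 1.0 - self.lesion_fraction

    @property
    def stage(self) -> str:
        return stage_of(self.lesion_fraction)

    def active_at_epoch(self, epoch: int, total_epochs: int) -> bool:
        """Whether the lesion applies during the given training epoch."""
        if self.onset == "before_training":
            return True
        if self.onset == "after_training":
            return epoch > total_epochs
        return epoch >= (self.onset_epoch or 1)


def apply_lesion(da: DASchedule, spec: LesionSpec) -> DASchedule:
    """Dopamine schedule with the lesion's rate multiplier applied."""
    return replace(da, multiplier=da.multiplier * spec.multiplier)


def stage_of(fraction: float) -> str:
    """Disease-stage label of a lesion fraction; 'unlabeled' off the grid."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("lesion fraction must lie in [0, 1]")
    for key, label in STAGE_LABELS.items():
        if abs(fraction - key) < 1e-12:
            return label
    return "unlabeled"


__all__ = ["LesionSpec", "apply_lesion", "stage_of", "STAGE_LABELS"]
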