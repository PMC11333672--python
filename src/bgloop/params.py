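"""Parameter registry for the basal-ganglia motor-loop model.

Every module takes its defaults from here: LIF membrane constants,
population sizes, connection counts and weights, background-drive rates,
the dopamine schedule, and the learning-rule constants. Keeping the
registry in one place makes a build auditable: tests assert that the
constructed network realises exactly these numbers.

Units convention: voltages in mV, conductances in nS, times in ms, firing
rates in spikes/ms. The membrane capacitance is expressed in units such
that C_m / g_L is the membrane time constant in ms (2.0 / 0.2 = 10 ms).
"""

from __future__ import annotations

from dataclasses import dataclass


# --------------------------------------------------------------------------
# LIF neuron
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NeuronParams:
    """Conductance-based leaky integrate-and-fire membrane constants.

    The defaults are the standard parameter set used for every neuron in
    the network. ``C_m``/``g_L`` gives a 10 ms membrane time constant.
    """

    C_m: float = 2.0            # membrane capacitance (model units)
    g_L: float = 0.2            # leak conductance (nS)
    E_L: float = -70.0          # leak reversal potential (mV)
    V_reset: float = -70.0      # post-spike reset potential (mV)
    V_th: float = -40.0         # spike threshold (mV)
    tau_syn_ex: float = 0.5     # excitatory conductance decay time (ms)
    tau_syn_in: float = 10.0    # inhibitory conductance decay time (ms)
    E_ex: float = 0.0           # excitatory reversal potential (mV)
    E_in: float = -85.0         # inhibitory reversal potential (mV)
    I_e: float = 0.0            # constant input current (model units)
    t_ref: float = 1.0          # absolute refractory period (ms)

    def __post_init__(self) -> None:
        if not (self.E_in < self.E_L <= self.V_reset < self.V_th < self.E_ex):
            raise ValueError(
                "reversal/threshold ordering violated: need "
                "E_in < E_L <= V_reset < V_th < E_ex, got "
                f"E_in={self.E_in}, E_L={self.E_L}, V_reset={self.V_reset}, "
                f"V_th={self.V_th}, E_ex={self.E_ex}"
            )
        if self.tau_syn_ex <= 0 or self.tau_syn_in <= 0:
            raise ValueError("synaptic time constants must be positive")
        if self.C_m <= 0 or self.g_L <= 0:
            raise ValueError("C_m and g_L must be positive")
        if self.t_ref < 0:
            raise ValueError("t_ref must be non-negative")

    @property
    def tau_m(self) -> float:
        """Membrane time constant C_m / g_L in ms."""
        return self.C_m / self.g_L


# --------------------------------------------------------------------------
# Learning rule
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LearningParams:
    """Constants of the two-phase Hebbian + error-driven learning rule.

    ``eps_ltp``/``eps_ltd`` are the cortico-striatal learning rates applied
    when the net raw weight change is positive (potentiation) or negative
    (depression); ``eps_cortical`` is the much slower rate of the purely
    Hebbian input-to-premotor-cortex pathway. Activations entering the rule
    are fractions of simulation steps with a spike inside the stated
    windows, so they live on a [0, 1] scale.
    """

    k_hebb: float = 0.01            # Hebbian/error-driven mixing coefficient
    eps_cortical: float = 0.00001   # input->PMC Hebbian learning rate
    eps_ltp: float = 0.1            # cortico-striatal LTP learning rate
    eps_ltd: float = 0.1            # cortico-striatal LTD learning rate
    striatal_window: float = 60.0   # activation window for striatal rule (ms)
    cortical_window: float = 60.0   # activation window for cortical rule (ms)
    feedback_duration: float = 200.0  # length of the feedback phase (ms)

    def __post_init__(self) -> None:
        if not 0.0 <= self.k_hebb <= 1.0:
            raise ValueError("k_hebb must lie in [0, 1]")
        for name in ("eps_cortical", "eps_ltp", "eps_ltd",
                     "striatal_window", "cortical_window", "feedback_duration"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


# --------------------------------------------------------------------------
# Task / simulation protocol
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TaskParams:
    """Trial-protocol constants: grid step, response gates, stimulus drive."""

    dt: float = 2.0                 # simulation step (ms)
    min_time: float = 400.0         # earliest permitted response (ms)
    max_time: float = 800.0         # response deadline (ms)
    response_window: float = 60.0   # window for the readout activation (ms)
    response_threshold: float = 0.25  # activation threshold for selection
    stimulus_rate: float = 0.55     # drive of active input units (spikes/ms)

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not self.min_time <= self.max_time:
            raise ValueError("min_time must not exceed max_time")
        if self.stimulus_rate < 0:
            raise ValueError("stimulus_rate must be non-negative")


# --------------------------------------------------------------------------
# Dopamine schedule
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DASchedule:
    """SNc firing-rate schedule (spikes/ms) with a lesion multiplier.

    The tonic rate holds during the response phase; after feedback the rate
    switches to ``burst`` (correct response) or ``dip`` (incorrect or no
    response). A lesion scales tonic and burst by ``multiplier``; the dip
    is an absolute silence and is never scaled.
    """

    tonic: float = 0.5
    burst: float = 1.0
    dip: float = 0.0
    multiplier: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.multiplier <= 1.0:
            raise ValueError("lesion multiplier must lie in [0, 1]")
        for name in ("tonic", "burst", "dip"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} rate must be non-negative")

    @property
    def effective_tonic(self) -> float:
        return self.tonic * self.multiplier

    @property
    def effective_burst(self) -> float:
        return self.burst * self.multiplier

    @property
    def effective_dip(self) -> float:
        return self.dip

    def rate_for(self, phase: str, correct: bool | None = None) -> float:
        if phase == "response":
            return self.effective_tonic
        if phase == "feedback":
            return self.effective_burst if correct else self.effective_dip
        raise ValueError(f"unknown phase {phase!r}")


# --------------------------------------------------------------------------
# Background drive
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BackgroundDrive:
    """Per-neuron Poisson background drive: rates (spikes/ms) and weights (nS).

    The premotor cortex, GPi and GPe receive independent excitatory Poisson
    trains emulating afferents from structures outside the model. The rates
    are fixed model constants; the weights of these noise synapses are not
    tabulated anywhere and are calibrated once (see the methods note) so
    that GPi and GPe are tonically active gates and the premotor cortex sits
    just below threshold, firing sparsely and irregularly, which lets an
    untrained network produce exploratory responses.
    """

    pmc_rate: float = 0.5
    gpi_rate: float = 16.0
    gpe_rate: float = 4.0
    pmc_weight: float = 0.35
    gpi_weight: float = 2.0
    gpe_weight: float = 0.1

    def __post_init__(self) -> None:
        for name in ("pmc_rate", "gpi_rate", "gpe_rate",
                     "pmc_weight", "gpi_weight", "gpe_weight"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def layer_drive(self) -> dict[str, tuple[float, float]]:
        """Mapping layer -> (rate, weight) for layers with background input."""
        return {
            "pmc": (self.pmc_rate, self.pmc_weight),
            "gpi": (self.gpi_rate, self.gpi_weight),
            "gpe": (self.gpe_rate, self.gpe_weight),
        }


# --------------------------------------------------------------------------
# Network tables
# --------------------------------------------------------------------------

#: Layer sizes; total 131 units.
LAYER_SIZES: dict[str, int] = {
    "input": 18,
    "striatum_go": 36,
    "striatum_nogo": 36,
    "gpi": 8,
    "gpe": 4,
    "stn": 9,
    "snc": 4,
    "thalamus": 4,
    "pmc": 8,
    "m1": 4,
}

#: Number of response channels; columnar layers split into this many columns.
N_COLUMNS = 4

#: Layers organised into response columns (others are diffuse).
COLUMNAR_LAYERS = (
    "striatum_go", "striatum_nogo", "gpi", "gpe", "thalamus", "pmc", "m1",
)

#: Layers implemented as Poisson spike sources rather than LIF units.
SOURCE_LAYERS = ("input", "snc")


@dataclass(frozen=True)
class GroupSpec:
    """Static description of one connection group.

    ``mapping`` is one of ``columnar`` (column i projects to column i,
    realised with ``multiplicity`` parallel synapses per pair), ``diffuse``
    (all-to-all across columns) or ``indegree`` (each target samples
    ``indegree`` distinct sources without replacement). ``weight`` is either
    a float or a ``(low, high)`` uniform range.
    """

    name: str
    source: str
    target: str
    sign: str                      # "exc" or "inh"
    count: int                     # total synapse count (table value)
    weight: float | tuple[float, float]
    mapping: str                   # "columnar" | "diffuse" | "indegree"
    multiplicity: int = 1
    indegree: int = 0
    plastic: bool = False


#: All connection groups with their synapse counts and healthy weights.
CONNECTION_TABLE: tuple[GroupSpec, ...] = (
    GroupSpec("input->striatum_go", "input", "striatum_go", "exc", 432,
              (0.02, 0.12), "indegree", indegree=12, plastic=True),
    GroupSpec("input->striatum_nogo", "input", "striatum_nogo", "exc", 432,
              (0.02, 0.12), "indegree", indegree=12, plastic=True),
    GroupSpec("striatum->striatum", "striatum", "striatum", "inh", 5184,
              (0.01, 0.04), "diffuse"),
    GroupSpec("pmc->striatum_go", "pmc", "striatum_go", "exc", 288,
              (0.4, 0.5), "columnar", multiplicity=4),
    GroupSpec("pmc->striatum_nogo", "pmc", "striatum_nogo", "exc", 288,
              1.0, "columnar", multiplicity=4),
    GroupSpec("snc->striatum_go", "snc", "striatum_go", "exc", 144,
              0.15, "diffuse"),
    GroupSpec("snc->striatum_nogo", "snc", "striatum_nogo", "inh", 144,
              0.3, "diffuse"),
    GroupSpec("striatum_go->gpi", "striatum_go", "gpi", "inh", 288,
              1.5, "columnar", multiplicity=4),
    GroupSpec("gpe->gpi", "gpe", "gpi", "inh", 32,
              1.0, "columnar", multiplicity=4),
    GroupSpec("stn->gpi", "stn", "gpi", "exc", 72,
              6.0, "diffuse"),
    GroupSpec("striatum_nogo->gpe", "striatum_nogo", "gpe", "inh", 144,
              1.0, "columnar", multiplicity=4),
    GroupSpec("gpe->stn", "gpe", "stn", "inh", 36,
              0.35, "diffuse"),
    GroupSpec("pmc->stn", "pmc", "stn", "exc", 72,
              (0.45, 0.85), "diffuse"),
    GroupSpec("input->pmc", "input", "pmc", "exc", 96,
              (0.0045, 0.055), "indegree", indegree=12, plastic=True),
    GroupSpec("thalamus->pmc", "thalamus", "pmc", "exc", 32,
              2.0, "columnar", multiplicity=4),
    GroupSpec("pmc->thalamus", "pmc", "thalamus", "exc", 32,
              1.5, "columnar", multiplicity=4),
    GroupSpec("gpi->thalamus", "gpi", "thalamus", "inh", 32,
              1.0, "columnar", multiplicity=4),
    GroupSpec("pmc->m1", "pmc", "m1", "exc", 32,
              2.0, "columnar", multiplicity=4),
)

#: Groups whose weights are updated by the learning rule.
PLASTIC_GROUPS = ("input->striatum_go", "input->striatum_nogo", "input->pmc")

#: Partition of the 18 input units over the four stimuli (block sizes).
STIMULUS_BLOCKS = (5, 5, 4, 4)


def total_neurons() -> int:
    return sum(LAYER_SIZES.values())


__all__ = [
    "NeuronParams", "LearningParams", "TaskParams", "DASchedule",
    "BackgroundDrive", "GroupSpec", "CONNECTION_TABLE", "LAYER_SIZES",
    "N_COLUMNS", "COLUMNAR_LAYERS", "SOURCE_LAYERS", "PLASTIC_GROUPS",
    "STIMULUS_BLOCKS", "total_neurons",
]
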