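# Methods

`bgloop` simulates the cortico-basal-ganglia-thalamo-cortical motor loop
at a mesoscopic scale: 131 point neurons organised into ten layers, four
parallel response channels ("columns"), dopamine-modulated two-phase
reinforcement learning on the cortico-striatal projections, and a
four-stimulus trial-and-error motor task. Dopamine depletion — the core
pathology of Parkinson's disease — is modelled as a multiplicative
reduction of the firing rate of the substantia nigra pars compacta (SNc)
units, and the package's experiment harness quantifies how graded
depletion degrades motor learning before it degrades motor execution.

## Neuron and synapse model

All units except the input layer and the SNc are conductance-based leaky
integrate-and-fire neurons with exponential-decay synaptic conductances:

    C_m dV/dt = -g_L (V - E_L) - g_ex (V - E_ex) - g_in (V - E_in) + I_e
    tau_syn dg/dt = -g        (g_ex, g_in incremented by the synaptic
                               weight in nS on each presynaptic spike)

with C_m/g_L = 10 ms, E_L = V_reset = -70 mV, V_th = -40 mV,
E_ex = 0 mV, E_in = -85 mV, tau_syn_ex = 0.5 ms, tau_syn_in = 10 ms and a
1 ms refractory period. The input layer and the SNc are Poisson spike
sources, because the experiments manipulate them directly by rate.

**Integration.** The simulation grid is dt = 2 ms. Because the
excitatory synaptic time constant (0.5 ms) is shorter than the step,
forward Euler is unusable and even an exact update that holds the
start-of-step conductance constant over the whole step misweights fast
excitation against slow inhibition by roughly the factor dt/tau. Each
step therefore (1) adds the delivered synaptic weights to the
conductances, (2) advances the membrane analytically toward the
conductance-weighted reversal potential using each conductance's exact
average over the step, `g0 * (tau/dt) * (1 - exp(-dt/tau))`, (3) decays
the conductances by their exact exponential factors, and (4) applies
threshold/reset bookkeeping. A refractory period shorter than the step
blocks exactly one subsequent step, so the maximum firing rate is one
spike per two steps (250 spikes/s), and the windowed activation measure
defined below saturates at 0.5. All synapses deliver with a uniform
one-step (2 ms) delay; no other delays are modelled.

## Network

Layer sizes (total 131): input 18, striatal Go 36, striatal NoGo 36,
GPi 8, GPe 4, STN 9, SNc 4, thalamus 4, premotor cortex (PMC) 8, M1 4.
Columnar layers split into four equal contiguous columns, one per
response. Connection counts follow the published table exactly and are
audited at construction; the audit is re-runnable (`audit_counts`, CLI
verb `audit`).

Columnar groups (Go→GPi, NoGo→GPe, GPe→GPi, GPi→thalamus,
thalamus↔PMC, PMC→M1, PMC→striatum) connect column i to column i only
and are realised with four parallel synapses per pair so that the
audited synapse counts equal the printed totals; dynamically this is
identical to a single synapse of four times the weight. Diffuse groups
(SNc→striatum, STN→GPi, PMC→STN, GPe→STN, striatal interneurons) are
all-to-all; the 72 × 72 = 5184 striatal interneuron count implies
autapses, which are included. The three input projections (to Go, NoGo
and PMC) give every target a fixed in-degree of 12 distinct input units,
sampled without replacement under the build seed.

One deliberate reading: the PMC→striatum count (288) is consistent with
both all-to-all (8 × 36) and columnar-with-multiplicity (2 × 9 × 4 × 4)
wiring. The columnar reading is used, because the chosen response must
leave a column-specific trace in striatal activity for the reinforcement
rule to assign credit to the selected channel; with diffuse wiring the
model demonstrably cannot learn the task (error stays near 70%
indefinitely).

**Background drive.** PMC, GPi and GPe receive independent excitatory
Poisson trains at 0.5, 16 and 4 spikes/ms per neuron. The weights of
these noise synapses are not part of the published parameter set and are
model constants calibrated once on healthy networks: 0.35 nS (PMC),
2.0 nS (GPi), 0.1 nS (GPe). The calibration targets were qualitative:
GPi and GPe tonically active (the gate closed at rest, thalamus silent),
PMC resting just below threshold so it fires sparsely and irregularly,
and an untrained network producing a response before the 800 ms deadline
in the majority of trials, spread over all four columns. These weights
were fixed before the lesion experiments and never revisited.

## Task protocol

A trial presents one stimulus — one of four disjoint blocks (5/5/4/4 in
index order) of the 18 input units — driven at 0.55 spikes/ms for the
whole trial. The stimulus drive rate is likewise a calibrated model
constant (the published protocol does not state one); it is set so that
the untrained-response requirement above holds.

*Response phase.* The network settles under tonic dopamine (SNc at
0.5 spikes/ms times the lesion multiplier). From the first full 60 ms
window onward, each PMC column's activation — the fraction of 2 ms steps
in the window in which a neuron spikes, averaged over the column — is
monitored. The first column to reach 0.25 is the response (ties at a
step go to the higher activation, then the lower column id); the
response time is the crossing time, gated to the protocol bounds
[400, 800] ms. If no column crosses by 800 ms the trial is a
no-response, counted as incorrect. Selection works mechanistically by
disinhibition: a striatal Go column inhibits its GPi column, releasing
the corresponding thalamus unit, whose reciprocal loop with the PMC
column then ignites; the STN (hyperdirect pathway) is driven by PMC and
held down by GPe, and raises the gating threshold globally when cortex
is broadly active.

*Feedback phase.* The trial continues for 200 ms with the SNc switched
to a burst (1.0 spikes/ms times the lesion multiplier) after a correct
response or to complete silence after an incorrect or absent response.
The dip is absolute regardless of lesion.

Between trials the dynamic state (membrane potentials, conductances,
refractory clocks) is reset to rest; synaptic weights persist. An epoch
is one pass over the four stimuli in fixed order (the order is
configurable); the task counts as learned after 10 consecutive
error-free epochs.

## Learning rule

Per plastic synapse i→j with weight w in [0, 1] (used directly as nS):

    d_hebb  = y+ (x+ - w)
    d_err   = x+ y+ - x- y-
    d_sberr = d_err (1 - w)   if d_err > 0,  else  d_err w
    dw      = eps [ k_hebb d_hebb + (1 - k_hebb) d_sberr ],  k_hebb = 0.01

with eps = 0.1 for cortico-striatal synapses (the LTP rate when the raw
combined change is positive, the LTD rate when negative; both 0.1 by
default but independently configurable) and Hebbian-only learning at
eps = 1e-5 for input→PMC. Weights are clipped to [0, 1] after each
update as a safety net over the soft bound.

Activations x, y are windowed spike fractions over 60 ms. The
response-phase (minus) snapshot is taken over the window ending at the
*selection event* — the step at which the winning column first crossed
threshold — and the feedback-phase (plus) snapshot over the final 60 ms
of feedback. Ending the minus window at the selection event rather than
at the 400 ms report matters: after selection the winner's loop
saturates at the refractory ceiling (activation 0.5) in both phases, so
a report-time snapshot erases the reward contrast on correct trials
while error trials still depress, and learning stalls at a ~13% error
plateau. Snapshotting at the crossing keeps the winner's minus
activation at the threshold level, preserving the burst-driven contrast;
with it the healthy network consolidates to sustained zero error.

The credit-assignment loop, end to end: a correct choice triggers a
dopamine burst, which further excites the already-active Go column (D1)
and silences NoGo (D2), so the active input→Go synapses of the winning
column potentiate; an error triggers a dip, the disinhibited NoGo column
of the chosen response suppresses its GPe→GPi chain, the ignited loop
collapses during feedback, and the feedback snapshot (taken after the
collapse) depresses the chosen column's input→Go synapses while the
input→NoGo synapses of that column potentiate.

## Lesion model

A lesion fraction f in [0, 1] multiplies the SNc tonic and burst rates
by (1 - f); the dip stays at zero. Nothing else changes: weights,
wiring and neuron counts are untouched, so a lesion applied after
training provably leaves the trained behavior identical. Fractions map
to disease-stage labels: 0 healthy, 0.2 preclinical, 0.3 early
prodromal, 0.4 prodromal, 0.5 clinical, 0.7 advanced. Onset can be
before training, between two epochs, or after training; it never
switches mid-trial.

## Experiments and analysis

A condition trains n independent networks (default 30, seeds
base_seed + i) for 300 epochs. On the across-network mean error curve,
the early phase ends when the mean error first falls below chance
(taken as 50%, as in the source analysis, although four-alternative
chance error is 75%; the threshold is configurable), and the
progressing phase ends at the last epoch of the first run of 10
consecutive epochs below 5%; the remainder is consolidation. The mean
curve's learning time is the progressing-phase end; separately, each
network's own learning time is the epoch at which it first completes 10
consecutive perfect epochs (censored at the run length if never), and
the condition's average learning time is the mean of these. Windowed
error rates are means of the mean curve over 30-epoch windows anchored
at the healthy phase starts (epochs 1, 31, 81), or over epochs 31-80
for the cross-condition comparison. Conditions are compared with
two-sided paired t-tests (networks paired by seed), Bonferroni-corrected
within each metric family across the lesioned conditions; zero-variance
differences are flagged as degenerate rather than reported as extreme
p-values. No-response trials enter error counts as errors and
response-time summaries at 800 ms.

## What the simulations do and do not show

The synthetic task is the study's own experimental design, not recorded
data: all inputs are Poisson processes and the "behavior" is the
network's column choice. Replicate networks differ only in initial
random weights, wiring samples and noise realisations. Conclusions
therefore concern the model mechanism — how dopamine's dynamic range
shapes trial-and-error learning in this circuit — and transfer to real
motor learning only insofar as the circuit abstraction holds. Fixture
curves (piecewise-constant error series with optional noise) exercise
the curve analysis without simulation and make no biological claim.

With the calibrated constants the healthy model completes learning in
every replicate, with a mean per-network learning time near 54 epochs,
an early phase near 15-20 epochs on the mean curve, a progressing phase
near 50-60 epochs, and an epoch 31-80 mean error near 4-6% (the
straggler tail of slow networks dominates this number). The source
study reports a 30-epoch early phase, 50-epoch progressing phase and
78-epoch mean learning time together with a sub-5% error in the 31-80
window; note that these cannot all hold for a single curve (a curve
above 50% error until epoch 30 cannot average below 5% over epochs
31-80), so this implementation favors the completion structure and
window error, at the cost of a faster early phase. Under lesions the
implementation reproduces the ordinal structure: preclinical lesions
(20-40%) always complete learning with graded slowing, the mean curve
at 70% (and usually 50%) never completes, window errors rise with
lesion up to ~60-70% at the severest lesion, and response time rises
steeply only at clinical-stage lesions.

## Numerical and design choices

- Determinism: one `numpy` Philox/PCG64 generator per network drives
  build, background, stimulus and dopamine sampling; every result is
  bit-reproducible from (config, base seed). Poisson inputs are
  pre-drawn per phase and fed to a compiled (numba) stepping kernel; a
  pure-python scalar reference implements the identical update and the
  tests require exact agreement between the two.
- Degenerate inputs: non-finite membrane state aborts with the neuron
  named; empty trial tables, out-of-range windows, invalid lesion
  fractions and malformed configs raise explicit errors.
- Problem sizes: the bundled analyses use 30 replicate networks for the
  healthy condition and 10-15 per lesion level; replicate counts are
  configuration values, and the statistics are computed identically at
  any count.

## Known limitations

- Free constants (background-synapse weights, stimulus drive) are
  calibrated, not published values; the absolute learning-time scale
  depends on them, and the published early-phase length could not be
  matched simultaneously with sharp consolidation.
- The 50%-lesion condition is marginal: some replicate batches complete
  learning very late instead of never.
- Mild lesions slow responses slightly but measurably, so the published
  response-time null result below 50% lesion reproduces only as a
  gradient (severe ≫ mild), not as strict non-significance at every
  replicate count.
- No spike-timing-dependent plasticity, eligibility traces,
  multi-compartment neurons, progressive degeneration during a trial,
  or compensation mechanisms; M1 passively mirrors PMC and is logged,
  not read.
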