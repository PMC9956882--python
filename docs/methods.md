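# Methods

## Model overview

`cortexstack` models a dissociated cortical culture grown in stacked layers
on a glass-microbead scaffold and recorded through a planar micro-electrode
array (MEA) that only sees the bottom ("readout") layer.  Each layer is a
square sheet of 1091 point neurons at 26 um pitch (planar density
~1480 cells/mm^2, area 736164 um^2), 20% of them inhibitory; layers are
stacked 50 um apart, giving ~30000 cells/mm^3.  Neurons are leaky
integrate-and-fire (LIF) units:

    tau_m dV/dt = (E_L - V) + (I_noise + I_syn) / g_L

with tau_m = 10 ms, E_L = V_reset = -70 mV, threshold -50 mV, g_L = 10 nS
and a 5 ms absolute refractory period.  Synaptic input is the difference of
two exponentially decaying currents (tau = 10 ms); an arriving presynaptic
spike increments the excitatory (inhibitory) current of the target by
alpha_EX * w (alpha_IN * w) with alpha_EX = 12, alpha_IN = 16, where the
weight w follows a planar Gaussian of inter-somatic distance
(sigma = 1000 um).  Conduction delays are distance / 0.5 mm/ms, ceiled to
the 0.1 ms integration grid.  The engine integrates all state with the
exponential Euler method (inputs held constant over a step, making the
per-step membrane update the exact closed-form relaxation), and the
independent background drive is redrawn per neuron every millisecond as
g_L * U{0..5} * noise_unit.

Wiring rules (no autapses; no inhibitory-to-inhibitory edges anywhere):

* **Rule 1 (Gaussian, "G")** — each ordered admissible pair connects with
  probability p_max * exp(-d^2 / 2 sigma^2), p_max = 0.2; out-degrees are
  then capped at 8% of the layer population (87 of 1091) by uniform random
  pruning.
* **Rule 2 (scale-free, "SF")** — per-neuron out-degree targets are drawn
  from a discrete power law over 100 evenly spaced degree values in
  [50, 200] with log-log slope -0.61; Gaussian-proposed edges are pruned
  down to the target.  Hubs land on random neurons.
* **3D stacking** — inter-layer edges originate from a configurable source
  population per layer (all neurons; a random 33%; a central 278-um disc; or
  five 129-um discs — the restricted schemes are equalised to exactly
  round(0.33 * 1091) = 360 sources so they stay comparable) and use the same
  kernels on the full 3D distance with peak probability p_max / 3.  Sources
  may project to any other layer; the Gaussian distance decay suppresses
  long hops.  The Rule-1 out-degree cap is applied per source to the
  inter-layer edge set.

Presets `G2D, SF2D, G3D, SFL03D, SFall3D, Grnd3D, GC3D, G5C3D` combine these
rules as in the study design (`SFL03D` applies Rule 2 only to the readout
layer; `SFall3D` to every layer; the last three use Rule 1 intra-layer with
restricted inter-layer sources).

## Analysis pipeline

All headline metrics refer to the readout layer. Single-neuron bursts use
the string method: maximal runs of >= 5 spikes with every inter-spike
interval <= 100 ms; BD is the run span.  A neuron is *active* if its rate
exceeds 0.1 sp/s and *burst-active* if it additionally exceeds 4 bursts/min;
MFR (sp/s) and MBR (bursts/min) average over those populations only.

Network bursts use the two-threshold population-event rule (>100 ms bounding
gaps, >= 20% node participation).  Two readings are implemented:
`method="spikes"` clusters the pooled spike train directly, and
`method="bursts"` (the default inside `analyze()`) clusters single-neuron
burst events.  The burst-event reading is used for the network statistics
because any tonic background firing — even the ~0.1 sp/s noise floor of this
model, ~100 sp/s pooled over 1091 neurons — makes >100 ms pooled-spike gaps
astronomically unlikely, so the pooled reading cannot yield finite
network-burst durations on realistic recordings.

Event shapes: per-event spike-time histograms (1 ms bins) are aligned to a
seeded randomly chosen reference event by the lag maximising the absolute
cross-correlation; events correlating > 0.4 with the reference enter the
average STH.  The IFR is the STH smoothed with a 10 ms Gaussian kernel (the
estimator is not otherwise constrained).  The plateau bounds t_on/t_off are
the first/last crossings of 80% of the STH peak (configurable; the
literature shows these instants without defining them).  The rising segment
is fitted with r(t) = a0 e^{(b0-1)t} + a1 e^{(b1-1)t} + a3 and the decaying
segment with s(t) = c0 e^{d0 t} + c1 e^{d1 t} by multi-start nonlinear least
squares (8 log-spaced exponent magnitudes); tau_rise = 1/|min(b0,b1) - 1|
and tau_decay = 1/|min(d0,d1)| with t in ms.  The (b-1) exponent convention
follows the published form of the rise equation; interpreting b as the raw
exponent is a one-line change in `fit_rise`.

Victor-Purpura distances use the standard dynamic programme (insert/delete
cost 1, shift cost q|dt|).  Layer similarity maps use q = 1/(100 ms) — tying
the shift cost to the burst time-scale — and similarity 1/(1 + distance),
normalised to the maximum off-diagonal entry; pooled layer trains longer
than 2000 spikes are uniformly subsampled to keep the quadratic DP
tractable.  Both choices are configurable.

Group statistics use the Kruskal-Wallis test with 25-75-percentile box
summaries computed from per-network values (numpy's linear-interpolation
percentile convention).

## Calibration of the synaptic and noise scales

Three scalar scales of the model are calibrated rather than taken at face
value, following the original tuning procedure in which the noise amplitude
and the synaptic (notably inhibitory) weights were swept until the network
produced stable, culture-like dynamics:

* **Weight-kernel amplitude** `DEFAULT_WEIGHT_SCALE_MV = 2.7e6` (as w/g_L in
  mV before the 1/(2 pi sigma^2) normalisation).  This is the single
  unit-fixing constant of the synaptic model: at sigma = 1000 um it yields a
  peak per-spike postsynaptic drive of alpha_EX * c/(2 pi sigma^2) ≈ 5 mV.
  Nominal printed values for this constant are dimensionally ambiguous and
  differ by six orders of magnitude depending on the length unit assumed in
  the Gaussian normalisation; neither extreme supports recurrent activity
  (0.002 mV per spike is drowned by the noise, 1900 mV per spike fires every
  target instantly).
* **Noise unit** `noise_unit_mv = 5.4` (nominal 6.4).  With the literal
  6.4 mV unit the noise alone drives every neuron at ~8.6 sp/s.  That is
  incompatible with the model's own reference behaviour: because inhibitory
  neurons receive no inhibition, no configuration can fire below the
  noise-only floor, yet an inhibition-dominated (50% inhibitory) culture is
  expected to sit near 0.08 sp/s.  The default puts the noise-only floor at
  ~0.2 sp/s, preserving the discrete U{0..5} form and the 1 ms refresh.
* **Inhibitory weight factor** `inhibitory_weight_factor = 1.2`, an extra
  multiplier on inhibitory efferent weights (the mean inhibitory synaptic
  weight was an explicitly swept quantity in the original tuning).  At
  factor 1.0 the wiring is excitation-dominated (in-degree-weighted drive
  ratio ~835:348 E:I) and any coupling strong enough to produce collective
  events ignites a permanent runaway.

## Dynamical regimes, and what this implementation does and does not reproduce

Mapping the (noise unit, weight scale, inhibitory factor) space — scans over
noise 5.2-6.4 mV, weight scale 3e5-2e7, factor 0.7-5.0, records up to 300 s,
multiple seeds — shows this architecture supports exactly three phases:

1. **silent** (sub-threshold noise only),
2. **asynchronous** — an inhibition-stabilised irregular state at
   ~1.5-4 sp/s, and
3. **saturated** — a refractory-limited ~165-190 sp/s runaway.

The transition from (2) to (3) is discontinuous and, once ignited, the
saturated state never collapses on experimental time-scales.  Multi-second
network bursts at moderate within-event rates — the regime implied jointly
by reference values MFR ~4 sp/s, BD ~1 s, NBD ~4 s, ~6 events/min — would
require a stable intermediate-rate branch that this connectivity (delta-
increment current synapses, no adaptation or short-term plasticity, E-to-E
loop gain above unity at any event-capable coupling) does not possess.

The frozen defaults therefore sit at the stable asynchronous point and
reproduce: in-vitro-scale irregular spiking (readout MFR ~2.5-3 sp/s in 2D),
the reduction of readout activity with added layers, the >190 sp/s runaway
at 10% inhibition, near-silence under inhibition dominance, and all
structural statistics exactly.  They do **not** reproduce second-scale burst
and network-burst durations: detected bursts are short (~0.2 s) statistical
rate excursions and 20%-participation network bursts are generally absent,
so burst-duration and network-burst-duration metrics read far below the
reference values (or are unavailable).  These discrepancies are reported as
computed; no threshold was adjusted to mask them.

## Problem sizes and numerical choices

* Simulations integrate 10 s settle + 60 s recording at dt = 0.1 ms; spikes
  are recorded at 10 kHz.  The batch profiles run 5 replicates per group
  (`desk_plan`) instead of the full 12-28 (`paper_plan`); both are provided.
* The acceptance script uses n = 5 two-dimensional replicates, one 3D
  network per layer count 2-6, and n = 3 four-layer replicates.
* The hot loop is numba-compiled; one master seed drives placement, wiring,
  noise and analysis tie-breaks through independent counter-derived run
  seeds, making every table byte-reproducible.
* Delays are ceiled to the grid with a one-step minimum (causality under
  discrete time).  Spike deliveries landing between grid points apply at the
  next step.  During the refractory window the membrane is clamped at the
  reset potential while synaptic currents continue to decay and accumulate.
* Degenerate inputs: empty neuron tables and unsorted spike trains raise;
  silent networks produce an `inactive` report instead of dividing by zero;
  infeasible scale-free degree targets (corner neurons with fewer admissible
  partners than their draw) are capped with a logged warning — at default
  geometry this affects ~5-10% of neurons and flattens the top of the
  degree distribution slightly.
* The runaway guard (500 sp/s) only flags; it is set above the documented
  ~190 sp/s instability so that regime remains observable.

## Synthetic fixtures

`make_fixtures` generates all test inputs programmatically: crafted spike
trains exercising every burst/network-burst branch, a <= 50-neuron toy
network plus a two-neuron 1-mm pair (delay exactly 2 ms), and
double-exponential STH shapes with known parameters for fit-recovery tests.
They share the production code paths (same placement and wiring routines),
so passing tests validate the real pipeline; they do not emulate biological
variability beyond what the model itself produces.

## Known limitations

* Mono-compartment LIF with current synapses; no conductance synapses,
  adaptation, short-term plasticity or dendritic structure — the stated
  scope of the model, and (see above) the proximate reason second-scale
  population events are not reproduced.
* Isotropic connectivity only; amorphous-scaffold (anisotropic) growth and
  multi-module cultures are out of scope.
* The Victor-Purpura layer similarity transform and its cost parameter are
  package choices (the original supplementary definition is not public);
  the similarity *map* contract (normalisation, step-distance classes) does
  not depend on them.
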