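# Model and methods

## The model

`prebotc` implements a conductance-based network model of the rhythm-
generating core of the preBötzinger complex (preBötC), the medullary
microcircuit that produces the inspiratory breathing rhythm.  One hundred
excitatory single-compartment neurons are coupled sparsely (connection
probability 13%, uniformly distributed weights up to 0.2 nS) through
depressing, zero-delay exponential synapses.  Each neuron carries

* the action-potential currents `I_Na` (m³h) and the delayed rectifier
  `I_K` (m⁴, α/β rate form),
* two high-threshold spike-shape currents: `I_SPK` (sodium-like, raises the
  spike peak) and `I_AHP` (potassium, deepens the afterhyperpolarization),
* the slowly inactivating persistent sodium current `I_NaP` (m·h,
  inactivation time constant up to 5 s) — the engine of intrinsic bursting,
* an optional calcium current `I_Ca` (off by default; a configuration hook
  exists but no parameter set ships),
* a potassium-dominated leak whose reversal follows a GHK-style expression
  in the ionic concentrations, a static excitatory drive `g_Tonic` (the
  excitability axis), and the dynamic synaptic current.

Reversal potentials derive from the ion concentrations
(`E = 26.54·ln(out/in)` mV); the leak reversal mixes Na⁺ and K⁺ with
relative permeabilities 1:42.  Changing the bath potassium (`K_bath`) moves
`E_K` and `E_Leak` and rescales every neuron's sampled leak conductance by
the ratio of distribution means `μ_Leak(K) = exp((K − 3.425)/4.05)` — the
sampled heterogeneity is preserved rather than redrawn (the alternative,
resampling, would decorrelate `g_Leak` from `g_NaP` mid-experiment).

Cellular heterogeneity is bivariate-normal: `g_NaP ~ N(3.33, 0.75²) nS`
and, conditionally, `g_Leak | g_NaP` normal with correlation ρ = 0.8 and
σ_Leak = 0.05·μ_Leak, both truncated at zero by resampling.  Spike-shape
conductances are either uniform across the population or drawn from
`U(0, 12) nS` to emulate natural spike-height variability.

Synaptic depression follows the mean-field rule dD/dt = (1 − D)/τ_D with
τ_D = 1 s, and D → (1 − 0.2)·D at each presynaptic spike; transmission is
weighted by the presynaptic D at spike time.

## Integration

States advance by explicit first-order Euler at fixed dt = 0.025 ms.
Within a step, gates are updated first from V(t) and the membrane then from
the updated gates (sequential Euler).  We chose this ordering because it
tracks the dt → 0 trajectory markedly better at this step size than the
fully simultaneous update (the measured AHP trough differs from the
fine-dt limit by < 0.01 mV versus ≈ 0.15 mV), at identical cost.  Gating
nonlinearities are evaluated from lookup tables on a 0.05 mV grid built
from the same closed-form kinetics used by the scalar reference
implementation (`membrane_derivative`); the tables are linearly
interpolated, and the dual route (kernel vs. reference) is covered by unit
tests.  Euler relaxation factors dt/τ can exceed one for the fastest gates
near the spike peak, so gates are clamped to [0, 1] after each step.
Spikes are logged at upward crossings of −35 mV with a 1 ms lockout against
numerical double-crossings.  Integration proceeds in 50 ms chunks; between
chunks the engine re-evaluates time-varying environments (hypoxia
schedules, bath or temperature ramps) and applies event-triggered clamps.
Runs start from V = −60 mV with every gate at its steady state and D = 1;
analysis discards a leading transient (5–10 s; the slow `I_NaP`
inactivation needs several seconds to settle).

Temperature enters through a Q10 of 1.5 applied to every gating, synaptic
and depression time constant (τ multiplied by `1.5^(−(T−27)/10)`), and
through the membrane capacitance, which grows 0.3% per °C from 36 pF at
27 °C.

## Spike-shape quantification

Spike height (peak V) and AHP (inter-spike minimum V) are measured on a
single neuron with `g_NaP = 0` (so bursting cannot corrupt the trough),
driven to steady repetitive spiking.  The published protocol leaves the
drive and trace handling open; the package fixes them once:

* drive = 0.40 nS, the smallest 0.05-grid drive that sustains repetitive
  spiking in the baseline cell;
* the trace is analysed at 0.5 ms resolution (a typical storage
  decimation; the broad trough is insensitive, the 1-ms-wide peak is
  clipped by a fraction of a millivolt);
* height and AHP are averaged over the last 40 steady-state inter-spike
  intervals of a 20 s run — 10-spike averages wobble by ±0.2 mV through
  sampling-phase beating between the inter-spike interval and the 0.5 ms
  sampling grid.

With these choices the baseline cell measures −17.91 mV height and
−55.12 mV AHP.

## Calibration of I_SPK and I_AHP

The spike-shape currents are specified by published observables rather than
published kinetics, so their gating is fixed by calibration
(`prebotc.calibration`): a deterministic coarse grid plus Nelder–Mead
refinement against the spike-height/AHP response curves (endpoints at
50 nS, the +3.5 mV height change at 5.816 nS, and height preservation
under `I_AHP`), under the structural constraint that both currents stay
closed at rest and around spike threshold (activation `m∞(−45 mV)` below
~10⁻³, which keeps the silent→spiking threshold within 5% of baseline —
the "without affecting excitability" requirement).

Two structural findings from the calibration, both load-bearing:

* `I_SPK` cannot share the sodium current's inactivation midpoint
  (−67.5 mV): at inter-spike potentials it would be ~70% inactivated, and
  no activation setting then raises the peak by more than ~15 mV — half
  the required range — even with every inactivation time constant freed.
  The fitted inactivation keeps the printed slope (−11.8 mV) and τ shape
  but a depolarized midpoint (−26 mV), making `I_SPK` a transient
  high-threshold current that self-terminates at the spike peak.
* `I_AHP` needs a slow, M-current-like voltage-dependent time constant
  (fitted τ_max = 20 ms).  An instantaneous high-threshold potassium gate
  closes during the downstroke and cannot deepen the trough; only a
  deactivation tail that outlasts the spike can.

Fitted values (persisted as package defaults): `I_SPK` activation
midpoint −22.5 mV, slope 3.25 mV, τ_max 0.1 ms; inactivation midpoint
−26 mV; `I_AHP` midpoint −26.5 mV, slope 4 mV, τ_max 20 ms (k_τ 25 mV).
Closure: height +10.99 mV at g_SPK = 50 nS (target +11.22), AHP
−60.66 mV at g_AHP = 50 nS (target −60.63), threshold shifts −2.1% and
+3.1%.

## Activity classification and burst capability

An uncoupled neuron's steady-state activity at a given drive is *silent*
(< 3 spikes), *bursting*, or *tonic*.  Bursting requires at least three
spike clusters — separated by gaps exceeding max(300 ms, 5× median ISI) —
with at least three spikes each.  The three-spike minimum matters: just
above the spiking threshold the model fires sparse doublets (~1 Hz
two-spike clusters) that are not bursts in any physiological sense but
would satisfy a two-spike rule.

A neuron is *burst-capable* when some drive produces bursting.  Bursting,
when possible, occupies a narrow drive band (0.02–0.06 nS wide) that opens
directly at the silent→spiking transition, so uniform drive grids are
unreliable classifiers at any affordable resolution.  The package instead
bisects each neuron's spiking threshold (batched short probes, 10 s each,
resolved to 0.005 nS; probes test a descending drive ladder first, because
very strong drives silence a neuron again through depolarization block)
and then classifies activity at seven fixed offsets from 0 to 0.23 nS
above the threshold, each with a 30 s run (8 s transient, 22 s analysis
window — long enough for three cycles of the slowest near-threshold
bursts).  Capability of a 100-neuron population resolves in ~35 s on one
core; classification batches are integrated as a single vectorized kernel
call.

## Population rhythm metrics

Population rate is spikes per 20 ms bin per neuron (Hz).  Burst peaks must
exceed 20% of the trace's 95th percentile and be 200 ms apart; the network
is *rhythmic* when at least five peaks occur with inter-peak CV < 0.5, the
trace is quiescent between bursts (median rate below half the mean peak
height), and the mean peak exceeds 5 Hz.  The quiescence and amplitude
floors separate genuine population bursts from the fast, low-amplitude
ripples of partially synchronized tonic firing, which otherwise satisfy
peak-count criteria; where exactly the underlying study drew this line is
not recorded, so these two floors are package choices.  Frequency is the
median per-cycle inverse inter-peak interval; burst duration, rise and
decay are measured at half-maximum of the cycle-triggered average above
its inter-burst baseline.  Pre-inspiratory participation counts neurons
spiking between 500 ms after one burst peak and 500 ms after the next,
with the window start pushed to the burst's end when bursts outlast
500 ms.

## Protocols

All protocol transforms are pure functions of a network realization or an
environment: partial `I_NaP` block (global or restricted to the initially
burst-capable/incapable subsets, membership frozen at baseline),
developmental scaling (factor `s` on all voltage-gated conductances except
`g_NaP`, which scales by `1 + m(s−1)` so all co-scaling ratios agree at
the control point), Q10 temperature scaling, bath-potassium changes, and
a two-sigmoid hypoxia schedule (fast −1 mV gating shift, midpoint 40 s,
steepness 5 s; slow intracellular Na⁺ accumulation 15 → 47.5 mM, midpoint
70 s, steepness 10 s; both start exactly at baseline before onset).  The
gating shift applies to the (in)activation midpoints of `I_Na` and
`I_SPK`, not `I_NaP`.

Event-triggered clamps reproduce phase-specific manipulations: at a fixed
time or at burst initiation — detected online as the peak of the smoothed
(50 ms) network-mean `h_NaP` during an inter-burst interval, armed only
after one completed population burst — the engine can disable synapses,
freeze `h_NaP`, freeze depression, both, or freeze `m_NaP` in neurons that
have not spiked since the previous burst.

## Problem sizes

The shipped benchmark suite uses the sizes at which the package's own
numbers were produced: single-neuron protocols at full length (20 s
quantification runs, dt = 0.025 ms); capability maps on an 8×8
(g_NaP, g_Leak) grid with 1 nS spike-shape steps and monotone pruning;
population fractions as means over three 100-neuron seeds; coupled-network
block experiments on one 100-neuron realization with 10% block steps,
0.025 nS drive search, and 30 s analysis windows (70 s at block ≥ 50%,
where surviving rhythms slow below 0.25 Hz and need longer windows to show
five cycles).

## What the generator emulates, and limits

The synthetic populations reproduce the study conditions: the bivariate
(g_NaP, g_Leak) distribution tied to bath potassium, uniform spike-shape
heterogeneity, Bernoulli connectivity with uniform weights.  They do not
model distance-dependent topology, inhibitory neurons, channel noise, or
multi-compartment morphology — so passing tests say nothing about those
features of the real preBötC.

Known limitations, established during validation and recorded here
deliberately:

* The calibrated model reproduces the spike-shape response curves and the
  critical conductances for bursting elimination (within 6–10%), but its
  bursting is more fragile than the published benchmarks under some
  conditional protocols: the hyperpolarizing sodium-gating shift *reduces*
  the burst-capable fraction here (a stable depolarization-block
  equilibrium opens just below threshold and swallows the spiking
  corridor of high-`g_NaP` neurons), warming to 37 °C raises capability by
  ~15 rather than ~37 percentage points, no neuron remains burst-capable
  at K_bath = 4 mM even at 37 °C, and the coupled rhythm survives global
  `I_NaP` block only to ~60% rather than 80–90%.  These discrepancies are
  properties of the unpublished degrees of freedom (the spike-shape
  current kinetics beyond the calibrated observables, and a calcium
  current for which no parameters are available); the directional effects
  (temperature raises capability, low potassium suppresses it, block
  tolerance grows with excitability) all reproduce.
* Burst capability is classifier-relative near the critical surface:
  hairline drive bands below ~0.01 nS and bursts slower than ~3 cycles per
  22 s window are not counted, by design.
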