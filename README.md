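# prebotc

A conductance-based model of rhythm generation in the preBötzinger complex
(preBötC), the brainstem microcircuit that produces the inspiratory
breathing rhythm — built to study how **spike shape** controls whether
neurons can burst intrinsically, and what that does (and does not) imply
about how the network rhythm is made.

The package is for computational neuroscientists who want to simulate
Hodgkin–Huxley preBötC networks with tunable spike shape: 100 sparsely
coupled excitatory neurons (connection probability 13%, depressing
exponential synapses), each carrying the spike-generating currents
`I_Na`/`I_K`, a slowly inactivating persistent sodium current `I_NaP`
(activation `m_NaP`, inactivation `h_NaP` with τ up to 5 s) that drives
intrinsic bursting, a potassium-dominated leak tied to the bath potassium
concentration, and two high-threshold currents that selectively reshape
the action potential:

* `I_SPK = g_SPK · m · h · (V − E_Na)` — raises spike height,
* `I_AHP = g_AHP · m · (V − E_K)` — deepens the afterhyperpolarization,

with membrane dynamics

```
C dV/dt = −I_Na − I_K − I_SPK − I_AHP − I_NaP − I_Ca − I_Leak − I_Tonic − I_Syn
τ_x(V) dx/dt = x_∞(V) − x
```

integrated by forward Euler at dt = 0.025 ms.  Heterogeneity follows a
bivariate normal (g_NaP, g_Leak) distribution (ρ = 0.8); synaptic
depression is mean-field (`D → 0.8·D` per presynaptic spike, τ_D = 1 s).
Small increases in spike height or AHP strip model neurons of intrinsic
bursting without touching `I_NaP` — which lets the model dissociate the
roles of pacemaker neurons, persistent sodium, and recurrent excitation in
rhythmogenesis, and explore how oxygenation, development, extracellular
potassium and temperature move the balance.  See `docs/methods.md` for the
full model description and design choices.

## Worked example

```
python examples/single_neuron_modes.py
```

```
tonic drive (nS)   spikes/s   activity mode
          0.10        0.0   silent
          0.20        0.0   silent
          0.24        7.6   bursting
          0.26       13.5   tonic
          0.40       34.4   tonic
          0.80       68.8   tonic
```

The canonical neuron (g_NaP = 3.33 nS, g_Leak = 3.5 nS) is *silent* at low
drive, fires *periodic bursts* in a narrow band of drives that opens right
at its spiking threshold, and spikes *tonically* above it.  That narrow
band is the object of study: raising g_SPK to ≈ 5.4 nS (spike height
+3.5 mV) or g_AHP to ≈ 19 nS closes it at every drive, making the neuron
"burst-incapable" — while the coupled network keeps producing a rhythm.

Other example scripts, one per capability: `spike_shape_curves.py`
(height/AHP response to the calibrated spike-shape currents),
`capability_map.py` (burst capability across (g_NaP, g_Leak) space and in
a sampled population), `network_rhythm.py` (emergent population rhythm,
frequency–drive relation, pre-inspiratory spiking),
`hypoxia_response.py` (biphasic response to a simulated oxygen challenge),
`phase_specific_clamps.py` (event-triggered clamps at burst initiation).

The main entry points are `prebotc.engine.integrate` /
`simulate_neurons` (vectorized Euler integration of networks or uncoupled
batches), `prebotc.network.build_network` (seeded sampling),
`prebotc.protocols` (capability classification, I_NaP block, hypoxia,
development, temperature, K_bath), `prebotc.analysis` (spike, mode and
rhythm metrics), and `prebotc.experiments.run_experiment` (manifest-driven
runs with reproducible output bundles).

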