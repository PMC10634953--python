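"""Conditional manipulations and experiment drivers.

Covers the protocol families explored with the model: excitability sweeps
and burst-capability classification, spike-shape parameter maps, partial
persistent-sodium block (global or restricted to burst-capable /
burst-incapable subsets), acute hypoxia (sodium-channel gating shift followed
by intracellular sodium accumulation), developmental conductance scaling,
bath-potassium changes, and temperature (Q10) scaling.

All transforms are pure: they return new objects and never mutate their
inputs, so protocols compose in whatever order an experiment declares.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .analysis import ActivityLabel, classify_activity, population_rate, rhythm_metrics
from .biophysics import IonEnvironment, NeuronParameters
from .engine import SimulationConfig, integrate, simulate_neurons
from .network import NetworkRealization, SynapseDynamics, mu_leak

__all__ = [
    "SweepGrid",
    "HypoxiaSchedule",
    "DevelopmentScaling",
    "default_gtonic_grid",
    "classify_modes",
    "classify_burst_capability",
    "population_capability",
    "map_capability_region",
    "apply_inap_block",
    "hypoxia_environment",
    "hypoxia_env_schedule",
    "development_scale",
    "temperature_scaling",
    "rhythmic_gtonic_range",
]


def default_gtonic_grid(lo: float = 0.0, hi: float = 2.0, step: float = 0.05):
    """Default excitability grid (nS) for activity-mode classification."""
    return np.round(np.arange(lo, hi + step / 2, step), 6)


@dataclass(frozen=True)
class SweepGrid:
    """A one-parameter sweep: which knob, its values, and shared context."""

    parameter: str
    values: np.ndarray
    cfg: SimulationConfig | None = None
    seed: int | None = None

    def __post_init__(self):
        v = np.asarray(self.values, float)
        if not np.all(np.isfinite(v)):
            raise ValueError("sweep values must be finite")
        if np.any(np.diff(v) < 0):
            raise ValueError("sweep values must be sorted ascending")
        object.__setattr__(self, "values", v)


# ---------------------------------------------------------------------------
# Activity-mode classification and burst capability
# ---------------------------------------------------------------------------

def classify_modes(
    template: NeuronParameters,
    env: IonEnvironment,
    cfg: SimulationConfig,
    *,
    g_NaP=None, g_Leak=None, g_SPK=None, g_AHP=None,
    g_tonic=0.0,
    k_bath_ref: float = 8.5,
) -> np.ndarray:
    """Activity labels of a batch of uncoupled neurons (one kernel pass).

    Scalar arguments broadcast against each other; the batch is integrated in
    one vectorized run and each neuron's spikes inside the analysis window
    ``[cfg.transient, cfg.duration]`` are labelled silent / bursting / tonic.
    """
    vals = [np.atleast_1d(np.asarray(x if x is not None else getattr(template, d), float))
            for x, d in ((g_NaP, "g_NaP"), (g_Leak, "g_Leak"),
                         (g_SPK, "g_SPK"), (g_AHP, "g_AHP"))]
    g_tonic = np.atleast_1d(np.asarray(g_tonic, float))
    n = max(max(v.size for v in vals), g_tonic.size)
    vals = [np.broadcast_to(v, (n,)).copy() if v.size in (1, n)
            else (_ for _ in ()).throw(ValueError("length mismatch")) for v in vals]
    g_tonic = np.broadcast_to(g_tonic, (n,)).copy()

    net = NetworkRealization(template=template, g_NaP=vals[0], g_Leak=vals[1],
                             g_SPK=vals[2], g_AHP=vals[3], K_bath_ref=k_bath_ref)
    rec = integrate(net, env, cfg, g_tonic=g_tonic, coupled=False)
    window = (cfg.transient, cfg.duration)
    trains = rec.spike_trains()
    return np.array([classify_activity(ts, window) for ts in trains], dtype=object)


def classify_burst_capability(
    p: NeuronParameters,
    env: IonEnvironment,
    g_tonic_grid=None,
    cfg: SimulationConfig | None = None,
) -> tuple[bool, np.ndarray]:
    """Whether any excitability level makes this neuron burst intrinsically.

    Sweeps the uncoupled neuron over ``g_tonic_grid`` and returns
    ``(capable, labels)``: the neuron is burst-capable iff at least one grid
    point is classified as bursting.
    """
    grid = np.asarray(g_tonic_grid if g_tonic_grid is not None
                      else default_gtonic_grid(), float)
    if cfg is None:
        cfg = SimulationConfig(duration=40_000.0, transient=10_000.0)
    labels = classify_modes(p, env, cfg, g_tonic=grid)
    capable = any(l == ActivityLabel.BURSTING for l in labels)
    return capable, labels


def population_capability(
    network: NetworkRealization,
    env: IonEnvironment,
    g_tonic_grid=None,
    cfg: SimulationConfig | None = None,
    batch_size: int = 6000,
) -> np.ndarray:
    """Burst capability of every neuron in a sampled population.

    Each neuron is swept (uncoupled) over the excitability grid; the
    (neuron x grid) product is flattened into vectorized batches.  Returns a
    boolean array of length N.
    """
    grid = np.asarray(g_tonic_grid if g_tonic_grid is not None
                      else default_gtonic_grid(), float)
    if cfg is None:
        cfg = SimulationConfig(duration=40_000.0, transient=10_000.0)
    n, g = network.n, grid.size
    nap = np.repeat(network.g_NaP, g)
    leak = np.repeat(network.g_Leak, g)
    spk = np.repeat(network.g_SPK, g)
    ahp = np.repeat(network.g_AHP, g)
    ton = np.tile(grid, n)
    bursting = np.zeros(n * g, dtype=bool)
    for lo in range(0, n * g, batch_size):
        hi = min(lo + batch_size, n * g)
        labels = classify_modes(network.template, env, cfg,
                                g_NaP=nap[lo:hi], g_Leak=leak[lo:hi],
                                g_SPK=spk[lo:hi], g_AHP=ahp[lo:hi],
                                g_tonic=ton[lo:hi],
                                k_bath_ref=network.K_bath_ref)
        bursting[lo:hi] = [l == ActivityLabel.BURSTING for l in labels]
    return bursting.reshape(n, g).any(axis=1)


#: Drive offsets (nS) above the spiking threshold probed by the adaptive
#: capability classifier.  Intrinsic bursting, when possible at all, occupies
#: a narrow drive band that begins at the silent->spiking transition (the
#: quiescent state destabilizes into the burst limit cycle), so probing a
#: short ladder above the per-neuron threshold finds it far more reliably
#: than any affordable fixed grid.
ADAPTIVE_OFFSETS = (0.0, 0.01, 0.02, 0.04, 0.07, 0.12, 0.2)


def _spike_counts(network, env, cfg, g_tonic):
    rec = integrate(network, env, cfg, g_tonic=g_tonic, coupled=False)
    ids = rec.spike_ids[rec.spike_times >= cfg.transient]
    return np.bincount(ids, minlength=network.n)


def spiking_thresholds(
    network: NetworkRealization,
    env: IonEnvironment,
    lo: float = 0.0,
    hi: float = 4.0,
    tol: float = 0.005,
    probe_cfg: SimulationConfig | None = None,
) -> np.ndarray:
    """Per-neuron smallest tonic drive (nS) that elicits spiking.

    Batched bisection with short probe runs; neurons that stay silent even at
    ``hi`` get NaN.
    """
    if probe_cfg is None:
        # the observation window must be long enough to catch slow bursting
        # near onset (inter-burst intervals of several seconds)
        probe_cfg = SimulationConfig(duration=10_000.0, transient=4_000.0)
    n = network.n
    lo_a = np.full(n, lo)
    hi_a = np.full(n, hi)
    # anchor the bracket at the smallest ladder drive that spikes: very high
    # drives can silence a neuron again through depolarization block, so
    # probing only at `hi` would misclassify it as never-spiking
    alive = np.zeros(n, dtype=bool)
    ladder = [hi]
    while ladder[-1] / 2 > lo + 0.05:
        ladder.append(ladder[-1] / 2)
    for g in ladder:
        spk = _spike_counts(network, env, probe_cfg, np.full(n, g)) > 0
        hi_a = np.where(spk, g, hi_a)
        alive |= spk
    while np.max(hi_a - lo_a) > tol:
        mid = 0.5 * (lo_a + hi_a)
        spk = _spike_counts(network, env, probe_cfg, mid) > 0
        hi_a = np.where(spk, mid, hi_a)
        lo_a = np.where(spk, lo_a, mid)
    thr = hi_a.copy()
    thr[~alive] = np.nan
    return thr


def population_capability_adaptive(
    network: NetworkRealization,
    env: IonEnvironment,
    cfg: SimulationConfig | None = None,
    offsets=ADAPTIVE_OFFSETS,
    probe_cfg: SimulationConfig | None = None,
    batch_size: int = 6000,
) -> np.ndarray:
    """Burst capability per neuron via threshold-anchored excitability probes.

    Finds each neuron's silent->spiking threshold by bisection, then runs
    full-length classification at drives ``threshold + offsets`` (the band of
    excitabilities where intrinsic bursting occurs when the neuron is capable
    of it).  Much finer effective drive resolution than a uniform grid at a
    fraction of the cost.
    """
    if cfg is None:
        cfg = SimulationConfig(duration=30_000.0, transient=8_000.0)
    thr = spiking_thresholds(network, env, probe_cfg=probe_cfg)
    n = network.n
    offs = np.asarray(offsets, float)
    k = offs.size
    ok = np.isfinite(thr)
    drives = (np.nan_to_num(thr, nan=1.0)[:, None] + offs[None, :]).ravel()
    nap = np.repeat(network.g_NaP, k)
    leak = np.repeat(network.g_Leak, k)
    spk = np.repeat(network.g_SPK, k)
    ahp = np.repeat(network.g_AHP, k)
    bursting = np.zeros(n * k, dtype=bool)
    for a in range(0, n * k, batch_size):
        b = min(a + batch_size, n * k)
        labels = classify_modes(network.template, env, cfg,
                                g_NaP=nap[a:b], g_Leak=leak[a:b],
                                g_SPK=spk[a:b], g_AHP=ahp[a:b],
                                g_tonic=drives[a:b],
                                k_bath_ref=network.K_bath_ref)
        bursting[a:b] = [l == ActivityLabel.BURSTING for l in labels]
    return bursting.reshape(n, k).any(axis=1) & ok


def critical_shape_conductance(
    template: NeuronParameters,
    env: IonEnvironment,
    which: str = "g_SPK",
    lo: float = 0.0,
    hi: float = 20.0,
    tol: float = 0.125,
    cfg: SimulationConfig | None = None,
) -> float:
    """Smallest spike-shape conductance abolishing intrinsic bursting.

    Bisects over ``which`` (g_SPK or g_AHP) for the given template neuron:
    at each candidate the adaptive capability classifier decides whether any
    excitability still produces bursting.  Requires the neuron to be capable
    at ``lo`` and incapable at ``hi``.
    """
    from .network import uncoupled_realization

    def capable_at(g):
        net = uncoupled_realization([replace(template, **{which: float(g)})])
        return bool(population_capability_adaptive(net, env, cfg=cfg)[0])

    if not capable_at(lo):
        raise ValueError(f"neuron not burst-capable at {which}={lo}")
    if capable_at(hi):
        raise ValueError(f"neuron still burst-capable at {which}={hi}")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if capable_at(mid):
            lo = mid
        else:
            hi = mid
    return hi


def map_capability_region(
    template: NeuronParameters,
    g_nap_values,
    g_leak_values,
    env: IonEnvironment,
    g_tonic_grid=None,
    cfg: SimulationConfig | None = None,
) -> np.ndarray:
    """Boolean burst-capability matrix over (g_NaP, g_Leak) space.

    Entry ``[i, j]`` is True iff the neuron with ``g_NaP = g_nap_values[i]``
    and ``g_Leak = g_leak_values[j]`` (spike-shape conductances taken from
    ``template``) is burst-capable.  With ``g_tonic_grid=None`` the adaptive
    threshold-anchored classifier is used (recommended: bursting drive bands
    are narrow); otherwise capability is evaluated on the fixed grid.  The
    capable region shrinks monotonically as the template's g_SPK or g_AHP
    grows.
    """
    nap = np.asarray(g_nap_values, float)
    leak = np.asarray(g_leak_values, float)
    net = NetworkRealization(
        template=template,
        g_NaP=np.repeat(nap, leak.size),
        g_Leak=np.tile(leak, nap.size),
        g_SPK=np.full(nap.size * leak.size, template.g_SPK),
        g_AHP=np.full(nap.size * leak.size, template.g_AHP),
    )
    if g_tonic_grid is None:
        capable = population_capability_adaptive(net, env, cfg=cfg)
    else:
        capable = population_capability(net, env, g_tonic_grid, cfg)
    return capable.reshape(nap.size, leak.size)


# ---------------------------------------------------------------------------
# Persistent-sodium block
# ---------------------------------------------------------------------------

def apply_inap_block(
    network: NetworkRealization,
    fraction: float,
    subset: str = "all",
    capable: np.ndarray | None = None,
) -> tuple[NetworkRealization, float]:
    """Scale down g_NaP of the selected neurons by ``1 - fraction``.

    ``subset`` is ``all``, ``burst-capable`` or ``burst-incapable``; the
    latter two require ``capable``, the capability mask computed on the
    *baseline* network (membership is frozen before any block).  Returns the
    blocked network and the remaining network-total g_NaP as a fraction of
    the input network's total.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("block fraction must lie in [0, 1]")
    if subset == "all":
        mask = np.ones(network.n, dtype=bool)
    elif subset in ("burst-capable", "burst-incapable"):
        if capable is None:
            raise ValueError("subset block requires the baseline capability mask")
        mask = np.asarray(capable, bool)
        if subset == "burst-incapable":
            mask = ~mask
    else:
        raise ValueError(f"unknown subset {subset!r}")
    out = network.copy()
    out.g_NaP[mask] *= (1.0 - fraction)
    total0 = float(network.g_NaP.sum())
    remaining = float(out.g_NaP.sum()) / total0 if total0 > 0 else 0.0
    return out, remaining


# ---------------------------------------------------------------------------
# Hypoxia
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HypoxiaSchedule:
    """Two sigmoidal time courses emulating acute hypoxia.

    A fast hyperpolarizing shift of the sodium-channel (in)activation
    midpoints (``dv_*``) is followed by a slower accumulation of
    intracellular sodium (``na_*``).  Steady-state endpoints: shift
    ``dv_amplitude`` (mV) and ``na_baseline + na_amplitude`` (mM).  Midpoints
    and steepnesses are in seconds; before ``onset`` both outputs sit exactly
    at baseline.
    """

    dv_amplitude: float = -1.0   # mV
    dv_midpoint: float = 40.0    # s after onset
    dv_steepness: float = 5.0    # s
    na_baseline: float = 15.0    # mM
    na_amplitude: float = 32.5   # mM
    na_midpoint: float = 70.0    # s after onset
    na_steepness: float = 10.0   # s
    onset: float = 0.0           # s

    def __post_init__(self):
        if self.na_baseline <= 0 or self.na_baseline + self.na_amplitude <= 0:
            raise ValueError("intracellular sodium must stay positive")


def _logistic(t, mid, steep):
    return 1.0 / (1.0 + math.exp(-np.clip((t - mid) / steep, -500, 500)))


def hypoxia_environment(t_s: float, sched: HypoxiaSchedule = HypoxiaSchedule()
                        ) -> tuple[float, float]:
    """(dV_half_Na shift in mV, Na_in in mM) at time ``t_s`` seconds."""
    if t_s < sched.onset:
        return 0.0, sched.na_baseline
    u = t_s - sched.onset
    dv = sched.dv_amplitude * _logistic(u, sched.dv_midpoint, sched.dv_steepness)
    na = sched.na_baseline + sched.na_amplitude * _logistic(
        u, sched.na_midpoint, sched.na_steepness)
    return float(dv), float(na)


def hypoxia_env_schedule(sched: HypoxiaSchedule, env0: IonEnvironment):
    """Engine schedule (t in ms -> IonEnvironment) for a hypoxia run."""

    def schedule(t_ms: float) -> IonEnvironment:
        dv, na = hypoxia_environment(t_ms / 1000.0, sched)
        return replace(env0, dV_half_Na=env0.dV_half_Na + dv, Na_in=na)

    return schedule


# ---------------------------------------------------------------------------
# Development, temperature
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DevelopmentScaling:
    """Developmental scaling of conductance densities.

    ``s`` multiplies every voltage-gated conductance except g_NaP, which is
    co-scaled by ``1 + m * (s - 1)`` so that all co-scaling ratios coincide
    at the control point ``s = 1``.  Leak and tonic drive are untouched.
    """

    s: float = 1.0
    m: float = 0.0

    def __post_init__(self):
        if self.s <= 0:
            raise ValueError("scaling factor must be positive")
        if self.m < 0:
            raise ValueError("g_NaP co-scaling ratio must be nonnegative")


def development_scale(network: NetworkRealization, d: DevelopmentScaling
                      ) -> NetworkRealization:
    """Apply developmental conductance scaling to a network realization."""
    out = network.copy()
    out.template = replace(
        network.template,
        g_Na=network.template.g_Na * d.s,
        g_K=network.template.g_K * d.s,
        g_Ca=network.template.g_Ca * d.s,
    )
    out.g_SPK = network.g_SPK * d.s
    out.g_AHP = network.g_AHP * d.s
    f_nap = 1.0 + d.m * (d.s - 1.0)
    if f_nap < 0:
        f_nap = 0.0  # co-scaling cannot make a conductance negative
    out.g_NaP = network.g_NaP * f_nap
    return out


def temperature_scaling(T: float, T_ref: float = 27.0, Q10: float = 1.5,
                        C_ref: float = 36.0) -> tuple[float, float]:
    """(tau scale, capacitance in pF) at temperature ``T`` (deg C).

    Every gating, synaptic-decay and depression-recovery time constant is
    multiplied by ``Q10 ** (-(T - T_ref) / 10)``; capacitance grows 0.3% per
    degree.
    """
    if Q10 <= 0:
        raise ValueError("Q10 must be positive")
    return Q10 ** (-(T - T_ref) / 10.0), C_ref * 1.003 ** (T - T_ref)


# ---------------------------------------------------------------------------
# Coupled-network rhythm range
# ---------------------------------------------------------------------------

def rhythmic_gtonic_range(
    network: NetworkRealization,
    env: IonEnvironment,
    g_tonic_values,
    cfg: SimulationConfig,
    dyn: SynapseDynamics | None = None,
    min_peaks: int = 5,
):
    """Closed interval of tonic drives where the coupled network is rhythmic.

    Simulates the coupled network at each drive, applies rhythm detection to
    the population-rate histogram of the post-transient window, and returns
    ``(lo, hi, table)`` where the bounds are the lowest/highest rhythmic grid
    points (None when no point is rhythmic) and ``table`` lists
    ``(g_tonic, RhythmMetrics)`` pairs.
    """
    values = np.asarray(g_tonic_values, float)
    table = []
    rhythmic = []
    for gt in values:
        rec = integrate(network, env, cfg, g_tonic=float(gt), dyn=dyn, coupled=True)
        t, rate = population_rate(
            rec.spike_times[rec.spike_times >= cfg.transient],
            network.n, (cfg.transient, cfg.duration))
        m = rhythm_metrics(t, rate, min_peaks=min_peaks)
        table.append((float(gt), m))
        rhythmic.append(m.is_rhythmic)
    rhythmic = np.asarray(rhythmic)
    if not np.any(rhythmic):
        return None, None, table
    idx = np.flatnonzero(rhythmic)
    return float(values[idx[0]]), float(values[idx[-1]]), table
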