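"""Fixed-step forward-Euler integration of single neurons, uncoupled batches,
and the synaptically coupled network.

The integrator advances every state variable with an explicit first-order
Euler step at a fixed dt (0.025 ms by default).  Integration proceeds in
short chunks (50 ms) between which time-varying environments (hypoxia
schedules, bath-potassium or temperature ramps) are re-evaluated and
event-triggered clamps (used for phase-specific manipulations of I_NaP and
the synapses) are applied.  Spikes are logged at the first step where the
membrane potential crosses -35 mV from below, with a 1 ms lockout against
numerical double-crossings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from . import _kernels, biophysics
from .biophysics import IonEnvironment, NeuronParameters, rate_tables

__all__ = [
    "SimulationConfig",
    "ClampEvent",
    "SimulationRecord",
    "integrate",
    "simulate_neurons",
    "detect_burst_initiation",
]

#: Default Q10 for gating rate constants and reference temperature (deg C).
Q10_DEFAULT = 1.5
T_REF = 27.0


def thermal_factors(env: IonEnvironment, C_ref: float, q10: float = Q10_DEFAULT):
    """(tau_scale, capacitance) at the environment's temperature.

    Every gating/synaptic time constant is multiplied by
    ``q10 ** (-(T - T_ref) / 10)`` and the capacitance grows by 0.3% per
    degree C above the reference.
    """
    dT = env.temperature - T_REF
    tau_scale = q10 ** (-dT / 10.0)
    C = C_ref * 1.003 ** dT
    return tau_scale, C


@dataclass
class SimulationConfig:
    """Integration settings.

    ``transient`` marks the initial window (ms) that analysis discards; the
    engine simulates it like any other period.  ``record_stride`` > 0 stores
    mean-field traces (and the membrane potential of ``record_v`` neurons)
    every that many steps; 0 disables trace recording.
    """

    duration: float            # ms
    dt: float = 0.025          # ms
    transient: float = 10_000.0  # ms
    record_stride: int = 0
    chunk: float = 50.0        # ms; schedule/clamp evaluation granularity
    q10: float = Q10_DEFAULT

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.duration < 0:
            raise ValueError("duration must be nonnegative")
        if self.transient > self.duration and self.duration > 0:
            raise ValueError("transient must not exceed duration")


@dataclass
class ClampEvent:
    """Event-triggered state clamp.

    ``trigger`` is ``("time", t_ms)`` or ``("burst_initiation",)``; the latter
    fires at the peak of the network-mean I_NaP inactivation recovery
    (h_NaP) during an inter-burst interval, once at least one population
    burst has completed.  ``action`` is one of ``disable-synapses``,
    ``freeze-m_NaP-in-nonspiked``, ``freeze-h_NaP``, ``freeze-depression``,
    ``freeze-h_NaP-and-depression``.  ``scope`` optionally restricts the
    clamp to a neuron-index subset (default: network-wide).
    """

    trigger: tuple
    action: str
    scope: Sequence[int] | None = None
    rate_threshold: float = 10.0  # Hz; population-burst detection level
    arm_after: float = 0.0        # ms; ignore burst-initiation triggers before

    _ACTIONS = (
        "disable-synapses",
        "freeze-m_NaP-in-nonspiked",
        "freeze-h_NaP",
        "freeze-depression",
        "freeze-h_NaP-and-depression",
    )

    def __post_init__(self):
        if self.action not in self._ACTIONS:
            raise ValueError(f"unknown clamp action {self.action!r}")
        kind = self.trigger[0]
        if kind not in ("time", "burst_initiation"):
            raise ValueError(f"unknown trigger {kind!r}")


@dataclass
class SimulationRecord:
    """Spike times, optional trajectories, and the event log of one run."""

    n: int
    dt: float
    duration: float
    transient: float
    spike_times: np.ndarray          # ms, time-ordered
    spike_ids: np.ndarray
    t_rec: np.ndarray | None = None  # ms, trace sample times
    traces: dict = field(default_factory=dict)
    events: list = field(default_factory=list)

    def spikes_of(self, i: int) -> np.ndarray:
        return self.spike_times[self.spike_ids == i]

    def spike_trains(self) -> list[np.ndarray]:
        order = np.argsort(self.spike_ids, kind="stable")
        ids = self.spike_ids[order]
        ts = self.spike_times[order]
        bounds = np.searchsorted(ids, np.arange(self.n + 1))
        return [ts[bounds[i]:bounds[i + 1]] for i in range(self.n)]

    def raster_frame(self):
        import pandas as pd

        return pd.DataFrame({"neuron_id": self.spike_ids, "time_ms": self.spike_times})

    def save_raster(self, path):
        self.raster_frame().to_csv(path, sep="\t", index=False)


class NonFiniteStateError(RuntimeError):
    """Raised when integration produces a non-finite state variable."""


def _env_key(env: IonEnvironment):
    return (env.Na_in, env.Na_out, env.K_in, env.K_bath, env.P_Na, env.P_K,
            env.temperature, env.dV_half_Na, env.E_syn, env.E_Ca)


def _as_array(val, n):
    arr = np.asarray(val, dtype=np.float64)
    if arr.ndim == 0:
        arr = np.full(n, float(arr))
    if arr.shape != (n,):
        raise ValueError(f"expected scalar or length-{n} array")
    return np.ascontiguousarray(arr)


_EMPTY_I64 = np.zeros(0, dtype=np.int64)
_EMPTY_F64 = np.zeros(0, dtype=np.float64)


def integrate(
    network,
    env: IonEnvironment,
    cfg: SimulationConfig,
    *,
    g_tonic=0.0,
    dyn=None,
    clamps: Sequence[ClampEvent] = (),
    schedule: Callable[[float], IonEnvironment] | None = None,
    coupled: bool | None = None,
    record_v=None,
    initial_v: float = -60.0,
) -> SimulationRecord:
    """Integrate a network realization (or uncoupled population).

    ``network`` provides per-neuron conductances and, when coupled, the
    connectivity and weight matrices (see :class:`prebotc.network.
    NetworkRealization`).  ``schedule`` maps time (ms) to an
    :class:`IonEnvironment`, re-evaluated every ``cfg.chunk`` ms; when it
    changes ``K_bath``, each neuron's leak conductance is rescaled by the
    ratio of distribution means so the sampled heterogeneity is preserved.
    """
    from .network import SynapseDynamics, mu_leak

    n = network.n
    if coupled is None:
        coupled = network.weights is not None and np.any(network.weights)
    dyn = dyn if dyn is not None else SynapseDynamics()

    template = network.template
    arrays = {
        "gNa": _as_array(network.g_Na, n),
        "gK": _as_array(network.g_K, n),
        "gSPK": _as_array(network.g_SPK, n),
        "gAHP": _as_array(network.g_AHP, n),
        "gNaP": _as_array(network.g_NaP, n),
        "gCa": _as_array(network.g_Ca, n),
        "gLeak": _as_array(network.g_Leak, n),
        "gTonic": _as_array(g_tonic, n),
    }
    g_leak_base = arrays["gLeak"].copy()

    if coupled:
        indptr, indices, weights = network.csr()
    else:
        indptr = np.zeros(n + 1, dtype=np.int64)
        indices, weights = _EMPTY_I64, _EMPTY_F64

    env_now = schedule(0.0) if schedule is not None else env
    # leak conductances were sampled at the network's reference K_bath; when
    # the running environment uses a different bath potassium, each neuron's
    # g_Leak is rescaled by the ratio of distribution means
    k_ref = getattr(network, "K_bath_ref", env.K_bath) or env.K_bath

    # state
    init = biophysics.steady_state_gates(template, env_now, initial_v)
    V = np.full(n, initial_v)
    G = np.tile(init.gates(), (n, 1))
    D = np.full(n, dyn.D0)
    syn = np.zeros(n)
    last_spike = np.full(n, -1e9)
    fr_mNaP = np.zeros(n, dtype=np.uint8)
    fr_hNaP = np.zeros(n, dtype=np.uint8)
    fr_D = np.zeros(n, dtype=np.uint8)
    syn_on = bool(coupled)

    dt = cfg.dt
    n_steps_total = int(round(cfg.duration / dt))
    steps_per_chunk = max(1, int(round(cfg.chunk / dt)))

    # recording buffers
    stride = int(cfg.record_stride)
    if stride > 0:
        if record_v is None:
            rec_idx = np.arange(0, dtype=np.int64)
        elif record_v is True:
            rec_idx = np.arange(n, dtype=np.int64)
        else:
            rec_idx = np.asarray(record_v, dtype=np.int64)
        n_rec_max = n_steps_total // stride + 2
        recV = np.empty((n_rec_max, rec_idx.size))
        rec_mean = np.empty((n_rec_max, 4))
    else:
        rec_idx = np.arange(0, dtype=np.int64)
        recV = np.empty((0, 0))
        rec_mean = np.empty((0, 4))

    cap = int(n * max(cfg.duration, 1.0) / 1000.0 * 50) + 4096
    sp_t = np.empty(cap)
    sp_i = np.empty(cap, dtype=np.int64)
    sp_n = 0
    rec_n = 0

    events: list = []
    pending = list(clamps)
    # online population-burst bookkeeping for burst-initiation triggers
    watch_bursts = any(c.trigger[0] == "burst_initiation" for c in pending)
    h_means: list[float] = []
    in_burst = False
    bursts_done = 0
    last_burst_end: float | None = None
    rate_thresh = min((c.rate_threshold for c in pending
                       if c.trigger[0] == "burst_initiation"), default=10.0)

    def apply_clamp(ev: ClampEvent, t_ms: float):
        nonlocal syn_on
        scope = (np.asarray(ev.scope, dtype=np.int64)
                 if ev.scope is not None else np.arange(n, dtype=np.int64))
        if ev.action == "disable-synapses":
            syn_on = False
            syn[:] = 0.0
        elif ev.action == "freeze-m_NaP-in-nonspiked":
            t_ref = last_burst_end if last_burst_end is not None else 0.0
            quiet = last_spike < t_ref
            sel = scope[quiet[scope]]
            fr_mNaP[sel] = 1
        elif ev.action == "freeze-h_NaP":
            fr_hNaP[scope] = 1
        elif ev.action == "freeze-depression":
            fr_D[scope] = 1
        elif ev.action == "freeze-h_NaP-and-depression":
            fr_hNaP[scope] = 1
            fr_D[scope] = 1
        events.append({"time_ms": t_ms, "event": "clamp", "action": ev.action,
                       "n_affected": int(scope.size)})

    tab = None
    key_prev = None
    step = 0
    while step < n_steps_total:
        t_ms = step * dt
        if schedule is not None:
            env_now = schedule(t_ms)
        key = _env_key(env_now)
        if key != key_prev:
            tau_scale, C_now = thermal_factors(env_now, template.C, cfg.q10)
            tab = rate_tables(template, env_now, dt, tau_scale)
            E_Na, E_K, E_Leak = biophysics.reversal_potentials(env_now)
            syn_decay = math.exp(-dt / (dyn.tau_syn * tau_scale))
            d_rate = dt / (dyn.tau_D * tau_scale)
            if env_now.K_bath != k_ref:
                arrays["gLeak"][:] = g_leak_base * (mu_leak(env_now.K_bath) / mu_leak(k_ref))
            else:
                arrays["gLeak"][:] = g_leak_base
            if key_prev is not None:
                events.append({"time_ms": t_ms, "event": "environment",
                               "K_bath": env_now.K_bath, "Na_in": env_now.Na_in,
                               "temperature": env_now.temperature,
                               "dV_half_Na": env_now.dV_half_Na})
            key_prev = key

        # time-triggered clamps due in this chunk
        chunk_end_t = min((step + steps_per_chunk) * dt, cfg.duration)
        for ev in list(pending):
            if ev.trigger[0] == "time" and ev.trigger[1] <= t_ms + 1e-9:
                apply_clamp(ev, t_ms)
                pending.remove(ev)

        n_steps = min(steps_per_chunk, n_steps_total - step)
        sp_before = sp_n
        done = 0
        while done < n_steps:
            sp_n, rec_n, status, did = _kernels.run_chunk(
                V, G, D, syn,
                arrays["gNa"], arrays["gK"], arrays["gSPK"], arrays["gAHP"],
                arrays["gNaP"], arrays["gCa"], arrays["gLeak"], arrays["gTonic"],
                tab,
                C_now, E_Na, E_K, E_Leak, env_now.E_Ca, env_now.E_syn,
                dt, n_steps - done, step + done,
                coupled, syn_on,
                indptr, indices, weights,
                syn_decay, d_rate, dyn.D0, dyn.alpha_D,
                fr_mNaP, fr_hNaP, fr_D,
                last_spike, sp_t, sp_i, sp_n,
                stride, rec_idx, recV, rec_mean, rec_n,
            )
            done += did
            if status == 1:  # spike buffer nearly full: double and resume
                sp_t = np.concatenate([sp_t, np.empty(sp_t.size)])
                sp_i = np.concatenate([sp_i, np.empty(sp_i.size, dtype=np.int64)])

        if not np.all(np.isfinite(V)):
            bad = int(np.flatnonzero(~np.isfinite(V))[0])
            raise NonFiniteStateError(
                f"non-finite membrane potential at t≈{chunk_end_t:.3f} ms, "
                f"neuron {bad}, variable V")

        step += n_steps

        if watch_bursts:
            # chunk-resolution population rate (Hz per neuron) and smoothed
            # mean h_NaP for the burst-initiation detector
            chunk_rate = (sp_n - sp_before) / n / (n_steps * dt / 1000.0)
            h_means.append(float(G[:, 7].mean()))
            if in_burst and chunk_rate < rate_thresh:
                in_burst = False
                bursts_done += 1
                last_burst_end = step * dt
            elif not in_burst and chunk_rate >= rate_thresh:
                in_burst = True
            # the smoothed mean h_NaP peaks at the moment the next burst
            # begins (inactivation overtakes recovery), so the sign change
            # itself is the trigger; it is armed only after one completed
            # population burst
            if bursts_done >= 1 and len(h_means) >= 3:
                h2, h1, h0 = h_means[-3], h_means[-2], h_means[-1]
                if h1 >= h2 and h0 < h1:
                    t_trig = step * dt
                    for ev in list(pending):
                        if (ev.trigger[0] == "burst_initiation"
                                and t_trig >= ev.arm_after):
                            apply_clamp(ev, t_trig)
                            pending.remove(ev)
                    if not any(c.trigger[0] == "burst_initiation" for c in pending):
                        watch_bursts = False

    for ev in pending:
        if ev.trigger[0] == "burst_initiation":
            events.append({"time_ms": cfg.duration, "event": "clamp-not-triggered",
                           "action": ev.action})

    order = np.argsort(sp_t[:sp_n], kind="stable")
    rec = SimulationRecord(
        n=n, dt=dt, duration=cfg.duration, transient=cfg.transient,
        spike_times=sp_t[:sp_n][order], spike_ids=sp_i[:sp_n][order],
        events=events,
    )
    if stride > 0:
        rec.t_rec = np.arange(rec_n) * stride * dt
        rec.traces = {
            "mean_V": rec_mean[:rec_n, 0].copy(),
            "mean_h_NaP": rec_mean[:rec_n, 1].copy(),
            "mean_D": rec_mean[:rec_n, 2].copy(),
            "mean_g_syn": rec_mean[:rec_n, 3].copy(),
        }
        if rec_idx.size:
            rec.traces["V"] = recV[:rec_n].copy()
            rec.traces["V_neurons"] = rec_idx.copy()
    return rec


def simulate_neurons(
    params: NeuronParameters | Sequence[NeuronParameters],
    env: IonEnvironment,
    cfg: SimulationConfig,
    g_tonic=0.0,
    *,
    record_v=None,
    schedule=None,
    initial_v: float = -60.0,
) -> SimulationRecord:
    """Integrate one or more *uncoupled* neurons.

    ``params`` may be a single parameter set (broadcast over an array of
    tonic drives, giving an excitability sweep) or a sequence of parameter
    sets sharing kinetics and capacitance.  Returns a
    :class:`SimulationRecord` whose neuron index matches the batch order.
    """
    from .network import uncoupled_realization

    if isinstance(params, NeuronParameters):
        g_tonic = np.atleast_1d(np.asarray(g_tonic, dtype=float))
        net = uncoupled_realization([params] * g_tonic.size)
    else:
        params = list(params)
        net = uncoupled_realization(params)
        g_tonic = _as_array(g_tonic, len(params))
    return integrate(net, env, cfg, g_tonic=g_tonic, coupled=False,
                     record_v=record_v, schedule=schedule, initial_v=initial_v)


def detect_burst_initiation(t_ms: np.ndarray, mean_h: np.ndarray,
                            smooth_ms: float = 50.0) -> float | None:
    """Time of the first interior peak of the (smoothed) network-mean h_NaP.

    Burst initiation is defined as the peak of I_NaP recovery from
    inactivation.  Returns None when the trace has no interior local maximum
    (e.g. monotonic input).
    """
    t_ms = np.asarray(t_ms, float)
    mean_h = np.asarray(mean_h, float)
    if t_ms.size < 3:
        return None
    dt = t_ms[1] - t_ms[0]
    w = max(1, int(round(smooth_ms / dt)))
    if w > 1:
        kernel = np.ones(w) / w
        sm = np.convolve(np.pad(mean_h, w, mode="edge"), kernel, mode="same")[w:-w]
    else:
        sm = mean_h
    d = np.diff(sm)
    # ignore the smoothing-length margins at both ends
    a, b = w, max(w, d.size - 1 - w)
    sign_change = np.flatnonzero((d[a:b - 1] > 0) & (d[a + 1:b] <= 0))
    if sign_change.size == 0:
        return None
    return float(t_ms[sign_change[0] + a + 1])
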