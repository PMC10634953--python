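"""Population sampling, random connectivity, and depressing synapses.

The model network is a sparse, purely excitatory population.  Cellular
heterogeneity enters through the persistent-sodium and leak conductances,
drawn from a bivariate normal distribution: g_NaP ~ N(mu_NaP, sigma_NaP) and,
conditionally, g_Leak | g_NaP ~ N(mu* , sigma*) with

    mu*    = mu_Leak + rho * (sigma_Leak / sigma_NaP) * (g_NaP - mu_NaP)
    sigma* = sqrt(1 - rho^2) * sigma_Leak

where the leak mean is tied to the bath potassium concentration through
mu_Leak = exp((K_bath - 3.425) / 4.05) and sigma_Leak = 0.05 * mu_Leak.
Connections are independent Bernoulli draws (no self-connections) with
uniformly distributed weights; transmission is instantaneous, exponentially
decaying, and scaled by the presynaptic short-term depression variable D,
which recovers toward D0 with time constant tau_D and drops by a fraction
alpha_D at each presynaptic spike.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .biophysics import IonEnvironment, NeuronParameters

__all__ = [
    "NetworkSpec",
    "SynapseDynamics",
    "NetworkRealization",
    "mu_leak",
    "sample_population",
    "sample_connectome",
    "build_network",
    "uncoupled_realization",
    "depression_step",
    "depression_fixed_point",
    "synaptic_conductance_step",
]


def mu_leak(k_bath: float) -> float:
    """Mean leak conductance (nS) implied by the bath potassium (mM)."""
    return math.exp((k_bath - 3.425) / 4.05)


def _dist_spec(d):
    """Normalize a conductance distribution spec: scalar or ('uniform', lo, hi)."""
    if np.isscalar(d):
        return ("const", float(d))
    kind, *args = d
    if kind != "uniform" or len(args) != 2:
        raise ValueError(f"unsupported distribution spec {d!r}")
    lo, hi = map(float, args)
    if hi < lo:
        raise ValueError("uniform range must have hi >= lo")
    return ("uniform", lo, hi)


@dataclass(frozen=True)
class NetworkSpec:
    """Construction parameters of a network realization."""

    N: int = 100
    p_syn: float = 0.13
    W_max: float = 0.2        # nS
    mu_NaP: float = 3.33      # nS
    sigma_NaP: float = 0.75   # nS
    rho: float = 0.8
    sigma_leak_frac: float = 0.05
    g_SPK_dist: object = 0.0  # scalar nS or ("uniform", lo, hi)
    g_AHP_dist: object = 0.0
    seed: int | None = None

    def __post_init__(self):
        if not 0 <= self.p_syn <= 1:
            raise ValueError("p_syn must lie in [0, 1]")
        if self.W_max < 0:
            raise ValueError("W_max must be nonnegative")
        if self.sigma_NaP <= 0:
            raise ValueError("sigma_NaP must be positive")
        if not abs(self.rho) < 1:
            raise ValueError("|rho| must be < 1")
        if self.N < 1:
            raise ValueError("N must be at least 1")
        _dist_spec(self.g_SPK_dist)
        _dist_spec(self.g_AHP_dist)


@dataclass(frozen=True)
class SynapseDynamics:
    """Exponential synapse with mean-field short-term depression."""

    tau_syn: float = 5.0    # ms
    D0: float = 1.0
    tau_D: float = 1000.0   # ms
    alpha_D: float = 0.2

    def __post_init__(self):
        if self.tau_syn <= 0 or self.tau_D <= 0:
            raise ValueError("time constants must be positive")
        if not 0 <= self.alpha_D <= 1:
            raise ValueError("alpha_D must lie in [0, 1]")


@dataclass
class NetworkRealization:
    """Sampled per-neuron parameters plus connectivity of one network."""

    template: NeuronParameters
    g_NaP: np.ndarray
    g_Leak: np.ndarray
    g_SPK: np.ndarray
    g_AHP: np.ndarray
    connectivity: np.ndarray | None = None  # (N, N) uint8, zero diagonal
    weights: np.ndarray | None = None       # (N, N) nS, row = presynaptic
    seed: int | None = None
    K_bath_ref: float = 8.5

    # homogeneous conductances (scalars broadcast by the engine) ------------
    @property
    def g_Na(self):
        return self.template.g_Na

    @property
    def g_K(self):
        return self.template.g_K

    @property
    def g_Ca(self):
        return self.template.g_Ca

    @property
    def n(self) -> int:
        return int(np.asarray(self.g_NaP).size)

    def __post_init__(self):
        for name in ("g_NaP", "g_Leak", "g_SPK", "g_AHP"):
            arr = np.ascontiguousarray(np.asarray(getattr(self, name), dtype=float))
            if np.any(arr < 0):
                raise ValueError(f"{name} contains negative conductances")
            setattr(self, name, arr)
        if self.connectivity is not None:
            c = np.asarray(self.connectivity)
            if c.shape != (self.n, self.n):
                raise ValueError("connectivity must be N x N")
            if np.any(np.diag(c) != 0):
                raise ValueError("self-connections are not allowed")

    def neuron(self, i: int) -> NeuronParameters:
        return replace(self.template, g_NaP=float(self.g_NaP[i]),
                       g_Leak=float(self.g_Leak[i]), g_SPK=float(self.g_SPK[i]),
                       g_AHP=float(self.g_AHP[i]))

    def csr(self):
        """Outgoing-adjacency CSR view (indptr, indices, weights) of W."""
        if self.connectivity is None:
            indptr = np.zeros(self.n + 1, dtype=np.int64)
            return indptr, np.zeros(0, dtype=np.int64), np.zeros(0)
        mask = self.connectivity.astype(bool)
        counts = mask.sum(axis=1)
        indptr = np.zeros(self.n + 1, dtype=np.int64)
        np.cumsum(counts, out=indptr[1:])
        indices = np.flatnonzero(mask.ravel()) % self.n
        w = self.weights[mask]
        return indptr, indices.astype(np.int64), np.ascontiguousarray(w, dtype=float)

    def copy(self) -> "NetworkRealization":
        return NetworkRealization(
            template=self.template,
            g_NaP=self.g_NaP.copy(), g_Leak=self.g_Leak.copy(),
            g_SPK=self.g_SPK.copy(), g_AHP=self.g_AHP.copy(),
            connectivity=None if self.connectivity is None else self.connectivity.copy(),
            weights=None if self.weights is None else self.weights.copy(),
            seed=self.seed, K_bath_ref=self.K_bath_ref,
        )

    # ------------------------------------------------------------------ io
    def neuron_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "neuron_id": np.arange(self.n),
            "g_NaP": self.g_NaP, "g_Leak": self.g_Leak,
            "g_SPK": self.g_SPK, "g_AHP": self.g_AHP,
        })

    def edge_table(self) -> pd.DataFrame:
        if self.connectivity is None:
            return pd.DataFrame(columns=["pre", "post", "weight"])
        pre, post = np.nonzero(self.connectivity)
        return pd.DataFrame({"pre": pre, "post": post,
                             "weight": self.weights[pre, post]})

    def save(self, neurons_path, edges_path):
        self.neuron_table().to_csv(neurons_path, sep="\t", index=False)
        self.edge_table().to_csv(edges_path, sep="\t", index=False)

    @classmethod
    def load(cls, neurons_path, edges_path, template: NeuronParameters = NeuronParameters(),
             K_bath_ref: float = 8.5) -> "NetworkRealization":
        nt = pd.read_csv(neurons_path, sep="\t")
        et = pd.read_csv(edges_path, sep="\t")
        n = len(nt)
        conn = np.zeros((n, n), dtype=np.uint8)
        w = np.zeros((n, n))
        if len(et):
            conn[et["pre"], et["post"]] = 1
            w[et["pre"], et["post"]] = et["weight"]
        return cls(template=template,
                   g_NaP=nt["g_NaP"].to_numpy(), g_Leak=nt["g_Leak"].to_numpy(),
                   g_SPK=nt["g_SPK"].to_numpy(), g_AHP=nt["g_AHP"].to_numpy(),
                   connectivity=conn, weights=w, K_bath_ref=K_bath_ref)


def _truncated_normal(rng, mean, sd, size=None):
    """Normal draws with negative values resampled (conductances are >= 0)."""
    out = rng.normal(mean, sd, size=size)
    bad = out < 0
    while np.any(bad):
        out = np.where(bad, rng.normal(mean, sd, size=np.shape(out)), out)
        bad = out < 0
    return out


def sample_population(spec: NetworkSpec, env: IonEnvironment,
                      rng: np.random.Generator | None = None,
                      template: NeuronParameters = NeuronParameters()):
    """Draw per-neuron conductances (g_NaP, g_Leak, g_SPK, g_AHP).

    g_Leak is drawn from its conditional distribution given g_NaP so the pair
    is bivariate normal with correlation ``spec.rho``; the leak mean follows
    the bath potassium of ``env``.  Negative draws are resampled.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    mu_l = mu_leak(env.K_bath)
    sigma_l = spec.sigma_leak_frac * mu_l
    g_nap = _truncated_normal(rng, spec.mu_NaP, spec.sigma_NaP, spec.N)
    cond_mean = mu_l + spec.rho * (sigma_l / spec.sigma_NaP) * (g_nap - spec.mu_NaP)
    cond_sd = math.sqrt(1.0 - spec.rho ** 2) * sigma_l
    g_leak = _truncated_normal(rng, cond_mean, cond_sd)

    def draw(dist):
        d = _dist_spec(dist)
        if d[0] == "const":
            return np.full(spec.N, d[1])
        return rng.uniform(d[1], d[2], spec.N)

    return g_nap, g_leak, draw(spec.g_SPK_dist), draw(spec.g_AHP_dist)


def sample_connectome(spec: NetworkSpec, rng: np.random.Generator | None = None):
    """Bernoulli connectivity (zero diagonal) with U(0, W_max) weights."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    conn = (rng.random((spec.N, spec.N)) < spec.p_syn).astype(np.uint8)
    np.fill_diagonal(conn, 0)
    weights = np.where(conn, rng.uniform(0.0, spec.W_max, (spec.N, spec.N)), 0.0)
    return conn, weights


def build_network(spec: NetworkSpec, env: IonEnvironment | None = None,
                  template: NeuronParameters = NeuronParameters(),
                  seed: int | None = None) -> NetworkRealization:
    """Sample a full network realization.

    Randomness flows from one seed through named substreams (population,
    connectome) so realizations are bitwise reproducible.
    """
    env = env if env is not None else IonEnvironment()
    seed = seed if seed is not None else spec.seed
    ss = np.random.SeedSequence(seed)
    pop_rng, conn_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    g_nap, g_leak, g_spk, g_ahp = sample_population(spec, env, pop_rng, template)
    conn, w = sample_connectome(spec, conn_rng)
    return NetworkRealization(template=template, g_NaP=g_nap, g_Leak=g_leak,
                              g_SPK=g_spk, g_AHP=g_ahp, connectivity=conn,
                              weights=w, seed=seed, K_bath_ref=env.K_bath)


def uncoupled_realization(params: Sequence[NeuronParameters]) -> NetworkRealization:
    """Wrap a list of parameter sets (shared kinetics) as an uncoupled batch."""
    params = list(params)
    t = params[0]
    return NetworkRealization(
        template=t,
        g_NaP=np.array([p.g_NaP for p in params]),
        g_Leak=np.array([p.g_Leak for p in params]),
        g_SPK=np.array([p.g_SPK for p in params]),
        g_AHP=np.array([p.g_AHP for p in params]),
    )


# ---------------------------------------------------------------------------
# Reference synapse updates (the integration kernel is checked against these)
# ---------------------------------------------------------------------------

def depression_step(D, spiked, dt: float, dyn: SynapseDynamics = SynapseDynamics()):
    """One Euler step of the depression variable; multiplicative drop on spikes."""
    D = np.asarray(D, dtype=float)
    out = D + dt * (dyn.D0 - D) / dyn.tau_D
    out = np.minimum(out, dyn.D0)
    return np.where(spiked, out * (1.0 - dyn.alpha_D), out)


def depression_fixed_point(T: float, dyn: SynapseDynamics = SynapseDynamics()) -> float:
    """Steady-state D reached just before each spike under periodic firing.

    For spikes every ``T`` ms, the per-cycle map D -> (1 - alpha_D) * D
    relaxed toward D0 for time T has fixed point
    ``D* = D0 (1 - e^(-T/tau_D)) / (1 - (1 - alpha_D) e^(-T/tau_D))``.
    """
    e = math.exp(-T / dyn.tau_D)
    return dyn.D0 * (1.0 - e) / (1.0 - (1.0 - dyn.alpha_D) * e)


def synaptic_conductance_step(drive, spiked, D, weights, connectivity, dt: float,
                              dyn: SynapseDynamics = SynapseDynamics()):
    """Advance the per-neuron aggregated synaptic drive by one step.

    The drive decays exponentially with tau_syn; every presynaptic spike adds
    ``W[j, i] * D[j]`` to each target ``i`` instantaneously (zero transmission
    delay).  Equivalent to summing per-event exponentials with one shared
    decay constant.
    """
    drive = np.asarray(drive, dtype=float) * math.exp(-dt / dyn.tau_syn)
    spiked = np.asarray(spiked, dtype=bool)
    if np.any(spiked):
        w_eff = (np.asarray(weights) * np.asarray(connectivity)).T  # post x pre
        drive = drive + w_eff[:, spiked] @ np.asarray(D, dtype=float)[spiked]
    return drive
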