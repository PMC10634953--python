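import math

import numpy as np
import pytest

from prebotc.biophysics import IonEnvironment, NeuronParameters
from prebotc.network import (
    NetworkRealization,
    NetworkSpec,
    SynapseDynamics,
    build_network,
    depression_fixed_point,
    depression_step,
    mu_leak,
    sample_connectome,
    sample_population,
    synaptic_conductance_step,
    uncoupled_realization,
)


class TestPopulationSampling:
    def test_leak_mean_from_bath_potassium(self):
        assert mu_leak(8.5) == pytest.approx(math.exp((8.5 - 3.425) / 4.05), rel=1e-12)
        assert mu_leak(8.5) == pytest.approx(3.501, abs=0.001)

    def test_gnap_moments(self, env):
        spec = NetworkSpec(N=20000, seed=0)
        g_nap, _, _, _ = sample_population(spec, env, np.random.default_rng(0))
        assert g_nap.mean() == pytest.approx(3.33, abs=3 * 0.75 / math.sqrt(20000))
        assert g_nap.std() == pytest.approx(0.75, rel=0.03)

    def test_correlation_matches_rho(self, env):
        spec = NetworkSpec(N=10000, seed=1)
        g_nap, g_leak, _, _ = sample_population(spec, env, np.random.default_rng(1))
        r = np.corrcoef(g_nap, g_leak)[0, 1]
        assert r == pytest.approx(0.8, abs=0.02)

    def test_rho_zero_decouples(self, env):
        spec = NetworkSpec(N=10000, rho=1e-12, seed=2)
        g_nap, g_leak, _, _ = sample_population(spec, env, np.random.default_rng(2))
        assert abs(np.corrcoef(g_nap, g_leak)[0, 1]) < 0.03
        assert g_leak.mean() == pytest.approx(mu_leak(8.5), rel=0.01)

    def test_conditional_sd_shrinks_by_sqrt(self, env):
        # residual sd after regressing g_Leak on g_NaP is sqrt(1-rho^2)*sigma
        spec = NetworkSpec(N=20000, rho=0.8, seed=3)
        g_nap, g_leak, _, _ = sample_population(spec, env, np.random.default_rng(3))
        slope = np.polyfit(g_nap, g_leak, 1)[0]
        resid = g_leak - slope * g_nap
        sigma_leak = 0.05 * mu_leak(8.5)
        assert resid.std() == pytest.approx(0.6 * sigma_leak, rel=0.05)

    def test_nonnegative_and_distributed_spike_conductances(self, env):
        spec = NetworkSpec(N=5000, g_SPK_dist=("uniform", 0.0, 12.0), seed=4)
        g_nap, g_leak, g_spk, _ = sample_population(spec, env, np.random.default_rng(4))
        assert (g_nap >= 0).all() and (g_leak >= 0).all()
        assert 0 <= g_spk.min() and g_spk.max() <= 12
        assert g_spk.mean() == pytest.approx(6.0, abs=0.2)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            NetworkSpec(p_syn=1.5)
        with pytest.raises(ValueError):
            NetworkSpec(rho=1.0)
        with pytest.raises(ValueError):
            NetworkSpec(g_SPK_dist=("gaussian", 0, 1))


class TestConnectome:
    def test_empty_at_zero_probability(self):
        conn, w = sample_connectome(NetworkSpec(N=20, p_syn=0.0, seed=0))
        assert conn.sum() == 0 and w.sum() == 0

    def test_complete_digraph_minus_diagonal(self):
        conn, _ = sample_connectome(NetworkSpec(N=3, p_syn=1.0, seed=0))
        assert conn.sum() == 6
        assert np.all(np.diag(conn) == 0)

    def test_edge_count_binomial(self):
        counts = [sample_connectome(NetworkSpec(N=100, p_syn=0.13, seed=s))[0].sum()
                  for s in range(5)]
        mean, sd = 9900 * 0.13, math.sqrt(9900 * 0.13 * 0.87)
        assert abs(np.mean(counts) - mean) < 3 * sd / math.sqrt(5)

    def test_weights_uniform_within_bounds(self):
        conn, w = sample_connectome(NetworkSpec(N=100, p_syn=0.5, W_max=0.2, seed=1))
        vals = w[conn.astype(bool)]
        assert 0 <= vals.min() and vals.max() <= 0.2
        assert vals.mean() == pytest.approx(0.1, abs=0.01)


class TestDepression:
    def test_single_spike_fractional_drop(self):
        assert depression_step(1.0, True, 0.025) == pytest.approx(0.8, abs=1e-4)

    def test_recovery_toward_ceiling(self):
        d = 0.5
        for _ in range(400):  # 400 * 10 ms = 4 s >> tau_D
            d = depression_step(d, False, 10.0)
        assert d == pytest.approx(1.0, abs=0.02)

    @pytest.mark.parametrize("period", [50.0, 200.0, 1000.0])
    def test_periodic_fixed_point_formula(self, period):
        # simulate the per-cycle map and compare with the closed form
        dyn = SynapseDynamics()
        dt = 0.1
        steps = int(round(period / dt))
        d = 1.0
        for _ in range(200):
            for k in range(steps):
                d = float(depression_step(d, k == steps - 1, dt, dyn))
        # d is post-spike; the formula gives the pre-spike steady state
        pre_spike = d / (1 - dyn.alpha_D)
        assert pre_spike == pytest.approx(depression_fixed_point(period, dyn), rel=5e-3)


class TestSynapticDrive:
    def test_efolding_decay(self):
        drive = np.array([1.0])
        for _ in range(5):
            drive = synaptic_conductance_step(drive, [False], [1.0],
                                              np.zeros((1, 1)), np.zeros((1, 1)), 1.0)
        assert drive[0] == pytest.approx(math.exp(-1.0), rel=1e-9)

    def test_spike_increment_weighted_by_depression(self):
        w = np.array([[0.0, 0.2], [0.0, 0.0]])
        c = np.array([[0, 1], [0, 0]])
        drive = synaptic_conductance_step(np.zeros(2), [True, False], [0.5, 1.0],
                                          w, c, 0.025)
        assert drive[1] == pytest.approx(0.2 * 0.5, rel=1e-6)
        assert drive[0] == 0.0

    def test_simultaneous_spikes_superpose(self):
        w = np.full((3, 3), 0.1)
        c = np.ones((3, 3), dtype=int)
        np.fill_diagonal(c, 0)
        drive = synaptic_conductance_step(np.zeros(3), [True, True, False],
                                          np.ones(3), w, c, 0.025)
        assert drive[2] == pytest.approx(0.2, rel=1e-6)


class TestRealization:
    def test_seed_determinism_bitwise(self, env):
        a = build_network(NetworkSpec(N=50), env, seed=123)
        b = build_network(NetworkSpec(N=50), env, seed=123)
        for attr in ("g_NaP", "g_Leak", "g_SPK", "g_AHP", "weights"):
            assert np.array_equal(getattr(a, attr), getattr(b, attr))
        assert np.array_equal(a.connectivity, b.connectivity)

    def test_different_seeds_differ(self, env):
        a = build_network(NetworkSpec(N=50), env, seed=1)
        b = build_network(NetworkSpec(N=50), env, seed=2)
        assert not np.array_equal(a.g_NaP, b.g_NaP)

    def test_no_self_connections(self, tiny_network):
        assert np.all(np.diag(tiny_network.connectivity) == 0)

    def test_csr_round_trip(self, tiny_network):
        indptr, indices, weights = tiny_network.csr()
        dense = np.zeros((tiny_network.n, tiny_network.n))
        for j in range(tiny_network.n):
            for e in range(indptr[j], indptr[j + 1]):
                dense[j, indices[e]] = weights[e]
        assert np.allclose(dense, tiny_network.weights * tiny_network.connectivity)

    def test_table_serialization_round_trip(self, tiny_network, tmp_path):
        tiny_network.save(tmp_path / "n.tsv", tmp_path / "e.tsv")
        back = NetworkRealization.load(tmp_path / "n.tsv", tmp_path / "e.tsv")
        assert np.allclose(back.g_NaP, tiny_network.g_NaP)
        assert np.allclose(back.weights, tiny_network.weights)
        assert np.array_equal(back.connectivity, tiny_network.connectivity)

    def test_neuron_accessor(self, tiny_network):
        p = tiny_network.neuron(3)
        assert isinstance(p, NeuronParameters)
        assert p.g_NaP == tiny_network.g_NaP[3]

    def test_uncoupled_wrapper(self):
        net = uncoupled_realization([NeuronParameters(), NeuronParameters(g_NaP=1.0)])
        assert net.n == 2
        assert net.weights is None
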