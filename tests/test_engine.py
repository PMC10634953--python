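import numpy as np
import pytest

from prebotc.analysis import classify_activity
from prebotc.biophysics import IonEnvironment, NeuronParameters
from prebotc.engine import (
    ClampEvent,
    NonFiniteStateError,
    SimulationConfig,
    detect_burst_initiation,
    integrate,
    simulate_neurons,
    thermal_factors,
)


class TestBasics:
    def test_zero_duration_empty_record(self, canonical, env):
        cfg = SimulationConfig(duration=0.0, transient=0.0)
        rec = simulate_neurons(canonical, env, cfg, g_tonic=0.5)
        assert rec.spike_times.size == 0

    def test_determinism(self, tiny_network, env):
        cfg = SimulationConfig(duration=3000.0, transient=0.0)
        a = integrate(tiny_network, env, cfg, g_tonic=0.4)
        b = integrate(tiny_network, env, cfg, g_tonic=0.4)
        assert np.array_equal(a.spike_times, b.spike_times)
        assert np.array_equal(a.spike_ids, b.spike_ids)

    def test_nonfinite_input_aborts_with_diagnostic(self, canonical, env):
        cfg = SimulationConfig(duration=200.0, transient=0.0)
        with pytest.raises(NonFiniteStateError, match="neuron"):
            simulate_neurons(canonical, env, cfg, g_tonic=float("nan"))

    def test_spike_refractory_lockout(self, canonical, env):
        cfg = SimulationConfig(duration=5000.0, transient=0.0)
        rec = simulate_neurons(canonical, env, cfg, g_tonic=1.0)
        assert np.all(np.diff(rec.spikes_of(0)) >= 1.0)

    def test_gates_stay_bounded(self, env):
        # drive hard; recorded trajectories must stay physical
        cfg = SimulationConfig(duration=2000.0, transient=0.0, record_stride=40)
        rec = simulate_neurons(NeuronParameters(g_SPK=20, g_AHP=20), env, cfg,
                               g_tonic=2.5, record_v=True)
        h = rec.traces["mean_h_NaP"]
        assert np.all((h >= 0) & (h <= 1))
        assert np.all(np.isfinite(rec.traces["V"]))


class TestKernelAgainstReference:
    def test_trajectory_matches_closed_form_euler(self, env):
        """The table-driven kernel reproduces a pure-Python sequential Euler
        integration built directly from the closed-form kinetics."""
        from prebotc.biophysics import (
            rectifier_activation,
            reversal_potentials,
            steady_state,
            steady_state_gates,
            time_constant,
        )

        p = NeuronParameters(g_Tonic=0.0)
        dt, n_steps = 0.025, 400
        g_tonic = 0.6
        e_na, e_k, e_leak = reversal_potentials(env)

        s = steady_state_gates(p, env, -55.0)
        v = -55.0
        gates = {n: getattr(s, n) for n in
                 ("m_Na", "h_Na", "m_K", "m_SPK", "h_SPK", "m_AHP",
                  "m_NaP", "h_NaP")}
        kins = {"m_Na": p.na_m, "h_Na": p.na_h, "m_SPK": p.spk_m,
                "h_SPK": p.spk_h, "m_AHP": p.ahp_m, "m_NaP": p.nap_m,
                "h_NaP": p.nap_h}
        vs_ref = []
        for _ in range(n_steps):
            for name, kin in kins.items():
                inf = float(steady_state(kin, v))
                tau = float(time_constant(kin, v))
                gates[name] = np.clip(gates[name] + dt / tau * (inf - gates[name]), 0, 1)
            m_inf, tau_k = rectifier_activation(p.k_rect, v)
            gates["m_K"] = np.clip(
                gates["m_K"] + dt / float(tau_k) * (float(m_inf) - gates["m_K"]), 0, 1)
            i_total = (
                p.g_Na * gates["m_Na"] ** 3 * gates["h_Na"] * (v - e_na)
                + p.g_K * gates["m_K"] ** 4 * (v - e_k)
                + p.g_SPK * gates["m_SPK"] * gates["h_SPK"] * (v - e_na)
                + p.g_AHP * gates["m_AHP"] * (v - e_k)
                + p.g_NaP * gates["m_NaP"] * gates["h_NaP"] * (v - e_na)
                + p.g_Leak * (v - e_leak)
                + g_tonic * (v - env.E_syn)
            )
            v = v + dt * (-i_total / p.C)
            vs_ref.append(v)

        cfg = SimulationConfig(duration=n_steps * dt, transient=0.0, record_stride=1)
        rec = simulate_neurons(p, env, cfg, g_tonic=g_tonic, record_v=True,
                               initial_v=-55.0)
        v_kernel = rec.traces["V"][1:, 0]  # first sample is the initial state
        np.testing.assert_allclose(v_kernel, vs_ref[:v_kernel.size], atol=5e-3)


class TestModes:
    def test_canonical_silent_bursting_tonic(self, canonical, env):
        # excitability sweep of the average intrinsic burster
        cfg = SimulationConfig(duration=26_000.0, transient=6_000.0)
        rec = simulate_neurons(canonical, env, cfg, g_tonic=np.array([0.05, 0.25, 0.8]))
        window = (cfg.transient, cfg.duration)
        labels = [classify_activity(rec.spikes_of(i), window).value for i in range(3)]
        assert labels == ["silent", "bursting", "tonic"]


class TestCoupling:
    def test_zero_weight_network_identical_to_uncoupled(self, tiny_network, env):
        cfg = SimulationConfig(duration=4000.0, transient=0.0)
        zeroed = tiny_network.copy()
        zeroed.weights = np.zeros_like(zeroed.weights)
        coupled = integrate(zeroed, env, cfg, g_tonic=0.4, coupled=True)
        uncoupled = integrate(tiny_network, env, cfg, g_tonic=0.4, coupled=False)
        assert np.array_equal(coupled.spike_times, uncoupled.spike_times)
        assert np.array_equal(coupled.spike_ids, uncoupled.spike_ids)

    def test_coupling_changes_activity(self, tiny_network, env):
        cfg = SimulationConfig(duration=4000.0, transient=0.0)
        a = integrate(tiny_network, env, cfg, g_tonic=0.4, coupled=True)
        b = integrate(tiny_network, env, cfg, g_tonic=0.4, coupled=False)
        assert a.spike_times.size != b.spike_times.size

    def test_dt_halving_spike_count_stable(self, canonical, env):
        counts = {}
        for dt in (0.025, 0.0125):
            cfg = SimulationConfig(duration=10_000.0, transient=0.0, dt=dt)
            rec = simulate_neurons(canonical, env, cfg, g_tonic=0.6)
            counts[dt] = rec.spike_times.size
        assert counts[0.0125] == pytest.approx(counts[0.025], rel=0.02)


class TestClamps:
    def test_time_triggered_freeze_holds_value(self, tiny_network, env):
        cfg = SimulationConfig(duration=3000.0, transient=0.0, record_stride=40)
        ev = ClampEvent(trigger=("time", 1500.0), action="freeze-h_NaP")
        rec = integrate(tiny_network, env, cfg, g_tonic=0.4, clamps=[ev])
        h = rec.traces["mean_h_NaP"]
        t = rec.t_rec
        after = h[t >= 1600.0]
        assert np.allclose(after, after[0], atol=1e-12)
        assert any(e.get("action") == "freeze-h_NaP" for e in rec.events)

    def test_disable_synapses_zeroes_drive(self, tiny_network, env):
        cfg = SimulationConfig(duration=3000.0, transient=0.0, record_stride=40)
        ev = ClampEvent(trigger=("time", 1500.0), action="disable-synapses")
        rec = integrate(tiny_network, env, cfg, g_tonic=0.4, clamps=[ev])
        g = rec.traces["mean_g_syn"]
        assert np.all(g[rec.t_rec >= 1600.0] == 0.0)

    def test_empty_clamp_list_is_noop(self, tiny_network, env):
        cfg = SimulationConfig(duration=2000.0, transient=0.0)
        a = integrate(tiny_network, env, cfg, g_tonic=0.4)
        b = integrate(tiny_network, env, cfg, g_tonic=0.4, clamps=[])
        assert np.array_equal(a.spike_times, b.spike_times)

    def test_unknown_action_rejected(self):
        with pytest.raises(ValueError):
            ClampEvent(trigger=("time", 0.0), action="freeze-everything")


class TestBurstInitiationDetector:
    def test_monotone_trace_no_trigger(self):
        t = np.arange(0, 5000.0, 10.0)
        assert detect_burst_initiation(t, np.linspace(0.2, 0.8, t.size)) is None

    def test_triangle_peak_located(self):
        t = np.arange(0, 4000.0, 10.0)
        h = np.concatenate([np.linspace(0.2, 0.9, 200), np.linspace(0.9, 0.2, 200)])
        trig = detect_burst_initiation(t, h, smooth_ms=50.0)
        assert trig == pytest.approx(2000.0, abs=60.0)


class TestThermalFactors:
    def test_reference_temperature_neutral(self):
        scale, c = thermal_factors(IonEnvironment(temperature=27.0), 36.0)
        assert scale == 1.0 and c == 36.0

    def test_q10_at_37(self):
        scale, c = thermal_factors(IonEnvironment(temperature=37.0), 36.0)
        assert scale == pytest.approx(1 / 1.5, rel=1e-12)
        assert c == pytest.approx(36.0 * 1.003 ** 10, rel=1e-12)


class TestRecordExport:
    def test_raster_export(self, tiny_network, env, tmp_path):
        cfg = SimulationConfig(duration=2000.0, transient=0.0)
        rec = integrate(tiny_network, env, cfg, g_tonic=0.5)
        path = tmp_path / "raster.tsv"
        rec.save_raster(path)
        import pandas as pd

        back = pd.read_csv(path, sep="\t")
        assert list(back.columns) == ["neuron_id", "time_ms"]
        assert len(back) == rec.spike_times.size

    def test_spike_trains_partition(self, tiny_network, env):
        cfg = SimulationConfig(duration=2000.0, transient=0.0)
        rec = integrate(tiny_network, env, cfg, g_tonic=0.5)
        trains = rec.spike_trains()
        assert sum(t.size for t in trains) == rec.spike_times.size
        for t in trains:
            assert np.all(np.diff(t) > 0)
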