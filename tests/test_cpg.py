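import numpy as np
import pytest

from fogsim.cpg import (
    CPGNetwork,
    PoolSpec,
    TeachParams,
    count_extrema,
    free_run,
    generate_teach_signals,
    hopf_derivatives,
    instantaneous_phase,
    step_rate,
    train_cpg,
)
from fogsim.fixtures import sinusoid_teach, toy_cpg


class TestTeachSignals:
    def test_hip_has_three_extrema_per_closed_cycle(self):
        teach = generate_teach_signals()
        assert count_extrema(teach.closed(0)) == 3

    def test_cycle_is_one_second_of_500_samples(self):
        teach = generate_teach_signals()
        assert teach.T == 500 and teach.dt == pytest.approx(1 / 500)

    def test_zero_amplitudes_give_silence(self):
        teach = generate_teach_signals(params=TeachParams(hip_amp=0.0, knee_amp=0.0))
        assert not np.any(teach.hip) and not np.any(teach.knee1) and not np.any(teach.knee2)

    def test_knees_vanish_at_hip_extrema(self):
        teach = generate_teach_signals()
        hip = teach.closed(0)
        d = np.diff(hip)
        ext = [0] + list(np.where(np.sign(d[1:]) * np.sign(d[:-1]) < 0)[0] + 1)
        peak = np.abs(teach.knee1).max()
        for i in ext:
            assert abs(teach.knee1[i % teach.T]) < 0.05 * peak
            assert abs(teach.knee2[i % teach.T]) < 0.05 * peak

    def test_too_short_cycle_rejected(self):
        with pytest.raises(ValueError):
            generate_teach_signals(T=50)


class TestInstantaneousPhase:
    def test_convention(self):
        assert instantaneous_phase(1e-12, -1.0) == pytest.approx(0.0)
        assert instantaneous_phase(1.0, 0.0) == pytest.approx(np.pi / 2)
        assert instantaneous_phase(-1.0, 0.0) == pytest.approx(-np.pi / 2)

    def test_zero_amplitude_is_an_error(self):
        with pytest.raises(ValueError):
            instantaneous_phase(0.0, 0.0)

    def test_range(self, rng):
        p, q = rng.normal(size=100), rng.normal(size=100)
        th = instantaneous_phase(p, q)
        assert np.all(th >= -np.pi) and np.all(th <= np.pi)


class TestHopfDynamics:
    def _single(self):
        pool = PoolSpec(1, xi=8.0, mu=1.0, eps=0.9, tau=0.0, omega_init=(2 * np.pi,))
        return CPGNetwork(pools=(pool,))

    def test_limit_cycle_is_stationary_in_amplitude(self):
        net = self._single()
        net.p[:] = 1.0
        net.q[:] = 0.0  # z = sqrt(mu) = 1
        d = hopf_derivatives(net)
        # dz/dt = (p dp + q dq)/z = 0 on the limit cycle
        dz = (net.p * d["dp"] + net.q * d["dq"]) / np.hypot(net.p, net.q)
        assert abs(dz[0]) < 1e-12

    def test_no_adaptation_without_forcing(self):
        net = self._single()
        d = hopf_derivatives(net, teach=None)
        assert np.all(d["domega"] == 0.0) and np.all(d["dalpha"] == 0.0)

    def test_amplitude_relaxes_at_rate_set_by_xi(self):
        # linearized decay of a radial perturbation: dz/dt = -2 xi z^2 dz
        net = self._single()
        eps0 = 0.01
        net.p[:] = 1.0 + eps0
        net.q[:] = 0.0
        for _ in range(25):  # 50 ms
            net.rk4_step(None)
        z = float(np.hypot(net.p, net.q)[0])
        expected = 1.0 + eps0 * np.exp(-2 * 8.0 * 25 * net.dt)
        assert z == pytest.approx(expected, abs=2e-4)

    def test_free_running_amplitude_converges_to_sqrt_mu(self):
        net = self._single()
        net.p[:] = 0.3
        net.q[:] = 0.1
        _, Q = free_run(net, 3, mutate=True)
        z = float(np.hypot(net.p, net.q)[0])
        assert z == pytest.approx(1.0, abs=1e-3)


class TestTraining:
    def test_adaptive_oscillator_locks_to_sinusoid_frequency(self):
        # start detuned by 25%; the forcing error pulls omega onto the teach
        net = toy_cpg(freq_hz=1.0, omega_init_hz=1.25, max_cycles=120)
        assert np.allclose(net.omega, 2 * np.pi, rtol=0.01)

    def test_output_weight_learns_sinusoid_amplitude(self):
        net = toy_cpg(freq_hz=1.0, amp=0.5, max_cycles=300, tolerance=0.01)
        assert np.allclose(net.alpha, 0.5, atol=0.02)

    def test_nonconvergence_signals(self):
        net = CPGNetwork()
        with pytest.raises(RuntimeError):
            train_cpg(net, generate_teach_signals(), max_cycles=2,
                      tolerance=1e-6, raise_on_failure=True)

    def test_trained_network_reproduces_teach_cycle(self, trained_network):
        teach = generate_teach_signals()
        _, Q = free_run(trained_network, 1)
        rms_hip = np.sqrt(np.mean((Q[0] - teach.hip) ** 2))
        assert rms_hip < 0.05
        for j in (1, 2):
            rms = np.sqrt(np.mean((Q[j] - teach.pool(j)) ** 2))
            assert rms < 0.12

    def test_free_run_step_rate_is_two_per_second(self, trained_network):
        _, Q = free_run(trained_network, 5)
        assert step_rate(Q[0], trained_network.dt) == pytest.approx(2.0, abs=0.02)

    def test_output_scales_linearly_with_alpha(self, trained_network):
        _, Q1 = free_run(trained_network, 1)
        alpha0 = trained_network.alpha.copy()
        trained_network.alpha = 2.0 * alpha0
        try:
            _, Q2 = free_run(trained_network, 1)
        finally:
            trained_network.alpha = alpha0
        assert np.allclose(Q2, 2.0 * Q1, atol=1e-9)

    def test_intra_pool_phase_offsets_hold_during_free_run(self, trained_network):
        snap = trained_network.snapshot()
        T = int(round(1.0 / trained_network.dt))
        psis = np.empty((T, trained_network.n_osc))
        for k in range(T):
            psis[k] = trained_network.psi
            trained_network.rk4_step(None)
        trained_network.restore(snap)
        nonref = trained_network.osc_in_pool != 0
        drift = psis[:, nonref].max(axis=0) - psis[:, nonref].min(axis=0)
        assert np.all(drift < 0.2)

    def test_inter_pool_relation_stays_locked_across_cycles(self, trained_network):
        # the hip and knee reference oscillators run at different
        # fundamentals, so the recorded inter-pool lag psi_G oscillates
        # within a cycle; locking means the oscillation is bounded and the
        # cycle-to-cycle shift stays small against the 2*pi phase scale
        snap = trained_network.snapshot()
        T = int(round(1.0 / trained_network.dt))
        psg = np.empty((T + 1, trained_network.n_pools))
        for k in range(T + 1):
            psg[k] = trained_network.psi_g
            trained_network.rk4_step(None)
        trained_network.restore(snap)
        swing = psg[:T, 1:].max(axis=0) - psg[:T, 1:].min(axis=0)
        assert np.all(swing < np.pi / 2)
        assert np.all(np.abs(psg[T, 1:] - psg[0, 1:]) < 0.2)

    def test_save_load_roundtrip(self, trained_network, tmp_path):
        path = tmp_path / "net.json"
        trained_network.save(path)
        clone = CPGNetwork.load(path)
        assert np.array_equal(clone.alpha, trained_network.alpha)
        assert np.array_equal(clone.omega, trained_network.omega)
        _, Qa = free_run(trained_network, 1)
        _, Qb = free_run(clone, 1)
        assert np.allclose(Qa, Qb)


class TestFixtures:
    def test_sinusoid_teach_shape(self):
        t = sinusoid_teach(freq_hz=2.0, amp=0.3)
        assert t.T == 500 and np.max(np.abs(t.hip)) == pytest.approx(0.3)
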