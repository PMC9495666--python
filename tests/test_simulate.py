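"""Generator checks: OU noise law, oscillator physics, fGn statistics, markers."""

import numpy as np
import pytest

from adiagait.cycles import detect_steps, invariant_table, segment_cycles
from adiagait.errors import ParameterError
from adiagait.kinematics import com_from_markers
from adiagait.si_metrics import hurst_dfa
from adiagait.simulate import (
    OscillatorConfig,
    StrideGenConfig,
    fgn_davies_harte,
    fgn_spectral,
    generate_fgn_strides,
    ou_noise,
    simulate_oscillator,
    synthesize_markers,
)

CYCLE_FREQ = 0.85  # Hz, base oscillator frequency of the default model


def _osc(n_cycles, eps, seed, dt=1.0 / 300.0, tau=12.0):
    # one gait cycle = two oscillator periods (peak-to-alternate-peak)
    duration = 2.0 * n_cycles / CYCLE_FREQ + 5.0
    return OscillatorConfig(
        omega0=2 * np.pi * CYCLE_FREQ, epsilon=eps, tau=tau,
        amplitude0=0.02, duration=duration, dt=dt, seed=seed,
    )


def _per_cycle_actions(cfg):
    q, p = simulate_oscillator(cfg)
    table = invariant_table(q, p, segment_cycles(detect_steps(q)))
    return table.table["ekbar_jkg"].to_numpy() / (np.pi * table.table["f_hz"].to_numpy())


class TestOUNoise:
    def test_autocorrelation_matches_closed_form(self):
        x = ou_noise(100_000, dt=0.01, tau=1.0, seed=1)
        lag = 100
        acf = np.corrcoef(x[:-lag], x[lag:])[0, 1]
        assert acf == pytest.approx(np.exp(-1.0), abs=0.05)

    def test_stationary_unit_variance(self):
        x = ou_noise(200_000, dt=0.05, tau=2.0, seed=2)
        assert np.mean(x) == pytest.approx(0.0, abs=0.02)
        assert np.std(x) == pytest.approx(1.0, abs=0.02)

    def test_single_draw_and_determinism(self):
        assert ou_noise(1, 0.01, 1.0, seed=3).shape == (1,)
        a = ou_noise(1000, 0.01, 1.0, seed=4)
        b = ou_noise(1000, 0.01, 1.0, seed=4)
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize("bad", [{"tau": -1.0}, {"dt": 0.0}, {"n": 0}])
    def test_invalid_parameters(self, bad):
        kwargs = {"n": 100, "dt": 0.01, "tau": 1.0} | bad
        with pytest.raises(ParameterError):
            ou_noise(kwargs["n"], kwargs["dt"], kwargs["tau"])


class TestOscillator:
    def test_noise_free_solution_is_exact_harmonic(self):
        cfg = OscillatorConfig(omega0=2 * np.pi, epsilon=0.0, amplitude0=0.02,
                               duration=10.0, dt=1 / 1200, seed=0)
        q, _ = simulate_oscillator(cfg)
        assert np.max(np.abs(q.values - 0.02 * np.cos(2 * np.pi * q.times))) < 1e-4

    def test_noise_free_energy_conservation_rk4(self):
        cfg = OscillatorConfig(omega0=2 * np.pi, epsilon=0.0, amplitude0=0.02,
                               duration=100.0, dt=1 / 1200, seed=0)
        q, p = simulate_oscillator(cfg)
        energy = 0.5 * p.values**2 + 0.5 * cfg.omega0**2 * q.values**2
        drift = (energy.max() - energy.min()) / energy.mean()
        assert drift < 1e-6

    def test_leapfrog_energy_bounded_no_secular_drift(self):
        # symplectic scheme: energy error oscillates at O((w dt)^2) but
        # shows no secular drift over the run
        cfg = OscillatorConfig(omega0=2 * np.pi, epsilon=0.0, amplitude0=0.02,
                               duration=100.0, dt=1 / 1200, seed=0,
                               integrator="leapfrog")
        q, p = simulate_oscillator(cfg)
        energy = 0.5 * p.values**2 + 0.5 * cfg.omega0**2 * q.values**2
        assert (energy.max() - energy.min()) / energy.mean() < 1e-4
        head = energy[: len(energy) // 10].mean()
        tail = energy[-len(energy) // 10:].mean()
        assert abs(tail - head) / energy.mean() < 1e-7

    def test_noise_free_action_identical_across_cycles(self):
        cfg = _osc(30, eps=0.0, seed=0, dt=1 / 1200)
        actions = _per_cycle_actions(cfg)
        assert np.ptp(actions) / np.mean(actions) < 1e-3

    def test_action_drift_small_and_monotone_in_epsilon(self):
        # adiabatic invariance: relative action spread grows with epsilon
        rel_sd = []
        for eps in (0.01, 0.03, 0.05):
            actions = _per_cycle_actions(_osc(200, eps=eps, seed=7))
            rel_sd.append(np.std(actions) / np.mean(actions))
        assert rel_sd[0] < rel_sd[1] < rel_sd[2]
        for eps, sd in zip((0.01, 0.03, 0.05), rel_sd):
            assert sd <= 5.0 * eps + 0.02

    def test_action_spread_at_study_conditions(self):
        # eps=0.03, tau=12 s, 500 cycles: empirically frozen bound
        actions = _per_cycle_actions(_osc(500, eps=0.03, seed=42, dt=1 / 600))
        assert np.std(actions) / np.mean(actions) <= 0.15

    def test_seed_determinism(self):
        cfg = _osc(20, eps=0.03, seed=5)
        q1, p1 = simulate_oscillator(cfg)
        q2, p2 = simulate_oscillator(cfg)
        np.testing.assert_array_equal(q1.values, q2.values)
        np.testing.assert_array_equal(p1.values, p2.values)

    def test_per_cycle_noise_mode_runs(self):
        cfg = OscillatorConfig(epsilon=0.03, duration=60.0, dt=1 / 300,
                               seed=1, noise_mode="per_cycle")
        q, _ = simulate_oscillator(cfg)
        assert np.isfinite(q.values).all()

    @pytest.mark.parametrize(
        "bad",
        [{"epsilon": -0.1}, {"tau": 0.0}, {"dt": 0.2}, {"duration": 1.0},
         {"noise_mode": "white"}, {"integrator": "euler"}],
    )
    def test_invalid_config(self, bad):
        with pytest.raises(ParameterError):
            OscillatorConfig(**bad)


class TestFgnStrides:
    def test_h_half_is_uncorrelated(self):
        s = generate_fgn_strides(StrideGenConfig(n_strides=1024, hurst_target=0.5,
                                                 seed=11))
        x = s.strides
        lag1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert abs(lag1) < 0.1

    def test_zero_cv_gives_constant_series(self):
        s = generate_fgn_strides(StrideGenConfig(n_strides=64, cv_target=0.0,
                                                 mean_si=1.18, seed=0))
        np.testing.assert_array_equal(s.strides, np.full(64, 1.18))

    def test_mean_and_cv_are_exact(self):
        cfg = StrideGenConfig(n_strides=512, hurst_target=0.8, mean_si=1.18,
                              cv_target=0.026, seed=3)
        s = generate_fgn_strides(cfg)
        assert np.mean(s.strides) == pytest.approx(1.18, rel=1e-12)
        assert np.std(s.strides, ddof=1) / np.mean(s.strides) == pytest.approx(
            0.026, rel=1e-9)

    def test_dfa_recovers_generator_hurst(self):
        ests = [
            hurst_dfa(generate_fgn_strides(
                StrideGenConfig(n_strides=512, hurst_target=0.8, seed=2000 + i)))
            for i in range(50)
        ]
        assert 0.7 <= np.mean(ests) <= 0.9

    def test_davies_harte_agrees_with_spectral_generator(self):
        # two independent fGn constructions give the same DFA scaling
        est_dh = np.mean([
            hurst_dfa(fgn_davies_harte(512, 0.8, np.random.default_rng(300 + i)))
            for i in range(30)
        ])
        est_sp = np.mean([
            hurst_dfa(fgn_spectral(512, 0.8, np.random.default_rng(400 + i)))
            for i in range(30)
        ])
        assert est_dh == pytest.approx(est_sp, abs=0.1)

    def test_davies_harte_matches_target_autocovariance(self):
        # lag-1 autocorrelation of fGn: 2^(2H-1) - 1
        h = 0.8
        acfs = []
        for i in range(40):
            x = fgn_davies_harte(1024, h, np.random.default_rng(500 + i))
            acfs.append(np.corrcoef(x[:-1], x[1:])[0, 1])
        assert np.mean(acfs) == pytest.approx(2 ** (2 * h - 1) - 1, abs=0.05)

    def test_excessive_cv_rejected(self):
        with pytest.raises(ParameterError):
            generate_fgn_strides(StrideGenConfig(n_strides=64, cv_target=0.5))

    @pytest.mark.parametrize("bad", [{"n_strides": 10}, {"hurst_target": 1.2},
                                     {"cv_target": -0.1}])
    def test_invalid_config(self, bad):
        with pytest.raises(ParameterError):
            StrideGenConfig(**bad)


class TestMarkers:
    @pytest.fixture
    def q_signal(self):
        cfg = OscillatorConfig(omega0=2 * np.pi, epsilon=0.0, amplitude0=0.02,
                               duration=10.0, dt=1 / 1200, seed=0)
        return simulate_oscillator(cfg)[0]

    def test_sample_count(self, q_signal):
        markers = synthesize_markers(q_signal, rate_out=120.0, marker_noise_sd=0.0)
        assert len(markers) == 1200

    def test_noiseless_round_trip(self, q_signal):
        markers = synthesize_markers(q_signal, rate_out=120.0, marker_noise_sd=0.0)
        com = com_from_markers(markers)
        ref = np.interp(com.times, q_signal.times, q_signal.values)
        assert np.max(np.abs(com.values - ref)) < 1e-6

    def test_noise_averaging(self, q_signal):
        # 4-marker mean reduces i.i.d. noise by sqrt(4); allow resampling slack
        markers = synthesize_markers(q_signal, rate_out=120.0, marker_noise_sd=0.5,
                                     seed=9)
        com = com_from_markers(markers)
        ref = 0.02 * np.cos(2 * np.pi * com.times)
        rms_mm = 1000.0 * np.sqrt(np.mean((com.values - ref) ** 2))
        assert rms_mm <= 0.5 / 2.0 + 0.1

    def test_offsets_must_average_to_zero(self, q_signal):
        with pytest.raises(ParameterError):
            synthesize_markers(q_signal, offsets_mm={
                "RASI": 1.0, "LASI": 1.0, "RPSI": 1.0, "LPSI": 1.0})

    def test_bad_rate_rejected(self, q_signal):
        with pytest.raises(ParameterError):
            synthesize_markers(q_signal, rate_out=0.0)
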