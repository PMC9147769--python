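"""Integration, peak metrics, longevity and steady-state classification."""

import numpy as np
import pytest

from vbdm import (
    ModelParameters,
    Trajectory,
    averaged_metrics,
    classify_steady_state,
    detect_peaks,
    integrate,
    interpeak_interval,
    summarize_run,
    system_longevity,
)
from vbdm.model import closed_rhs


class TestIntegrate:
    def test_decoupled_decay_without_bacteria(self, worked_params):
        """With B=0 the viral pool decays as V_i * exp(-m t) exactly and
        N stays put."""
        p = worked_params.with_(B_i=0.0)
        traj = integrate(p, duration=2000.0, output_step=10.0,
                         rtol=1e-10, atol=1e-14)
        np.testing.assert_allclose(traj.B, 0.0)
        np.testing.assert_allclose(traj.N, p.N_i, rtol=1e-9)
        expected = p.V_i * np.exp(-p.m_decay * traj.t)
        np.testing.assert_allclose(traj.V, expected, rtol=1e-6)

    def test_conserved_combination_without_losses(self, worked_params):
        """With phi=0 and d=0, N + (alpha(1-g)/mu) B is a first integral."""
        p = worked_params.with_(phi=0.0, d_death=0.0, V_i=0.0)
        traj = integrate(p, duration=20_000.0, output_step=20.0)
        c = p.alpha * (1 - p.g_exudate) / p.mu
        invariant = traj.N + c * traj.B
        drift = np.abs(invariant - invariant[0]) / invariant[0]
        assert drift.max() < 1e-4

    def test_bacteria_monotone_without_predation_or_death(self, worked_params):
        p = worked_params.with_(phi=0.0, d_death=0.0, V_i=0.0)
        traj = integrate(p, duration=5000.0, output_step=10.0)
        while_n_positive = traj.N > 1e-6
        b = traj.B[while_n_positive]
        assert np.all(np.diff(b) >= -1e-6 * b[:-1])

    def test_output_step_only_affects_sampling(self, worked_params):
        coarse = integrate(worked_params, 2000.0, output_step=50.0)
        fine = integrate(worked_params, 2000.0, output_step=10.0)
        on_coarse = np.isin(fine.t, coarse.t)
        np.testing.assert_allclose(
            fine.B[on_coarse], coarse.B, rtol=1e-5
        )

    def test_nonnegative_states(self, worked_params):
        traj = integrate(worked_params.with_(beta=250.0), 15_000.0, 5.0)
        assert traj.N.min() >= 0.0
        assert traj.B.min() >= 0.0
        assert traj.V.min() >= 0.0

    def test_qualitative_boom_bust_and_burst_size_effect(self, worked_params):
        """Bacteria rise, viruses follow with delay, the system cycles and
        DOM declines overall; larger burst size sustains more cycles."""
        counts = {}
        for beta in (10.0, 100.0, 250.0):
            traj = integrate(worked_params.with_(beta=beta), 15_000.0, 5.0)
            peaks_b = detect_peaks(traj.B, traj.t)
            peaks_v = detect_peaks(traj.V, traj.t)
            counts[beta] = len(peaks_b)
            assert traj.N[-1] < traj.N[0]
            if len(peaks_b) and len(peaks_v):
                assert peaks_v[0] > peaks_b[0]  # viral peak lags
        assert counts[10.0] <= counts[100.0] <= counts[250.0]
        assert counts[250.0] > 1

    def test_duration_must_be_positive(self, worked_params):
        with pytest.raises(ValueError):
            integrate(worked_params, duration=-5.0)

    def test_fixed_step_rk4_oracle_agrees(self, worked_params):
        """A small-step classical RK4 integration reproduces the adaptive
        solution to < 0.1% relative error over the first 2000 h."""
        p = worked_params.with_(beta=250.0)
        traj = integrate(p, 2000.0, output_step=2.0)
        h = 0.02
        steps_per_sample = int(round(2.0 / h))
        y = np.array([p.N_i, p.B_i, p.V_i])
        rk4 = [y.copy()]
        f = lambda y: closed_rhs(y, p)
        for _ in range(len(traj.t) - 1):
            for _ in range(steps_per_sample):
                k1 = f(y)
                k2 = f(np.clip(y + 0.5 * h * k1, 0, None))
                k3 = f(np.clip(y + 0.5 * h * k2, 0, None))
                k4 = f(np.clip(y + h * k3, 0, None))
                y = y + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
                y = np.clip(y, 0.0, None)
            rk4.append(y.copy())
        rk4 = np.array(rk4).T
        adaptive = np.vstack([traj.N, traj.B, traj.V])
        scale = np.abs(rk4) + 1e-12 * np.abs(rk4).max(axis=1, keepdims=True)
        rel = np.abs(adaptive - rk4) / scale
        assert rel.max() < 1e-3


class TestPeakDetection:
    def test_constant_series_has_no_peaks(self):
        t = np.arange(100.0)
        assert detect_peaks(np.full_like(t, 5.0), t).size == 0

    def test_single_hump(self):
        t = np.arange(0.0, 100.0)
        series = 1e6 * np.exp(-((t - 40.0) ** 2) / 50.0) + 1.0
        peaks = detect_peaks(series, t)
        assert peaks.size == 1
        assert peaks[0] == 40.0

    def test_short_series_empty(self):
        assert detect_peaks(np.array([1.0, 2.0]), np.array([0.0, 1.0])).size == 0

    def test_small_ripples_ignored(self):
        # 1%-amplitude ripple on a large baseline: no factor-10 prominence
        t = np.arange(0.0, 1000.0)
        series = 1e5 * (1.0 + 0.01 * np.sin(t / 10.0))
        assert detect_peaks(series, t).size == 0

    def test_matches_sign_change_scan_on_worked_run(self, worked_params):
        """Detected peaks are a subset of the discrete-derivative sign
        changes, and every huge oscillation is found."""
        traj = integrate(worked_params.with_(beta=250.0), 15_000.0, 5.0)
        peaks = detect_peaks(traj.B, traj.t)
        db = np.diff(traj.B)
        sign_change_times = traj.t[1:-1][(db[:-1] > 0) & (db[1:] <= 0)]
        assert peaks.size > 1
        assert np.diff(peaks).min() > 0
        for pk in peaks:
            assert np.min(np.abs(sign_change_times - pk)) <= 10.0


class TestIntervalAndLongevity:
    def test_mean_spacing(self):
        assert interpeak_interval(np.array([100.0, 200.0, 300.0])) == 100.0

    def test_single_peak_undefined(self):
        assert np.isnan(interpeak_interval(np.array([100.0])))

    def test_longevity_zero_when_never_alive(self, worked_params):
        t = np.arange(0.0, 100.0)
        traj = Trajectory(
            t=t, N=np.zeros_like(t), B=np.full_like(t, 0.5),
            V=np.full_like(t, 1e6), params=worked_params,
        )
        assert system_longevity(traj) == 0.0

    def test_longevity_is_duration_when_always_alive(self, synthetic_trajectory):
        traj = synthetic_trajectory
        assert system_longevity(traj) == traj.duration

    def test_longevity_last_crossing_not_first(self, worked_params):
        """Populations may dip below the floor mid-run and recover."""
        t = np.arange(0.0, 1000.0)
        b = np.full_like(t, 100.0)
        b[200:300] = 0.1          # transient dip
        v = np.full_like(t, 50.0)
        v[t > 800.0] = 0.01       # final collapse
        traj = Trajectory(t=t, N=np.ones_like(t), B=b, V=v, params=worked_params)
        assert system_longevity(traj) == 800.0


class TestSteadyState:
    def test_constant_dom_oscillating_populations(self, synthetic_trajectory):
        steady, drift = classify_steady_state(
            synthetic_trajectory, window=10_000.0
        )
        assert steady
        assert drift == pytest.approx(0.0, abs=1e-12)

    def test_linear_decline_rejected(self, worked_params):
        t = np.arange(0.0, 50_001.0, 50.0)
        n = 30.0 * (1.0 - 0.2 * t / t[-1])  # 20% decline start to end
        traj = Trajectory(
            t=t, N=n, B=np.full_like(t, 1e5), V=np.full_like(t, 1e6),
            params=worked_params,
        )
        steady, drift = classify_steady_state(traj, window=10_000.0)
        assert not steady
        assert drift < -0.10

    def test_extinction_in_final_window_rejected(self, worked_params):
        t = np.arange(0.0, 50_001.0, 50.0)
        b = np.full_like(t, 1e5)
        b[t > 45_000.0] = 0.5  # dies at the end despite steady DOM
        traj = Trajectory(
            t=t, N=np.full_like(t, 30.0), B=b, V=np.full_like(t, 1e6),
            params=worked_params,
        )
        steady, drift = classify_steady_state(traj, window=10_000.0)
        assert not steady
        assert abs(drift) <= 0.10

    def test_window_too_large_is_an_error(self, synthetic_trajectory):
        with pytest.raises(ValueError, match="window"):
            classify_steady_state(synthetic_trajectory, window=30_000.0)


class TestAveragedMetrics:
    def test_constant_ratio(self, worked_params):
        t = np.arange(0.0, 1000.0)
        traj = Trajectory(
            t=t, N=np.ones_like(t), B=np.full_like(t, 1e5),
            V=np.full_like(t, 1e6), params=worked_params,
        )
        avg_vbr, avg_e = averaged_metrics(traj)
        assert avg_vbr == pytest.approx(10.0)
        assert avg_e == 0.0  # closed mode has no elevator flux

    def test_open_average_e_matches_quadrature_of_b(self, worked_params):
        p = worked_params.with_(mode="open", f_elevator=72.416)
        traj = integrate(p, duration=5000.0, output_step=10.0)
        _, avg_e = averaged_metrics(traj)
        coef = p.f_elevator * (p.alpha / p.mu) * p.d_death
        expected = coef * np.trapezoid(traj.B, traj.t) / (traj.t[-1] - traj.t[0])
        assert avg_e == pytest.approx(expected, rel=1e-9)

    def test_undefined_vbr_when_no_bacteria(self, worked_params):
        t = np.arange(0.0, 100.0)
        traj = Trajectory(
            t=t, N=np.ones_like(t), B=np.zeros_like(t),
            V=np.full_like(t, 1e6), params=worked_params,
        )
        avg_vbr, _ = averaged_metrics(traj)
        assert np.isnan(avg_vbr)


class TestSummarizeRun:
    def test_summary_fields_consistent(self, worked_params):
        traj = integrate(worked_params.with_(beta=100.0), 15_000.0, 5.0)
        s = summarize_run(traj)
        assert s.longevity <= traj.duration
        assert len(s.peak_times_B) >= 1
        assert not s.steady_state  # closed run, finite DOM
        assert s.avg_E == 0.0
        assert s.avg_VBR > 0

    def test_json_roundtrip(self, worked_params, tmp_path):
        import json

        traj = integrate(worked_params, 2000.0, 10.0)
        path = tmp_path / "summary.json"
        summarize_run(traj).to_json(path)
        payload = json.loads(path.read_text())
        assert payload["params"]["beta"] == worked_params.beta
        assert "longevity" in payload and "avg_VBR" in payload
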