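"""Event kinetics: detection, widths, decay and rise constants, SNR."""

import numpy as np
import pytest
from scipy.signal import argrelmax

from dopafilm.errors import DataError
from dopafilm.baseline import compute_dff
from dopafilm.kinetics import (
    EventMetrics,
    analyze_trace,
    event_frequency,
    find_events,
    fit_tau_off,
    snr,
    tau_peak,
    tau_quantile_range,
    temporal_fwhm,
)

from conftest import single_site_config, single_site_movie, site_box_trace


def _transient(n, fr, t0, amp, tau_rise=0.15, tau_decay=2.0, noise=0.0, seed=0):
    """Alpha-like transient: (1 - exp(-t/tr)) * exp(-t/td) after onset."""
    t = np.arange(n) / fr
    tr = np.zeros(n)
    after = t >= t0
    dt = t[after] - t0
    tr[after] = amp * (1 - np.exp(-dt / tau_rise)) * np.exp(-dt / tau_decay)
    if noise:
        tr = tr + np.random.default_rng(seed).normal(0, noise, n)
    return tr


class TestFindEvents:
    def test_flat_noise_yields_no_events(self):
        rng = np.random.default_rng(0)
        trace = rng.normal(0, 0.004, 400)
        assert find_events(trace, 10.0, min_prominence=0.02, min_snr=5.0) == []

    def test_single_transient_found_at_peak(self):
        fr = 10.0
        trace = _transient(200, fr, t0=8.0, amp=0.2, noise=0.002)
        events = find_events(trace, fr)
        assert len(events) == 1
        assert events[0].peak_frame == pytest.approx(np.argmax(trace), abs=1)

    def test_two_transients_match_bruteforce_scan(self):
        fr = 20.0
        trace = (
            _transient(300, fr, 3.0, 0.15, tau_decay=0.8, noise=0.002, seed=4)
            + _transient(300, fr, 7.0, 0.2, tau_decay=0.8)
        )
        events = find_events(trace, fr, min_prominence=0.02, min_snr=5.0)
        assert len(events) == 2
        # oracle: exhaustive local-maximum scan with the same prominence rule
        local_max = argrelmax(trace)[0]
        strong = {
            i for i in local_max
            if trace[i] - trace[max(0, i - 40) : i + 40].min() >= 0.02
        }
        assert {e.peak_frame for e in events} <= strong

    def test_short_trace_rejected(self):
        with pytest.raises(DataError):
            find_events(np.zeros(3), 10.0)


class TestTemporalFwhm:
    def test_gaussian_closed_form(self):
        fr = 50.0
        t = np.arange(600) / fr
        trace = 0.2 * np.exp(-((t - 6.0) ** 2) / (2 * 0.5**2))
        p = int(np.argmax(trace))
        ev = EventMetrics(t_peak_s=p / fr, peak_frame=p, amplitude_dff=0.2, snr=np.inf)
        assert temporal_fwhm(trace, ev, fr) == pytest.approx(2.3548 * 0.5, rel=0.02)

    def test_one_sided_exponential(self):
        # instant rise, exp(-t/tau) decay: width = tau * ln 2
        fr = 100.0
        t = np.arange(1200) / fr
        trace = np.where(t >= 3.0, 0.3 * np.exp(-(t - 3.0) / 2.0), 0.0)
        ev = EventMetrics(
            t_peak_s=3.0, peak_frame=300, amplitude_dff=0.3, snr=np.inf
        )
        assert temporal_fwhm(trace, ev, fr) == pytest.approx(2.0 * np.log(2), rel=0.02)

    def test_sampling_invariance(self):
        widths = []
        for fr in (10.0, 20.0):
            n = int(30 * fr)
            trace = _transient(n, fr, 5.0, 0.2, tau_decay=1.5)
            ev = find_events(trace, fr)[0]
            widths.append(temporal_fwhm(trace, ev, fr))
        assert abs(widths[0] - widths[1]) < 1.0 / 10.0

    def test_uncrossed_side_reports_reason(self):
        fr = 10.0
        trace = np.linspace(0, 0.3, 50)  # rises to the end, never decays
        ev = EventMetrics(t_peak_s=4.9, peak_frame=49, amplitude_dff=0.3, snr=10.0)
        assert temporal_fwhm(trace, ev, fr) is None
        assert "fwhm" in ev.reasons


class TestTauOff:
    def test_exact_exponential(self):
        fr = 10.0
        t = np.arange(150) / fr
        trace = 0.25 * np.exp(-t / 2.0)
        ev = EventMetrics(t_peak_s=0.0, peak_frame=0, amplitude_dff=0.25, snr=np.inf)
        assert fit_tau_off(trace, ev, fr) == pytest.approx(2.0, abs=1e-3)

    @pytest.mark.parametrize("snr_level", [10.0, 20.0, 50.0])
    def test_noisy_recovery_bias(self, snr_level):
        # mean over replicates within 10% across SNR levels
        fr, tau = 10.0, 3.83
        taus = []
        for seed in range(12):
            rng = np.random.default_rng(seed)
            t = np.arange(250) / fr
            amp = 0.25
            trace = amp * np.exp(-t / tau) + rng.normal(0, amp / snr_level, len(t))
            ev = EventMetrics(0.0, 0, amp, snr_level)
            fit = fit_tau_off(trace, ev, fr)
            if fit is not None:
                taus.append(fit)
        assert np.mean(taus) == pytest.approx(tau, rel=0.10)

    def test_offset_recovered_by_three_parameter_fit(self):
        fr = 10.0
        t = np.arange(200) / fr
        trace = 0.2 * np.exp(-t / 2.5) + 0.02
        ev = EventMetrics(0.0, 0, 0.2, np.inf)
        assert fit_tau_off(trace, ev, fr) == pytest.approx(2.5, rel=0.05)

    def test_too_short_window_reports_reason(self):
        ev = EventMetrics(0.0, 0, 0.2, np.inf)
        out = fit_tau_off(np.array([0.2, 0.1, 0.05, 0.02]), ev, 10.0)
        assert out is None


class TestTauPeak:
    def test_linear_ramp_onset(self):
        # linear rise over 1 s then flat: curvature peaks at the ramp foot
        fr = 20.0
        t = np.arange(200) / fr
        trace = np.clip((t - 3.0) / 1.0, 0, 1) * 0.2
        ev = EventMetrics(4.0, 80, 0.2, np.inf)
        assert tau_peak(trace, ev, fr) == pytest.approx(1.0, abs=0.2)

    def test_alpha_function_matches_dense_grid_oracle(self):
        fr = 20.0
        tau_r, tau_d = 0.25, 2.5
        t0 = 3.0
        n = int(20 * fr)
        trace = _transient(n, fr, t0, 0.2, tau_r, tau_d)
        ev = find_events(trace, fr)[0]
        got = tau_peak(trace, ev, fr)
        # oracle: second derivative of the continuous model on a dense grid
        tt = np.linspace(0, 20, 40001)
        dt = tt[1] - tt[0]
        model = np.where(
            tt >= t0,
            0.2 * (1 - np.exp(-(tt - t0) / tau_r)) * np.exp(-(tt - t0) / tau_d),
            0.0,
        )
        second = np.gradient(np.gradient(model, dt), dt)
        t_pk = tt[np.argmax(model)]
        pre = (tt < t_pk) & (tt > t_pk - 3.0)
        onset = tt[pre][np.argmax(second[pre])]
        oracle = t_pk - onset
        assert got == pytest.approx(oracle, abs=1.5 / fr)

    def test_rise_time_scale_recovered(self):
        # transient tuned so the dense-grid rise time is ~0.46 s
        fr = 20.0
        trace = _transient(400, fr, 5.0, 0.2, tau_rise=0.16, tau_decay=3.8)
        ev = find_events(trace, fr)[0]
        got = tau_peak(trace, ev, fr)
        assert got == pytest.approx(0.46, rel=0.25)


class TestTauQuantileRange:
    def test_hand_quantiles_one_to_ten(self):
        assert tau_quantile_range(np.arange(1.0, 11.0)) == pytest.approx(7.2)

    def test_degenerate_all_equal(self):
        assert tau_quantile_range(np.full(12, 3.0)) == 0.0

    def test_scale_equivariance(self):
        vals = np.random.default_rng(0).lognormal(1.0, 0.4, 40)
        assert tau_quantile_range(2 * vals) == pytest.approx(
            2 * tau_quantile_range(vals)
        )

    def test_too_few_values(self):
        assert tau_quantile_range([1.0] * 9) is None


class TestSnrAndRates:
    def test_snr_arithmetic(self):
        rng = np.random.default_rng(1)
        base = 100 + rng.normal(0, 2.0, 60)
        trace = np.concatenate([base, [base.mean() + 10.0]])
        got = snr(trace, peak_frame=60, baseline_window=slice(0, 60))
        assert got == pytest.approx(10.0 / base.std(ddof=1), rel=1e-9)

    def test_zero_sd_flagged_infinite(self):
        trace = np.concatenate([np.full(20, 5.0), [6.0]])
        assert snr(trace, 20, slice(0, 20)) == np.inf

    def test_event_frequency(self):
        assert event_frequency(10, 50.0) == pytest.approx(0.2)
        assert event_frequency(0, 50.0) == 0.0
        with pytest.raises(DataError):
            event_frequency(1, 0.0)


class TestSimulatedFixtures:
    def test_evoked_fixture_snr_exceeds_30(self):
        # a 4-quantum evoked response at default camera noise
        cfg = single_site_config(
            duration_s=20.0, shot_noise=True, read_noise_sd=5.0, quantal_cv=0.25,
            Q_quantum=6e4,
        )
        movie, truth = single_site_movie(cfg, [8.0], seed=2)
        x, y, _ = (truth.site_positions_um[0], truth.site_positions_um[0][1], None)
        trace = site_box_trace(movie, truth.site_positions_um[0][0],
                               truth.site_positions_um[0][1])
        peak = int(np.argmax(trace))
        assert snr(trace, peak) > 30

    def test_minis_fixture_snr_exceeds_5(self):
        cfg = single_site_config(
            duration_s=20.0, shot_noise=True, read_noise_sd=5.0, quantal_cv=0.25,
        )
        movie, truth = single_site_movie(cfg, [8.0], seed=3)
        trace = site_box_trace(movie, truth.site_positions_um[0][0],
                               truth.site_positions_um[0][1])
        peak = int(np.argmax(trace))
        assert snr(trace, peak) > 5

    def test_spontaneous_rate_recovered_in_poisson_band(self):
        # one site firing Poisson minis at 0.29 s^-1 for 120 s
        from dopafilm.simcore import ReleaseSchedule, generate_dataset

        cfg = single_site_config(
            duration_s=120.0, shot_noise=True, read_noise_sd=5.0, quantal_cv=0.25,
            Q_quantum=3e4,
        )
        px = cfg.pixel_size_um
        x0 = y0 = 16 * px
        schedule = ReleaseSchedule(sites=[(x0, y0, True)], spont_rate_hz=0.29)
        movie, truth = generate_dataset(cfg, schedule, seed=8)
        base = compute_dff(movie)
        cx, cy = int(round(x0 / px)), int(round(y0 / px))
        trace = base.dFF[:, cy - 2 : cy + 3, cx - 2 : cx + 3].mean(axis=(1, 2))
        summary = analyze_trace(trace, cfg.frame_rate_hz, min_prominence=0.015)
        expected = 0.29 * cfg.duration_s
        band = 1.96 * np.sqrt(expected)
        assert abs(len(summary.events) - expected) <= band

    def test_reduced_clearance_broadens_transients(self):
        # reuptake blockade (lower k_uptake) must widen the trace FWHM
        widths = {}
        for label, k_up in (("control", 25.0), ("blocked", 6.25)):
            cfg = single_site_config(duration_s=25.0, k_uptake_s=k_up, Q_quantum=6e4)
            movie, truth = single_site_movie(cfg, [8.0])
            trace = site_box_trace(movie, truth.site_positions_um[0][0],
                                   truth.site_positions_um[0][1])
            dff = trace / trace[:50].mean() - 1.0
            ev = find_events(dff, cfg.frame_rate_hz)[0]
            widths[label] = temporal_fwhm(dff, ev, cfg.frame_rate_hz)
        assert widths["blocked"] > widths["control"]

    def test_gain_invariance_of_dff_metrics(self):
        fr = 10.0
        trace = _transient(300, fr, 10.0, 0.2, noise=0.003)
        ev1 = find_events(trace, fr)[0]
        ev2 = find_events(3.0 * trace, fr)[0]
        f1 = temporal_fwhm(trace, ev1, fr)
        f2 = temporal_fwhm(3.0 * trace, ev2, fr)
        assert f1 == pytest.approx(f2, rel=1e-6)
        t1 = fit_tau_off(trace, ev1, fr)
        t2 = fit_tau_off(3.0 * trace, ev2, fr)
        assert t1 == pytest.approx(t2, rel=0.02)
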