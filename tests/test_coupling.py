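"""Phase/envelope extraction, slow-wave/spindle cross-correlation,
modulation index and surrogate calibration."""

import dataclasses

import numpy as np
import pytest

from tcsleep import (
    BandDefinition,
    InsufficientEventsError,
    ParameterError,
    SimParams,
    SWA_BAND,
    circular_mean_deg,
    comodulogram,
    cross_region_phase_coupling,
    extract_phase_and_envelope,
    modulation_index,
    normalized_crosscorr,
    simulate_hypnogram,
    simulate_recording,
    surrogate_null,
    sw_spindle_crosscorr,
)

from conftest import make_hypnogram

FS = 200.0


def make_sw_spindle_signal(delay_s, fs=FS, dur=240.0, seed=0):
    """Isolated slow-wave bumps every 4 s, each followed by a 12 Hz
    spindle burst at a fixed delay."""
    t = np.arange(int(dur * fs)) / fs
    rng = np.random.default_rng(seed)
    x = 5.0 * rng.standard_normal(t.size)
    for c in np.arange(5.0, dur - 5.0, 4.0):
        x += 150 * np.exp(-0.5 * ((t - c) / 0.25) ** 2)
        m = np.abs(t - (c + delay_s)) < 0.25
        x[m] += 60 * np.hanning(m.sum()) * np.sin(2 * np.pi * 12 * (t[m] - c - delay_s))
    return x, make_hypnogram([("NREM", int(dur))])


class TestPhaseEnvelope:
    def test_pure_sine_envelope_and_phase_rate(self):
        t = np.arange(int(120 * FS)) / FS
        x = 40.0 * np.sin(2 * np.pi * 2.0 * t)
        phase, env = extract_phase_and_envelope(x, FS, SWA_BAND)
        interior = slice(int(20 * FS), int(-20 * FS))
        # constant to 1% in the interior (the low-frequency band edge
        # leaves slow filter transients, hence the wide margin); the
        # absolute level carries the band-pass gain at 2 Hz
        assert np.allclose(env[interior], env[interior].mean(), rtol=0.01)
        assert env[interior].mean() == pytest.approx(40.0, rel=0.02)
        unwrapped = np.unwrap(np.deg2rad(phase[interior]))
        cycles = (unwrapped[-1] - unwrapped[0]) / (2 * np.pi)
        expected = 2.0 * (len(t[interior]) / FS)
        assert cycles == pytest.approx(expected, rel=0.01)

    def test_signal_maxima_sit_at_180_degrees(self):
        """Trough = 0, peak = 180 convention."""
        t = np.arange(int(120 * FS)) / FS
        x = np.sin(2 * np.pi * 1.0 * t)
        phase, _ = extract_phase_and_envelope(x, FS, SWA_BAND)
        maxima = np.flatnonzero((x[1:-1] > x[:-2]) & (x[1:-1] > x[2:])) + 1
        maxima = maxima[(maxima > 10 * FS) & (maxima < 110 * FS)]
        err = np.abs(((phase[maxima] - 180.0) + 180) % 360 - 180)
        assert np.max(err) <= 2.0

    def test_amplitude_modulation_recovered(self):
        """Envelope of a(t) sin(2 pi f t) tracks a(t) within 2%."""
        t = np.arange(int(240 * FS)) / FS
        a = 10.0 + 5.0 * np.sin(2 * np.pi * 0.05 * t)
        x = a * np.sin(2 * np.pi * 12.0 * t)
        _, env = extract_phase_and_envelope(
            x, FS, BandDefinition("sp", 10.0, 16.0))
        interior = slice(int(10 * FS), int(-10 * FS))
        assert np.max(np.abs(env[interior] - a[interior]) / a[interior]) < 0.02

    def test_band_vs_fs_rejected(self):
        with pytest.raises(ParameterError):
            extract_phase_and_envelope(np.zeros(1000), 20.0,
                                       BandDefinition("bad", 10.0, 16.0))


class TestCrossCorr:
    def test_identity_peak_at_zero(self):
        rng = np.random.default_rng(1)
        y = rng.standard_normal(5000)
        x = y[1000:4000]
        res = normalized_crosscorr(x, y, FS, max_lag_s=2.0)
        assert res.peak_lag_s == 0.0
        assert res.peak_cc == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("delay", [-0.5, 0.0, 0.3, 0.5])
    def test_injected_delay_recovered(self, delay):
        x, hyp = make_sw_spindle_signal(delay)
        res = sw_spindle_crosscorr(x, FS, hyp)
        assert res.peak_lag_s == pytest.approx(delay, abs=1.0 / FS)

    def test_independent_envelope_below_shuffled_null(self):
        """With spindles placed independently of slow waves the observed
        peak correlation is not extreme under a shuffled-peak null."""
        t = np.arange(int(300 * FS)) / FS
        rng = np.random.default_rng(7)
        x = 5.0 * rng.standard_normal(t.size)
        for c in np.arange(5.0, 295.0, 4.0):
            x += 150 * np.exp(-0.5 * ((t - c) / 0.25) ** 2)
        for c in rng.uniform(5.0, 295.0, size=70):
            m = np.abs(t - c) < 0.25
            x[m] += 60 * np.hanning(m.sum()) * np.sin(2 * np.pi * 12 * (t[m] - c))
        hyp = make_hypnogram([("NREM", 300)])
        res = sw_spindle_crosscorr(x, FS, hyp)
        x_coupled, hyp2 = make_sw_spindle_signal(0.0, seed=7)
        coupled = sw_spindle_crosscorr(x_coupled, FS, hyp2)
        assert res.peak_cc < coupled.peak_cc

    def test_too_few_peaks_raises(self):
        hyp = make_hypnogram([("NREM", 10)])
        x = np.random.default_rng(0).standard_normal(int(10 * FS))
        with pytest.raises(InsufficientEventsError):
            sw_spindle_crosscorr(x, FS, hyp)


class TestModulationIndex:
    def test_constant_amplitude_gives_zero(self):
        rng = np.random.default_rng(2)
        phase = rng.uniform(0, 360, size=90_000)
        res = modulation_index(phase, np.ones_like(phase))
        assert res.mi == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(res.bin_amp, 1.0 / res.n_bins)

    def test_cosine_profile_matches_numerical_integration(self):
        """amp = 1 + cos(phase - 180): MI equals the normalized KL of the
        binned cosine profile computed by independent quadrature."""
        n_bins = 18
        edges = np.linspace(0, 360, n_bins + 1)
        # dense quadrature of the mean amplitude per bin
        p_k = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            xs = np.linspace(lo, hi, 20001)
            p_k.append(np.trapezoid(1 + np.cos(np.deg2rad(xs - 180.0)), xs) / (hi - lo))
        p_k = np.asarray(p_k) / np.sum(p_k)
        expected_mi = (np.log(n_bins) + np.sum(p_k * np.log(p_k))) / np.log(n_bins)

        rng = np.random.default_rng(3)
        phase = rng.uniform(0, 360, size=400_000)
        amp = 1 + np.cos(np.deg2rad(phase - 180.0))
        res = modulation_index(phase, amp, n_bins=n_bins)
        assert res.mi == pytest.approx(expected_mi, rel=0.02)
        assert abs(((res.preferred_phase_deg - 180) + 180) % 360 - 180) <= 2.0

    def test_amplitude_scale_invariance(self):
        rng = np.random.default_rng(4)
        phase = rng.uniform(0, 360, size=10_000)
        amp = rng.random(10_000)
        assert modulation_index(phase, amp).mi == \
            pytest.approx(modulation_index(phase, 37.0 * amp).mi, abs=1e-14)

    def test_single_bin_concentration_gives_one(self):
        phase = np.full(1000, 90.0)
        amp = np.ones(1000)
        assert modulation_index(phase, amp).mi == pytest.approx(1.0)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ParameterError):
            modulation_index(np.zeros(10), np.zeros(11))


class TestComodulogram:
    def test_peak_at_injected_pair_and_monotone_in_coupling(self):
        """couple_prob = 1 puts the comodulogram maximum at the
        (slow-oscillation, spindle) cell, and beats couple_prob = 0."""
        pf = np.arange(0.5, 4.01, 0.5)
        af = np.arange(8.0, 18.01, 2.0)
        mis = {}
        for cp in (0.0, 1.0):
            p = SimParams(duration_s=900.0, seed=31, couple_prob=cp)
            hyp = simulate_hypnogram(p)
            rec, _ = simulate_recording(hyp, p)
            mask = hyp.sample_mask("NREM", rec.fs, rec.n_samples)
            mis[cp] = comodulogram(rec.get("ACC"), rec.get("AD"), rec.fs,
                                   pf, af, sample_mask=mask)
        i, j = np.unravel_index(np.argmax(mis[1.0]), mis[1.0].shape)
        assert (pf[i], af[j]) == (1.0, 12.0)
        k = np.argmin(np.abs(af - 12.0))
        assert mis[1.0][i, k] > mis[0.0][i, k]

    def test_band_collision_rejected(self):
        x = np.zeros(int(60 * FS))
        with pytest.raises(ParameterError, match="collide"):
            comodulogram(x, x, FS, np.array([2.0, 6.0]), np.array([8.0]))


class TestSurrogates:
    def test_strong_coupling_gives_minimal_p(self):
        rng = np.random.default_rng(5)
        phase = rng.uniform(0, 360, size=30_000)
        amp = 1 + np.cos(np.deg2rad(phase - 180.0))
        res = surrogate_null(phase, amp, FS, n_surrogates=99, min_shift_s=10.0)
        assert res.surrogate_p == pytest.approx(1.0 / 100.0)

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(6)
        phase = rng.uniform(0, 360, size=20_000)
        amp = rng.random(20_000)
        p1 = surrogate_null(phase, amp, FS, seed=42).surrogate_p
        p2 = surrogate_null(phase, amp, FS, seed=42).surrogate_p
        assert p1 == p2

    def test_too_few_surrogates_rejected(self):
        with pytest.raises(ParameterError):
            surrogate_null(np.zeros(10_000), np.zeros(10_000), FS, n_surrogates=5)


class TestCrossRegion:
    def test_shared_slow_oscillation_phase_recovered(self):
        """Two regions sharing the slow oscillation with spindles locked
        at 180 degrees recover that phase with high concentration."""
        p = SimParams(duration_s=900.0, seed=32, couple_prob=1.0)
        hyp = simulate_hypnogram(p)
        rec, _ = simulate_recording(hyp, p)
        res = cross_region_phase_coupling(rec.get("ACC"), rec.get("AD"),
                                          rec.fs, hyp)
        assert abs(((res.preferred_phase_deg - 180) + 180) % 360 - 180) <= 5.0
        assert res.resultant_length > 0.8

    def test_uniform_phases_have_small_resultant(self):
        rng = np.random.default_rng(8)
        n = 4000
        m, r = circular_mean_deg(rng.uniform(0, 360, size=n))
        # R is Rayleigh with scale 1/sqrt(2n); 3/sqrt(n) is a ~1e-4 tail
        assert r <= 3.0 / np.sqrt(n)
        _, r_small = circular_mean_deg(rng.uniform(0, 360, size=50))
        assert r > 0  # positive bias at finite n, shrinking with n

    def test_single_event_degenerate_case(self):
        m, r = circular_mean_deg(np.array([123.0]))
        assert m == pytest.approx(123.0) and r == pytest.approx(1.0)
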