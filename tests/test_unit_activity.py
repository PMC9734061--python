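"""Spike-band filter contract, state-resolved rates, transition PETHs
and burst detection against a brute-force chain-enumeration oracle."""

import numpy as np
import pytest
from scipy import signal as sps

from tcsleep import (
    BurstCriteria,
    InsufficientEventsError,
    ParameterError,
    SimParams,
    SpikeTrain,
    burst_stats,
    detect_bursts,
    simulate_hypnogram,
    simulate_spike_train,
    spike_band_filter,
    spike_band_sos,
    state_firing_rate,
    transition_peth,
)

from conftest import make_hypnogram


def brute_force_bursts(times, criteria):
    """Independent oracle: split the train into maximal chains of ISIs
    <= max_intraburst_isi; a chain is a burst iff it has >= min_spikes
    and its first spike follows silence >= min_preceding_silence."""
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        return []
    isi_max = criteria.max_intraburst_isi_ms / 1000.0 + 1e-9
    silence = criteria.min_preceding_silence_ms / 1000.0 - 1e-9
    chains = np.split(np.arange(t.size), np.flatnonzero(np.diff(t) > isi_max) + 1)
    out = []
    for ch in chains:
        if len(ch) < criteria.min_spikes:
            continue
        first = ch[0]
        if first > 0 and t[first] - t[first - 1] < silence:
            continue
        out.append((float(t[first]), len(ch), float((t[ch[-1]] - t[first]) * 1000)))
    return out


def random_train(rng, n_max=1000):
    """Mixture of burst-like and tonic inter-spike intervals."""
    n = int(rng.integers(2, n_max))
    isis = np.where(rng.random(n) < 0.3,
                    rng.uniform(0.001, 0.02, size=n),
                    rng.exponential(0.15, size=n) + 0.002)
    return np.cumsum(isis)


class TestSpikeBandFilter:
    def test_passband_ripple_within_spec(self):
        """Design response within 0.1 dB of unity across the passband."""
        sos = spike_band_sos(20_000.0)
        freqs = np.linspace(700, 3800, 50)
        _, h = sps.sosfreqz(sos, worN=freqs, fs=20_000.0)
        gain_db = 20 * np.log10(np.abs(h))
        assert np.all(gain_db <= 0.0 + 1e-6)
        assert np.all(gain_db >= -0.1 - 1e-6)

    def test_stopband_attenuation(self):
        sos = spike_band_sos(20_000.0)
        _, h = sps.sosfreqz(sos, worN=[100.0, 9000.0], fs=20_000.0)
        assert np.all(20 * np.log10(np.abs(h)) <= -40.0)

    def test_tone_gains_end_to_end(self):
        """1 kHz passes near unity, 100 Hz is strongly attenuated, after
        zero-phase (two-pass) application."""
        fs = 20_000.0
        t = np.arange(int(fs)) / fs
        inner = slice(2000, -2000)
        for f0, lo, hi in [(1000.0, 0.95, 1.01), (100.0, 0.0, 0.01)]:
            y = spike_band_filter(np.sin(2 * np.pi * f0 * t), fs)
            gain = y[inner].std() / np.sin(2 * np.pi * f0 * t)[inner].std()
            assert lo <= gain <= hi

    def test_nyquist_violation_rejected(self):
        with pytest.raises(ParameterError):
            spike_band_filter(np.zeros(100), 8000.0)
        with pytest.raises(ParameterError):
            spike_band_sos(7000.0)


class TestStateFiringRate:
    def test_uniform_train_same_rate_everywhere(self):
        rng = np.random.default_rng(0)
        dur = 3000.0
        times = np.sort(rng.uniform(0, dur, size=int(5 * dur)))
        times = times[np.diff(times, prepend=-1) > 0]
        hyp = make_hypnogram([("Wake", 1000), ("NREM", 1000), ("REM", 1000)])
        rates = state_firing_rate(SpikeTrain("u", "TRN", times), hyp)
        for s in ("Wake", "NREM", "REM"):
            se = np.sqrt(5.0 / 1000.0)
            assert rates[s] == pytest.approx(5.0, abs=3 * se)

    def test_no_spikes_all_zero(self):
        hyp = make_hypnogram([("Wake", 10), ("NREM", 10)])
        rates = state_firing_rate(SpikeTrain("u", "TRN", np.array([])), hyp)
        assert rates["Wake"] == 0.0 and rates["NREM"] == 0.0

    def test_absent_state_undefined(self):
        hyp = make_hypnogram([("Wake", 10)])
        rates = state_firing_rate(SpikeTrain("u", "TRN", np.array([1.0])), hyp)
        assert rates["REM"] is None

    def test_rates_recompose_overall_rate(self):
        rng = np.random.default_rng(1)
        hyp = make_hypnogram([("Wake", 300), ("NREM", 500), ("REM", 200)])
        times = np.sort(rng.uniform(0, 1000.0, size=2000))
        rates = state_firing_rate(SpikeTrain("u", "TRN", times), hyp)
        total = sum(rates[s] * n for s, n in
                    [("Wake", 300), ("NREM", 500), ("REM", 200)])
        assert total == pytest.approx(len(times))


class TestTransitionPeth:
    def test_step_rate_recovered_exactly(self):
        """A train stepping 10 Hz to 2 Hz at every Wake-to-NREM
        transition gives pre-bins at 10 and post-bins at 2."""
        hyp = make_hypnogram([("Wake", 60), ("NREM", 60)] * 5)
        spikes = []
        for k in range(5):
            a = 120.0 * k
            spikes += list(a + np.arange(0, 60, 0.1))
            spikes += list(a + 60 + np.arange(0, 60, 0.5))
        train = SpikeTrain("u", "TRN", np.array(spikes))
        peth = transition_peth(train, hyp, ("Wake", "NREM"))
        assert peth.n_transitions == 5
        assert np.allclose(peth.rate[:20], 10.0)
        assert np.allclose(peth.rate[20:], 2.0)

    def test_homogeneous_train_flat(self):
        rng = np.random.default_rng(2)
        hyp = make_hypnogram([("Wake", 60), ("NREM", 60)] * 20)
        times = np.sort(rng.uniform(0, 2400.0, size=int(2400 * 8)))
        peth = transition_peth(SpikeTrain("u", "TRN", times), hyp,
                               ("Wake", "NREM"))
        se = np.sqrt(8.0 / peth.n_transitions)
        assert np.all(np.abs(peth.rate - 8.0) < 4 * se)

    def test_conservation_of_spike_count(self):
        rng = np.random.default_rng(3)
        hyp = make_hypnogram([("Wake", 50), ("NREM", 50)] * 6)
        times = np.sort(rng.uniform(0, 600.0, size=1500))
        train = SpikeTrain("u", "TRN", times)
        peth = transition_peth(train, hyp, ("Wake", "NREM"), min_flank_s=20.0)
        trans = [100.0 * k + 50.0 for k in range(6)]
        inside = sum(int(np.sum((times >= t0 - 20) & (times < t0 + 20)))
                     for t0 in trans)
        assert np.sum(peth.rate) * peth.bin_s * peth.n_transitions == \
            pytest.approx(inside)

    def test_no_qualifying_transition_raises(self):
        hyp = make_hypnogram([("Wake", 5), ("NREM", 5)] * 4)
        with pytest.raises(InsufficientEventsError):
            transition_peth(SpikeTrain("u", "TRN", np.array([1.0])), hyp,
                            ("Wake", "NREM"), min_flank_s=20.0)


class TestDetectBursts:
    def test_hand_enumerated_example(self):
        """[0.500, 0.503, 0.506, 1.000, 1.800, 1.804]: a 3-spike burst,
        a tonic spike, a 2-spike burst."""
        train = SpikeTrain("u", "TRN",
                           np.array([0.500, 0.503, 0.506, 1.000, 1.800, 1.804]))
        bursts = detect_bursts(train, BurstCriteria())
        assert [(b.start_s, b.n_spikes) for b in bursts] == [(0.5, 3), (1.8, 2)]
        assert bursts[0].dur_ms == pytest.approx(6.0)
        assert bursts[1].dur_ms == pytest.approx(4.0)

    def test_all_long_isis_no_bursts(self):
        train = SpikeTrain("u", "TRN", np.arange(0.0, 10.0, 0.5))
        assert detect_bursts(train) == []

    def test_brute_force_oracle_equivalence(self):
        rng = np.random.default_rng(4)
        criteria = BurstCriteria()
        for _ in range(100):
            times = random_train(rng)
            got = [(b.start_s, b.n_spikes, b.dur_ms)
                   for b in detect_bursts(SpikeTrain("u", "r", times), criteria)]
            expected = brute_force_bursts(times, criteria)
            assert len(got) == len(expected)
            for g, e in zip(got, expected):
                assert g[0] == pytest.approx(e[0], abs=1e-12)
                assert g[1] == e[1]
                assert g[2] == pytest.approx(e[2], abs=1e-6)

    def test_tonic_spikes_far_from_bursts_do_not_change_output(self):
        base = np.array([1.000, 1.005, 1.010, 5.000, 5.004])
        extra = np.sort(np.concatenate([base, [0.5, 3.0, 7.0]]))
        b1 = detect_bursts(SpikeTrain("u", "r", base))
        b2 = detect_bursts(SpikeTrain("u", "r", extra))
        assert b1 == b2

    def test_burst_plus_tonic_partition(self):
        rng = np.random.default_rng(5)
        times = random_train(rng, n_max=500)
        criteria = BurstCriteria()
        bursts = detect_bursts(SpikeTrain("u", "r", times), criteria)
        n_burst_spikes = sum(b.n_spikes for b in bursts)
        assert n_burst_spikes <= times.size
        # every burst's spikes are actual spikes of the train
        for b in bursts:
            i = np.searchsorted(times, b.start_s)
            assert times[i] == pytest.approx(b.start_s)

    def test_simulator_ground_truth_recovered_exactly(self):
        p = SimParams(duration_s=900.0, seed=41)
        hyp = simulate_hypnogram(p)
        train, truth = simulate_spike_train(hyp, p)
        got = detect_bursts(train, BurstCriteria(
            max_intraburst_isi_ms=p.intraburst_isi_ms,
            min_preceding_silence_ms=p.pre_burst_silence_ms))
        assert len(got) == len(truth)
        for g, e in zip(got, truth):
            assert g.start_s == pytest.approx(e.start_s, abs=1e-12)
            assert g.n_spikes == e.n_spikes


class TestBurstStats:
    def test_density_arithmetic(self):
        """30 bursts in 15 NREM minutes is 2 per minute."""
        hyp = make_hypnogram([("NREM", 900), ("Wake", 300)])
        from tcsleep import BurstEvent
        bursts = [BurstEvent(10.0 + 20 * k, 3, 10.0) for k in range(30)]
        stats = burst_stats(bursts, hyp, state="NREM")
        assert stats["density_per_min"] == pytest.approx(2.0)

    def test_spikes_per_burst_recovered(self):
        p = SimParams(duration_s=900.0, seed=42, spikes_per_burst=(4, 4))
        hyp = simulate_hypnogram(p)
        train, _ = simulate_spike_train(hyp, p)
        bursts = detect_bursts(train, BurstCriteria(
            max_intraburst_isi_ms=p.intraburst_isi_ms,
            min_preceding_silence_ms=p.pre_burst_silence_ms))
        stats = burst_stats(bursts, hyp, state="NREM")
        assert stats["n_bursts"] > 10
        assert stats["mean_spikes"] == 4.0

    def test_empty_bursts_zero_density(self, all_nrem_hyp):
        stats = burst_stats([], all_nrem_hyp, state="NREM")
        assert stats["density_per_min"] == 0.0 and stats["mean_spikes"] is None

    def test_zero_state_time_rejected(self):
        hyp = make_hypnogram([("Wake", 60)])
        with pytest.raises(InsufficientEventsError):
            burst_stats([], hyp, state="NREM")


def test_criteria_validation():
    with pytest.raises(ParameterError):
        BurstCriteria(min_preceding_silence_ms=5.0, max_intraburst_isi_ms=10.0)
    with pytest.raises(ParameterError):
        BurstCriteria(min_spikes=1)
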