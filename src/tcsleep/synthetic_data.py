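"""Synthetic polysomnography with known ground truth.

Generates the three ingredients of a mouse sleep recording so that every
analysis stage in this package has a recoverable answer:

* a semi-Markov vigilance-state sequence (Wake / NREM / REM) with
  exponential episode durations and a ``fragmentation`` divisor that
  multiplies episode counts while leaving time-in-state untouched;
* multichannel signals built per 1-s epoch from the state's spectral
  recipe — 1/f^alpha background everywhere, a slow oscillation plus
  injected spindle events (10-16 Hz sinusoids under a Hann envelope,
  optionally phase-locked to the slow-oscillation cycle) during NREM,
  theta during REM, and an EMG channel that is loud in Wake only;
* spike trains with a dead-time-corrected Poisson tonic mode plus
  discrete burst events (fixed intra-burst inter-spike interval, an
  enforced silent gap before each burst), per state.

Phase convention (used package-wide): the slow-oscillation trough is
0deg and the peak 180deg, so a spindle locked to the slow-wave peak has
``couple_phase_deg = 180``.

All randomness flows from one integer seed expanded into fixed,
independent sub-streams (hypnogram / channel noise / events / units), so
identical parameters give bit-identical output and each product is
reproducible on its own.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .io_formats import (
    BurstEvent,
    Hypnogram,
    ParameterError,
    Recording,
    SpikeTrain,
    SpindleEvent,
)

__all__ = [
    "SimParams",
    "GroundTruth",
    "simulate_hypnogram",
    "simulate_recording",
    "simulate_spike_train",
    "so_phase_deg",
]

# fixed sub-stream tags (never reordered: reproducibility contract)
_STREAM_HYPNOGRAM = 0
_STREAM_EVENTS = 1
_STREAM_NOISE = 2      # + channel index
_STREAM_UNITS = 1000   # + unit index


@dataclass
class SimParams:
    """Generator parameters. Amplitudes in microvolts, rates in the
    units of their names.

    The defaults describe an untreated control animal in baseline sleep;
    a "fragmented" condition is the same set with ``fragmentation > 1``
    (more, shorter Wake/NREM episodes; identical state totals), and a
    treated-like condition is simply another parameter set built with
    :func:`dataclasses.replace`.
    """

    fs: float = 200.0
    duration_s: float = 3600.0
    #: mean episode duration per state, seconds (exponential draws)
    mean_episode_s: dict = field(
        default_factory=lambda: {"Wake": 100.0, "NREM": 120.0, "REM": 60.0}
    )
    fragmentation: float = 1.0
    rem_entry_prob: float = 0.25
    # --- NREM oscillatory content ---
    spindle_rate_per_min: float = 8.0
    spindle_dur_s: tuple = (0.5, 1.5)
    spindle_amp_uv: float = 100.0       # peak-to-trough at the envelope peak
    spindle_freq_hz: float = 12.0
    so_freq_hz: float = 1.0
    so_amp_uv: float = 150.0
    couple_prob: float = 0.7
    couple_phase_deg: float = 180.0
    # --- REM / background / EMG ---
    theta_freq_hz: float = 7.0
    theta_amp_uv: float = 60.0
    noise_exponent: float = 1.0         # 1/f^alpha background slope
    noise_rms_uv: float = 20.0
    emg_wake_rms_uv: float = 40.0
    emg_sleep_rms_uv: float = 8.0
    # --- spike trains (per state) ---
    tonic_rate_hz: dict = field(
        default_factory=lambda: {"Wake": 8.0, "NREM": 5.0, "REM": 10.0}
    )
    burst_rate_per_min: dict = field(
        default_factory=lambda: {"Wake": 1.0, "NREM": 20.0, "REM": 0.5}
    )
    spikes_per_burst: tuple = (2, 6)
    intraburst_isi_ms: float = 5.0
    pre_burst_silence_ms: float = 100.0
    seed: int = 0

    def validate(self) -> None:
        pos = {
            "fs": self.fs, "duration_s": self.duration_s,
            "fragmentation": self.fragmentation,
            "spindle_amp_uv": self.spindle_amp_uv,
            "spindle_freq_hz": self.spindle_freq_hz,
            "so_freq_hz": self.so_freq_hz, "so_amp_uv": self.so_amp_uv,
            "noise_rms_uv": self.noise_rms_uv,
            "intraburst_isi_ms": self.intraburst_isi_ms,
            "pre_burst_silence_ms": self.pre_burst_silence_ms,
        }
        for name, v in pos.items():
            if v <= 0:
                raise ParameterError(f"{name} must be > 0, got {v}")
        for name, d in (("mean_episode_s", self.mean_episode_s),
                        ("tonic_rate_hz", self.tonic_rate_hz)):
            for k, v in d.items():
                if v <= 0:
                    raise ParameterError(f"{name}[{k}] must be > 0, got {v}")
        if not 0 <= self.couple_prob <= 1:
            raise ParameterError("couple_prob must lie in [0, 1]")
        if not 0 <= self.couple_phase_deg < 360:
            raise ParameterError("couple_phase_deg must lie in [0, 360)")
        if not 0 <= self.rem_entry_prob <= 1:
            raise ParameterError("rem_entry_prob must lie in [0, 1]")
        if self.spindle_dur_s[0] <= 0 or self.spindle_dur_s[0] > self.spindle_dur_s[1]:
            raise ParameterError("spindle_dur_s must be a (min, max) with 0 < min <= max")


@dataclass
class GroundTruth:
    """Everything the generator injected, for parameter-recovery tests.

    ``true_spindles`` holds one entry per injected event; the same event
    appears on every EEG/LFP channel (a network event), so the listed
    times apply to all of them.
    """

    true_spindles: list[SpindleEvent]
    true_so_peaks_s: np.ndarray
    true_bursts: dict[str, list[BurstEvent]]
    params: SimParams


def _rng(params: SimParams, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(params.seed), *key]))


# ---------------------------------------------------------------------------
# hypnogram
# ---------------------------------------------------------------------------

def simulate_hypnogram(params: SimParams, epoch_s: float = 1.0) -> Hypnogram:
    """Semi-Markov vigilance-state sequence discretized to scoring epochs.

    Episode durations are exponential with mean
    ``mean_episode_s[state] / fragmentation``; transitions are
    Wake -> NREM, NREM -> REM with probability ``rem_entry_prob`` (else
    back to Wake), REM -> Wake. The chain starts in Wake.
    """
    params.validate()
    if params.duration_s < 3 * max(params.mean_episode_s.values()):
        warnings.warn(
            "duration_s < 3 x the longest mean episode: architecture "
            "statistics will be unstable", stacklevel=2)
    rng = _rng(params, _STREAM_HYPNOGRAM)
    n_epochs = int(round(params.duration_s / epoch_s))
    labels: list[str] = []
    state = "Wake"
    while len(labels) < n_epochs:
        mean = params.mean_episode_s[state] / params.fragmentation
        dur = rng.exponential(mean)
        n = max(1, int(round(dur / epoch_s)))
        labels.extend([state] * n)
        if state == "Wake":
            state = "NREM"
        elif state == "NREM":
            state = "REM" if rng.random() < params.rem_entry_prob else "Wake"
        else:
            state = "Wake"
    return Hypnogram(labels=np.array(labels[:n_epochs], dtype=object), epoch_s=epoch_s)


# ---------------------------------------------------------------------------
# signals
# ---------------------------------------------------------------------------

def _one_over_f_noise(n: int, alpha: float, rms: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with a 1/f^alpha amplitude spectrum and given RMS."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    with np.errstate(divide="ignore"):
        gain = np.where(f > 0, f ** (-alpha / 2.0), 0.0)
    x = np.fft.irfft(spec * gain, n)
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def so_phase_deg(t_s, so_freq_hz: float):
    """Slow-oscillation phase (degrees) at time ``t_s`` under the
    package convention trough = 0deg, peak = 180deg.

    The generator's slow oscillation is
    ``-so_amp * cos(2 pi f t)``, whose trough sits at integer cycles, so
    the conventional phase is simply ``(360 f t) mod 360``.
    """
    return np.mod(360.0 * so_freq_hz * np.asarray(t_s, dtype=float), 360.0)


def _nrem_episode_spans(hyp: Hypnogram) -> list[tuple[float, float]]:
    spans = []
    labels = hyp.labels
    i = 0
    while i < len(labels):
        j = i
        while j < len(labels) and labels[j] == labels[i]:
            j += 1
        if labels[i] == "NREM":
            spans.append((i * hyp.epoch_s, j * hyp.epoch_s))
        i = j
    return spans


def _place_spindles(hyp: Hypnogram, params: SimParams, rng: np.random.Generator
                    ) -> list[tuple[float, float]]:
    """Choose (center, duration) pairs inside NREM episodes.

    A ``couple_prob`` fraction of centers is pinned to the requested
    slow-oscillation phase; the rest land uniformly. Events are kept
    non-overlapping (0.25 s guard) so each injected spindle is a
    distinct detectable object.
    """
    spans = _nrem_episode_spans(hyp)
    nrem_s = sum(b - a for a, b in spans)
    if nrem_s == 0:
        return []
    n_events = rng.poisson(params.spindle_rate_per_min * nrem_s / 60.0)
    weights = np.array([b - a for a, b in spans]) / nrem_s
    guard = 0.25
    placed: list[tuple[float, float]] = []

    def collides(c, d):
        return any(abs(c - c0) < (d + d0) / 2 + guard for c0, d0 in placed)

    cycle = 1.0 / params.so_freq_hz
    frac = params.couple_phase_deg / 360.0
    for _ in range(n_events):
        dur = rng.uniform(*params.spindle_dur_s)
        coupled = rng.random() < params.couple_prob
        for _attempt in range(80):
            a, b = spans[rng.choice(len(spans), p=weights)]
            if b - a < dur + 2 * guard:
                continue
            if coupled:
                # admissible slow-oscillation cycles whose target phase
                # falls inside the episode with room for the envelope
                k_lo = int(np.ceil((a + dur / 2) / cycle - frac))
                k_hi = int(np.floor((b - dur / 2) / cycle - frac))
                if k_hi < k_lo:
                    continue
                center = (rng.integers(k_lo, k_hi + 1) + frac) * cycle
            else:
                center = rng.uniform(a + dur / 2, b - dur / 2)
            if not collides(center, dur):
                placed.append((float(center), float(dur)))
                break
    placed.sort()
    return placed


def simulate_recording(hyp: Hypnogram, params: SimParams
                       ) -> tuple[Recording, GroundTruth]:
    """Build the 8-channel recording matching ``hyp`` plus its ground truth.

    Every EEG/LFP channel receives independent 1/f^alpha background noise
    plus the *shared* NREM slow oscillation, the shared injected spindle
    events and the shared REM theta (they model network-wide events, so
    cross-region coupling is recoverable); the EMG channel is broadband
    noise, loud during Wake.
    """
    params.validate()
    if params.spindle_freq_hz <= 2.0 * params.so_freq_hz:
        raise ParameterError(
            "spindle band overlaps the slow-oscillation band "
            f"(spindle {params.spindle_freq_hz} Hz vs SO {params.so_freq_hz} Hz)")
    fs = params.fs
    n = int(round(hyp.duration_s * fs))
    t = np.arange(n) / fs

    nrem = hyp.sample_mask("NREM", fs, n).astype(float)
    rem = hyp.sample_mask("REM", fs, n).astype(float)
    wake = hyp.sample_mask("Wake", fs, n).astype(float)

    # slow oscillation: -A cos(2 pi f t), trough at phase 0deg
    so = -params.so_amp_uv / 2.0 * np.cos(2 * np.pi * params.so_freq_hz * t) * nrem
    theta_rng = _rng(params, _STREAM_EVENTS, 1)
    theta = (params.theta_amp_uv / 2.0
             * np.sin(2 * np.pi * params.theta_freq_hz * t
                      + theta_rng.uniform(0, 2 * np.pi)) * rem)

    ev_rng = _rng(params, _STREAM_EVENTS)
    placements = _place_spindles(hyp, params, ev_rng)
    spindles = np.zeros(n)
    true_events = []
    for center, dur in placements:
        i0 = int(round((center - dur / 2) * fs))
        i1 = int(round((center + dur / 2) * fs))
        seg = np.arange(i0, i1)
        env = np.hanning(len(seg))
        carrier = np.sin(2 * np.pi * params.spindle_freq_hz * (t[seg] - center)
                         + ev_rng.uniform(0, 2 * np.pi))
        spindles[seg] += params.spindle_amp_uv / 2.0 * env * carrier
        true_events.append(SpindleEvent(
            channel="EEG_front", start_s=i0 / fs, end_s=i1 / fs,
            peak_amp_uv=params.spindle_amp_uv,
            peak_freq_hz=params.spindle_freq_hz, energy=float("nan")))

    so_peak_candidates = (np.arange(0, hyp.duration_s * params.so_freq_hz) + 0.5
                          ) / params.so_freq_hz
    idx = np.minimum((so_peak_candidates * fs).astype(int), n - 1)
    true_so_peaks = so_peak_candidates[nrem[idx] > 0]

    channels = ["EEG front", "EEG par", "ACC", "AD", "TRN", "Brr", "VPL", "EMG"]
    roles = ["EEG_front", "EEG_par", "ACC", "AD", "TRN", "Brr", "VPL", "EMG"]
    signals = np.empty((len(channels), n))
    for ci, role in enumerate(roles):
        rng = _rng(params, _STREAM_NOISE, ci)
        if role == "EMG":
            white = rng.standard_normal(n)
            signals[ci] = white * (params.emg_wake_rms_uv * wake
                                   + params.emg_sleep_rms_uv * (1.0 - wake))
        else:
            bg = _one_over_f_noise(n, params.noise_exponent, params.noise_rms_uv, rng)
            signals[ci] = bg + so + spindles + theta

    rec = Recording(signals=signals, fs=fs, channels=channels, roles=roles)
    gt = GroundTruth(true_spindles=true_events,
                     true_so_peaks_s=np.asarray(true_so_peaks),
                     true_bursts={}, params=replace(params))
    return rec, gt


# ---------------------------------------------------------------------------
# spike trains
# ---------------------------------------------------------------------------

def simulate_spike_train(hyp: Hypnogram, params: SimParams,
                         unit_id: str = "u0", region: str = "TRN",
                         stream: Optional[int] = None
                         ) -> tuple[SpikeTrain, list[BurstEvent]]:
    """One unit's spike train: state-dependent tonic firing plus bursts.

    Tonic spikes form a dead-time-corrected Poisson process (refractory
    period equal to ``intraburst_isi_ms`` so no tonic pair can mimic a
    burst) whose *output* rate equals ``tonic_rate_hz[state]``. Bursts
    are Poisson-placed at ``burst_rate_per_min[state]``, contain
    ``spikes_per_burst`` spikes at exactly ``intraburst_isi_ms`` spacing,
    and each is guaranteed a silent gap of at least
    ``pre_burst_silence_ms`` before its first spike, so the returned
    burst list is exact ground truth under the generating criteria.

    ``stream`` selects the random sub-stream (defaults to a hash of
    ``unit_id``) so multiple units are independent yet reproducible.
    """
    params.validate()
    isi = params.intraburst_isi_ms / 1000.0
    silence = params.pre_burst_silence_ms / 1000.0
    if isi >= silence:
        raise ParameterError(
            "intraburst_isi_ms must be smaller than pre_burst_silence_ms; "
            "otherwise the burst criteria are degenerate")
    if stream is None:
        stream = sum(ord(c) for c in unit_id) % 997
    rng = _rng(params, _STREAM_UNITS + int(stream))

    # state segments [start, end)
    segments = []
    labels = hyp.labels
    i = 0
    while i < len(labels):
        j = i
        while j < len(labels) and labels[j] == labels[i]:
            j += 1
        segments.append((labels[i], i * hyp.epoch_s, j * hyp.epoch_s))
        i = j

    # --- bursts (placed first; they own their silent gaps) ---
    bursts: list[tuple[float, int]] = []
    for state, a, b in segments:
        rate = params.burst_rate_per_min.get(state, 0.0) / 60.0
        if rate <= 0:
            continue
        count = rng.poisson(rate * (b - a))
        starts = np.sort(rng.uniform(a, b, size=count))
        sizes = rng.integers(params.spikes_per_burst[0],
                             params.spikes_per_burst[1] + 1, size=count)
        for s, k in zip(starts, sizes):
            if s - silence < a or s + (k - 1) * isi >= b:
                continue
            bursts.append((float(s), int(k)))
    bursts.sort()
    kept: list[tuple[float, int]] = []
    for s, k in bursts:
        if kept:
            prev_s, prev_k = kept[-1]
            prev_end = prev_s + (prev_k - 1) * isi
            if s - prev_end <= silence + isi:
                continue
        kept.append((s, k))
    burst_events = [BurstEvent(start_s=s, n_spikes=k, dur_ms=(k - 1) * isi * 1000.0)
                    for s, k in kept]
    burst_spikes = np.concatenate(
        [s + np.arange(k) * isi for s, k in kept]) if kept else np.empty(0)

    # --- tonic spikes: renewal process, ISI = refractory + Exp ---
    tonic_all = []
    for state, a, b in segments:
        lam = params.tonic_rate_hz.get(state, 0.0)
        if lam <= 0:
            continue
        if lam * isi >= 1.0:
            raise ParameterError(
                f"tonic_rate_hz[{state}]={lam} is unattainable with a "
                f"{params.intraburst_isi_ms} ms refractory period")
        lam_eff = lam / (1.0 - lam * isi)   # so the output rate is lam
        dur = b - a
        n_draw = int(lam * dur + 6 * np.sqrt(lam * dur + 1)) + 8
        isis = isi + rng.exponential(1.0 / lam_eff, size=n_draw)
        times = a + np.cumsum(isis)
        tonic_all.append(times[times < b])
    tonic = np.sort(np.concatenate(tonic_all)) if tonic_all else np.empty(0)
    if tonic.size > 1:
        # re-impose the dead time across segment boundaries so no tonic
        # pair can ever satisfy the intra-burst ISI criterion
        keep_idx = [0]
        for i in range(1, tonic.size):
            if tonic[i] - tonic[keep_idx[-1]] > isi:
                keep_idx.append(i)
        tonic = tonic[keep_idx]

    # carve out each burst's protected window: the preceding silence,
    # the burst itself, and a trailing refractory so no tonic spike can
    # extend or violate a ground-truth burst
    if kept and tonic.size:
        drop = np.zeros(tonic.size, dtype=bool)
        for s, k in kept:
            end = s + (k - 1) * isi
            drop |= (tonic >= s - silence) & (tonic <= end + isi)
        tonic = tonic[~drop]

    spikes = np.sort(np.concatenate([tonic, burst_spikes]))
    train = SpikeTrain(unit_id=unit_id, region=region, spike_times_s=spikes)
    return train, burst_events
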