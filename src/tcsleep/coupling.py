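"""Slow-wave / spindle coupling within and across regions.

Three families of measures:

* **Event-time coupling** — a normalized cross-correlation between
  slow-wave peaks and the spindle-band envelope: slow-wave peaks are
  detected in the 0.5-4 Hz band during NREM, the envelope is excised
  around each peak and averaged, and the triggered average is
  Pearson-correlated against the slow-wave template at every lag, so a
  spindle envelope that systematically follows slow-wave peaks by
  ``d`` seconds produces a correlation peak at ``+d``.
* **Phase-amplitude coupling (PAC)** — the dependence of spindle-band
  amplitude on slow-oscillation phase, summarized by the normalized
  entropy-deficit modulation index over phase bins (MI = 0 for a
  uniform phase-amplitude profile, 1 when all amplitude sits in one
  bin), with a circular-shift surrogate null for calibration, and a
  comodulogram scanning (phase frequency x amplitude frequency) pairs.
* **Cross-region phase coupling** — the slow-oscillation phase of one
  region sampled at detected spindle envelope peaks of another,
  summarized by the circular mean and resultant length.

Phase convention everywhere: signal trough = 0deg, peak = 180deg.
Filters are zero-phase 4th-order Butterworth band-passes (no phase
distortion, the standard choice in cross-frequency-coupling work).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal as sps

from .io_formats import (
    BandDefinition,
    Hypnogram,
    InsufficientEventsError,
    ParameterError,
    SPINDLE_BAND,
    SWA_BAND,
)
from .spindle_detection import SpindleDetectorParams, detect_spindles

__all__ = [
    "CrossCorrResult",
    "PACResult",
    "PhaseCouplingResult",
    "extract_phase_and_envelope",
    "normalized_crosscorr",
    "sw_spindle_crosscorr",
    "modulation_index",
    "comodulogram",
    "surrogate_null",
    "cross_region_phase_coupling",
    "circular_mean_deg",
]


@dataclass
class CrossCorrResult:
    lags_s: np.ndarray
    cc: np.ndarray
    peak_lag_s: float
    peak_cc: float
    n_events: int = 0


@dataclass
class PACResult:
    phase_band: BandDefinition
    amp_band: BandDefinition
    n_bins: int
    bin_amp: np.ndarray          # mean normalized amplitude per bin, sums to 1
    mi: float
    preferred_phase_deg: float
    surrogate_p: Optional[float] = None


@dataclass
class PhaseCouplingResult:
    phases_deg: np.ndarray       # slow-wave phase at each spindle peak
    bin_centers_deg: np.ndarray
    hist: np.ndarray             # event counts per phase bin
    preferred_phase_deg: float
    resultant_length: float


def circular_mean_deg(phases_deg: np.ndarray,
                      weights: Optional[np.ndarray] = None
                      ) -> tuple[float, float]:
    """Weighted circular mean (degrees in [0, 360)) and resultant length."""
    ph = np.deg2rad(np.asarray(phases_deg, dtype=float))
    w = np.ones_like(ph) if weights is None else np.asarray(weights, dtype=float)
    z = np.sum(w * np.exp(1j * ph)) / np.sum(w)
    return float(np.rad2deg(np.angle(z)) % 360.0), float(np.abs(z))


def extract_phase_and_envelope(signal: np.ndarray, fs: float,
                               band: BandDefinition
                               ) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous phase (degrees, trough = 0 / peak = 180) and
    envelope (uV) of ``signal`` in ``band``.

    Zero-phase 4th-order Butterworth band-pass followed by the analytic
    signal; the +180deg offset converts the analytic-signal convention
    (0 at the signal maximum) to the package's trough-zero convention.
    """
    if fs < 4 * band.hi_hz:
        raise ParameterError(
            f"fs = {fs} Hz too low for band {band.name!r} "
            f"(upper edge {band.hi_hz} Hz); need fs >= 4x the upper edge")
    sos = sps.butter(4, [band.lo_hz, band.hi_hz], btype="bandpass",
                     fs=fs, output="sos")
    filtered = sps.sosfiltfilt(sos, np.asarray(signal, dtype=float))
    analytic = sps.hilbert(filtered)
    phase_deg = (np.rad2deg(np.angle(analytic)) + 180.0) % 360.0
    return phase_deg, np.abs(analytic)


def normalized_crosscorr(x: np.ndarray, y: np.ndarray, fs: float,
                         max_lag_s: float) -> CrossCorrResult:
    """Pearson correlation of ``x`` against ``y`` shifted by each lag.

    ``y`` must be longer than ``x`` by at least ``2 * max_lag_s`` so the
    overlap stays full-length at every lag; positive lags mean features
    of ``y`` occur *after* those of ``x``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    L = int(round(max_lag_s * fs))
    if y.size < x.size + 2 * L:
        raise ParameterError("y must exceed x by 2*max_lag_s for full overlap")
    off = (y.size - x.size) // 2
    xc = x - x.mean()
    xs = xc / (np.linalg.norm(xc) or 1.0)
    lags = np.arange(-L, L + 1)
    cc = np.empty(lags.size)
    for i, lag in enumerate(lags):
        seg = y[off + lag: off + lag + x.size]
        segc = seg - seg.mean()
        denom = np.linalg.norm(segc)
        cc[i] = float(xs @ segc / denom) if denom > 0 else 0.0
    k = int(np.argmax(cc))
    return CrossCorrResult(lags_s=lags / fs, cc=cc,
                           peak_lag_s=float(lags[k] / fs), peak_cc=float(cc[k]))


def sw_spindle_crosscorr(signal: np.ndarray, fs: float, hyp: Hypnogram,
                         sw_band: BandDefinition = SWA_BAND,
                         spindle_band: BandDefinition = SPINDLE_BAND,
                         max_lag_s: float = 2.0,
                         peak_percentile: float = 75.0) -> CrossCorrResult:
    """Normalized cross-correlation between slow-wave peaks and the
    spindle envelope within one channel.

    Slow-wave peaks are local maxima of the slow-wave-band signal inside
    NREM whose height exceeds the given percentile of NREM peak heights.
    The spindle envelope is excised around each peak and averaged; the
    average is Pearson-correlated at every lag against the slow-wave
    template (the peak-triggered average of the slow-wave signal), so
    ``peak_lag_s > 0`` means the spindle envelope follows the slow wave.
    """
    signal = np.asarray(signal, dtype=float)
    nrem = hyp.sample_mask("NREM", fs, signal.size)
    if not nrem.any():
        raise InsufficientEventsError("no NREM epochs")
    sos = sps.butter(4, [sw_band.lo_hz, sw_band.hi_hz], btype="bandpass",
                     fs=fs, output="sos")
    sw = sps.sosfiltfilt(sos, signal)
    _, env = extract_phase_and_envelope(signal, fs, spindle_band)

    locs, props = sps.find_peaks(sw, height=0.0)
    locs = locs[nrem[locs]]
    if locs.size == 0:
        raise InsufficientEventsError("no slow-wave peaks inside NREM")
    thresh = np.percentile(sw[locs], peak_percentile)
    locs = locs[sw[locs] >= thresh]

    L = int(round(max_lag_s * fs))
    locs = locs[(locs >= 2 * L) & (locs < signal.size - 2 * L)]
    if locs.size < 10:
        raise InsufficientEventsError(
            f"only {locs.size} usable slow-wave peaks (need >= 10)")

    tmpl = np.mean([sw[i - L:i + L + 1] for i in locs], axis=0)
    trig_env = np.mean([env[i - 2 * L:i + 2 * L + 1] for i in locs], axis=0)
    res = normalized_crosscorr(tmpl, trig_env, fs, max_lag_s)
    res.n_events = int(locs.size)
    return res


def _binned_amplitude(phase_deg: np.ndarray, amp: np.ndarray, n_bins: int
                      ) -> np.ndarray:
    bins = np.minimum((np.asarray(phase_deg) / 360.0 * n_bins).astype(int),
                      n_bins - 1)
    sums = np.bincount(bins, weights=amp, minlength=n_bins)
    counts = np.bincount(bins, minlength=n_bins)
    means = np.divide(sums, counts, out=np.zeros(n_bins), where=counts > 0)
    total = means.sum()
    return means / total if total > 0 else means


def _mi_from_distribution(p: np.ndarray) -> float:
    n = p.size
    nz = p[p > 0]
    entropy = -float(np.sum(nz * np.log(nz)))
    return (np.log(n) - entropy) / np.log(n)


def modulation_index(phase_deg: np.ndarray, amp: np.ndarray,
                     n_bins: int = 18,
                     phase_band: BandDefinition = SWA_BAND,
                     amp_band: BandDefinition = SPINDLE_BAND) -> PACResult:
    """Normalized entropy-deficit modulation index over phase bins.

    The amplitude series is averaged within each of ``n_bins`` phase
    bins and normalized to a distribution P; the index is
    ``KL(P || uniform) / log(n_bins)``, zero iff P is uniform and 1 when
    all amplitude concentrates in a single bin (empty bins contribute
    0 log 0 = 0). The preferred phase is the amplitude-weighted circular
    mean. The index is invariant to scaling the amplitude series.
    """
    phase_deg = np.asarray(phase_deg, dtype=float)
    amp = np.asarray(amp, dtype=float)
    if phase_deg.shape != amp.shape:
        raise ParameterError("phase and amplitude series must have equal length")
    if n_bins < 4:
        raise ParameterError("n_bins must be >= 4")
    p = _binned_amplitude(phase_deg, amp, n_bins)
    pref, _ = circular_mean_deg(phase_deg, weights=amp)
    return PACResult(phase_band=phase_band, amp_band=amp_band, n_bins=n_bins,
                     bin_amp=p, mi=_mi_from_distribution(p),
                     preferred_phase_deg=pref)


def surrogate_null(phase_deg: np.ndarray, amp: np.ndarray, fs: float,
                   n_surrogates: int = 200, min_shift_s: float = 10.0,
                   seed: int = 0, n_bins: int = 18) -> PACResult:
    """Modulation index with a circular-shift surrogate p-value.

    The amplitude series is circularly shifted by uniform random offsets
    of at least ``min_shift_s`` (shifting, not shuffling, preserves its
    autocorrelation); ``surrogate_p = (1 + #{MI_surr >= MI})/(1 + n)``.
    """
    if n_surrogates < 19:
        raise ParameterError("n_surrogates must be >= 19")
    phase_deg = np.asarray(phase_deg, dtype=float)
    amp = np.asarray(amp, dtype=float)
    n = phase_deg.size
    min_shift = int(round(min_shift_s * fs))
    if n <= 2 * min_shift:
        raise ParameterError("series must be longer than 2 x min_shift_s")
    res = modulation_index(phase_deg, amp, n_bins)

    bins = np.minimum((phase_deg / 360.0 * n_bins).astype(int), n_bins - 1)
    counts = np.bincount(bins, minlength=n_bins)
    rng = np.random.default_rng(seed)
    shifts = rng.integers(min_shift, n - min_shift, size=n_surrogates)
    n_ge = 0
    for s in shifts:
        rolled = np.roll(amp, int(s))
        sums = np.bincount(bins, weights=rolled, minlength=n_bins)
        means = np.divide(sums, counts, out=np.zeros(n_bins), where=counts > 0)
        p = means / means.sum()
        if _mi_from_distribution(p) >= res.mi:
            n_ge += 1
    res.surrogate_p = (1 + n_ge) / (1 + n_surrogates)
    return res


def comodulogram(phase_signal: np.ndarray, amp_signal: np.ndarray, fs: float,
                 phase_freqs: np.ndarray, amp_freqs: np.ndarray,
                 phase_bw_hz: float = 0.4, amp_bw_hz: float = 2.0,
                 n_bins: int = 18,
                 sample_mask: Optional[np.ndarray] = None) -> np.ndarray:
    """Matrix of modulation indexes over (phase frequency x amplitude
    frequency) pairs.

    Each phase band is ``center +/- phase_bw_hz`` (floored at 0.05 Hz)
    on ``phase_signal``; each amplitude band is ``center +/- amp_bw_hz``
    on ``amp_signal``. Overlapping phase/amplitude bands raise, as do
    bands beyond Nyquist. ``sample_mask`` restricts the MI computation
    (e.g. to NREM samples). Returns shape
    ``(len(phase_freqs), len(amp_freqs))``.
    """
    phase_freqs = np.asarray(phase_freqs, dtype=float)
    amp_freqs = np.asarray(amp_freqs, dtype=float)
    p_hi = phase_freqs.max() + phase_bw_hz
    a_lo = amp_freqs.min() - amp_bw_hz
    if p_hi > a_lo:
        raise ParameterError(
            f"phase bands (up to {p_hi} Hz) collide with amplitude bands "
            f"(down to {a_lo} Hz)")
    if amp_freqs.max() + amp_bw_hz >= fs / 2:
        raise ParameterError("amplitude bands exceed Nyquist")

    phases = []
    for f0 in phase_freqs:
        band = BandDefinition(f"phase_{f0}", max(f0 - phase_bw_hz, 0.05),
                              f0 + phase_bw_hz)
        ph, _ = extract_phase_and_envelope(phase_signal, fs, band)
        phases.append(ph)
    envs = []
    for f0 in amp_freqs:
        band = BandDefinition(f"amp_{f0}", f0 - amp_bw_hz, f0 + amp_bw_hz)
        _, env = extract_phase_and_envelope(amp_signal, fs, band)
        envs.append(env)

    mi = np.empty((phase_freqs.size, amp_freqs.size))
    for i, ph in enumerate(phases):
        for j, env in enumerate(envs):
            if sample_mask is not None:
                p = _binned_amplitude(ph[sample_mask], env[sample_mask], n_bins)
            else:
                p = _binned_amplitude(ph, env, n_bins)
            mi[i, j] = _mi_from_distribution(p)
    return mi


def cross_region_phase_coupling(sw_region_signal: np.ndarray,
                                amp_region_signal: np.ndarray,
                                fs: float, hyp: Hypnogram,
                                sw_band: BandDefinition = SWA_BAND,
                                spindle_band: BandDefinition = SPINDLE_BAND,
                                n_bins: int = 18,
                                detector: Optional[SpindleDetectorParams] = None
                                ) -> PhaseCouplingResult:
    """Slow-oscillation phase of region A at spindle peaks of region B.

    Spindles are detected in ``amp_region_signal``; at each event's
    envelope peak the instantaneous slow-wave phase of
    ``sw_region_signal`` is sampled. Returns the circular histogram,
    circular mean and resultant length of those phases.
    """
    if len(sw_region_signal) != len(amp_region_signal):
        raise ParameterError("region signals must have equal length")
    detector = detector or SpindleDetectorParams(band=spindle_band)
    events = detect_spindles(amp_region_signal, fs, hyp, detector)
    if not events:
        raise InsufficientEventsError("no spindle events detected")
    phase, _ = extract_phase_and_envelope(sw_region_signal, fs, sw_band)
    _, env = extract_phase_and_envelope(amp_region_signal, fs, spindle_band)
    peaks = []
    for ev in events:
        s, e = int(round(ev.start_s * fs)), int(round(ev.end_s * fs))
        peaks.append(s + int(np.argmax(env[s:e])))
    phases = phase[np.asarray(peaks)]
    pref, r = circular_mean_deg(phases)
    hist, edges = np.histogram(phases, bins=n_bins, range=(0.0, 360.0))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return PhaseCouplingResult(phases_deg=phases, bin_centers_deg=centers,
                               hist=hist, preferred_phase_deg=pref,
                               resultant_length=r)
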