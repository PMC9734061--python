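"""Sleep-spindle detection from continuous-wavelet-transform energy.

The detector mirrors the standard rodent pipeline: band-limited CWT
energy (complex Morlet by default, frequency B-spline available) is
averaged across center frequencies spanning the spindle band
(10-16 Hz), smoothed, and normalized by its NREM mean. Candidate events
are contiguous supra-threshold stretches under a two-threshold
hysteresis rule (must exceed the high threshold somewhere, extend down
to the low threshold), merged across sub-``merge_gap_s`` gaps, and kept
when their duration lies in [0.4 s, 2.0 s] — spindles are waxing-waning
events longer than 400 ms — and at least half the event overlaps NREM
epochs. Thresholds are expressed in SDs of the normalized energy over
NREM, so detection times are invariant to signal scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import signal as sps

from .io_formats import (
    BandDefinition,
    Hypnogram,
    InsufficientDataError,
    ParameterError,
    SPINDLE_BAND,
    SpindleEvent,
)

__all__ = ["SpindleDetectorParams", "spindle_energy", "detect_spindles",
           "spindle_stats"]

_WAVELETS = {"complex_morlet": "cmor1.5-1.0", "freq_bspline": "fbsp2-1.0-1.5"}


@dataclass
class SpindleDetectorParams:
    band: BandDefinition = field(default_factory=lambda: SPINDLE_BAND)
    wavelet: str = "complex_morlet"
    n_freqs: int = 13
    thresh_hi_sd: float = 2.5
    thresh_lo_sd: float = 1.0
    smooth_s: float = 0.1
    min_dur_s: float = 0.4
    max_dur_s: float = 2.0
    merge_gap_s: float = 0.1

    def validate(self) -> None:
        if self.wavelet not in _WAVELETS:
            raise ParameterError(
                f"wavelet must be one of {sorted(_WAVELETS)}, got {self.wavelet!r}")
        if not (self.thresh_hi_sd >= self.thresh_lo_sd > 0):
            raise ParameterError("need thresh_hi_sd >= thresh_lo_sd > 0")
        if not (0 < self.min_dur_s < self.max_dur_s):
            raise ParameterError("need 0 < min_dur_s < max_dur_s")
        if self.n_freqs < 2:
            raise ParameterError("n_freqs must be >= 2")


def spindle_energy(signal: np.ndarray, fs: float,
                   params: SpindleDetectorParams | None = None,
                   nrem_mask: np.ndarray | None = None
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normalized CWT energy in the spindle band.

    Returns ``(energy, freqs, energy_matrix)``: the per-sample smoothed
    energy divided by its NREM mean (overall mean when no mask is
    given), the wavelet center frequencies, and the unsmoothed
    per-frequency magnitude-squared matrix (n_freqs x n_samples).
    """
    params = params or SpindleDetectorParams()
    params.validate()
    if fs < 4 * params.band.hi_hz:
        raise ParameterError(
            f"fs = {fs} Hz too low for the {params.band.hi_hz} Hz band edge; "
            "resample to at least 4x the upper band edge first")
    signal = np.asarray(signal, dtype=float)
    if signal.size < 10 * params.smooth_s * fs:
        raise InsufficientDataError("recording shorter than 10 x smooth_s")

    name = _WAVELETS[params.wavelet]
    freqs = np.linspace(params.band.lo_hz, params.band.hi_hz, params.n_freqs)
    scales = pywt.frequency2scale(name, freqs / fs)
    coefs, actual = pywt.cwt(signal, scales, name, sampling_period=1.0 / fs,
                             method="fft")
    matrix = np.abs(coefs) ** 2
    energy = matrix.mean(axis=0)

    win = max(1, int(round(params.smooth_s * fs)))
    kernel = np.ones(win) / win
    energy = np.convolve(energy, kernel, mode="same")

    ref = energy[nrem_mask] if nrem_mask is not None else energy
    mean = float(ref.mean()) if ref.size else 0.0
    if mean > 0:
        energy = energy / mean
    return energy, np.asarray(actual), matrix


def _hysteresis_events(energy: np.ndarray, lo: float, hi: float) -> list[tuple[int, int]]:
    above_lo = energy > lo
    edges = np.flatnonzero(np.diff(above_lo.astype(np.int8)))
    starts = edges[above_lo[edges + 1]] + 1
    ends = edges[~above_lo[edges + 1]] + 1
    if above_lo[0]:
        starts = np.concatenate([[0], starts])
    if above_lo[-1]:
        ends = np.concatenate([ends, [len(energy)]])
    return [(s, e) for s, e in zip(starts, ends) if np.any(energy[s:e] > hi)]


def detect_spindles(signal: np.ndarray, fs: float, hyp: Hypnogram,
                    params: SpindleDetectorParams | None = None,
                    channel: str = "") -> list[SpindleEvent]:
    """Detect spindle events in one channel paired with a hypnogram.

    Events are half-open ``[start_s, end_s)``; ``peak_amp_uv`` is the
    peak-to-trough excursion of the band-filtered signal within the
    event, ``peak_freq_hz`` the wavelet center frequency of maximal
    event energy, and ``energy`` the mean normalized energy. Events with
    under 50% NREM overlap at transitions are dropped; events between
    50% and 100% are kept with ``in_nrem=False`` marking the transition.
    """
    params = params or SpindleDetectorParams()
    params.validate()
    nrem = hyp.sample_mask("NREM", fs, len(signal))
    if not nrem.any():
        raise InsufficientDataError("hypnogram contains no NREM epochs")
    energy, freqs, matrix = spindle_energy(signal, fs, params, nrem_mask=nrem)

    ref = energy[nrem]
    lo = ref.mean() + params.thresh_lo_sd * ref.std()
    hi = ref.mean() + params.thresh_hi_sd * ref.std()
    cand = _hysteresis_events(energy, lo, hi)

    # boundary refinement: a waxing-waning event extends beyond its
    # suprathreshold core, so walk each edge outward downhill to the
    # nearest local minimum of the smoothed energy, stopping at the
    # noise floor (the NREM median energy) so boundaries never wander
    # through background stretches
    floor = float(np.median(ref))
    refined = []
    for s, e in cand:
        while s > 0 and energy[s - 1] <= energy[s] and energy[s - 1] > floor:
            s -= 1
        while e < len(energy) and energy[e] <= energy[e - 1] and energy[e] > floor:
            e += 1
        refined.append((s, e))

    merged: list[list[int]] = []
    gap = int(round(params.merge_gap_s * fs))
    for s, e in refined:
        if merged and s - merged[-1][1] < gap:
            merged[-1][1] = max(e, merged[-1][1])
        else:
            merged.append([s, e])

    sos = sps.butter(4, [params.band.lo_hz, params.band.hi_hz],
                     btype="bandpass", fs=fs, output="sos")
    filtered = sps.sosfiltfilt(sos, signal)

    events = []
    for s, e in merged:
        dur = (e - s) / fs
        if not params.min_dur_s <= dur <= params.max_dur_s:
            continue
        frac_nrem = float(nrem[s:e].mean())
        if frac_nrem < 0.5:
            continue
        seg = filtered[s:e]
        events.append(SpindleEvent(
            channel=channel,
            start_s=s / fs,
            end_s=e / fs,
            peak_amp_uv=float(seg.max() - seg.min()),
            peak_freq_hz=float(freqs[np.argmax(matrix[:, s:e].mean(axis=1))]),
            energy=float(energy[s:e].mean()),
            in_nrem=bool(frac_nrem >= 1.0),
        ))
    return events


def spindle_stats(events: list[SpindleEvent], hyp: Hypnogram,
                  window: tuple[float, float] | None = None) -> dict:
    """Spindle rate per NREM minute plus mean amplitude and length.

    The rate denominator is the NREM time inside ``window``; means run
    over events starting inside the window. With no events the rate is
    0 and the means are ``None``.
    """
    if window is None:
        window = (0.0, hyp.duration_s)
    w0, w1 = window
    if w1 <= w0:
        raise ParameterError(f"empty window {window}")
    e0 = int(np.ceil(w0 / hyp.epoch_s))
    e1 = min(int(np.floor(w1 / hyp.epoch_s)), hyp.n_epochs)
    nrem_min = float(np.sum(hyp.labels[e0:e1] == "NREM")) * hyp.epoch_s / 60.0
    if nrem_min == 0:
        raise InsufficientDataError("window contains no NREM time: rate undefined")
    sel = [ev for ev in events if w0 <= ev.start_s < w1]
    return {
        "rate_per_min": len(sel) / nrem_min,
        "mean_amp_uv": float(np.mean([e.peak_amp_uv for e in sel])) if sel else None,
        "mean_dur_s": float(np.mean([e.dur_s for e in sel])) if sel else None,
        "n_events": len(sel),
        "nrem_minutes": nrem_min,
    }
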