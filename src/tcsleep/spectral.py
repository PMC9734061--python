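"""Welch power spectral density and band-power analysis.

Defaults follow standard rodent sleep-EEG practice: 8-s windows with
75% overlap, total-power normalization so recordings are comparable
across animals, and delta sub-bands delta1 (0.75-1.75 Hz) and delta2
(2.75-3.5 Hz) of slow-wave activity (0.5-4 Hz). The taper is Hann.

State-masked estimation averages modified periodograms over every
window that lies fully inside a run of masked epochs, so a masked
estimate with an all-true mask equals the plain Welch estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy import signal as sps

from .io_formats import (
    BandDefinition,
    Hypnogram,
    InsufficientDataError,
    ParameterError,
)

__all__ = ["Psd", "welch_psd", "normalize_psd", "band_power", "swa_timecourse"]


@dataclass
class Psd:
    """A (possibly state-masked, possibly normalized) Welch PSD."""

    freqs_hz: np.ndarray
    power: np.ndarray              # uV^2/Hz, or dimensionless if normalized
    normalized: bool
    window_s: float
    overlap_frac: float
    state_mask: Optional[np.ndarray] = None
    n_windows: int = 0


def _admissible_starts(mask: np.ndarray, nperseg: int, step: int) -> np.ndarray:
    """Start indices of windows lying fully inside True-runs of ``mask``.

    Windows advance by ``step`` from the start of each run, mirroring
    Welch segmentation restarted per run.
    """
    starts = []
    n = len(mask)
    i = 0
    while i < n:
        if not mask[i]:
            i += 1
            continue
        j = i
        while j < n and mask[j]:
            j += 1
        starts.extend(range(i, j - nperseg + 1, step))
        i = j
    return np.asarray(starts, dtype=int)


def welch_psd(signal: np.ndarray, fs: float, window_s: float = 8.0,
              overlap_frac: float = 0.75,
              epochs: Optional[Hypnogram] = None,
              state: str = "NREM",
              sample_mask: Optional[np.ndarray] = None) -> Psd:
    """Welch PSD (Hann taper, density scaling) of ``signal``.

    Restrict the estimate to a vigilance state by passing ``epochs``
    (a paired hypnogram) and ``state``, or an explicit boolean
    ``sample_mask``; only windows entirely inside masked runs enter the
    average.
    """
    signal = np.asarray(signal, dtype=float)
    if not 0 <= overlap_frac < 1:
        raise ParameterError("overlap_frac must lie in [0, 1)")
    nperseg = int(round(window_s * fs))
    if nperseg < 2:
        raise ParameterError("window_s too short for this sampling rate")
    if signal.size < nperseg:
        raise InsufficientDataError(
            f"signal ({signal.size} samples) shorter than one {window_s}-s window")
    step = max(1, int(round(nperseg * (1 - overlap_frac))))

    if epochs is not None:
        sample_mask = epochs.sample_mask(state, fs, signal.size)
    if sample_mask is None:
        freqs, power = sps.welch(signal, fs=fs, window="hann", nperseg=nperseg,
                                 noverlap=nperseg - step, detrend="constant",
                                 scaling="density")
        n_win = (signal.size - nperseg) // step + 1
        return Psd(freqs, power, False, window_s, overlap_frac, None, n_win)

    starts = _admissible_starts(np.asarray(sample_mask, bool), nperseg, step)
    if starts.size == 0:
        raise InsufficientDataError(
            "no admissible window lies fully inside the masked epochs")
    segs = np.stack([signal[s:s + nperseg] for s in starts])
    freqs, pxx = sps.periodogram(segs, fs=fs, window="hann",
                                 detrend="constant", scaling="density", axis=-1)
    return Psd(freqs, pxx.mean(axis=0), False, window_s, overlap_frac,
               np.asarray(sample_mask, bool), len(starts))


def normalize_psd(psd: Psd) -> Psd:
    """Divide by total power (trapezoidal integral over the computed
    range) so the PSD integrates to 1."""
    if psd.normalized:
        raise ParameterError("PSD is already normalized")
    total = float(np.trapezoid(psd.power, psd.freqs_hz))
    if total <= 0:
        raise ParameterError("degenerate input: total power is zero")
    return replace(psd, power=psd.power / total, normalized=True)


def band_power(psd: Psd, band: BandDefinition) -> float:
    """Trapezoidal integral of the PSD over ``[band.lo_hz, band.hi_hz)``.

    Edges not on the frequency grid are linearly interpolated, so
    adjacent bands sum exactly to their covering band.
    """
    f, p = psd.freqs_hz, psd.power
    if band.lo_hz < f[0] or band.hi_hz > f[-1]:
        raise ParameterError(
            f"band {band.name!r} ({band.lo_hz}-{band.hi_hz} Hz) outside "
            f"the PSD range {f[0]}-{f[-1]} Hz")
    grid = f[(f > band.lo_hz) & (f < band.hi_hz)]
    xs = np.concatenate([[band.lo_hz], grid, [band.hi_hz]])
    ys = np.interp(xs, f, p)
    return float(np.trapezoid(ys, xs))


def swa_timecourse(signal: np.ndarray, fs: float, hyp: Hypnogram,
                   band: BandDefinition, bin_s: float,
                   normalize_to: str = "first_bin",
                   state: str = "NREM", window_s: float = 8.0,
                   overlap_frac: float = 0.75) -> list[tuple[float, Optional[float]]]:
    """Time course of normalized band power over consecutive time bins.

    Each bin's PSD uses only windows inside that bin's ``state`` epochs
    and is total-power normalized before the band integral. Bins with
    no admissible window yield ``None`` (never interpolated). The series
    is finally divided by the first non-missing value
    (``normalize_to="first_bin"``) or by the mean of non-missing values
    (``"mean"``).
    """
    if bin_s < window_s:
        raise ParameterError("bin_s must be at least one Welch window")
    if normalize_to not in ("first_bin", "mean"):
        raise ParameterError("normalize_to must be 'first_bin' or 'mean'")
    signal = np.asarray(signal, dtype=float)
    state_mask = hyp.sample_mask(state, fs, signal.size)
    nbin = int(round(bin_s * fs))
    values: list[Optional[float]] = []
    starts = list(range(0, signal.size - nbin + 1, nbin))
    for s in starts:
        m = np.zeros(signal.size, dtype=bool)
        m[s:s + nbin] = state_mask[s:s + nbin]
        try:
            psd = welch_psd(signal, fs, window_s, overlap_frac, sample_mask=m)
            values.append(band_power(normalize_psd(psd), band))
        except InsufficientDataError:
            values.append(None)
    present = [v for v in values if v is not None]
    if not present:
        raise InsufficientDataError("no bin has an admissible window")
    ref = present[0] if normalize_to == "first_bin" else float(np.mean(present))
    return [(s / fs, None if v is None else v / ref)
            for s, v in zip(starts, values)]
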