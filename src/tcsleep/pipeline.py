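"""End-to-end deterministic analysis run.

``run_pipeline`` simulates a recording from one parameter set, writes
the raw products (EDF signals, hypnogram CSV, ground-truth and spike
tables), runs every analysis stage on them, and writes the results as
CSV/JSON. Identical parameters (including the seed) produce
byte-identical output files, which is the package's reproducibility
contract and is enforced by a test.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from . import io_formats as iof
from . import sleep_architecture as arch
from . import spectral
from . import spindle_detection as spd
from . import coupling
from . import unit_activity as ua
from .synthetic_data import SimParams, simulate_hypnogram, simulate_recording, \
    simulate_spike_train

__all__ = ["run_pipeline"]


def _jsonable(x):
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, np.ndarray):
        return [_jsonable(v) for v in x.tolist()]
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    return x


def run_pipeline(params: SimParams, out_dir, analysis_role: str = "EEG_front",
                 pac_roles: tuple[str, str] = ("ACC", "AD")) -> dict:
    """Simulate, write, analyze, and write results under ``out_dir``.

    Returns the results dictionary that was written to
    ``results.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    hyp = simulate_hypnogram(params)
    rec, gt = simulate_recording(hyp, params)
    train, true_bursts = simulate_spike_train(hyp, params, unit_id="u0",
                                              region="TRN")

    iof.write_recording(rec, out / "recording.edf", format="edf")
    iof.write_hypnogram(hyp, out / "hypnogram.csv")
    iof.write_events(gt.true_spindles, out / "true_spindles.csv",
                     kind=iof.SpindleEvent)
    iof.write_events(true_bursts, out / "true_bursts.csv", kind=iof.BurstEvent)
    iof.write_spike_trains([train], out / "spikes.csv")

    sig = rec.get(analysis_role)

    episodes = arch.segment_episodes(hyp)
    summary = arch.architecture_summary(episodes, hyp)
    iof.write_events(episodes, out / "episodes.csv", kind=iof.Episode)

    psd = spectral.normalize_psd(
        spectral.welch_psd(sig, rec.fs, epochs=hyp, state="NREM"))
    bands = {b.name: spectral.band_power(psd, b)
             for b in (iof.SWA_BAND, iof.DELTA1_BAND, iof.DELTA2_BAND)}

    det = spd.SpindleDetectorParams()
    events = spd.detect_spindles(sig, rec.fs, hyp, det, channel=analysis_role)
    iof.write_events(events, out / "spindles.csv", kind=iof.SpindleEvent)
    sp_stats = spd.spindle_stats(events, hyp)

    xcorr = coupling.sw_spindle_crosscorr(sig, rec.fs, hyp)
    nrem_mask = hyp.sample_mask("NREM", rec.fs, rec.n_samples)
    ph, _ = coupling.extract_phase_and_envelope(rec.get(pac_roles[0]), rec.fs,
                                                iof.SWA_BAND)
    _, env = coupling.extract_phase_and_envelope(rec.get(pac_roles[1]), rec.fs,
                                                 iof.SPINDLE_BAND)
    pac = coupling.modulation_index(ph[nrem_mask], env[nrem_mask])

    bursts = ua.detect_bursts(train, ua.BurstCriteria(
        max_intraburst_isi_ms=params.intraburst_isi_ms,
        min_preceding_silence_ms=params.pre_burst_silence_ms))
    iof.write_events(bursts, out / "bursts.csv", kind=iof.BurstEvent)
    b_stats = ua.burst_stats(bursts, hyp, state="NREM")
    rates = ua.state_firing_rate(train, hyp)

    results = {
        "params": _jsonable(asdict(params)),
        "architecture": {
            "episodes_per_h": summary.episodes_per_h,
            "mean_episode_dur_s": summary.mean_episode_dur_s,
            "percent_time": summary.percent_time,
        },
        "band_power_normalized": bands,
        "spindles": sp_stats,
        "sw_spindle_xcorr": {"peak_lag_s": xcorr.peak_lag_s,
                             "peak_cc": xcorr.peak_cc,
                             "n_events": xcorr.n_events},
        "pac": {"mi": pac.mi,
                "preferred_phase_deg": pac.preferred_phase_deg,
                "bin_amp": _jsonable(pac.bin_amp)},
        "unit": {"state_rates_hz": rates,
                 "burst_stats": b_stats,
                 "n_true_bursts": len(true_bursts)},
    }
    results = _jsonable(results)
    (out / "results.json").write_text(
        json.dumps(results, indent=1, sort_keys=True) + "\n")
    return results
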