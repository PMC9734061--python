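"""Hypnogram-level sleep architecture: episodes, fragmentation metrics,
state latencies and time-in-state time courses.

Episode segmentation follows the scoring conventions of rodent
polysomnography: maximal runs of one label, an optional absorption rule
for brief interruptions, and a consolidation rule (a "stable" episode
must exceed a minimum duration, 20 s for NREM latency) for latencies.
Artifact epochs always break runs and are excluded from percent-time
denominators unless requested otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .io_formats import Episode, Hypnogram, ParameterError, VIGILANCE_STATES

__all__ = [
    "ArchitectureSummary",
    "segment_episodes",
    "architecture_summary",
    "latency_to_state",
    "timecourse_percent_state",
]


@dataclass
class ArchitectureSummary:
    """Per-state episode counts, durations and time shares over a window.

    ``episodes_per_h`` counts episodes *starting* inside the window;
    ``percent_time`` comes from epoch labels, so discarded short runs
    still contribute their time.
    """

    episodes_per_h: dict[str, float]
    mean_episode_dur_s: dict[str, float]
    percent_time: dict[str, float]
    window: tuple[float, float]


def _runs(hyp: Hypnogram) -> list[Episode]:
    labels = hyp.labels
    out = []
    i = 0
    while i < len(labels):
        j = i
        while j < len(labels) and labels[j] == labels[i]:
            j += 1
        out.append(Episode(state=str(labels[i]), start_s=i * hyp.epoch_s,
                           dur_s=(j - i) * hyp.epoch_s))
        i = j
    return out


def segment_episodes(hyp: Hypnogram, min_dur_s: float = 0.0,
                     interruption_s: float = 0.0) -> list[Episode]:
    """Segment a hypnogram into vigilance-state episodes.

    A run of a different state shorter than ``interruption_s`` that is
    flanked on both sides by the same state is absorbed into the
    surrounding episode (applied repeatedly until stable; Artifact runs
    are never absorbed and never absorb). Surviving episodes shorter
    than ``min_dur_s`` are then dropped from the returned list — their
    time still counts toward percent-time, which is computed from epoch
    labels, not episodes.

    ``min_dur_s = 0`` disables the duration filter; a nonzero value
    smaller than one epoch is a contradiction and raises.
    """
    if 0 < min_dur_s < hyp.epoch_s:
        raise ParameterError("min_dur_s must be 0 or at least one epoch")
    if interruption_s < 0:
        raise ParameterError("interruption_s must be >= 0")
    episodes = _runs(hyp)

    changed = True
    while changed and interruption_s > 0:
        changed = False
        for k in range(1, len(episodes) - 1):
            prev, cur, nxt = episodes[k - 1], episodes[k], episodes[k + 1]
            if (cur.dur_s < interruption_s and cur.state != "Artifact"
                    and prev.state == nxt.state and prev.state != "Artifact"
                    and cur.state != prev.state):
                merged = Episode(state=prev.state, start_s=prev.start_s,
                                 dur_s=prev.dur_s + cur.dur_s + nxt.dur_s)
                episodes = episodes[:k - 1] + [merged] + episodes[k + 2:]
                changed = True
                break

    if min_dur_s > 0:
        episodes = [e for e in episodes if e.dur_s >= min_dur_s]
    return episodes


def architecture_summary(episodes: list[Episode], hyp: Hypnogram,
                         window: Optional[tuple[float, float]] = None,
                         include_artifact_time: bool = False
                         ) -> ArchitectureSummary:
    """Episode rates, mean durations and time-in-state over ``window``.

    An episode counts toward the window containing its start. Percent
    time is computed from epoch labels within the window; Artifact
    epochs are excluded from the denominator unless
    ``include_artifact_time`` is set.
    """
    if window is None:
        window = (0.0, hyp.duration_s)
    w0, w1 = window
    if w1 <= w0:
        raise ParameterError(f"empty window {window}")
    hours = (w1 - w0) / 3600.0

    per_h, mean_dur = {}, {}
    for state in ("Wake", "NREM", "REM"):
        sel = [e for e in episodes if e.state == state and w0 <= e.start_s < w1]
        per_h[state] = len(sel) / hours
        mean_dur[state] = float(np.mean([e.dur_s for e in sel])) if sel else float("nan")

    e0 = int(np.ceil(w0 / hyp.epoch_s))
    e1 = min(int(np.floor(w1 / hyp.epoch_s)), hyp.n_epochs)
    lab = hyp.labels[e0:e1]
    denom = len(lab) if include_artifact_time else int(np.sum(lab != "Artifact"))
    pct = {}
    for state in ("Wake", "NREM", "REM"):
        pct[state] = 100.0 * np.sum(lab == state) / denom if denom else float("nan")
    return ArchitectureSummary(episodes_per_h=per_h, mean_episode_dur_s=mean_dur,
                               percent_time=pct, window=(w0, w1))


def latency_to_state(hyp: Hypnogram, ref_s: float, state: str,
                     min_stable_s: float = 20.0) -> Optional[float]:
    """Latency from ``ref_s`` to the first stable run of ``state``.

    A run qualifies when its duration from ``ref_s`` onward is at least
    ``min_stable_s`` (runs already in progress at ``ref_s`` count with
    their remaining duration). Returns ``None`` — never 0 — when no
    such run exists.
    """
    if min_stable_s < hyp.epoch_s:
        raise ParameterError("min_stable_s must be at least one epoch")
    if state not in VIGILANCE_STATES:
        raise ParameterError(f"unknown state {state!r}")
    if not 0 <= ref_s <= hyp.duration_s:
        raise ParameterError("ref_s outside hypnogram")
    for ep in _runs(hyp):
        if ep.state != state or ep.end_s <= ref_s:
            continue
        start = max(ep.start_s, ref_s)
        if ep.end_s - start >= min_stable_s:
            return start - ref_s
    return None


def timecourse_percent_state(hyp: Hypnogram, state: str, bin_s: float
                             ) -> list[tuple[float, float]]:
    """Per-bin percentage of time spent in ``state``.

    ``bin_s`` must be a multiple of the epoch length; the trailing
    partial bin, if any, is computed over the epochs it contains.
    """
    ratio = bin_s / hyp.epoch_s
    if abs(ratio - round(ratio)) > 1e-9 or bin_s <= 0:
        raise ParameterError("bin_s must be a positive multiple of epoch_s")
    per = int(round(ratio))
    mask = hyp.state_mask(state)
    out = []
    for i0 in range(0, hyp.n_epochs, per):
        chunk = mask[i0:i0 + per]
        out.append((i0 * hyp.epoch_s, 100.0 * float(np.mean(chunk))))
    return out
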