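"""On-disk formats and shared domain types for polysomnography analysis.

Signals travel as EDF (the polysomnography interchange standard, 16-bit)
or as a lossless float32 binary with a JSON sidecar; hypnograms, event
tables and spike tables are plain CSV; results are JSON.

Conventions used throughout the package:

* all event times are seconds from recording start (float); Zeitgeber
  time is carried only on :class:`Recording` as ``t0_zt``;
* intervals are half-open ``[start_s, end_s)`` so that tilings never
  double-count an epoch;
* channel roles (which electrode a channel label denotes) are resolved
  through a configurable regex mapping, not hard-coded labels.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "CorruptFileError",
    "ParameterError",
    "InsufficientDataError",
    "InsufficientEventsError",
    "VIGILANCE_STATES",
    "CHANNEL_ROLES",
    "DEFAULT_ROLE_PATTERNS",
    "Recording",
    "Hypnogram",
    "Episode",
    "BandDefinition",
    "SpindleEvent",
    "SpikeTrain",
    "BurstEvent",
    "read_recording",
    "write_recording",
    "read_hypnogram",
    "write_hypnogram",
    "read_events",
    "write_events",
    "read_spike_trains",
    "write_spike_trains",
    "pair_check",
]


class FormatError(ValueError):
    """A file does not satisfy the declared format contract."""


class CorruptFileError(FormatError):
    """A file is structurally inconsistent (e.g. unequal channel lengths)."""


class ParameterError(ValueError):
    """An analysis parameter violates its documented precondition."""


class InsufficientDataError(ValueError):
    """Not enough signal/epochs to compute the requested quantity."""


class InsufficientEventsError(ValueError):
    """Too few discrete events to compute the requested quantity."""


#: The vigilance-state alphabet scored in 1-s epochs from EEG + EMG.
VIGILANCE_STATES = ("Wake", "NREM", "REM", "Artifact")

#: Channel roles of the recording montage: two cortical EEG screws,
#: depth LFPs (anterior cingulate, anterodorsal thalamus, thalamic
#: reticular nucleus, barrel cortex, ventral posterolateral thalamus)
#: and nuchal EMG.
CHANNEL_ROLES = ("EEG_front", "EEG_par", "ACC", "AD", "TRN", "Brr", "VPL", "EMG")

#: Default label-regex -> role mapping.  Case-insensitive, matched in
#: order; override with the ``role_patterns`` argument of
#: :func:`read_recording` for other montages.
DEFAULT_ROLE_PATTERNS: dict[str, str] = {
    r"eeg[\s_-]*f": "EEG_front",
    r"eeg[\s_-]*p": "EEG_par",
    r"\bacc\b": "ACC",
    r"\bad\b": "AD",
    r"\btrn\b": "TRN",
    r"\bbrr\b": "Brr",
    r"\bvpl\b": "VPL",
    r"emg": "EMG",
}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Recording:
    """Multichannel electrophysiology signal block.

    Parameters
    ----------
    signals
        Array of shape ``(n_channels, n_samples)`` in microvolts.
    fs
        Sampling rate in Hz.
    channels
        Ordered channel labels.
    roles
        Role tag per channel, each drawn from :data:`CHANNEL_ROLES`;
        each role may appear at most once.
    t0_zt
        Recording start in Zeitgeber hours (lights-on = ZT0).
    """

    signals: np.ndarray
    fs: float
    channels: list[str]
    roles: list[str]
    t0_zt: float = 0.0

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim != 2:
            raise CorruptFileError("signals must be a (n_channels, n_samples) array")
        if self.fs <= 0:
            raise FormatError("sampling rate must be positive")
        n = self.signals.shape[0]
        if not (len(self.channels) == len(self.roles) == n):
            raise CorruptFileError("channel labels/roles do not match signal rows")
        bad = [r for r in self.roles if r not in CHANNEL_ROLES]
        if bad:
            raise FormatError(f"unknown channel roles {bad}; allowed: {CHANNEL_ROLES}")
        dup = {r for r in self.roles if self.roles.count(r) > 1}
        if dup:
            raise FormatError(f"duplicate channel roles {sorted(dup)}")

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def get(self, role: str) -> np.ndarray:
        """Return the signal of the channel carrying ``role``."""
        try:
            return self.signals[self.roles.index(role)]
        except ValueError:
            raise KeyError(f"recording has no channel with role {role!r}") from None


@dataclass
class Hypnogram:
    """Per-epoch vigilance labels; the temporal scaffold of every
    state-conditioned computation."""

    labels: np.ndarray
    epoch_s: float = 1.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        if self.epoch_s <= 0:
            raise FormatError("epoch_s must be positive")
        bad = sorted(set(self.labels) - set(VIGILANCE_STATES))
        if bad:
            raise FormatError(
                f"unknown vigilance labels {bad}; allowed alphabet: {VIGILANCE_STATES}"
            )

    @property
    def n_epochs(self) -> int:
        return len(self.labels)

    @property
    def duration_s(self) -> float:
        return self.n_epochs * self.epoch_s

    def state_mask(self, state: str) -> np.ndarray:
        """Boolean mask over epochs equal to ``state``."""
        if state not in VIGILANCE_STATES:
            raise ParameterError(f"unknown state {state!r}")
        return self.labels == state

    def sample_mask(self, state: str, fs: float, n_samples: Optional[int] = None) -> np.ndarray:
        """Expand the epoch mask for ``state`` to a per-sample mask at ``fs``."""
        per = int(round(self.epoch_s * fs))
        m = np.repeat(self.state_mask(state), per)
        if n_samples is not None:
            if len(m) < n_samples:
                m = np.concatenate([m, np.zeros(n_samples - len(m), dtype=bool)])
            m = m[:n_samples]
        return m


@dataclass(frozen=True)
class Episode:
    """Maximal run of one vigilance state."""

    state: str
    start_s: float
    dur_s: float

    @property
    def end_s(self) -> float:
        return self.start_s + self.dur_s


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band ``[lo_hz, hi_hz)``."""

    name: str
    lo_hz: float
    hi_hz: float

    def __post_init__(self) -> None:
        if not (0 <= self.lo_hz < self.hi_hz):
            raise ParameterError(
                f"band {self.name!r}: need 0 <= lo_hz < hi_hz, got ({self.lo_hz}, {self.hi_hz})"
            )

    def overlaps(self, other: "BandDefinition") -> bool:
        return self.lo_hz < other.hi_hz and other.lo_hz < self.hi_hz


# Canonical bands: slow-wave activity, the two delta sub-bands (the
# lower-edge variant of delta-2 that appears in some reports is provided
# alongside), theta and the spindle band.
SWA_BAND = BandDefinition("SWA", 0.5, 4.0)
DELTA1_BAND = BandDefinition("delta1", 0.75, 1.75)
DELTA2_BAND = BandDefinition("delta2", 2.75, 3.5)
DELTA2_BAND_WIDE = BandDefinition("delta2_wide", 2.5, 3.5)
THETA_BAND = BandDefinition("theta", 6.0, 9.0)
SPINDLE_BAND = BandDefinition("spindle", 10.0, 16.0)


@dataclass(frozen=True)
class SpindleEvent:
    """A detected (or injected) sleep spindle."""

    channel: str
    start_s: float
    end_s: float
    peak_amp_uv: float
    peak_freq_hz: float
    energy: float
    in_nrem: bool = True

    @property
    def dur_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def peak_s(self) -> float:
        return 0.5 * (self.start_s + self.end_s)


@dataclass
class SpikeTrain:
    """Spike times of one sorted unit."""

    unit_id: str
    region: str
    spike_times_s: np.ndarray

    def __post_init__(self) -> None:
        self.spike_times_s = np.asarray(self.spike_times_s, dtype=float)
        if self.spike_times_s.size and np.any(np.diff(self.spike_times_s) <= 0):
            raise FormatError(f"unit {self.unit_id}: spike times must be strictly increasing")

    @property
    def n_spikes(self) -> int:
        return self.spike_times_s.size


@dataclass(frozen=True)
class BurstEvent:
    """A high-frequency burst episode within one spike train."""

    start_s: float
    n_spikes: int
    dur_ms: float


# ---------------------------------------------------------------------------
# signal I/O (EDF and lossless binary + JSON sidecar)
# ---------------------------------------------------------------------------

def _resolve_roles(labels: Sequence[str], role_patterns: dict[str, str]) -> list[str]:
    roles = []
    for lab in labels:
        for pat, role in role_patterns.items():
            if re.search(pat, lab, flags=re.IGNORECASE):
                roles.append(role)
                break
        else:
            raise FormatError(f"channel label {lab!r} matches no role pattern")
    return roles


def _edf_field(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise FormatError(f"EDF header field {text!r} exceeds {width} bytes")
    return b.ljust(width)


def _write_edf(rec: Recording, path: Path) -> None:
    """Write an EDF file (16-bit, 1-s data records).

    No installed library exports EDF, so the writer is implemented here
    against the published header layout; round-trips are validated by
    reading back through :mod:`mne`.
    """
    fs = rec.fs
    spr = int(round(fs))
    if abs(spr - fs) > 1e-9:
        raise FormatError("EDF export requires an integer sampling rate")
    n_rec = rec.n_samples // spr
    if n_rec * spr != rec.n_samples:
        raise FormatError("EDF export requires a whole number of 1-s records")
    nch = len(rec.channels)

    pmaxs = []
    for sig in rec.signals:
        m = float(np.max(np.abs(sig))) if sig.size else 0.0
        # quantization step = 2*pmax/65535; keep pmax representable in 8 chars
        pmaxs.append(float(f"{max(m, 1e-3) * 1.0001:.6g}"))

    hdr = b""
    hdr += _edf_field("0", 8)                                   # version
    hdr += _edf_field("X X X X", 80)                            # patient id
    hdr += _edf_field(f"Startdate X ZT {rec.t0_zt:.4f}", 80)    # recording id
    hdr += _edf_field("01.01.01", 8) + _edf_field("00.00.00", 8)
    hdr += _edf_field(str(256 * (nch + 1)), 8)
    hdr += _edf_field("", 44)
    hdr += _edf_field(str(n_rec), 8)
    hdr += _edf_field("1", 8)                                   # record duration (s)
    hdr += _edf_field(str(nch), 4)
    cols = [
        [_edf_field(lab, 16) for lab in rec.channels],
        [_edf_field("", 80)] * nch,                             # transducer
        [_edf_field("uV", 8)] * nch,
        [_edf_field(f"{-p:.6g}", 8) for p in pmaxs],
        [_edf_field(f"{p:.6g}", 8) for p in pmaxs],
        [_edf_field("-32768", 8)] * nch,
        [_edf_field("32767", 8)] * nch,
        [_edf_field("", 80)] * nch,                             # prefilter
        [_edf_field(str(spr), 8)] * nch,
        [_edf_field("", 32)] * nch,
    ]
    for col in cols:
        hdr += b"".join(col)

    digital = []
    for sig, p in zip(rec.signals, pmaxs):
        d = np.round((sig + p) / (2 * p) * 65535.0 - 32768.0)
        digital.append(np.clip(d, -32768, 32767).astype("<i2"))
    with open(path, "wb") as fh:
        fh.write(hdr)
        for r in range(n_rec):
            for d in digital:
                fh.write(d[r * spr:(r + 1) * spr].tobytes())


def _read_edf(path: Path, role_patterns: dict[str, str]) -> Recording:
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    labels = list(raw.ch_names)
    data = raw.get_data(units="uV")
    t0_zt = 0.0
    m = re.search(rb"ZT ([0-9.+-eE]+)", _edf_recording_id(path))
    if m:
        t0_zt = float(m.group(1))
    return Recording(
        signals=np.asarray(data, dtype=float),
        fs=float(raw.info["sfreq"]),
        channels=labels,
        roles=_resolve_roles(labels, role_patterns),
        t0_zt=t0_zt,
    )


def _edf_recording_id(path: Path) -> bytes:
    with open(path, "rb") as fh:
        fh.seek(8 + 80)
        return fh.read(80)


def _write_binary(rec: Recording, path: Path) -> None:
    path = Path(path)
    meta = {
        "fs": rec.fs,
        "channels": rec.channels,
        "roles": rec.roles,
        "t0_zt": rec.t0_zt,
        "n_samples": rec.n_samples,
        "dtype": "float32",
    }
    rec.signals.astype("<f4").tofile(path)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))


def _read_binary(path: Path, role_patterns: dict[str, str]) -> Recording:
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise FormatError(f"missing JSON sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    data = np.fromfile(path, dtype="<f4")
    nch = len(meta["channels"])
    if data.size != nch * meta["n_samples"]:
        raise CorruptFileError(
            f"{path}: expected {nch}x{meta['n_samples']} samples, found {data.size}"
        )
    roles = meta.get("roles") or _resolve_roles(meta["channels"], role_patterns)
    return Recording(
        signals=data.reshape(nch, meta["n_samples"]).astype(float),
        fs=float(meta["fs"]),
        channels=list(meta["channels"]),
        roles=list(roles),
        t0_zt=float(meta.get("t0_zt", 0.0)),
    )


def read_recording(
    path,
    format: str = "edf",
    role_patterns: Optional[dict[str, str]] = None,
    require_roles: Sequence[str] = (),
) -> Recording:
    """Read a multichannel recording from disk.

    Parameters
    ----------
    path
        File path; ``<path>.json`` sidecar expected for binary format.
    format
        ``"edf"`` or ``"binary"`` (float32 + JSON sidecar).
    role_patterns
        Label-regex to role mapping; defaults to
        :data:`DEFAULT_ROLE_PATTERNS`.
    require_roles
        Roles that must be present; a missing one raises
        :class:`FormatError`.
    """
    patterns = role_patterns if role_patterns is not None else DEFAULT_ROLE_PATTERNS
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "edf":
        rec = _read_edf(path, patterns)
    elif format == "binary":
        rec = _read_binary(path, patterns)
    else:
        raise ParameterError(f"unknown recording format {format!r}")
    missing = [r for r in require_roles if r not in rec.roles]
    if missing:
        raise FormatError(f"recording lacks required channel roles {missing}")
    return rec


def write_recording(rec: Recording, path, format: str = "edf") -> None:
    """Write ``rec`` to disk as EDF (16-bit) or lossless binary."""
    path = Path(path)
    if format == "edf":
        _write_edf(rec, path)
    elif format == "binary":
        _write_binary(rec, path)
    else:
        raise ParameterError(f"unknown recording format {format!r}")


# ---------------------------------------------------------------------------
# hypnogram CSV
# ---------------------------------------------------------------------------

def read_hypnogram(path, epoch_s: float = 1.0) -> Hypnogram:
    """Read a hypnogram CSV with columns ``epoch_index,label``.

    Indices must be contiguous from 0 and labels drawn from
    :data:`VIGILANCE_STATES`.
    """
    df = pd.read_csv(path)
    if not {"epoch_index", "label"} <= set(df.columns):
        raise FormatError("hypnogram CSV must have columns epoch_index,label")
    idx = df["epoch_index"].to_numpy()
    if len(idx) == 0:
        raise FormatError("empty hypnogram")
    if not np.array_equal(idx, np.arange(len(idx))):
        raise FormatError("epoch_index must be contiguous integers starting at 0")
    labels = df["label"].astype(str).to_numpy()
    bad = sorted(set(labels) - set(VIGILANCE_STATES))
    if bad:
        raise FormatError(
            f"unknown vigilance labels {bad}; allowed alphabet: {VIGILANCE_STATES}"
        )
    return Hypnogram(labels=labels, epoch_s=epoch_s)


def write_hypnogram(hyp: Hypnogram, path) -> None:
    pd.DataFrame(
        {"epoch_index": np.arange(hyp.n_epochs), "label": hyp.labels}
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# event tables and spike tables
# ---------------------------------------------------------------------------

_EVENT_SCHEMAS = {
    SpindleEvent: ["channel", "start_s", "end_s", "dur_s", "peak_amp_uv",
                   "peak_freq_hz", "energy", "in_nrem"],
    BurstEvent: ["start_s", "n_spikes", "dur_ms"],
    Episode: ["state", "start_s", "dur_s"],
}


def write_events(events: Sequence, path, kind: Optional[type] = None) -> None:
    """Write a homogeneous event list to CSV with a stable column order.

    ``kind`` is required for an empty list (to pick the header); times
    are written with microsecond precision.
    """
    events = list(events)
    if events:
        kinds = {type(e) for e in events}
        if len(kinds) > 1:
            raise TypeError(f"mixed event kinds {sorted(k.__name__ for k in kinds)}")
        kind = kinds.pop()
    if kind is None or kind not in _EVENT_SCHEMAS:
        raise TypeError("kind must be SpindleEvent, BurstEvent or Episode")
    cols = _EVENT_SCHEMAS[kind]
    rows = [{c: getattr(e, c) for c in cols} for e in events]
    df = pd.DataFrame(rows, columns=cols)
    df.to_csv(path, index=False, float_format="%.6f")


def read_events(path, kind: type) -> list:
    """Read an event CSV written by :func:`write_events`."""
    if kind not in _EVENT_SCHEMAS:
        raise TypeError("kind must be SpindleEvent, BurstEvent or Episode")
    df = pd.read_csv(path)
    cols = _EVENT_SCHEMAS[kind]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    out = []
    for _, row in df.iterrows():
        kwargs = {c: row[c] for c in cols if c != "dur_s" or kind is Episode}
        if kind is SpindleEvent:
            kwargs["in_nrem"] = bool(row["in_nrem"])
        if kind is BurstEvent:
            kwargs["n_spikes"] = int(row["n_spikes"])
        out.append(kind(**kwargs))
    return out


def write_spike_trains(trains: Sequence[SpikeTrain], path) -> None:
    rows = []
    for tr in trains:
        for t in tr.spike_times_s:
            rows.append({"unit_id": tr.unit_id, "region": tr.region, "spike_time_s": t})
    pd.DataFrame(rows, columns=["unit_id", "region", "spike_time_s"]).to_csv(
        path, index=False, float_format="%.6f"
    )


def read_spike_trains(path) -> list[SpikeTrain]:
    df = pd.read_csv(path)
    need = {"unit_id", "region", "spike_time_s"}
    if not need <= set(df.columns):
        raise FormatError(f"spike CSV must have columns {sorted(need)}")
    out = []
    for (uid, region), grp in df.groupby(["unit_id", "region"], sort=True):
        out.append(SpikeTrain(str(uid), str(region),
                              np.sort(grp["spike_time_s"].to_numpy())))
    return out


def pair_check(rec: Recording, hyp: Hypnogram) -> None:
    """Fail loudly when recording and hypnogram durations disagree by
    more than one epoch."""
    if abs(rec.duration_s - hyp.duration_s) > hyp.epoch_s:
        raise FormatError(
            f"recording ({rec.duration_s:.1f} s) and hypnogram "
            f"({hyp.duration_s:.1f} s) differ by more than one epoch"
        )
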