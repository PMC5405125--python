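"""Recordings, force traces, gait events, and their file formats.

The native on-disk recording format is a flat binary matrix plus a JSON
sidecar describing shape, dtype, sampling rate, labels and sensor
positions.  EDF/BDF files are read through :mod:`mne` when it is
installed.  Event tables are tab-separated text with a
``sample<TAB>label`` header.

Gait events are detected from the vertical ground-reaction force: an
initial foot contact is the sample where the force first exceeds the
threshold (15 N by default) and a toe-off the sample where it drops
back below it.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "ForceSeries",
    "EventSeries",
    "detect_gait_events",
    "read_recording",
    "write_recording",
    "read_events",
    "write_events",
    "write_report",
]


@dataclass
class Recording:
    """Multichannel EEG matrix in microvolts.

    Parameters
    ----------
    data
        ``(n_channels, n_samples)`` array, μV.
    fs
        Sampling rate, Hz.
    labels
        Unique per-channel names; generated as ``E001…`` when omitted.
    positions
        Optional ``(n_channels, 2)`` or ``(n_channels, 3)`` sensor
        coordinates (arbitrary units, used only for neighbourhoods).
    condition
        Free-form tag, e.g. ``"eyes-open"`` or ``"blindfolded"``.
    """

    data: np.ndarray
    fs: float
    labels: Optional[Sequence[str]] = None
    positions: Optional[np.ndarray] = None
    condition: str = ""

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")
        if self.labels is None:
            self.labels = [f"E{i + 1:03d}" for i in range(self.data.shape[0])]
        self.labels = list(self.labels)
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("number of labels does not match channel count")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=float)
            if self.positions.shape[0] != self.data.shape[0]:
                raise ValueError("positions must have one row per channel")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, data: np.ndarray) -> "Recording":
        """Return a new recording with the same metadata and new samples."""
        return Recording(
            data=np.asarray(data, dtype=float),
            fs=self.fs,
            labels=list(self.labels),
            positions=None if self.positions is None else self.positions.copy(),
            condition=self.condition,
        )


@dataclass
class ForceSeries:
    """Vertical ground-reaction force in newtons at a fixed rate."""

    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    def __len__(self) -> int:
        return self.samples.size


@dataclass
class EventSeries:
    """Ordered event times as 0-based sample indices with string labels."""

    times: np.ndarray
    labels: Sequence[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.int64).ravel()
        if not self.labels:
            self.labels = ["EVT"] * self.times.size
        self.labels = list(self.labels)
        if len(self.labels) != self.times.size:
            raise ValueError("one label per event time is required")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            bad = int(np.flatnonzero(np.diff(self.times) <= 0)[0])
            raise ValueError(
                "event times must be strictly increasing; "
                f"violation at row {bad + 1} (time {self.times[bad + 1]} "
                f"after {self.times[bad]})"
            )

    def __len__(self) -> int:
        return self.times.size

    def with_label(self, label: str) -> "EventSeries":
        """Subset of events whose label equals ``label``."""
        keep = [i for i, lab in enumerate(self.labels) if lab == label]
        return EventSeries(self.times[keep], [self.labels[i] for i in keep])


def detect_gait_events(
    force: ForceSeries,
    threshold_newtons: float = 15.0,
    debounce_ms: float = 100.0,
    foot: str = "R",
) -> EventSeries:
    """Detect foot contacts and toe-offs from a ground-reaction force.

    A contact (``<foot>HS``) is an upward crossing of the threshold and a
    toe-off (``<foot>TO``) a downward crossing.  Any crossing within
    ``debounce_ms`` of the last accepted event is ignored — a minimum
    stance/swing duration that absorbs sensor chatter at the threshold —
    and strict contact/toe-off alternation is enforced starting from the
    first contact.
    """
    f = force.samples
    if f.size == 0:
        raise ValueError("force series is empty")
    if not np.all(np.isfinite(f)):
        raise ValueError("force series contains non-finite samples")
    above = f >= threshold_newtons
    flips = np.flatnonzero(np.diff(above.astype(np.int8)))
    debounce = int(round(debounce_ms / 1000.0 * force.fs))
    times: list[int] = []
    labels: list[str] = []
    last_accepted = None
    expect_contact = True
    for i in flips:
        t = int(i + 1)  # first sample on the new side of the threshold
        if last_accepted is not None and t - last_accepted < debounce:
            continue
        if above[t] != expect_contact:  # alternation: skip out-of-phase crossing
            continue
        times.append(t)
        labels.append(f"{foot}HS" if expect_contact else f"{foot}TO")
        last_accepted = t
        expect_contact = not expect_contact
    return EventSeries(np.array(times, dtype=np.int64), labels)


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------


def write_recording(recording: Recording, path: str | Path) -> Path:
    """Write a recording as raw binary + JSON sidecar.

    ``path`` is the sidecar path (``.json``); the matrix is stored next
    to it as little-endian float64, C order, in a ``.dat`` file.
    Returns the sidecar path.
    """
    path = Path(path)
    if path.suffix != ".json":
        path = path.with_suffix(".json")
    dat = path.with_suffix(".dat")
    arr = np.ascontiguousarray(recording.data, dtype="<f8")
    arr.tofile(dat)
    sidecar = {
        "format": "tcreject-flat",
        "data_file": dat.name,
        "dtype": "<f8",
        "order": "C",
        "shape": list(arr.shape),
        "fs": recording.fs,
        "unit": "uV",
        "labels": list(recording.labels),
        "positions": None
        if recording.positions is None
        else recording.positions.tolist(),
        "condition": recording.condition,
    }
    path.write_text(json.dumps(sidecar, indent=1))
    return path


def _read_flat(path: Path) -> Recording:
    meta = json.loads(path.read_text())
    if meta.get("format") != "tcreject-flat":
        raise ValueError(f"{path} is not a flat-recording sidecar")
    if meta.get("unit", "uV") != "uV":
        raise ValueError(f"unsupported unit {meta['unit']!r}; expected uV")
    dat = path.parent / meta["data_file"]
    data = np.fromfile(dat, dtype=meta["dtype"]).reshape(meta["shape"])
    pos = meta.get("positions")
    return Recording(
        data=data,
        fs=float(meta["fs"]),
        labels=meta["labels"],
        positions=None if pos is None else np.asarray(pos, dtype=float),
        condition=meta.get("condition", ""),
    )


def _read_edf(path: Path) -> Recording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise ImportError(
            "reading EDF/BDF requires the 'mne' package (tcreject[edf])"
        ) from exc
    reader = mne.io.read_raw_bdf if path.suffix.lower() == ".bdf" else mne.io.read_raw_edf
    raw = reader(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> microvolts
    return Recording(data=data, fs=float(raw.info["sfreq"]), labels=raw.ch_names)


def read_recording(path: str | Path, fmt: Optional[str] = None) -> Recording:
    """Read a recording from flat-binary sidecar or EDF/BDF.

    ``fmt`` may be ``"flat"``, ``"edf"`` or ``"bdf"``; by default it is
    inferred from the file extension.
    """
    path = Path(path)
    if fmt is None:
        fmt = {".json": "flat", ".edf": "edf", ".bdf": "bdf"}.get(path.suffix.lower())
        if fmt is None:
            raise ValueError(f"cannot infer recording format from {path.name!r}")
    if fmt == "flat":
        return _read_flat(path)
    if fmt in ("edf", "bdf"):
        return _read_edf(path)
    raise ValueError(f"unknown recording format {fmt!r}")


def write_events(events: EventSeries, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"sample": events.times, "label": events.labels}).to_csv(
        path, sep="\t", index=False
    )
    return path


def read_events(path: str | Path) -> EventSeries:
    """Read a ``sample<TAB>label`` table; rejects non-monotonic times."""
    table = pd.read_csv(path, sep="\t")
    if "sample" not in table.columns:
        raise ValueError(f"{path}: missing required 'sample' column")
    labels = (
        table["label"].astype(str).tolist()
        if "label" in table.columns
        else ["EVT"] * len(table)
    )
    return EventSeries(table["sample"].to_numpy(dtype=np.int64), labels)


def write_report(decisions, path: str | Path) -> Path:
    """Serialize one or more decision records to JSON.

    ``decisions`` may be a single decision object (anything exposing
    ``to_dict``), a mapping of names to such objects, or a plain dict.
    """
    path = Path(path)

    def _conv(obj):
        if hasattr(obj, "to_dict"):
            return obj.to_dict()
        if isinstance(obj, dict):
            return {k: _conv(v) for k, v in obj.items()}
        return obj

    payload = _conv(decisions)
    path.write_text(json.dumps(payload, indent=1, default=_json_default))
    return path


def _json_default(obj):
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
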