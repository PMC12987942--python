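"""Data model, container I/O and stimulus-locked segmentation.

A microneurography recording is a single extracellular voltage trace (µV,
nominally sampled at 10 kHz) together with the onsets of the electrical
stimuli that were delivered during the experiment.  Low-frequency
"background" pulses (one every ~4 s) evoke exactly one time-locked spike per
activated C-fiber; "additional" pulses inserted between them mimic extra
fiber activity.  Segmenting the trace at stimulus onsets aligns each fiber's
responses at a near-constant latency — the vertical *tracks* of the marking
method.

Two segmentation modes are provided:

* ``segment_marking`` cuts only at background onsets (fixed ~4 s windows);
  additional pulses do not cut.
* ``segment_ground_truth`` cuts before *every* pulse, producing
  variable-length windows so that every electrically evoked spike is
  time-locked to its own stimulus.

All event times are absolute seconds from the recording start, sample
indices are 0-based, and windows are half-open ``[start, end)``.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np
import pandas as pd

from ._errors import EmptyInputError, FormatError, ValidationError

__all__ = [
    "StimulusEvent",
    "SpikeAnnotation",
    "SegmentWindow",
    "Track",
    "Recording",
    "read_recording",
    "write_recording",
    "segment_marking",
    "segment_ground_truth",
    "compute_latencies",
    "classify_spike_origin",
    "BACKGROUND_SPLIT_S",
]

#: Minimum inter-spike interval (s) for a spike to count as background-evoked,
#: consistent with the 4 s background stimulation period.
BACKGROUND_SPLIT_S = 3.8

STIMULUS_KINDS = ("background", "additional")
ORIGIN_KINDS = ("background_evoked", "additional_evoked", "other")


@dataclass(frozen=True)
class StimulusEvent:
    """A single electrical stimulation pulse."""

    time: float
    kind: str = "background"

    def __post_init__(self) -> None:
        if self.kind not in STIMULUS_KINDS:
            raise ValidationError(f"unknown stimulus kind {self.kind!r}")


@dataclass(frozen=True)
class SpikeAnnotation:
    """A ground-truth spike timestamp with its fiber (track) label."""

    time: float
    track: str
    origin: str = "other"

    def __post_init__(self) -> None:
        if self.origin not in ORIGIN_KINDS:
            raise ValidationError(f"unknown spike origin {self.origin!r}")


@dataclass(frozen=True)
class SegmentWindow:
    """Half-open window ``[start, end)`` defined by one stimulus."""

    start: float
    end: float
    stimulus_index: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValidationError(
                f"window start {self.start} must precede end {self.end}"
            )

    def __contains__(self, t: float) -> bool:
        return self.start <= t < self.end


@dataclass
class Track:
    """One labeled fiber: ordered spike times with per-spike latencies (ms)."""

    label: str
    spike_times: np.ndarray
    latencies: np.ndarray

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        self.latencies = np.asarray(self.latencies, dtype=float)
        if len(self.spike_times) != len(self.latencies):
            raise ValidationError("spike_times and latencies must be equal length")
        if np.any(np.diff(self.spike_times) <= 0):
            raise ValidationError(f"track {self.label!r}: spike times must increase")
        finite = self.latencies[np.isfinite(self.latencies)]
        if np.any(finite <= 0):
            raise ValidationError(f"track {self.label!r}: latencies must be > 0")


@dataclass
class Recording:
    """A continuous voltage trace plus stimulus events and optional annotations.

    Parameters
    ----------
    samples
        Voltage samples in µV.
    rate
        Sampling frequency in Hz (nominally 10 000).
    t0
        Absolute start time of the recording in seconds (0 by convention).
    stimuli
        Stimulation pulses, strictly increasing in time.
    annotations
        Optional ground-truth spikes (time, track label, origin).
    """

    samples: np.ndarray
    rate: float = 10_000.0
    t0: float = 0.0
    stimuli: list[StimulusEvent] = field(default_factory=list)
    annotations: list[SpikeAnnotation] | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValidationError("samples must be a 1-D voltage series")
        if not self.rate > 0:
            raise ValidationError("sampling rate must be positive")
        times = self.stimulus_times
        if len(times) and np.any(np.diff(times) <= 0):
            raise ValidationError("stimulus times must be strictly increasing")
        end = self.t0 + self.duration
        if len(times) and (times[0] < self.t0 or times[-1] > end):
            raise ValidationError("stimulus times fall outside the recording span")
        if self.annotations:
            ann = np.array([a.time for a in self.annotations])
            if ann.min() < self.t0 or ann.max() > end:
                raise ValidationError("annotation times fall outside the recording")

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return len(self.samples) / self.rate

    @property
    def stimulus_times(self) -> np.ndarray:
        return np.array([s.time for s in self.stimuli], dtype=float)

    @property
    def stimulus_kinds(self) -> np.ndarray:
        return np.array([s.kind for s in self.stimuli], dtype=object)

    def sample_index(self, t: float) -> int:
        """Nearest sample index for absolute time ``t`` (seconds)."""
        return int(round((t - self.t0) * self.rate))

    def annotation_frame(self) -> pd.DataFrame:
        """Annotations as a DataFrame (time_s, track, origin)."""
        if not self.annotations:
            return pd.DataFrame(columns=["time_s", "track", "origin"])
        return pd.DataFrame(
            {
                "time_s": [a.time for a in self.annotations],
                "track": [a.track for a in self.annotations],
                "origin": [a.origin for a in self.annotations],
            }
        )


# ---------------------------------------------------------------------------
# Container I/O
#
# HDF5 layout: /signal/samples [float32, µV] with attrs rate, t0;
#              /stimuli/time [s], /stimuli/kind;
#              /annotations/time [s], /annotations/track, /annotations/origin.
# CSV dialect (hand-editable fixtures): a directory with signal.csv
# (sample_index,voltage_uV; header comment carries rate/t0), stimuli.csv
# (time_s,kind) and optional annotations.csv (time_s,track,origin).
# ---------------------------------------------------------------------------


def _infer_format(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    p = Path(path)
    if p.suffix.lower() in (".h5", ".hdf5"):
        return "hdf5"
    return "csv"


def write_recording(rec: Recording, path: str | Path, format: str | None = None) -> None:
    """Persist a recording to the neutral HDF5 or 3-file CSV container."""
    fmt = _infer_format(path, format)
    if fmt == "hdf5":
        _write_hdf5(rec, Path(path))
    elif fmt == "csv":
        _write_csv(rec, Path(path))
    else:
        raise FormatError(f"unknown container format {fmt!r}")


def read_recording(path: str | Path, format: str | None = None) -> Recording:
    """Load and validate a recording from the HDF5 or CSV container."""
    fmt = _infer_format(path, format)
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file or directory: {path}")
    if fmt == "hdf5":
        return _read_hdf5(path)
    if fmt == "csv":
        return _read_csv(path)
    raise FormatError(f"unknown container format {fmt!r}")


def _write_hdf5(rec: Recording, path: Path) -> None:
    with h5py.File(path, "w") as f:
        sig = f.create_group("signal")
        sig.create_dataset("samples", data=rec.samples.astype(np.float32))
        sig.attrs["rate"] = float(rec.rate)
        sig.attrs["t0"] = float(rec.t0)
        sig.attrs["units"] = "uV"
        stim = f.create_group("stimuli")
        stim.create_dataset("time", data=rec.stimulus_times)
        stim.create_dataset(
            "kind", data=np.array([s.kind for s in rec.stimuli], dtype="S16")
        )
        if rec.annotations is not None:
            ann = f.create_group("annotations")
            ann.create_dataset("time", data=[a.time for a in rec.annotations])
            ann.create_dataset(
                "track", data=np.array([a.track for a in rec.annotations], dtype="S64")
            )
            ann.create_dataset(
                "origin",
                data=np.array([a.origin for a in rec.annotations], dtype="S32"),
            )


def _require(f: h5py.File, key: str):
    if key not in f:
        raise FormatError(f"container is missing required dataset {key!r}")
    return f[key]


def _read_hdf5(path: Path) -> Recording:
    with h5py.File(path, "r") as f:
        sig = _require(f, "signal")
        samples = np.asarray(_require(sig, "samples"), dtype=float)
        if "rate" not in sig.attrs:
            raise FormatError("container is missing required attribute signal/rate")
        rate = float(sig.attrs["rate"])
        t0 = float(sig.attrs.get("t0", 0.0))
        stim = _require(f, "stimuli")
        times = np.asarray(_require(stim, "time"), dtype=float)
        kinds = [k.decode() for k in np.asarray(_require(stim, "kind"))]
        stimuli = [StimulusEvent(t, k) for t, k in zip(times, kinds)]
        annotations = None
        if "annotations" in f:
            ann = f["annotations"]
            annotations = [
                SpikeAnnotation(float(t), tr.decode(), o.decode())
                for t, tr, o in zip(ann["time"], ann["track"], ann["origin"])
            ]
    return Recording(samples, rate=rate, t0=t0, stimuli=stimuli, annotations=annotations)


def _write_csv(rec: Recording, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    with open(path / "signal.csv", "w", newline="") as fh:
        fh.write(f"# rate_hz={rec.rate!r} t0_s={rec.t0!r}\n")
        w = csv.writer(fh)
        w.writerow(["sample_index", "voltage_uV"])
        for i, v in enumerate(rec.samples):
            w.writerow([i, repr(float(v))])
    with open(path / "stimuli.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_s", "kind"])
        for s in rec.stimuli:
            w.writerow([repr(s.time), s.kind])
    if rec.annotations is not None:
        with open(path / "annotations.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["time_s", "track", "origin"])
            for a in rec.annotations:
                w.writerow([repr(a.time), a.track, a.origin])


def _read_csv(path: Path) -> Recording:
    if not path.is_dir():
        raise FormatError(f"CSV container must be a directory: {path}")
    sig_path = path / "signal.csv"
    if not sig_path.exists():
        raise FormatError("container is missing signal.csv")
    with open(sig_path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise FormatError("signal.csv is missing the '# rate_hz=... t0_s=...' header")
        meta = dict(tok.split("=") for tok in header[1:].split())
        if "rate_hz" not in meta:
            raise FormatError("signal.csv header is missing rate_hz")
        rate = float(meta["rate_hz"])
        t0 = float(meta.get("t0_s", 0.0))
        frame = pd.read_csv(fh)
    if "voltage_uV" not in frame.columns:
        raise FormatError("signal.csv is missing column voltage_uV")
    samples = frame["voltage_uV"].to_numpy(dtype=float)
    stim_path = path / "stimuli.csv"
    if not stim_path.exists():
        raise FormatError("container is missing stimuli.csv")
    sf = pd.read_csv(stim_path)
    for col in ("time_s", "kind"):
        if col not in sf.columns:
            raise FormatError(f"stimuli.csv is missing column {col}")
    stimuli = [StimulusEvent(float(t), str(k)) for t, k in zip(sf.time_s, sf.kind)]
    annotations = None
    ann_path = path / "annotations.csv"
    if ann_path.exists():
        af = pd.read_csv(ann_path)
        annotations = [
            SpikeAnnotation(float(t), str(tr), str(o))
            for t, tr, o in zip(af.time_s, af.track, af.origin)
        ]
    return Recording(samples, rate=rate, t0=t0, stimuli=stimuli, annotations=annotations)


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------


def _windows_from_onsets(onsets: np.ndarray, indices: np.ndarray, rec_end: float) -> list[SegmentWindow]:
    windows = []
    for j, (t, i) in enumerate(zip(onsets, indices)):
        end = onsets[j + 1] if j + 1 < len(onsets) else rec_end
        windows.append(SegmentWindow(float(t), float(end), int(i)))
    return windows


def segment_marking(rec: Recording) -> list[SegmentWindow]:
    """Cut the trace at background stimulus onsets only.

    One window per background stimulus, from its onset to the next
    background onset; the last window extends to the end of the recording.
    Additional pulses do not cut windows.
    """
    kinds = rec.stimulus_kinds
    idx = np.flatnonzero(kinds == "background")
    if len(idx) == 0:
        raise EmptyInputError("recording has no background stimuli")
    onsets = rec.stimulus_times[idx]
    return _windows_from_onsets(onsets, idx, rec.t0 + rec.duration)


def segment_ground_truth(rec: Recording) -> list[SegmentWindow]:
    """Cut the trace before every stimulus, background and additional alike.

    Produces variable-length windows that tile the stimulated span, so that
    any evoked spike is aligned to the pulse that caused it.  With no
    additional pulses present this reduces exactly to ``segment_marking``.
    """
    if len(rec.stimuli) == 0:
        raise EmptyInputError("recording has no stimuli")
    onsets = rec.stimulus_times
    return _windows_from_onsets(onsets, np.arange(len(onsets)), rec.t0 + rec.duration)


def compute_latencies(
    spike_times: Sequence[float],
    windows: Sequence[SegmentWindow],
    stimuli: Sequence[StimulusEvent],
) -> pd.DataFrame:
    """Latency (ms) of each spike relative to its window-defining stimulus.

    Returns a DataFrame with columns ``spike_time``, ``window_index``,
    ``stimulus_index`` and ``latency_ms``.  A spike falling before the first
    window (or after the last) gets ``window_index`` -1 and NaN latency —
    flagged, not dropped.
    """
    times = np.asarray(spike_times, dtype=float)
    starts = np.array([w.start for w in windows])
    rows = []
    for t in times:
        k = int(np.searchsorted(starts, t, side="right")) - 1
        if k < 0 or t >= windows[k].end:
            rows.append((t, -1, -1, np.nan))
            continue
        stim = stimuli[windows[k].stimulus_index]
        rows.append((t, k, windows[k].stimulus_index, (t - stim.time) * 1000.0))
    return pd.DataFrame(
        rows, columns=["spike_time", "window_index", "stimulus_index", "latency_ms"]
    )


def classify_spike_origin(
    spike_times: Sequence[float], split_s: float = BACKGROUND_SPLIT_S
) -> np.ndarray:
    """Label each spike of one track as background- or additional-evoked.

    A spike is background-evoked iff the interval to the previous spike in
    the track is at least ``split_s`` (default 3.8 s, consistent with the
    4 s stimulation period).  The first spike is background-evoked by
    convention: the first response in these protocols is always to a
    background pulse.
    """
    times = np.asarray(spike_times, dtype=float)
    if len(times) == 0:
        return np.array([], dtype=object)
    if np.any(np.diff(times) <= 0):
        raise ValidationError("spike times must be strictly increasing")
    origins = np.empty(len(times), dtype=object)
    origins[0] = "background_evoked"
    gaps = np.diff(times)
    origins[1:] = np.where(gaps >= split_s, "background_evoked", "additional_evoked")
    return origins
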