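"""Knowledge-constrained threshold spike detection.

Detection is deliberately split from sorting: a permissive amplitude
threshold finds candidate peaks with high recall, while two knowledge-driven
constraints cut the false-positive load:

* **Latency-jump gating** — activity-dependent conduction-velocity slowing
  (ADS) delays a fiber's response to the *subsequent* background pulse.  Any
  background-response latency exceeding a running baseline by more than the
  minimal latency deviation (0.9 ms) therefore implicates the *preceding*
  4 s interval as one containing extra activity; only those intervals are
  searched.
* **Artifact blanking** — peaks within 100 ms of a window's stimulus onset
  are discarded as stimulation artifacts.

The threshold itself is suggested from the sorted background-evoked peak
amplitudes of the track of interest (smallest amplitude), falling back to a
manual choice when their coefficient of variation is high.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from ._errors import EmptyInputError, InsufficientDataError, ValidationError
from .recording_model import Recording, SegmentWindow

__all__ = [
    "DetectionConfig",
    "DetectedPeak",
    "ThresholdSuggestion",
    "WindowFlag",
    "suggest_threshold",
    "constrain_search_space",
    "detect_peaks",
]

POLARITIES = ("positive", "negative", "absolute")


@dataclass
class DetectionConfig:
    """Threshold detector parameters.

    ``threshold`` is in µV (always positive; ``polarity`` selects the sign
    convention), ``artifact_blank_ms`` suppresses the post-stimulus artifact
    window, ``latency_jump_ms`` is the minimal latency deviation used for
    search-space gating, and ``min_peak_separation_ms`` enforces a minimum
    spacing between accepted peaks (well below the ≥5 ms interval implied by
    the <200 Hz C-fiber firing bound, since distinct fibers may fire closer).
    """

    threshold: float
    polarity: str = "positive"
    artifact_blank_ms: float = 100.0
    latency_jump_ms: float = 0.9
    min_peak_separation_ms: float = 1.0

    def __post_init__(self) -> None:
        if not self.threshold > 0:
            raise ValidationError("threshold must be positive")
        if self.polarity not in POLARITIES:
            raise ValidationError(f"unknown polarity {self.polarity!r}")
        if self.artifact_blank_ms < 0:
            raise ValidationError("artifact_blank_ms must be >= 0")
        if not self.latency_jump_ms > 0:
            raise ValidationError("latency_jump_ms must be > 0")


@dataclass(frozen=True)
class DetectedPeak:
    """A suprathreshold local extremum inside a flagged window."""

    time: float
    amplitude: float
    window_index: int


@dataclass
class ThresholdSuggestion:
    sorted_amplitudes: np.ndarray
    suggested: float
    high_variance: bool
    cv: float


@dataclass(frozen=True)
class WindowFlag:
    """A window marked for spike search; ``uncertain`` marks windows without
    a background response, which inherit the previous latency baseline."""

    index: int
    uncertain: bool = False


def suggest_threshold(
    background_peak_amplitudes: Sequence[float], cv_cutoff: float = 0.3
) -> ThresholdSuggestion:
    """Sort background peak amplitudes ascending and suggest the smallest.

    When the coefficient of variation exceeds ``cv_cutoff`` the distribution
    is too broad for the minimum rule and ``high_variance`` is set so the
    caller can supply a manual threshold instead.
    """
    amps = np.sort(np.asarray(background_peak_amplitudes, dtype=float))
    if amps.size == 0:
        raise EmptyInputError("no background peak amplitudes")
    mean = float(amps.mean())
    cv = float(amps.std() / mean) if mean != 0 else np.inf
    return ThresholdSuggestion(
        sorted_amplitudes=amps,
        suggested=float(amps[0]),
        high_variance=bool(cv > cv_cutoff),
        cv=cv,
    )


def constrain_search_space(
    track_latencies_ms: Sequence[float],
    latency_jump_ms: float = 0.9,
    baseline_width: int = 5,
) -> list[WindowFlag]:
    """Flag windows whose *following* background response is delayed.

    ``track_latencies_ms`` holds one latency per segmentation window for the
    track of interest (NaN where the track did not respond).  Window ``k``
    is flagged when the latency of the next responded window exceeds the
    running baseline by more than ``latency_jump_ms``: ADS causality places
    the extra activity in the interval *preceding* the delayed response.
    The baseline is the running median of the last ``baseline_width``
    latencies that did not themselves jump, which tolerates slow drift.
    Windows without a response are flagged as ``uncertain`` and searched.
    """
    lat = np.asarray(track_latencies_ms, dtype=float)
    responded = np.flatnonzero(np.isfinite(lat))
    if len(responded) < 2:
        raise InsufficientDataError("need at least 2 responded windows")
    flagged: dict[int, bool] = {}
    for k in range(len(lat)):
        if not np.isfinite(lat[k]):
            flagged[k] = True  # uncertain: no response to gate on
    clean: deque[float] = deque(maxlen=max(1, baseline_width))
    clean.append(float(lat[responded[0]]))
    for j in range(len(responded) - 1):
        k, k_next = int(responded[j]), int(responded[j + 1])
        baseline = float(np.median(clean))
        if lat[k_next] - baseline > latency_jump_ms:
            flagged.setdefault(k, False)
        else:
            clean.append(float(lat[k_next]))
    return [WindowFlag(k, uncertain=flagged[k]) for k in sorted(flagged)]


def detect_peaks(
    rec: Recording,
    windows: Sequence[SegmentWindow],
    flagged: Sequence[WindowFlag | int],
    cfg: DetectionConfig,
) -> list[DetectedPeak]:
    """Threshold peak detection restricted to flagged windows.

    A peak is a local extremum under the configured polarity whose magnitude
    meets the threshold, at least ``min_peak_separation_ms`` from any higher
    accepted peak, and at least ``artifact_blank_ms`` after the stimulus
    onset of its window.  Reported amplitudes are raw (signed) sample
    values; reported times are the extremum sample times.
    """
    if len(flagged) == 0:
        warnings.warn("no flagged windows: nothing to search", stacklevel=2)
        return []
    indices = [f.index if isinstance(f, WindowFlag) else int(f) for f in flagged]
    distance = max(1, int(round(cfg.min_peak_separation_ms * rec.rate / 1000.0)))
    peaks: list[DetectedPeak] = []
    for k in indices:
        w = windows[k]
        s0 = max(0, rec.sample_index(w.start + cfg.artifact_blank_ms / 1000.0))
        s1 = min(len(rec.samples), rec.sample_index(w.end))
        if s1 - s0 < 3:
            continue
        seg = rec.samples[s0:s1]
        if cfg.polarity == "positive":
            sig = seg
        elif cfg.polarity == "negative":
            sig = -seg
        else:
            sig = np.abs(seg)
        loc, _ = find_peaks(sig, height=cfg.threshold, distance=distance)
        for p in loc:
            peaks.append(
                DetectedPeak(
                    time=rec.t0 + (s0 + int(p)) / rec.rate,
                    amplitude=float(seg[p]),
                    window_index=k,
                )
            )
    return peaks
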