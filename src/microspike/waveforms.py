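"""Spike waveform extraction, templates and pre-sorting quality indices.

Waveforms are fixed 30-sample snippets (3 ms at 10 kHz) aligned on the
largest downward slope, i.e. the negative peak of the first difference of
the raw trace.  Per-track mean waveforms (templates) drive track-of-interest
selection, MAD-based SNR, a begin/middle/end drift check, and pairwise
template distances (MSE/RMSE/MAE) used as sortability indicators: the more
similar two fiber templates, the poorer the expected sorting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._errors import (
    BoundaryError,
    DegenerateSignalError,
    EmptyInputError,
    InsufficientDataError,
)
from .recording_model import Recording

__all__ = [
    "WAVEFORM_LEN",
    "MAD_SCALE",
    "SpikeWaveform",
    "Template",
    "SnrResult",
    "DriftResult",
    "TemplateDistances",
    "QualityReport",
    "extract_and_align",
    "compute_template",
    "compute_snr",
    "drift_test",
    "template_distances",
    "select_track_of_interest",
]

#: Snippet length in samples: 3 ms at the nominal 10 kHz sampling rate.
WAVEFORM_LEN = 30

#: Gaussian-consistency constant relating MAD to the standard deviation.
MAD_SCALE = 0.6745


@dataclass
class SpikeWaveform:
    """A 30-sample aligned snippet of the voltage trace (µV)."""

    values: np.ndarray
    center_index: int
    source_time: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (WAVEFORM_LEN,):
            raise ValueError(f"waveform must have exactly {WAVEFORM_LEN} samples")
        if not 0 <= self.center_index < WAVEFORM_LEN:
            raise ValueError("center_index out of range")


@dataclass
class Template:
    """Per-track mean waveform; amplitude is the max absolute value (µV)."""

    values: np.ndarray
    n_spikes: int
    track: str | None = None
    amplitude: float = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.n_spikes < 1:
            raise ValueError("template must average at least one spike")
        self.amplitude = float(np.max(np.abs(self.values)))


@dataclass
class SnrResult:
    snr: float
    noise_sd: float


@dataclass
class DriftResult:
    """Begin/middle/end templates plus the maximal pairwise RMSE between them."""

    templates: tuple[Template, Template, Template]
    drift_rmse: float
    subset_sizes: tuple[int, int, int]


@dataclass
class TemplateDistances:
    """Pairwise MSE/RMSE/MAE matrices over templates and their off-diagonal minima."""

    labels: list[str]
    mse: np.ndarray
    rmse: np.ndarray
    mae: np.ndarray
    min_distance: dict[str, float]


@dataclass
class QualityReport:
    track: str
    snr: float
    noise_sd: float
    drift: DriftResult | None
    distances: TemplateDistances | None

    def to_dict(self) -> dict:
        out: dict = {"track": self.track, "snr": self.snr, "noise_sd": self.noise_sd}
        if self.drift is not None:
            out["drift_rmse"] = self.drift.drift_rmse
            out["drift_subset_sizes"] = list(self.drift.subset_sizes)
            out["drift_amplitudes"] = [t.amplitude for t in self.drift.templates]
        if self.distances is not None:
            out["template_labels"] = list(self.distances.labels)
            out["min_template_distance"] = dict(self.distances.min_distance)
        return out


def extract_and_align(
    rec: Recording, t: float, search_halfwidth_ms: float = 1.0
) -> SpikeWaveform:
    """Extract the 30-sample snippet centered on the largest downward slope.

    Within ``t`` ± ``search_halfwidth_ms`` the sample minimizing the forward
    first difference of the raw trace is located; the snippet spans 15
    samples before to 14 after it (``center_index`` = 15).  Raises
    :class:`BoundaryError` if the window would clip the recording edge and
    :class:`DegenerateSignalError` on a flat segment.
    """
    i = rec.sample_index(t)
    hw = max(1, int(round(search_halfwidth_ms * rec.rate / 1000.0)))
    half = WAVEFORM_LEN // 2
    lo, hi = i - hw, i + hw
    if lo < 0 or hi + 1 >= len(rec.samples):
        raise BoundaryError("alignment search region clipped by recording edge")
    diffs = np.diff(rec.samples[lo : hi + 2])
    if np.allclose(diffs, 0.0):
        raise DegenerateSignalError("flat signal: alignment is undefined")
    center = lo + int(np.argmin(diffs))
    if center - half < 0 or center + half > len(rec.samples):
        raise BoundaryError("waveform window clipped by recording edge")
    values = rec.samples[center - half : center + half].copy()
    return SpikeWaveform(
        values=values, center_index=half, source_time=rec.t0 + center / rec.rate
    )


def compute_template(
    waveforms: Sequence[SpikeWaveform], track: str | None = None
) -> Template:
    """Element-wise mean of aligned waveforms."""
    if len(waveforms) == 0:
        raise EmptyInputError("cannot build a template from zero waveforms")
    stack = np.stack([w.values for w in waveforms])
    return Template(values=stack.mean(axis=0), n_spikes=len(waveforms), track=track)


def compute_snr(template: Template, noise: np.ndarray) -> SnrResult:
    """Template amplitude over the MAD-estimated noise standard deviation.

    ``noise`` should be a ~40 ms segment taken before the first evoked spike
    so it is free of fiber activity.  ``noise_sd = MAD(noise) / 0.6745``.
    """
    noise = np.asarray(noise, dtype=float)
    if noise.size == 0:
        raise EmptyInputError("empty noise segment")
    mad = float(np.median(np.abs(noise - np.median(noise))))
    if mad == 0.0:
        raise DegenerateSignalError("noise MAD is zero; SNR undefined")
    noise_sd = mad / MAD_SCALE
    return SnrResult(snr=template.amplitude / noise_sd, noise_sd=noise_sd)


def drift_test(track_waveforms: Sequence[SpikeWaveform]) -> DriftResult:
    """Compare begin/middle/end templates of one track.

    The temporally ordered waveforms are split into three contiguous subsets
    of near-equal size (remainders go to the earliest subsets); the drift
    score is the maximal pairwise RMSE between the three templates.
    """
    if len(track_waveforms) < 3:
        raise InsufficientDataError("drift test needs at least 3 waveforms")
    parts = np.array_split(np.arange(len(track_waveforms)), 3)
    templates = tuple(
        compute_template([track_waveforms[i] for i in idx]) for idx in parts
    )
    rmse = 0.0
    for a in range(3):
        for b in range(a + 1, 3):
            d = templates[a].values - templates[b].values
            rmse = max(rmse, float(np.sqrt(np.mean(d**2))))
    return DriftResult(
        templates=templates,
        drift_rmse=rmse,
        subset_sizes=tuple(len(p) for p in parts),
    )


def template_distances(templates: Sequence[Template]) -> TemplateDistances:
    """Pairwise MSE, RMSE and MAE between (background-evoked) templates.

    The minimum over off-diagonal pairs is retained per metric as an
    indicator of the most overlapping — least sortable — template pair.
    """
    if len(templates) < 2:
        raise InsufficientDataError("need at least 2 templates for distances")
    k = len(templates)
    mse = np.zeros((k, k))
    mae = np.zeros((k, k))
    for a in range(k):
        for b in range(a + 1, k):
            d = templates[a].values - templates[b].values
            mse[a, b] = mse[b, a] = float(np.mean(d**2))
            mae[a, b] = mae[b, a] = float(np.mean(np.abs(d)))
    rmse = np.sqrt(mse)
    off = ~np.eye(k, dtype=bool)
    labels = [t.track if t.track is not None else f"T{i}" for i, t in enumerate(templates)]
    return TemplateDistances(
        labels=labels,
        mse=mse,
        rmse=rmse,
        mae=mae,
        min_distance={
            "mse": float(mse[off].min()),
            "rmse": float(rmse[off].min()),
            "mae": float(mae[off].min()),
        },
    )


def select_track_of_interest(templates: Sequence[Template]) -> str:
    """Label of the highest-amplitude template; ties broken lexicographically."""
    if len(templates) == 0:
        raise EmptyInputError("no templates to select from")
    best_amp = max(t.amplitude for t in templates)
    tied = sorted(
        t.track if t.track is not None else "" for t in templates
        if t.amplitude == best_amp
    )
    if len(tied) > 1:
        warnings.warn(
            f"track-of-interest tie at amplitude {best_amp:g}; "
            f"choosing {tied[0]!r} lexicographically",
            stacklevel=2,
        )
    return tied[0]
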