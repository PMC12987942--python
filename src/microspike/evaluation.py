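"""Ground-truth evaluation, cross-system alignment and firing metrics.

Detection and sorting are evaluated independently by tolerance-window
matching of timestamps (greedy nearest-first, one-to-one; 2 ms tolerance
for detection).  Undefined ratios (division by zero) are reported as None,
never coerced.  Utilities for comparing against an externally sorted result
(per-stimulus piecewise-constant offset correction, 10 ms post-stimulus
artifact exclusion, ±3 ms matching) and for the proof-of-concept firing
measures (instantaneous frequency, binned rates) live here too.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._errors import EmptyInputError, ValidationError

__all__ = [
    "ConfusionCounts",
    "Metrics",
    "match_events",
    "compute_metrics",
    "sorting_confusion",
    "align_external",
    "exclude_stimulus_artifacts",
    "firing_metrics",
    "sorter_agreement",
]

#: Physiologically implausible instantaneous rate for C-fibers (Hz).
MAX_PLAUSIBLE_RATE_HZ = 200.0


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValidationError("confusion counts must be non-negative")


@dataclass
class Metrics:
    """Derived rates; None marks an undefined (0/0) quantity."""

    f1: float | None
    precision: float | None
    recall: float | None
    fdr: float | None
    fp_per_tp: float | None
    fp_per_interval: float | None

    def to_dict(self) -> dict:
        return {
            "f1": self.f1,
            "precision": self.precision,
            "recall": self.recall,
            "fdr": self.fdr,
            "fp_per_tp": self.fp_per_tp,
            "fp_per_interval": self.fp_per_interval,
        }


def _check_sorted(x: np.ndarray, name: str) -> None:
    if np.any(np.diff(x) < 0):
        raise ValidationError(f"{name} must be sorted ascending")


def match_events(
    pred: Sequence[float],
    truth: Sequence[float],
    tol_ms: float,
    n_negative_windows: int | None = None,
) -> tuple[list[tuple[int, int]], ConfusionCounts]:
    """Greedy nearest-first one-to-one matching within ±``tol_ms``.

    Candidate pairs are taken in order of increasing |Δt|; each event is
    consumed at most once.  Matched predictions are TP, unmatched
    predictions FP, unmatched truth FN.  TN follows the detection
    convention — flagged windows containing neither a truth event nor a
    detection — and is filled in only when the caller supplies
    ``n_negative_windows``.
    """
    p = np.asarray(pred, dtype=float)
    t = np.asarray(truth, dtype=float)
    _check_sorted(p, "pred")
    _check_sorted(t, "truth")
    if not tol_ms > 0:
        raise ValidationError("tolerance must be positive")
    tol = tol_ms / 1000.0
    pairs: list[tuple[float, int, int]] = []
    j0 = 0
    for i, tp_ in enumerate(p):
        j0 = int(np.searchsorted(t, tp_ - tol, side="left"))
        j = j0
        while j < len(t) and t[j] <= tp_ + tol:
            pairs.append((abs(tp_ - t[j]), i, j))
            j += 1
    pairs.sort()
    used_p: set[int] = set()
    used_t: set[int] = set()
    matches: list[tuple[int, int]] = []
    for _, i, j in pairs:
        if i in used_p or j in used_t:
            continue
        used_p.add(i)
        used_t.add(j)
        matches.append((i, j))
    counts = ConfusionCounts(
        tp=len(matches),
        fp=len(p) - len(matches),
        fn=len(t) - len(matches),
        tn=n_negative_windows if n_negative_windows is not None else 0,
    )
    return matches, counts


def _ratio(num: float, den: float) -> float | None:
    return num / den if den > 0 else None


def compute_metrics(c: ConfusionCounts, n_intervals: int = 1) -> Metrics:
    """Precision, recall, F1, FDR, FP/TP and FP per stimulation interval."""
    if n_intervals < 1:
        raise ValidationError("n_intervals must be >= 1")
    return Metrics(
        f1=_ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn),
        precision=_ratio(c.tp, c.tp + c.fp),
        recall=_ratio(c.tp, c.tp + c.fn),
        fdr=_ratio(c.fp, c.tp + c.fp),
        fp_per_tp=_ratio(c.fp, c.tp),
        fp_per_interval=c.fp / n_intervals,
    )


def sorting_confusion(
    detected_times: Sequence[float],
    assigned_labels: Sequence[str],
    truth_times: Sequence[float],
    truth_labels: Sequence[str],
    track: str,
    tol_ms: float,
) -> ConfusionCounts:
    """Fiber-of-interest confusion for a sorted detection result.

    TP: detected spike matched (±tol) to a truth spike of ``track`` and
    assigned ``track``.  FP: assigned ``track`` without such a match.
    FN: truth spike of ``track`` with no correctly assigned detection.
    TN: detected spike correctly not assigned ``track``.
    """
    det = np.asarray(detected_times, dtype=float)
    lab = np.asarray(assigned_labels, dtype=object)
    tt = np.asarray(truth_times, dtype=float)
    tl = np.asarray(truth_labels, dtype=object)
    if track not in set(tl) and track not in set(lab):
        raise ValidationError(f"unknown track label {track!r}")
    order = np.argsort(det, kind="stable")
    det, lab = det[order], lab[order]
    t_order = np.argsort(tt, kind="stable")
    tt, tl = tt[t_order], tl[t_order]
    matches, _ = match_events(det, tt, tol_ms)
    matched_truth = {i: j for i, j in matches}
    tp = fp = tn = 0
    correct_truth: set[int] = set()
    for i in range(len(det)):
        j = matched_truth.get(i)
        truth_is_track = j is not None and tl[j] == track
        if lab[i] == track:
            if truth_is_track:
                tp += 1
                correct_truth.add(j)
            else:
                fp += 1
        elif not truth_is_track:
            tn += 1
    fn = int(np.sum(tl == track)) - len(correct_truth)
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def align_external(
    external_times: Sequence[float],
    anchor_pairs: Sequence[tuple[float, float]],
) -> np.ndarray:
    """Piecewise-constant offset correction of externally sorted timestamps.

    ``anchor_pairs`` holds per-stimulus ``(external_time, reference_time)``
    anchors; each external event is shifted by the offset of its nearest
    preceding anchor (the first anchor for events before it).
    """
    if len(anchor_pairs) == 0:
        raise EmptyInputError("need at least one anchor pair")
    ext = np.asarray(external_times, dtype=float)
    anchors = np.asarray(anchor_pairs, dtype=float)
    if np.any(np.diff(anchors[:, 0]) < 0):
        raise ValidationError("anchors must be sorted by external time")
    offsets = anchors[:, 0] - anchors[:, 1]
    idx = np.clip(np.searchsorted(anchors[:, 0], ext, side="right") - 1, 0, None)
    return ext - offsets[idx]


def exclude_stimulus_artifacts(
    times: Sequence[float],
    stimulus_times: Sequence[float],
    window_ms: float = 10.0,
) -> np.ndarray:
    """Drop events falling within ``window_ms`` after any stimulus onset."""
    t = np.asarray(times, dtype=float)
    stim = np.sort(np.asarray(stimulus_times, dtype=float))
    if len(stim) == 0 or len(t) == 0:
        return t.copy()
    idx = np.searchsorted(stim, t, side="right") - 1
    prev = np.where(idx >= 0, stim[np.clip(idx, 0, None)], -np.inf)
    keep = (t - prev) >= window_ms / 1000.0
    keep |= idx < 0
    return t[keep]


def firing_metrics(
    spike_times: Sequence[float],
    bin_s: float = 4.0,
    max_rate_hz: float = MAX_PLAUSIBLE_RATE_HZ,
) -> dict:
    """Instantaneous frequency and binned spike rate of one fiber.

    ``if_hz[i] = 1 / (t[i+1] - t[i])``; the binned series counts spikes in
    consecutive ``bin_s`` windows from the first covered bin boundary at 0.
    Intervals implying rates at or above ``max_rate_hz`` (including the
    infinite rate of duplicate timestamps) are flagged as physiologically
    implausible rather than silently kept.
    """
    t = np.asarray(spike_times, dtype=float)
    _check_sorted(t, "spike_times")
    isi = np.diff(t)
    with np.errstate(divide="ignore"):
        if_hz = np.where(isi > 0, 1.0 / np.where(isi > 0, isi, 1.0), np.inf)
    implausible = np.flatnonzero(if_hz >= max_rate_hz)
    if len(t):
        n_bins = int(np.floor(t.max() / bin_s)) + 1
        edges = np.arange(n_bins + 1) * bin_s
        counts, _ = np.histogram(t, bins=edges)
    else:
        counts = np.array([], dtype=int)
        edges = np.array([0.0])
    return {
        "if_hz": if_hz,
        "if_times": t[1:],
        "bin_edges_s": edges,
        "bin_counts": counts,
        "bin_rate_hz": counts / bin_s,
        "implausible_if_indices": implausible,
    }


def sorter_agreement(
    a: Sequence[float], b: Sequence[float], tol_ms: float
) -> dict[str, int]:
    """Partition two sorters' spike sets into both / only_a / only_b."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    matches, counts = match_events(np.sort(a), np.sort(b), tol_ms)
    return {"both": counts.tp, "only_a": counts.fp, "only_b": counts.fn}
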