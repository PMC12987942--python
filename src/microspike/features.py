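"""Waveform feature sets for spike classification.

Three fixed-length vectors are computed per 30-sample waveform:

* ``w_raw`` (30) — the raw snippet itself;
* ``spdf`` (23) — shape/phase/distribution descriptors of the waveform and
  its first and second forward differences (extremum amplitudes and their
  sample times, pre-/post-peak slopes, half-width, peak-to-peak amplitude
  and duration, energy, absolute area, derivative zero-crossing counts and
  standardized 3rd/4th moments);
* ``spdf_fv3`` (3) — a coordinate projection of ``spdf``; by default the
  negative-peak amplitude of the first difference, the peak-to-peak
  amplitude and the half-width.

The 23-descriptor list below is the package's frozen, versioned definition;
it is guarded by golden-vector tests, and downstream classifier code
depends only on the vector length.  All computations are deterministic and
pure.  Amplitude-type descriptors scale linearly with the waveform while
time-type descriptors (sample positions, widths, counts, moments) are
scale-invariant.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from ._errors import ValidationError
from .waveforms import WAVEFORM_LEN, SpikeWaveform

__all__ = [
    "FEATURE_NAMES",
    "FV3_DEFAULT",
    "FEATURE_SETS",
    "features_raw",
    "features_spdf",
    "features_spdf_fv3",
    "featurize",
]

FEATURE_NAMES: tuple[str, ...] = (
    "amp_max",              # 0  maximum of the waveform (µV)
    "amp_min",              # 1  minimum of the waveform (µV)
    "t_amp_max",            # 2  sample index of the maximum
    "t_amp_min",            # 3  sample index of the minimum
    "peak_to_peak",         # 4  amp_max - amp_min (µV)
    "pp_duration",          # 5  |t_amp_max - t_amp_min| (samples)
    "d1_max",               # 6  maximum of the first difference
    "d1_min",               # 7  minimum of the first difference (steepest fall)
    "t_d1_max",             # 8
    "t_d1_min",             # 9
    "d2_max",               # 10 maximum of the second difference
    "d2_min",               # 11
    "t_d2_max",             # 12
    "t_d2_min",             # 13
    "pre_peak_slope",       # 14 mean slope from start to the maximum
    "post_peak_slope",      # 15 mean slope from the maximum to the end
    "half_width",           # 16 samples with value >= amp_max / 2
    "energy",               # 17 sum of squares
    "abs_area",             # 18 sum of absolute values
    "d1_zero_crossings",    # 19 sign changes of the first difference
    "d2_zero_crossings",    # 20 sign changes of the second difference
    "skewness",             # 21 standardized 3rd moment (0 on flat input)
    "kurtosis",             # 22 excess standardized 4th moment
)

#: Default FV3 membership: first-difference negative-peak amplitude,
#: peak-to-peak amplitude, half-width.
FV3_DEFAULT: tuple[str, str, str] = ("d1_min", "peak_to_peak", "half_width")

FEATURE_SETS = {"spdf": 23, "spdf_fv3": 3, "w_raw": WAVEFORM_LEN}


def _values(w: SpikeWaveform | np.ndarray) -> np.ndarray:
    v = w.values if isinstance(w, SpikeWaveform) else np.asarray(w, dtype=float)
    if v.shape != (WAVEFORM_LEN,):
        raise ValidationError(f"waveform must have {WAVEFORM_LEN} samples, got {v.shape}")
    if not np.all(np.isfinite(v)):
        raise ValidationError("waveform contains non-finite values")
    return v


def _zero_crossings(x: np.ndarray) -> int:
    s = np.sign(x)
    s = s[s != 0]
    if s.size < 2:
        return 0
    return int(np.sum(s[1:] != s[:-1]))


def _standardized_moment(x: np.ndarray, order: int) -> float:
    sd = float(x.std())
    if sd == 0.0:
        return 0.0
    z = (x - x.mean()) / sd
    m = float(np.mean(z**order))
    return m - 3.0 if order == 4 else m


def features_raw(w: SpikeWaveform | np.ndarray) -> np.ndarray:
    """The 30 raw waveform samples, copied."""
    return _values(w).copy()


def features_spdf(w: SpikeWaveform | np.ndarray) -> np.ndarray:
    """The frozen 23-dimensional shape-descriptor vector."""
    v = _values(w)
    d1 = np.diff(v)
    d2 = np.diff(v, n=2)
    t_max = int(np.argmax(v))
    t_min = int(np.argmin(v))
    amp_max = float(v[t_max])
    amp_min = float(v[t_min])
    pre_slope = (amp_max - float(v[0])) / t_max if t_max > 0 else 0.0
    n_last = len(v) - 1
    post_slope = (float(v[-1]) - amp_max) / (n_last - t_max) if t_max < n_last else 0.0
    half_width = int(np.sum(v >= amp_max / 2.0)) if amp_max > 0 else int(np.sum(v >= amp_max))
    out = np.array(
        [
            amp_max,
            amp_min,
            float(t_max),
            float(t_min),
            amp_max - amp_min,
            float(abs(t_max - t_min)),
            float(d1.max()),
            float(d1.min()),
            float(np.argmax(d1)),
            float(np.argmin(d1)),
            float(d2.max()),
            float(d2.min()),
            float(np.argmax(d2)),
            float(np.argmin(d2)),
            pre_slope,
            post_slope,
            float(half_width),
            float(np.sum(v**2)),
            float(np.sum(np.abs(v))),
            float(_zero_crossings(d1)),
            float(_zero_crossings(d2)),
            _standardized_moment(v, 3),
            _standardized_moment(v, 4),
        ]
    )
    return out


def features_spdf_fv3(
    w: SpikeWaveform | np.ndarray,
    members: Sequence[str | int] = FV3_DEFAULT,
) -> np.ndarray:
    """Three configurable coordinates of the SPDF vector.

    ``members`` may name descriptors or give indices into the 23-vector.
    """
    if len(members) != 3:
        raise ValidationError("FV3 requires exactly 3 member descriptors")
    idx = []
    for m in members:
        if isinstance(m, str):
            if m not in FEATURE_NAMES:
                raise ValidationError(f"unknown SPDF descriptor {m!r}")
            idx.append(FEATURE_NAMES.index(m))
        else:
            if not 0 <= int(m) < len(FEATURE_NAMES):
                raise ValidationError(f"SPDF index {m} out of range")
            idx.append(int(m))
    return features_spdf(w)[idx]


def featurize(
    waveforms: Sequence[SpikeWaveform | np.ndarray], feature_set: str
) -> np.ndarray:
    """Stack one feature vector per waveform into an (n, d) matrix."""
    if feature_set == "w_raw":
        fn = features_raw
    elif feature_set == "spdf":
        fn = features_spdf
    elif feature_set == "spdf_fv3":
        fn = features_spdf_fv3
    else:
        raise ValidationError(f"unknown feature set {feature_set!r}")
    if len(waveforms) == 0:
        return np.empty((0, FEATURE_SETS[feature_set]))
    return np.stack([fn(w) for w in waveforms])
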