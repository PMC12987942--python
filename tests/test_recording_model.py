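import h5py
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import microspike as ms
from microspike.recording_model import compute_latencies


def _toy_recording(with_annotations=True) -> ms.Recording:
    rng = np.random.default_rng(5)
    return ms.Recording(
        samples=rng.normal(size=100_000),
        rate=10_000.0,
        stimuli=[
            ms.StimulusEvent(0.0, "background"),
            ms.StimulusEvent(1.0, "additional"),
            ms.StimulusEvent(4.0, "background"),
        ],
        annotations=[
            ms.SpikeAnnotation(0.25, "T1", "background_evoked"),
            ms.SpikeAnnotation(1.25, "T1", "additional_evoked"),
            ms.SpikeAnnotation(4.26, "T1", "background_evoked"),
        ]
        if with_annotations
        else None,
    )


@pytest.mark.parametrize("fmt,name", [("hdf5", "rec.h5"), ("csv", "rec_csv")])
def test_container_roundtrip_is_identity(tmp_path, fmt, name):
    """write_recording followed by read_recording preserves every field."""
    rec = _toy_recording()
    path = tmp_path / name
    ms.write_recording(rec, path, format=fmt)
    back = ms.read_recording(path, format=fmt)
    np.testing.assert_allclose(back.samples, rec.samples, atol=1e-6)
    assert back.rate == rec.rate and back.t0 == rec.t0
    assert [(s.time, s.kind) for s in back.stimuli] == [
        (s.time, s.kind) for s in rec.stimuli
    ]
    assert [(a.time, a.track, a.origin) for a in back.annotations] == [
        (a.time, a.track, a.origin) for a in rec.annotations
    ]


def test_minimal_container(tmp_path):
    rec = ms.Recording(
        samples=np.zeros(10), rate=10_000.0, stimuli=[ms.StimulusEvent(0.0)]
    )
    path = tmp_path / "mini.h5"
    ms.write_recording(rec, path)
    back = ms.read_recording(path)
    assert len(back.samples) == 10 and len(back.stimuli) == 1
    assert back.annotations is None


def test_simulator_file_preserves_annotation_count(tmp_path):
    """The container round-trips the simulator's full event log."""
    rec = ms.simulate(ms.preset("A3_like", duration_s=40.0, seed=2))
    path = tmp_path / "sim.h5"
    ms.write_recording(rec, path)
    back = ms.read_recording(path)
    assert len(back.annotations) == len(rec.annotations)


def test_malformed_container_names_missing_field(tmp_path):
    path = tmp_path / "broken.h5"
    with h5py.File(path, "w") as f:
        f.create_group("signal").create_dataset("samples", data=np.zeros(5))
        f["signal"].attrs["rate"] = 10_000.0
    with pytest.raises(ms.FormatError, match="stimuli"):
        ms.read_recording(path)


def test_nonincreasing_stimuli_rejected():
    with pytest.raises(ms.ValidationError):
        ms.Recording(
            samples=np.zeros(100_000),
            stimuli=[ms.StimulusEvent(4.0), ms.StimulusEvent(4.0)],
        )


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------


def test_segment_marking_periodic(simple_recording):
    windows = ms.segment_marking(simple_recording)
    assert [(w.start, w.end) for w in windows] == [(0.0, 4.0), (4.0, 8.0), (8.0, 12.0)]


def test_segment_marking_ignores_additional_pulses():
    rec = ms.Recording(
        samples=np.zeros(80_000),
        stimuli=[
            ms.StimulusEvent(0.0, "background"),
            ms.StimulusEvent(1.0, "additional"),
            ms.StimulusEvent(1.2, "additional"),
            ms.StimulusEvent(4.0, "background"),
        ],
    )
    windows = ms.segment_marking(rec)
    assert [(w.start, w.end) for w in windows] == [(0.0, 4.0), (4.0, 8.0)]


def test_segment_marking_jittered_onsets():
    onsets = [0.0, 4.02, 7.98]
    rec = ms.Recording(
        samples=np.zeros(120_000),
        stimuli=[ms.StimulusEvent(t, "background") for t in onsets],
    )
    windows = ms.segment_marking(rec)
    lengths = [w.end - w.start for w in windows]
    expected = list(np.diff(onsets)) + [12.0 - onsets[-1]]
    np.testing.assert_allclose(lengths, expected)


def test_segment_ground_truth_cuts_every_pulse():
    rec = ms.Recording(
        samples=np.zeros(60_000),
        stimuli=[
            ms.StimulusEvent(0.0, "background"),
            ms.StimulusEvent(1.0, "additional"),
            ms.StimulusEvent(2.0, "additional"),
            ms.StimulusEvent(4.0, "background"),
        ],
    )
    windows = ms.segment_ground_truth(rec)
    assert [(w.start, w.end) for w in windows] == [
        (0.0, 1.0),
        (1.0, 2.0),
        (2.0, 4.0),
        (4.0, 6.0),
    ]


def test_ground_truth_reduces_to_marking_without_additional(simple_recording):
    marking = ms.segment_marking(simple_recording)
    gt = ms.segment_ground_truth(simple_recording)
    assert [(w.start, w.end) for w in marking] == [(w.start, w.end) for w in gt]


def test_ground_truth_window_count_equals_stimulus_count():
    rec = ms.simulate(ms.preset("A5_like", duration_s=40.0, seed=4))
    assert len(ms.segment_ground_truth(rec)) == len(rec.stimuli)


def test_segmentation_requires_stimuli():
    rec = ms.Recording(samples=np.zeros(100_000))
    with pytest.raises(ms.EmptyInputError):
        ms.segment_marking(rec)
    with pytest.raises(ms.EmptyInputError):
        ms.segment_ground_truth(rec)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    onsets=st.lists(
        st.floats(0.01, 40.0, allow_nan=False), min_size=1, max_size=15, unique=True
    ),
    kinds=st.lists(st.booleans(), min_size=15, max_size=15),
)
def test_windows_tile_the_stimulated_span(onsets, kinds):
    """Both segmentations tile first-stimulus → recording-end, no overlap."""
    onsets = sorted(round(t, 4) for t in onsets)
    if len(set(onsets)) < len(onsets):
        return
    stimuli = [
        ms.StimulusEvent(t, "background" if (i == 0 or kinds[i]) else "additional")
        for i, t in enumerate(onsets)
    ]
    rec = ms.Recording(samples=np.zeros(420_000), stimuli=stimuli)
    for windows in (ms.segment_marking(rec), ms.segment_ground_truth(rec)):
        total = sum(w.end - w.start for w in windows)
        assert total == pytest.approx(rec.duration - windows[0].start)
        for a, b in zip(windows, windows[1:]):
            assert a.end == pytest.approx(b.start)


# ---------------------------------------------------------------------------
# Latencies and spike origin
# ---------------------------------------------------------------------------


def test_latency_is_time_from_defining_stimulus(simple_recording):
    windows = ms.segment_marking(simple_recording)
    df = compute_latencies([4.250], windows, simple_recording.stimuli)
    assert df.latency_ms.iloc[0] == pytest.approx(250.0)
    assert df.window_index.iloc[0] == 1


def test_spike_before_first_stimulus_is_flagged_not_dropped():
    rec = ms.Recording(
        samples=np.zeros(120_000),
        stimuli=[ms.StimulusEvent(2.0, "background"), ms.StimulusEvent(6.0, "background")],
    )
    windows = ms.segment_marking(rec)
    df = compute_latencies([1.0, 2.3], windows, rec.stimuli)
    assert df.window_index.tolist() == [-1, 0]
    assert np.isnan(df.latency_ms.iloc[0])


def test_constant_latency_fiber_stays_within_jitter(clean_single_fiber):
    rec = clean_single_fiber
    windows = ms.segment_marking(rec)
    times = [a.time for a in rec.annotations]
    df = compute_latencies(times, windows, rec.stimuli)
    assert df.latency_ms.max() - df.latency_ms.min() < 1e-6


def test_latency_increases_after_burst():
    """Activity-dependent slowing delays the background response that
    follows a burst of additional-pulse-evoked spikes."""
    fiber = ms.SimFiber(
        label="T1", base_latency_ms=250.0, amplitude_uv=8.0,
        ads_delta_ms=2.0, latency_jitter_ms=0.0, amplitude_jitter=0.0,
    )
    cfg = ms.SimConfig(
        duration_s=24.0, fibers=[fiber],
        extra_pulses_per_interval=(5, 5), extra_pulse_freq_hz=(4.0, 4.0),
        noise_sd_uv=0.0, seed=0,
    )
    rec = ms.simulate(cfg)
    windows = ms.segment_marking(rec)
    bg = [a.time for a in rec.annotations if a.origin == "background_evoked"]
    df = compute_latencies(bg, windows, rec.stimuli)
    lat = df.latency_ms.to_numpy()
    assert lat[1] > lat[0] + 2.0  # 5 spikes x 2 ms, minus recovery


@pytest.mark.parametrize(
    "times,expected",
    [
        ([0.0, 4.0, 8.0], ["background_evoked"] * 3),
        (
            [0.0, 4.0, 4.5, 8.0],
            ["background_evoked", "background_evoked", "additional_evoked", "additional_evoked"],
        ),
        ([3.0], ["background_evoked"]),
    ],
)
def test_origin_split_at_3_8_seconds(times, expected):
    assert list(ms.classify_spike_origin(times)) == expected


def test_origin_rejects_non_monotone_times():
    with pytest.raises(ms.ValidationError):
        ms.classify_spike_origin([1.0, 1.0, 2.0])


@settings(deadline=None, max_examples=40, derandomize=True)
@given(
    gaps=st.lists(st.floats(0.1, 8.0, allow_nan=False), min_size=1, max_size=12),
    shift=st.floats(-50.0, 50.0, allow_nan=False),
)
def test_origin_is_shift_invariant(gaps, shift):
    times = np.cumsum(gaps)
    base = list(ms.classify_spike_origin(times))
    shifted = list(ms.classify_spike_origin(times + shift))
    assert base == shifted
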