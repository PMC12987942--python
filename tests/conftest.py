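import numpy as np
import pytest

import microspike as ms


def two_fiber_config(snr: float = 9.5, duration_s: float = 60.0, seed: int = 0,
                     **overrides) -> ms.SimConfig:
    """A1-style two-fiber configuration with the interest fiber at `snr`."""
    cfg = ms.preset("A1_like", duration_s=duration_s, seed=seed)
    scale = snr / cfg.fibers[0].amplitude_uv
    for f in cfg.fibers:
        f.amplitude_uv *= scale
    for key, val in overrides.items():
        setattr(cfg, key, val)
    return cfg


def background_waveforms(rec: ms.Recording):
    """Background-evoked waveforms and track labels from the annotations."""
    waves, labels = [], []
    for a in rec.annotations or []:
        if a.origin != "background_evoked":
            continue
        try:
            waves.append(ms.extract_and_align(rec, a.time))
            labels.append(a.track)
        except ms.BoundaryError:
            continue
    return waves, labels


@pytest.fixture(scope="session")
def a1_recording() -> ms.Recording:
    """A noisy two-fiber recording under the high-SNR stimulation regime."""
    return ms.simulate(ms.preset("A1_like", duration_s=60.0, seed=7))


@pytest.fixture(scope="session")
def clean_single_fiber() -> ms.Recording:
    """Noiseless, jitter-free single-fiber recording: 10 background pulses,
    no additional stimuli, constant latency."""
    fiber = ms.SimFiber(
        label="T1",
        base_latency_ms=250.0,
        amplitude_uv=8.0,
        response_prob=1.0,
        amplitude_jitter=0.0,
        latency_jitter_ms=0.0,
        ads_delta_ms=0.0,
    )
    cfg = ms.SimConfig(
        duration_s=40.0,
        fibers=[fiber],
        extra_pulses_per_interval=(0, 0),
        noise_sd_uv=0.0,
        seed=0,
    )
    return ms.simulate(cfg)


@pytest.fixture()
def simple_recording() -> ms.Recording:
    """Hand-built 12 s flat recording with three background stimuli."""
    return ms.Recording(
        samples=np.zeros(120_000),
        rate=10_000.0,
        stimuli=[ms.StimulusEvent(t, "background") for t in (0.0, 4.0, 8.0)],
    )
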