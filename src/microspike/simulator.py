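"""Synthetic single-electrode microneurography recordings with ground truth.

The generator emulates the ground-truth stimulation protocol: periodic
0.25 Hz background pulses with a variable number of additional pulses per
interval, 2–5 fibers with stable per-fiber latencies, activity-dependent
conduction-velocity slowing (ADS), low-amplitude biphasic spikes and
band-limited (500–1000 Hz) Gaussian noise.  Every emitted spike is
annotated with its time, fiber and origin, so the simulator's event log is
the ground truth against which detection and sorting are scored.

ADS is modeled as an additive latency state: each emitted spike adds
``ads_delta`` ms, and the state decays as ``exp(-Δt / ads_tau)`` between
events.  This reproduces the qualitative physiology — slowing scales with
the number of preceding spikes and recovers slowly — without claiming
biophysical kinetics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import butter, sosfilt

from ._errors import ValidationError
from .recording_model import Recording, SpikeAnnotation, StimulusEvent

__all__ = ["SimFiber", "SimConfig", "simulate", "preset", "PRESET_NAMES"]


@dataclass
class SimFiber:
    """Generative parameters of one simulated C-fiber.

    ``base_latency_ms`` is the conduction latency under rest; ``ads_delta_ms``
    the per-spike latency increment with recovery constant ``ads_tau_s``.
    ``refractory_ms`` enforces the <200 Hz physiological firing bound.
    """

    label: str
    base_latency_ms: float
    amplitude_uv: float
    width_ms: float = 1.5
    ads_delta_ms: float = 2.0
    ads_tau_s: float = 60.0
    response_prob: float = 1.0
    refractory_ms: float = 5.0
    amplitude_jitter: float = 0.05
    latency_jitter_ms: float = 0.1

    def __post_init__(self) -> None:
        if not self.base_latency_ms > 0:
            raise ValidationError("base latency must be positive")
        if not 0 < self.response_prob <= 1:
            raise ValidationError("response_prob must be in (0, 1]")
        if self.refractory_ms < 5.0:
            raise ValidationError("refractory must be >= 5 ms (<200 Hz firing)")
        if self.amplitude_uv <= 0 or self.width_ms <= 0:
            raise ValidationError("amplitude and width must be positive")


@dataclass
class SimConfig:
    """Recording-level generative parameters (defaults mirror the stimulation
    regimes used in the ground-truth protocol: 0.25 Hz background pulses,
    1–9 extra pulses per interval at 2–10 Hz, 500–1000 Hz noise band)."""

    duration_s: float
    fibers: list[SimFiber]
    rate: float = 10_000.0
    background_period_s: float = 4.0
    extra_pulses_per_interval: tuple[int, int] = (1, 9)
    extra_pulse_freq_hz: tuple[float, float] = (2.0, 10.0)
    extra_start_offset_s: float = 0.3
    min_gap_to_next_background_s: float = 1.0
    noise_sd_uv: float = 1.0
    noise_band_hz: tuple[float, float] = (500.0, 1000.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s < 2 * self.background_period_s:
            raise ValidationError("duration must cover >= 2 background periods")
        lo, hi = self.extra_pulses_per_interval
        if lo < 0 or hi < lo:
            raise ValidationError("invalid extra-pulse count range")
        flo, fhi = self.extra_pulse_freq_hz
        if flo <= 0 or fhi < flo:
            raise ValidationError("invalid extra-pulse frequency range")
        if self.noise_sd_uv < 0:
            raise ValidationError("noise_sd must be >= 0")
        if not len(self.fibers):
            raise ValidationError("need at least one fiber")


def _biphasic_kernel(rate: float, width_ms: float) -> tuple[np.ndarray, int]:
    """Difference-of-Gaussians biphasic spike shape, positive peak = 1.

    Returns the sampled kernel and the index of its positive peak.
    """
    s1 = width_ms * 0.25
    s2 = width_ms * 0.25
    delay = width_ms * 0.45
    span = width_ms * 4.0
    t = np.arange(-span, span + delay, 1000.0 / rate)  # ms grid
    k = np.exp(-(t**2) / (2 * s1**2)) - 0.9 * np.exp(-((t - delay) ** 2) / (2 * s2**2))
    peak = int(np.argmax(k))
    return k / k[peak], peak


def _stimulus_train(cfg: SimConfig, rng: np.random.Generator) -> list[StimulusEvent]:
    bg = np.arange(0.0, cfg.duration_s, cfg.background_period_s)
    events = [StimulusEvent(float(t), "background") for t in bg]
    lo, hi = cfg.extra_pulses_per_interval
    for i in range(len(bg) - 1):
        n = int(rng.integers(lo, hi + 1))
        f = float(rng.uniform(*cfg.extra_pulse_freq_hz))
        if n == 0:
            continue
        start = bg[i] + cfg.extra_start_offset_s
        latest = bg[i + 1] - cfg.min_gap_to_next_background_s
        times = start + np.arange(n) / f
        times = times[times <= latest]
        events.extend(StimulusEvent(float(t), "additional") for t in times)
    events.sort(key=lambda e: e.time)
    return events


def _fiber_spikes(
    fiber: SimFiber, pulses: list[StimulusEvent], rng: np.random.Generator
) -> list[SpikeAnnotation]:
    spikes: list[SpikeAnnotation] = []
    slow = 0.0
    last_pulse: float | None = None
    last_spike = -math.inf
    for p in pulses:
        if last_pulse is not None:
            slow *= math.exp(-(p.time - last_pulse) / fiber.ads_tau_s)
        last_pulse = p.time
        responds = rng.random() < fiber.response_prob
        jitter = rng.normal(0.0, fiber.latency_jitter_ms) if fiber.latency_jitter_ms else 0.0
        if not responds:
            continue
        latency_ms = fiber.base_latency_ms + slow + jitter
        t_spike = p.time + latency_ms / 1000.0
        if t_spike - last_spike < fiber.refractory_ms / 1000.0:
            continue
        origin = "background_evoked" if p.kind == "background" else "additional_evoked"
        spikes.append(SpikeAnnotation(time=t_spike, track=fiber.label, origin=origin))
        slow += fiber.ads_delta_ms
        last_spike = t_spike
    return spikes


def _bandlimited_noise(
    n: int, rate: float, band: tuple[float, float], sd: float, rng: np.random.Generator
) -> np.ndarray:
    white = rng.standard_normal(n)
    sos = butter(2, band, btype="bandpass", fs=rate, output="sos")
    filtered = sosfilt(sos, white)
    measured = filtered.std()
    if measured == 0:
        return np.zeros(n)
    return filtered * (sd / measured)


def simulate(cfg: SimConfig) -> Recording:
    """Generate a fully annotated synthetic recording.

    Identical configurations (including ``seed``) yield bit-identical
    recordings; the annotation list equals the set of injected waveforms.
    """
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.rate))
    stimuli = _stimulus_train(cfg, rng)
    samples = np.zeros(n)
    annotations: list[SpikeAnnotation] = []
    for fiber in cfg.fibers:
        spikes = _fiber_spikes(fiber, stimuli, rng)
        kernel, k_peak = _biphasic_kernel(cfg.rate, fiber.width_ms)
        for sp in spikes:
            idx = int(round(sp.time * cfg.rate))
            if idx >= n:
                continue
            amp = fiber.amplitude_uv * float(
                rng.lognormal(0.0, fiber.amplitude_jitter)
            ) if fiber.amplitude_jitter else fiber.amplitude_uv
            lo = idx - k_peak
            hi = lo + len(kernel)
            k_lo = max(0, -lo)
            k_hi = len(kernel) - max(0, hi - n)
            samples[max(0, lo) : min(n, hi)] += amp * kernel[k_lo:k_hi]
            annotations.append(sp)
    if cfg.noise_sd_uv > 0:
        samples = samples + _bandlimited_noise(
            n, cfg.rate, cfg.noise_band_hz, cfg.noise_sd_uv, rng
        )
    annotations.sort(key=lambda a: a.time)
    return Recording(
        samples=samples,
        rate=cfg.rate,
        t0=0.0,
        stimuli=stimuli,
        annotations=annotations,
    )


# ---------------------------------------------------------------------------
# Presets mirroring the study's recording regimes: fiber counts, extra-pulse
# ranges and target SNR per recording.  The track-of-interest amplitude is
# target_SNR x noise_sd (unit noise), secondary fibers take descending
# amplitude ratios; base latencies spread over 150-350 ms (plausible C-fiber
# conduction delays; unverified against any published value).
# ---------------------------------------------------------------------------

_AMP_RATIOS = (1.0, 0.65, 0.5, 0.42, 0.36)
_BASE_LATENCIES = (250.0, 180.0, 310.0, 150.0, 330.0)
_WIDTHS = (1.5, 1.2, 1.8, 1.35, 1.65)

_PRESETS: dict[str, dict] = {
    "A1_like": dict(n_fibers=2, snr=9.5, pulses=(3, 9), freq=(3.0, 5.0)),
    "A2_like": dict(n_fibers=2, snr=6.8, pulses=(3, 9), freq=(4.0, 4.0)),
    "A3_like": dict(n_fibers=2, snr=5.5, pulses=(3, 7), freq=(5.0, 10.0)),
    "A4_like": dict(n_fibers=3, snr=3.1, pulses=(3, 7), freq=(2.0, 2.0)),
    "A5_like": dict(n_fibers=5, snr=6.8, pulses=(3, 3), freq=(2.0, 8.0)),
    "A6_like": dict(n_fibers=3, snr=5.5, pulses=(1, 7), freq=(5.0, 8.0)),
    "AC_like": dict(n_fibers=2, snr=11.8, pulses=(1, 9), freq=(2.0, 10.0)),
}

PRESET_NAMES = tuple(_PRESETS)


def preset(name: str, duration_s: float = 120.0, seed: int = 0) -> SimConfig:
    """A SimConfig matching one of the study-like recording regimes.

    Fiber count, extra-pulse count/frequency ranges and the target SNR of
    the highest-amplitude fiber follow the named regime; duration and seed
    are caller-controlled.
    """
    if name not in _PRESETS:
        raise ValidationError(f"unknown preset {name!r}; options: {PRESET_NAMES}")
    p = _PRESETS[name]
    noise_sd = 1.0
    fibers = [
        SimFiber(
            label=f"T{i + 1}",
            base_latency_ms=_BASE_LATENCIES[i],
            amplitude_uv=p["snr"] * noise_sd * _AMP_RATIOS[i],
            width_ms=_WIDTHS[i],
            ads_delta_ms=2.0,
            response_prob=0.95,
        )
        for i in range(p["n_fibers"])
    ]
    return SimConfig(
        duration_s=duration_s,
        fibers=fibers,
        extra_pulses_per_interval=p["pulses"],
        extra_pulse_freq_hz=p["freq"],
        noise_sd_uv=noise_sd,
        seed=seed,
    )
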