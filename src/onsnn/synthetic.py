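"""Synthetic EEG-like streams with controllable input and concept drift.

Generates labeled multichannel segments whose class identity lives in
the relative power of the canonical EEG bands (delta 1-4 Hz, theta 4-8,
alpha 8-13, beta 13-30). Each segment is a sum of band-limited
sinusoids at randomized frequencies and phases, scaled by the class's
band-amplitude profile, plus 1/f (pink) and white noise. The default
profiles give the stress class a beta-dominant spectrum and the
positive class an alpha-dominant one, with the neutral class balanced
— a generic caricature of stress-EEG spectral findings, not a model of
any particular cohort.

Two kinds of non-stationarity can be injected into a generated stream:

* input drift — a global amplitude rescaling from a given sample
  onwards, changing the input distribution but not the labels;
* concept drift — a relabeling of the class sources from a given
  sample onwards (the generators are untouched, the posterior flips).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .aer import EEGSegment
from .network import StreamSample

__all__ = [
    "BANDS",
    "DEFAULT_CLASS_PROFILES",
    "SynthConfig",
    "generate_segment",
    "generate_stream",
    "inject_input_drift",
    "inject_concept_drift",
]

BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}

# relative band amplitudes (uV) per class: stress is beta-dominant,
# positive alpha-dominant, neutral balanced
DEFAULT_CLASS_PROFILES: dict[str, dict[str, float]] = {
    "stress": {"delta": 0.6, "theta": 0.6, "alpha": 0.5, "beta": 2.0},
    "neutral": {"delta": 1.0, "theta": 1.0, "alpha": 1.0, "beta": 1.0},
    "positive": {"delta": 0.6, "theta": 0.6, "alpha": 2.0, "beta": 0.5},
}


@dataclass(frozen=True)
class DriftEvent:
    """One scheduled drift: kind is 'input' (scale) or 'concept' (mapping)."""

    at: int
    kind: str
    scale: float = 1.0
    mapping: tuple[tuple[str, str], ...] = ()


@dataclass(frozen=True)
class SynthConfig:
    n_channels: int = 4
    channel_names: tuple[str, ...] = ("FP1", "FP2", "T7", "T8")
    sampling_rate: float = 256.0
    duration: float = 5.0
    n_samples: int = 72
    classes: tuple[str, ...] = ("stress", "neutral", "positive")
    class_profiles: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: DEFAULT_CLASS_PROFILES)
    sinusoids_per_band: int = 3
    pink_exponent: float = 1.0
    pink_sigma: float = 0.5
    white_sigma: float = 0.5
    drift_schedule: tuple[DriftEvent, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.channel_names) != self.n_channels:
            raise ValueError("channel_names must match n_channels")
        if self.n_samples % len(self.classes) != 0:
            raise ValueError("n_samples must divide evenly across classes")
        for cls in self.classes:
            if cls not in self.class_profiles:
                raise ValueError(f"no band profile for class {cls!r}")
            if any(a < 0 for a in self.class_profiles[cls].values()):
                raise ValueError("band amplitudes must be >= 0")

    @property
    def n_timepoints(self) -> int:
        return int(round(self.duration * self.sampling_rate))

    @property
    def per_class(self) -> int:
        return self.n_samples // len(self.classes)


def _pink_noise(rng: np.random.Generator, n: int, exponent: float) -> np.ndarray:
    """Unit-variance 1/f^exponent noise via spectral shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    freqs[0] = freqs[1]  # avoid the DC divide
    spec *= freqs ** (-exponent / 2.0)
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_segment(class_label: str, config: SynthConfig, seed) -> EEGSegment:
    """One class-conditional segment, deterministic in (class, config, seed)."""
    if class_label not in config.classes:
        raise ValueError(f"unknown class {class_label!r}")
    rng = np.random.default_rng(seed)
    T = config.n_timepoints
    t = np.arange(T) / config.sampling_rate
    profile = config.class_profiles[class_label]
    values = np.zeros((config.n_channels, T))
    for c in range(config.n_channels):
        x = np.zeros(T)
        for band, (lo, hi) in BANDS.items():
            amp = profile.get(band, 0.0)
            if amp == 0.0:
                continue
            k = config.sinusoids_per_band
            freqs = rng.uniform(lo, hi, size=k)
            phases = rng.uniform(0, 2 * np.pi, size=k)
            x += (amp / np.sqrt(k)) * np.sin(
                2 * np.pi * freqs[:, None] * t + phases[:, None]).sum(axis=0)
        if config.pink_sigma > 0:
            x += config.pink_sigma * _pink_noise(rng, T, config.pink_exponent)
        if config.white_sigma > 0:
            x += config.white_sigma * rng.standard_normal(T)
        values[c] = x
    return EEGSegment(values=values, sampling_rate=config.sampling_rate,
                      channel_names=config.channel_names)


def generate_stream(config: SynthConfig) -> list[StreamSample]:
    """A labeled stream: exact per-class counts, seeded interleaved order,
    drift schedule applied."""
    ss = np.random.SeedSequence(config.seed)
    order_seed, *segment_seeds = ss.spawn(config.n_samples + 1)
    labels = np.repeat(np.asarray(config.classes, dtype=object), config.per_class)
    np.random.default_rng(order_seed).shuffle(labels)
    stream = [
        StreamSample(
            segment=generate_segment(str(lbl), config, segment_seeds[i]),
            label=str(lbl),
            index=i,
        )
        for i, lbl in enumerate(labels)
    ]
    for ev in config.drift_schedule:
        if ev.kind == "input":
            stream = inject_input_drift(stream, ev.at, ev.scale)
        elif ev.kind == "concept":
            stream = inject_concept_drift(stream, ev.at, dict(ev.mapping))
        else:
            raise ValueError(f"unknown drift kind {ev.kind!r}")
    return stream


def inject_input_drift(stream: Sequence[StreamSample], at: int,
                       scale: float) -> list[StreamSample]:
    """Rescale segment amplitudes from sample ``at`` onward; labels unchanged."""
    stream = list(stream)
    if not 0 <= at < len(stream):
        raise IndexError(f"drift index {at} out of range for {len(stream)} samples")
    out = []
    for i, s in enumerate(stream):
        if i >= at and scale != 1.0:
            seg = EEGSegment(values=s.segment.values * scale,
                             sampling_rate=s.segment.sampling_rate,
                             channel_names=s.segment.channel_names)
            s = StreamSample(segment=seg, label=s.label, index=s.index)
        out.append(s)
    return out


def inject_concept_drift(stream: Sequence[StreamSample], at: int,
                         mapping: Mapping[str, str]) -> list[StreamSample]:
    """Relabel class sources from sample ``at`` onward; inputs unchanged.

    ``mapping`` must be a bijection over the labels it touches: a sample
    generated by class c is labeled mapping(c) from ``at`` on, so the
    class posteriors change while the input distribution does not.
    """
    stream = list(stream)
    if not 0 <= at < len(stream):
        raise IndexError(f"drift index {at} out of range for {len(stream)} samples")
    if len(set(mapping.values())) != len(mapping):
        raise ValueError("concept-drift mapping must be a bijection")
    out = []
    for i, s in enumerate(stream):
        if i >= at:
            new = mapping.get(s.label, s.label)
            if new != s.label:
                s = StreamSample(segment=s.segment, label=new, index=s.index)
        out.append(s)
    return out
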