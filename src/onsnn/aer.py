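"""Address Event Representation (AER) spike encoding.

Converts continuous multichannel signals into ternary spike trains. For
each channel the first-order temporal difference is compared against an
adaptive threshold ``mean(tempdiff) + f * std(tempdiff)`` computed over
the whole segment: differences above the threshold emit an excitatory
(+1) event, differences below its negation emit an inhibitory (-1)
event, and everything in between stays silent (0). The threshold factor
``f`` controls sparsity: larger ``f`` means fewer events.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AERParams",
    "EEGSegment",
    "SpikeTrain",
    "temporal_difference",
    "aer_threshold",
    "encode",
]


@dataclass(frozen=True)
class AERParams:
    """Encoder parameters.

    Parameters
    ----------
    f : float
        Dimensionless threshold factor (default 0.7). Must be >= 0.
    """

    f: float = 0.7

    def __post_init__(self) -> None:
        if self.f < 0:
            raise ValueError(f"threshold factor f must be >= 0, got {self.f}")


@dataclass(frozen=True)
class EEGSegment:
    """One multichannel signal segment (channels x timepoints), in uV.

    ``values`` has one row per channel; all rows share a length of at
    least 2 samples. ``channel_names`` are unique, ordered labels.
    """

    values: np.ndarray
    sampling_rate: float = 256.0
    channel_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("segment values must be a 2-D channels x timepoints array")
        if values.shape[1] < 2:
            raise ValueError("segment needs at least 2 timepoints")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        names = self.channel_names or tuple(f"ch{i}" for i in range(values.shape[0]))
        if len(names) != values.shape[0]:
            raise ValueError("channel_names length must match channel count")
        if len(set(names)) != len(names):
            raise ValueError("channel_names must be unique")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "channel_names", tuple(names))

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class SpikeTrain:
    """Ternary event matrix (channels x timepoints), entries in {-1, 0, +1}."""

    events: np.ndarray
    channel_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        events = np.asarray(self.events, dtype=np.int8)
        if events.ndim != 2:
            raise ValueError("spike events must be a 2-D channels x timepoints array")
        if not np.isin(events, (-1, 0, 1)).all():
            raise ValueError("spike events must be ternary (-1, 0, +1)")
        object.__setattr__(self, "events", events)

    @property
    def n_events(self) -> int:
        """Total number of nonzero events (spikes of either sign)."""
        return int(np.count_nonzero(self.events))


def temporal_difference(segment: EEGSegment) -> np.ndarray:
    """First-order difference per channel: element (c, t) is x[t+1] - x[t].

    Returns a (channels x (timepoints-1)) array.
    """
    return np.diff(segment.values, axis=1)


def aer_threshold(tempdiff: np.ndarray, params: AERParams) -> float:
    """Adaptive spike threshold for one channel: mean + f * population std."""
    tempdiff = np.asarray(tempdiff, dtype=float)
    if tempdiff.size == 0:
        raise ValueError("cannot compute AER threshold of an empty difference vector")
    # population (ddof=0) standard deviation: fixed for reproducibility
    return float(np.mean(tempdiff) + params.f * np.std(tempdiff))


def encode(segment: EEGSegment, params: AERParams = AERParams()) -> SpikeTrain:
    """Encode a segment into a ternary spike train.

    Per channel, with threshold ``thr`` from :func:`aer_threshold`: a
    difference strictly above ``thr`` emits +1, strictly below ``-thr``
    emits -1, otherwise 0. Time step 0 has no predecessor and is silent.
    Ties at the threshold emit no spike.
    """
    diffs = temporal_difference(segment)
    events = np.zeros(segment.values.shape, dtype=np.int8)
    for c in range(segment.n_channels):
        thr = aer_threshold(diffs[c], params)
        events[c, 1:] = np.where(diffs[c] > thr, 1, np.where(diffs[c] < -thr, -1, 0))
    return SpikeTrain(events=events, channel_names=segment.channel_names)
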