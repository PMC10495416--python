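"""Network assembly and the test-then-train streaming loop.

Wires the AER encoder, the LIF hidden layer with STDP + intrinsic
plasticity, and the evolving rank-order output repository into a single
online classifier, and provides the two ablation baselines:

* online with structural plasticity (the full model): output neurons
  evolve during a short initiation phase and afterwards only on
  classification errors; errors also trigger hidden-layer self-pruning
  and elimination of unreliable output neurons;
* online without structural plasticity: one output neuron per sample,
  no pruning or elimination;
* batch mode: a train/test split where the training samples each evolve
  one neuron and the test samples are classified with all learning
  frozen.

Every sample is classified *before* any learning from it happens
(test-then-train), so the prequential accuracy trace is an honest
estimate of streaming performance.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, field, fields
from typing import Optional, Sequence

import numpy as np

from .aer import AERParams, EEGSegment, SpikeTrain, encode
from .evaluation import EvalTrace, StreamResult
from .lif import IPParams, LIFParams, LIFPopulation, ip_update, lif_step
from .output import (
    OutputRepository,
    ROParams,
    classify,
    eliminate_neurons,
    evolve_neuron,
    rank_order_vector,
)
from .plasticity import (
    PruneParams,
    STDPParams,
    SynapticMatrix,
    init_weights,
    self_prune,
    stdp_apply,
)

__all__ = [
    "NetworkConfig",
    "StreamSample",
    "StepOutcome",
    "NetworkState",
    "process_sample",
    "run_online",
    "run_batch",
]


@dataclass(frozen=True)
class NetworkConfig:
    """All hyperparameters, with the published defaults.

    The per-component parameter objects are derived views; mutate a
    config with :func:`dataclasses.replace`.
    """

    # AER encoder
    f: float = 0.7
    # LIF membrane
    v_thresh: float = 0.05
    v_rest: float = 0.0
    R: float = 1.0
    C: float = 10.0
    # STDP
    A_plus: float = 0.001
    A_minus: float = 0.001
    tau_pos: float = 10.0
    tau_neg: float = 10.0
    w_max: float = 0.5
    w_min: float = -0.5
    pair_window: int = 50
    # intrinsic plasticity
    theta_pos: float = 0.001
    theta_neg: float = 0.000001
    threshold_floor_fraction: float = 0.1
    # pruner
    sp_thresh: int = 1
    # output layer
    alpha: float = 1.0
    mod: float = 0.8
    d: float = 0.001
    min_errors: int = 3
    # architecture / protocol
    n_hidden: int = 100
    n_init_samples: int = 15
    structural_plasticity: bool = True
    mode: str = "online"
    train_fraction: float = 0.70
    seed: int = 0
    init_sigma: float = 0.1
    # ablation switches
    stdp_enabled: bool = True
    ip_enabled: bool = True
    # optional per-pass drift update of initiation neurons (under-determined
    # mechanism; off by default)
    update_initiation_neurons: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie strictly between 0 and 1")
        if self.n_hidden < 1 or self.n_init_samples < 0:
            raise ValueError("n_hidden >= 1 and n_init_samples >= 0 required")
        if self.mode not in ("online", "batch"):
            raise ValueError("mode must be 'online' or 'batch'")

    # component views -------------------------------------------------------

    def aer_params(self) -> AERParams:
        return AERParams(f=self.f)

    def lif_params(self) -> LIFParams:
        return LIFParams(v_thresh_init=self.v_thresh, v_rest=self.v_rest,
                         R=self.R, C=self.C)

    def ip_params(self) -> IPParams:
        return IPParams(theta_pos=self.theta_pos, theta_neg=self.theta_neg,
                        floor_fraction=self.threshold_floor_fraction)

    def stdp_params(self) -> STDPParams:
        return STDPParams(A_plus=self.A_plus, A_minus=self.A_minus,
                          tau_pos=self.tau_pos, tau_neg=self.tau_neg,
                          w_max=self.w_max, w_min=self.w_min,
                          pair_window=self.pair_window)

    def prune_params(self) -> PruneParams:
        return PruneParams(sp_thresh=self.sp_thresh)

    def ro_params(self) -> ROParams:
        return ROParams(alpha=self.alpha, mod=self.mod, d=self.d)

    @classmethod
    def from_toml(cls, path) -> "NetworkConfig":
        """Load a config from a TOML file using these field names."""
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass(frozen=True)
class StreamSample:
    """One labeled segment at a position in the stream."""

    segment: EEGSegment
    label: str
    index: int


@dataclass(frozen=True)
class StepOutcome:
    """Per-sample log record emitted by :func:`process_sample`."""

    index: int
    true_label: str
    predicted_label: Optional[str]
    correct: Optional[bool]
    distance: Optional[float]
    repo_size: int
    spikes_received: int
    spikes_generated: int
    pruned_count: int
    evolved: bool
    eliminated_count: int


@dataclass
class NetworkState:
    """Everything the streaming loop carries between samples."""

    config: NetworkConfig
    classes: tuple[str, ...]
    synapses: SynapticMatrix
    population: LIFPopulation
    repo: OutputRepository
    trace: EvalTrace
    samples_seen: int = 0
    spikes_received_total: int = 0
    spikes_generated_total: int = 0
    structural_events: list[dict] = field(default_factory=list)
    initiation_snapshot: Optional[OutputRepository] = None

    @classmethod
    def initialize(cls, classes: Sequence[str], n_inputs: int,
                   config: NetworkConfig) -> "NetworkState":
        synapses = init_weights(n_inputs, config.n_hidden, seed=config.seed,
                                sigma=config.init_sigma, params=config.stdp_params())
        population = LIFPopulation.fresh(config.n_hidden, config.lif_params())
        return cls(
            config=config,
            classes=tuple(classes),
            synapses=synapses,
            population=population,
            repo=OutputRepository(),
            trace=EvalTrace(classes=tuple(classes)),
        )


def _propagate(state: NetworkState, spikes: SpikeTrain, learn: bool
               ) -> np.ndarray:
    """Run one sample through the hidden layer; returns the spike raster.

    The membrane potentials start from rest for each segment (segments
    are disjoint 5-s windows); thresholds persist across samples so that
    intrinsic plasticity acts on the whole stream.
    """
    config = state.config
    lif_p = config.lif_params()
    ip_p = config.ip_params()
    pop = state.population
    W = state.synapses.W
    events = spikes.events
    T = events.shape[1]
    raster = np.zeros((config.n_hidden, T), dtype=bool)
    pop.v = np.full(config.n_hidden, lif_p.v_rest)
    apply_ip = learn and config.ip_enabled
    for t in range(T):
        if apply_ip:
            ip_update(pop, ip_p)
        I = events[:, t] @ W  # signed ternary events weight the currents
        _, spiked = lif_step(pop, I, lif_p)
        raster[:, t] = spiked
    return raster


def process_sample(state: NetworkState, sample: StreamSample,
                   learn: bool = True, score: bool = True,
                   force_evolve: Optional[bool] = None) -> StepOutcome:
    """Run one test-then-train step; mutates ``state``.

    ``force_evolve`` overrides the structural-plasticity policy (used by
    the batch trainer, which evolves a neuron per training sample).
    """
    if sample.label not in state.classes:
        raise ValueError(f"unknown label {sample.label!r}; known: {state.classes}")
    config = state.config
    spikes = encode(sample.segment, config.aer_params())
    raster = _propagate(state, spikes, learn)
    if learn and config.stdp_enabled:
        stdp_apply(state.synapses, spikes, raster, config.stdp_params())
    candidate = rank_order_vector(raster, config.ro_params())

    # TEST: classify before any supervised learning from this sample
    predicted = distance = winner_id = None
    if len(state.repo):
        predicted, distance, winner_id = classify(candidate, state.repo)
    correct = (predicted == sample.label) if predicted is not None else None
    if predicted is not None and score:
        state.trace.record(sample.label, predicted)
        winner = next(n for n in state.repo.neurons if n.neuron_id == winner_id)
        if correct:
            winner.wins_correct += 1
        else:
            winner.wins_wrong += 1

    # TRAIN: structural changes only on errors (or during initiation)
    in_initiation = state.samples_seen < config.n_init_samples
    if force_evolve is not None:
        should_evolve = force_evolve
    elif not learn:
        should_evolve = False
    elif not config.structural_plasticity:
        should_evolve = True  # one neuron per sample, the no-SP baseline
    else:
        # an unclassifiable sample (empty repository) counts as an error
        should_evolve = in_initiation or correct is not True

    pruned = 0
    eliminated = 0
    if should_evolve:
        neuron = evolve_neuron(state.repo, candidate, sample.label,
                               sample_index=sample.index,
                               is_initiation=in_initiation)
        state.structural_events.append(
            {"event": "evolve", "index": sample.index, "id": neuron.neuron_id,
             "label": sample.label, "initiation": in_initiation})
    if (learn and config.structural_plasticity and not in_initiation
            and correct is False):
        counts = raster.sum(axis=1)
        ceiling = float(state.population.v_thr.max())
        self_prune(state.population, counts, config.prune_params())
        pruned = int((counts < config.sp_thresh).sum())
        if pruned:
            state.structural_events.append(
                {"event": "prune", "index": sample.index, "count": pruned,
                 "ceiling": ceiling})
        removed = eliminate_neurons(state.repo, config.min_errors)
        eliminated = len(removed)
        for n in removed:
            state.structural_events.append(
                {"event": "eliminate", "index": sample.index, "id": n.neuron_id,
                 "label": n.label})
    if (learn and config.update_initiation_neurons and predicted is not None
            and correct):
        # optional per-pass refinement: nudge the winning neuron towards the
        # candidate by the drift step, component-wise
        winner = next(n for n in state.repo.neurons if n.neuron_id == winner_id)
        winner.weights += config.d * np.sign(candidate - winner.weights)

    state.samples_seen += 1
    if state.samples_seen == config.n_init_samples and state.initiation_snapshot is None:
        state.initiation_snapshot = OutputRepository.from_json(state.repo.to_json())
    received = spikes.n_events
    generated = int(raster.sum())
    state.spikes_received_total += received
    state.spikes_generated_total += generated
    return StepOutcome(
        index=sample.index,
        true_label=sample.label,
        predicted_label=predicted,
        correct=correct,
        distance=distance,
        repo_size=len(state.repo),
        spikes_received=received,
        spikes_generated=generated,
        pruned_count=pruned,
        evolved=should_evolve,
        eliminated_count=eliminated,
    )


def _outcomes_frame(outcomes: list[StepOutcome]):
    import pandas as pd

    return pd.DataFrame([o.__dict__ for o in outcomes])


def _stream_classes(stream: Sequence[StreamSample]) -> tuple[str, ...]:
    seen: dict[str, None] = {}
    for s in stream:
        seen.setdefault(s.label, None)
    return tuple(sorted(seen))


def run_online(stream: Sequence[StreamSample], config: NetworkConfig,
               return_state: bool = False):
    """Single-pass test-then-train over the stream.

    With ``config.structural_plasticity`` off this is the no-SP online
    baseline: a neuron per sample, no pruning or elimination. Returns a
    :class:`StreamResult` (and the final state when requested).
    """
    stream = list(stream)
    if not stream:
        raise ValueError("stream must be nonempty")
    state = NetworkState.initialize(_stream_classes(stream),
                                    stream[0].segment.n_channels, config)
    outcomes = [process_sample(state, s) for s in stream]
    result = StreamResult(
        outcomes=_outcomes_frame(outcomes),
        trace=state.trace,
        final_repo_size=len(state.repo),
        spikes_received=state.spikes_received_total,
        spikes_generated=state.spikes_generated_total,
        mode="online",
    )
    return (result, state) if return_state else result


def run_batch(stream: Sequence[StreamSample], config: NetworkConfig,
              return_state: bool = False):
    """Train on the leading fraction of the stream, test frozen on the rest.

    The first ``floor(train_fraction * n)`` samples each evolve one
    output neuron (unsupervised STDP/IP learning active, no structural
    plasticity beyond neuron-per-sample); the remaining samples are
    classified with every form of learning frozen, and the standard
    accuracy over them is reported.
    """
    stream = list(stream)
    if not stream:
        raise ValueError("stream must be nonempty")
    n_train = math.floor(config.train_fraction * len(stream))
    if n_train < 1:
        raise ValueError("train_fraction leaves an empty training set")
    if n_train >= len(stream):
        raise ValueError("train_fraction leaves an empty test set")
    state = NetworkState.initialize(_stream_classes(stream),
                                    stream[0].segment.n_channels, config)
    outcomes = []
    for s in stream[:n_train]:
        outcomes.append(process_sample(state, s, learn=True, score=False,
                                       force_evolve=True))
    for s in stream[n_train:]:
        outcomes.append(process_sample(state, s, learn=False, score=True,
                                       force_evolve=False))
    result = StreamResult(
        outcomes=_outcomes_frame(outcomes),
        trace=state.trace,
        final_repo_size=len(state.repo),
        spikes_received=state.spikes_received_total,
        spikes_generated=state.spikes_generated_total,
        mode="batch",
    )
    return (result, state) if return_state else result
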