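"""Evolving rank-order output layer.

Each output neuron stores a weight vector over the hidden layer built
from one sample's hidden spike raster: the rank-order (RO) rule assigns
``alpha * mod**rank`` by order of first spike (earliest spike gets rank
0, hence the largest weight; silent neurons get 0), after which a small
drift ``d`` is added for every later step on which the neuron spiked
and subtracted for every silent step — so the final vector carries both
first-spike latency order and firing-rate information.

Classification is nearest-neighbour by Euclidean distance between the
incoming sample's candidate vector and the stored neurons; the winner's
label is the prediction. The repository starts empty, evolves one
neuron per sample during initiation, then (with structural plasticity)
only on errors; evolved neurons that keep winning wrongly are
eliminated, but the initiation set and the last neuron of any class are
always preserved.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ROParams",
    "OutputNeuron",
    "OutputRepository",
    "rank_order_vector",
    "classify",
    "evolve_neuron",
    "eliminate_neurons",
]


@dataclass(frozen=True)
class ROParams:
    """Rank-order learning parameters: alpha, modulation factor, drift."""

    alpha: float = 1.0
    mod: float = 0.8
    d: float = 0.001

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if not 0 < self.mod <= 1:
            raise ValueError("mod must lie in (0, 1]")


@dataclass
class OutputNeuron:
    weights: np.ndarray
    label: str
    created_at: int
    neuron_id: int
    wins_correct: int = 0
    wins_wrong: int = 0
    is_initiation: bool = False

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if not np.isfinite(self.weights).all():
            raise ValueError("output-neuron weights must be finite")


@dataclass
class OutputRepository:
    """Ordered, evolving collection of labeled output neurons."""

    neurons: list[OutputNeuron] = field(default_factory=list)
    _next_id: int = 0

    def __len__(self) -> int:
        return len(self.neurons)

    @property
    def class_set(self) -> set[str]:
        return {n.label for n in self.neurons}

    def counts_by_class(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for n in self.neurons:
            out[n.label] = out.get(n.label, 0) + 1
        return out

    # -- persistence --------------------------------------------------------

    def to_csv(self, path) -> None:
        """One row per neuron: id, label, created_at, counters, weights."""
        with open(path, "w") as fh:
            n_w = len(self.neurons[0].weights) if self.neurons else 0
            cols = ["id", "label", "created_at", "wins_correct", "wins_wrong",
                    "is_initiation"] + [f"w{i}" for i in range(n_w)]
            fh.write(",".join(cols) + "\n")
            for n in self.neurons:
                row = [str(n.neuron_id), n.label, str(n.created_at),
                       str(n.wins_correct), str(n.wins_wrong),
                       str(int(n.is_initiation))]
                row += [repr(w) for w in n.weights]
                fh.write(",".join(row) + "\n")

    def to_json(self) -> str:
        return json.dumps(
            {
                "next_id": self._next_id,
                "neurons": [
                    {
                        "id": n.neuron_id,
                        "label": n.label,
                        "created_at": n.created_at,
                        "wins_correct": n.wins_correct,
                        "wins_wrong": n.wins_wrong,
                        "is_initiation": n.is_initiation,
                        "weights": n.weights.tolist(),
                    }
                    for n in self.neurons
                ],
            }
        )

    @classmethod
    def from_json(cls, payload: str) -> "OutputRepository":
        d = json.loads(payload)
        repo = cls(_next_id=d["next_id"])
        for nd in d["neurons"]:
            repo.neurons.append(
                OutputNeuron(
                    weights=np.asarray(nd["weights"], dtype=float),
                    label=nd["label"],
                    created_at=nd["created_at"],
                    neuron_id=nd["id"],
                    wins_correct=nd["wins_correct"],
                    wins_wrong=nd["wins_wrong"],
                    is_initiation=nd["is_initiation"],
                )
            )
        return repo


class RepositoryEmptyError(RuntimeError):
    """Raised when classification is attempted before any neuron exists."""


def rank_order_vector(
    hidden_raster: np.ndarray, params: ROParams = ROParams()
) -> np.ndarray:
    """Candidate weight vector from one sample's hidden spike raster.

    ``hidden_raster`` is (n_hidden x timepoints), boolean/0-1. Neurons
    are ranked by first-spike time (ties broken by neuron index); rank r
    gets ``alpha * mod**r``. Never-spiking neurons get 0. Each step after
    a neuron's first spike then drifts its weight by +d (spike) or -d
    (silence). An all-silent raster yields the zero vector.
    """
    raster = np.asarray(hidden_raster).astype(bool)
    if raster.ndim != 2:
        raise ValueError("hidden raster must be 2-D (neurons x timepoints)")
    n, T = raster.shape
    weights = np.zeros(n)
    spiked = raster.any(axis=1)
    if not spiked.any():
        return weights
    first = np.where(spiked, raster.argmax(axis=1), T)
    # stable argsort: earliest first-spike gets rank 0, index breaks ties
    order = np.argsort(first[spiked], kind="stable")
    idx = np.flatnonzero(spiked)[order]
    weights[idx] = params.alpha * params.mod ** np.arange(idx.size)
    if params.d != 0:
        steps_after = T - 1 - first[spiked]  # steps following the first spike
        spikes_after = raster[spiked].sum(axis=1) - 1  # excluding the first
        weights[spiked] += params.d * (2 * spikes_after - steps_after)
    return weights


def classify(
    candidate: np.ndarray, repo: OutputRepository
) -> tuple[str, float, int]:
    """Label of the nearest stored neuron by Euclidean distance.

    Ties go to the earliest-created neuron (repository order is by
    creation, so the first minimum wins). Returns (label, distance, id).
    """
    if not repo.neurons:
        raise RepositoryEmptyError("output repository is empty; nothing to classify with")
    candidate = np.asarray(candidate, dtype=float)
    W = np.stack([n.weights for n in repo.neurons])
    dists = np.linalg.norm(W - candidate, axis=1)
    by_age = sorted(range(len(repo.neurons)),
                    key=lambda i: (repo.neurons[i].created_at, repo.neurons[i].neuron_id))
    winner = min(by_age, key=lambda i: dists[i])
    return repo.neurons[winner].label, float(dists[winner]), repo.neurons[winner].neuron_id


def evolve_neuron(
    repo: OutputRepository,
    candidate: np.ndarray,
    true_label: str,
    sample_index: int,
    is_initiation: bool = False,
) -> OutputNeuron:
    """Append a new output neuron holding the candidate vector and true label."""
    neuron = OutputNeuron(
        weights=np.asarray(candidate, dtype=float).copy(),
        label=true_label,
        created_at=sample_index,
        neuron_id=repo._next_id,
        is_initiation=is_initiation,
    )
    repo._next_id += 1
    repo.neurons.append(neuron)
    return neuron


def eliminate_neurons(repo: OutputRepository, min_errors: int = 3) -> list[OutputNeuron]:
    """Drop evolved neurons that mostly win wrongly; returns the removed ones.

    A neuron is eliminated when it is not an initiation neuron, has
    ``wins_wrong >= min_errors`` and ``wins_wrong > wins_correct`` — but
    never when it is the last remaining neuron of its class.
    """
    removed: list[OutputNeuron] = []
    counts = repo.counts_by_class()
    kept: list[OutputNeuron] = []
    for n in repo.neurons:
        eliminable = (
            not n.is_initiation
            and n.wins_wrong >= min_errors
            and n.wins_wrong > n.wins_correct
            and counts[n.label] > 1
        )
        if eliminable:
            removed.append(n)
            counts[n.label] -= 1
        else:
            kept.append(n)
    repo.neurons = kept
    return removed
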