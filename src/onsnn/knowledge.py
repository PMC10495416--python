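"""Interpretation of trained models.

After a stream has been processed, the model state itself carries
information about the input classes: the output repository holds one
weight vector per remembered sample (a numerical representation of the
segment that evolved it), and the input->hidden synaptic matrix has
accumulated the spatiotemporal correlations of the inputs through STDP.

Three read-outs are provided:

* class-centroid distances — the Euclidean distance of each class's
  mean output-neuron weight vector from a designated baseline class
  (the neutral state, typically);
* channel fan-out — per input channel, the summed excitatory, summed
  inhibitory and net synaptic weight fanning out to the hidden layer;
* initiation-vs-final drift — per initiation neuron, how far its
  weight vector moved between the end of initiation and stream end.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .output import OutputRepository
from .plasticity import SynapticMatrix

__all__ = [
    "KnowledgeReport",
    "class_centroid_distances",
    "channel_fanout",
    "initial_vs_final_drift",
    "build_report",
]


@dataclass(frozen=True)
class KnowledgeReport:
    class_centroids: Mapping[str, np.ndarray]
    centroid_distances: Mapping[str, float]
    baseline_class: str
    channel_fanout: Mapping[str, dict]
    initial_vs_final: Mapping[int, float]

    def to_dict(self) -> dict:
        return {
            "baseline_class": self.baseline_class,
            "centroid_distances": dict(self.centroid_distances),
            "channel_fanout": {k: dict(v) for k, v in self.channel_fanout.items()},
            "initial_vs_final": {str(k): v for k, v in self.initial_vs_final.items()},
        }


def class_centroid_distances(
    repo: OutputRepository, baseline_class: str
) -> tuple[dict[str, np.ndarray], dict[str, float]]:
    """Per-class centroids and their Euclidean distances to the baseline.

    The centroid of a class is the mean of its output neurons' weight
    vectors. Raises ``ValueError`` if the baseline class (or any class
    needed) has no neurons.
    """
    if baseline_class not in repo.class_set:
        raise ValueError(f"baseline class {baseline_class!r} has no neurons in the repository")
    centroids: dict[str, np.ndarray] = {}
    for cls in sorted(repo.class_set):
        vecs = [n.weights for n in repo.neurons if n.label == cls]
        centroids[cls] = np.mean(vecs, axis=0)
    base = centroids[baseline_class]
    distances = {
        cls: float(np.linalg.norm(centroids[cls] - base))
        for cls in centroids
        if cls != baseline_class
    }
    return centroids, distances


def channel_fanout(syn: SynapticMatrix, channel_names: Sequence[str]) -> dict[str, dict]:
    """Per-channel summed excitatory / inhibitory / net fan-out weights."""
    if len(channel_names) != syn.n_inputs:
        raise ValueError(
            f"{len(channel_names)} channel names for {syn.n_inputs} weight rows")
    out: dict[str, dict] = {}
    for name, row in zip(channel_names, syn.W):
        exc = float(row[row > 0].sum())
        inh = float(row[row < 0].sum())
        out[name] = {"excitatory": exc, "inhibitory": inh, "net": float(row.sum())}
    return out


def initial_vs_final_drift(
    initial: OutputRepository, final: OutputRepository
) -> dict[int, float]:
    """Euclidean distance each initiation neuron moved between snapshots.

    Neurons are matched by id; every initiation neuron present in the
    initial snapshot must still exist in the final repository.
    """
    final_by_id = {n.neuron_id: n for n in final.neurons}
    out: dict[int, float] = {}
    for n in initial.neurons:
        if not n.is_initiation:
            continue
        if n.neuron_id not in final_by_id:
            raise ValueError(f"initiation neuron id {n.neuron_id} missing from final snapshot")
        out[n.neuron_id] = float(
            np.linalg.norm(final_by_id[n.neuron_id].weights - n.weights))
    return out


def build_report(
    repo: OutputRepository,
    syn: SynapticMatrix,
    channel_names: Sequence[str],
    baseline_class: str,
    initiation_snapshot: OutputRepository | None = None,
) -> KnowledgeReport:
    """Assemble the full interpretation report for one trained model."""
    centroids, distances = class_centroid_distances(repo, baseline_class)
    drift = (
        initial_vs_final_drift(initiation_snapshot, repo)
        if initiation_snapshot is not None
        else {}
    )
    return KnowledgeReport(
        class_centroids=centroids,
        centroid_distances=distances,
        baseline_class=baseline_class,
        channel_fanout=channel_fanout(syn, channel_names),
        initial_vs_final=drift,
    )
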