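"""Stream evaluation: prequential accuracy, sensitivity, efficiency.

Prequential (test-then-train) accuracy is the running mean of the 0/1
correctness sequence, maintained incrementally:

    acc(t) = acc(t-1) + (c_t - acc(t-1)) / (t - t_init + 1),

which equals the batch arithmetic mean of correctness at every step.
Sensitivity is the true-positive rate of a designated positive class
(stress, in the EEG application). The spike ratio — hidden-layer spikes
generated divided by input spikes received — summarizes the temporal
sparsification achieved by intrinsic plasticity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EvalTrace",
    "StreamResult",
    "prequential_update",
    "sensitivity",
    "spike_ratio",
]


@dataclass
class EvalTrace:
    """Incrementally updated correctness trace and confusion matrix."""

    classes: tuple[str, ...]
    t_init: int = 0
    correctness: list[bool] = field(default_factory=list)
    acc_pre: list[float] = field(default_factory=list)
    confusion: np.ndarray = field(default=None)  # true x predicted

    def __post_init__(self) -> None:
        if self.confusion is None:
            k = len(self.classes)
            self.confusion = np.zeros((k, k), dtype=int)

    @property
    def final_accuracy(self) -> Optional[float]:
        return self.acc_pre[-1] if self.acc_pre else None

    def record(self, true_label: str, predicted_label: str) -> None:
        """Score one test-then-train prediction."""
        correct = true_label == predicted_label
        i = self.classes.index(true_label)
        j = self.classes.index(predicted_label)
        self.confusion[i, j] += 1
        prequential_update(self, correct)


def prequential_update(trace: EvalTrace, correct: bool) -> EvalTrace:
    """Append one 0/1 outcome and extend the running-accuracy trace."""
    trace.correctness.append(bool(correct))
    c = 1.0 if correct else 0.0
    if not trace.acc_pre:
        trace.acc_pre.append(c)
    else:
        prev = trace.acc_pre[-1]
        t = len(trace.acc_pre)  # zero-based step index relative to t_init
        trace.acc_pre.append(prev + (c - prev) / (t + 1))
    return trace


def sensitivity(confusion: np.ndarray, classes: Sequence[str], positive_class: str) -> float:
    """TP / (TP + FN) for the designated positive class.

    Raises ``ValueError`` when no sample of the positive class was
    scored (the rate is undefined).
    """
    if positive_class not in classes:
        raise ValueError(f"unknown positive class {positive_class!r}")
    confusion = np.asarray(confusion)
    i = list(classes).index(positive_class)
    total = confusion[i].sum()
    if total == 0:
        raise ValueError(f"no samples of class {positive_class!r} were scored; "
                         "sensitivity is undefined")
    return float(confusion[i, i] / total)


def spike_ratio(received: int, generated: int) -> float:
    """Hidden-layer sparsification ratio: spikes generated / spikes received."""
    if received <= 0:
        raise ValueError("spike ratio undefined: no spikes were received")
    return generated / received


@dataclass
class StreamResult:
    """Full outcome of one streaming (or batch) run."""

    outcomes: pd.DataFrame  # one row per StepOutcome
    trace: EvalTrace
    final_repo_size: int
    spikes_received: int
    spikes_generated: int
    mode: str = "online"

    @property
    def final_accuracy(self) -> Optional[float]:
        return self.trace.final_accuracy

    @property
    def spike_ratio(self) -> Optional[float]:
        if self.spikes_received == 0:
            return None
        return spike_ratio(self.spikes_received, self.spikes_generated)

    def sensitivity(self, positive_class: str) -> float:
        return sensitivity(self.trace.confusion, self.trace.classes, positive_class)

    def summary(self, positive_class: Optional[str] = None) -> dict:
        out = {
            "mode": self.mode,
            "samples_scored": len(self.trace.correctness),
            "final_accuracy": self.final_accuracy,
            "final_repo_size": self.final_repo_size,
            "spikes_received": self.spikes_received,
            "spikes_generated": self.spikes_generated,
            "spike_ratio": self.spike_ratio,
        }
        if positive_class is not None:
            try:
                out["sensitivity"] = self.sensitivity(positive_class)
            except ValueError:
                out["sensitivity"] = None
        return out
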