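"""Leaky integrate-and-fire hidden layer with intrinsic plasticity.

The membrane potential of each neuron follows the RC-circuit equation

    tau_m * dv/dt = v_rest - v + R * I(t),    tau_m = R * C,

integrated with forward Euler at one step per input sample period. A
neuron spikes when its potential reaches its own threshold and resets to
``v_rest`` (no refractory period).

Intrinsic plasticity (IP) adapts each neuron's threshold towards firing
homeostasis: a neuron that spiked on the previous step raises its
threshold by ``N * theta_pos * v_init``; a silent neuron lowers it by
``N * theta_neg * v_init``. Down-regulation is floored at a configurable
fraction of the initial threshold so thresholds can never reach the
resting potential (which would make the neuron fire on any input).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["LIFParams", "IPParams", "LIFPopulation", "lif_step", "ip_update"]


@dataclass(frozen=True)
class LIFParams:
    """Membrane parameters. tau_m = R * C; dt is one sample period (unit step)."""

    v_thresh_init: float = 0.05
    v_rest: float = 0.0
    R: float = 1.0
    C: float = 10.0
    dt: float = 1.0

    def __post_init__(self) -> None:
        if self.R <= 0 or self.C <= 0 or self.dt <= 0:
            raise ValueError("R, C and dt must all be positive")
        if self.v_thresh_init <= self.v_rest:
            raise ValueError("initial threshold must exceed the resting potential")

    @property
    def tau_m(self) -> float:
        return self.R * self.C


@dataclass(frozen=True)
class IPParams:
    """Intrinsic-plasticity learning rates (both dimensionless, >= 0).

    ``theta_pos`` up-regulates thresholds after a spike; ``theta_neg``
    slowly down-regulates them during silence. ``floor_fraction`` sets
    the lowest admissible threshold as a fraction of the initial value.
    """

    theta_pos: float = 0.001
    theta_neg: float = 0.000001
    floor_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.theta_pos < 0 or self.theta_neg < 0:
            raise ValueError("IP learning rates must be >= 0")
        if not 0 < self.floor_fraction <= 1:
            raise ValueError("floor_fraction must lie in (0, 1]")


@dataclass
class LIFPopulation:
    """Mutable state of N hidden neurons: potentials, thresholds, last spikes."""

    v: np.ndarray
    v_thr: np.ndarray
    v_init: float
    last_spiked: np.ndarray
    n: int = field(init=False)

    def __post_init__(self) -> None:
        self.v = np.asarray(self.v, dtype=float)
        self.v_thr = np.asarray(self.v_thr, dtype=float)
        self.last_spiked = np.asarray(self.last_spiked, dtype=bool)
        if not (self.v.shape == self.v_thr.shape == self.last_spiked.shape):
            raise ValueError("v, v_thr and last_spiked must share one shape")
        if self.v.ndim != 1 or self.v.size < 1:
            raise ValueError("population must hold at least one neuron")
        self.n = self.v.size

    @classmethod
    def fresh(cls, n: int, params: LIFParams) -> "LIFPopulation":
        """A population at rest with uniform initial thresholds."""
        if n < 1:
            raise ValueError("need at least one neuron")
        return cls(
            v=np.full(n, params.v_rest),
            v_thr=np.full(n, params.v_thresh_init),
            v_init=params.v_thresh_init,
            last_spiked=np.zeros(n, dtype=bool),
        )

    def copy(self) -> "LIFPopulation":
        return LIFPopulation(
            v=self.v.copy(),
            v_thr=self.v_thr.copy(),
            v_init=self.v_init,
            last_spiked=self.last_spiked.copy(),
        )

    # -- checkpoint / resume ------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "v": self.v.tolist(),
                "v_thr": self.v_thr.tolist(),
                "v_init": self.v_init,
                "last_spiked": self.last_spiked.astype(int).tolist(),
            }
        )

    @classmethod
    def from_json(cls, payload: str) -> "LIFPopulation":
        d = json.loads(payload)
        return cls(
            v=np.asarray(d["v"], dtype=float),
            v_thr=np.asarray(d["v_thr"], dtype=float),
            v_init=float(d["v_init"]),
            last_spiked=np.asarray(d["last_spiked"], dtype=bool),
        )


def lif_step(
    pop: LIFPopulation, I: np.ndarray, params: LIFParams
) -> tuple[LIFPopulation, np.ndarray]:
    """Advance the population one Euler step under input current ``I``.

    Returns the updated population (mutated in place) and the boolean
    spike vector. Neurons whose potential reaches their threshold spike
    and reset to ``v_rest``.
    """
    I = np.asarray(I, dtype=float)
    if I.shape != pop.v.shape:
        raise ValueError(f"current vector shape {I.shape} != population size {pop.n}")
    pop.v += (params.dt / params.tau_m) * (params.v_rest - pop.v + params.R * I)
    spikes = pop.v >= pop.v_thr
    pop.v[spikes] = params.v_rest
    pop.last_spiked = spikes
    return pop, spikes


def ip_update(pop: LIFPopulation, params: IPParams) -> LIFPopulation:
    """Adapt thresholds from the previous step's spike pattern.

    Spiked neurons: v_thr += N * theta_pos * v_init.
    Silent neurons: v_thr -= N * theta_neg * v_init, floored at
    ``floor_fraction * v_init`` above rest.
    """
    up = pop.n * params.theta_pos * pop.v_init
    down = pop.n * params.theta_neg * pop.v_init
    pop.v_thr = np.where(pop.last_spiked, pop.v_thr + up, pop.v_thr - down)
    floor = params.floor_fraction * pop.v_init
    np.maximum(pop.v_thr, floor, out=pop.v_thr)
    return pop
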