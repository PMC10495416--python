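"""Unsupervised plasticity: STDP on input->hidden synapses and self-pruning.

STDP follows the classic exponential pair rule. With ``dt`` the post
minus pre spike-time difference,

    F(dt) =  A_plus  * exp(-dt / tau_pos)   for dt > 0   (LTP)
    F(dt) = -A_minus * exp( dt / tau_neg)   for dt < 0   (LTD)
    F(0)  = 0,

and pairs farther apart than ``pair_window`` steps contribute nothing.
The cumulative delta over every (pre, post) spike pair in a sample is
applied once at sample end, then clipped to [w_min, w_max]. An input
event of either sign (excitatory or inhibitory) counts as a presynaptic
spike for pairing purposes; the event sign enters the dynamics through
the signed input current, not through the learning rule.

Self-pruning temporarily silences hidden neurons that spiked fewer than
``sp_thresh`` times during the just-processed sample by raising their
threshold to the population maximum; IP down-regulation later recovers
them. It is triggered only after a classification error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .aer import SpikeTrain
from .lif import LIFPopulation

__all__ = [
    "STDPParams",
    "PruneParams",
    "SynapticMatrix",
    "init_weights",
    "stdp_pair_delta",
    "stdp_apply",
    "self_prune",
]


@dataclass(frozen=True)
class STDPParams:
    A_plus: float = 0.001
    A_minus: float = 0.001
    tau_pos: float = 10.0
    tau_neg: float = 10.0
    w_max: float = 0.5
    w_min: float = -0.5
    pair_window: int = 50  # 5 * max(tau): beyond that F < A * e^-5

    def __post_init__(self) -> None:
        if self.w_min >= self.w_max:
            raise ValueError("w_min must be below w_max")
        if self.tau_pos <= 0 or self.tau_neg <= 0:
            raise ValueError("STDP time constants must be positive")
        if self.pair_window <= 0:
            raise ValueError("pair_window must be positive")


@dataclass(frozen=True)
class PruneParams:
    """Self-pruning spike-count threshold (Table of defaults: 1)."""

    sp_thresh: int = 1

    def __post_init__(self) -> None:
        if self.sp_thresh < 0:
            raise ValueError("sp_thresh must be >= 0")


@dataclass
class SynapticMatrix:
    """Input->hidden weights, shape (n_inputs, n_hidden), bounded."""

    W: np.ndarray
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.W.ndim != 2:
            raise ValueError("weight matrix must be 2-D (inputs x hidden)")

    @property
    def n_inputs(self) -> int:
        return self.W.shape[0]

    @property
    def n_hidden(self) -> int:
        return self.W.shape[1]

    def to_csv(self, path) -> None:
        """Inputs as rows, hidden neurons as columns."""
        header = ",".join(f"h{j}" for j in range(self.n_hidden))
        np.savetxt(path, self.W, delimiter=",", header=header, comments="")


def init_weights(
    n_inputs: int,
    n_hidden: int,
    seed: int,
    sigma: float = 0.1,
    params: STDPParams = STDPParams(),
) -> SynapticMatrix:
    """Zero-mean Gaussian weights, clipped to [w_min, w_max], seeded."""
    if n_inputs < 1 or n_hidden < 1:
        raise ValueError("layer sizes must be >= 1")
    rng = np.random.default_rng(seed)
    W = rng.normal(0.0, sigma, size=(n_inputs, n_hidden)) if sigma > 0 else np.zeros(
        (n_inputs, n_hidden)
    )
    np.clip(W, params.w_min, params.w_max, out=W)
    return SynapticMatrix(W=W, rng_seed=seed)


def stdp_pair_delta(delta_t: float, params: STDPParams) -> float:
    """Weight change for one pre/post pair at timing difference post - pre."""
    if delta_t == 0 or abs(delta_t) > params.pair_window:
        return 0.0
    if delta_t > 0:
        return params.A_plus * float(np.exp(-delta_t / params.tau_pos))
    return -params.A_minus * float(np.exp(delta_t / params.tau_neg))


def stdp_apply(
    syn: SynapticMatrix,
    pre_spikes: SpikeTrain,
    post_spikes: np.ndarray,
    params: STDPParams = STDPParams(),
) -> SynapticMatrix:
    """Apply the cumulative STDP delta for one sample, then clip.

    ``post_spikes`` is a boolean/0-1 raster (n_hidden x timepoints)
    covering the same window as ``pre_spikes``. For every synapse (i, j)
    the delta sums F(t_post - t_pre) over all spike pairs within the
    pair window. Implemented as a sum of lagged raster products, which
    is exactly the double loop over pairs.
    """
    pre = (np.asarray(pre_spikes.events) != 0).astype(float)
    post = np.asarray(post_spikes, dtype=float)
    if post.ndim != 2 or post.shape[1] != pre.shape[1]:
        raise ValueError(
            "pre and post rasters must cover the same sample window "
            f"(pre T={pre.shape[1]}, post shape={post.shape})"
        )
    if pre.shape[0] != syn.n_inputs or post.shape[0] != syn.n_hidden:
        raise ValueError("raster neuron counts do not match the weight matrix")
    T = pre.shape[1]
    delta = np.zeros_like(syn.W)
    for lag in range(1, min(params.pair_window, T - 1) + 1):
        # post fires `lag` steps after pre -> LTP
        ltp = params.A_plus * np.exp(-lag / params.tau_pos)
        delta += ltp * (pre[:, : T - lag] @ post[:, lag:].T)
        # post fires `lag` steps before pre -> LTD
        ltd = params.A_minus * np.exp(-lag / params.tau_neg)
        delta -= ltd * (pre[:, lag:] @ post[:, : T - lag].T)
    syn.W = np.clip(syn.W + delta, params.w_min, params.w_max)
    return syn


def self_prune(
    pop: LIFPopulation, spike_counts: np.ndarray, params: PruneParams = PruneParams()
) -> LIFPopulation:
    """Silence low-firing neurons by raising their threshold to the population max.

    ``spike_counts`` are per-neuron totals over the just-processed
    sample. Neurons with count < sp_thresh get v_thr = max(v_thr) taken
    before the call; they stay in the network and recover through IP
    down-regulation. Weights are untouched.
    """
    counts = np.asarray(spike_counts)
    if counts.shape != pop.v_thr.shape:
        raise ValueError("spike_counts must have one entry per neuron")
    ceiling = pop.v_thr.max()
    pop.v_thr = np.where(counts < params.sp_thresh, ceiling, pop.v_thr)
    return pop
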