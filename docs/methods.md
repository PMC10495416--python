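# Methods

This note documents the model as implemented, the parameter choices,
the synthetic data the tests run on, and the numerical/design decisions
taken where the architecture leaves room. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Model and assumptions

The network is a feed-forward three-layer spiking classifier operating
on fixed-length multichannel segments. The central assumption of the
whole design is that class identity is expressed in the *timing
structure* of threshold-crossing events: the AER encoder deliberately
normalizes each channel's amplitude scale (its threshold is
`mean + f·std` of the segment's own differences), so a model
downstream of it can only ever see when events occur, not how large
the underlying signal was.

### Spike encoding

The encoder is the three-state (excitatory / silent / inhibitory)
symmetric-threshold convention: +1 when the temporal difference
strictly exceeds the threshold, −1 when it falls strictly below the
negated threshold. The threshold uses the *population* standard
deviation (no Bessel correction) and is computed per channel over the
whole segment, not as a running statistic — segments arrive whole, and
a batch threshold keeps encoding deterministic and order-free within a
segment. Time step 0 has no predecessor and is always silent. Ties at
the threshold emit nothing.

### Hidden layer

Leaky integrate-and-fire with forward Euler and `dt` equal to one
sample period; with the default R = 1, C = 10 this makes the membrane
time constant 10 sample steps (≈ 39 ms at 256 Hz), i.e. the membrane
low-passes the event train on roughly the beta-band time scale. Input
current is the signed, weighted sum of the ternary events (one input
node per channel). After a spike the potential resets to `v_rest`;
there is no refractory period. Membrane potentials restart from rest
at each segment (segments are disjoint windows); thresholds and
synaptic weights persist across the stream.

Intrinsic plasticity runs at every time step using the previous step's
spike flags: +`N·θ₊·v_init` after a spike, −`N·θ₋·v_init` otherwise.
Two consequences worth knowing:

* the long-run equilibrium firing rate is `(θ₋/θ₊)·T` spikes per
  neuron per T-step sample — ≈ 1.3 at the defaults (θ₊ = 1e-3,
  θ₋ = 1e-6, T = 1280) regardless of drive strength. IP is the
  mechanism behind the hidden layer's temporal sparseness, and it
  works by *flattening rate differences*;
* unbounded down-regulation would drive thresholds to the resting
  potential and make neurons fire on anything, so thresholds are
  floored at `floor_fraction · v_init` (default 10%).

STDP is the classic exponential pair rule, accumulated over all
(pre, post) spike pairs of a sample and applied once at sample end —
the cumulative form admits an exact brute-force oracle, which the test
suite exploits. An input event of either sign counts as a presynaptic
spike for pairing; polarity affects the dynamics only through the
signed current. Pairs farther apart than `pair_window` = 5·max(τ₊, τ₋)
= 50 steps are ignored (their contribution is < e⁻⁵ of the maximum).
Weights are clipped to [w_min, w_max] after every update. The initial
weights are zero-mean Gaussian with σ = 0.1 (configurable), clipped to
the same bounds.

Self-pruning, triggered only after a classification error, raises the
threshold of every neuron that emitted fewer than `sp_thresh` spikes
in the just-processed sample to the population's current maximum
threshold. Pruned neurons stay in the network; IP down-regulation
slowly lowers their threshold until they can fire again, so pruning is
a temporary silencing, not a deletion. No separate recovery timer is
kept.

### Output layer

The candidate vector for a sample combines a latency code (α·mod^rank
of first-spike order; silent neurons get exactly 0) and a rate code
(the per-step ±d drift after the first spike, which works out to
`d·(2·extra_spikes − steps_after_first)`). First-spike ties are broken
by neuron index, deterministically. Classification is 1-nearest-
neighbour in Euclidean distance over all N hidden dimensions; distance
ties go to the earliest-created neuron. Self-pruned (silent) neurons
contribute zeros to the candidate automatically — no explicit masking.

The repository lifecycle: empty at stream start; the first 15 samples
each evolve one labeled "initiation" neuron (predictions are still
made and scored from the second sample on, as soon as one neuron
exists); afterwards a neuron is evolved only when the prediction was
wrong (or impossible). Elimination — the mechanism that adapts the
repertoire under concept drift — removes an evolved neuron once it has
won wrongly at least `min_errors` times (default 3) *and* has more
wrong than correct wins. Two guards: initiation neurons are never
eliminated, and a class is never emptied. A per-pass drift update of
the initiation neurons' weights exists behind
`update_initiation_neurons` but is off by default: the mechanism is
under-determined, and enabling a guessed version changed nothing
measurable in our experiments.

With structural plasticity off, the same loop becomes the online
baseline (one neuron per sample, nothing pruned or eliminated). Batch
mode evolves one neuron for each of the first ⌊0.7·n⌋ samples in
stream order (for 72 samples: 50 training neurons, 22 test
predictions) and then freezes every form of learning — weights,
thresholds and the repository — before classifying the rest; standard
accuracy is reported there, prequential accuracy everywhere else.

## Hyperparameters

| name | default | units / meaning |
|---|---|---|
| f | 0.7 | AER threshold factor (dimensionless) |
| v_thresh, v_rest | 0.05, 0 | initial threshold and resting potential (V) |
| R, C | 1, 10 | membrane resistance/capacitance; τ_m = 10 steps |
| A₊, A₋ | 0.001 | max STDP potentiation / depression |
| τ₊, τ₋ | 10 | STDP time constants (steps) |
| w_max, w_min | ±0.5 | synaptic bounds |
| θ₊, θ₋ | 1e-3, 1e-6 | IP up/down learning rates |
| sp_thresh | 1 | self-pruning spike-count threshold |
| α, mod, d | 1, 0.8, 0.001 | rank-order and drift parameters |
| n_hidden | 100 | hidden neurons (not dictated by the architecture) |
| n_init_samples | 15 | initiation neurons |
| min_errors | 3 | elimination threshold (our rule; see above) |
| init_sigma | 0.1 | σ of the Gaussian weight init |
| pair_window | 50 | STDP pair cutoff (5·max τ) |

The IP learning rates are, in the original setting, tuned per subject
by an unspecified criterion; the fixed defaults above are used
throughout and both rates are exposed in the config. `n_hidden` is
likewise not fixed by the architecture; 100 keeps the IP step
(`N·θ₊·v_init` = 10% of the initial threshold per spike) in a regime
where thresholds equilibrate within a few samples.

## Synthetic data

Each segment is, per channel, a sum of band-limited sinusoids (3 per
band at uniformly random frequencies and phases within delta 1–4,
theta 4–8, alpha 8–13, beta 13–30 Hz), scaled by the class's band
profile, plus unit-variance 1/f noise (σ = 0.5) and white noise
(σ = 0.5). Default profiles give stress a beta-dominant spectrum
(beta 2.0, alpha 0.5), positive an alpha-dominant one (mirrored), and
neutral a flat one — a deliberately generic caricature of stress-EEG
band findings. Streams are 72 samples, 24 per class, seeded shuffle;
input drift rescales amplitudes from a given index, concept drift
permutes the label sources from a given index.

What the generator does *not* emulate — and why that matters for
interpreting test results: real EEG has cross-channel coherence and
topographic class signatures, transient oscillatory bursts, and
evoked (stimulus-locked) latency structure. The generated channels
are independent and stationary with random phases, so there is no
reliable latency information for the first-spike code, and — because
the AER threshold normalizes amplitude per segment — class identity
survives only in within-segment timing statistics, which IP's rate
clamp further flattens. Passing tests therefore demonstrate that the
rules are implemented exactly and the streaming contracts hold; the
absolute accuracy on these streams (≈ 0.36–0.49 over seeds against a
0.33 chance level, as recomputed by `scripts/acceptance.py`) is a
property of this stream family and sets no expectation for real EEG.
The full model and its no-structural-plasticity baseline perform
equivalently on these streams for the same reason: the mechanisms
structural plasticity contributes (eliminating stale neurons after
abrupt drift) pay off only when within-class candidate variance is
small relative to the drift-induced displacement, which this
representation does not achieve. The efficiency results, in contrast,
are robust here: IP reduces hidden spiking by roughly an order of
magnitude and more (the no-IP ablation generates ~30× the spikes), and
the spike ratio lands in the few-percent range.

## Numerical choices and degenerate inputs

* Population (ddof = 0) standard deviation in the AER threshold;
  strict inequalities; ties emit no spike. A channel whose threshold
  is negative (possible when the mean difference is strongly negative)
  resolves the overlapping conditions in favour of the excitatory
  spike.
* Forward Euler; spike when `v ≥ v_thr` after the update; reset to
  `v_rest`. The Euler solution matches the RC closed form to O(dt)
  for subthreshold constant input (tested).
* All-silent hidden rasters yield a zero candidate vector and are
  classified like any other (distance to every stored neuron is then
  the norm of its weights).
* An unclassifiable sample (empty repository, only possible when
  `n_init_samples = 0`) is treated as an error for training purposes.
* The batch split uses ⌊train_fraction·n⌋ training samples (floor, so
  that 0.70 of 72 gives the canonical 50/22 split).
* Determinism: every stochastic component (weight init, stream
  generation, shuffling) derives from explicit integer seeds; two runs
  with the same config and stream are bit-identical (tested).

## Known limitations

* Single subject / single stream: no pooling or transfer across
  streams, by design.
* No refractory period, no conductance synapses, no triplet or
  weight-dependent STDP.
* The elimination rule and the initiation-neuron per-pass update are
  interpretations where the architecture is under-specified; both are
  isolated behind config parameters.
* EDF/BDF readers are out of scope; inputs are preprocessed delimited
  matrices.
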