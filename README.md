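# onsnn — online neuroplasticity spiking neural network

`onsnn` implements a three-layer spiking neural network that classifies
multichannel physiological time series (the motivating application is
EEG-based cognitive-state recognition: stress / neutral / positive)
**while learning on the fly**, one sample at a time, under the
test-then-train protocol. It is aimed at researchers studying online
learning under concept drift with biologically inspired models, and at
anyone who needs a compact, fully seeded reference implementation of the
constituent plasticity rules.

## The model

A labeled stream of segments (channels × time, e.g. 4 channels × 1280
points for 5 s at 256 Hz) is processed single-pass:

1. **Spike encoding (AER).** Per channel, the temporal difference
   `tempdiff(t) = x(t) − x(t−1)` is compared against an adaptive
   threshold `mean(tempdiff) + f·std(tempdiff)` computed over the
   segment: above it an excitatory spike (+1), below its negation an
   inhibitory spike (−1), otherwise silence.
2. **Hidden layer (LIF + STDP + IP).** N leaky integrate-and-fire
   neurons, `τ_m dv/dt = v_rest − v + R·I(t)` with `I(t) = Σ_i W_ij s_i(t)`,
   forward-Euler at one step per sample point. Input→hidden weights
   learn by pair-based STDP, `F(Δt) = A₊ e^(−Δt/τ₊)` for post-after-pre
   and `−A₋ e^(Δt/τ₋)` for pre-after-post, accumulated over a sample and
   clipped to `[w_min, w_max]`. Intrinsic plasticity adapts each
   threshold: `v_thr += N·θ₊·v_init` after a spike, `−N·θ₋·v_init`
   otherwise — enforcing sparse, homeostatic firing.
3. **Output layer (evolving rank-order classifier).** Each sample's
   hidden raster becomes a candidate vector: `α·mod^rank` by order of
   first spike, then a per-step drift ±d after the first spike.
   Classification is nearest-neighbour by Euclidean distance over the
   stored output neurons. The repository starts empty, evolves one
   neuron per sample for the first 15 samples, and afterwards only on
   classification errors; errors also self-prune low-firing hidden
   neurons (threshold raised to the population maximum, recoverable)
   and eliminate output neurons that repeatedly win wrongly.

Two ablation baselines ship with the runtime: the same online network
without structural plasticity (one output neuron per sample, no
pruning/elimination) and a batch 70/30 train/test variant with learning
frozen at test time. Evaluation is prequential (running mean of the 0/1
correctness), plus per-class sensitivity and the hidden-layer spike
ratio (spikes generated / spikes received).

Because the EEG recordings behind the motivating study are not publicly
deposited, the package includes a first-class synthetic generator:
class-conditional sums of band-limited sinusoids (delta/theta/alpha/
beta) with 1/f and white noise, with injectable input drift (amplitude
rescaling) and concept drift (label-source permutation).

## Worked example

```python
from onsnn import (SynthConfig, NetworkConfig, DriftEvent,
                   generate_stream, run_online)

swap = DriftEvent(at=36, kind="concept",
                  mapping=(("stress", "positive"), ("positive", "stress")))
stream = generate_stream(SynthConfig(seed=7, drift_schedule=(swap,)))
result = run_online(stream, NetworkConfig(seed=7))
print(f"final prequential accuracy: {result.final_accuracy:.3f}")
print(f"output neurons retained:    {result.final_repo_size}")
print(f"hidden spike ratio:         {result.spike_ratio:.4f}")
print(f"stress sensitivity:         {result.sensitivity('stress'):.3f}")
```

prints

```
final prequential accuracy: 0.437
output neurons retained:    43
hidden spike ratio:         0.0168
stress sensitivity:         0.375
```

A 72-sample stream (24 per class) with the class posteriors swapped at
sample 36 is classified online; the network keeps 43 output neurons
(versus 72 for the no-structural-plasticity baseline) and the hidden
layer emits ~1.7 spikes per 100 received — the intrinsic-plasticity
sparsification at work. Accuracy on these fully synthetic streams is
modest; see `docs/methods.md` for what the generator does and does not
emulate and for the resulting performance envelope.

The same pipeline is scriptable from the shell:

```sh
onsnn simulate --seed 7 --concept-drift-at 36 --out data/
onsnn run --mode online --sp on --data data/ --labels data/labels.csv \
          --seed 7 --reps 5 --out runs/demo
onsnn extract --model runs/demo/model --baseline neutral --out report.json
```

`run` writes `outcomes.csv` (per-step log), `trace.csv` (prequential
accuracy), `repository.csv`, `weights.csv`, `events.csv` (every
evolve/prune/eliminate) and `summary.json` (mean ± σ over repetitions);
`extract` produces the model-interpretation report (class-centroid
distances to a baseline class, per-channel synaptic fan-out,
initiation-vs-final neuron drift).

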