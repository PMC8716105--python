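# Methods

## The model

A synapse in this package is a pair (release probability `p`, strength
`m`).  On every presentation of an input, each synapse independently
either releases neurotransmitter (probability `p`) or fails, so the
effective weight is the Bernoulli product

    w = r · m,    r ~ Bernoulli(p),    E[w] = w̄ = p · m.

A unit computes `σ(Σᵢ rᵢ mᵢ aᵢ)` — ReLU in hidden layers, softmax at the
readout, the sign function for the perceptron; there are no bias terms.
Masks are redrawn independently for every example of every forward pass
(each action potential is an independent release event), in every layer
including the readout.

## The learning rule

One shared update direction `g = ∂L/∂w̄` (mini-batch mean; cross-entropy
loss) drives two updates per step:

1. **Strengths.**  `w̄ ← w̄ − η_eff · g`, with `m = w̄/p` maintained under
   the post-update `p`.  Equivalently
   `m ← (p⁽ᵗ⁾ m⁽ᵗ⁾ − η g)/p⁽ᵗ⁺¹⁾`; the two forms agree to 1e-12 relative
   error (tested).  The gradient is taken through the *sampled* network:
   `∂L/∂mᵢ` uses the drawn mask and converts by the chain rule
   `∂L/∂w̄ᵢ = (1/pᵢ)·∂L/∂mᵢ`.  An optional ℓ2 term `λ·w̄` penalises the
   expected weight (the energy carrier).
2. **Release probabilities (metaplasticity).**

       p ← p + p_up   if |g| > g_lim
       p ← p − p_down if |g| ≤ g_lim

   clipped to `[p_min, 1]` with `p_min = 0.25` (also the default initial
   value).  For Gaussian `g ~ N(0, σ²)` the per-step increase probability
   is `erfc(g_lim/(σ√2))`, monotone in `σ²` = the diagonal empirical
   Fisher information — which is why high-`p` synapses end up being the
   high-Fisher, functionally important ones.

**Consolidation** (lifelong experiments only): the per-synapse learning
rate is `η_eff = η₀(1 − p)`, and a release probability crossing
`p_freeze` is frozen *at* `p_freeze` permanently (strengths stay
plastic).  Capping at the threshold rather than at the post-increment
value is deliberate: it guarantees `1 − p ≥ 1 − p_freeze > 0`, i.e.
consolidated synapses keep a small reserve of plasticity.  With the
perceptron constants (`p_up = p_down = 0.2`, clamp at 0.25) the
alternative — freezing wherever the increment lands — lets `p` reach 1.0
exactly (e.g. 0.25 → 0.45 → 0.65 → 0.85 → 1.0), which zeroes the
learning rate and makes the consolidated unit unable to learn at all; we
verified this failure mode empirically before fixing the semantics.

The **ghost control** lets a shadow variable `p̃` evolve under the same
rule and drive `η_eff` and freezing, while transmission keeps a fixed
`p = 0.5`: consolidation without transmission stochasticity.

## Parameters

| constant | energy family | lifelong ANN | perceptron |
|---|---|---|---|
| p_up / p_down | 0.07 / 0.07 | 0.005 / 0.005039 | 0.2 / 0.2 |
| g_lim | 1e-3 | 5e-4 | 0.1 |
| η (base) | 0.05 | 0.05 | 1.0 |
| p_init | 0.25 | 0.5 | 0.5 |
| p_freeze | — (consolidation off) | 0.9 | 0.9 |

`MetaplasticityConfig` defaults to the energy set; `.lifelong()` and
`.perceptron()` carry the published MNIST-scale lifelong constants
(p_up = 0.0516, p_down = 0.0520, g_lim = 1e-3, η₀ ∈ {0.01, 0.001}) and
the perceptron set.  Metaplasticity constants must be calibrated to the
gradient scale and training horizon of the data they run on (they are
the exchange rate between "how fast tasks are learned" and "how fast
importance consolidates"); following the usual procedure of coarse
tuning on a single scenario and transferring to the rest, the desk-scale
lifelong experiments in `stochsyn.presets` use the middle column above.
The MNIST-scale constants lose the learn-versus-freeze race on the
smaller tasks: gradients are ~2–5× smaller, learning needs ~10× more
steps, and synapses freeze before the first task is learned.  The
perceptron's initial `p = 0.5` (not stated alongside its other
constants) is the uninformative midpoint and makes the ±0.2 ladder land
exactly on the freeze threshold.

## Synthetic data

`generate_synthetic_classification` emulates digit-image data: inputs
are high-dimensional with high entropy, but the task-relevant
information is a low-dimensional class identity.  Each of `n_classes`
classes owns a binary {0, 1} prototype on `relevant_dim` randomly chosen
coordinates (strongly contrasting "pixels"); examples add Gaussian noise
of SD `noise_sd = 0.3` there, all other coordinates are unit-variance
Gaussian nuisance independent of the label; every feature is min-max
scaled to [0, 1].  Defaults (10 classes, 784 dims, 20 relevant, 6:1
train/test) mirror the scale of the image benchmarks.

What it does *not* emulate: spatial pixel correlations, the
near-constant dark borders of digit images (our nuisance dimensions are
*active* noise, a harder transmission regime), and class-imbalance.
Passing tests on this generator therefore show that the mechanisms —
sparse high-`p` allocation, Fisher correspondence, consolidation — do
not depend on image structure, but say nothing about absolute accuracies
on real data.  The IDX reader allows running the same pipelines on
MNIST-format files when replication on real data is wanted.

## Experiment scale

The mask-per-example-per-synapse contractions make training cost
`O(batch · fan_in · fan_out)` per layer per step.  The experiments
bundled in `stochsyn.presets` therefore run the method at a reduced
width, chosen once so that the entire battery (tests plus acceptance
script) completes in well under an hour on one CPU:

* **energy / analysis family**: 80 inputs (20 relevant), layers
  80-40-40-10, 6000 training examples, batch 100.  Energy sweeps train
  70 epochs per (λ, seed); analysis runs (Fisher, lesion, sparsity,
  histogram) train 300 epochs, the long-time regime in which release
  probabilities of unimportant synapses have decayed and the sparse
  important subset (< 50 % of synapses at p ≥ 0.9) is visible.
* **lifelong family**: 80 inputs (60 relevant — high-SNR tasks that are
  learned quickly, the regime consolidation is designed for), layers
  80-64-64-2.  Split protocol: 5 class-pair parity tasks, 100 epochs per
  task.  Permuted protocol: parity of all ten classes under 5 fixed input
  permutations, 60 epochs per task — permutations remap every
  coordinate, so interference (and hence the value of consolidation) is
  maximal; the split tasks at this scale barely interfere, which is why
  the retention comparison uses the permuted protocol.
* **perceptron**: exactly the published protocol — 5 tasks × 100
  patterns of dimension 1000, batches of 5, 25 passes, 10 repetitions.

## Numerical and design choices

* The three-index mask contractions run in float32 numba kernels; all
  state arrays (`p`, `m`, `w̄`) and the update algebra are float64.
  Gradients are consumed at the ~1e-3 scale, three orders above float32
  resolution.
* Update ordering per step: compute `g` → new `p` → `w̄` step with
  `η_eff` of the *pre-update* `p` → `m = w̄/p_new` (both updates read the
  same state; the division uses the post-update `p`).
* `|g|` exactly equal to `g_lim` takes the decrease branch.
* Energy = Σ|p·m| (magnitude of the mean postsynaptic current), not a
  squared measure.
* Mutual information is the plug-in estimate in bits on a held-out set;
  sampled evaluation (mean class score over K = 10 mask draws) for the
  energy family.  Lifelong accuracies use expected-weight evaluation:
  lifelong networks have small weights, and at desk scale their sampled
  evaluation is dominated by release noise rather than by what the
  network has learned.
* Lesion removal zeroes strengths cumulatively; ties in `p` break by |m|
  ascending, then index.  Fraction 1 leaves a constant predictor
  (chance accuracy on balanced labels).
* Sparsity baseline: importance labels shuffled uniformly over a layer's
  synapses (100 shuffles); two-sample KS statistic against the pooled
  shuffled per-neuron distribution; high/low-importance neurons are ±2
  shuffled SD from the shuffled mean.
* The fixed-release control matches the *global* mean release
  probability of the trained plastic model (per-λ, per-seed, paired).
* Degenerate inputs: empty count tables, empty datasets, non-finite
  gradients and out-of-range labels raise `ValueError`; a perceptron
  tie (zero weighted sum) predicts +1.

## Known limitations

* Bernoulli single-release-site transmission only; no short-term
  plasticity, no spiking, no biases, no multi-site binomial model.
* The reduced experiment scale reproduces orderings and
  correspondences (which synapse class has higher Fisher information,
  which model variant is more energy-efficient or forgets less), not
  the absolute accuracies of image benchmarks.
* Split tasks at desk scale interfere too little to show forgetting;
  conclusions about retention come from the permuted protocol.
* The continuous-mixing protocol's transition window length is a free
  parameter (`transition_fraction`, default 0.2).
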