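# stochsyn

Neural networks whose synapses transmit *stochastically*, for studying how
presynaptic failures shape energy-efficient coding and lifelong learning.

When an action potential reaches a synapse there is a substantial
probability that no neurotransmitter is released.  `stochsyn` models each
synapse as a Bernoulli release event `r ~ Bernoulli(p)` gating a strength
`m`, so the effective weight is `w = r·m` with expectation `w̄ = p·m`.  On
top of ordinary gradient learning of the expected strengths,

    w̄⁽ᵗ⁺¹⁾ = w̄⁽ᵗ⁾ − η g,     g = ∂L/∂w̄,

a simple metaplasticity rule adapts each release probability to the size of
the learning signal it keeps receiving,

    p ← p + p_up   if |g| > g_lim,
    p ← p − p_down if |g| ≤ g_lim,      p ∈ [0.25, 1],

which (for noise-dominated gradients) raises `p` with probability
`erfc(g_lim/(σ√2))` — monotone in the synapse's diagonal empirical Fisher
information `F = E[g²]`.  Release probabilities therefore come to encode
synaptic importance.  Two consequences are implemented and measured here:

* **Energy efficiency** — with an ℓ2 penalty on `w̄` (the proxy for the
  metabolic cost of postsynaptic currents), the network concentrates high
  `p` on a sparse important subset of synapses and extracts more
  task-relevant mutual information per unit of energy than deterministic or
  fixed-release controls.
* **Consolidation** — scaling each synapse's learning rate by `(1 − p)` and
  freezing `p` at a threshold `p_freeze` stabilises important synapses,
  improving stability–plasticity trade-offs in sequential-task learning,
  both for gradient-trained multilayer networks and for a gradient-free
  sign-unit perceptron.

The package is a library: `stochsyn.network` (the stochastic forward
model), `stochsyn.plasticity` (the learning rule and consolidation),
`stochsyn.metrics` (energy, plug-in mutual information, empirical Fisher,
lesion curves, neuron-level sparsity), `stochsyn.tasks` (synthetic data,
split/permuted/continuous lifelong protocols, perceptron patterns, an IDX
reader for MNIST-format files), `stochsyn.perceptron`,
`stochsyn.harness` (experiment orchestration) and `stochsyn.presets`
(the desk-scale study conditions).  `examples/` holds one short narrative
script per capability.

## Worked example

```console
$ python examples/perceptron_memorisation.py
standard                  first-task accuracy 0.813, 5-task mean 0.881
stochastic_consolidated   first-task accuracy 0.837, 5-task mean 0.903

the gradient-free perceptron rule benefits from the same
consolidation mechanism as the gradient-trained networks.
```

Five tasks of 100 random ±1 patterns (dimension 1000) are memorised
sequentially.  After all five, the standard perceptron has overwritten
part of task 1 (accuracy 0.81 there, 0.88 averaged over tasks), while the
consolidated stochastic perceptron — same rule, plus release-probability
metaplasticity, `(1 − p)` learning-rate scaling and freezing at 0.9 —
retains more of every task.  `examples/train_and_analyze.py` prints the
corresponding analysis for the multilayer network (Fisher/release-
probability correspondence, lesion curves, sparsity), and
`examples/energy_tradeoff.py` and `examples/lifelong_learning.py` the two
experiment families.

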