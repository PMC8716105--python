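"""Stochastic synaptic transmission basics.

Builds a two-layer network whose synapses release with probability p,
draws release masks, and shows that the effective weights r*m are
unbiased estimates of the expected weights p*m.
"""

import numpy as np

import stochsyn as ss

net = ss.init_network([8, 4, 3], p_init=0.5, rng=0)
x = np.random.default_rng(1).random(8)

out_expected, _ = ss.forward_expected(net, x)
print("expected-weight class probabilities:", np.round(out_expected[0], 3))

rng = np.random.default_rng(2)
draws = np.array(
    [ss.forward_stochastic(net, x, rng, return_cache=False)[0][0]
     for _ in range(2000)]
)
print("mean of 2000 stochastic passes:     ", np.round(draws.mean(0), 3))
print("(class probabilities differ per draw; their mean tracks the")
print(" expected-weight pass up to the softmax nonlinearity)")

layer = net.layers[0]
masks = ss.sample_release(layer, rng, batch_shape=(10_000,)).r
err = np.abs((masks * layer.m).mean(0) - layer.w_bar).max()
print(f"max |mean(r*m) - p*m| over 1e4 draws: {err:.2e}  (unbiased transmission)")
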