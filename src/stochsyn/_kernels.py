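"""Numba kernels for the per-example release-mask contractions.

The model redraws a Bernoulli mask per synapse and per example, so every
forward/backward pass contracts a (batch, fan_out, fan_in) mask with the
strength matrix and the activations.  These loops dominate training time;
fusing them avoids the large temporaries a vectorised implementation needs.
All kernels take float32 data with boolean masks.
"""

from __future__ import annotations

import numba
import numpy as np


@numba.njit(cache=True)
def masked_forward(r, m, a):
    """z[b, j] = sum_i r[b, j, i] * m[j, i] * a[b, i]."""
    B, J, I = r.shape
    z = np.zeros((B, J), dtype=np.float32)
    for b in range(B):
        for j in range(J):
            s = np.float32(0.0)
            for i in range(I):
                # branchless: bool * product vectorises, a branch does not
                s += r[b, j, i] * (m[j, i] * a[b, i])
            z[b, j] = s
    return z


@numba.njit(cache=True)
def masked_backward(delta, r, m):
    """back[b, i] = sum_j delta[b, j] * r[b, j, i] * m[j, i]."""
    B, J, I = r.shape
    back = np.zeros((B, I), dtype=np.float32)
    for b in range(B):
        for j in range(J):
            d = delta[b, j]
            if d != 0.0:
                for i in range(I):
                    if r[b, j, i]:
                        back[b, i] += d * m[j, i]
    return back


@numba.njit(cache=True)
def masked_grad(delta, r, a):
    """g[j, i] = sum_b delta[b, j] * r[b, j, i] * a[b, i].

    With squared inputs this also yields the per-example squared-gradient
    sum needed for the empirical Fisher information (r^2 = r).
    """
    B, J, I = r.shape
    g = np.zeros((J, I), dtype=np.float32)
    for b in range(B):
        for j in range(J):
            d = delta[b, j]
            if d != 0.0:
                for i in range(I):
                    if r[b, j, i]:
                        g[j, i] += d * a[b, i]
    return g
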