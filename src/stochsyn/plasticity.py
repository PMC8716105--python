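"""Presynaptic metaplasticity: the learning rule and its consolidation.

Learning has two coupled parts per step, driven by one shared update
direction ``g`` (the mini-batch averaged gradient of the cross-entropy loss
with respect to the *expected* strengths ``w_bar = p * m``):

1. the expected strength moves down the gradient,
   ``w_bar <- w_bar - eta_eff * g``;
2. the release probability moves up by ``p_up`` wherever ``|g| > g_lim``
   (the synapse keeps receiving substantial updates, so it matters) and down
   by ``p_down`` otherwise, clamped to ``[p_min, 1]``.

Consolidation, used in lifelong learning, scales the learning rate per
synapse by ``(1 - p)`` and permanently freezes ``p`` once it surpasses
``p_freeze`` (strengths stay plastic).  A ghost-probability control lets the
metaplastic variable evolve and modulate plasticity while transmission keeps
a fixed release probability, isolating consolidation from transmission
stochasticity.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from pathlib import Path

import numpy as np
import yaml
from scipy.special import erfc

from ._kernels import masked_backward, masked_grad
from .network import ForwardCache, NetworkState, P_MIN_DEFAULT


@dataclass(frozen=True)
class MetaplasticityConfig:
    """Constants of the release-probability rule, shared by all synapses.

    Defaults are the energy-experiment set; :meth:`lifelong` and
    :meth:`perceptron` give the other two published parameterisations.
    """

    p_up: float = 0.07
    p_down: float = 0.07
    g_lim: float = 0.001
    p_min: float = P_MIN_DEFAULT
    p_freeze: float = 0.9
    eta0: float = 0.05
    lambda_l2: float = 0.0
    consolidation_on: bool = False
    ghost_mode: bool = False

    def __post_init__(self):
        if not (0.0 < self.p_up < 1.0 and 0.0 < self.p_down < 1.0):
            raise ValueError("p_up and p_down must lie in (0, 1)")
        if self.g_lim <= 0.0:
            raise ValueError("g_lim must be positive")
        if not (self.p_min <= self.p_freeze <= 1.0):
            raise ValueError("need p_min <= p_freeze <= 1")

    @classmethod
    def lifelong(cls, eta0: float = 0.01, **kw) -> "MetaplasticityConfig":
        """Constants used for the sequential-task experiments."""
        return cls(
            p_up=0.0516,
            p_down=0.0520,
            g_lim=0.001,
            eta0=eta0,
            consolidation_on=True,
            **kw,
        )

    @classmethod
    def perceptron(cls, **kw) -> "MetaplasticityConfig":
        """Constants used for the perceptron pattern-memorisation tasks."""
        return cls(
            p_up=0.2,
            p_down=0.2,
            g_lim=0.1,
            p_freeze=0.9,
            eta0=1.0,
            consolidation_on=True,
            **kw,
        )

    def replace(self, **kw) -> "MetaplasticityConfig":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "MetaplasticityConfig":
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "MetaplasticityConfig":
        """Load constants from a YAML (or JSON) mapping."""
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_file(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))


@dataclass
class UpdateDirection:
    """Per-synapse gradient of the loss with respect to expected strengths."""

    g: list[np.ndarray]

    def __iter__(self):
        return iter(self.g)


def _relu_grad(z: np.ndarray) -> np.ndarray:
    return (z > 0.0).astype(float)


def backprop_deltas(
    net: NetworkState, labels: np.ndarray, cache: ForwardCache
) -> list[np.ndarray]:
    """Per-example error signals ``dL_b/dz^(l)`` for cross-entropy loss.

    Backpropagation runs through the network that was actually sampled: for
    stochastic caches the effective weight ``r * m`` carries the signal, for
    expected caches ``w_bar`` does.
    """
    y = np.asarray(labels)
    B = cache.output.shape[0]
    if y.min() < 0 or y.max() >= net.n_classes:
        raise ValueError("label out of range")
    delta = cache.output.copy()
    delta[np.arange(B), y] -= 1.0  # softmax - onehot, per example
    deltas = [None] * len(net.layers)
    deltas[-1] = delta
    for li in range(len(net.layers) - 2, -1, -1):
        nxt = net.layers[li + 1]
        mask = cache.masks[li + 1]
        if mask is None:
            back = deltas[li + 1] @ nxt.w_bar
        else:
            back = masked_backward(
                deltas[li + 1].astype(np.float32), mask, nxt.m.astype(np.float32)
            )
        deltas[li] = back * _relu_grad(cache.pre[li])
    return deltas


def compute_update_direction(
    net: NetworkState,
    labels: np.ndarray,
    cache: ForwardCache,
    cfg: MetaplasticityConfig,
) -> UpdateDirection:
    """Mini-batch averaged gradient with respect to ``w_bar``, per layer.

    For a sampled cache, ``dL/dm_i`` uses the drawn mask (a synapse that
    failed to release contributes nothing for that example) and is converted
    by the chain rule ``dL/dw_bar_i = (1/p_i) dL/dm_i``.  An l2 penalty on
    the expected weights adds ``lambda_l2 * w_bar``.
    """
    if cache is None or cache.output is None:
        raise ValueError("compute_update_direction requires a forward cache")
    deltas = backprop_deltas(net, labels, cache)
    B = cache.output.shape[0]
    gs = []
    for lyr, delta, a, mask in zip(net.layers, deltas, cache.inputs, cache.masks):
        if mask is None:
            g = (delta.T @ a) / B  # gradient w.r.t. w_bar directly
        else:
            g_m = (
                masked_grad(
                    delta.astype(np.float32), mask, a.astype(np.float32)
                ).astype(float)
                / B
            )
            g = g_m / lyr.p
        if cfg.lambda_l2 > 0.0:
            g = g + cfg.lambda_l2 * lyr.w_bar
        gs.append(g)
    return UpdateDirection(g=gs)


def update_release_probabilities(
    net: NetworkState, g: UpdateDirection, cfg: MetaplasticityConfig
) -> None:
    """Apply the metaplastic step to ``p`` (or the ghost array), in place.

    Increment by ``p_up`` where ``|g| > g_lim``, decrement by ``p_down``
    where ``|g| <= g_lim``; clip to ``[p_min, 1]``; frozen entries never
    move.  With consolidation on, an entry crossing ``p_freeze`` freezes
    *at* ``p_freeze``: the consolidated synapse keeps ``1 - p > 0``, so its
    strength retains a small degree of plasticity.
    """
    for lyr, gl in zip(net.layers, g):
        meta = lyr.meta_p
        step = np.where(np.abs(gl) > cfg.g_lim, cfg.p_up, -cfg.p_down)
        new = np.clip(meta + step, cfg.p_min, 1.0)
        if cfg.consolidation_on:
            new = np.minimum(new, cfg.p_freeze)
        np.copyto(meta, new, where=~lyr.frozen)
        if cfg.consolidation_on:
            lyr.frozen |= meta >= cfg.p_freeze


def effective_learning_rate(
    lyr, cfg: MetaplasticityConfig
) -> np.ndarray | float:
    """Per-synapse learning rate: ``eta0 * (1 - p)`` under consolidation."""
    if cfg.consolidation_on:
        return cfg.eta0 * (1.0 - lyr.meta_p)
    return cfg.eta0


def update_expected_strengths(
    net: NetworkState, g: UpdateDirection, cfg: MetaplasticityConfig
) -> None:
    """Gradient step on ``w_bar`` in place, with ``m`` kept as ``w_bar / p``.

    Assumes the current ``p`` is the one ``m`` should be divided by; see
    :func:`apply_update` for the full step ordering.
    """
    for lyr, gl in zip(net.layers, g):
        if not np.all(np.isfinite(gl)):
            raise ValueError("non-finite entries in update direction")
        eta = effective_learning_rate(lyr, cfg)
        w_bar = lyr.p * lyr.m - eta * gl
        lyr.m = w_bar / lyr.p


def apply_update(
    net: NetworkState, g: UpdateDirection, cfg: MetaplasticityConfig
) -> None:
    """One full learning step from a shared update direction ``g``.

    Ordering: the strength update uses the learning-rate modulation of the
    *pre-update* ``p`` (both updates read the same state), the new ``w_bar``
    is divided by the *post-update* ``p`` so that ``m = w_bar / p`` holds
    after the step.
    """
    for lyr, gl in zip(net.layers, g):
        if not np.all(np.isfinite(gl)):
            raise ValueError("non-finite entries in update direction")
    etas = [effective_learning_rate(lyr, cfg) for lyr in net.layers]
    w_bars = [lyr.p * lyr.m - eta * gl for lyr, eta, gl in zip(net.layers, etas, g)]
    update_release_probabilities(net, g, cfg)
    for lyr, w_bar in zip(net.layers, w_bars):
        lyr.m = w_bar / lyr.p


def explicit_strength_update(
    p_old: np.ndarray,
    p_new: np.ndarray,
    m_old: np.ndarray,
    eta,
    g: np.ndarray,
) -> np.ndarray:
    """Closed-form strength update ``m' = (p m - eta g) / p'``.

    Algebraically identical to updating ``w_bar`` and re-deriving ``m``;
    kept as the explicit form for cross-checking.
    """
    return (p_old * m_old - eta * g) / p_new


def analytic_increase_probability(sigma: float, g_lim: float) -> float:
    """Probability that a zero-mean Gaussian update direction exceeds g_lim.

    For ``g ~ N(0, sigma^2)``, ``Pr[|g| > g_lim] = erfc(g_lim / (sigma
    sqrt(2)))`` — monotone in sigma, hence in the Fisher information
    ``E[g^2] = sigma^2``: synapses whose gradients fluctuate more are more
    likely to have their release probability increased.
    """
    if sigma <= 0.0:
        raise ValueError("sigma must be positive")
    return float(erfc(g_lim / (sigma * np.sqrt(2.0))))
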