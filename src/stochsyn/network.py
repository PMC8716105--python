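"""Layered networks whose synapses transmit stochastically.

Each synapse carries a strength ``m`` and a presynaptic release probability
``p``.  On every presentation of an input, each synapse independently either
releases (with probability ``p``) or fails, so the effective weight is the
Bernoulli product ``w = r * m`` with expectation ``w_bar = p * m``.  Hidden
layers use a rectifier nonlinearity, the readout applies a softmax; the
networks carry no bias terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._kernels import masked_forward

P_MIN_DEFAULT = 0.25


@dataclass
class SynapseLayer:
    """One fully connected layer of stochastic synapses.

    Attributes
    ----------
    p : ndarray, shape (fan_out, fan_in)
        Release probability per synapse, clamped to ``[p_min, 1]``.
    m : ndarray, shape (fan_out, fan_in)
        Synaptic strength per synapse.
    frozen : ndarray of bool, shape (fan_out, fan_in)
        Synapses whose release probability is consolidated and no longer
        plastic.  Strengths remain plastic even when frozen.
    ghost_p : ndarray or None
        Metaplastic state of the ghost-probability control: it evolves and
        modulates plasticity exactly like ``p`` would, while transmission
        keeps using the fixed ``p`` stored on the layer.
    """

    p: np.ndarray
    m: np.ndarray
    frozen: np.ndarray
    ghost_p: np.ndarray | None = None

    @property
    def fan_in(self) -> int:
        return self.m.shape[1]

    @property
    def fan_out(self) -> int:
        return self.m.shape[0]

    @property
    def w_bar(self) -> np.ndarray:
        """Expected weight matrix ``p * m`` (elementwise)."""
        return self.p * self.m

    @property
    def meta_p(self) -> np.ndarray:
        """The release-probability array the learning rule reads and writes.

        This is ``ghost_p`` for the ghost control and ``p`` otherwise.
        """
        return self.p if self.ghost_p is None else self.ghost_p


@dataclass
class NetworkState:
    """An ordered stack of :class:`SynapseLayer` with fixed architecture.

    ``activation`` selects the hidden nonlinearity: ``"relu"`` for the
    multilayer networks (softmax readout), ``"sign"`` for perceptron use.
    """

    layers: list[SynapseLayer]
    activation: str = "relu"
    p_min: float = P_MIN_DEFAULT

    @property
    def layer_sizes(self) -> list[int]:
        return [self.layers[0].fan_in] + [lyr.fan_out for lyr in self.layers]

    @property
    def n_classes(self) -> int:
        return self.layers[-1].fan_out

    def copy(self) -> "NetworkState":
        return NetworkState(
            layers=[
                SynapseLayer(
                    p=lyr.p.copy(),
                    m=lyr.m.copy(),
                    frozen=lyr.frozen.copy(),
                    ghost_p=None if lyr.ghost_p is None else lyr.ghost_p.copy(),
                )
                for lyr in self.layers
            ],
            activation=self.activation,
            p_min=self.p_min,
        )


@dataclass
class ReleaseMask:
    """Binary release outcomes for one layer, one draw per synapse."""

    r: np.ndarray
    seed_info: object = None


@dataclass
class ForwardCache:
    """Activations and masks retained for gradient computation."""

    inputs: list[np.ndarray] = field(default_factory=list)  # a^(l), layer input
    pre: list[np.ndarray] = field(default_factory=list)  # z^(l), pre-activation
    masks: list[np.ndarray | None] = field(default_factory=list)  # r^(l) or None
    output: np.ndarray | None = None  # softmax probabilities


def init_network(
    layer_sizes: list[int],
    p_init: float = P_MIN_DEFAULT,
    rng: np.random.Generator | int | None = None,
    activation: str = "relu",
    p_min: float = P_MIN_DEFAULT,
) -> NetworkState:
    """Create a network with uniform strengths and a flat release probability.

    Strengths are drawn uniformly on ``[-1/sqrt(fan_in), +1/sqrt(fan_in)]``
    (the Kaiming-uniform bound ``sqrt(6/fan_in)`` divided by ``sqrt(6)``);
    release probabilities start at ``p_init`` everywhere, nothing is frozen.
    """
    if len(layer_sizes) < 2:
        raise ValueError("need at least an input and an output layer size")
    if any(s <= 0 for s in layer_sizes):
        raise ValueError(f"layer sizes must be positive, got {layer_sizes}")
    if not (p_min <= p_init <= 1.0):
        raise ValueError(f"p_init={p_init} outside [{p_min}, 1]")
    rng = np.random.default_rng(rng)
    layers = []
    for fan_in, fan_out in zip(layer_sizes[:-1], layer_sizes[1:]):
        bound = 1.0 / np.sqrt(fan_in)
        m = rng.uniform(-bound, bound, size=(fan_out, fan_in))
        layers.append(
            SynapseLayer(
                p=np.full((fan_out, fan_in), float(p_init)),
                m=m,
                frozen=np.zeros((fan_out, fan_in), dtype=bool),
            )
        )
    return NetworkState(layers=layers, activation=activation, p_min=p_min)


def sample_release(
    layer: SynapseLayer,
    rng: np.random.Generator | int | None,
    batch_shape: tuple[int, ...] = (),
) -> ReleaseMask:
    """Draw independent Bernoulli release outcomes, one per synapse.

    With ``batch_shape=(B,)`` a fresh mask is drawn per example, matching the
    semantics of one independent release event per action potential.
    """
    rng = np.random.default_rng(rng)
    u = rng.random(size=batch_shape + layer.p.shape, dtype=np.float32)
    return ReleaseMask(r=u < layer.p)


def _activate(z: np.ndarray, activation: str) -> np.ndarray:
    if activation == "relu":
        return np.maximum(z, 0.0)
    if activation == "sign":
        # tie at exactly zero resolves to +1 (documented tie-break)
        return np.where(z >= 0.0, 1.0, -1.0)
    raise ValueError(f"unknown activation {activation!r}")


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def forward_stochastic(
    net: NetworkState,
    inputs: np.ndarray,
    rng: np.random.Generator | int | None,
    return_cache: bool = True,
) -> tuple[np.ndarray, ForwardCache | None]:
    """Stochastic forward pass: each example sees fresh release masks.

    Each unit computes ``sigma(sum_i r_i m_i a_i)``; the readout layer
    returns softmax class probabilities.  The cache retains activations,
    pre-activations and masks for gradient computation.
    """
    X = np.atleast_2d(np.asarray(inputs, dtype=float))
    if X.shape[1] != net.layers[0].fan_in:
        raise ValueError(
            f"input dim {X.shape[1]} != first-layer fan_in {net.layers[0].fan_in}"
        )
    rng = np.random.default_rng(rng)
    cache = ForwardCache() if return_cache else None
    # the three-index mask contractions dominate run time; they run in
    # single precision (gradients are consumed at ~1e-3 scale, far above
    # float32 resolution), while all state arrays stay float64
    a = X.astype(np.float32)
    n_layers = len(net.layers)
    for li, lyr in enumerate(net.layers):
        mask = sample_release(lyr, rng, batch_shape=(a.shape[0],)).r
        z = masked_forward(mask, lyr.m.astype(np.float32), a)
        if cache is not None:
            cache.inputs.append(a)
            cache.pre.append(z)
            cache.masks.append(mask)
        if li < n_layers - 1:
            a = _activate(z, net.activation)
        else:
            a = softmax(z)
    if cache is not None:
        cache.output = a
    return a, cache


def forward_expected(
    net: NetworkState,
    inputs: np.ndarray,
    return_cache: bool = False,
) -> tuple[np.ndarray, ForwardCache | None]:
    """Deterministic forward pass using expected weights ``w_bar = p * m``."""
    X = np.atleast_2d(np.asarray(inputs, dtype=float))
    if X.shape[1] != net.layers[0].fan_in:
        raise ValueError(
            f"input dim {X.shape[1]} != first-layer fan_in {net.layers[0].fan_in}"
        )
    cache = ForwardCache() if return_cache else None
    a = X
    n_layers = len(net.layers)
    for li, lyr in enumerate(net.layers):
        z = a @ lyr.w_bar.T
        if cache is not None:
            cache.inputs.append(a)
            cache.pre.append(z)
            cache.masks.append(None)
        if li < n_layers - 1:
            a = _activate(z, net.activation)
        else:
            a = softmax(z)
    if cache is not None:
        cache.output = a
    return a, cache


def save_network(net: NetworkState, path) -> None:
    """Serialise a network to a single ``.npz`` key->array container.

    Keys are ``layer{i}_p``, ``layer{i}_m``, ``layer{i}_frozen`` and
    optionally ``layer{i}_ghost_p``, plus ``activation``, ``p_min`` and
    ``layer_sizes`` metadata.  Round-trips bit-exactly.
    """
    arrays: dict[str, np.ndarray] = {
        "activation": np.array(net.activation),
        "p_min": np.array(net.p_min),
        "n_layers": np.array(len(net.layers)),
    }
    for i, lyr in enumerate(net.layers):
        arrays[f"layer{i}_p"] = lyr.p
        arrays[f"layer{i}_m"] = lyr.m
        arrays[f"layer{i}_frozen"] = lyr.frozen
        if lyr.ghost_p is not None:
            arrays[f"layer{i}_ghost_p"] = lyr.ghost_p
    np.savez(path, **arrays)


def load_network(path) -> NetworkState:
    """Inverse of :func:`save_network`."""
    with np.load(path, allow_pickle=False) as data:
        n_layers = int(data["n_layers"])
        layers = []
        for i in range(n_layers):
            layers.append(
                SynapseLayer(
                    p=data[f"layer{i}_p"],
                    m=data[f"layer{i}_m"],
                    frozen=data[f"layer{i}_frozen"],
                    ghost_p=data.get(f"layer{i}_ghost_p"),
                )
            )
        return NetworkState(
            layers=layers,
            activation=str(data["activation"]),
            p_min=float(data["p_min"]),
        )
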