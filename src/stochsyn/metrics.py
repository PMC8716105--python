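"""Measurement battery for trained stochastic-release networks.

Covers the energy proxy (summed magnitude of expected synaptic strength),
the task-relevant mutual information between labels and network predictions,
the diagonal empirical Fisher information per synapse, lesion curves, and
neuron-level sparsity statistics built on the release-probability notion of
synaptic importance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp, pearsonr

from ._kernels import masked_grad
from .network import NetworkState, forward_expected, forward_stochastic
from .plasticity import backprop_deltas


@dataclass
class InfoEnergyPoint:
    """One (mutual information, energy) operating point of a trained model."""

    mutual_information: float  # bits
    energy: float  # summed |p*m|, model units
    lambda_l2: float
    model_variant: str
    accuracy: float = float("nan")
    seed: int | None = None


@dataclass
class FisherEstimate:
    """Diagonal empirical Fisher information, one nonnegative value per synapse."""

    F: list[np.ndarray]

    def flat(self) -> np.ndarray:
        return np.concatenate([f.ravel() for f in self.F])


@dataclass
class LesionCurve:
    fractions_removed: np.ndarray
    accuracy: np.ndarray
    ordering: str  # "low_p_first" | "random"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fraction_removed": self.fractions_removed,
                "accuracy": self.accuracy,
                "ordering": self.ordering,
            }
        )


@dataclass
class SparsityReport:
    """Neuron-level statistics of important (high release probability) synapses."""

    important_input_fraction: np.ndarray  # per neuron of the probed layer
    shuffled_fractions: np.ndarray  # pooled over shuffles
    ks_statistic: float
    n_low: int
    n_medium: int
    n_high: int
    input_output_correlation: float
    p_important: float

    def summary(self) -> dict:
        return {
            "ks_statistic": self.ks_statistic,
            "n_low": self.n_low,
            "n_medium": self.n_medium,
            "n_high": self.n_high,
            "input_output_correlation": self.input_output_correlation,
            "p_important": self.p_important,
        }


def synaptic_energy(net: NetworkState) -> float:
    """Total energy proxy: sum over all synapses of ``|p_i * m_i|``.

    The expected synaptic strength tracks the size of the mean postsynaptic
    current, the dominant metabolic cost of signal transmission.
    """
    return float(sum(np.abs(lyr.w_bar).sum() for lyr in net.layers))


def mutual_information(joint_counts: np.ndarray) -> float:
    """Plug-in mutual information of a label x prediction count table, in bits."""
    c = np.asarray(joint_counts, dtype=float)
    total = c.sum()
    if c.size == 0 or total <= 0:
        raise ValueError("joint count table must be non-empty with positive total")
    if (c < 0).any():
        raise ValueError("counts must be nonnegative")
    pj = c / total
    py = pj.sum(axis=1, keepdims=True)
    pz = pj.sum(axis=0, keepdims=True)
    nz = pj > 0
    return float(np.sum(pj[nz] * np.log2(pj[nz] / (py @ pz)[nz])))


def entropy_bits(counts: np.ndarray) -> float:
    """Plug-in entropy of a count vector, in bits."""
    c = np.asarray(counts, dtype=float)
    p = c / c.sum()
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def predict_classes(
    net: NetworkState,
    X: np.ndarray,
    mode: str = "sampled",
    n_samples: int = 10,
    rng=None,
) -> np.ndarray:
    """Arg-max class predictions; sampled mode averages class scores over
    ``n_samples`` independent release-mask draws."""
    if mode == "expected":
        probs, _ = forward_expected(net, X)
    elif mode == "sampled":
        rng = np.random.default_rng(rng)
        probs = np.zeros((X.shape[0], net.n_classes))
        for _ in range(n_samples):
            out, _ = forward_stochastic(net, X, rng, return_cache=False)
            probs += out
        probs /= n_samples
    else:
        raise ValueError(f"unknown evaluation mode {mode!r}")
    return probs.argmax(axis=1)


def evaluate_predictions(
    net: NetworkState,
    X: np.ndarray,
    y: np.ndarray,
    mode: str = "sampled",
    n_samples: int = 10,
    rng=None,
) -> tuple[np.ndarray, float]:
    """Joint (label, prediction) counts and accuracy on a labelled set."""
    y = np.asarray(y)
    z = predict_classes(net, X, mode=mode, n_samples=n_samples, rng=rng)
    k = net.n_classes
    joint = np.zeros((k, k), dtype=int)
    np.add.at(joint, (y, z), 1)
    accuracy = float(np.trace(joint) / joint.sum())
    return joint, accuracy


def empirical_fisher(
    net: NetworkState,
    X: np.ndarray,
    y: np.ndarray,
    rng=None,
    batch_size: int = 100,
) -> FisherEstimate:
    """Diagonal empirical Fisher: mean over examples of squared per-example
    gradients of the log-likelihood with respect to expected strengths.

    Gradients run through freshly sampled release masks with the ``1/p``
    conversion, i.e. the same estimator that drives learning, but squared
    per example rather than batch-averaged.
    """
    X = np.atleast_2d(X)
    y = np.asarray(y)
    if X.shape[0] == 0:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(rng)
    acc = [np.zeros_like(lyr.m) for lyr in net.layers]
    n = X.shape[0]
    for start in range(0, n, batch_size):
        Xb, yb = X[start : start + batch_size], y[start : start + batch_size]
        _, cache = forward_stochastic(net, Xb, rng)
        deltas = backprop_deltas(net, yb, cache)
        for li, (lyr, delta, a, mask) in enumerate(
            zip(net.layers, deltas, cache.inputs, cache.masks)
        ):
            # per-example g^2 summed over the batch; r^2 = r for 0/1 masks
            sq = masked_grad(
                (delta**2).astype(np.float32), mask, (a**2).astype(np.float32)
            ).astype(float)
            acc[li] += sq / lyr.p**2
    return FisherEstimate(F=[a / n for a in acc])


def _lesion_order(net: NetworkState, ordering: str, rng) -> np.ndarray:
    """Global synapse ranking for removal: ascending p (ties by |m|, then
    index) or uniformly random."""
    p_flat = np.concatenate([lyr.p.ravel() for lyr in net.layers])
    m_flat = np.concatenate([lyr.m.ravel() for lyr in net.layers])
    n = p_flat.size
    if ordering == "low_p_first":
        return np.lexsort((np.arange(n), np.abs(m_flat), p_flat))
    if ordering == "random":
        return np.random.default_rng(rng).permutation(n)
    raise ValueError(f"unknown lesion ordering {ordering!r}")


def lesion_curve(
    net: NetworkState,
    X: np.ndarray,
    y: np.ndarray,
    ordering: str = "low_p_first",
    fractions: np.ndarray | None = None,
    mode: str = "sampled",
    n_samples: int = 10,
    rng=None,
) -> LesionCurve:
    """Accuracy after cumulatively removing a growing fraction of synapses.

    Removal zeroes the strength (hence the expected weight); release
    probabilities are untouched so the ranking stays fixed.
    """
    if fractions is None:
        fractions = np.linspace(0.0, 1.0, 11)
    fractions = np.asarray(fractions, dtype=float)
    if (fractions < 0).any() or (fractions > 1).any():
        raise ValueError("fractions must lie in [0, 1]")
    rng = np.random.default_rng(rng)
    order = _lesion_order(net, ordering, rng)
    sizes = [lyr.m.size for lyr in net.layers]
    offsets = np.cumsum([0] + sizes)
    total = offsets[-1]
    work = net.copy()
    accs = []
    prev_k = 0
    for frac in np.sort(fractions):
        k = int(round(frac * total))
        for idx in order[prev_k:k]:
            li = np.searchsorted(offsets, idx, side="right") - 1
            work.layers[li].m.ravel()[idx - offsets[li]] = 0.0
        prev_k = k
        _, acc = evaluate_predictions(
            work, X, y, mode=mode, n_samples=n_samples, rng=rng
        )
        accs.append(acc)
    return LesionCurve(
        fractions_removed=np.sort(fractions),
        accuracy=np.array(accs),
        ordering=ordering,
    )


def important_mask(net: NetworkState, p_important: float = 0.9) -> list[np.ndarray]:
    """Boolean importance per synapse: release probability >= threshold."""
    return [lyr.p >= p_important for lyr in net.layers]


def sparsity_report(
    net: NetworkState,
    layer: int = 1,
    p_important: float = 0.9,
    n_shuffles: int = 100,
    rng=None,
) -> SparsityReport:
    """Neuron-level sparsity of importance in one hidden layer.

    For each postsynaptic neuron of ``layer`` we take the fraction of its
    input synapses that are important (p >= ``p_important``).  The baseline
    shuffles the important/unimportant labels uniformly over the layer's
    synapses; the two-sample KS statistic compares the real per-neuron
    distribution with the pooled shuffled one.  Neurons at least two
    shuffled-baseline standard deviations above (below) the shuffled mean
    count as high (low) importance.  The input-output correlation is the
    Pearson r between a neuron's number of important inputs and important
    outputs (needs ``layer`` to have a successor).
    """
    if not (0 <= layer < len(net.layers)):
        raise IndexError(f"layer {layer} out of range")
    rng = np.random.default_rng(rng)
    imp = net.layers[layer].p >= p_important  # (fan_out, fan_in)
    fan_out, fan_in = imp.shape
    real_frac = imp.mean(axis=1)

    flat = imp.ravel()
    shuffled = np.empty((n_shuffles, fan_out))
    for s in range(n_shuffles):
        perm = rng.permutation(flat).reshape(fan_out, fan_in)
        shuffled[s] = perm.mean(axis=1)
    pooled = shuffled.ravel()
    ks = float(ks_2samp(real_frac, pooled).statistic)

    mu, sd = pooled.mean(), pooled.std()
    n_high = int((real_frac >= mu + 2 * sd).sum()) if sd > 0 else 0
    n_low = int((real_frac <= mu - 2 * sd).sum()) if sd > 0 else 0
    n_medium = fan_out - n_high - n_low

    if layer + 1 < len(net.layers):
        imp_out = net.layers[layer + 1].p >= p_important  # (next_out, fan_out)
        in_counts = imp.sum(axis=1).astype(float)
        out_counts = imp_out.sum(axis=0).astype(float)
        if in_counts.std() == 0.0 or out_counts.std() == 0.0:
            r = float("nan")
        else:
            r = float(pearsonr(in_counts, out_counts).statistic)
    else:
        r = float("nan")

    return SparsityReport(
        important_input_fraction=real_frac,
        shuffled_fractions=pooled,
        ks_statistic=ks,
        n_low=n_low,
        n_medium=n_medium,
        n_high=n_high,
        input_output_correlation=r,
        p_important=p_important,
    )


def release_probability_histogram(
    net: NetworkState, bins: int = 20
) -> pd.DataFrame:
    """Histogram of all release probabilities, as a tidy frame."""
    p = np.concatenate([lyr.p.ravel() for lyr in net.layers])
    counts, edges = np.histogram(p, bins=bins, range=(0.0, 1.0))
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )


def save_summary(path, **scalars) -> None:
    """Write scalar metrics to a JSON summary file."""
    with open(path, "w") as fh:
        json.dump({k: float(v) for k, v in scalars.items()}, fh, indent=2)
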