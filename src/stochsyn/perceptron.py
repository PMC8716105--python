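"""A sign-unit perceptron with stochastic release and presynaptic consolidation.

The classical perceptron memorises random +/-1 patterns with its
gradient-free rule.  Here each input synapse additionally carries a release
probability, updates are averaged over batches of five patterns (so the
update direction has graded magnitudes the metaplasticity rule can
threshold), and the consolidated variant modulates plasticity by ``(1 - p)``
and freezes release probabilities — the same machinery as the multilayer
networks, with no gradients anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .plasticity import MetaplasticityConfig
from .tasks import TaskSequence

PERCEPTRON_BATCH = 5


@dataclass
class PerceptronState:
    """Per-input-synapse state of a single sign unit.

    ``variant`` is ``"standard"`` (deterministic, p fixed at 1, no release
    dynamics) or ``"stochastic_consolidated"`` (sampled release, metaplastic
    p, learning-rate modulation and freezing).
    """

    p: np.ndarray
    m: np.ndarray
    frozen: np.ndarray
    variant: str = "stochastic_consolidated"

    @property
    def w_bar(self) -> np.ndarray:
        return self.p * self.m

    @classmethod
    def init(
        cls, dim: int, variant: str = "stochastic_consolidated", p_init: float = 0.5
    ) -> "PerceptronState":
        """Fresh zero-strength unit.  The default ``p_init=0.5`` makes the
        +/-0.2 metaplastic steps land exactly on the freeze threshold 0.9,
        so consolidated synapses keep the residual plasticity ``1 - p =
        0.1`` rather than saturating at ``p = 1``."""
        if variant not in ("standard", "stochastic_consolidated"):
            raise ValueError(f"unknown perceptron variant {variant!r}")
        p0 = 1.0 if variant == "standard" else p_init
        return cls(
            p=np.full(dim, p0),
            m=np.zeros(dim),
            frozen=np.zeros(dim, dtype=bool),
            variant=variant,
        )


def labels_to_signs(labels: np.ndarray) -> np.ndarray:
    """Map {0, 1} class labels to the perceptron's -1/+1 targets."""
    return 2.0 * np.asarray(labels) - 1.0


def perceptron_predict(
    state: PerceptronState,
    patterns: np.ndarray,
    rng=None,
    mode: str = "sampled",
) -> np.ndarray:
    """Predict +/-1 per pattern; a zero weighted sum resolves to +1.

    ``mode="sampled"`` draws one release mask per pattern (the standard
    variant has p = 1, so it is deterministic either way);
    ``mode="expected"`` uses the expected weights.
    """
    X = np.atleast_2d(patterns)
    if X.shape[1] != state.m.size:
        raise ValueError("pattern dimension mismatch")
    if mode == "expected" or state.variant == "standard":
        z = X @ state.w_bar
    elif mode == "sampled":
        rng = np.random.default_rng(rng)
        r = rng.random((X.shape[0], state.p.size)) < state.p
        z = np.einsum("bi,i,bi->b", r, state.m, X, optimize=True)
    else:
        raise ValueError(f"unknown prediction mode {mode!r}")
    return np.where(z >= 0.0, 1.0, -1.0)


def perceptron_batch_update(
    state: PerceptronState,
    patterns: np.ndarray,
    labels: np.ndarray,
    cfg: MetaplasticityConfig,
    rng=None,
) -> np.ndarray:
    """One averaged perceptron step on a batch (nominally of five patterns).

    Each pattern contributes the classical correction
    ``(label - prediction)/2 * pattern`` (zero when already correct); ``g``
    is the batch mean.  Expected strengths move by ``+eta_eff * g`` with the
    ``(1 - p)`` modulation in the consolidated variant, then the release
    probabilities follow the shared threshold rule.  Returns ``g``.
    """
    X = np.atleast_2d(patterns)
    if X.shape[0] == 0:
        raise ValueError("empty batch")
    t = labels_to_signs(labels)
    pred = perceptron_predict(state, X, rng=rng, mode="sampled")
    g = (((t - pred) / 2.0)[:, None] * X).mean(axis=0)

    if state.variant == "standard":
        state.m = state.m + cfg.eta0 * g
        return g

    eta = cfg.eta0 * (1.0 - state.p) if cfg.consolidation_on else cfg.eta0
    w_bar = state.p * state.m + eta * g
    step = np.where(np.abs(g) > cfg.g_lim, cfg.p_up, -cfg.p_down)
    p_new = np.clip(state.p + step, cfg.p_min, 1.0)
    if cfg.consolidation_on:
        # freezing caps p at the threshold so (1 - p) stays positive
        p_new = np.minimum(p_new, cfg.p_freeze)
    state.p = np.where(state.frozen, state.p, p_new)
    if cfg.consolidation_on:
        state.frozen |= state.p >= cfg.p_freeze
    state.m = w_bar / state.p
    return g


def accuracy(
    state: PerceptronState, patterns: np.ndarray, labels: np.ndarray,
    mode: str = "expected", rng=None,
) -> float:
    pred = perceptron_predict(state, patterns, rng=rng, mode=mode)
    return float((pred == labels_to_signs(labels)).mean())


def run_lifelong_perceptron(
    tasks: TaskSequence,
    cfg: MetaplasticityConfig | None = None,
    variant: str = "stochastic_consolidated",
    n_passes: int = 25,
    rng=None,
    eval_mode: str = "expected",
) -> np.ndarray:
    """Train tasks sequentially; return the task x checkpoint accuracy matrix.

    Row ``k`` holds the accuracy on every task after finishing task ``k``
    (training accuracy on each task's own patterns — the perceptron's job is
    memorisation).  Patterns are visited in batches of five, reshuffled each
    pass; evaluation uses expected weights by default.
    """
    if cfg is None:
        cfg = MetaplasticityConfig.perceptron()
    rng = np.random.default_rng(rng)
    dim = tasks[0].dim
    state = PerceptronState.init(dim, variant=variant)
    matrix = np.full((len(tasks), len(tasks)), np.nan)
    for k, task in enumerate(tasks):
        X, y = task.inputs, task.labels
        n = len(task)
        for _ in range(n_passes):
            order = rng.permutation(n)
            for start in range(0, n, PERCEPTRON_BATCH):
                idx = order[start : start + PERCEPTRON_BATCH]
                perceptron_batch_update(state, X[idx], y[idx], cfg, rng=rng)
        for j, other in enumerate(tasks):
            matrix[k, j] = accuracy(
                state, other.inputs, other.labels, mode=eval_mode, rng=rng
            )
    return matrix
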