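"""Orchestration of the two experiment families and the analysis suite.

Model variants
--------------
``plastic_stochastic``
    Sampled release, metaplastic release probabilities (the full model).
``fixed_release``
    Sampled release at one fixed, uniform probability; no p-dynamics.
    Used with the probability matched to a trained plastic model's mean.
``deterministic``
    p = 1 everywhere, expected-weight forward pass, no p-dynamics: a plain
    multilayer perceptron trained by SGD.
``ghost``
    Transmission fixed at p = 0.5 while ghost probabilities evolve under the
    metaplasticity rule and modulate plasticity/freezing — consolidation
    without transmission stochasticity.
``no_consolidation``
    Sampled release and p-dynamics, but no learning-rate modulation and no
    freezing.

All experiments are driven by explicit seeds; paired comparisons (ablation
variants) share the data order and initial strengths, differing only in the
ablated mechanism.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .network import NetworkState, init_network, forward_expected, forward_stochastic
from .plasticity import (
    MetaplasticityConfig,
    apply_update,
    compute_update_direction,
    update_expected_strengths,
)
from .metrics import (
    InfoEnergyPoint,
    empirical_fisher,
    evaluate_predictions,
    lesion_curve,
    mutual_information,
    release_probability_histogram,
    sparsity_report,
    synaptic_energy,
)
from .tasks import LabelledDataset, TaskSequence

VARIANTS = (
    "plastic_stochastic",
    "fixed_release",
    "deterministic",
    "ghost",
    "no_consolidation",
)


@dataclass
class RunConfig:
    """Everything needed to reproduce one experiment run."""

    experiment: str = "energy"  # energy | lifelong | perceptron
    model_variant: str = "plastic_stochastic"
    hidden: tuple[int, ...] = (200, 200)
    batch_size: int = 100
    epochs: int = 50
    meta: MetaplasticityConfig = field(default_factory=MetaplasticityConfig)
    lambda_grid: tuple[float, ...] = (1e-4, 3e-4, 1e-3, 3e-3)
    seeds: tuple[int, ...] = (0, 1, 2)
    eval_mode: str = "sampled"
    eval_samples: int = 10
    fixed_p: float = 0.5
    p_init: float = 0.25

    def __post_init__(self):
        if self.model_variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.model_variant!r}")
        if self.model_variant == "ghost" and self.experiment == "energy":
            raise ValueError("ghost control is a lifelong-learning ablation")

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "meta" in d:
            d["meta"] = MetaplasticityConfig.from_dict(d["meta"])
        for k in ("hidden", "lambda_grid", "seeds"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class AccuracyMatrix:
    """Task x checkpoint accuracy grid for lifelong-learning evaluation.

    ``matrix[k, j]`` is the test accuracy on task ``j`` after training task
    ``k``.
    """

    matrix: np.ndarray

    @property
    def first_task_curve(self) -> np.ndarray:
        return self.matrix[:, 0]

    @property
    def final_mean(self) -> float:
        return float(np.nanmean(self.matrix[-1]))

    @property
    def final_row(self) -> np.ndarray:
        return self.matrix[-1]

    def to_frame(self) -> pd.DataFrame:
        n = self.matrix.shape[1]
        df = pd.DataFrame(
            self.matrix, columns=[f"task_{j}" for j in range(n)]
        )
        df.insert(0, "after_task", np.arange(self.matrix.shape[0]))
        return df


def make_network(
    layer_sizes: list[int],
    variant: str,
    rng,
    p_init: float = 0.25,
    fixed_p: float = 0.5,
) -> NetworkState:
    """Initialise a network for the given model variant.

    The strength draw consumes the generator identically for every variant,
    so paired-seed comparisons share initial strengths exactly.
    """
    net = init_network(layer_sizes, p_init=p_init, rng=rng)
    if variant == "deterministic":
        for lyr in net.layers:
            lyr.p.fill(1.0)
    elif variant == "fixed_release":
        for lyr in net.layers:
            lyr.p.fill(fixed_p)
    elif variant == "ghost":
        for lyr in net.layers:
            lyr.ghost_p = np.full_like(lyr.p, p_init)
            lyr.p.fill(0.5)
    elif variant not in ("plastic_stochastic", "no_consolidation"):
        raise ValueError(f"unknown variant {variant!r}")
    return net


def _variant_behaviour(variant: str, meta: MetaplasticityConfig):
    """(forward_mode, p_dynamics, effective MetaplasticityConfig)."""
    if variant == "deterministic":
        return "expected", False, meta.replace(consolidation_on=False)
    if variant == "fixed_release":
        return "sampled", False, meta.replace(consolidation_on=False)
    if variant == "no_consolidation":
        return "sampled", True, meta.replace(consolidation_on=False)
    if variant == "ghost":
        return "sampled", True, meta.replace(consolidation_on=True)
    return "sampled", True, meta  # plastic_stochastic


@dataclass
class TrainLog:
    """Per-step means of |g| and p, and the frozen fraction."""

    mean_abs_g: list[float] = field(default_factory=list)
    mean_p: list[float] = field(default_factory=list)
    frozen_fraction: list[float] = field(default_factory=list)

    def record(self, net: NetworkState, g) -> None:
        self.mean_abs_g.append(
            float(np.mean([np.abs(gl).mean() for gl in g]))
        )
        self.mean_p.append(float(np.mean([lyr.meta_p.mean() for lyr in net.layers])))
        self.frozen_fraction.append(
            float(np.mean([lyr.frozen.mean() for lyr in net.layers]))
        )


def train_network(
    net: NetworkState,
    train_set: LabelledDataset,
    meta: MetaplasticityConfig,
    epochs: int,
    batch_size: int = 100,
    rng=None,
    variant: str = "plastic_stochastic",
    log: TrainLog | None = None,
) -> NetworkState:
    """SGD over epochs of shuffled mini-batches; updates ``net`` in place."""
    rng = np.random.default_rng(rng)
    forward_mode, p_dynamics, cfg = _variant_behaviour(variant, meta)
    X, y = train_set.inputs, train_set.labels
    n = len(train_set)
    for _ in range(epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            if forward_mode == "sampled":
                _, cache = forward_stochastic(net, X[idx], rng)
            else:
                _, cache = forward_expected(net, X[idx], return_cache=True)
            g = compute_update_direction(net, y[idx], cache, cfg)
            if p_dynamics:
                apply_update(net, g, cfg)
            else:
                update_expected_strengths(net, g, cfg)
            if log is not None:
                log.record(net, g)
    return net


def train_batch_stream(
    net: NetworkState,
    stream,
    meta: MetaplasticityConfig,
    rng=None,
    variant: str = "plastic_stochastic",
) -> NetworkState:
    """Train on a pre-built ``(inputs, labels, task)`` batch stream (used for
    the continuous protocol, where no task boundaries exist)."""
    rng = np.random.default_rng(rng)
    forward_mode, p_dynamics, cfg = _variant_behaviour(variant, meta)
    for Xb, yb, _ in stream:
        if forward_mode == "sampled":
            _, cache = forward_stochastic(net, Xb, rng)
        else:
            _, cache = forward_expected(net, Xb, return_cache=True)
        g = compute_update_direction(net, yb, cache, cfg)
        if p_dynamics:
            apply_update(net, g, cfg)
        else:
            update_expected_strengths(net, g, cfg)
    return net


def mean_release_probability(net: NetworkState) -> float:
    return float(np.mean(np.concatenate([lyr.p.ravel() for lyr in net.layers])))


def _accuracy(net, ds: LabelledDataset, cfg: RunConfig, rng) -> float:
    _, acc = evaluate_predictions(
        net, ds.inputs, ds.labels, mode=cfg.eval_mode,
        n_samples=cfg.eval_samples, rng=rng,
    )
    return acc


def train_energy_experiment(
    dataset: LabelledDataset,
    cfg: RunConfig | None = None,
) -> pd.DataFrame:
    """The energy/information sweep over the l2 grid, for all three models.

    For each seed and each l2 strength the plastic-stochastic model is
    trained first; the fixed-release control then reuses that model's final
    mean release probability, and the deterministic control runs with p = 1.
    Returns a tidy frame of :class:`InfoEnergyPoint` rows.
    """
    if cfg is None:
        cfg = RunConfig(experiment="energy")
    layer_sizes = [dataset.dim, *cfg.hidden, dataset.n_classes]
    train, test = dataset.train, dataset.test
    points: list[InfoEnergyPoint] = []
    for seed in cfg.seeds:
        for lam in cfg.lambda_grid:
            meta = cfg.meta.replace(lambda_l2=lam, consolidation_on=False)
            # plastic stochastic
            rng = np.random.default_rng(seed)
            net = make_network(layer_sizes, "plastic_stochastic", rng,
                               p_init=cfg.p_init)
            train_network(net, train, meta, cfg.epochs, cfg.batch_size, rng,
                          variant="plastic_stochastic")
            matched_p = mean_release_probability(net)
            points.append(_measure(net, test, lam, "plastic_stochastic", seed, cfg))
            # fixed release, probability matched to the trained plastic model
            rng = np.random.default_rng(seed)
            net = make_network(layer_sizes, "fixed_release", rng,
                               fixed_p=matched_p)
            train_network(net, train, meta, cfg.epochs, cfg.batch_size, rng,
                          variant="fixed_release")
            points.append(_measure(net, test, lam, "fixed_release", seed, cfg))
            # deterministic
            rng = np.random.default_rng(seed)
            net = make_network(layer_sizes, "deterministic", rng)
            train_network(net, train, meta, cfg.epochs, cfg.batch_size, rng,
                          variant="deterministic")
            points.append(_measure(net, test, lam, "deterministic", seed, cfg))
    return pd.DataFrame([asdict(pt) for pt in points])


def _measure(net, test, lam, variant, seed, cfg) -> InfoEnergyPoint:
    rng = np.random.default_rng(seed + 10_000)
    mode = "expected" if variant == "deterministic" else cfg.eval_mode
    joint, acc = evaluate_predictions(
        net, test.inputs, test.labels, mode=mode,
        n_samples=cfg.eval_samples, rng=rng,
    )
    return InfoEnergyPoint(
        mutual_information=mutual_information(joint),
        energy=synaptic_energy(net),
        lambda_l2=lam,
        model_variant=variant,
        accuracy=acc,
        seed=seed,
    )


def best_info_per_energy(points: pd.DataFrame) -> pd.Series:
    """Best MI/energy ratio per model variant, averaged over seeds."""
    pts = points.copy()
    pts["ratio"] = pts["mutual_information"] / pts["energy"]
    return pts.groupby(["model_variant", "seed"])["ratio"].max().groupby(
        "model_variant"
    ).mean()


def train_lifelong_experiment(
    tasks: TaskSequence,
    cfg: RunConfig | None = None,
    seed: int = 0,
    return_histograms: bool = False,
):
    """Sequential training over a task sequence with per-checkpoint evaluation.

    Returns an :class:`AccuracyMatrix` (rows: after each task, columns: test
    accuracy per task) and optionally the release-probability histogram at
    every checkpoint.
    """
    if cfg is None:
        cfg = RunConfig(
            experiment="lifelong",
            epochs=10,
            meta=MetaplasticityConfig.lifelong(),
        )
    n_out = tasks[0].n_classes
    layer_sizes = [tasks[0].dim, *cfg.hidden, n_out]
    rng = np.random.default_rng(seed)
    net = make_network(
        layer_sizes, cfg.model_variant, rng, p_init=cfg.p_init, fixed_p=cfg.fixed_p
    )
    matrix = np.full((len(tasks), len(tasks)), np.nan)
    hists = []
    eval_rng = np.random.default_rng(seed + 20_000)
    for k, task in enumerate(tasks):
        train_network(
            net, task.train, cfg.meta, cfg.epochs, cfg.batch_size, rng,
            variant=cfg.model_variant,
        )
        for j, other in enumerate(tasks):
            matrix[k, j] = _accuracy(net, other.test, cfg, eval_rng)
        if return_histograms:
            hists.append(release_probability_histogram(net))
    result = AccuracyMatrix(matrix=matrix)
    if return_histograms:
        return result, net, hists
    return result, net


def train_joint_upper_bound(
    tasks: TaskSequence, cfg: RunConfig, seed: int = 0
) -> float:
    """Train on all tasks simultaneously; mean test accuracy over tasks.

    Serves as the reference ceiling for sequential training.
    """
    merged = LabelledDataset(
        inputs=np.vstack([t.train.inputs for t in tasks]),
        labels=np.concatenate([t.train.labels for t in tasks]),
        n_classes=tasks[0].n_classes,
    )
    layer_sizes = [tasks[0].dim, *cfg.hidden, tasks[0].n_classes]
    rng = np.random.default_rng(seed)
    net = make_network(layer_sizes, cfg.model_variant, rng, p_init=cfg.p_init)
    train_network(
        net, merged, cfg.meta, cfg.epochs * len(tasks), cfg.batch_size, rng,
        variant=cfg.model_variant,
    )
    eval_rng = np.random.default_rng(seed + 20_000)
    return float(np.mean([_accuracy(net, t.test, cfg, eval_rng) for t in tasks]))


def run_analysis_suite(
    net: NetworkState,
    dataset: LabelledDataset,
    rng=None,
    p_important: float = 0.9,
    lesion_fractions=None,
    sparsity_layer: int = 1,
) -> dict:
    """Bundle all post-training measurements of one network on one dataset."""
    rng = np.random.default_rng(rng)
    test = dataset.test if dataset.split is not None else dataset
    joint, acc = evaluate_predictions(
        net, test.inputs, test.labels, mode="sampled", n_samples=10, rng=rng
    )
    fisher = empirical_fisher(net, test.inputs, test.labels, rng=rng)
    lesions = {
        ordering: lesion_curve(
            net, test.inputs, test.labels, ordering=ordering,
            fractions=lesion_fractions, rng=rng,
        )
        for ordering in ("low_p_first", "random")
    }
    p_all = np.concatenate([lyr.p.ravel() for lyr in net.layers])
    return {
        "energy": synaptic_energy(net),
        "mutual_information": mutual_information(joint),
        "accuracy": acc,
        "fisher": fisher,
        "lesion": lesions,
        "sparsity": sparsity_report(
            net, layer=sparsity_layer, p_important=p_important, rng=rng
        ),
        "p_histogram": release_probability_histogram(net),
        "fraction_high_p": float((p_all >= p_important).mean()),
    }
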