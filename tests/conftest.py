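"""Shared fixtures.

The expensive trained networks and experiment sweeps are session-scoped so
that several acceptance checks (Fisher/release correspondence, lesion
ordering, sparsity, energy efficiency, ablation) reuse the same runs.
"""

from __future__ import annotations

import numpy as np
import pytest

import stochsyn as ss
from stochsyn import presets


@pytest.fixture(scope="session")
def energy_dataset():
    return presets.energy_dataset()


@pytest.fixture(scope="session")
def lifelong_dataset():
    return presets.lifelong_dataset()


@pytest.fixture(scope="session")
def small_net():
    return ss.init_network([6, 4, 3], p_init=0.5, rng=1)


@pytest.fixture(scope="session")
def analysis_runs(energy_dataset):
    """Three seeds of the long-horizon analysis training run, with the full
    measurement suite evaluated on each."""
    runs = []
    for seed in presets.SEEDS:
        rng = np.random.default_rng(seed)
        net = ss.make_network(
            [presets.DIM, *presets.ENERGY_HIDDEN, 10], "plastic_stochastic", rng
        )
        ss.train_network(
            net,
            energy_dataset.train,
            presets.energy_meta(lambda_l2=presets.ANALYSIS_LAMBDA),
            presets.ANALYSIS_EPOCHS,
            batch_size=100,
            rng=rng,
        )
        suite = ss.run_analysis_suite(
            net,
            energy_dataset,
            rng=seed + 100,
            lesion_fractions=np.array([0.0, 0.25, 0.5, 0.75, 1.0]),
        )
        runs.append((net, suite))
    return runs


@pytest.fixture(scope="session")
def energy_points(energy_dataset):
    return ss.train_energy_experiment(energy_dataset, presets.energy_config())


@pytest.fixture(scope="session")
def split_ablation():
    """Paired-seed split-task runs for the consolidation ablation."""
    tasks = presets.split_tasks()
    results = {}
    for variant in ("plastic_stochastic", "ghost", "no_consolidation"):
        cfg = presets.lifelong_config(variant, protocol="split")
        results[variant] = [
            ss.train_lifelong_experiment(tasks, cfg, seed=seed)[0]
            for seed in presets.SEEDS
        ]
    return results


@pytest.fixture(scope="session")
def permuted_retention():
    """Full model vs no-consolidation on permuted parity tasks (two paired
    seeds; the per-seed retention curves are nearly identical)."""
    tasks = presets.permuted_parity_tasks()
    results = {}
    for variant in ("plastic_stochastic", "no_consolidation"):
        cfg = presets.lifelong_config(variant, protocol="permuted")
        results[variant] = [
            ss.train_lifelong_experiment(tasks, cfg, seed=seed)[0]
            for seed in (0, 1)
        ]
    return results


@pytest.fixture(scope="session")
def perceptron_results():
    """Lifelong perceptron accuracy matrices, ten seeds per variant."""
    out = {"standard": [], "stochastic_consolidated": []}
    for seed in range(10):
        tasks = ss.generate_perceptron_tasks(rng=1000 + seed)
        for variant in out:
            out[variant].append(
                ss.run_lifelong_perceptron(tasks, variant=variant, rng=seed)
            )
    return out
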