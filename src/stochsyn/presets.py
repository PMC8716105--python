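"""Preset study conditions for the desk-scale experiments.

Two experiment families share one input family (the synthetic
low-dimensional-signal classification task) at sizes chosen so a full
experiment trains in seconds-to-minutes on one CPU:

* **energy / analysis family** — 10-class task with a 20-dimensional
  relevant subspace inside 80 inputs, network 80-40-40-10, the
  energy-experiment rule constants (p_up = p_down = 0.07, g_lim = 1e-3,
  eta = 0.05, consolidation off).
* **lifelong family** — a 60-dimensional relevant subspace (high-SNR tasks
  that are learned quickly, the regime consolidation is designed for),
  network 80-64-64-2, consolidation on.  The metaplasticity constants are
  coarsely calibrated once on a single scenario and reused everywhere,
  mirroring how such constants must be matched to the gradient scale and
  training horizon of the data they run on: eta0 = 0.05, p_up = 0.005,
  p_down = 0.005039 (the slight down-bias mirrors the published
  asymmetry), g_lim = 5e-4, p_init = 0.5, freeze at 0.9.

The synthetic generator itself defaults to a 784-dimensional task
mirroring digit-image scale; these presets down-size it so that the full
acceptance battery runs within minutes.
"""

from __future__ import annotations

from .harness import RunConfig
from .plasticity import MetaplasticityConfig
from .tasks import LabelledDataset, TaskSequence, generate_synthetic_classification, \
    make_permuted_tasks, make_split_tasks

DIM = 80
N_TRAIN = 6000
N_TEST = 1000
NOISE_SD = 0.3
DATASET_SEED = 7  # fixed data draw; model seeds vary across repetitions

ENERGY_RELEVANT_DIM = 20
ENERGY_HIDDEN = (40, 40)
ENERGY_EPOCHS = 70
ANALYSIS_EPOCHS = 300  # long-time regime: release probabilities settle
ANALYSIS_LAMBDA = 1e-3
LAMBDA_GRID = (1e-4, 3e-4, 1e-3, 3e-3)

LIFELONG_RELEVANT_DIM = 60
LIFELONG_HIDDEN = (64, 64)
LIFELONG_EPOCHS_SPLIT = 100
LIFELONG_EPOCHS_PERMUTED = 60
LIFELONG_P_INIT = 0.5

SEEDS = (0, 1, 2)


def energy_meta(lambda_l2: float = 0.0) -> MetaplasticityConfig:
    """Energy-family rule constants (consolidation off)."""
    return MetaplasticityConfig(
        p_up=0.07, p_down=0.07, g_lim=1e-3, eta0=0.05,
        lambda_l2=lambda_l2, consolidation_on=False,
    )


def lifelong_meta() -> MetaplasticityConfig:
    """Lifelong-family rule constants, calibrated to the desk-scale tasks."""
    return MetaplasticityConfig(
        p_up=0.005, p_down=0.005039, g_lim=5e-4, eta0=0.05,
        p_freeze=0.9, consolidation_on=True,
    )


def energy_dataset(rng=DATASET_SEED) -> LabelledDataset:
    return generate_synthetic_classification(
        n_classes=10, dim=DIM, relevant_dim=ENERGY_RELEVANT_DIM,
        n_train=N_TRAIN, n_test=N_TEST, noise_sd=NOISE_SD, rng=rng,
    )


def lifelong_dataset(rng=DATASET_SEED) -> LabelledDataset:
    return generate_synthetic_classification(
        n_classes=10, dim=DIM, relevant_dim=LIFELONG_RELEVANT_DIM,
        n_train=N_TRAIN, n_test=N_TEST, noise_sd=NOISE_SD, rng=rng,
    )


def split_tasks(rng=DATASET_SEED) -> TaskSequence:
    return make_split_tasks(lifelong_dataset(rng), n_tasks=5)


def permuted_parity_tasks(rng=DATASET_SEED, perm_rng=11) -> TaskSequence:
    """Binary parity of all ten classes under per-task input permutations.

    Permutations remap every input coordinate, so consecutive tasks
    interfere maximally — the protocol where forgetting, and hence the
    value of consolidation, is visible at desk scale.
    """
    ds = lifelong_dataset(rng)
    base = LabelledDataset(ds.inputs, ds.labels % 2, 2, ds.split)
    return make_permuted_tasks(base, n_tasks=5, rng=perm_rng)


def energy_config(seeds=SEEDS) -> RunConfig:
    return RunConfig(
        experiment="energy", hidden=ENERGY_HIDDEN, epochs=ENERGY_EPOCHS,
        meta=energy_meta(), lambda_grid=LAMBDA_GRID, seeds=tuple(seeds),
    )


def lifelong_config(variant: str, protocol: str = "split") -> RunConfig:
    epochs = LIFELONG_EPOCHS_SPLIT if protocol == "split" else LIFELONG_EPOCHS_PERMUTED
    return RunConfig(
        experiment="lifelong", model_variant=variant, hidden=LIFELONG_HIDDEN,
        epochs=epochs, meta=lifelong_meta(), p_init=LIFELONG_P_INIT,
        fixed_p=0.5, eval_mode="expected",
    )
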