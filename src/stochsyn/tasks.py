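"""Task generators and readers for the classification experiments.

The native input is a synthetic high-dimensional classification task whose
task-relevant information lives in a low-dimensional subspace — mimicking
digit images, which carry high entropy while the relevant information is
only the class identity.  On top of single datasets the module builds the
lifelong-learning protocols (split with parity labels, permuted inputs,
continuous mixing) and random +/-1 pattern sets for the perceptron.  An IDX
reader allows running the same pipelines on MNIST-format files.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class LabelledDataset:
    """Inputs, integer labels and train/test tags for one task."""

    inputs: np.ndarray  # (n_examples, dim)
    labels: np.ndarray  # (n_examples,)
    n_classes: int
    split: np.ndarray | None = None  # "train"/"test" per example, or None

    def __post_init__(self):
        self.inputs = np.atleast_2d(np.asarray(self.inputs, dtype=float))
        self.labels = np.asarray(self.labels, dtype=int)
        if not np.isfinite(self.inputs).all():
            raise ValueError("inputs contain non-finite values")
        if self.labels.min(initial=0) < 0 or self.labels.max(initial=0) >= self.n_classes:
            raise ValueError("labels out of [0, n_classes)")

    def __len__(self) -> int:
        return self.inputs.shape[0]

    @property
    def dim(self) -> int:
        return self.inputs.shape[1]

    def subset(self, idx) -> "LabelledDataset":
        return LabelledDataset(
            inputs=self.inputs[idx],
            labels=self.labels[idx],
            n_classes=self.n_classes,
            split=None if self.split is None else self.split[idx],
        )

    def _tagged(self, tag: str) -> "LabelledDataset":
        if self.split is None:
            raise ValueError("dataset has no train/test tags")
        return self.subset(self.split == tag)

    @property
    def train(self) -> "LabelledDataset":
        return self._tagged("train")

    @property
    def test(self) -> "LabelledDataset":
        return self._tagged("test")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.inputs)
        df.columns = [f"x{i}" for i in range(self.dim)]
        df["label"] = self.labels
        if self.split is not None:
            df["split"] = self.split
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, n_classes: int) -> "LabelledDataset":
        xcols = [c for c in df.columns if c.startswith("x")]
        return cls(
            inputs=df[xcols].to_numpy(dtype=float),
            labels=df["label"].to_numpy(dtype=int),
            n_classes=n_classes,
            split=df["split"].to_numpy() if "split" in df else None,
        )


@dataclass
class TaskSequence:
    """Ordered tasks for sequential training.

    Boundary metadata (which task an example came from) exists for
    evaluation only; the learner-facing stream exposes inputs and labels
    alone.
    """

    tasks: list[LabelledDataset]
    protocol: str = "synthetic"
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.tasks)

    def __iter__(self):
        return iter(self.tasks)

    def __getitem__(self, k) -> LabelledDataset:
        return self.tasks[k]


def generate_synthetic_classification(
    n_classes: int = 10,
    dim: int = 784,
    relevant_dim: int = 20,
    n_train: int = 6000,
    n_test: int = 1000,
    noise_sd: float = 0.3,
    rng=None,
) -> LabelledDataset:
    """High-dimensional inputs whose class information is low-dimensional.

    Each class owns an on/off prototype (entries 0 or 1, like strongly
    contrasting pixels) on ``relevant_dim`` randomly chosen coordinates;
    examples add Gaussian noise of standard deviation ``noise_sd`` there,
    while the remaining coordinates carry pure unit-variance Gaussian
    nuisance, independent of the label.  Every feature is min-max scaled to
    [0, 1].  Train/test are tagged 6:1 by default, with labels balanced
    across classes.
    """
    if not (0 < relevant_dim <= dim):
        raise ValueError("need 0 < relevant_dim <= dim")
    rng = np.random.default_rng(rng)
    n = n_train + n_test
    relevant = rng.choice(dim, size=relevant_dim, replace=False)
    prototypes = rng.integers(0, 2, size=(n_classes, relevant_dim)).astype(float)
    labels = np.tile(np.arange(n_classes), n // n_classes + 1)[:n]
    rng.shuffle(labels)
    X = rng.standard_normal((n, dim))  # nuisance everywhere, overwritten below
    X[:, relevant] = prototypes[labels] + noise_sd * rng.standard_normal(
        (n, relevant_dim)
    )
    lo, hi = X.min(axis=0), X.max(axis=0)
    X = (X - lo) / np.where(hi > lo, hi - lo, 1.0)
    split = np.array(["train"] * n_train + ["test"] * n_test)
    return LabelledDataset(inputs=X, labels=labels, n_classes=n_classes, split=split)


def make_split_tasks(dataset: LabelledDataset, n_tasks: int) -> TaskSequence:
    """Sequential binary parity tasks over consecutive class pairs.

    Task ``k`` holds the examples of classes ``2k`` and ``2k+1``, relabelled
    by parity (even class -> 0, odd class -> 1).
    """
    if dataset.n_classes < 2 * n_tasks:
        raise ValueError(
            f"{n_tasks} split tasks need {2 * n_tasks} classes, "
            f"dataset has {dataset.n_classes}"
        )
    tasks = []
    for k in range(n_tasks):
        sel = (dataset.labels == 2 * k) | (dataset.labels == 2 * k + 1)
        sub = dataset.subset(sel)
        tasks.append(
            LabelledDataset(
                inputs=sub.inputs,
                labels=sub.labels % 2,
                n_classes=2,
                split=sub.split,
            )
        )
    return TaskSequence(tasks=tasks, protocol="split_parity")


def make_permuted_tasks(
    dataset: LabelledDataset, n_tasks: int, rng=None
) -> TaskSequence:
    """Tasks differing by a fixed random permutation of input coordinates.

    Task 0 is the identity permutation; later tasks draw independent
    permutations.
    """
    rng = np.random.default_rng(rng)
    tasks = []
    perms = []
    for k in range(n_tasks):
        perm = np.arange(dataset.dim) if k == 0 else rng.permutation(dataset.dim)
        perms.append(perm)
        tasks.append(
            LabelledDataset(
                inputs=dataset.inputs[:, perm],
                labels=dataset.labels,
                n_classes=dataset.n_classes,
                split=dataset.split,
            )
        )
    return TaskSequence(
        tasks=tasks, protocol="permuted", metadata={"permutations": perms}
    )


def make_continuous_sequence(
    tasks: TaskSequence,
    transition_fraction: float = 0.2,
    batch_size: int = 100,
    rng=None,
) -> list[tuple[np.ndarray, np.ndarray, int]]:
    """Batch stream with smooth mixing across task boundaries.

    Around each boundary a transition window of ``transition_fraction`` of a
    task's length mixes the outgoing and incoming task: the probability of
    drawing from the outgoing task decreases linearly through the window.
    Yields ``(inputs, labels, dominant_task)`` batches; the task index is
    evaluation metadata only.  Total example count is preserved.
    """
    if not (0.0 <= transition_fraction < 1.0):
        raise ValueError("transition_fraction must lie in [0, 1)")
    if len(tasks) < 2:
        raise ValueError("need at least two tasks")
    rng = np.random.default_rng(rng)
    train = [t.train if t.split is not None else t for t in tasks]
    pools = [rng.permutation(len(t)) .tolist() for t in train]
    lengths = [len(t) for t in train]
    bounds = np.cumsum([0] + lengths)
    total = bounds[-1]

    def incoming_prob(t: int) -> tuple[int, float]:
        """Task index owning slot t and the probability the *next* task
        intrudes (linear ramp inside the window straddling the boundary)."""
        k = int(np.searchsorted(bounds, t, side="right") - 1)
        k = min(k, len(train) - 1)
        if k + 1 >= len(train):
            return k, 0.0
        w = transition_fraction * lengths[k]
        dist_to_boundary = bounds[k + 1] - t
        if w <= 0 or dist_to_boundary > w:
            return k, 0.0
        # ramps from 0 at window start to 1/2 at the boundary; the mirror
        # half of the window lies in task k+1's stretch
        return k, 0.5 * (1.0 - dist_to_boundary / w)

    def outgoing_prob(t: int) -> tuple[int, float]:
        k = int(np.searchsorted(bounds, t, side="right") - 1)
        k = min(k, len(train) - 1)
        if k == 0:
            return k, 0.0
        w = transition_fraction * lengths[k]
        dist_from_boundary = t - bounds[k]
        if w <= 0 or dist_from_boundary >= w:
            return k, 0.0
        return k, 0.5 * (1.0 - dist_from_boundary / w)

    def draw(task_idx: int) -> tuple[np.ndarray, int]:
        pool = pools[task_idx]
        if pool:
            i = pool.pop()
        else:  # pool exhausted inside a mixing window: resample
            i = int(rng.integers(len(train[task_idx])))
        return train[task_idx].inputs[i], train[task_idx].labels[i]

    stream = []
    for start in range(0, total, batch_size):
        xs, ys = [], []
        dominant = int(np.searchsorted(bounds, start, side="right") - 1)
        dominant = min(dominant, len(train) - 1)
        for t in range(start, min(start + batch_size, total)):
            k, q_in = incoming_prob(t)
            _, q_out = outgoing_prob(t)
            u = rng.random()
            if q_in > 0 and u < q_in:
                src = k + 1
            elif q_out > 0 and u < q_out:
                src = k - 1
            else:
                src = k
            x, y = draw(src)
            xs.append(x)
            ys.append(y)
        stream.append((np.array(xs), np.array(ys), dominant))
    return stream


def generate_perceptron_tasks(
    n_tasks: int = 5,
    n_patterns: int = 100,
    dim: int = 1000,
    rng=None,
) -> TaskSequence:
    """Random +/-1 patterns with random +/-1 labels, independent per task."""
    rng = np.random.default_rng(rng)
    tasks = []
    for _ in range(n_tasks):
        X = rng.choice([-1.0, 1.0], size=(n_patterns, dim))
        y = rng.choice([0, 1], size=n_patterns)  # 0 -> -1, 1 -> +1 downstream
        tasks.append(LabelledDataset(inputs=X, labels=y, n_classes=2))
    return TaskSequence(tasks=tasks, protocol="perceptron")


_IDX_DTYPES = {0x08: np.uint8, 0x09: np.int8, 0x0B: ">i2", 0x0C: ">i4",
               0x0D: ">f4", 0x0E: ">f8"}


def _read_idx(path) -> np.ndarray:
    with open(path, "rb") as fh:
        header = fh.read(4)
        if len(header) < 4 or header[0] != 0 or header[1] != 0:
            raise ValueError(f"{path}: bad IDX magic number {header!r}")
        dtype_code, ndim = header[2], header[3]
        if dtype_code not in _IDX_DTYPES:
            raise ValueError(f"{path}: unknown IDX dtype code {dtype_code:#x}")
        shape = struct.unpack(f">{ndim}i", fh.read(4 * ndim))
        data = np.frombuffer(fh.read(), dtype=_IDX_DTYPES[dtype_code])
        if data.size != int(np.prod(shape)):
            raise ValueError(f"{path}: truncated IDX payload")
        return data.reshape(shape)


def write_idx(path, array: np.ndarray) -> None:
    """Write an unsigned-byte IDX file (the MNIST container layout)."""
    arr = np.ascontiguousarray(array, dtype=np.uint8)
    with open(path, "wb") as fh:
        fh.write(bytes([0, 0, 0x08, arr.ndim]))
        fh.write(struct.pack(f">{arr.ndim}i", *arr.shape))
        fh.write(arr.tobytes())


def load_idx_images(images_path, labels_path, n_classes: int = 10) -> LabelledDataset:
    """Read an IDX image/label file pair into a flat [0, 1]-scaled dataset."""
    images = _read_idx(images_path)
    labels = _read_idx(labels_path)
    if images.shape[0] != labels.shape[0]:
        raise ValueError("image and label counts differ")
    X = images.reshape(images.shape[0], -1).astype(float) / 255.0
    return LabelledDataset(
        inputs=X, labels=labels.astype(int), n_classes=n_classes
    )
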