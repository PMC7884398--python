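"""Learning vector quantization (LVQ1) on flattened activation maps.

The classifier lives in the 81-dimensional space of max-normalized
activation-map vectors (row-major flattening of the 9x9 lattice, the
same neuron-index convention as the SOM).  Each class owns one or more
prototype vectors; prediction is the label of the nearest prototype
(Euclidean), which partitions the space into Voronoi cells.

Training follows the classical LVQ1 rule with a constant learning rate:
per epoch the examples are visited in seeded shuffled order, and the
single nearest prototype moves toward the example when their labels
match and away when they differ, by ``learning_rate * (x - p)``.  The
per-epoch loss is the misclassification ratio on the training set,
evaluated after the epoch.  Defaults (learning rate 0.001, 1000 epochs,
one prototype per class, class-mean initialization) are the smallest
configuration consistent with the problem; everything is deterministic
for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .activation import ActivationMap
from .errors import StageError

_INIT_MODES = ("class_mean", "sample")


@dataclass
class LvqConfig:
    learning_rate: float = 0.001
    epochs: int = 1000
    prototypes_per_class: int = 1
    init: str = "class_mean"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.learning_rate >= 0:
            raise StageError("learning rate must be >= 0")
        if self.epochs < 1:
            raise StageError("epochs must be >= 1")
        if self.prototypes_per_class < 1:
            raise StageError("need at least one prototype per class")
        if self.init not in _INIT_MODES:
            raise StageError(f"unknown init mode {self.init!r}")


@dataclass
class LvqModel:
    """Labeled prototypes plus the training-loss curve."""

    prototypes: np.ndarray  # (n_prototypes, dim)
    labels: list[str]  # per prototype, insertion order = tie-break order
    config: LvqConfig
    loss_curve: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.prototypes = np.asarray(self.prototypes, dtype=np.float64)
        if len(self.labels) != len(self.prototypes):
            raise StageError("one label per prototype required")
        if len(set(self.labels)) < 2:
            raise StageError("LVQ model needs prototypes from >= 2 classes")
        if not np.all(np.isfinite(self.prototypes)):
            raise StageError("prototypes must be finite")

    def to_dict(self) -> dict:
        return {
            "config": asdict(self.config),
            "labels": list(self.labels),
            "prototypes": [[float(v) for v in p] for p in self.prototypes],
            "loss_curve": [float(v) for v in self.loss_curve],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LvqModel":
        return cls(prototypes=np.asarray(d["prototypes"], dtype=np.float64),
                   labels=list(d["labels"]), config=LvqConfig(**d["config"]),
                   loss_curve=[float(v) for v in d["loss_curve"]])


def flatten_map(amap: ActivationMap) -> np.ndarray:
    """Row-major 81-vector of a map's normalized values.

    Component ``i`` is neuron ``i`` in the shared row-major convention,
    i.e. lattice position (i // cols, i % cols) — identical to the row
    order of the activation-map CSV.
    """
    return np.asarray(amap.normalized, dtype=np.float64).copy()


def _nearest(prototypes: np.ndarray, x: np.ndarray) -> int:
    diff = prototypes - x
    return int(np.argmin(np.einsum("ij,ij->i", diff, diff)))


def _init_prototypes(x: np.ndarray, y: np.ndarray, classes: list[str],
                     config: LvqConfig,
                     rng: np.random.Generator) -> tuple[np.ndarray, list[str]]:
    protos, labels = [], []
    for cls in classes:
        members = x[y == cls]
        for _ in range(config.prototypes_per_class):
            if config.init == "class_mean":
                protos.append(members.mean(axis=0))
            else:  # sample
                protos.append(members[rng.integers(0, len(members))].copy())
            labels.append(cls)
    return np.asarray(protos, dtype=np.float64), labels


def train_lvq(vectors: np.ndarray | list[np.ndarray], labels: list[str],
              config: LvqConfig | None = None) -> LvqModel:
    """Fit an LVQ1 model to labeled activation vectors."""
    config = config or LvqConfig()
    x = np.asarray(vectors, dtype=np.float64)
    y = np.asarray(labels)
    if x.ndim != 2 or len(x) != len(y):
        raise StageError("vectors must be (n, dim) with one label per row")
    if not np.all(np.isfinite(x)):
        raise StageError("training vectors must be finite")
    classes = list(dict.fromkeys(labels))  # order of first appearance
    if len(classes) < 2:
        raise StageError("LVQ training requires examples from >= 2 classes")

    ss = np.random.SeedSequence(config.seed).spawn(2)
    protos, proto_labels = _init_prototypes(x, y, classes, config,
                                            np.random.default_rng(ss[0]))
    rng = np.random.default_rng(ss[1])
    proto_y = np.asarray(proto_labels)

    loss_curve: list[float] = []
    for _ in range(config.epochs):
        for i in rng.permutation(len(x)):
            j = _nearest(protos, x[i])
            step = config.learning_rate * (x[i] - protos[j])
            protos[j] += step if proto_y[j] == y[i] else -step
        pred = proto_y[_nearest_all(protos, x)]
        loss_curve.append(float(np.mean(pred != y)))
    return LvqModel(prototypes=protos, labels=proto_labels, config=config,
                    loss_curve=loss_curve)


def _nearest_all(prototypes: np.ndarray, x: np.ndarray) -> np.ndarray:
    # squared distances via explicit difference: same tie behavior as _nearest
    d = ((x[:, None, :] - prototypes[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d, axis=1)


def predict(model: LvqModel, vector: np.ndarray) -> str:
    """Label of the nearest prototype; ties go to insertion order."""
    v = np.asarray(vector, dtype=np.float64)
    if not np.all(np.isfinite(v)):
        raise StageError("query vector must be finite")
    return model.labels[_nearest(model.prototypes, v)]


def predict_many(model: LvqModel, vectors: np.ndarray) -> list[str]:
    x = np.asarray(vectors, dtype=np.float64)
    return [model.labels[j] for j in _nearest_all(model.prototypes, x)]
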