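"""Kohonen self-organizing map on 4-channel normalized voxel vectors.

The SOM is a 9x9 lattice of 81 "neurons", each a 4-component codebook
vector in the calibrated, variance-normalized mpMRI intensity space.  The
lattice size follows the 3^4 = 81 reading of the input space: three
intensity levels (low/medium/high) per channel over four channels.  Each
neuron is one discrete mpMRI "phenotype" to which tumor voxels are
assigned by closest Euclidean proximity (the best matching unit, BMU).

Training is the classical sequential rule with a bubble neighborhood: at
each of ``iterations`` steps one voxel vector is drawn uniformly at
random (with replacement), and the BMU plus every neuron within the
current lattice Chebyshev radius takes a full step of the current
learning rate toward the sample.  Learning rate and radius both follow
inverse-time decay ``r(t) = r0 / (1 + t / (T/2))``.  Defaults: learning
rate 0.2, initial radius 1.0, bubble neighborhood, 1,000,000 iterations.

Everything is double precision and deterministic for a fixed seed;
neuron indexing is row-major with index 0 at lattice position (0, 0),
the convention shared with the activation-map and LVQ modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.spatial.distance import cdist

from .errors import NumericError, StageError
from .preprocess import VoxelFeatureTable


@dataclass
class SomConfig:
    rows: int = 9
    cols: int = 9
    neighborhood: str = "bubble"
    learning_rate: float = 0.2
    radius: float = 1.0  # initial bubble radius, lattice units
    iterations: int = 1_000_000
    decay: str = "asymptotic"  # r(t) = r0 / (1 + t/(T/2))
    seed: int = 0
    n_checkpoints: int = 10  # quantization-error log entries during training

    def __post_init__(self) -> None:
        if self.rows * self.cols < 1:
            raise StageError("lattice must have at least one neuron")
        if not 0 < self.learning_rate <= 1:
            raise StageError("learning rate must be in (0, 1]")
        if self.iterations < 1:
            raise StageError("iterations must be >= 1")
        if self.neighborhood != "bubble":
            raise StageError(f"unsupported neighborhood {self.neighborhood!r}")
        if self.decay != "asymptotic":
            raise StageError(f"unsupported decay schedule {self.decay!r}")

    @property
    def n_neurons(self) -> int:
        return self.rows * self.cols


@dataclass
class SomModel:
    """Trained or initialized SOM: codebook, configuration, training log."""

    codebook: np.ndarray  # (n_neurons, 4), row-major neuron order
    config: SomConfig
    training_log: list[tuple[int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.codebook = np.asarray(self.codebook, dtype=np.float64)
        if self.codebook.shape[0] != self.config.n_neurons:
            raise StageError(
                f"codebook has {self.codebook.shape[0]} vectors for a "
                f"{self.config.rows}x{self.config.cols} lattice"
            )
        if not np.all(np.isfinite(self.codebook)):
            raise NumericError("codebook contains non-finite values")

    def lattice_positions(self) -> np.ndarray:
        """(n_neurons, 2) array of (row, col) per neuron, row-major."""
        r, c = np.divmod(np.arange(self.config.n_neurons), self.config.cols)
        return np.column_stack([r, c])

    def to_dict(self) -> dict:
        return {
            "config": asdict(self.config),
            "codebook": [[float(v) for v in row] for row in self.codebook],
            "training_log": [[int(i), float(q)] for i, q in self.training_log],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SomModel":
        return cls(
            codebook=np.asarray(d["codebook"], dtype=np.float64),
            config=SomConfig(**d["config"]),
            training_log=[(int(i), float(q)) for i, q in d["training_log"]],
        )


def _require_normalized(data: VoxelFeatureTable | np.ndarray) -> np.ndarray:
    if isinstance(data, VoxelFeatureTable):
        if data.stage != "normalized":
            raise StageError(f"SOM requires normalized input, got stage {data.stage!r}")
        x = data.values
    else:
        x = np.asarray(data, dtype=np.float64)
    if x.ndim != 2 or len(x) == 0:
        raise StageError("SOM input must be a non-empty (n, 4) matrix")
    return x


def init_som(config: SomConfig, data: VoxelFeatureTable | np.ndarray) -> SomModel:
    """Initialize the codebook by sampling data rows with replacement.

    Sampling initialization keeps the codebook inside the data's range
    regardless of the normalization scale; the draw is made with a child
    stream of ``config.seed`` so init and training are independently
    reproducible.
    """
    x = _require_normalized(data)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[0])
    idx = rng.integers(0, len(x), size=config.n_neurons)
    return SomModel(codebook=x[idx].copy(), config=config)


def _chebyshev_matrix(config: SomConfig) -> np.ndarray:
    r, c = np.divmod(np.arange(config.n_neurons), config.cols)
    return np.maximum(np.abs(r[:, None] - r[None, :]),
                      np.abs(c[:, None] - c[None, :]))


def train_som(model: SomModel, data: VoxelFeatureTable | np.ndarray) -> SomModel:
    """Run the sequential bubble-SOM updates and return the trained model.

    The input model is not modified.  The training log holds the
    quantization error before training (iteration 0) and after each of
    ``n_checkpoints`` equal slices of the schedule.
    """
    x = _require_normalized(data)
    cfg = model.config
    codebook = model.codebook.copy()
    cheb = _chebyshev_matrix(cfg)
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(2)[1])

    T = cfg.iterations
    half_life = T / 2.0
    sample_idx = rng.integers(0, len(x), size=T)

    log: list[tuple[int, float]] = [(0, _qe(codebook, x))]
    checkpoints = np.unique(
        np.linspace(T / cfg.n_checkpoints, T, cfg.n_checkpoints).astype(np.int64)
    )
    next_cp = 0
    for t in range(T):
        decay = 1.0 + t / half_life
        alpha = cfg.learning_rate / decay
        radius = cfg.radius / decay
        sample = x[sample_idx[t]]
        diff = codebook - sample
        bmu = int(np.argmin(np.einsum("ij,ij->i", diff, diff)))
        if radius < 1.0:  # bubble shrunk to the BMU alone
            codebook[bmu] += alpha * (sample - codebook[bmu])
            ok = np.isfinite(codebook[bmu]).all()
        else:
            hood = cheb[bmu] <= radius
            codebook[hood] += alpha * (sample - codebook[hood])
            ok = np.isfinite(codebook[hood]).all()
        if not ok:
            raise NumericError(f"non-finite codebook update at iteration {t}")
        if next_cp < len(checkpoints) and t + 1 == checkpoints[next_cp]:
            log.append((t + 1, _qe(codebook, x)))
            next_cp += 1
    return SomModel(codebook=codebook, config=cfg, training_log=log)


def find_bmu(model: SomModel, vector: np.ndarray) -> int:
    """Row-major index of the codebook vector nearest (Euclidean) to ``vector``.

    Ties are broken toward the smallest index.
    """
    v = np.asarray(vector, dtype=np.float64)
    if not np.all(np.isfinite(v)):
        raise StageError("query vector must be finite")
    diff = model.codebook - v
    return int(np.argmin(np.einsum("ij,ij->i", diff, diff)))


def bmu_indices(model: SomModel, data: VoxelFeatureTable | np.ndarray) -> np.ndarray:
    """Vectorized BMU lookup for every row of ``data`` (same tie rule)."""
    x = _require_normalized(data)
    d = cdist(x, model.codebook, metric="sqeuclidean")
    return np.argmin(d, axis=1)


def _qe(codebook: np.ndarray, x: np.ndarray) -> float:
    d = cdist(x, codebook, metric="euclidean")
    return float(d.min(axis=1).mean())


def quantization_error(model: SomModel, data: VoxelFeatureTable | np.ndarray) -> float:
    """Mean Euclidean distance from each data row to its BMU."""
    x = _require_normalized(data)
    return _qe(model.codebook, x)
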