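"""Activation maps: per-tumor BMU hit histograms on the SOM lattice.

Assigning every tumor voxel to its best matching unit turns four 3D MRI
volumes into a single 9x9 grid of hit counts — the tumor's 2D mpMRI
"fingerprint".  Hit counts are max-normalized per map (divide by that
map's largest count), so the busiest neuron is exactly 1.0; raw counts
are retained alongside, which keeps pooling and differential-neuron
ranking exact.

Differential neurons between two pooled maps are ranked by the
difference of per-class hit *fractions* (hits / total voxels of that
class), not a ratio — a ratio would blow up on neurons one class never
visits.  The sign pattern of the resulting neuron phenotypes is the
interpretable readout: neurons favored by sarcomatoid tumors sit at
hypointense T1-family phenotypes, non-sarcomatoid ones at
contrast-enhancing phenotypes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import StageError
from .preprocess import VoxelFeatureTable
from .som import SomModel, bmu_indices


@dataclass
class ActivationMap:
    """Hit counts of one tumor (or voxel pool) over the SOM lattice."""

    label: str
    raw_hits: np.ndarray  # (n_neurons,) non-negative ints, row-major
    normalized: np.ndarray  # raw_hits / max(raw_hits), in [0, 1]
    total_voxels: int
    rows: int = 9
    cols: int = 9

    @classmethod
    def from_hits(cls, label: str, raw_hits: np.ndarray,
                  rows: int = 9, cols: int = 9) -> "ActivationMap":
        raw_hits = np.asarray(raw_hits, dtype=np.int64)
        if raw_hits.shape != (rows * cols,):
            raise StageError(
                f"expected {rows * cols} hit counts, got shape {raw_hits.shape}"
            )
        if np.any(raw_hits < 0):
            raise StageError("hit counts must be non-negative")
        total = int(raw_hits.sum())
        if total < 1:
            raise StageError("an all-zero activation map is undefined under "
                             "max-normalization")
        normalized = raw_hits / raw_hits.max()
        return cls(label=label, raw_hits=raw_hits, normalized=normalized,
                   total_voxels=total, rows=rows, cols=cols)

    @property
    def grid(self) -> np.ndarray:
        """The normalized map reshaped to the (rows, cols) lattice."""
        return self.normalized.reshape(self.rows, self.cols)

    @property
    def fractions(self) -> np.ndarray:
        """Per-neuron hit fraction raw_hits / total_voxels (sums to 1)."""
        return self.raw_hits / self.total_voxels


def compute_activation_map(model: SomModel,
                           table: VoxelFeatureTable) -> ActivationMap:
    """Count each tumor voxel's BMU into a lattice histogram."""
    if table.n_voxels == 0:
        raise StageError(f"subject {table.subject_id}: empty voxel table")
    bmus = bmu_indices(model, table)
    hits = np.bincount(bmus, minlength=model.config.n_neurons)
    return ActivationMap.from_hits(table.subject_id, hits,
                                   rows=model.config.rows,
                                   cols=model.config.cols)


def pooled_activation_map(model: SomModel, tables: list[VoxelFeatureTable],
                          label: str = "pooled") -> ActivationMap:
    """Activation map of the voxels of several tumors pooled together.

    Pooling is at raw-voxel level, so raw hit counts are exactly the
    element-wise sum of the constituent maps' counts.
    """
    if not tables:
        raise StageError("pooled_activation_map requires at least one table")
    hits = np.zeros(model.config.n_neurons, dtype=np.int64)
    for t in tables:
        if t.n_voxels == 0:
            raise StageError(f"subject {t.subject_id}: empty voxel table")
        hits += np.bincount(bmu_indices(model, t),
                            minlength=model.config.n_neurons)
    return ActivationMap.from_hits(label, hits, rows=model.config.rows,
                                   cols=model.config.cols)


def rank_differential_neurons(map_a: ActivationMap, map_b: ActivationMap,
                              k: int) -> list[int]:
    """Neurons most activated by class A relative to class B.

    Sorted by descending difference of hit fractions
    ``hits_a/total_a - hits_b/total_b``; ties go to the smaller neuron
    index.  Returns the first ``k`` indices.
    """
    n = len(map_a.raw_hits)
    if len(map_b.raw_hits) != n:
        raise StageError("maps come from different lattices")
    if not 0 <= k <= n:
        raise StageError(f"k must be in [0, {n}], got {k}")
    diff = map_a.fractions - map_b.fractions
    order = sorted(range(n), key=lambda i: (-diff[i], i))
    return order[:k]


def neuron_phenotype_maps(model: SomModel) -> np.ndarray:
    """Per-channel lattice images of the codebook (the neuron phenotypes).

    Returns a (4, rows, cols) array: grid ``c`` holds codebook component
    ``c`` at each neuron's lattice position.  Values are in normalized
    units — 0 is the pooled training+validation mean intensity on that
    scan type, +/-1 is one pooled SD above/below it.
    """
    cfg = model.config
    return model.codebook.T.reshape(4, cfg.rows, cfg.cols).copy()


def render_activation_map(amap: ActivationMap, path) -> None:
    """Optional grayscale PNG of a map (white = 0 hits, black = max hits)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(3, 3))
    ax.imshow(amap.grid, cmap="gray_r", vmin=0.0, vmax=1.0)
    ax.set_xticks([])
    ax.set_yticks([])
    ax.set_title(amap.label, fontsize=9)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
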