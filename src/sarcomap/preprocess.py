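"""Intensity calibration and variance normalization of tumor voxels.

Scanner and protocol differences make raw MRI intensities incomparable
across subjects, so each subject is calibrated against their own
contralateral normal renal cortex: tumor T2W intensities are divided by
the cortex mean on T2W, and all three T1-family intensities (unenhanced,
arterial CE, venous CE) by the cortex mean on unenhanced T1W.  Any
per-subject multiplicative scanner gain that is shared within a sequence
family therefore cancels exactly.

Calibrated voxels from the training + validation cohorts are then pooled
*at voxel level* (large tumors contribute more voxels) to fit per-channel
means and standard deviations; every table — including the held-out test
cohort — is variance-normalized with those same frozen statistics.  The
standard deviation uses the population convention (divide by n), so
refitting on a normalized pool returns mean 0 / SD 1 exactly and
normalization is a fixed point.

A leakage guard refuses to fit channel statistics on any table tagged as
test-cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import CalibrationError, DataError, LeakageError, StageError
from .mri_io import StudyVolumes

CHANNELS = ("c_t2", "c_t1", "c_t1art", "c_t1ven")
STAGES = ("calibrated", "normalized")


@dataclass
class CortexReference:
    """Per-subject calibration denominators from the contralateral cortex."""

    t2_cortex_mean: float
    t1_cortex_mean: float
    cortex_voxel_count: int

    def __post_init__(self) -> None:
        if not (self.t2_cortex_mean > 0 and self.t1_cortex_mean > 0):
            raise CalibrationError(
                f"cortex means must be strictly positive, got "
                f"T2W={self.t2_cortex_mean}, T1W={self.t1_cortex_mean}"
            )
        if self.cortex_voxel_count < 1:
            raise CalibrationError("cortex mask is empty")


@dataclass
class VoxelFeatureTable:
    """Per-tumor-voxel 4-channel intensities with provenance tags.

    ``data`` has one row per tumor-mask voxel with columns
    (i, j, k, c_t2, c_t1, c_t1art, c_t1ven); ``stage`` records whether the
    values are cortex-calibrated or additionally variance-normalized, and
    ``cohort`` carries the subject's cohort tag for the leakage guard.
    """

    subject_id: str
    data: pd.DataFrame
    stage: str
    cohort: str = "training"

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise StageError(f"unknown stage {self.stage!r}")
        values = self.values
        if not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))
            i = int(bad[0, 0])
            coord = tuple(int(v) for v in self.data.iloc[i][["i", "j", "k"]])
            raise DataError(
                f"subject {self.subject_id}: non-finite intensity at voxel {coord}"
            )

    @property
    def n_voxels(self) -> int:
        return len(self.data)

    @property
    def values(self) -> np.ndarray:
        """(n_voxels, 4) float64 channel matrix, column order = CHANNELS."""
        return self.data.loc[:, list(CHANNELS)].to_numpy(dtype=np.float64)

    def to_csv(self, path) -> None:
        out = self.data.copy()
        out.insert(0, "subject_id", self.subject_id)
        out["stage"] = self.stage
        out["cohort"] = self.cohort
        out.to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "VoxelFeatureTable":
        df = pd.read_csv(path)
        stage = str(df["stage"].iloc[0])
        cohort = str(df["cohort"].iloc[0])
        subject = str(df["subject_id"].iloc[0])
        cols = ["i", "j", "k", *CHANNELS]
        return cls(subject_id=subject, data=df[cols].reset_index(drop=True),
                   stage=stage, cohort=cohort)


@dataclass
class ChannelStats:
    """Per-channel mean/SD of pooled training+validation calibrated voxels."""

    means: np.ndarray  # (4,)
    sds: np.ndarray  # (4,), population convention, strictly positive
    n_voxels: int

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=np.float64)
        self.sds = np.asarray(self.sds, dtype=np.float64)
        if self.means.shape != (4,) or self.sds.shape != (4,):
            raise ValueError("ChannelStats requires 4 means and 4 SDs")
        if not np.all(self.sds > 0):
            raise DataError(f"channel SDs must be strictly positive, got {self.sds}")

    def to_dict(self) -> dict:
        return {
            "channels": list(CHANNELS),
            "means": [float(m) for m in self.means],
            "sds": [float(s) for s in self.sds],
            "n_voxels": int(self.n_voxels),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ChannelStats":
        return cls(means=np.array(d["means"]), sds=np.array(d["sds"]),
                   n_voxels=int(d["n_voxels"]))


def compute_cortex_reference(study: StudyVolumes) -> CortexReference:
    """Arithmetic means of T2W and unenhanced T1W over the cortex mask."""
    mask = study.cortex_mask
    n = int(mask.sum())
    t2_mean = float(study.volumes["T2W"][mask].mean())
    t1_mean = float(study.volumes["T1W"][mask].mean())
    return CortexReference(t2_cortex_mean=t2_mean, t1_cortex_mean=t1_mean,
                           cortex_voxel_count=n)


def calibrate(study: StudyVolumes, ref: CortexReference,
              cohort: str = "training") -> VoxelFeatureTable:
    """Divide tumor voxel intensities by the subject's cortex means.

    T2W is divided by the cortex T2W mean; all three T1-family channels by
    the cortex mean on *unenhanced* T1W.  One row per tumor-mask voxel, in
    row-major voxel-index order.
    """
    idx = np.argwhere(study.tumor_mask)
    if idx.size == 0:
        raise DataError(f"subject {study.subject_id}: tumor mask is empty")
    mask = study.tumor_mask
    cols = {
        "i": idx[:, 0], "j": idx[:, 1], "k": idx[:, 2],
        "c_t2": study.volumes["T2W"][mask] / ref.t2_cortex_mean,
        "c_t1": study.volumes["T1W"][mask] / ref.t1_cortex_mean,
        "c_t1art": study.volumes["T1W_CEart"][mask] / ref.t1_cortex_mean,
        "c_t1ven": study.volumes["T1W_CEven"][mask] / ref.t1_cortex_mean,
    }
    return VoxelFeatureTable(subject_id=study.subject_id,
                             data=pd.DataFrame(cols), stage="calibrated",
                             cohort=cohort)


def fit_channel_stats(tables: list[VoxelFeatureTable]) -> ChannelStats:
    """Pool calibrated voxels across tables and fit per-channel mean/SD.

    Pooling is at voxel level, so a 50 cm^3 tumor weighs ten times a
    5 cm^3 one.  Tables tagged ``cohort="test"`` are refused outright —
    test subjects must never influence the normalization.
    """
    if not tables:
        raise StageError("fit_channel_stats requires at least one table")
    for t in tables:
        if t.cohort == "test":
            raise LeakageError(
                f"subject {t.subject_id} is test-cohort; channel statistics "
                "must be fitted on training+validation voxels only"
            )
        if t.stage != "calibrated":
            raise StageError(
                f"subject {t.subject_id}: expected stage 'calibrated', got {t.stage!r}"
            )
    pooled = np.concatenate([t.values for t in tables], axis=0)
    if len(pooled) < 2:
        raise DataError("need >= 2 pooled voxels to fit channel statistics")
    means = pooled.mean(axis=0)
    sds = pooled.std(axis=0, ddof=0)  # population SD: fixed-point property
    if np.any(sds == 0):
        ch = CHANNELS[int(np.argmax(sds == 0))]
        raise DataError(f"degenerate data: zero SD on channel {ch}")
    return ChannelStats(means=means, sds=sds, n_voxels=len(pooled))


def normalize(table: VoxelFeatureTable, stats: ChannelStats) -> VoxelFeatureTable:
    """Variance-normalize a calibrated table with frozen channel statistics."""
    if table.stage != "calibrated":
        raise StageError(
            f"normalize expects a calibrated table, got stage {table.stage!r}"
        )
    data = table.data.copy()
    for c, m, s in zip(CHANNELS, stats.means, stats.sds):
        data[c] = (data[c] - m) / s
    return replace(table, data=data, stage="normalized")
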