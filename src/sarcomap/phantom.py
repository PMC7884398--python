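"""Synthetic co-registered 4-channel MRI phantom cohorts.

No patient images ship with this package, so every pipeline stage is
exercised on seeded phantoms that emulate the *structure* of the study
data: four co-registered volumes per subject (T2W, unenhanced T1W,
arterial CE T1W, venous CE T1W) with an ellipsoidal tumor and a disjoint
ellipsoidal contralateral-cortex region, per-subject multiplicative
scanner gains (one for the T2 channel, one shared by the whole T1
family, mirroring the single unenhanced-T1 cortex mean that calibrates
all three), intra-tumor phenotype subpopulations drawn from class
mixtures, and additive Gaussian noise.

Class profiles are specified on the *calibrated* scale (units of the
cortex mean) and encode the discriminating pattern: sarcomatoid tumors
are hypointense on the three T1-family channels, non-sarcomatoid tumors
hyperintense on the contrast-enhanced channels, and the non-sarcomatoid
class carries more subpopulations (its activation maps look "busier").
With zero noise and a single subpopulation the calibration equations
invert exactly: generated raw intensities divided by the generated
cortex means return the configured profile means for any gain draw.

Shapes are ellipsoids rather than anatomical kidneys on purpose — the
pipeline only ever consumes masked voxel sets, so shape realism buys
nothing downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import ConfigError
from .mri_io import SEQUENCES, StudyRecord

T1_FAMILY = ("T1W", "T1W_CEart", "T1W_CEven")


@dataclass
class PhenotypeProfile:
    """One intra-tumor subpopulation: calibrated-scale means/SDs + weight."""

    means: tuple[float, float, float, float]  # (T2W, T1W, T1W_CEart, T1W_CEven)
    sds: tuple[float, float, float, float]
    weight: float

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.sds):
            raise ConfigError("profile SDs must be non-negative")
        if not 0 < self.weight <= 1:
            raise ConfigError("profile weight must be in (0, 1]")


def default_profiles() -> dict[str, list[PhenotypeProfile]]:
    """Class phenotype mixtures used by the default phantom cohort.

    sRCC subpopulations sit below the cross-class average on all three
    T1-family channels (hypointense) and are tighter (sparser maps);
    nsRCC gets one more subpopulation with broader spread and strong
    contrast enhancement.
    """
    return {
        "sRCC": [
            PhenotypeProfile(means=(0.90, 0.45, 0.55, 0.60),
                             sds=(0.02, 0.02, 0.02, 0.02), weight=0.6),
            PhenotypeProfile(means=(1.40, 0.55, 0.70, 0.70),
                             sds=(0.02, 0.02, 0.02, 0.02), weight=0.4),
        ],
        "nsRCC": [
            PhenotypeProfile(means=(1.10, 0.95, 1.90, 1.60),
                             sds=(0.25, 0.25, 0.25, 0.25), weight=0.40),
            PhenotypeProfile(means=(0.80, 1.05, 1.50, 1.30),
                             sds=(0.25, 0.25, 0.25, 0.25), weight=0.35),
            PhenotypeProfile(means=(1.30, 1.15, 1.25, 1.45),
                             sds=(0.25, 0.25, 0.25, 0.25), weight=0.25),
        ],
    }


@dataclass
class PhantomConfig:
    """Geometry, cohort sizes and signal model of a phantom cohort."""

    shape: tuple[int, int, int] = (64, 64, 32)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)  # mm
    #: subjects per class per cohort, keyed by cohort name
    cohort_sizes: dict = field(default_factory=lambda: {
        "training": 8, "validation": 3, "test": 5})
    tumor_volume_range: tuple[float, float] = (2.0, 12.0)  # cm^3
    #: raw-scale cortex intensity level per sequence (before gain)
    cortex_levels: dict = field(default_factory=lambda: {
        "T2W": 400.0, "T1W": 300.0, "T1W_CEart": 600.0, "T1W_CEven": 500.0})
    background_level: float = 60.0  # raw units, times the family gain
    t2_gain_range: tuple[float, float] = (0.5, 2.0)
    t1_gain_range: tuple[float, float] = (0.5, 2.0)
    noise_sd: float = 5.0  # additive Gaussian, raw units
    profiles: dict = field(default_factory=default_profiles)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(g <= 0 for g in (*self.t2_gain_range, *self.t1_gain_range)):
            raise ConfigError("scanner gains must be strictly positive")
        if self.noise_sd < 0:
            raise ConfigError("noise SD must be >= 0")
        for cls, profs in self.profiles.items():
            total = sum(p.weight for p in profs)
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(
                    f"{cls}: subpopulation weights sum to {total}, expected 1")

    @property
    def voxel_volume_cm3(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0


def _ellipsoid_mask(shape, spacing, center_vox, radii_mm) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    acc = np.zeros(shape, dtype=np.float64)
    for g, c, r, sp in zip(grids, center_vox, radii_mm, spacing):
        acc += ((g - c) * sp / r) ** 2
    return acc <= 1.0


def _tumor_radii(volume_cm3: float) -> tuple[float, float, float]:
    # prolate ellipsoid with axes a = b, c = 1.4 a; V = 4/3 pi a^2 c
    a = ((volume_cm3 * 1000.0) * 3.0 / (4.0 * np.pi * 1.4)) ** (1.0 / 3.0)
    return (a, a, 1.4 * a)


def _place_regions(config: PhantomConfig, volume_cm3: float
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Tumor ellipsoid in the left half of the grid, cortex in the right."""
    shape, spacing = config.shape, config.spacing
    tumor_center = (shape[0] * 0.28, shape[1] * 0.5, shape[2] * 0.5)
    cortex_center = (shape[0] * 0.75, shape[1] * 0.5, shape[2] * 0.5)
    tumor = _ellipsoid_mask(shape, spacing, tumor_center, _tumor_radii(volume_cm3))
    cortex = _ellipsoid_mask(shape, spacing, cortex_center, (14.0, 14.0, 18.0))
    if not tumor.any() or not cortex.any():
        raise ConfigError("degenerate phantom geometry: empty region")
    if np.any(tumor & cortex):
        raise ConfigError("phantom tumor and cortex regions overlap; "
                          "reduce tumor_volume_range for this grid")
    return tumor, cortex


def _save_nifti(data: np.ndarray, spacing, path: Path) -> None:
    # float64 storage keeps the calibration round-trip exact to ~1 ulp
    affine = np.diag([*spacing, 1.0])
    dtype = np.uint8 if data.dtype == np.uint8 else np.float64
    img = nib.Nifti1Image(np.asarray(data, dtype=dtype), affine)
    img.header.set_zooms(spacing)
    nib.save(img, str(path))


def generate_subject(config: PhantomConfig, class_label: str,
                     rng: np.random.Generator, volume: float | None = None
                     ) -> tuple[dict[str, np.ndarray], np.ndarray, np.ndarray, float]:
    """Simulate one subject; returns (volumes, tumor_mask, cortex_mask, gain pair)."""
    lo, hi = config.tumor_volume_range
    if volume is None:
        volume = float(rng.uniform(lo, hi))
    tumor, cortex = _place_regions(config, volume)
    n_tumor = int(tumor.sum())

    g_t2 = float(np.exp(rng.uniform(np.log(config.t2_gain_range[0]),
                                    np.log(config.t2_gain_range[1]))))
    g_t1 = float(np.exp(rng.uniform(np.log(config.t1_gain_range[0]),
                                    np.log(config.t1_gain_range[1]))))
    gains = {"T2W": g_t2, "T1W": g_t1, "T1W_CEart": g_t1, "T1W_CEven": g_t1}

    profiles = config.profiles[class_label]
    weights = np.asarray([p.weight for p in profiles])
    assign = rng.choice(len(profiles), size=n_tumor, p=weights)

    volumes: dict[str, np.ndarray] = {}
    for ci, seq in enumerate(SEQUENCES):
        family_gain = gains[seq]
        # calibrated-scale tumor intensities for this channel
        mu = np.asarray([p.means[ci] for p in profiles])[assign]
        sd = np.asarray([p.sds[ci] for p in profiles])[assign]
        calib = rng.normal(mu, sd)
        # raw scale: calibrated value x (gain x cortex reference level);
        # the reference level is the T2W cortex for T2W and the
        # *unenhanced T1W* cortex for all three T1-family channels
        ref_level = config.cortex_levels["T2W" if seq == "T2W" else "T1W"]
        vol = np.full(config.shape, config.background_level * family_gain)
        vol[tumor] = calib * family_gain * ref_level
        vol[cortex] = config.cortex_levels[seq] * family_gain
        if config.noise_sd > 0:
            vol = vol + rng.normal(0.0, config.noise_sd, size=config.shape)
        volumes[seq] = vol
    return volumes, tumor, cortex, n_tumor * config.voxel_volume_cm3


def generate_cohort(config: PhantomConfig, out_dir: str | Path) -> list[StudyRecord]:
    """Write a full phantom cohort (NIfTI volumes, masks, CSV manifest).

    Subjects are generated per cohort and pair in a fixed order from a
    single seeded stream, so identical configs give byte-identical
    files.  Tumor volumes are matched between classes — each nsRCC/sRCC
    pair shares one volume draw, emulating the volume-matched cohort
    design that controls tumor size as a confounder.  The manifest's
    ``tumor_volume_cm3`` is the mask voxel count times the voxel volume
    (bookkeeping, not the continuous draw), so it always matches the
    mask exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    records = []
    rows = []
    for cohort in ("training", "validation", "test"):
        for i in range(config.cohort_sizes[cohort]):
            pair_volume = float(rng.uniform(*config.tumor_volume_range))
            for class_label in ("nsRCC", "sRCC"):
                sid = f"{cohort[:5]}_{class_label}_{i:02d}"
                volumes, tumor, cortex, mask_volume = generate_subject(
                    config, class_label, rng, volume=pair_volume)
                paths = {}
                for seq in SEQUENCES:
                    p = out_dir / f"{sid}_{seq}.nii.gz"
                    _save_nifti(volumes[seq], config.spacing, p)
                    paths[seq] = p
                tpath = out_dir / f"{sid}_tumor_mask.nii.gz"
                cpath = out_dir / f"{sid}_cortex_mask.nii.gz"
                _save_nifti(tumor.astype(np.uint8), config.spacing, tpath)
                _save_nifti(cortex.astype(np.uint8), config.spacing, cpath)
                records.append(StudyRecord(
                    subject_id=sid, class_label=class_label, cohort=cohort,
                    tumor_volume=mask_volume, sequence_paths=paths,
                    tumor_mask_path=tpath, cortex_mask_path=cpath))
                rows.append({
                    "subject_id": sid, "class": class_label, "cohort": cohort,
                    "tumor_volume_cm3": repr(mask_volume),
                    "t2w_path": paths["T2W"].name,
                    "t1w_path": paths["T1W"].name,
                    "t1w_ceart_path": paths["T1W_CEart"].name,
                    "t1w_ceven_path": paths["T1W_CEven"].name,
                    "tumor_mask_path": tpath.name,
                    "cortex_mask_path": cpath.name,
                    "augmented": 0,
                })

    import csv

    with open(out_dir / "manifest.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        writer.writeheader()
        writer.writerows(rows)
    return records


def config_to_dict(config: PhantomConfig) -> dict:
    d = asdict(config)
    d["profiles"] = {
        cls: [asdict(p) for p in profs] for cls, profs in config.profiles.items()
    }
    return d
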