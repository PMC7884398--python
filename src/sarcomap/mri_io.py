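"""Reading and validation of study volumes, masks and cohort manifests.

A *study* is one subject's four co-registered MRI volumes (T2W, unenhanced
T1W fat-sat, arterial-phase CE T1W, venous-phase CE T1W) plus two binary
masks (tumor, contralateral renal cortex) on the same voxel grid.  Volumes
are accepted only as NIfTI-1 (.nii/.nii.gz); DICOM conversion and
inter-sequence registration are upstream of this package.  Masks must use
foreground value 1 exactly — any other nonzero value is an error, so no
silent threshold is ever applied.

The module also owns the portable artifact formats: activation-map CSVs
and JSON helpers used by the model serializers.  All of them round-trip
bit-exactly (floats are written with ``repr`` precision).
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np

from .errors import CoregistrationError, ManifestError, MaskError

SEQUENCES = ("T2W", "T1W", "T1W_CEart", "T1W_CEven")
CLASS_LABELS = ("sRCC", "nsRCC", "unknown")
COHORTS = ("training", "validation", "test")

#: manifest column -> sequence key for the four volume path columns
_SEQ_COLUMNS = {
    "t2w_path": "T2W",
    "t1w_path": "T1W",
    "t1w_ceart_path": "T1W_CEart",
    "t1w_ceven_path": "T1W_CEven",
}
_REQUIRED_COLUMNS = (
    "subject_id",
    "class",
    "cohort",
    "tumor_volume_cm3",
    *_SEQ_COLUMNS,
    "tumor_mask_path",
    "cortex_mask_path",
)


@dataclass
class StudyRecord:
    """One manifest row: identity, label, cohort and file locations."""

    subject_id: str
    class_label: str
    cohort: str
    tumor_volume: float  # cm^3, as declared in the manifest
    sequence_paths: Mapping[str, Path]
    tumor_mask_path: Path
    cortex_mask_path: Path
    augmented: bool = False  # member of the augmented training pair


@dataclass
class StudyVolumes:
    """Loaded, validated study: four float64 grids plus boolean masks."""

    subject_id: str
    volumes: Mapping[str, np.ndarray]  # keyed by SEQUENCES, identical shapes
    tumor_mask: np.ndarray
    cortex_mask: np.ndarray
    spacing: tuple[float, float, float]  # mm
    #: tumor-mask voxel count x voxel volume, for cross-check vs manifest
    tumor_volume_from_mask: float = field(default=0.0)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.tumor_mask.shape

    @property
    def voxel_volume_cm3(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0


def _validate_record(row: Mapping[str, object], base: Path) -> StudyRecord:
    label = str(row["class"])
    cohort = str(row["cohort"])
    if label not in CLASS_LABELS:
        raise ManifestError(f"unknown class label {label!r} (expected one of {CLASS_LABELS})")
    if cohort not in COHORTS:
        raise ManifestError(f"unknown cohort {cohort!r} (expected one of {COHORTS})")
    if cohort in ("training", "validation") and label == "unknown":
        raise ManifestError(
            f"subject {row['subject_id']!r}: class label must be known for "
            f"{cohort} cohort subjects"
        )
    try:
        volume = float(row["tumor_volume_cm3"])  # type: ignore[arg-type]
    except (TypeError, ValueError) as exc:
        raise ManifestError(f"tumor_volume_cm3 not numeric: {row['tumor_volume_cm3']!r}") from exc
    if not volume > 0:
        raise ManifestError(f"subject {row['subject_id']!r}: tumor_volume_cm3 must be > 0, got {volume}")
    aug_raw = str(row.get("augmented", "0")).strip().lower()
    if aug_raw not in ("0", "1", "true", "false", ""):
        raise ManifestError(f"augmented flag must be boolean-like, got {aug_raw!r}")
    return StudyRecord(
        subject_id=str(row["subject_id"]),
        class_label=label,
        cohort=cohort,
        tumor_volume=volume,
        sequence_paths={seq: base / str(row[col]) for col, seq in _SEQ_COLUMNS.items()},
        tumor_mask_path=base / str(row["tumor_mask_path"]),
        cortex_mask_path=base / str(row["cortex_mask_path"]),
        augmented=aug_raw in ("1", "true"),
    )


def read_manifest(path: str | Path) -> list[StudyRecord]:
    """Read a cohort manifest (CSV or JSON) into validated records.

    Relative file paths in the manifest are resolved against the manifest's
    own directory.  Raises :class:`ManifestError` naming the first missing
    column or the offending value.
    """
    path = Path(path)
    base = path.parent
    if path.suffix.lower() == ".json":
        rows = json.loads(path.read_text())
        if not isinstance(rows, list) or not rows:
            raise ManifestError(f"{path}: JSON manifest must be a non-empty list of objects")
    else:
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                raise ManifestError(f"{path}: empty manifest")
            rows = list(reader)
        if not rows:
            raise ManifestError(f"{path}: manifest has a header but no rows")
    for col in _REQUIRED_COLUMNS:
        for row in rows:
            if col not in row or row[col] in (None, ""):
                raise ManifestError(f"{path}: missing required column {col!r}")
    records = [_validate_record(row, base) for row in rows]
    ids = [r.subject_id for r in records]
    if len(set(ids)) != len(ids):
        raise ManifestError(f"{path}: duplicate subject ids")
    return records


def _load_nifti(path: Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise CoregistrationError(f"{path}: expected a 3D volume, got shape {data.shape}")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, zooms


def load_study(record: StudyRecord) -> StudyVolumes:
    """Load and validate one subject's volumes and masks.

    Enforces the co-registration contract (identical grids and spacing for
    all six images), strict mask binarity (values 0/1 only), non-empty and
    mutually disjoint masks.  Intensities are promoted to float64.
    """
    volumes: dict[str, np.ndarray] = {}
    spacing: tuple[float, float, float] | None = None
    shape: tuple[int, ...] | None = None
    for seq in SEQUENCES:
        data, zooms = _load_nifti(record.sequence_paths[seq])
        if shape is None:
            shape, spacing = data.shape, zooms
        elif data.shape != shape:
            raise CoregistrationError(
                f"subject {record.subject_id}: {seq} grid {data.shape} != T2W grid {shape}"
            )
        elif not np.allclose(zooms, spacing, atol=1e-3):
            raise CoregistrationError(
                f"subject {record.subject_id}: {seq} spacing {zooms} != T2W spacing {spacing}"
            )
        volumes[seq] = data

    masks = {}
    for name, mpath in (("tumor", record.tumor_mask_path), ("cortex", record.cortex_mask_path)):
        data, zooms = _load_nifti(mpath)
        if data.shape != shape:
            raise CoregistrationError(
                f"subject {record.subject_id}: {name} mask grid {data.shape} != T2W grid {shape}"
            )
        vals = np.unique(data)
        if not np.all(np.isin(vals, (0.0, 1.0))):
            raise MaskError(
                f"subject {record.subject_id}: {name} mask contains values other than 0/1: "
                f"{vals[~np.isin(vals, (0.0, 1.0))][:5]}"
            )
        mask = data == 1.0
        if not mask.any():
            raise MaskError(f"subject {record.subject_id}: {name} mask is empty")
        masks[name] = mask
    if np.any(masks["tumor"] & masks["cortex"]):
        raise MaskError(f"subject {record.subject_id}: tumor and cortex masks overlap")

    assert spacing is not None
    voxel_cm3 = float(np.prod(spacing)) / 1000.0
    return StudyVolumes(
        subject_id=record.subject_id,
        volumes=volumes,
        tumor_mask=masks["tumor"],
        cortex_mask=masks["cortex"],
        spacing=spacing,
        tumor_volume_from_mask=int(masks["tumor"].sum()) * voxel_cm3,
    )


# ---------------------------------------------------------------------------
# Artifact serialization


def write_activation_map(amap, path: str | Path) -> None:
    """Write an activation map as CSV (81 rows: neuron, raw_hits, normalized).

    A leading ``# label=...`` comment carries the map's subject/pool label.
    Floats are written with repr precision so the matching reader
    round-trips bit-exactly.
    """
    from .activation import ActivationMap  # local import, avoids cycle

    if not isinstance(amap, ActivationMap):
        raise TypeError("write_activation_map expects an ActivationMap")
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write(f"# label={amap.label}\n")
        writer = csv.writer(fh)
        writer.writerow(["neuron", "raw_hits", "normalized"])
        for n, (h, v) in enumerate(zip(amap.raw_hits, amap.normalized)):
            writer.writerow([n, int(h), repr(float(v))])


def read_activation_map(path: str | Path):
    """Read an activation map written by :func:`write_activation_map`."""
    from .activation import ActivationMap

    path = Path(path)
    with open(path, newline="") as fh:
        first = fh.readline()
        if not first.startswith("# label="):
            raise ManifestError(f"{path}: not an activation-map CSV (missing label line)")
        label = first[len("# label="):].rstrip("\n")
        reader = csv.DictReader(fh)
        hits = []
        for row in reader:
            hits.append(int(row["raw_hits"]))
    return ActivationMap.from_hits(label, np.asarray(hits, dtype=np.int64))


def save_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True))


def load_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def volumes_consistent(record: StudyRecord, study: StudyVolumes) -> bool:
    """True when the mask-derived tumor volume matches the manifest within one voxel."""
    return math.isclose(
        record.tumor_volume,
        study.tumor_volume_from_mask,
        abs_tol=study.voxel_volume_cm3 + 1e-12,
    )
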