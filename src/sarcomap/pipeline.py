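"""End-to-end orchestration: manifest -> calibration -> SOM -> maps -> LVQ -> metrics.

The run follows the training/validation/testing discipline strictly:

1. calibrate every subject against their own contralateral cortex;
2. fit channel statistics on pooled training+validation voxels only and
   variance-normalize every table (test tables use the frozen stats);
3. train the SOM on the pooled training-cohort voxels;
4. compute an activation map per subject;
5. optionally run leave-k-out cross-validation over the combined
   training+validation cohort and report the selected splits;
6. train the final LVQ on the training cohort ("simple validation"),
   and score training, validation and test cohorts.

Test subjects never reach any fitting step — the channel-stats leakage
guard enforces it structurally, and an optional ``expected_cohorts``
mapping in the run config aborts the run if the manifest's cohort
assignment was tampered with.  Every artifact is written in a portable
format under the run directory along with a provenance log (config,
seeds, package version), and reruns with an identical config reproduce
the artifacts bit-exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .activation import compute_activation_map
from .errors import ConfigError, LeakageError, SarcomapError, StageError
from .evaluation import (ConfusionMatrix, SplitPlan, confusion_from_predictions,
                         confusion_metrics, cross_validate,
                         enumerate_leave_k_out, select_model)
from .lvq import LvqConfig, LvqModel, flatten_map, predict, train_lvq
from .mri_io import (StudyRecord, load_json, load_study, read_manifest,
                     save_json, write_activation_map)
from .preprocess import (ChannelStats, calibrate, compute_cortex_reference,
                         fit_channel_stats, normalize)
from .som import SomConfig, SomModel, init_som, train_som


@dataclass
class RunConfig:
    manifest: str
    out_dir: str
    som: SomConfig = field(default_factory=SomConfig)
    lvq: LvqConfig = field(default_factory=LvqConfig)
    use_augmented: bool = True  # augmented pair joins training pools
    stats_include_augmented: bool = True  # ... and the channel-stats pool
    cv_k: int = 6
    cv_threshold: float = 83.0
    cv_balanced_only: bool = False
    cv_max_splits: int = 0  # 0 disables CV; -1 = exhaustive; >0 = subsample
    cv_seed: int = 0
    #: optional subject_id -> cohort mapping; mismatch with the manifest aborts
    expected_cohorts: dict | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if isinstance(d.get("som"), dict):
            d["som"] = SomConfig(**d["som"])
        if isinstance(d.get("lvq"), dict):
            d["lvq"] = LvqConfig(**d["lvq"])
        return cls(**d)


@dataclass
class PipelineResult:
    run_dir: Path
    channel_stats: ChannelStats
    som_model: SomModel
    lvq_model: LvqModel
    metrics: pd.DataFrame  # one row per cohort
    cv_table: pd.DataFrame | None
    selected_splits: list[SplitPlan] | None
    predictions: dict  # subject_id -> predicted label


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _check_cohorts(records: list[StudyRecord], config: RunConfig) -> None:
    if config.expected_cohorts is None:
        return
    actual = {r.subject_id: r.cohort for r in records}
    for sid, cohort in config.expected_cohorts.items():
        if actual.get(sid) != cohort:
            raise LeakageError(
                f"cohort assignment mismatch for subject {sid!r}: run config "
                f"expects {cohort!r}, manifest says {actual.get(sid)!r} — "
                "refusing to run (possible test-cohort leakage)"
            )


def _training_pool(records: list[StudyRecord], use_augmented: bool) -> list[StudyRecord]:
    return [r for r in records
            if r.cohort == "training" and (use_augmented or not r.augmented)]


def run_full_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the whole workflow and write all artifacts under ``out_dir``."""
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)

    records = read_manifest(config.manifest)
    _check_cohorts(records, config)
    by_id = {r.subject_id: r for r in records}
    labels = {r.subject_id: r.class_label for r in records}

    # --- calibration ------------------------------------------------------
    calibrated = {}
    for r in records:
        try:
            study = load_study(r)
            ref = compute_cortex_reference(study)
            calibrated[r.subject_id] = calibrate(study, ref, cohort=r.cohort)
        except SarcomapError as exc:
            raise type(exc)(f"[calibrate/{r.subject_id}] {exc}") from exc

    # --- channel statistics on training+validation voxels only -----------
    stats_pool = [
        calibrated[r.subject_id] for r in records
        if r.cohort in ("training", "validation")
        and (config.stats_include_augmented or not r.augmented)
    ]
    stats = fit_channel_stats(stats_pool)
    normalized = {sid: normalize(t, stats) for sid, t in calibrated.items()}
    save_json(stats.to_dict(), run_dir / "channel_stats.json")

    # --- SOM on the training cohort voxel pool ----------------------------
    som_pool = _training_pool(records, config.use_augmented)
    som_x = np.concatenate([normalized[r.subject_id].values for r in som_pool])
    som_model = train_som(init_som(config.som, som_x), som_x)
    save_json(som_model.to_dict(), run_dir / "som_model.json")

    # --- activation maps for every subject --------------------------------
    maps_dir = run_dir / "maps"
    maps_dir.mkdir(exist_ok=True)
    maps = {}
    for r in records:
        amap = compute_activation_map(som_model, normalized[r.subject_id])
        maps[r.subject_id] = amap
        write_activation_map(amap, maps_dir / f"{r.subject_id}.csv")

    # --- optional leave-k-out cross-validation ----------------------------
    cv_table = None
    selected = None
    if config.cv_max_splits != 0:
        cv_ids = [r.subject_id for r in records
                  if r.cohort in ("training", "validation") and not r.augmented]
        max_splits = None if config.cv_max_splits < 0 else config.cv_max_splits
        stream = enumerate_leave_k_out(cv_ids, config.cv_k, labels,
                                       max_splits=max_splits,
                                       seed=config.cv_seed)
        cv_table = cross_validate(maps, labels, config.lvq, stream)
        cv_table.to_csv(run_dir / "cv_results.csv", index=False)
        selected = select_model(cv_table, config.cv_threshold,
                                require_balanced=config.cv_balanced_only)
        save_json({"selected": [
            {"training_ids": list(p.training_ids),
             "validation_ids": list(p.validation_ids),
             "balanced": p.balanced} for p in selected
        ]}, run_dir / "selected_splits.json")

    # --- final LVQ on the training cohort (simple validation) -------------
    lvq_pool = _training_pool(records, config.use_augmented)
    x_train = np.asarray([flatten_map(maps[r.subject_id]) for r in lvq_pool])
    y_train = [r.class_label for r in lvq_pool]
    lvq_model = train_lvq(x_train, y_train, config.lvq)
    save_json(lvq_model.to_dict(), run_dir / "lvq_model.json")

    # --- per-cohort metrics ----------------------------------------------
    predictions = {sid: predict(lvq_model, flatten_map(m))
                   for sid, m in maps.items()}
    metric_rows = []
    for cohort in ("training", "validation", "test"):
        members = [r for r in records if r.cohort == cohort]
        if not members:
            continue
        cm = confusion_from_predictions(
            [r.class_label for r in members],
            [predictions[r.subject_id] for r in members])
        row = confusion_metrics(cm)
        metric_rows.append({
            "cohort": cohort, "n": cm.total,
            "accuracy_pct": round(row.accuracy, 2),
            "fpr_pct": round(row.fpr, 2),
            "fnr_pct": round(row.fnr, 2),
            "ppv_pct": None if row.ppv is None else round(row.ppv, 2),
            "npv_pct": None if row.npv is None else round(row.npv, 2),
        })
    metrics = pd.DataFrame(metric_rows)
    metrics.to_csv(run_dir / "metrics.csv", index=False)

    # --- provenance -------------------------------------------------------
    save_json({
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "seeds": {"som": config.som.seed, "lvq": config.lvq.seed,
                  "cv": config.cv_seed},
        "cohorts": {r.subject_id: r.cohort for r in records},
        "channel_stats_pool": [t.subject_id for t in stats_pool],
        "som_training_pool": [r.subject_id for r in som_pool],
        "lvq_training_pool": [r.subject_id for r in lvq_pool],
        "final_model": "lvq_model.json",
    }, run_dir / "provenance.json")

    return PipelineResult(run_dir=run_dir, channel_stats=stats,
                          som_model=som_model, lvq_model=lvq_model,
                          metrics=metrics, cv_table=cv_table,
                          selected_splits=selected, predictions=predictions)


def lock_final_model(run_dir: str | Path) -> None:
    """Mark the run's LVQ model as final; the test stage refuses any other.

    Once a model has been tested, revising it and retesting on the same
    cohort is not permitted; this lock makes the discipline mechanical.
    """
    run_dir = Path(run_dir)
    prov_path = run_dir / "provenance.json"
    prov = load_json(prov_path) if prov_path.exists() else {}
    model_blob = (run_dir / "lvq_model.json").read_bytes()
    prov["final_model_sha256"] = hashlib.sha256(model_blob).hexdigest()
    save_json(prov, run_dir / "provenance.json")


def check_final_model(run_dir: str | Path) -> None:
    """Raise if the run's LVQ model differs from the locked final model."""
    run_dir = Path(run_dir)
    prov_path = run_dir / "provenance.json"
    if not prov_path.exists():
        return
    prov = load_json(prov_path)
    locked = prov.get("final_model_sha256")
    if locked is None:
        return
    current = hashlib.sha256((run_dir / "lvq_model.json").read_bytes()).hexdigest()
    if current != locked:
        raise ConfigError(
            "the LVQ model in this run directory differs from the locked "
            "final model; testing a revised model on the same cohort is not "
            "permitted"
        )
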