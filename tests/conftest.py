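"""Shared fixtures: a small seeded phantom cohort run through preprocessing.

Everything is generated at test time; nothing is read from checked-in data.
"""

import numpy as np
import pytest

import sarcomap as sm


@pytest.fixture(scope="session")
def phantom_dir(tmp_path_factory):
    """Small phantom cohort on disk: 3+3 training, 1+1 validation, 2+2 test."""
    out = tmp_path_factory.mktemp("phantom")
    config = sm.PhantomConfig(
        seed=11, cohort_sizes={"training": 3, "validation": 1, "test": 2})
    sm.generate_cohort(config, out)
    return out


@pytest.fixture(scope="session")
def records(phantom_dir):
    return sm.read_manifest(phantom_dir / "manifest.csv")


@pytest.fixture(scope="session")
def calibrated_tables(records):
    tables = {}
    for r in records:
        study = sm.load_study(r)
        ref = sm.compute_cortex_reference(study)
        tables[r.subject_id] = sm.calibrate(study, ref, cohort=r.cohort)
    return tables


@pytest.fixture(scope="session")
def channel_stats(records, calibrated_tables):
    pool = [calibrated_tables[r.subject_id] for r in records
            if r.cohort in ("training", "validation")]
    return sm.fit_channel_stats(pool)


@pytest.fixture(scope="session")
def normalized_tables(calibrated_tables, channel_stats):
    return {sid: sm.normalize(t, channel_stats)
            for sid, t in calibrated_tables.items()}


@pytest.fixture(scope="session")
def trained_som(records, normalized_tables):
    """SOM trained on the phantom training-cohort voxel pool."""
    x = np.concatenate([normalized_tables[r.subject_id].values
                        for r in records if r.cohort == "training"])
    config = sm.SomConfig(iterations=50_000, seed=11)
    return sm.train_som(sm.init_som(config, x), x)


@pytest.fixture(scope="session")
def labels(records):
    return {r.subject_id: r.class_label for r in records}
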