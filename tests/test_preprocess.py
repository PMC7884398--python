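"""Cortex calibration and variance normalization."""

import numpy as np
import pandas as pd
import pytest

import sarcomap as sm
from sarcomap.errors import CalibrationError, DataError, LeakageError, StageError
from sarcomap.preprocess import CHANNELS


def _study(t2, t1, t1art, t1ven, tumor, cortex, spacing=(2.0, 2.0, 2.0)):
    return sm.StudyVolumes(
        subject_id="synthetic", spacing=spacing,
        volumes={"T2W": t2, "T1W": t1, "T1W_CEart": t1art, "T1W_CEven": t1ven},
        tumor_mask=tumor, cortex_mask=cortex)


@pytest.fixture()
def toy_study():
    """4^3 grid, 2-voxel tumor, 2-voxel cortex, hand-set intensities."""
    shape = (4, 4, 4)
    rng = np.random.default_rng(3)
    vols = [rng.uniform(50, 500, shape) for _ in range(4)]
    tumor = np.zeros(shape, dtype=bool)
    cortex = np.zeros(shape, dtype=bool)
    tumor[0, 0, 0] = tumor[0, 0, 1] = True
    cortex[3, 3, 3] = cortex[3, 3, 2] = True
    return _study(*vols, tumor, cortex)


class TestCortexReference:
    def test_constant_field_mean(self, toy_study):
        toy_study.volumes["T2W"][toy_study.cortex_mask] = 200.0
        ref = sm.compute_cortex_reference(toy_study)
        assert ref.t2_cortex_mean == 200.0

    def test_two_point_mean(self, toy_study):
        toy_study.volumes["T1W"][toy_study.cortex_mask] = [100.0, 300.0]
        ref = sm.compute_cortex_reference(toy_study)
        assert ref.t1_cortex_mean == 200.0

    def test_phantom_cortex_mean_within_sampling_bound(self):
        """Phantom cortex mean lands within 4 sigma/sqrt(n) of its level x gain."""
        config = sm.PhantomConfig(
            seed=21, cohort_sizes={"training": 1, "validation": 1, "test": 1})
        from sarcomap.phantom import generate_subject
        rng = np.random.default_rng(21)
        vols, tumor, cortex, _ = generate_subject(config, "nsRCC", rng)
        # replay the seeded stream to recover the true gain draws
        replay = np.random.default_rng(21)
        replay.uniform(*config.tumor_volume_range)  # tumor volume draw
        g_t2 = np.exp(replay.uniform(*np.log(config.t2_gain_range)))
        g_t1 = np.exp(replay.uniform(*np.log(config.t1_gain_range)))
        study = _study(vols["T2W"], vols["T1W"], vols["T1W_CEart"],
                       vols["T1W_CEven"], tumor, cortex)
        ref = sm.compute_cortex_reference(study)
        n = int(cortex.sum())
        bound = 4 * config.noise_sd / np.sqrt(n)
        assert abs(ref.t2_cortex_mean - g_t2 * config.cortex_levels["T2W"]) <= bound
        assert abs(ref.t1_cortex_mean - g_t1 * config.cortex_levels["T1W"]) <= bound

    def test_nonpositive_mean_rejected(self, toy_study):
        toy_study.volumes["T2W"][toy_study.cortex_mask] = 0.0
        with pytest.raises(CalibrationError):
            sm.compute_cortex_reference(toy_study)


class TestCalibrate:
    def test_self_ratio_and_forced_arithmetic(self, toy_study):
        ref = sm.CortexReference(t2_cortex_mean=150.0, t1_cortex_mean=200.0,
                                 cortex_voxel_count=2)
        toy_study.volumes["T2W"][0, 0, 0] = 150.0
        toy_study.volumes["T1W_CEart"][0, 0, 0] = 300.0
        table = sm.calibrate(toy_study, ref)
        assert table.data["c_t2"].iloc[0] == 1.0
        assert table.data["c_t1art"].iloc[0] == 1.5

    def test_gain_invariance(self, toy_study):
        """Per-family multiplicative gains cancel through the cortex means."""
        ref = sm.compute_cortex_reference(toy_study)
        base = sm.calibrate(toy_study, ref).values
        g, h = 3.7, 0.4
        scaled = _study(toy_study.volumes["T2W"] * g,
                        toy_study.volumes["T1W"] * h,
                        toy_study.volumes["T1W_CEart"] * h,
                        toy_study.volumes["T1W_CEven"] * h,
                        toy_study.tumor_mask, toy_study.cortex_mask)
        other = sm.calibrate(scaled, sm.compute_cortex_reference(scaled)).values
        assert np.allclose(other, base, rtol=1e-12, atol=0)

    def test_non_finite_voxel_reported_with_coordinates(self, toy_study):
        toy_study.volumes["T1W"][0, 0, 1] = np.nan
        ref = sm.CortexReference(100.0, 100.0, 2)
        with pytest.raises(DataError, match=r"\(0, 0, 1\)"):
            sm.calibrate(toy_study, ref)

    def test_row_count_conservation(self, toy_study):
        ref = sm.compute_cortex_reference(toy_study)
        table = sm.calibrate(toy_study, ref)
        assert table.n_voxels == int(toy_study.tumor_mask.sum())


def _table(values, stage="calibrated", cohort="training", sid="t"):
    values = np.asarray(values, dtype=float)
    df = pd.DataFrame({
        "i": np.arange(len(values)), "j": 0, "k": 0,
        **{c: values[:, ci] for ci, c in enumerate(CHANNELS)},
    })
    return sm.VoxelFeatureTable(subject_id=sid, data=df, stage=stage,
                                cohort=cohort)


class TestChannelStats:
    def test_two_point_population_stats(self):
        stats = sm.fit_channel_stats([_table([[0] * 4, [2] * 4])])
        assert np.array_equal(stats.means, [1, 1, 1, 1])
        assert np.array_equal(stats.sds, [1, 1, 1, 1])  # population SD

    def test_duplication_idempotence(self):
        t = _table([[0] * 4, [1] * 4, [3] * 4])
        single = sm.fit_channel_stats([t])
        double = sm.fit_channel_stats([t, t])
        assert np.array_equal(single.means, double.means)
        assert np.array_equal(single.sds, double.sds)

    def test_leakage_guard(self):
        t = _table([[0] * 4, [2] * 4], cohort="test")
        with pytest.raises(LeakageError):
            sm.fit_channel_stats([t])

    def test_zero_sd_rejected(self):
        with pytest.raises(DataError, match="zero SD"):
            sm.fit_channel_stats([_table([[1] * 4, [1] * 4])])


class TestNormalize:
    def test_centering_and_unit_step(self):
        stats = sm.ChannelStats(means=np.full(4, 5.0), sds=np.full(4, 2.0),
                                n_voxels=10)
        out = sm.normalize(_table([[5] * 4, [7] * 4]), stats)
        assert np.array_equal(out.values[0], [0, 0, 0, 0])
        assert np.array_equal(out.values[1], [1, 1, 1, 1])
        assert out.stage == "normalized"

    def test_stage_mismatch_rejected(self):
        stats = sm.ChannelStats(np.zeros(4), np.ones(4), 2)
        normalized = sm.normalize(_table([[0] * 4, [1] * 4]), stats)
        with pytest.raises(StageError):
            sm.normalize(normalized, stats)

    def test_fixed_point(self, records, normalized_tables):
        """Refitting stats on normalized train+val voxels changes nothing."""
        pool = [normalized_tables[r.subject_id] for r in records
                if r.cohort in ("training", "validation")]
        relabeled = [_table(t.values, stage="calibrated", sid=t.subject_id)
                     for t in pool]
        refit = sm.fit_channel_stats(relabeled)
        assert np.allclose(refit.means, 0.0, atol=1e-10)
        assert np.allclose(refit.sds, 1.0, atol=1e-10)
        again = sm.normalize(relabeled[0], refit)
        assert np.allclose(again.values, pool[0].values, atol=1e-9)

    def test_closure_on_pooled_phantom(self, records, normalized_tables):
        """Pooled normalized train+val voxels have mean 0 and SD 1."""
        x = np.concatenate([normalized_tables[r.subject_id].values
                            for r in records
                            if r.cohort in ("training", "validation")])
        assert np.allclose(x.mean(axis=0), 0.0, atol=1e-10)
        assert np.allclose(x.std(axis=0, ddof=0), 1.0, atol=1e-10)
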