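"""Cortex calibration and variance normalization of tumor voxels.

Shows the two preprocessing identities: per-subject scanner gains cancel
through the cortex means, and pooled training+validation voxels come out
with per-channel mean 0 / SD 1 after normalization.
"""

import tempfile
from pathlib import Path

import numpy as np

import sarcomap as sm

out = Path(tempfile.mkdtemp())
config = sm.PhantomConfig(seed=2, cohort_sizes={"training": 2,
                                                "validation": 1, "test": 1})
records = sm.generate_cohort(config, out)

calibrated = {}
for r in records:
    study = sm.load_study(r)
    ref = sm.compute_cortex_reference(study)
    calibrated[r.subject_id] = sm.calibrate(study, ref, cohort=r.cohort)
    if r.subject_id == records[0].subject_id:
        print(f"{r.subject_id}: cortex T2W mean {ref.t2_cortex_mean:.1f}, "
              f"T1W mean {ref.t1_cortex_mean:.1f} (raw units, include the "
              "subject's scanner gain)")

# channel statistics come from training+validation voxels only
pool = [t for t in calibrated.values() if t.cohort != "test"]
stats = sm.fit_channel_stats(pool)
print("\npooled calibrated channel means:", np.round(stats.means, 3))
print("pooled calibrated channel SDs:  ", np.round(stats.sds, 3))

normalized = {sid: sm.normalize(t, stats) for sid, t in calibrated.items()}
x = np.concatenate([normalized[t.subject_id].values for t in pool])
print("\nafter normalization the pooled train+val voxels have")
print("  mean:", np.round(x.mean(axis=0), 12))
print("  SD:  ", np.round(x.std(axis=0), 12))
# 0 now means "average tumor voxel intensity on that scan type";
# +/-1 means one pooled SD above/below it.  Test-cohort tables reuse
# these frozen statistics, so nothing about the test subjects leaks in.
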