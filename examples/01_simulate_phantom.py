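"""Generate a synthetic phantom cohort and inspect its manifest.

Each subject gets four co-registered NIfTI volumes (T2W, T1W,
arterial/venous CE T1W), a tumor mask and a contralateral-cortex mask,
plus a manifest row.  Tumor volumes are matched between the sRCC and
nsRCC classes, and each subject carries its own random scanner gains.
"""

import tempfile
from pathlib import Path

import sarcomap as sm

out = Path(tempfile.mkdtemp()) / "phantom"
config = sm.PhantomConfig(seed=1, cohort_sizes={"training": 2,
                                                "validation": 1, "test": 1})
records = sm.generate_cohort(config, out)

print(f"wrote {len(records)} subjects to {out}\n")
for r in records:
    print(f"  {r.subject_id:20s} {r.class_label:6s} {r.cohort:10s} "
          f"{r.tumor_volume:6.2f} cm^3")

# The manifest volume is the tumor-mask voxel count times the voxel
# volume, so it agrees with the mask by construction; class pairs within
# a cohort share the same tumor volume (the matched-volume design).
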