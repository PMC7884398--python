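"""Train the 9x9 SOM and fingerprint tumors as activation maps.

Every tumor voxel is assigned to its best matching unit; the per-neuron
hit counts, max-normalized, are the tumor's 2D mpMRI fingerprint.
Pooled class maps and their differential neurons expose the class
phenotypes: sRCC-leaning neurons are hypointense on the T1 family.
"""

import tempfile
from pathlib import Path

import numpy as np

import sarcomap as sm

out = Path(tempfile.mkdtemp())
records = sm.generate_cohort(
    sm.PhantomConfig(seed=3, cohort_sizes={"training": 4, "validation": 0,
                                           "test": 0}), out)

tables = {}
for r in records:
    study = sm.load_study(r)
    tables[r.subject_id] = sm.calibrate(
        study, sm.compute_cortex_reference(study), cohort=r.cohort)
stats = sm.fit_channel_stats(list(tables.values()))
norm = {sid: sm.normalize(t, stats) for sid, t in tables.items()}

x = np.concatenate([t.values for t in norm.values()])
som = sm.train_som(sm.init_som(sm.SomConfig(iterations=100_000, seed=3), x), x)
print(f"SOM trained on {len(x)} voxels; quantization error "
      f"{som.training_log[0][1]:.3f} -> {som.training_log[-1][1]:.3f}")

amap = sm.compute_activation_map(som, norm[records[0].subject_id])
print(f"\n{amap.label}: {amap.total_voxels} voxels, busiest neuron "
      f"{int(np.argmax(amap.raw_hits))} with {amap.raw_hits.max()} hits")

pooled = {
    cls: sm.pooled_activation_map(
        som, [norm[r.subject_id] for r in records if r.class_label == cls],
        label=cls)
    for cls in ("sRCC", "nsRCC")
}
top_s = sm.rank_differential_neurons(pooled["sRCC"], pooled["nsRCC"], 5)
top_n = sm.rank_differential_neurons(pooled["nsRCC"], pooled["sRCC"], 5)
print(f"\nneurons most activated by sRCC relative to nsRCC: {top_s}")
print(f"neurons most activated by nsRCC relative to sRCC: {top_n}")

grids = sm.neuron_phenotype_maps(som)
t1_family = som.codebook[np.ix_(top_s, [1, 2, 3])].mean()
print(f"mean T1-family phenotype of the sRCC-leaning neurons: {t1_family:+.2f} "
      "(negative = hypointense, in pooled-SD units)")
active = {cls: int(np.sum(m.fractions >= 0.01)) for cls, m in pooled.items()}
print(f"neurons holding >=1% of class hits: sRCC {active['sRCC']}, "
      f"nsRCC {active['nsRCC']} (nsRCC maps are busier)")
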