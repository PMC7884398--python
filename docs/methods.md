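# Methods

## Problem and model

The package implements a two-stage prototype-learning pipeline for
classifying renal tumors on four co-registered MRI channels (T2W,
unenhanced T1W fat-sat, arterial- and venous-phase CE T1W): an
unsupervised 9×9 Kohonen self-organizing map (SOM) quantizes the
4-dimensional voxel intensity space into 81 "phenotype" neurons, each
tumor is reduced to an 81-bin best-matching-unit hit histogram (its
activation map), and a supervised LVQ1 classifier separates sarcomatoid
from non-sarcomatoid fingerprints in that 81-dimensional space.  The
approach assumes (i) voxel intensities are comparable across subjects
*after* cortex calibration, (ii) the four channels at a voxel capture
the locally relevant tissue contrast (no spatial texture is used), and
(iii) class identity is expressed in the *composition* of a tumor's
phenotypes, not in its shape or location — masks are consumed as bags
of voxels.

## Preprocessing

Tumor voxels are calibrated by each subject's contralateral normal
renal cortex: T2W by the cortex mean on T2W, and all three T1-family
channels by the cortex mean on unenhanced T1W.  A single shared
multiplicative gain per sequence family therefore cancels exactly; the
package's gain-invariance property tests this at 1e-12 relative error.
Cortex voxels are used untrimmed (no outlier handling), and negative or
zero calibrated values pass through unclamped.

Variance normalization pools calibrated voxels of the
training+validation cohorts at *voxel* level — a 50 cm³ tumor weighs
ten times a 5 cm³ one — and uses the **population SD** (divide by n).
That convention makes normalization a fixed point: refitting statistics
on normalized pooled voxels returns exactly mean 0 / SD 1.  Test-cohort
tables are always normalized with the frozen training+validation
statistics, and the fitting routine refuses any test-tagged table
outright (leakage guard).  Whether the augmented training pair
contributes voxels to the statistics is a configuration flag
(`stats_include_augmented`, default on).

## SOM

* lattice 9×9 (81 = 3⁴: three intensity levels per channel over four
  channels), row-major neuron indexing with index 0 at (0, 0) — the
  same convention used by activation-map CSVs and LVQ vectors;
* bubble neighborhood: the BMU and every neuron within the current
  lattice Chebyshev radius take a full step toward the sample;
* learning rate 0.2 and initial radius 1.0, both decayed by inverse
  time, `r(t) = r0 / (1 + t/(T/2))` — with radius 1.0 the bubble
  shrinks to the BMU alone after the first iteration, so the default
  dynamics are close to online k-means;
* 1,000,000 sequential iterations by default, samples drawn uniformly
  with replacement (the contract is independent of pool size);
* codebook initialized by sampling data rows (scale-robust, and keeps
  the codebook inside the data's bounding box — each later update is a
  convex step toward a data point);
* all arithmetic double precision; deterministic for a fixed seed via
  independent child streams for initialization and training;
* the training log records quantization error (mean distance to BMU)
  before training and at ten equal checkpoints.

The training cohort for the SOM is configurable between the augmented
(18-tumor) and non-augmented (16-tumor) definitions; the source
material is ambiguous between the two and the package defaults to the
augmented cohort while exposing `use_augmented`.

## Activation maps

Hit counts are max-normalized per map (divide by that map's largest
count): each map's busiest neuron is exactly 1.0.  Raw counts are kept
alongside, so pooled maps are exact element-wise sums and no
information is lost to normalization.  Differential neurons between two
pooled class maps are ranked by the difference of per-class hit
fractions (hits / class total voxels) — a difference rather than a
ratio, which would be undefined on unvisited neurons; ties break toward
the smaller index.  Neuron phenotype grids are the codebook components
laid out on the lattice, in normalized units (0 = pooled mean, ±1 = ±1
pooled SD on that scan type).

## LVQ

LVQ1 with a constant learning rate (default 0.001, 1000 epochs, one
prototype per class).  Prototypes initialize at the class means of the
training vectors (deterministic; a seeded "sample" mode exists).  Per
epoch the examples are visited in seeded shuffled order; only the
nearest prototype moves (toward a same-class example, away from a
different-class one).  The loss curve is the training-set
misclassification ratio after each epoch.  Inputs are the
max-normalized activation values, not raw hits.  Prediction is
nearest-prototype with ties broken by insertion order.

## Evaluation conventions

Positive class is sRCC.  FPR and FNR use the **total cohort size** as
denominator, not the class size, so `accuracy + FPR + FNR = 100` is an
identity; this differs from the conventional per-class definitions and
is deliberate — it is the convention under which the package's
reference confusion tables are mutually consistent.  PPV/NPV are
flagged undefined (not thrown) when their denominators vanish.
Leave-k-out splits are enumerated in lexicographic order of sorted
subject ids; `max_splits` draws a seeded uniform subsample for
desk-scale runs, since every split trains an LVQ.  Exhaustive
enumeration of all 134,596 leave-6-out splits is supported behind that
same flag (`max_splits=-1` in the run config).

One statistical caveat discovered while validating the cross-validation
machinery: under label permutation, *unbalanced* leave-k-out splits are
biased below chance (a held-out class excess is mirrored by a
training-side deficit), and even balanced splits within one permuted
cohort give correlated accuracies whose mean wanders several points
from 50%.  The package's permutation-null test therefore averages over
independent permutations and balanced splits only; users running
permutation analyses on real cohorts should do the same.

## Phantom generator

The generator emulates the *structure* of the study data, not MRI
physics: ellipsoidal tumor and cortex regions (the pipeline consumes
only masked voxel sets, so shape realism buys nothing), per-subject
multiplicative scanner gains — one for T2W and one shared by the whole
T1 family, mirroring the single unenhanced-T1 cortex mean that
calibrates all three — class-specific mixtures of intra-tumor phenotype
subpopulations specified on the calibrated scale, and additive Gaussian
noise on the raw scale.

Defaults (chosen once for testability; not claimed to match clinical
data): 64×64×32 grid at 2 mm isotropic spacing; 8+8/3+3/5+5 subjects
per cohort; tumor volumes 2–12 cm³ drawn once per nsRCC/sRCC pair
(volume-matched classes, mirroring the matched-cohort design that
controls tumor size as a confounder); gains log-uniform in [0.5, 2];
noise SD 5 raw units against cortex levels of 300–600.  sRCC has two
tight subpopulations (SD 0.02) hypointense on the T1 family; nsRCC has
three broad ones (SD 0.25) with strong contrast enhancement.  The
spread contrast plus volume matching is what makes pooled sRCC maps
reproducibly sparser than nsRCC maps (the "busier" nsRCC pattern): SOM
hit allocation is close to mass-proportional under data-sampled
initialization, so without matched class masses the active-neuron count
would be dominated by random tumor-volume imbalance rather than by
phenotype structure.

What passing phantom tests do **not** show: robustness to registration
error, partial-volume effects, bias fields, non-multiplicative scanner
differences, intra-class biological variability beyond the configured
mixtures, or any claim about real-data accuracy.  The phantom task is
deliberately well-separated; end-to-end 100% phantom accuracy means the
machinery is correct, not that the clinical problem is easy.

## Numerical choices and degenerate inputs

* BMU and nearest-prototype ties break toward the smallest index /
  first insertion; exact ties are measure-zero on real data but the
  rule is fixed and tested.
* An all-zero activation map is refused (max-normalization undefined);
  empty masks, non-binary masks (any value other than 0/1), grid or
  spacing mismatches, non-finite voxels (reported with coordinates),
  zero/negative cortex means, zero channel SDs and single-class LVQ
  inputs all raise typed errors.
* Floats in artifacts are written with repr precision; manifests,
  activation maps and model JSONs round-trip bit-exactly, and full
  pipeline reruns with identical configs reproduce artifacts
  byte-identically.

## Problem sizes used in tests and the acceptance script

The library default of 1,000,000 SOM iterations reflects the intended
production setting; the test suite and acceptance script train at
100,000 iterations (or less for unit-level checks) on phantom cohorts
of a few thousand voxels, and cross-validation subsamples 10–30 splits.
These are the package's own desk-scale choices; all properties checked
are size-independent contracts (identities, invariances, convergence
directions) rather than asymptotic claims.

## Known limitations

* Inter-sequence co-registration, tumor contouring and cortex
  segmentation are upstream: inputs must already share one grid.
* Only NIfTI-1 volumes are accepted; DICOM conversion is out of scope.
* The LVQ is the plain LVQ1 rule; no LVQ2/3, GLVQ, relevance learning
  or probabilistic outputs.
* No statistical testing of per-neuron class differences and no ROC
  analysis; the evaluation reports the fixed-threshold confusion
  metrics described above.
* With one prototype per class and class-mean initialization the
  classifier is close to a nearest-centroid rule; its advantages are
  interpretability and determinism, not capacity.
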