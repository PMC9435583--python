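# megfc

Segment-level classification of focal-seizure subtypes from resting-state
MEG functional connectivity.

Temporal-lobe epilepsy presents as two focal-seizure subtypes: complex
partial seizures (CPS, with impaired awareness) and simple partial
seizures (SPS, awareness preserved). The two groups are hard to separate
clinically, but their resting-state cortical networks differ. `megfc`
implements, as a tested and reusable pipeline, an MEG connectome
classifier of CPS vs SPS: spike-guarded segment extraction, imaginary-
coherency functional connectivity over a 74-parcel Destrieux grid,
univariate F-score feature ranking, overlap-rate stability selection
across cross-validation folds, and an RBF-kernel SVM. Because clinical
MEG recordings of this kind are not publicly deposited, the package ships
a first-class synthetic cohort generator that plants known lag-coupled
connectivity differences between the groups, so every stage can be
exercised — and the method's recovery behaviour measured — end to end.

It is intended for researchers in MEG/EEG connectomics and clinical
machine learning who want a reproducible reference implementation of this
analysis (or its pieces: the connectivity estimator, the selector, the
stability wrapper compose with scikit-learn pipelines).

## Method

**Segments.** Around every annotated epileptic spike a ±10 s guard window
is excluded; remaining clean stretches of each 120-s block are cut into
non-overlapping 10-s windows, a trailing partial window is kept if it is
at least 4 s, and every kept window is trimmed to 4 s. Signals are
band-passed 1–70 Hz (zero-phase), notched at 50 Hz, anti-alias filtered
at 40 Hz and decimated to 100 Hz; automated amplitude/gradient z-score
thresholds stand in for manual artifact screening.

**Connectivity.** For channels x, y with cross-spectrum S_xy(f)
(Welch, 1-s Hann windows, 50% overlap), coherency is

    C_xy(f) = S_xy(f) / sqrt(S_xx(f) S_yy(f))

and the edge value of one segment is FC_xy = mean over 1–40 Hz of
|Im C_xy(f)|. The imaginary part is blind to instantaneous (zero-lag)
mixing, so volume-conduction-like crosstalk cancels and only lagged
interaction registers. Each 74×74 matrix is flattened to its lower
triangle plus diagonal: C(74,2) + 74 = 2,775 features per segment.

**Selection and classification.** Per feature i, with class means
x̄ᵢ⁽±⁾, pooled mean x̄ᵢ and unbiased within-class variances s²ᵢ⁽±⁾:

    Fᵢ = [ (x̄ᵢ⁽⁻⁾ − x̄ᵢ)² + (x̄ᵢ⁽⁺⁾ − x̄ᵢ)² ] / [ s²ᵢ⁽⁺⁾ + s²ᵢ⁽⁻⁾ ]

Inside each of 14 folds (leave-one-subject-subset-out, or repeated random
90/10 sample splits) the top 1% of features by F-score (k = 28 of 2,775)
feeds an RBF SVM (C = 1.2, γ = 5). Features selected in ≥ 12 of 14 folds
form the *stable set*; stable features whose mean F-score exceeds 75% of
the maximum are flagged as *strong edges*. The final classifier is
retrained on the full training pool restricted to the stable set and
evaluated once on two held-out subject subsets (CPS positive:
accuracy, sensitivity, specificity).

## Worked example

A reduced synthetic cohort (6 subjects per group, 16 parcels, three
planted lag-coupled edges) runs in a couple of seconds:

```python
import json
from megfc import RunConfig, run_pipeline

cfg = RunConfig(
    n_subjects_per_group=6, n_parcels=16,
    segments_per_subject_range=(10, 16),
    edges=((0, 5), (2, 9), (3, 12)),   # planted lag-coupled group differences
    overlap_threshold=3, n_reps=6, seed=7,
)
res = run_pipeline(cfg, out_dir="example")
print(json.dumps(res.metrics["schemes"]["subsets"], indent=2))
print(res.edge_tables["subsets"].to_string(index=False))
```

prints

```
{
  "validation_mean_pct": 100.0,
  "validation_min_pct": 100.0,
  "validation_max_pct": 100.0,
  "test_accuracy_pct": 94.23076923076923,
  "test_sensitivity_pct": 96.15384615384616,
  "test_specificity_pct": 92.3076923076923,
  "subject_majority_accuracy": 1.0,
  "n_stable_features": 1
}
 rank  feature_index      roi_1      roi_2  overlap_count  mean_fscore  strong  coincident
    1             47 parcel_009 parcel_002              4      6.65672    True        True
```

Fold validation accuracies are perfect on this easy cohort; held-out
test segments classify at 94% (96% sensitivity on CPS, 92% specificity
on SPS), and the one feature stable across all 4 folds is exactly the
planted edge (2, 9) — feature index 47 in the lower-triangle traversal —
flagged strong and found by both schemes (`coincident`). At the full
study scale (16+16 subjects, 74 parcels, five planted edges at coupling
strength 0.6 with a 20 ms lag) both schemes recover all five planted
edges and classify held-out subjects' segments essentially perfectly.

The same stages are available from the shell:

```sh
megfc simulate --config cohort.yaml --out cohort.h5 --seed 1
megfc preprocess --in cohort.h5 --out segments.h5
megfc connect --segments segments.h5 --out fc.h5
megfc classify --features fc.h5 --scheme subsets --out report/
megfc run --config cohort.yaml --out report/   # everything at once
```

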