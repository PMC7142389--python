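# vbmlearn

Coarse-to-fine discriminative analysis of voxel-based-morphometry (VBM)
tissue maps: a pipeline for classifying two groups of subjects (e.g.
patients vs. controls) from smoothed gray- or white-matter volumes, and for
locating the brain regions that drive the classification.

Structural-MRI group studies face a severe dimensionality problem: a
preprocessed tissue map has tens of thousands of voxels, while cohorts
rarely exceed a few dozen subjects per group. `vbmlearn` attacks this with a
two-stage feature selection wrapped around a linear support-vector machine:

1. **Coarse screen** — at every voxel the pooled two-sample t statistic

   ```
   T = (x̄₁ − x̄₂) / sqrt( ((N₁−1)S₁² + (N₂−1)S₂²)/(N₁+N₂−2) · (1/N₁ + 1/N₂) )
   ```

   is thresholded at a two-sided p < α (default 0.05), and surviving voxels
   are kept only if they form a 3D connected cluster of at least
   `min_cluster` voxels (default 50) — the standard extent filter against
   isolated false positives.

2. **Fine selection (SVM-RFE)** — a soft-margin linear SVM
   (`min ½‖ω‖² + C Σζᵢ`, C = 1.0 by default) is fit on the surviving
   voxels; its weights are recovered from the dual as ω = Σ αᵢyᵢxᵢ, features
   are ranked by ωᵢ², and the weakest 5% of the remaining set is removed per
   round until a target fraction is retained (40% is a common choice for
   gray matter, 14% for white matter).

3. **Classification and evaluation** — the final linear SVM is evaluated by
   leave-one-out cross-validation, with proportion-based confusion entries
   (TP = N₁/N, TN = M₁/M, so TP+FN = TN+FP = 1) and the metrics ACC, SN, SP,
   GM = √(SN·SP), Dice DM, F2M, plus ROC/AUC. Selection can be re-run inside
   every fold (`nested`, leakage-free, the default) or computed once on all
   subjects (`pooled`, emulating the common but optimistic protocol).

4. **Biomarker report** — connected clusters of the retained voxels at or
   above the extent threshold are tabulated with sizes, peak-|T| world (MNI-
   style) coordinates, and majority atlas labels.

A seeded synthetic-cohort generator (smooth volumes with planted spherical
group effects and exact ground truth) makes the entire pipeline testable
without any MRI download.

## Worked example

```python
import vbmlearn as vl

spec = vl.CohortSpec(
    grid_shape=(16, 16, 16), n_group1=34, n_group2=34,
    blobs=(vl.BlobSpec(center=(8, 8, 8), radius=3.0, effect=0.5),),
    subject_sd=0.02, voxel_sd=0.1, fwhm_mm=6.0, voxel_size_mm=2.0, seed=7,
)
volumes, labels, truth = vl.generate_cohort(spec)

model = vl.CoarseToFineVBM.from_volumes(
    volumes, labels,
    screening=vl.ScreeningConfig(alpha=0.05, min_cluster=50),
    rfe=vl.RFEConfig(C=1.0, elim_fraction=0.05, retain_fraction=0.40),
)
res = model.fit()
print(res.summary(model.evaluate(mode="nested")))
```

prints

```
        Coarse-to-fine VBM discriminative analysis
==============================================================
Subjects:             68  (+1: 34, -1: 34)
Voxels in mask:       4096
Screening:            alpha=0.05, min_cluster=50, connectivity=26
  surviving voxels:   2850 in 1 cluster(s)
RFE:                  C=1.0, elim/round=0.05, retain=0.4
  retained voxels:    1140 (18 elimination round(s))
Final SVM:            |support vectors|=12, bias=-1.6246
--------------------------------------------------------------
Leave-one-out (nested selection):
  ACC=1.0000  SN=1.0000  SP=1.0000
  GM=1.0000  DM=1.0000  F2M=1.0000  AUC=1.0000
==============================================================
```

The 68 synthetic subjects differ by a single radius-3 spherical effect of
0.5 intensity units against ~0.1 voxel noise — a deliberately strong,
recoverable signal — so screening finds one supra-threshold cluster, RFE
keeps the best 40% of it, and nested leave-one-out classifies every subject
correctly. A region report with a synthetic atlas then lists each retained
cluster with its size, peak coordinate (mm) and majority label:

```python
atlas = vl.make_synthetic_atlas(spec.grid_shape, 8, seed=0)
atlas.affine = spec.affine
for r in res.regions(atlas=atlas)[:3]:
    print(f"cluster {r.cluster_id}: size={r.size} peak={r.peak_world} "
          f"label={r.majority_label}")
# cluster 1: size=781 peak=(20.0, 30.0, 4.0) label=6
# cluster 2: size=259 peak=(16.0, 16.0, 18.0) label=8
# cluster 3: size=71 peak=(4.0, 28.0, 20.0) label=7
```

The same workflow is available from the shell
(`vbmlearn simulate / screen / select / evaluate / report / run`), driven by
a JSON or YAML config with a single seed; rerunning the same config gives a
byte-identical `summary.json`.

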