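# fusimorph

Geometry-only rupture-risk analysis for vertebral artery fusiform
aneurysms (VAFA), built as a tested, reproducible pipeline.

Fusiform aneurysms are spindle-shaped dilations without a discrete neck;
deciding whether to treat one means weighing rupture risk against
procedural risk.  This package implements an analysis strategy whose
premise is that the *parent vessel* — the artery proximal and distal of
the aneurysm, deliberately excluding the aneurysm itself — carries enough
geometric signal to predict rupture status.  It is written for
researchers in vascular morphometry who want every step of that claim as
inspectable, seedable code, exercised end to end on synthetic vascular
phantoms with known ground truth.

## The pipeline

From a triangulated vessel surface (STL) or a precomputed centreline with
annotated aneurysm endpoints `a` and `b` (1-based centreline indices):

1. **Centreline differential geometry** — a C² cubic spline through the
   ordered centreline points gives arc length, the Frenet–Serret frame,
   curvature `κ = |r′×r″|/|r′|³` and torsion
   `τ = (r′×r″)·r‴/|r′×r″|²`.
2. **Cross-sections** — the surface is sliced perpendicular to the
   tangent at every centreline point, rasterized, and measured: area `A`,
   major/minor axis lengths, eccentricity
   `e = sqrt(1 − (minor/major)²)`, equivalent diameter `2·sqrt(A/π)`,
   solidity, extent, and the area change rate `dA/ds`.
3. **Five-segment splitting** — change-point style: the threshold is the
   standard deviation of `A` outside `[a, b]`; scanning outward from the
   aneurysm, the first point deviating from the neck baseline by more
   than the threshold bounds the adjacent segment, with fallback
   `default_s = min((a−1)/2, (n−b)/2)`.  Result: P2, P1, aneurysm, D1,
   D2, the four vessel segments all holding `s` points.
4. **382 aneurysm-excluding features** — per-segment max / mean / std /
   trapezoidal integration / total variation of each geometric index,
   proximal/distal ratios (P1/D1 and P2/D2), endpoint values and ratios,
   segment lengths and tortuosities, the neck angle `α` and distance `d`
   between the tangents at `a` and `b`, and end-to-end distances.  With
   identifier and outcome columns a cohort becomes an `n × 384` table.
5. **Consensus feature selection** — Welch t-test screen at `p ≤ 0.1`,
   then four methods (largest |t|, RFE×{linear SVM, L2 logistic
   regression, random forest}, each keeping 5 features) repeated 30
   times on stratified 80% subsamples.  Consensus: the union of each
   method's top-2 most frequent features, and the features selected in
   at least 20/30 runs by some method.
6. **Four classifiers** — linear SVM, L2 logistic regression (liblinear),
   KNN (k=5), and a Gini tree with depth 3 for ≥4 features else 2 —
   evaluated by leave-one-out and by 100 stratified 80/20 splits, with
   signed linear coefficients and a node-by-node tree export.

Because the clinical dataset behind this kind of study cannot be
redistributed, `fusimorph.synthetic` generates cohorts of vascular
phantoms (default 37 cases, 12 ruptured) with fully known geometry and
class effects planted on the five headline features of the analysis:
proximal/distal mean-curvature ratio, distal-2 endpoint diameter,
proximal-2 eccentricity variability, proximal curvature integral, and
the P2/D2 area ratio.  See `docs/methods.md` for the generator's design
and its limits.

## Worked example

```sh
fusimorph run-all --seed 1 --out run1
```

generates a 37-case phantom cohort, extracts everything, and writes all
stage artefacts under `run1/` (ground-truth tables, profiles,
`segmentation.tsv`, `feature_matrix.tsv`, `frequency_table.tsv`,
`consensus.json`, `evaluation.tsv`, `coefficients.tsv`, `tree.txt`, and
a `manifest.json` with every derived seed).  On this seed the
frequency table starts

```
rank  kbest_t              freq  rfe_svm              freq  rfe_lr                freq  rfe_rf               freq
1     Eccentricity_std_P2  30    Eccentricity_std_P2  30    Eccentricity_std_P2   30    Eccentricity_std_P2  30
2     Curvature_mean_PD    30    Curvature_mean_PD    30    Curvature_mean_PD     30    Curvature_mean_PD    30
3     Tortuosity_P         30    CrossArea_mean_PD2   20    EquivDiameter_std_D2  16    Tortuosity_P         29
```

— the proximal-2 eccentricity variability and the proximal/distal
curvature ratio are selected in all 30 repetitions by all four methods.
The evaluation report prints

```
feature_set      model  n_features  loo_accuracy  split_accuracy
 top2_union svm_linear           3         100.0         100.000
 top2_union  logreg_l2           3         100.0         100.000
 top2_union        knn           3         100.0         100.000
 top2_union       tree           3          97.3          96.125
```

(the planted effects separate the classes almost perfectly; accuracies
are percentages over 37 leave-one-out folds and 100 stratified 80/20
splits).  The signed coefficients carry the planted directions —
ruptured cases have a *smaller* curvature ratio and *more variable*
proximal-2 eccentricity:

```
                     SVM      LR
Curvature_mean_PD   -0.733  -1.287
Eccentricity_std_P2  1.053   1.441
```

and `tree.txt` holds the depth-limited tree fitted to all 37 cases:

```
Curvature_mean_PD <= 0.835 | samples=37 value=[25, 12] class=unruptured
  leaf | samples=12 value=[0, 12] class=ruptured
  leaf | samples=25 value=[25, 0] class=unruptured
```

(`value` is the (unruptured, ruptured) case count reaching the node;
the node class follows the majority).  `fusimorph sensitivity` re-runs
segmentation, features and selection at 0.9×/1.0×/1.1× of the area
threshold and tabulates which consensus features persist.

The same stages are available piecewise (`synth`, `extract`, `segment`,
`features`, `select`, `evaluate`) and as library calls
(`fusimorph.run_pipeline`, `fusimorph.extract_cohort`, ...).

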