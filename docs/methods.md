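# Methods

`fusimorph` re-implements a geometry-only rupture-risk analysis for
vertebral artery fusiform aneurysms as a tested pipeline and exercises it
end to end on synthetic vascular phantoms.  This note documents the model
and procedure, the parameters that matter, what the phantom generator does
and does not emulate, and the numerical and design choices made where the
procedure left them open.

## The analysis

A case is a vessel surface with an annotated fusiform aneurysm: two 1-based
centreline indices `a` and `b` bound the dilated span.  The pipeline is:

1. **Centreline geometry.** A C²-continuous cubic spline is fitted per
   coordinate against the chord-length parameter (smoothing 0 by default,
   i.e. interpolation), and arc length is computed by dense trapezoidal
   quadrature of the spline speed.  Curvature and torsion come from the
   spline derivatives, `kappa = |r' x r''| / |r'|³` and
   `tau = (r' x r'') · r''' / |r' x r''|²`, together with the
   Frenet-Serret tangent/normal/binormal frame.  Where `kappa` falls below
   1e-8 mm⁻¹ the normal, binormal and torsion are undefined; such points
   are flagged and torsion is reported as 0, and downstream statistics skip
   flagged points.  An interpolating cubic was verified sufficient: on a
   helix with R = 2 mm, c = 1 mm/rad sampled at 100 points it recovers the
   closed forms `kappa = R/(R²+c²)`, `tau = c/(R²+c²)` to ~0.2%.
2. **Cross-sections.** The surface is cut by the plane through each
   centreline point perpendicular to the tangent; the nearest closed loop
   is rasterized (pixel-centre-inside rule, default pitch 0.05 mm — the
   source imaging resolution is unknown, so the pitch is an explicit free
   parameter) and measured: area, major/minor axis lengths and
   eccentricity of the moment-equivalent ellipse, equivalent diameter
   `2·sqrt(A/pi)`, solidity, extent, and the area change rate `dA/ds`
   (central differences).  Extent's bounding box is aligned to the
   region's principal axes, a deliberate deviation from the image-axis
   convention: arbitrary slice planes have no canonical image axes, and
   the principal-axis convention makes the value rotation-invariant.
   Synthetic phantoms with analytically elliptical sections can bypass
   meshing entirely through equivalent closed forms; the two routes agree
   within raster tolerance (tested).
3. **Segmentation.** The vessel is split into five contiguous segments
   P2, P1, [a, b], D1, D2 with equal non-aneurysm point counts `s`.  The
   threshold is the sample standard deviation of the areas outside
   [a, b]; scanning outward from the aneurysm, the first point whose area
   deviates from the neck baseline (`ps` at `a` proximally, `pe` at `b`
   distally) by more than the threshold sets that side's extent; `s` is
   the minimum of both sides and the fallback
   `default_s = floor(min((a-1)/2, (n-b)/2))`.  Open points resolved here:
   a single exceeding point suffices (no run-length requirement), the scan
   uses absolute deviation with strict inequality, and one shared `s`
   serves all four segments (per-side lengths would contradict the
   equal-count construction).  `s` below 3 points is rejected as
   meaningless.  A ±10% threshold sensitivity mode re-runs everything at
   0.9× and 1.1×.
4. **Features.** 382 aneurysm-excluding features per case; the registry
   enumeration is documented in `fusimorph.features` (segment statistics,
   proximal/distal ratios, endpoint values and ratios, lengths, neck
   angle/distance, end-to-end distances).  The authoritative source list
   is not public, so this registry is a reconstruction constrained to the
   same total; the shipped manifest (`registry_manifest.tsv`) records it
   exactly.  "Variation" is implemented as total variation `sum |Δx|`
   (it captures the wave-like proximal curvature pattern the analysis
   highlights); the range max−min was considered and rejected as
   redundant with max on near-monotone segments.  Ratios are oriented
   proximal/distal (numerator/denominator); the source text is
   inconsistent on orientation, and sign conclusions are symmetric under
   reciprocals.  `Ratio_Dpnordnor1/2` are endpoint-diameter ratios,
   `LineDist` the straight end-to-end distance and `PointDist` the
   end-to-end arc length; all three are reconstructions.  A zero ratio
   denominator yields a flagged NaN which screening later drops.
5. **Selection.** Welch two-sample t-tests screen features at p ≤ 0.1
   (Welch rather than pooled-variance because of the 12 vs 25 imbalance;
   Student's is a config option).  Screening runs once on the full data;
   the four methods — largest |t|, RFE around linear SVM, L2 logistic
   regression and random forest, each selecting k = 5 — are then repeated
   30 times on stratified 80% subsamples (unstratified draws of a 12/25
   cohort too often lose the minority class).  Features are standardized
   before the linear RFE estimators.  Consensus sets: the union of each
   method's two most frequent features (rank-2 ties all included), and
   the features selected at least ⌈2/3·30⌉ = 20 times by some method.
6. **Models and evaluation.** Linear-kernel SVM (C = 1), L2 logistic
   regression (liblinear), KNN (k = 5, Euclidean) and a Gini decision
   tree with max depth 3 for feature sets of size ≥ 4 and 2 otherwise.
   SVM/LR/KNN are standardized with training-fold statistics only; trees
   run unscaled.  Accuracy is estimated by leave-one-out and by 100
   stratified 80/20 splits (stratification again forced by the class
   imbalance).  Linear coefficients are reported sign-oriented toward the
   ruptured class, and the fitted tree is exported node by node
   (samples, per-class counts, majority class).

## The phantom generator

No clinical meshes can ship with the package, so `fusimorph.synthetic`
generates phantoms with known analytic geometry: a centreline that is
either an exact helix (closed-form curvature/torsion) or a curve
integrated by RK4 from prescribed curvature/torsion profiles; an area
series with a raised-cosine fusiform bulge between `a` and `b` (default
phantom: n = 100 points, a = 41, b = 60, leaving the fallback segment
length 20 on both sides); near-elliptical sections with controllable
eccentricity; and optionally a watertight lofted tube surface whose
ellipses ride the Frenet frame (carried through locally straight spots and
sign-aligned between rings).  Lofting requires `kappa × semi-major < 0.95`
and raises a loft error naming the offending index otherwise, so strongly
curved fat phantoms are analysed through the closed-form profile route.

A cohort (default 37 cases, 12 ruptured) draws case-level anatomy
identically for both classes: calibre ~ 7 mm² (log-sd 0.15), far-field
curvature ~ 0.18 mm⁻¹ (log-sd 0.18), point spacing ~ 0.30 mm (log-sd
0.14) anti-correlated with curvature (ρ = −0.8; tortuous vessels cover
less span between landmarks), a gentle 20–35% proximal-to-distal area
taper trend (this trend, not pixel noise, dominates the change-point
threshold, keeping the first-exceedance scan stable), short-wavelength
curvature waves, per-case wave asymmetry, distal-half eccentricity
offsets, a proximal-end truncation artefact, and 0.5–1.5% multiplicative
area noise.  The rupture label shifts exactly six knobs, all in the
direction the analysis targets for ruptured cases: the near-neck proximal curvature
level down and distal level up (the proximal/distal contrast is local to
within ~6.5 mm of the neck), the proximal run length down, the far-distal
area scale down, the distal end-diameter pinch down, the distal-end
eccentricity down, and the proximal-2 eccentricity variability up.  Each
knob was placed so that one registry feature is the dominant readout of
its effect direction — respectively `Curvature_mean_PD`,
`Curvature_integration_P`, `CrossArea_mean_PD2`, `Diameter_normalD2` and
`Eccentricity_std_P2` — while sibling features of the same direction are
diluted by the class-independent spreads above.  Effect sizes were
calibrated once on large-cohort effect-size landscapes to make the
end-to-end pipeline separable but not trivially so; a zeroed effect
configuration makes the classes exchangeable.

What the phantoms do **not** emulate: bifurcations and side branches,
non-elliptical lumen cross-sections, wall thickness, imaging artefacts
beyond isotropic area noise, inter-feature correlation structure of real
anatomy, and any haemodynamics.  Passing tests therefore demonstrate that
the pipeline's machinery is correct and that planted geometric signals of
realistic magnitude survive the full selection/evaluation protocol — not
that clinically reported accuracies generalize.

## Numerical choices and degenerate inputs

- Curvature floor 1e-8 mm⁻¹ marks undefined frames; flagged, not NaN.
- Spline endpoint derivatives are one-sided (no phantom points).
- Rasterization uses the pixel-centre-inside rule (unbiased as the pitch
  shrinks, and trivially brute-forceable for testing); a contour smaller
  than one pixel is a resolution error.
- Multi-loop slices keep the loop whose centroid is nearest the
  centreline point; ties go to the larger loop.
- Disconnected masks are measured on the largest component with a warning.
- Segment statistics need ≥ 3 points; > 50% flagged points in a segment is
  an unreliable-feature error, and such per-case failures are collected
  and reported, never silently dropped.
- Ties in |t| ranking break by registry order; rank-2 frequency ties are
  all included in the top-2 sets (and logged).
- All randomness flows from one master seed through a documented
  per-stage derivation (`numpy` SeedSequence); identical seeds reproduce
  cohorts, matrices and selection tables bit for bit.

## Problem sizes used by the test-suite

The structural and geometric checks run at full scale (37-case cohorts,
1,000-series segmentation oracle).  The selection-recovery check runs the
complete 30-repetition, four-method protocol once at the default
threshold; its permutation-null companion uses a small number of
label-permutation replicates, and the ±10% sensitivity check runs the
full protocol at 0.9× and 1.1×.  The evaluation-calibration check uses 50
label permutations of the leave-one-out protocol.  These sizes are the
package's chosen defaults for a routine verification run; all of them are
plain parameters and can be raised.

Two calibration facts the test-suite measures are worth stating plainly.
First, leave-one-out accuracy under label permutation is pessimistically
biased: all four models score several points *below* the majority-class
rate (anti-learning), so permutation checks of this pipeline should be
read one-sided — the absence of optimistic bias is the meaningful
conclusion, not equality with the majority rate.  Second, selection
frequency under a *fixed* label permutation saturates: the screen keeps
only the handful of by-chance-associated features, and the strongest of
them is re-selected in essentially every subsample.  Frequency therefore
measures within-permutation consistency, not significance; a proper null
reference must compare across many permutations, not within one.

## Known limitations

- The registry is a reconstruction; only its total (382) and the named
  named headline features are anchored.
- The consensus "top-2 union" is sensitive to method concordance: when
  all four selection methods agree on the same two strongest features,
  the union degenerates toward two features, whereas diverse per-method
  preferences widen it.  Real-data method diversity is an empirical
  accident that synthetic cohorts reproduce only approximately.
- At a single cross-section, the major axis, equivalent diameter and area
  are deterministically linked (`MaxD = EqD (1-e^2)^(-1/4)`), so endpoint
  features built on them are statistical clones under any area-based
  planted effect; with elliptical phantom sections the distal endpoint
  *diameter* cannot be made decisively more informative than its area
  siblings, and the consensus rotates among the three.  Real lumens,
  which flatten non-elliptically, can break this tie.
- Torsion estimates inherit third-derivative noise from short-wavelength
  curvature structure; torsion-based features are correspondingly noisier
  than curvature-based ones.
- The loft cannot represent vessels with curvature radius smaller than
  the lumen semi-axis; such phantoms are analysed via closed-form
  profiles only.
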