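# Methods

`cwmorph` analyses breathing kinematics of the chest wall (CW) as a problem in
landmark-based 3D geometric morphometrics. The input is the motion of 89
reflective markers on the torso surface, as recorded by optoelectronic
plethysmography (OEP); the output is a decomposition of each breath into a
**size** change (centroid size) and a **shape** change (Procrustes/shape-space
coordinates), with paired nonparametric tests of how those changes differ
between breathing conditions and postures.

## Coordinate convention

Right-handed axes in millimetres: +z cranial, +y ventral, +x towards the
subject's left. Missing marker coordinates are NaN plus a boolean mask; zeros
are always valid coordinates.

## The marker template and its triangulation

The standard OEP 89-marker placement is proprietary in its exact geometry, so
the package uses a documented stand-in with the same cardinality and
compartment structure: 8 circumferential rows of 11 markers on an
elliptical-cross-section torso (rows `A1`–`A4` abdominal, `T1`–`T4` thoracic,
caudal to cranial) plus one cranial apex marker (`APEX`), 8 × 11 + 1 = 89.
Default torso dimensions are 300 × 220 × 500 mm (width × depth × height),
with a smooth axial taper so the surface is star-shaped about the torso axis.

The enclosed-volume computation needs a closed, consistently oriented
triangulation over these markers. `default_topology` builds one: side quads
between adjacent rows split into triangles, a fan from the top row to the
apex, and a fan triangulation of the bottom polygon — 174 triangles, V − E +
F = 89 − 261 + 174 = 2, every edge traversed once in each direction. Any
alternative geometric model can be injected as a JSON triangle list, so the
classic OEP connectivity can be dropped in verbatim if available.

## Enclosed volume and breath endpoints

The CW volume of a frame is the divergence-theorem sum of signed tetrahedra
(origin, v1, v2, v3) over the mesh triangles. For a closed oriented surface
this is independent of the origin (asserted by test) and positive for outward
orientation.

End-expiration (EX) and end-inspiration (IN) are local minima and maxima of
the volume signal. Two maxima and two minima are selected per recording. The
default policy ranks candidate extrema by topographic prominence with a
minimum separation of `min_period_s` (default 1.5 s, ties to the earlier
peak); a `consecutive` policy that takes the first cycles in time is also
available, since either reading of "select two peaks" is defensible. No
smoothing is applied by default.

Marker dropout interacts badly with a per-frame volume: with 89 markers, even
1% independent per-marker dropout leaves most frames incomplete. Detection
therefore runs on a gap-filled copy of the trajectory (per-marker linear
interpolation in time, `interpolate_gaps`); the *extracted configurations*
always come from the raw frames, and their missing landmarks are estimated by
thin-plate splines, never by temporal interpolation.

## Missing-landmark estimation (TPS)

The interpolating 3D thin-plate spline uses kernel U(r) = r with a full 3D
affine part and the usual side conditions annihilating affine components; the
dense (k + 4) × (k + 4) system is solved directly (k = 89). Bending energy is
the |quadratic form| of the non-affine weights, zero exactly when the map is
affine. Exactly coplanar control points make the affine block rank-deficient;
the solver warns and falls back to a minimum-norm least-squares solution.

For an incomplete configuration, a TPS is solved from a complete reference to
the configuration over the shared landmarks, and missing positions are read
off by mapping the reference's corresponding landmarks. Reference priority:

1. consensus of the same subject's complete configurations (≥ 2 of them);
2. consensus of all complete configurations in the cohort;
3. the time-mean shape of the subject's gap-filled recording.

Tier 3 exists because under realistic dropout a strictly complete endpoint
configuration can be rare. Configurations missing more than
`max_missing_frac` (default 20%) of landmarks are refused rather than
estimated. Estimation happens on raw coordinates, before superimposition.

## Superimposition and shape space

Centroid size CS is the square root of the summed squared distances of
landmarks to their centroid. Generalized Procrustes analysis translates every
configuration to the origin, scales it to unit CS (full Procrustes / Kendall
shape; size is analysed separately through CS), registers all to the first
configuration, then iteratively re-registers to the consensus until the RMS
distance to consensus changes by less than `tol` (default 1e−8, max 100
sweeps; non-convergence is flagged, not raised). Reflections are forbidden by
default. Procrustes distance is the Euclidean distance between superimposed
unit-CS coordinate sets — the partial/tangent convention of mainstream
morphometric software; no tangent projection beyond mean-centering is applied
before PCA, appropriate for the small shape variation of breathing data.

The stopping rule is a practical choice: for tightly clustered morphometric
data it reaches the (unique) fixed point to well below 1e−6; for artificially
dispersed shapes near the diameter of shape space it can halt earlier, which
affects none of the intended use.

PCA is an eigendecomposition of the variance–covariance matrix of the
flattened Procrustes coordinates (computed via SVD of the centered data).
Each component's sign is fixed so its largest-magnitude loading is positive,
making score medians comparable across runs. `shape_at_scores` reconstructs
the theoretical shape mean + Σ scoreᵢ·PCᵢ for visualisation and warping.

## Functional size and shape, respiratory vectors

Per subject × breathing condition, with the two cycles of each instant
averaged (per-cycle values are also emitted for audit):

* **FS** (functional size, mm) = mean CS(IN) − mean CS(EX), computed on
  pre-scaling centroid sizes, hence identical before and after GPA;
* **FSh** (functional shape, dimensionless) = Procrustes distance between the
  mean IN and mean EX shapes. The default re-superimposes the two mean shapes
  optimally (pairwise partial Procrustes distance), which is independent of
  the consensus frame and recovers generator ground truth exactly in
  noise-free data; the plain consensus-frame distance is available as
  `method="gpa_frame"`.

Respiratory vectors are per-condition means over subjects of the EX → IN
PC-score displacement in the PC1–PC2 plane, with their norm ("module") as a
scalar summary of breathing motion amplitude in shape space.

## Hypothesis battery

All contrasts are paired within subject and tested two-sided with the
Wilcoxon signed-rank test: zero differences dropped, ties mid-ranked, exact
null distribution when the number of non-zero pairs is ≤ 25 with untied
absolute differences, else a normal approximation with continuity and tie
corrections. The reported statistic is W = sum of positive-difference ranks.
No multiple-testing correction is applied by default (a Holm option exists).
Stars: *** < 0.001, ** < 0.01, * < 0.05.

Per posture group (to keep posture out of the contrasts): H1_size CS(IN) vs
CS(EX) within each condition; H2_size FS(QB) vs FS(REC); H3_size CS at
matched instants across conditions; H1_shape PC1/PC2 scores IN vs EX per
condition; H2_shape FSh(QB) vs FSh(REC); H3_shape PC1/PC2 at matched
instants across conditions — 14 reports per posture. The joint two-posture
GPA+PCA is kept as the exploratory scope.

## Synthetic cohort generator

The generator emulates the acquisition setting so every stage is testable
without recordings: 89-marker template, two postures (SIT-like seated-flexed,
STA-like standing-extended), two conditions (QB quiet breathing, REC
recovery breathing after exercise), 60 Hz (SIT) / 100 Hz (STA) sampling.

* **Breathing**: each marker's radial distance from the torso axis follows
  r(t) = r₀·(1 + a·sin(2πft)), with a the thoracic or abdominal fractional
  amplitude of the active condition. Defaults: QB 0.008/0.012
  (thoracic/abdominal), REC 0.030/0.040, breathing rate 0.25 Hz — on the
  default torso this gives quiet-breathing tidal excursions of roughly
  0.5–0.7 L and recovery excursions of ~2.5 L, with the abdomen leading, the
  tidal-volume contrast that distinguishes the two conditions. A sinusoid is
  used deliberately: it gives closed-form endpoint phases (EX at 3π/2, IN at
  π/2) for exact ground truth.
* **Posture**: articulated flexion — markers above the waist rotate about a
  mediolateral axis through the waist, the angle ramping linearly to
  `flexion_angle_deg` at the torso top (+20° SIT-like, −5° STA-like). A
  whole-body rigid rotation would be removed by Procrustes registration;
  bending makes posture a genuine shape factor, as it is in real data.
* **Subject variation**: i.i.d. Gaussian perturbation of the template
  (default sd 5 mm). **Noise**: additive Gaussian, default 0.5 mm.
  **Dropout**: two-state Markov occlusions with geometric run lengths of mean
  0.3 s and stationary missing probability `dropout_prob` (default 0.01) —
  contiguous runs, not frame flicker. Noise and dropout levels of the real
  systems are not published; these defaults are placeholders at plausible
  magnitudes, not estimates.
* **Seeding**: one root seed; per-subject substreams spawned
  deterministically, so runs are bit-reproducible.

Ground truth per subject × condition: the noise-free EX/IN fields, true FS,
true FSh (pairwise Procrustes distance of the unit-size truth shapes) and
true tidal volume. `simulate_endpoint_configs` is a fast path that emits only
noisy endpoint configurations (no trajectories), used for simulation studies
where the endpoint-detection stage is not itself under study.

What the generator does **not** emulate: rib-level articular kinematics,
respiratory-muscle physiology, breath-to-breath variability of rate and
amplitude, realistic anthropometric covariance between subjects, soft-tissue
artefact. Tests passing on synthetic cohorts therefore validate the
*computational* pipeline (geometry, registration, statistics, calibration),
not claims about human physiology.

## Problem sizes and numerical choices

The bundled analyses run a 27-subject cohort (14 SIT + 13 STA, 8
configurations each, 216 into the joint GPA) with 20 s recordings, and
calibration studies of 400 null / 200 effect simulated cohorts at n = 14 via
the endpoint fast path — sizes chosen so a complete run stays interactive on
one CPU. Tolerances: GPA tol 1e−8; TPS conditioning warning at cond > 1e12;
endpoint ties broken toward earlier time; degenerate statistical contrasts
(all zero differences) are reported as such and never silently dropped.

## Known limitations

* The stand-in template/triangulation yields volumes comparable to, but not
  identical with, the proprietary OEP geometric model; absolute volumes
  should not be compared across models.
* FSh from the consensus frame (`gpa_frame`) upper-bounds the pairwise
  distance; the two differ at third order for small variation.
* The exact Wilcoxon path requires untied absolute differences; continuous
  synthetic data essentially always satisfies this, heavily rounded real
  data may silently shift to the corrected normal approximation.
* C3D reading requires the optional `ezc3d` dependency; the canonical
  interchange format is the long-CSV dialect.
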