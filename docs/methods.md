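# Methods

## Problem and pipeline overview

Left-ventricular electroanatomic mapping produces an irregular cloud of a
few hundred to a few thousand endocardial points, each carrying unipolar and
bipolar electrogram voltage (mV), local activation time (LAT, ms) and
impedance (Ω). Chambers differ in size, position and orientation between
patients, so raw coordinates are not comparable. The pipeline (1) normalizes
each cloud onto a fixed tessellated sphere, (2) computes substrate features
globally and per region, (3) merges them with clinical covariates into a
patient × variable table, and (4) fits and searches predictive models for a
binary major-arrhythmic-event (MAE) outcome.

## Spherical normalization

**Tessellation.** The sphere is divided into `n_lon = 120` equal longitude
sectors × `n_bands = 120` bands of equal height in z. By Archimedes' hat-box
theorem a band of height Δz has area 2πRΔz independent of latitude, so all
14,400 faces have exactly equal area; equality holds to floating-point
round-off (≤ 1e−9 relative), and face lookup from a direction is O(1).
Alternative constructions (geodesic polyhedra, equal-area pixelizations)
give only approximately equal cells and require search structures; the
band/sector grid is exact and trivially indexable. Faces near the poles are
elongated; none of the feature definitions depend on face shape.

**Projection.** The cloud centroid (arithmetic mean) is placed at the sphere
center and each point is assigned to the face containing its
centroid-to-point direction. The face count was chosen (by the original
design) so a face almost never receives two points; when it does, the point
whose direction is closest to the face center wins, the others are dropped,
and the collision count is reported in the diagnostics. At the default
density (1,500 points / 14,400 faces) roughly 1–2 % of points collide, which
bounds the granularity of any face-count-based extent.

**Canonical frame.** Principal axes of the centered cloud: longest axis to
z, second to x, y = z × x (always a proper rotation — chirality is never
flipped). Signs are data-driven and deterministic: z points toward the
hemisphere with later mean activation (an apex proxy), x toward higher mean
unipolar voltage; exact ties (e.g. constant channels) fall back to making
the largest-magnitude axis component positive. A `frame="fixed"` mode skips
the rotation for workflows where the acquisition frame is already
standardized — ground-truth recovery tests use it because planted-patch
regions are defined in the acquisition frame. With near-degenerate minor
axes (the LV is roughly prolate) the x/y axes of the *population* are
ill-determined, but the sample principal axes are equivariant under rotation
of a given cloud, so features remain rigid-motion invariant; regional
indices of near-symmetric chambers should still be interpreted with care.

**Regions.** The 8 regions are the octants of the canonical frame, mapped to
indices 1–8 by a configurable sign-triple table and carrying nominal
anatomical labels (1 anterior sub-mitral, 2 posterior mid-apical, 3
antero-septal mitro-aortic valvular, 4 postero-septal mid-apical, 5
antero-lateral sub-valvular mitro-aortic, 6 postero-lateral mid-basal, 7
antero-lateral mid-basal, 8 apical/infero-apical). With 120 × 120 faces the
octant boundaries fall exactly on cell edges, so each region holds exactly
1,800 faces. This is geometric regionalization with anatomical names, not
image-based registration.

## Substrate features

**Gradient value (GR, ms/mm).** For each point, the maximum |ΔLAT|/distance
over neighbors within `gr_radius_mm = 7` mm; pairs closer than 0.1 mm are
skipped rather than divided by. 7 mm matches the spatial scale at which
deceleration zones are assessed clinically; the neighbor radius is applied
after rescaling the cloud to a reference RMS centroid distance of 35 mm
(a typical LV endocardial shell), which keeps GR in ms/mm of a reference
chamber and makes the whole feature vector invariant to uniform scaling of
the input. The scalar summary is the 95th percentile of per-point values
(robust to a single noisy pair; configurable), the regional value is the
per-region maximum. Note that a single small deceleration zone can leave the
95th percentile at zero while still dominating its regional maximum — the
regional values are the sensitive readout for focal disease.

**Range-relative thresholds.** VLT and LAT use "top 20 % of the observed
range" cuts (strictly above `min + 0.8·(max − min)`), mirroring the original
design. Such thresholds are *relative*: they always label the extreme band
of whatever variation is present, so a map with no genuine substrate but
some variation still gets a nonzero extent, and the uniform map (zero range)
correctly gets zero.

**VLT.** The per-face difference d = bipolar − unipolar. Healthy tissue has
strongly negative d (unipolar ≫ bipolar); intramural/epicardial substrate
depresses unipolar voltage while bipolar stays normal, moving d *upward*
toward zero — so the top 20 % of the signed range is exactly the
pathological signature, and the signed difference is the default. An
absolute-difference variant (`vlt_signed=False`) is available but selects
healthy tissue under a unipolar-depression pathology and is therefore not
recommended.

**LAT extent.** "Late" is the latest 20 % of the LAT range (the literal text
of the rule this implements is direction-ambiguous; `late_direction=
"earliest"` gives the other reading). The default denominator is the count
of *non-late* faces — implemented literally, so the extent can exceed 100 %;
`late_denominator="total"` normalizes by all occupied faces.

**Scar Areas.** Faces with bipolar voltage < 0.5 mV, the conventional
dense-scar cutoff (the 0.5–1.5 mV border zone is not separately extracted).

**Clustering.** Critical/late/scar faces only count toward an extent in
clusters of at least `min_cluster = 3` faces ("an area", not an isolated
point). Because occupied faces are sparse on the 14,400-face grid (~10 %
occupancy at default density), edge-adjacency on the grid would never
connect them; two occupied faces are therefore clustered when their center
directions are within `cluster_angle_deg = 8°` geodesically (≈ 5 mm on the
35 mm reference chamber, comfortably above the ~3 mm mean spacing of 1,500
points). `cluster_angle_deg=None` restores literal grid edge-adjacency.

**Regional extents** use the same global threshold and clusters, counted and
normalized within each region; regional impedance is the mean over occupied
faces per region, NaN for empty regions.

## Synthetic data

The generator emulates the *statistics* of an export, not electrogram
biophysics. Points are sampled uniformly (area-exact rejection sampling) on
an ellipsoidal shell with semi-axes 30/30/40 mm, jittered radially (sd
1 mm). Healthy channel levels: bipolar 3 mV, unipolar 10 mV, LAT 0 ms,
impedance 100 Ω, with per-channel Gaussian noise (defaults 0.3 mV, 1 mV,
5 ms, 8 Ω). Abnormalities are angular caps centered on a region's octant
direction: dense-scar caps override the bipolar mean (overlaps take the most
depressed value), late caps add an LAT offset, VLT caps subtract a unipolar
depression, and an isthmus ramps LAT by `step_ms` over `width_mm` along a
tangent direction inside a cap, producing a ≈ step/width ms/mm deceleration
zone. Everything is driven by one integer seed; identical scenario + seed
gives a bit-identical export.

Clinical covariates: NYHA uniform on {1..4}; truncated normals for sPAP
(30 ± 8, ≥ 10 mmHg), TAPSE (18 ± 4 mm), LVEF (45 ± 12 %), iLVEDV
(80 ± 25 mL/m²), creatinine (1.0 ± 0.3 mg/dL), BMI (26 ± 4); Bernoulli
binaries at literature-plausible prevalences (e.g. male sex 0.70,
hypertension 0.50, HFrEF 0.30, arrhythmic storm 0.15). Substrate scalars
(GR 4 ± 2.5 ms/mm, LAT 20 ± 12 %, VLT 15 ± 10 %, ScarAreas 10 ± 8 %, all
truncated at 0) can be drawn directly for isolated modelling experiments;
the full pipeline computes them from generated maps instead.

Outcomes are Bernoulli with P(MAE) = expit(−21.007 + 3.889·NYHA +
0.262·sPAP + 0.034·LAT + 0.492·GR + 2.638·Hypertension) — the published
multivariable polynomial reused as generative truth. Under the covariate
distributions above this yields an event rate near 0.5 with a wide logit
spread, which is deliberately favorable for coefficient-recovery
experiments; it is *not* a calibrated epidemiological event rate.

What passing tests on this generator do **not** show: real electrogram
morphology (fragmentation, double potentials), realistic spatial covariance
of voltage/LAT noise, mapping-density inhomogeneity (operators oversample
abnormal areas), or real anatomy in the region labels. Results on synthetic
data validate the *computations*, not clinical performance.

## Modelling protocol

Stratified 80:20 train/test split; 3-fold stratified cross-validation inside
the training set; the test set is never touched during fitting, imputation
or standardization (imputation fills and scaler statistics come from
training rows only). Metrics: AUC by rank statistic, plus accuracy,
precision, sensitivity and specificity at a 0.5 probability threshold.
Single-class evaluation sets return NaN for AUC (and precision when no
positive predictions exist) rather than a fabricated value.

Families: unpenalized maximum-likelihood logistic regression (coefficients
reported on the original variable scale; quasi-separation — detected by
non-convergence or standardized coefficients beyond 50 — triggers an
L2-bounded refit with a warning, preventing the runaway coefficients that
separation otherwise produces); a literal linear-probability OLS option;
linear-kernel SVM (coefficients unscaled to the original variable scale);
RBF-kernel SVM with Platt-calibrated probabilities; and a one-hidden-layer
(16 units, early stopping) neural network. `hidden_units=0` delegates the
network to the logistic path (its mathematical reduction). Class imbalance
is left unadjusted.

**Model search** pre-ranks candidates by univariate AUC on the training set,
keeps a pool (default 20), and exhaustively scores every subset of size
1..`max_vars` (default 8) by mean cross-validated AUC, tie-broken by mean
accuracy then subset size then name order (making the ranking independent of
candidate ordering). A `max_subsets` guard refuses combinatorially explosive
configurations. The top `top_k = 6` subsets are refitted on the full
training set and reported with train/test metrics, coefficients (linear
families) or mean-|Shapley| importances (nonlinear families), plus a
variable-frequency table across the selected models.

**Shapley attribution** uses the interventional value function (coalition
features from the instance, the rest from background rows) with permutation
sampling; each permutation's marginal contributions telescope, so additivity
(attributions sum to prediction minus background expectation) is exact at
any sample count, while per-feature values converge at the Monte-Carlo rate.
An exact 2^p enumeration mode serves as ground truth for small p.

## Numerical and degenerate-input choices

- Face areas are computed from cell boundaries, not asserted; equality holds
  to ≤ 1e−9 relative.
- Points coincident with the centroid cannot be projected; they are dropped
  and counted (`n_dropped`), and an all-coincident cloud is an error.
- Rank-deficient (coplanar) clouds cannot be canonically oriented: error.
- Fewer than 2 occupied faces make every extent undefined: NaN + warning.
- Coincident point pairs (< 0.1 mm) never enter a gradient denominator.
- Strict inequalities at all range thresholds, so constant channels give
  zero extents rather than everything-critical.
- Pipeline CSV output uses fixed 6-decimal formatting; a rerun of the same
  config is byte-identical. One global seed fans out to per-stage seeds via
  `SeedSequence(seed, spawn_key=(stage,))`.

## Default problem sizes

Defaults were chosen as desk-scale study conditions: 1,500 points per map,
20,000 patients for coefficient-recovery experiments, 50 random maps of
≤ 500 points for oracle-equivalence checks, 20 trials for invariance and
planted-recovery checks, and small search pools (8 candidates, ≤ 3 variables
per model) in the demonstration pipeline.

## Known limitations

- Regions are octants with anatomical *names*; no registration to imaging.
- The late-potential denominator ("non-late") can exceed 100 % by design.
- Range-relative thresholds make VLT and LAT non-comparable across maps with
  very different dynamic ranges.
- The search is a surrogate for an unspecified original procedure; with many
  correlated candidates the top-k subsets are unstable at small n.
- Collisions (multiple points per face) discard data; at much higher mapping
  densities a finer tessellation should be configured.
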