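# Methods

This note documents the models, numerical choices and limitations behind
`grain3d`. Units are millimetres throughout; densities are points/mm².

## What the synthetic generator emulates

The generator stands in for a structured-light scan of grains placed
vertically on a flat stage. Its defaults mirror that acquisition setting:

- **Point density** 35 pts/mm² (≈ 0.17 mm average minimum point spacing),
  sampled approximately uniformly in area. Superellipsoid surfaces are
  sampled by radial rejection: directions drawn uniformly on the unit
  sphere are mapped radially to the surface (the inside–outside function is
  positively homogeneous, so the radial scale has a closed form) and
  accepted with probability proportional to the area element
  `t(u)²/cos(alpha)`.
- **Surface noise** Gaussian, sd 0.05 mm, applied along the outward normal
  — the scanner's single-sided accuracy class. Real scanner noise is
  spatially correlated and milder than this iid model, so the synthetic
  setting is the harder one for the estimators below.
- **Grain model** superellipsoids with semi-axes (length/2, width/2,
  thickness/2) and two shape exponents spanning sphere → lens → blocky
  silhouettes. With exponents (1, 1) the shape is an exact ellipsoid whose
  volume `(4/3)πabc` serves as the analytic oracle. Rice-like defaults:
  length ~ N(8, 0.3), width ~ N(3, 0.12), thickness ~ N(2, 0.08) mm.
- **Unfilled grains** shrink thickness by ×0.55; the filled/unfilled
  contrast is deliberately concentrated in thickness because an
  undeveloped endosperm leaves the hull thin while length and width are
  hull-determined.
- **Scene** one planar stage patch (≥ 100×100 mm) plus up to 25 grains in
  a 6×4+1 grid at 20 mm spacing, long axis vertical; the lowest 5 % of
  each grain's height is removed to model the stage-contact shadow.

Not emulated: raster patterns, view-dependent dropout, inter-reflection,
touching grains. Passing tests therefore demonstrate the geometry and
statistics of the pipeline under scanner-like sampling; they do not
certify behaviour on artefacts the generator does not produce.

## Preprocessing and segmentation

The preprocessing chain is principal-axes transform → voxel-grid
downsampling (each voxel replaced by its gravity centre, voxel index
`floor(x/leaf)` with no origin snapping) → statistical outlier removal
(keep points whose mean k-NN distance ≤ μ + α·σ; defaults k = 50,
α = 1.0). Eigenvector signs are fixed so each axis's largest-magnitude
component is positive and det = +1, which makes the transform
deterministic.

Plane fitting is three-point RANSAC (default 200 iterations, 0.2 mm inlier
distance, seeded) with a total-least-squares refit on the consensus set.
Points less than 0.5 mm above the plane are discarded with it.

Region growing joins a k-NN neighbour (k = 30) to the current region when
its normal is within the angle threshold of the current point's normal,
and promotes it to a seed when its surface-variation curvature is below
0.08. The angle threshold defaults to 35°: at scanner-like spacings
(0.17–0.3 mm) a grain rim has curvature radius down to ~0.3 mm (thin,
unfilled grains), so adjacent-point normal angles legitimately reach
30–55° and tighter thresholds fragment single grains. The threshold only
has to reject the near-90° grain-to-stage transition — cross-grain merging
is geometrically impossible at the 20 mm placement spacing.

## Noise-adaptive measurement scales

Two distinct estimators in the trait stage are sensitive to iid surface
noise in different ways, and each gets its own noise-adaptive scale. Both
scales derive from a robust in-pipeline noise estimate σ̂ (1.4826 × median
absolute distance of a point to the best-fit plane of its 8 nearest
neighbours, corrected for fit leverage), which keeps the whole measurement
scale-covariant: scaling a cloud by s scales lengths by s, areas by s² and
volumes by s³ to floating-point accuracy.

**Surface integrals (area, volume).** Triangulating raw noisy points tilts
every face; the Heron sum then overestimates area by roughly
`E[sec(tilt)] ≈ 1 + 2σ_eff²/leaf²`, which exceeds 10 % at 0.05 mm noise
and 0.17 mm spacing. The mesh is therefore built on a voxel-resampled
cloud whose leaf solves `σ_eff²/leaf² = 1e-3` with
`σ_eff = σ̂/sqrt(ρ·leaf²)`, i.e. `leaf = (σ̂²/(ρ·1e-3))^{1/4}`, clipped to
[2×, 6×] the median NN spacing and capped at thickness/4 so slender grains
keep a resolvable cross-section. On clean clouds the formula collapses to
the fine end and curvature is fully resolved.

**Box extents.** `max − min` is a max-statistic: the raw extreme rides the
largest noise excursion (+2–7 % on width/thickness at these settings).
Each of the six extreme caps is instead estimated by regression: the
points within a 6σ̂ band below the raw extreme are fitted with a quadratic
in the two tangential coordinates (scale-safe ridge), and the extent side
is the maximum of the fitted surface over the band points. On flat caps
the fit collapses to the cap plane and noise averages out; on rims and
tips it recovers the local paraboloid apex. The principal frame itself is
estimated from the full-resolution cloud, where axis wobble is smallest.

## Meshing

`triangulate_surface` is a greedy projection-style reconstruction. Each
point's neighbourhood (radius min(search radius, 2.5 × median NN spacing))
is projected onto its tangent plane; the point's 2D Delaunay star proposes
candidate triangles. Local triangulations are *regular* triangulations
with tiny symbolic weights derived from global point indices, so
co-circular neighbourhoods (regular grids) are broken identically in every
star. Candidates are then accepted greedily by descending (vote count,
shape quality) under a directed-edge exclusivity rule — every candidate is
wound counter-clockwise about the outward point normal, so directed-edge
exclusivity simultaneously enforces edge-manifoldness, rejects the
crossing-diagonal double covers of degenerate neighbourhoods, and yields a
consistent outward winding. A final patch pass closes small boundary loops
(≤ 12 edges) with anchored fans under the same guards; larger openings
(the stage-contact cut) are left for `fill_holes`, which fans each simple
boundary loop to its centroid. On a noise-free 20 k-point sphere sample
the result leaves ~1 % of total edge length on the boundary before
filling.

Volume uses the central-plane prism sum: each face contributes its
projected area on the plane z = 0 through the centroid times the absolute
z of its own centroid. This is exact for prisms and converges for smooth
closed surfaces that are graphs above and below the central plane — which
is why it is computed in the grain's box frame, where z is the thickness
axis and the central plane cuts the grain across its flat dimension. The
divergence-theorem estimator (signed tetrahedra) is kept as the
independent cross-check and agrees with the prism sum within 0.5 % on
closed convex fixtures.

Projection silhouettes use a concave hull: 2D Delaunay triangles whose
longest edge is at most 3× the sampling scale are kept, and the silhouette
is the largest-area outer boundary loop (isolated interior pinholes are
sampling artefacts, not silhouette features). The sampling scale is the
median NN distance floored by the bounding-box density, because front and
back surfaces overlay in a projection and collapse the raw median.

## Error metrics and classification protocol

MAPE, RMSE and the determination coefficient compare system measurements y
against manual references x. The determination coefficient is implemented
exactly as the system formula it reproduces,
`R² = 1 − Σ(x_i−y_i)² / Σ(x_i−ȳ)²` with ȳ the mean of the *system*
values; note this differs from the textbook definition (which centres the
denominator on x̄) and can exceed textbook R² when the system is biased.
The denominator can only vanish when every manual value equals the system
mean; that case is flagged rather than raised.

Standardisation uses the population standard deviation (ddof = 0);
zero-variance columns are flagged and output as zeros. Tenfold
cross-validation shuffles with the given seed and stratifies by class
(plain random folds are available); reported accuracy is the mean of the
ten fold accuracies and precision/recall/F1 are macro-averaged over
classes and folds. Classifier settings follow the published protocol this
harness reproduces: CART (entropy, depth 4, random splitter), random
forest (depth 2, Gini, 24 estimators), SVM (RBF kernel, C = 6), Gaussian
naive Bayes, BP network (layers 100/50, 2000 iterations, initial learning
rate 3.237e-4), XGBoost (20 estimators, depth 5, learning rate 0.3,
logistic loss). Feature importances for the tree methods are fold-averaged
and normalised to sum 1.

## Problem sizes and determinism

The shipped tests and validation scripts run at desk scale: the reference
sphere at full scanner density (~44 k points), scenes of 25 grains at
12 pts/mm² (~220 k points), isolated grains at 35 pts/mm², and
classification tables of 200 grains. Every stochastic component (sampling,
noise, RANSAC, fold shuffling, tree/network fits) takes an explicit seed,
and identical seeds give bit-identical results on the same platform.

## Known limitations

- Scene-segmented grains lose their stage-contact band (occlusion plus the
  plane-removal margin), so lengths measured from scenes are lower bounds;
  dimension accuracy is specified for complete grain clouds.
- The prism-projection volume assumes the grain is star-shaped about its
  central plane; strongly concave grains would need the divergence
  estimator instead.
- The triangulation targets smooth, densely sampled, approximately
  closed surfaces; thin slivers or sampling gaps larger than the
  connection radius produce boundary loops that hole filling closes with
  flat fans.
- Touching grains are out of scope: the placement protocol's 20 mm
  spacing is assumed, and region growing will not split contacting
  objects.
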