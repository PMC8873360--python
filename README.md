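# grain3d

Desk-scale 3D point-cloud morphometry for cereal grains.

Grain shape (length, width, thickness, volume, surface area) and grain
plumpness (filled vs unfilled, i.e. developed vs undeveloped endosperm)
drive yield and are core measurements in rice, wheat and corn breeding.
Manual calliper measurement is slow and subjective; a structured-light
scanner can capture a whole stage of vertically placed grains as a dense
point cloud in minutes. `grain3d` implements the complete analysis side of
such a system — and, because no scanner is needed to test it, ships a
synthetic-scene generator with known ground truth so every stage is
verifiable against analytic solids.

The pipeline:

1. **Preprocessing** — principal-axes transform `T_A = M_T (T_0 − A)`
   (rows of `M_T` are covariance eigenvectors, `A` the centroid),
   voxel-grid downsampling to gravity centres, statistical outlier removal
   (drop points whose mean k-NN distance exceeds `mu + alpha*sigma`).
2. **Segmentation** — RANSAC fit of the sample-stage plane, removal of the
   stage, then region growing on normals and curvature to isolate each
   grain; grains are matched to their 6x4+1 placement-grid cells.
3. **Traits** — per grain: the oriented bounding box gives
   `l = x_max − x_min`, `w = y_max − y_min`, `h = z_max − z_min` in the
   principal frame; a greedy projection-style triangulation plus boundary
   hole filling gives a closed mesh; surface area is the Heron sum
   `S = Σ_i sqrt(p_i(p_i−a_i)(p_i−b_i)(p_i−c_i))`; volume is the
   central-plane prism sum `V = Σ_faces S_proj × |h_0|` (projected face
   area times absolute face-centroid height), cross-checked by the
   divergence-theorem estimator; the three principal-plane silhouettes
   give section areas `S_yz, S_xz, S_xy`, perimeters `C_yz, C_xz, C_xy`
   and compactness indices `c = C²/(4πA)`. Together with the ratio traits
   (`l/w`, `S/V`, `V/h`, ...) this yields 25 traits per grain.
4. **Analysis** — Z-score standardisation `X* = (X−μ)/σ`, Pearson
   correlation matrices, manual-vs-system error metrics (MAPE, RMSE, R²),
   and a six-method tenfold cross-validation harness (CART, random forest,
   SVM, Gaussian naive Bayes, BP neural network, XGBoost) with
   feature-importance ranking for filled/unfilled classification.

## Worked example

The tool validates its area and volume estimators the way a metrology lab
would: against a reference sphere. `python examples/01_sphere_validation.py`
prints:

```
points sampled        : 43982
surface area          : 1277.02 mm^2 (analytic 1256.64)
  relative error      : 1.62 %
volume (prism)        : 4207.29 mm^3 (analytic 4188.79)
  relative error      : 0.44 %
volume (divergence)   : 4180.11 mm^3  (independent estimator)
box extents           : 19.97 x 19.97 x 19.96 mm (true 20.00)
```

A 10 mm-radius sphere is sampled at scanner-like density (0.17 mm point
spacing) with 0.05 mm Gaussian surface noise; the measurement chain
recovers its surface area within 1.6 % and its volume within 0.5 % of the
analytic values, and the prism-projection volume agrees with the
independent divergence-theorem estimate.

The other examples cover the remaining capabilities, each printing what it
computes and the ground truth it is checked against:

- `examples/02_scene_to_traits.py` — simulate a 25-grain stage scan,
  segment it (25/25 grains recovered, bijective grid assignment) and score
  the recovered dimensions with MAPE/RMSE/R².
- `examples/03_single_grain_traits.py` — all 25 traits of one ellipsoidal
  grain next to their closed-form values.
- `examples/04_classify_filled_unfilled.py` — the tenfold-CV protocol on a
  simulated filled/unfilled trait table; thickness dominates the XGBoost
  importance ranking, as expected when the class contrast is endosperm
  development.

A thin CLI wraps the same library calls:

```sh
grain3d simulate --n-grains 25 --seed 3 --out scene.ply --truth truth.json
grain3d preprocess scene.ply --out pre.ply
grain3d segment pre.ply --layout 6x4+1 --out-dir grains/
grain3d traits grains/ --out traits.csv
grain3d classify traits.csv --method xgboost --seed 7
```

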