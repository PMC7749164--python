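# Methods

`skintopo` quantifies the micro-relief of skin-surface images by persistent
homology and uses the resulting descriptors to predict transepidermal water
loss (TEWL), the standard measure of skin-barrier function. This note
records the model, the numerical choices, and their rationale.

## Scientific model

Healthy skin relief is a regular network of sulci (furrows) enclosing
polygonal cristae (ridge plateaus). Barrier dysfunction correlates with a
loss of this regularity. Topology captures regularity directly: in a
superlevel-set filtration of a suitable scalar field over the image,
connected components (0-dimensional features) track sulci segments and
holes (1-dimensional features) track the enclosed crista cells. Regular
relief yields many holes with similar birth–death profiles; irregular
relief yields fewer, more dispersed ones.

## Pipeline

1. **Preprocess** — RGB frames are converted to luma grayscale (BT.601
   weights, rounded), optionally trimmed to a fixed 1400×1200 window from
   the top-left corner (removing vendor overlays at the frame edge), and
   decomposed with a 10-level `db1` wavelet (periodization mode). Zeroing
   the coarse levels removes illumination gradients; keeping levels 4–10
   retains the relief scales. The cleaned image is binarized with Otsu's
   between-class-variance threshold (the smallest maximizing threshold;
   pixels above it are white), and the white set optionally eroded with a
   3×3 cross element to thin spurious bridges.
2. **Filtration** — three scalar fields are supported:
   - *kNN density*: on a coarse node grid (spacing 10 px), the distance
     `r_k` to the k-th nearest white pixel (k = 100) gives the density
     estimate `k / (n_white · π · r_k²)`. Nodes whose radius is zero are
     capped at the smallest positive radius on the grid. Diagrams are
     log-scaled, since the density spans orders of magnitude.
   - *Signed distance*: Manhattan distance to the opposite colour,
     positive on white, negative on black; a one-colour image receives the
     sentinel ±(width + height).
   - *Raw grayscale* intensities.
3. **Persistence** — superlevel-set cubical persistent homology of the
   field. Components use 8-connectivity with a union-find sweep in
   decreasing value order under the elder rule; holes are bounded
   4-connected components of the complement, obtained by a dual
   increasing-order sweep with a virtual outside node. Each pair carries
   the grid coordinates of its birth (local maximum) and death
   (merge/filling) locations, so features can be mapped back onto the
   image. Zero-persistence pairs are dropped; the one surviving component
   is flagged essential with the global minimum as a death sentinel.
4. **Diagram summaries** — pairs are re-expressed as mid-life
   `(birth + death)/2` and life-time `birth − death`. Ten per-image
   scalars (counts plus mean/SD of mid-life and life-time per dimension;
   sample SD, `n−1`) feed a univariate screen: one simple linear
   regression of TEWL on each of 14 variables (age, sex, temperature,
   humidity, and the ten topology summaries), with Benjamini–Hochberg
   false-discovery-rate adjustment.
5. **Vectorization** — for multivariate prediction, each diagram dimension
   is embedded on a 20×20 partition of the (mid-life, life-time) plane
   whose extent is fitted on training diagrams only. Either raw
   per-region counts (followed by a near-zero-variance column filter,
   frequency ratio > 95/5 and unique fraction < 10%) or a persistence
   image: each point contributes an isotropic Gaussian (σ = 0.1 by
   default) weighted linearly by life-time, integrated per region in
   closed form via Gaussian CDF differences.
6. **Regression** — subjects (never images) are split 70/30. Features are
   standardized and reduced by PCA, keeping components with variance
   contribution > 0.01; age, sex, temperature, and humidity are appended.
   Seven regressors are available (random forest with 200 trees, RBF SVM,
   elastic net, linear and tree gradient boosting, a small MLP, ordinary
   least squares), each tuned over a small grid by 10× repeated
   subject-grouped 10-fold cross-validation on RMSE. Per-image
   predictions are aggregated to subjects by the median, and R², RMSE,
   and MAE are reported on held-out subjects. Significance of the
   held-out R² is assessed by permuting subject-level responses
   (plug-in p-value over 20 permutations). For tree models, impurity
   importances are mapped back to diagram regions through the absolute
   PCA loadings and averaged over 10 re-splits; the generators of the
   top region can be overlaid on the source image (0-dim births red,
   1-dim deaths blue).

## Synthetic generator

Real reference images are private, so the package ships a generator whose
defaults emulate the study conditions at half linear scale: a 700×600 frame
whose texture is the Voronoi partition of a jittered hexagonal lattice
(pitch 40 px). Pixels within 6 px of a cell boundary (difference of the
two nearest-site distances) form the sulci network and are drawn *bright*
(210) against dark cristae (70) — this orientation makes Otsu's white set
the enclosing network, so that 1-dimensional persistence counts crista
cells, matching how the analysis treats real images where hollow sulci
receive large filtration values. A linear brightness gradient (30 levels)
and Gaussian pixel noise (SD 8) imitate illumination and sensor effects.

The per-subject regularity parameter `jitter` (site displacement SD as a
fraction of the pitch, drawn uniformly from [0.05, 0.85]) drives the
response: `TEWL = 8 + 15·jitter + N(0, 2)`, floored at 1 g·m⁻²·h⁻¹.
Moisture readings respond mostly to humidity and only weakly to texture.
Covariates are age (uniform 0–64), sex (Bernoulli ½), and narrow normal
temperature/humidity around controlled room conditions (20 °C, 50 %).
The subject, response-noise, and texture seed streams are independent, so
a slope-0 specification is an image-identical negative control. The
generator models texture regularity only; it does not attempt realistic
grayscale statistics, anisotropy, or site-specific relief patterns.

At this half scale the analysis defaults differ from full-frame settings
in two places, chosen once from the geometry: one erosion iteration
(ridges are ~6 px wide; heavier erosion disconnects the network) and
wavelet detail levels 4–10 (the relief scales of a 700-px frame).

## Numerical choices

- Otsu's threshold is implemented in-package because the exact tie-break
  (smallest maximizing threshold) matters for reproducibility; it is
  verified against an exhaustive 256-threshold search. Wavelets, distance
  transforms, labelling, OLS, FDR, PCA, and the regressors use
  PyWavelets, SciPy, statsmodels, scikit-learn, and XGBoost.
- The persistence core is authored here (the union-find/duality pair
  tracking is the package's contribution). It is verified in the test
  suite against an independent boundary-matrix-reduction oracle on a
  subdivided cubical complex that realizes 8-connectivity, against
  connected-component labelling at every threshold, and against the Euler
  characteristic.
- All stochastic steps (cohort generation, splits, cross-validation,
  estimators, permutations) derive from explicit seeds; a rerun with the
  same configuration is bit-reproducible.

## Limitations

- Absolute accuracies on real cohorts depend on instrumentation and
  population; the shipped experiments demonstrate behaviour on synthetic
  cohorts only.
- The dim-0/dim-1 sweep is pure Python/NumPy; full-resolution
  (1400×1200) signed-distance filtrations work but take minutes per
  image, so grid-based kNN filtrations are the default for cohort-scale
  runs.
- Permutation p-values use 20 permutations by default; resolution below
  0.05 requires raising `n_permutations`.
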