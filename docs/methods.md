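# Methods

## Model overview

`brainmux` models brain aging through the spatial redistribution of tissue
contrast in structural T1 volumes. Each subject's registered, skull-stripped
volume is tiled by a fixed template grid of rectangular patches
(10 × 15 × 20 voxels along the coronal, axial, and sagittal directions; 300
per hemisphere, 600 in total). Each patch is read as a 3000-component
intensity vector, and the absolute Pearson correlation between every pair of
vectors defines a weighted, symmetric 600 × 600 network per subject — one
layer of a multiplex whose node set (the patches) is shared across the
cohort. Because all subjects occupy the same template space, node *i* covers
approximately the same anatomical district in everyone, and age-related
change in tissue composition shows up as change in the layer's weights.

Eight nodal metrics summarize each layer:

- **strength** `s_i = Σ_j w_ij`, the weighted degree;
- **inverse participation** `Y_i = Σ_j (w_ij / s_i)²`, the concentration of a
  node's weight over its neighbors (1 for a single dominant connection,
  1/(N−1) for uniform weights);
- **multistrength** `m_i = s_i · A / o_i`, the layer's strength relative to
  the across-layer mean, where `o_i` is the overlapping strength (strength
  summed over the A reference layers);
- **multi-inverse participation** `Ym_i = (s_i / o_i)²`, the layer's squared
  share of the node's across-layer strength;
- the **degree-conditional mean** of each of the four, where node *i*
  receives the mean of the metric over all nodes with its exact degree
  (Kronecker-delta matching; equal-width degree binning is available for
  highly heterogeneous degree sequences).

Stacked metric-major this gives M = 8 × |N| features per subject (4800 at
the default grid). A feedforward network with four hidden layers of 200,
100, 50, and 20 tanh units regresses chronological age on these features;
Ridge, Lasso, Random Forest, and ε-SVR serve as baselines. Performance is
assessed by repeated k-fold cross-validation (MAE, RMSE, Pearson ρ per
repetition), residual heteroscedasticity by the Breusch-Pagan test, and
age-range effects by per-bin metrics with a Kruskal-Wallis comparison of
absolute-error distributions.

## Design choices in detail

**Degree on a dense weighted graph.** The conditional metrics require a
degree, which a fully connected weighted network does not naturally have.
Degrees are defined by a weight cutoff τ (`k_i = #{j : w_ij ≥ τ}`), default
the per-layer median of off-diagonal weights. The median guarantees a
non-degenerate degree distribution on arbitrary inputs; τ is configurable
and recorded with every result.

**Multiplex reference and leakage.** `m` and `Ym` depend on the cohort
through the overlapping strength `o_i`. During cross-validation the
reference is computed from training-fold layers only and frozen before test
subjects are featurized (`MultiplexFeatureSource`), so no test-subject
information reaches any feature. The normalization `s·A/o` makes `m_i = 1`
for a layer that matches the multiplex average at node *i*, `2` for one with
twice the average strength, and so on; the convention is switchable
(`mode="overlap"` yields the plain overlapping strength) so alternative
multiplex conventions can be compared.

**Grid selection.** Tiling a brain-shaped mask rarely yields exactly 300
boxes per hemisphere, so the grid tiles each hemisphere's mask bounding box
(anchored at its minimum corner) and keeps the 300 boxes with the highest
in-mask occupancy, ties resolved by corner-lexicographic order. Patch boxes
are half-open, 0-based, and axis-aligned; for odd sagittal dimensions the
left hemisphere takes ⌊dim/2⌋ slices. The grid is computed once from the
template and reused for every subject.

**Zero-variance handling.** A constant patch vector has no defined
correlation; its weights are set to 0 with a warning. Isolated nodes
(s_i = 0) get Y_i = 0 rather than NaN so the feature matrix stays finite.

**Deep net training.** The backend is a multilayer perceptron trained with
Adam (learning rate 10⁻³, up to 400 epochs, L2 weight decay 10⁻⁴, early
stopping on a 10% validation split, seed-controlled initialization). Targets
are z-scored internally and mapped back at prediction, since tanh output
paths train poorly on raw year scales. A constant training target is
predicted exactly (the mean is the closed-form least-squares solution and
the validation R² that drives early stopping is undefined there). Features
are z-scored with training-fold statistics before every model, deep or
classical.

**Feature importance.** Importance follows the weight-path construction
over the first two hidden layers: absolute weights are column-normalized
into shares P and Q, multiplied along every input→hidden1→hidden2 path, and
summed; the vector is rescaled to max 1. Selection repeats the ranking over
50 (default) random 90% subject subsamples, marks the top 5% quantile per
run, and keeps features whose occurrence count beats a one-sided binomial
test at rate q with Bonferroni correction over the M features. The selection
net defaults to strong weight decay (L2 = 1): weight-path importance is only
informative when irrelevant input weights are shrunk, and L2 spreads weight
across correlated informative inputs rather than letting each random
initialization pick an arbitrary sparse subset.

**Heteroscedasticity test.** Squared residuals are regressed on
chronological age (the natural lifespan covariate; switchable to predicted
age), LM = n·R² against χ²(1). Constant squared residuals short-circuit to
(0, 1) with a warning.

**Age bins.** Default edges 7/20/40/60/80 with half-open bins and a closed
last bin, so boundary ages are assigned deterministically. The
Kruskal-Wallis test compares per-bin absolute errors by default (signed
errors optional); empty bins are skipped with a warning.

## Synthetic phantoms

The volume-tier generator emulates the two gross effects of aging visible
to this pipeline: GM-like intensity falls linearly with age
(−0.002 intensity/year from 0.50) and the CSF-like outer shell thickens
(+0.001 normalized thickness/year from 0.05), inside two cuboid
"hemispheres" of nested tissue shells (CSF 0.10 / GM / WM 0.80 on the
normalized T1-like scale). Subject-level variability comes from a smoothed
Gaussian texture (correlation length 3 voxels, SD 0.02) plus voxelwise noise
(SD 0.01). The default hemisphere extent (60 × 150 × 100) makes the default
patch grid tile exactly 300 full boxes per side; a reduced extent
(30 × 75 × 40, 60 nodes) is used for desk-scale end-to-end runs. Ages are
drawn uniformly on 7–80 years (optionally stratified into the four lifespan
bins).

What the phantoms do **not** emulate: cortical geometry, registration error,
scanner/site effects, non-monotone developmental change, and MRI physics
(bias fields, artifacts). Passing the end-to-end tests therefore shows that
the pipeline recovers a monotone tissue-composition signal through the
network representation — not that it attains any particular accuracy on real
cohorts.

The feature-tier generator plants `n_signal` columns following
`a·age_n + b·σ((age−mid)/12)` (signed coefficient magnitudes uniform on
[0.5, 1.5], noise SD 0.1) among standard-normal null columns, with ground
truth indices returned, for fast tests of the regression and selection
stages.

## Problem sizes and numerical conventions

Desk-scale defaults used by the shipped tests and the acceptance script:
120-subject phantom cohorts on the 60-node grid under 10-fold × 5 CV;
feature-selection checks with n = 300, M = 100, 20 resampling runs at a
15% marking quantile; Breusch-Pagan calibration with 1000 null simulations
of n = 500. The full 600-node grid is exercised for structural checks
(grid counts, one 600 × 600 layer, the 4800-column feature row).

Weights are stored in double precision with the upper triangle computed once
and mirrored, so symmetry is bit-exact. Grid construction, feature assembly,
and cross-validation are deterministic given their seeds; per-repetition and
per-fold seeds are derived arithmetically from the base seed so that nested
procedures (e.g. the sample-size curve at fraction 1.0) reproduce the plain
repeated-CV result exactly.

## Known limitations

- The multistrength/multi-inverse-participation conventions and the degree
  threshold are package choices among several defensible multiplex
  conventions; all are config-switchable and recorded in outputs.
- The deep net's training schedule is a generic Adam setup, not a tuned
  replication of any particular framework's defaults.
- Min–max intensity normalization is sensitive to single outlier voxels;
  percentile clipping is available but off by default.
- Feature selection assumes the deep net fits well on 90% subsamples; on
  cohorts with weak signal the occurrence counts degrade gracefully toward
  the binomial null and nothing is selected.
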