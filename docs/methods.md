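# Methods

## Representative regional signals

The package's core operation replaces the conventional regional mean with a
pair-count-weighted average over "effective" voxels. All voxel pairs with
endpoints in different parcellation regions are scored by Pearson
correlation; self-pairs and negative correlations are set to zero, so pair
weights live in [0, 1]. A threshold r\* is selected on a grid
{δ, 2δ, …, 1 − δ} (default δ = 0.01) as the largest value at which every
region still owns at least one voxel with a surviving pair. The
representative series of a region is Σ_k (N_k/N)·A_k over its voxels, with
N_k the surviving-pair count of voxel k and N = Σ_k N_k, i.e. a convex
combination of the effective voxels' series.

Decisions taken where the procedure is genuinely open:

* **Threshold rule.** The feasibility criteria alone admit every threshold
  below some maximum; we return the *largest* feasible grid value — the most
  selective definition of "effective" that still covers all regions. The
  retention comparison is inclusive (r ≥ r\*), which makes the feasibility
  region monotone in the threshold and the scan reproducible.
* **Pair budget.** Pairs are composed exhaustively whenever the number of
  cross-region pairs is at most 2×10⁶ (exact at desk scale); above that a
  seeded uniform sample without replacement is drawn (default 100 pairs per
  voxel). Criterion I is evaluated on the computed pair set: only scored
  pairs can certify a voxel as effective, so exhaustive mode gives the
  strict interpretation.
* **Degenerate voxels.** Constant (zero-variance) series have no defined
  correlation and are excluded before pairing, with a logged count.
* **Effectiveness is single-pass:** a surviving pair certifies both of its
  endpoints; we do not require the partner voxel to be effective in turn
  (the fixed-point variant would be strictly harder to satisfy and is not
  needed for the criteria to make sense).

## Networks

Regional signals are correlated into a full weighted graph under the same
zeroing rule. Two simplifications:

* **Spanning tree.** Because edge weights are correlations (affinity, not
  cost), the "minimum spanning tree" of connectome practice is implemented
  as the *maximum*-total-weight spanning tree via Kruskal on descending
  weights — identical to the minimum tree on distance 1 − r. The
  positive-weight graph must be connected; disconnection raises an error
  reporting the component count.
* **Sparsity thresholding.** The budget is round(S·n(n−1)/2) edges
  (round-half-away-from-zero, a fixed rule for cross-implementation
  reproducibility), kept in descending weight with ties broken by ascending
  (i, j) index. Edge sets are therefore nested across the standard sweep
  S ∈ {6, 12, 18, 24, 30, 36}%. Connectivity is *not* enforced by default;
  an `ensure_connected` option unions the spanning-tree edges into each
  thresholded graph, and the achieved sparsity is recorded either way.

## Node metrics

Degree is the binary connection count (not strength). Betweenness is exact
weighted betweenness with edge length 1/w (the standard choice in weighted
connectome toolboxes; scale-invariant in weight ratios), computed via
Brandes' algorithm; the alternative 1 − w transform is available as an
option. Clustering is Onnela's weighted coefficient with weights normalised
by the network maximum. Normalized betweenness b_i = B_i/⟨B⟩ has mean
exactly 1; it is undefined (reported NaN, no hubs) when every B_i = 0, as on
a complete graph. Hub calls use the conventional strict cutoff b_i > 1.7.

## Group analysis

Per node and per metric (degree, BC, clustering), groups are compared by
Welch's t-test — group variances are nowhere asserted equal, so the pooled
variant would be unjustified. Bonferroni calibration multiplies p by
m = 3 × n_nodes (the full family of one pairwise comparison; the family must
be pinned for reproducibility), capped at 1. A node is selected as a feature
when ≥ 2 of its 3 calibrated p-values fall below α = 0.05; zero-variance
degenerate tests get p = 1 with a logged note.

Classification uses an RBF-kernel SVM with stratified k-fold (default 10)
cross-validation. Within every training fold: feature selection is refit
(selecting on the whole cohort leaks test information and is offered only as
a clearly labelled *descriptive* mode), features are standardised with
training-fold statistics, and C and γ are chosen by an inner 3-fold grid
search over log-spaced values (no values are prescribed a priori, so they
must be data-driven and fold-contained). When a training fold selects no
node — common under strict Bonferroni at small n — the classifier falls back
to all-node features; this adds no leakage and keeps the null at chance
while still using the metric information. Accuracy, specificity and
sensitivity come from pooled out-of-fold predictions with the patient group
as positive class. Everything is deterministic given the seed.

Group hub tables are computed descriptively from group-averaged full
adjacency matrices thresholded at 12% sparsity; the per-node BC contrast
uses Welch t-tests on normalized betweenness with an n_nodes Bonferroni
family and reports the direction of significant changes.

## Synthetic cohorts

The generator emulates the *shape and statistical structure* the method
assumes, not scanner physics:

* A parcellation of R connected, near-equal regions grown by round-robin
  BFS from farthest-point seeds over an ellipsoidal foreground (a stand-in
  for an anatomical atlas that removes any external dependency while
  preserving the 90-label contract; R is configurable).
* One latent series per region drawn from a stationary Gaussian AR(1)
  process (lag-1 autocorrelation 0.3) whose innovation covariance is the
  group's R × R matrix; the AR construction preserves the planted
  cross-region correlations exactly while giving the temporal smoothness of
  band-passed BOLD. Default T = 130 time points (the order implied by a
  140-volume acquisition minus 10 discarded); any T ≥ 20 is accepted.
* Each voxel is `fraction · latent + noise` with fraction 0.8 and baseline
  noise SD 1.0. Per-voxel noise scales are log-normal (σ = 0.75), giving a
  several-fold spread of voxel quality within a region — the heterogeneity
  regime (partial-volume voxels, vascular artefacts, variable tSNR) that
  motivates weighting voxels at all. With homogeneous voxels the unweighted
  mean is the statistically optimal representative and any weighting scheme
  can only match it; heterogeneous noise is the minimal realistic condition
  under which voxel selection pays off. The noise-free, fraction-1 limit
  still makes all voxels of a region exactly identical.
* Group differences are planted through covariance: per-group base
  correlation plus "hub" regions whose correlation to all others is
  elevated (eigenvalue-clipped back to a valid correlation matrix).

What the generator does **not** model: hemodynamic response, motion,
physiological noise, spatial smoothing correlations between neighbouring
voxels, registration error. Passing tests therefore demonstrate correctness
and calibration of the *pipeline* under its assumed data model, not
performance on real ADNI-like data.

## Study conditions for the simulation experiments

Chosen once as desk-scale conditions: 20-region parcellations on an
8×8×6 grid (~200 voxels), T = 80, 15 subjects per group, exhaustive
pairing, 12% sparsity networks, 10-fold CV, 20 replicates for the
method-comparison and hub-recovery studies; metric-level calibration
studies use 90 nodes and 30 subjects per group (200 null replicates for
the family-wise selection rate, 50 for planted-effect power, 20 cohorts
for the null CV band). The patient group has base/hub correlations
0.20/0.45 against the control's 0.35/0.70 at shared noise settings.

At this scale the conventional-mean arm of the comparison often performs at
or *below* chance: its node metrics carry so little group signal that the
fold-wise SVM fits training noise. The comparison claim is therefore
directional (the highly-available representative's accuracy ≥ the mean's in
the large majority of replicates), not a reproduction of any particular
accuracy level, which at full cohort size (hundreds of subjects, thousands
of voxels per region) would differ.

## Known limitations

* The threshold search is global: one r\* for the whole brain, set by the
  worst-connected region. A region-wise threshold would be a different
  method.
* Sparsity-thresholded graphs can be disconnected (see `ensure_connected`).
* Betweenness ties at equal path length depend on floating-point equality;
  with continuous correlation weights exact ties essentially never occur.
* The SVM grid is small by design; at desk scale a larger grid only
  increases variance of the fold-wise choice.
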