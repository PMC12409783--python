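# Methods

`stweave` analyses spot-based spatial transcriptomics (ST) data with a
paired histology image.  Each spot carries three views: a gene
expression profile, an image-derived feature vector from the histology
patch under the spot, and a spatial coordinate.  The package provides
the operators to refine and combine these views, the diagnostics to
decide *which* combination a dataset supports, and a ground-truth
simulator to benchmark the whole loop.

## Working representation

Every modality is reduced to the top *q* = 20 principal components of
its (filtered, optionally normalized) feature matrix.  Features
detected in fewer than 1% of spots (`min_frac = 0.01`, threshold
`ceil(min_frac * n)`, "detected" = nonzero) are dropped first.  Count
data are total-count normalized and log1p-transformed; the pipeline
skips this step automatically when a matrix contains negative values
(e.g. the simulator's Gaussian features).  PCA uses a deterministic
sign convention (largest-magnitude loading positive), so results are
bit-reproducible.  All spot-to-spot similarity used downstream is the
negative Euclidean distance in this 20-PC space.

## Image featurization

The slide is cut into per-spot square patches (default 64 px, even
sizes, half-open windows centered by the floor convention;
out-of-bounds pixels padded white, matching H&E background).  The
default featurizer is the RGB profile: per channel, the mean, standard
deviation, and a normalized `hist_bins`-bin intensity histogram
(F = 3·(2 + bins)).  It is deterministic, needs no downloads, and
separates morphologies that differ in stain color/texture intensity.
ImageNet-pretrained VGG16/ResNet50 backends (penultimate pooled layer)
are available behind the optional `cnn` extra; a seeded random-weight
"tiny-random" network exercises the CNN contract in tests.  Only the
RGB path is required anywhere.

## Spatial-aware refinement

Two single-pass convex-combination smoothers (output values stay inside
the local input range; constant input is a fixed point):

* **SME smoothing** of expression: for spot i and spatial neighbors
  N(i), weights `w_ij = max(0, cos(img_i, img_j)) · exp(−d_ij²/(2h²))`,
  smoothed profile `(x_i + Σ w_ij x_j)/(1 + Σ w_ij)`.  Rectifying
  negative cosines keeps weights nonnegative.  The bandwidth h defaults
  to the median nearest-neighbor distance, which self-scales between
  grid units and pixels.
* **Spatial kernel refinement** of a latent embedding: row-normalized
  Gaussian kernel `K_ij = exp(−d_ij²/(2h²))` applied to the embedding
  matrix.  It interpolates between the identity (h→0) and the global
  column mean (h→∞) and commutes with orthogonal transforms of the
  latent space.  This fills the pipeline slot of spatially aware
  dimension-reduction methods without their probabilistic machinery.

Spatial neighbors default to kNN with k = 6 (hex-packed Visium arrays
have six immediate neighbors) and to 4-connectivity grid adjacency on
integer-lattice (simulated) coordinates; the choice and k are config
knobs echoed into every report because results depend on them.
Externally computed spot-similarity matrices (e.g. from an MCMC-based
spatial clustering) can enter integration through a classical-MDS
adapter (`similarity_to_embedding`) with distances 1 − similarity.

## Weighted-nearest-neighbor integration

Per-spot modality weights measure relative predictive power.  For
modality m with embedding z^m: the *within* prediction of spot i is the
mean of z^m over i's kNN computed in m; the *cross* prediction is the
mean over i's kNN computed in the other modality.  The score

    r_i^m = (‖z_i^m − cross‖ − ‖z_i^m − within‖) / s_i^m,

with `s_i^m` the distance to i's nearest within-modality neighbor
(+1e−12), is large when m's own neighborhood predicts the profile much
better than the other modality's neighborhood.  Weights are the two-way
softmax of (r^gene, r^image): always in [0,1], summing to 1, and
exactly 0.5 for identical modalities.  This closed form preserves the
defining mechanism of published WNN (per-spot modality weighting) while
remaining recomputable by a straight-line oracle in the tests.  One
consequence worth noting: the weights reward *internal* predictability,
so a modality whose rows were permuted (correspondence destroyed,
structure kept) still earns ~0.5 — only a genuinely structureless
modality is down-weighted.

Fused affinities over the union of both modalities' kNN edge sets
(k_nn = 20):

    θ_ij = w_gene_i · exp(−d_gene(i,j)/σ_i^g) + w_image_i · exp(−d_img(i,j)/σ_i^m),

with local bandwidth σ_i = distance to the ⌈k_nn/2⌉-th within-modality
neighbor.  `affinity_fuse` pins both weights at 0.5 (unweighted
baseline); `concat_embed` concatenates globally standardized matrices
scaled by α and 1−α.  Fused graphs are clustered by spectral clustering
on the max-symmetrized affinity matrix (Leiden with resolution
bisection as the alternative); embeddings by seeded k-means with fixed
cluster counts.

Strategies compose as "+"-joined token strings — GENE, IMAGE, SME, SK,
WNN, FUSE, CONCAT — e.g. `SME+SK+WNN` smooths expression, embeds both
modalities, kernel-refines both, then fuses.  Published combination
names map onto this grammar (gene + spatially aware PCA → `GENE+SK`,
SME-normalized pipeline → `SME`, spatially aware refinement of both
modalities followed by WNN → `SK+WNN`, and so on).

## Diagnostics and the recommender

All three diagnostics run on 20-PC spaces:

* **Average Similarity**: per spot, mean distance to |N(i)| seeded
  random non-neighbors minus mean distance to neighbors; pass when
  ≥ 0.  The pass fraction measures overall spatial coherence.
* **High-Similarity Non-Neighbor (HSNN)**: per spot, the 95th-percentile
  similarity over all non-neighbors (linear-interpolation quantile)
  minus the best (X) / median (Y) neighbor similarity; X > 0 flags the
  spot.  This pinpoints locality exceptions — e.g. distant twins.  A
  caption-style variant (best non-neighbor instead of the quantile) was
  considered and rejected as too sensitive: a single similar distant
  spot flags almost everything.
* **Modality Concordance**: Euclidean distances of 5000 seeded random
  distinct spot pairs in each modality; a pair is discordant when it is
  in the closest 10% of one modality and the farthest 10% of the other.
  Verdict "consistent" when the discordant fraction ≤ 0.05.  The corner
  quantiles and cutoff are package choices — under fully independent
  isotropic modalities the expected discordant fraction is
  2·0.1·0.1 = 0.02, so 0.05 separates "independent-level" disagreement
  from structured conflict.

The recommender needs both spatial diagnostics to pass a threshold
(default 0.90: observed datasets cluster at 93–99% when coherent and
74–84% when not) for the spatial verdict: (spatial, concordant) →
spatial-aware processing + integration (`SK+WNN`); (¬spatial,
concordant) → integration only (`WNN`); (spatial, ¬concordant) →
spatial-aware only (`GENE+SK`); (¬spatial, ¬concordant) → plain gene
PCA (`GENE`).  Mixed spatial verdicts count as not-spatial, which
reproduces the observed kidney-style routing to integration.  Per-spot
non-neighbor sampling excludes only i and N(i).

## Simulator

Defaults: 30×30 lattice (900 spots), k = 10 clusters (k ∈ {4,6,8,10}
supported, even k required by the confounding), 200 genes, 100 image
features, marker effect μ = 1, noise σ = 1, 20 disjoint markers per
group, entry-wise Bernoulli dropout on expression only.  Centers sit on
a jittered near-square sub-lattice.  Distinct pattern: nearest-center
labels (spatially exclusive territories).  Ambiguous pattern: labels
sampled from a distance softmax with bandwidth τ; τ="auto" bisects the
*expected* nearest-center agreement to 0.80 ± 0.005 (closed form, no
sampling), so ~20% of spots sit in "wrong" territory.  Modality
confounding merges cluster pairs — (0,1)(2,3)… for genes,
(1,2)…(k−1,0) for image — so each modality resolves only k/2 groups
while the pair of group labels identifies every cluster; the per-run
information ceiling ARI(truth, merged groups) is computable exactly.
`render_synthetic_slide` paints each spot's patch with its image
group's color plus pixel noise, giving the image pathway an end-to-end
fixture.

What the simulator does *not* emulate: count-valued (NB/ZINB)
expression, within-cluster spatial autocorrelation, spatially smooth
expression gradients, stain variation, or partial/overlapping
confounding.  Two consequences matter when reading test results.
First, at 90% entry-wise dropout the surviving group signal of this
generator falls below the PCA detectability threshold at this problem
size for any μ/σ (the dropout mask contributes variance d(1−d)μ² that
scales with the signal itself), so gene-PC diagnostics and gene-only
clustering sit near chance there — dropout-aggregated diagnostic
percentages are far below those of coherent real tissue, and fusing
the gene modality at 90% dropout cannot improve on the undropped image
modality.  Second, hard pairwise merging makes same-group spots
exchangeable in similarity rank, which puts a floor of roughly
1 − 0.75^|N(i)| on the HSNN flagging rate regardless of noise level.
Both behaviors are properties of the stated generator, not
implementation artifacts; the acceptance script reports whatever the
stated conditions produce.

## Numerical choices

kNN ties break to the lower spot index; k-means uses 10 seeded
restarts; the softmax and Gaussian kernels are computed with
max-subtraction in the log domain so extreme bandwidths do not
underflow; quantiles are linear-interpolation throughout; a master seed
fans out to per-stage seeds through a CRC32-keyed SeedSequence, so any
stage can be re-run independently and all outputs are bit-reproducible
given (config, seed).  Benchmark problem sizes in the tests (10
replicates per condition, 900-spot grids; 3 replicates for the
slowest aggregate checks) keep the full suite in the minutes range.

## Known limitations

Real published datasets (HER2 breast, PDAC, DLPFC, mouse kidney,
Visium HD) need external downloads and pretrained CNN weights; the
package ships only parameter presets (`stweave.presets`) to attempt
them out-of-band, and their printed ARIs are not reproduced here.
External spatial methods (probabilistic spatial PCA, MCMC spatial
clustering, density-aware spectral fusion, NMF/CCA-family factor
methods) are out of scope; the adapter interface accepts their output
similarity matrices instead.
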