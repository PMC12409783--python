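# stweave

Multi-modal analysis of spot-based spatial transcriptomics (ST) with a
paired histology image: per-spot image featurization, spatial-aware
refinement, weighted-nearest-neighbor (WNN) modality integration,
spatial-coherence diagnostics that recommend an analysis strategy, a
ground-truth simulator, and ARI-based evaluation.

## Who this is for

ST experiments (Visium-style arrays) measure three views per capture
spot: gene expression **G**, image-derived features **I** from the
histology patch under the spot, and spatial location **S**.  Many
analysis strategies exist — use genes alone, smooth them spatially,
fold in morphology, fuse genes and image per spot — and none wins on
every dataset.  `stweave` is for analysts who want (a) the building
blocks of these strategies behind one grammar, and (b) *diagnostics*
that say which strategy a given dataset actually supports, instead of
trying all of them.

## The core pieces

**Per-spot WNN fusion.** Each modality m is embedded in its top-20 PC
space z^m.  Spot i's modality score compares how well z_i^m is
predicted by the mean of its k nearest neighbors computed *within* m
versus computed in the *other* modality:

    r_i^m = ( ||z_i^m − ẑ_i^cross|| − ||z_i^m − ẑ_i^within|| ) / s_i^m

(s_i^m = distance to the nearest within-m neighbor).  Per-spot weights
w_i = softmax(r_i^gene, r_i^image) ∈ [0,1], w_gene + w_image = 1, and
fused affinities over the kNN-union edge set are

    θ_ij = w_gene_i · e^{−d_gene(i,j)/σ_i^g} + w_image_i · e^{−d_img(i,j)/σ_i^m}.

**Diagnostics.**  With similarity = −Euclidean distance on top-20 PCs:
*Average Similarity* (mean similarity to spatial neighbors vs an equal
number of random non-neighbors, per spot), *High-Similarity
Non-Neighbor* (best/median neighbor similarity vs the 95th-percentile
non-neighbor similarity, flagging locality exceptions), and *Modality
Concordance* (gene vs image distances of 5000 random spot pairs).  The
verdict triple maps to a strategy: spatial-aware + integration
(`SK+WNN`), integration only (`WNN`), spatial-aware only (`GENE+SK`),
or plain gene PCA (`GENE`).

**Simulator.**  Lattice spots, k cluster centers, labels either by
nearest center (*distinct* territories) or sampled from a distance
softmax (*ambiguous*, bandwidth calibrated to 80% nearest-center
agreement).  Cluster identity is confounded across modalities — genes
merge cluster pairs (0,1)(2,3)…, image merges (1,2)…(k−1,0) — so only
the two modalities together identify all k clusters.  Gaussian marker
blocks, entry-wise dropout on expression only.  Ground truth makes
every strategy scoreable by adjusted Rand index (ARI).

See `docs/methods.md` for assumptions, defaults, and limitations.

## Worked example

```python
import stweave as sw
from stweave.pipeline import auto_analyze

# distinct spatial pattern, 10 clusters, 60% expression dropout
res = sw.simulate(sw.SimConfig(pattern="distinct", k=10, dropout=0.6, seed=1))
out = auto_analyze(res.dataset, K=10, seed=1)
r = out.report
print(f"avg_pass_frac    {r.avg_pass_frac:.3f}")
print(f"hsnn_pass_frac   {r.hsnn_pass_frac:.3f}")
print(f"discordant_frac  {r.discordant_frac:.4f}")
print(f"recommendation   {r.recommendation.value}")
print(f"strategy         {out.strategy}")
print(f"ARI vs truth     {out.ari:.3f}")
```

prints

```
avg_pass_frac    0.720
hsnn_pass_frac   0.352
discordant_frac  0.0196
recommendation   INTEGRATION_ONLY
strategy         WNN
ARI vs truth     0.486
```

Reading it: at 60% dropout the gene PC space keeps only partial
spatial coherence (72% of spots are closer to their neighbors than to
random spots; the non-neighbor diagnostic flags many locality
exceptions, a known property of this generator's merged cluster
groups), while the two modalities agree (2% discordant pairs), so the
recommender routes to modality integration without spatial smoothing
and the fused WNN clustering reaches ARI 0.486 against truth.  For
scale: either modality alone can reach at most ARI ≈ 0.63 here (each
resolves only 5 of the 10 clusters by construction), and fusing both
at low noise recovers truth exactly (ARI = 1.0).

The same run from the shell:

```bash
stweave simulate --pattern distinct --k 10 --dropout 0.6 --seed 1 --out sim/
stweave auto --data sim/ --k 10 --seed 1 --out run/
stweave plot --report run/report.json --kind hsnn --out hsnn.png   # needs diagnose --full for per-spot plots
```

Other subcommands: `features` (patch → RGB/CNN features), `preprocess`,
`refine` (SME / spatial kernel), `integrate --strategy "SK+WNN"`,
`diagnose`, `cluster`, `evaluate`.  Every run writes a `config.json`
echoing all effective parameters and the seed.

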