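# Methods

## Problem and model

`maskst` integrates two or more spatial-transcriptomics (ST) slices — each a
spot×gene count matrix with 2-D spot coordinates — into a single joint latent
embedding in which (i) spots from different slices mix freely (batch
correction), (ii) spots of the same tissue domain cluster together, and
(iii) the tissue's geometric organization is preserved. The pipeline has five
steps:

1. **Initial integration.** A masked graph-attention autoencoder is trained
   on the disjoint union of within-slice spatial k-NN graphs (k = 6).
2. **Joint clustering.** Full-covariance Gaussian-mixture EM on the initial
   embedding assigns every spot of every slice to one of `n_clusters` shared
   domains.
3. **Cluster-wise local alignment.** For each adjacent slice pair and each
   shared cluster, an optimal-transport coupling matches the two clusters'
   spots; assembled block-diagonally these couplings are the "hard-links".
4. **Coordinate unification.** The couplings place all slices in one
   coordinate frame (three strategies below).
5. **Final integration.** The same autoencoder is retrained on a pooled
   spatial k-NN graph (k = 15) over the unified coordinates, with hard-link
   edges added, producing the final joint embedding.

### Backbone

Each graph-attention layer computes, for spot *u* with neighborhood N(u)
(which always contains *u* itself),

    h_u' = ε( Σ_{v∈N(u)} α_uv · W h_v ),
    α_uv = softmax_{v∈N(u)} σ(aᵀ [W h_u ⊕ W h_v]),

with σ the logistic function, ε = ELU on hidden layers and identity on
output layers. The encoder has widths in→512→32 and the decoder mirrors it
(32→512→in) with its own attention parameters. A two-layer MLP projector maps
the 32-dim latent space to a representation space, and a generator — an
encoder+projector of identical architecture but independent parameters —
processes the *unmasked* input to produce latent regression targets.

### Losses

A random subset of spots (fraction `mask_rate`, default 0.1) has its input
features zeroed; before decoding, latent rows of a second random subset
(`remask_rate`, default 0.1, resampled every epoch over all nodes) are zeroed
again. Training minimizes a scaled cosine error on the masked
reconstructions,

    L_masked = mean_{i∈V̄} (1 − cos(x_i, z_i))^γ,       γ = 1 by default,

plus `lambda_latent` (default 1) times the same error between projector
outputs and generator targets over all spots, and — in a second training
phase — a triplet loss over cross-slice mutual nearest neighbors (MNNs, k = 5
in embedding space):

    L_triplet = mean max(d(a,p) − d(a,n) + α, 0),       α = 1 (margin).

Anchors/positives are MNN pairs between consecutive slices (both
orientations); negatives are drawn uniformly from the positive's slice.
Triplets are refreshed from the current embedding every `triplet_refresh`
(default 100) epochs. All parameter sets (encoder, decoder, projector,
generator) are trained jointly with one Adam optimizer (lr 1e-3), full-graph
(no minibatching). Rows of zero norm get cos := 0 (unit loss contribution)
with a warning.

The model is implemented on a small reverse-mode automatic-differentiation
engine over numpy (`maskst._autodiff`), with graph gather/scatter expressed
through precomputed sparse incidence structure; gradients are verified
against central finite differences in the test suite.

### Spatial graphs

k-NN neighborhoods are **tie-inclusive**: every spot whose distance equals
the k-th nearest distance (relative tolerance 1e-6) is included. On lattice
coordinates whole neighbor shells are exactly equidistant, and the usual
index-order tie-breaking would make the graph — and therefore the embedding —
depend on row order; tie inclusion makes graph construction
permutation-invariant and exactly symmetric for coincident spot clouds.
Graphs are union-symmetrized, unit-weighted (attention learns the
weighting), and every node carries a self-edge.

### Cluster-wise coupling (hard-links)

For each shared cluster with spot sets I (slice h) and J (slice h+1), the
solver couples the intra-cluster spatial distance matrices D_I and D_J by
conditional gradient (Frank–Wolfe) with exact line search on

    (1 − α_f) ⟨C, Π⟩  +  α_f Σ_{i,k,j,l} (D_I[i,k] − D_J[j,l])² Π_ij Π_kl,

where C is the squared-Euclidean cost between the spots' normalized
expression profiles and `fuse_alpha` = α_f (default 0.1) weights the
geometric Gromov–Wasserstein (GW) term — the fused formulation of PASTE,
applied per cluster. `fuse_alpha = 1` (or absent C) gives pure GW on the
spatial distances; that path is cross-checked against exhaustive
permutation enumeration on small clusters.

Why fused, and why partial: with hard uniform marginals, pure GW between a
full cluster and a partially overlapping one *must* stretch the smaller
cluster across the larger (the marginals force every spot's mass to be
placed), which misplaces correspondences whenever slices overlap only
partially. The expression term disambiguates, and for size-mismatched
cluster pairs the fused solve additionally uses **partial OT via a dummy
node**: per-spot capacity 1/max(|I|,|J|) on both sides, with a zero-cost
dummy on the smaller side absorbing the larger side's excess mass. The dummy
is exempt from the geometric term. Spots without a genuine counterpart ship
their mass to the dummy instead of corrupting real matches. The inner linear
OT steps are solved exactly (Hungarian assignment for balanced uniform
problems, HiGHS LP otherwise). Conditional-gradient runs are restarted from
several deterministic initializations (product measure, distance-profile
matching, linear-OT-on-C, and exact best-permutation for tiny blocks); the
lowest-objective solution is kept.

### Coordinate unification

* **Pairwise (default for 2 slices).** The coupling-weighted Procrustes
  problem min Σ π_ij ‖z_i − R z'_j − v‖² (orthogonal R) is solved in closed
  form by weighted centering + SVD, then refined by a trimmed re-fit on the
  argmax correspondences: residuals above twice the median are dropped and
  the rigid fit repeated (≤3 rounds). The refinement removes the small
  (~0.1 lattice pitch) offsets that diffuse coupling mass otherwise leaves
  and lets exactly-matching spots register to machine precision.
* **Replacement (default for >2 slices).** Every spot's highest-confidence
  counterpart (argmax of the row-normalized plan, ties to the lower index)
  is chained backward so each spot of slice i>1 inherits the coordinates of
  its chain ancestor on slice 1. Spots without transport mass keep their own
  coordinates.
* **Transformation.** Per-slice rigid transforms (translation + rotation)
  are found by seeded differential evolution (population 30, 200
  generations, translations bounded by the bounding-box diagonal, rotation
  in [−π, π]), minimizing the mean distance between correspondence-linked
  spots plus a penalty on the fraction of spots without a nearby counterpart
  (radius = 2× median spot spacing). Recommended for many (>10) slices.
* **Horizontal.** No coordinate change; hard-links enter the final graph as
  direct edges (for sections that tile side-by-side rather than stack).

In the final graph the hard-link edges are merged into the pooled k = 15
spatial k-NN graph in all modes except the soft-link-only ablation.

### Ablation variants

`full` (everything), `mlp` (no graph aggregation, no masking or latent
loss), `gae` (graph autoencoder without masking/latent loss), `hardlink_only`
(no triplet loss), `mask_only` (no triplet or latent loss), `softlink_only`
(final stage trained on the original intra-slice graphs, without hard-link
edges or unified coordinates). Initial integration and alignment are
identical across variants so the hard-links are comparable.

### Metrics

Alignment maps each anchor spot to its Euclidean-nearest partner in the
joint embedding (ties toward the lower index). On that map: layer-wise
alignment accuracy (distribution of ordinal layer shifts; sums to 1),
matching ratio (#anchors / #distinct aligned spots; 1.0 is the bijective
ideal), spot-to-spot alignment accuracy and matched-pair Pearson (ground
truth required), and aligned/misaligned/unaligned spot classes. Batch mixing
is the integration LISI with Gaussian-kernel neighbor weights
(perplexity 30), normalized to [0,1] as (LISI−1)/(B−1). Geometry
preservation compares spatial coordinates with a 2-D projection of the
embedding — PCA by default (deterministic; UMAP optional) — via the Pearson
correlation of pairwise-distance vectors (negatives clipped to 0) and
standardized Procrustes dissimilarity, averaged over slices.

## Synthetic data

The generator emulates a Visium-like capture array: spots on a unit-pitch
triangular lattice (rectangular or hexagon-shaped footprint), 7 ordered
layer domains as horizontal row bands, and disjoint per-layer gene programs:
block k of the gene panel has negative-binomial mean 5.0 inside layer k and
0.5 outside, with NB shape 2.0. An optional per-gene log-normal batch factor
(`batch_shift`) emulates slice-level batch effects. Default study scale:
hexagonal patch of radius 16 (817 spots), 200 genes.

Partial-overlap partners are built by rotation and cropping: coordinates are
rotated, spots landing within half a lattice pitch of an original site are
snapped onto it (inheriting that site's expression, which defines the
ground-truth correspondence), and the rest are dropped. For the 20–100%
overlap series the rotation is the lattice's own 60° symmetry about a
lattice-site pivot: rotated spots coincide exactly with sites, and the
retained region — the intersection of the hexagonal footprint with its
displaced image — is a contiguous lens. The pivot displacement is the coarse
overlap knob and a guillotine crop along x, bisected on its threshold, is
the fine knob (achieved ratios within 0.005 of the 20/40/60/80/100%
targets). An arbitrary-angle centroid rotation is also available; at
non-symmetry angles, snapping produces moiré-patterned (fragmented)
retained sets, which is why the series construction uses symmetry angles.

What the simulation does **not** emulate: UMI saturation and depth
variation between slices, irregular tissue boundaries, spatial expression
gradients within a domain, segmentation/fiducial artifacts, and genuinely
distinct adjacent sections (matched spots are expression-identical by
construction). Passing the synthetic acceptance checks therefore
demonstrates the pipeline's mechanics — graph construction, coupling,
registration, embedding — not performance on real adjacent-section data.

## Numerical and design choices

* Activation ε = ELU (the backbone only requires a smooth nonlinearity);
  encoder/decoder outputs linear so embeddings and reconstructions are
  unconstrained.
* Single attention head by default; multi-head averaging available.
* Default epochs 500+500 in the model config; the bundled experiments and
  acceptance runs use 60+60 at a few hundred to ~1600 spots, which is past
  the loss plateau at that size.
* Masking counts are deterministic given the seed
  (round(rate·N) without replacement); the re-mask subset is resampled
  every epoch over all nodes (configurable to stay within the masked set).
* Generator trained by gradient jointly with the rest (not an
  exponential-moving-average copy).
* GMM clustering uses a permutation-invariant initialization (quantile bins
  along the first principal component) so cluster labels are equivariant
  under spot reordering; reg_covar 1e-4.
* One root seed fans out to per-stage seeds via a splitmix-style hash of the
  stage name; every random draw flows through a stage generator, making
  whole runs bit-reproducible.
* Degenerate inputs: all-zero count rows normalize to zero rows; zero-norm
  cosine terms contribute 1 with a warning; a coupling concentrated on one
  pair degenerates Procrustes to a pure translation; an empty triplet list
  contributes zero loss with a warning; clusters present on only one slice
  of a pair are skipped and reported.

## Known limitations

* Full-graph training on dense numpy arrays: practical to a few thousand
  spots per slice; no minibatching or GPU path.
* The expression term in the fused coupling assumes the shared gene panel is
  informative across slices; with strong uncorrected batch effects
  `fuse_alpha` closer to 1 (more geometric) may be preferable.
* Layer-wise accuracy assumes a totally ordered label set; non-layered
  tissues should read only shift 0 (same-domain fraction).
* The replacement sweep copies coordinates (many-to-one); downstream
  k-NN graphs tolerate coincident spots by construction, but the unified
  coordinates are not a diffeomorphic reconstruction of the tissue.
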