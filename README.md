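# maskst — multi-slice spatial transcriptomics integration

Serial tissue sections profiled with spatial transcriptomics (Visium,
MERFISH, Stereo-seq, …) measure the same anatomy across slices, but each
slice arrives in its own coordinate frame, with its own batch effects, and
often only partially overlapping its neighbors. `maskst` learns a **joint
spot embedding** across slices that mixes batches, separates tissue domains,
and preserves the tissue's geometry — so downstream clustering, spot-to-spot
alignment, trajectory and marker analyses can treat the slices as one
dataset.

## Method

The core is a masked graph-attention autoencoder trained twice:

1. **Initial integration** on the union of within-slice spatial k-NN graphs
   (k = 6). Each attention layer aggregates
   `h_u = ε(Σ_{v∈N(u)} α_uv W h_v)` with
   `α_uv = softmax_v σ(aᵀ[W h_u ⊕ W h_v])`; encoder widths in→512→32, a
   mirrored decoder, plus an MLP projector and a generator twin on the
   unmasked input. Training zeroes a random subset of spot profiles
   (re-masking their latent rows before decoding) and minimizes the scaled
   cosine error `mean_{i∈V̄}(1 − cos(x_i, z_i))^γ` plus a latent consistency
   term, then adds a triplet loss `max(d(a,p) − d(a,n) + α, 0)` over
   cross-slice mutual nearest neighbors ("soft-links").
2. **Joint clustering** (Gaussian-mixture EM) of the initial embedding
   yields shared domains; per domain, a cluster-wise optimal-transport
   coupling of the two slices' spatial distance structures (fused
   Gromov–Wasserstein, conditional-gradient solver) produces spot-to-spot
   **hard-links**, which unify the slices' coordinates (weighted Procrustes
   for a pair; a backward coordinate-replacement sweep or per-slice rigid
   transforms for stacks) and enter the final k-NN graph (k = 15) as edges.
   **Final integration** retrains the autoencoder on that graph.

Also included: integration metrics (spot alignment accuracy, matching
ratio, layer-wise accuracy, matched-pair Pearson, iLISI, isometry
correlation, Procrustes dissimilarity, ARI), ablation variants
(`full`, `mlp`, `gae`, `hardlink_only`, `mask_only`, `softlink_only`), and a
synthetic hexagonal-lattice slice simulator with exact spot-level ground
truth at 20–100% overlap. See `docs/methods.md` for the full model
description and design choices.

## Worked example

Simulate a layered reference slice and a fully overlapping partner, then
integrate:

```bash
maskst simulate --overlaps 1.0 --radius 9 --layers 7 --genes 100 \
    --seed 0 --out sim/
maskst integrate --slices sim/reference.h5ad sim/overlap100.h5ad \
    --n-clusters 7 --seed 0 --out out/
```

`simulate` prints the achieved overlap of each partner:

```
overlap100: 271 spots, achieved overlap 1.000 (rotation 0.00°)
```

`integrate` writes `embedding.npy`/`embedding.csv` (542×32 joint embedding),
`clusters.tsv`, a per-pair `mapping_*.tsv` (anchor spot, aligned spot,
transport weight) and `manifest.json`, and prints the metrics report:

```json
{
  "ilisi": 0.9826528665148488,
  "isometry_correlation": 0.04126210389478957,
  "procrustes_dissimilarity": 0.9943372508445707,
  "ari": 0.4462888422880567
}
```

iLISI ≈ 0.98 means spots from the two slices are almost perfectly
interleaved in the embedding (1 = ideal mixing); ARI compares the GMM
domains against the generating layer labels. The geometry scores compare
spot coordinates with a deterministic 2-D *PCA* projection of the 32-dim
embedding and are conservative on this synthetic: layered bands make the
leading embedding axes effectively one-dimensional (layer identity), so
little of the 2-D layout survives two PCA axes (UMAP projections, available
via `metrics.embed_2d(..., method="umap")`, recover more). Spot-level
alignment is nonetheless exact here — see the reproduction script below.
In Python the same pipeline is three calls:

```python
from maskst import generate_hex_slice, rotate_and_crop, preprocess, run
from maskst.pipeline import PipelineConfig

ref = generate_hex_slice(footprint="hexagon", radius=9, n_genes=100, seed=0)
pair = rotate_and_crop(ref, 0.0)                  # exact-copy partner
slices = preprocess([ref, pair.simulated])
result = run(slices, PipelineConfig(n_clusters=7, seed=0))
result.embedding.matrix                           # spots × 32
```

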