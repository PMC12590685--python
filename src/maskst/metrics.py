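"""Integration-quality metrics.

Alignment metrics map each anchor spot to its Euclidean-nearest partner
in the joint embedding and score the map against domain labels
(layer-wise accuracy, matching ratio, aligned/misaligned/unaligned spot
classes) or against a simulation ground truth (spot alignment accuracy,
Pearson correlation of matched embeddings).  Mixing is quantified by a
normalized integration LISI; geometry preservation by the correlation of
pairwise distances (isometry correlation) and by Procrustes
dissimilarity between spatial coordinates and a 2-D projection of the
embedding (PCA by default, for determinism).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import procrustes as _scipy_procrustes
from scipy.spatial.distance import cdist, pdist
from scipy.stats import pearsonr
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "PairAlignment",
    "align_by_embedding",
    "classify_spots",
    "layer_wise_alignment_accuracy",
    "matching_ratio",
    "spot_alignment_accuracy",
    "pearson_matched",
    "ilisi",
    "isometry_correlation",
    "procrustes_dissimilarity",
    "ari",
    "embed_2d",
]


@dataclass
class PairAlignment:
    """Nearest-neighbor map from every slice-1 (anchor) spot to one
    slice-2 spot, with optional aligned/misaligned/unaligned classes."""

    aligned_to: np.ndarray            # anchor index -> slice-2 index
    anchor_class: np.ndarray | None = None   # per anchor: aligned/misaligned
    unaligned: np.ndarray | None = None      # slice-2 spots hit by no anchor


def align_by_embedding(H1: np.ndarray, H2: np.ndarray) -> PairAlignment:
    """Map each row of H1 to its Euclidean-nearest row of H2 (ties toward
    the lower index)."""
    H1, H2 = np.asarray(H1, float), np.asarray(H2, float)
    D = cdist(H1, H2)
    aligned = D.argmin(axis=1)
    hit = np.zeros(H2.shape[0], dtype=bool)
    hit[aligned] = True
    return PairAlignment(aligned_to=aligned, unaligned=np.flatnonzero(~hit))


def classify_spots(alignment: PairAlignment, labels1: np.ndarray,
                   labels2: np.ndarray) -> PairAlignment:
    """Anchor spots whose aligned partner shares their domain label are
    'aligned', otherwise 'misaligned'; slice-2 spots hit by no anchor are
    'unaligned'."""
    labels1, labels2 = np.asarray(labels1), np.asarray(labels2)
    same = labels1 == labels2[alignment.aligned_to]
    cls = np.where(same, "aligned", "misaligned")
    return PairAlignment(aligned_to=alignment.aligned_to, anchor_class=cls,
                         unaligned=alignment.unaligned)


def layer_wise_alignment_accuracy(alignment: PairAlignment,
                                  labels1: np.ndarray, labels2: np.ndarray,
                                  layer_order: list) -> np.ndarray:
    """Distribution of anchor→aligned layer shifts (|rank difference| in an
    ordered layer list).  Entry 0 is the same-layer fraction; the vector
    sums to 1."""
    rank = {lab: r for r, lab in enumerate(layer_order)}
    r1 = np.array([rank[l] for l in np.asarray(labels1)])
    r2 = np.array([rank[l] for l in np.asarray(labels2)[alignment.aligned_to]])
    shifts = np.abs(r1 - r2)
    L = len(layer_order)
    counts = np.bincount(shifts, minlength=L)[:L]
    return counts / counts.sum()


def matching_ratio(alignment: PairAlignment) -> float:
    """#anchor spots / #distinct aligned spots; 1.0 for a bijection on
    equal-size slices."""
    n_anchors = len(alignment.aligned_to)
    n_distinct = len(np.unique(alignment.aligned_to))
    return n_anchors / n_distinct


def spot_alignment_accuracy(alignment: PairAlignment,
                            truth_map: np.ndarray) -> float:
    """Fraction of anchor spots whose aligned partner equals the ground-
    truth correspondence (−1 marks anchors without a truth partner)."""
    truth = np.asarray(truth_map)
    valid = truth >= 0
    if not valid.any():
        raise ValueError("truth map is empty")
    return float((alignment.aligned_to[valid] == truth[valid]).mean())


def pearson_matched(H1: np.ndarray, H2: np.ndarray,
                    truth_map: np.ndarray) -> float:
    """Pearson r over the concatenated embedding coordinates of all ground-
    truth matched spot pairs."""
    truth = np.asarray(truth_map)
    valid = truth >= 0
    a = np.asarray(H1, float)[valid].ravel()
    b = np.asarray(H2, float)[truth[valid]].ravel()
    return float(pearsonr(a, b)[0])


def _simpson_weights(dists: np.ndarray, perplexity: float,
                     tol: float = 1e-5, max_iter: int = 64) -> np.ndarray:
    """Gaussian-kernel neighbor weights with entropy matched to
    log(perplexity) by bisection on the bandwidth (t-SNE style)."""
    target = np.log(perplexity)
    beta = 1.0
    lo, hi = 0.0, np.inf
    d2 = dists ** 2
    for _ in range(max_iter):
        w = np.exp(-beta * (d2 - d2.min()))
        s = w.sum()
        p = w / s
        h = -np.sum(p * np.log(np.maximum(p, 1e-300)))
        if abs(h - target) < tol:
            break
        if h > target:
            lo = beta
            beta = beta * 2 if not np.isfinite(hi) else (beta + hi) / 2
        else:
            hi = beta
            beta = (lo + beta) / 2
    return p


def ilisi(embedding: np.ndarray, slice_of: np.ndarray,
          perplexity: float = 30.0) -> float:
    """Integration LISI normalized to [0, 1].

    Per spot, Gaussian-kernel neighbor weights define batch probabilities
    whose inverse Simpson index lies in [1, B]; the mean is rescaled as
    (LISI − 1)/(B − 1), so 0 means a single slice (no mixing possible)
    and 1 perfectly even mixing across all B slices."""
    emb = np.asarray(embedding, float)
    slice_of = np.asarray(slice_of)
    batches, inv = np.unique(slice_of, return_inverse=True)
    B = len(batches)
    if B == 1:
        return 0.0
    n = emb.shape[0]
    k = int(min(n - 1, max(int(3 * perplexity), 10)))
    nn = NearestNeighbors(n_neighbors=k + 1).fit(emb)
    dists, idx = nn.kneighbors(emb)
    lisi = np.empty(n)
    for i in range(n):
        nbr_d = dists[i, 1:]
        nbr_i = idx[i, 1:]
        p = _simpson_weights(nbr_d, min(perplexity, k))
        pb = np.bincount(inv[nbr_i], weights=p, minlength=B)
        lisi[i] = 1.0 / np.sum(pb ** 2)
    return float(np.clip((lisi.mean() - 1.0) / (B - 1.0), 0.0, 1.0))


def embed_2d(embedding: np.ndarray, method: str = "pca",
             seed: int = 0) -> np.ndarray:
    """Deterministic 2-D projection of the latent embedding (PCA default;
    UMAP optional)."""
    emb = np.asarray(embedding, float)
    if emb.shape[1] == 2:
        return emb
    if method == "pca":
        return PCA(n_components=2, random_state=seed).fit_transform(emb)
    if method == "umap":
        import umap
        return umap.UMAP(n_components=2, random_state=seed).fit_transform(emb)
    raise ValueError(f"unknown 2-D projection method {method!r}")


def isometry_correlation(coords_per_slice: list[np.ndarray],
                         embedding_2d_per_slice: list[np.ndarray]) -> float:
    """Mean per-slice Pearson correlation between the pairwise-distance
    vectors of spatial coordinates and of the 2-D embedding; negative
    correlations are clipped to 0 so the score lies in [0, 1]."""
    vals = []
    for c, e in zip(coords_per_slice, embedding_2d_per_slice):
        r = pearsonr(pdist(np.asarray(c, float)), pdist(np.asarray(e, float)))[0]
        vals.append(max(0.0, float(r)))
    return float(np.mean(vals))


def procrustes_dissimilarity(coords_per_slice: list[np.ndarray],
                             embedding_2d_per_slice: list[np.ndarray]) -> float:
    """Mean per-slice standardized residual after optimal translation,
    scaling and orthogonal (rotation/reflection) superposition; in [0, 1],
    0 for any similarity transform of the coordinates."""
    vals = []
    for c, e in zip(coords_per_slice, embedding_2d_per_slice):
        _, _, d = _scipy_procrustes(np.asarray(c, float), np.asarray(e, float))
        vals.append(float(d))
    return float(np.mean(vals))


def ari(labels_pred, labels_true) -> float:
    """Adjusted Rand Index between two labelings (1 = perfect agreement)."""
    return float(adjusted_rand_score(np.asarray(labels_true),
                                     np.asarray(labels_pred)))
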