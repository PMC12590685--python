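"""Soft-links: mutual-nearest-neighbor triplets and the triplet loss.

Cross-slice spot pairs that are mutually k-nearest in the joint embedding
space act as anchor/positive pairs; negatives are drawn uniformly from
the positive's slice.  The loss max(d(a,p) − d(a,n) + α, 0), averaged
over triplets, pulls matched spots together and pushes random cross-slice
spots apart.  Triplets are refreshed from the latest embedding every
`triplet_refresh` epochs during phase-2 training.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from . import _autodiff as adf
from ._autodiff import Tensor

__all__ = ["Triplet", "mutual_nearest_neighbors", "build_triplets",
           "triplet_loss", "refresh_schedule", "triplets_for_slices"]

_EPS = 1e-12


@dataclass(frozen=True)
class Triplet:
    """Global node ids: anchor and positive on different slices (mutual
    nearest neighbors), negative from the positive's slice."""

    anchor: int
    positive: int
    negative: int


def _knn_indices(D: np.ndarray, k: int) -> np.ndarray:
    """Row-wise k smallest columns of D, ties toward lower index."""
    order = np.argsort(D, axis=1, kind="stable")
    return order[:, :k]


def mutual_nearest_neighbors(H1: np.ndarray, H2: np.ndarray,
                             k: int = 5) -> list[tuple[int, int]]:
    """Pairs (i, j) with j among i's k nearest rows of H2 and vice versa
    (Euclidean distance in embedding space)."""
    if k < 1:
        raise ValueError("k must be ≥ 1")
    H1, H2 = np.asarray(H1, float), np.asarray(H2, float)
    if H1.size == 0 or H2.size == 0:
        raise ValueError("empty embedding")
    D = cdist(H1, H2)
    k12 = min(k, H2.shape[0])
    k21 = min(k, H1.shape[0])
    nn12 = _knn_indices(D, k12)
    nn21 = _knn_indices(D.T, k21)
    back = [set(row) for row in nn21]
    pairs = []
    for i in range(H1.shape[0]):
        for j in nn12[i]:
            if i in back[j]:
                pairs.append((i, int(j)))
    return pairs


def build_triplets(mnn_pairs, slice1_nodes: np.ndarray, slice2_nodes: np.ndarray,
                   rng: np.random.Generator, max_retries: int = 100
                   ) -> list[Triplet]:
    """Two triplets per MNN pair (each orientation); negatives uniform over
    the opposite slice.  Node id arrays map local indices to global ids."""
    slice1_nodes = np.asarray(slice1_nodes)
    slice2_nodes = np.asarray(slice2_nodes)
    triplets: list[Triplet] = []
    for i, j in mnn_pairs:
        a1, p1 = int(slice1_nodes[i]), int(slice2_nodes[j])
        for a, p, pool in ((a1, p1, slice2_nodes), (p1, a1, slice1_nodes)):
            neg = None
            for _ in range(max_retries):
                cand = int(pool[rng.integers(len(pool))])
                if cand != p:
                    neg = cand
                    break
            if neg is None:
                raise RuntimeError(
                    "could not sample a negative distinct from the positive "
                    f"(slice of size {len(pool)})")
            triplets.append(Triplet(anchor=a, positive=p, negative=neg))
    return triplets


def triplet_loss(H, triplets, alpha: float = 1.0):
    """Mean over triplets of max(d(a,p) − d(a,n) + α, 0), Euclidean d.

    Accepts a numpy embedding (returns float) or an autodiff tensor."""
    if alpha <= 0:
        raise ValueError("margin alpha must be > 0")
    if not triplets:
        warnings.warn("empty triplet list: triplet loss is 0", RuntimeWarning,
                      stacklevel=2)
        return 0.0
    a = np.array([t.anchor for t in triplets], dtype=np.intp)
    p = np.array([t.positive for t in triplets], dtype=np.intp)
    n = np.array([t.negative for t in triplets], dtype=np.intp)
    symbolic = isinstance(H, Tensor)
    Ht = H if symbolic else Tensor(np.asarray(H, float))
    Ha, Hp, Hn = (adf.gather_rows(Ht, idx) for idx in (a, p, n))
    dp = adf.sqrt(adf.add(adf.row_sum(adf.power(adf.sub(Ha, Hp), 2.0)), _EPS))
    dn = adf.sqrt(adf.add(adf.row_sum(adf.power(adf.sub(Ha, Hn), 2.0)), _EPS))
    per = adf.relu(adf.add(adf.sub(dp, dn), Tensor(alpha)))
    out = adf.mean_all(per)
    return out if symbolic else float(out.data)


def refresh_schedule(epoch: int, triplet_refresh: int = 100) -> bool:
    """True exactly when phase-2 epoch `epoch` starts a triplet refresh."""
    return epoch % max(int(triplet_refresh), 1) == 0


def triplets_for_slices(embedding: np.ndarray, slice_sizes: list[int],
                        k: int, rng: np.random.Generator) -> list[Triplet]:
    """MNN triplets for every consecutive slice pair of a stacked embedding."""
    offsets = np.concatenate([[0], np.cumsum(slice_sizes)])
    triplets: list[Triplet] = []
    for s in range(len(slice_sizes) - 1):
        n1 = np.arange(offsets[s], offsets[s + 1])
        n2 = np.arange(offsets[s + 1], offsets[s + 2])
        pairs = mutual_nearest_neighbors(embedding[n1], embedding[n2], k=k)
        triplets.extend(build_triplets(pairs, n1, n2, rng))
    return triplets
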