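"""Slice-level data structures, preprocessing and spatial graph construction.

A multi-slice spatial-transcriptomics experiment is represented as a list
of :class:`STSlice` objects (one tissue section each: counts, coordinates,
optional domain labels).  Preprocessing total-count normalizes and
log-transforms counts and restricts all slices to the intersection of
their per-slice highly-variable-gene sets, so every slice exposes the same
feature columns in the same order.  Spatial k-nearest-neighbor graphs —
within one slice or over the pooled coordinates of several slices — are
returned as :class:`MultiSliceGraph` objects: undirected, unit-weighted,
with a self-edge at every node.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc
import scipy.io
import scipy.sparse as sp

from ._utils import check_finite

__all__ = [
    "STSlice",
    "MultiSliceGraph",
    "PreprocessConfig",
    "preprocess",
    "build_intra_knn",
    "build_unified_knn",
    "read_slices",
    "read_slice_h5ad",
    "read_slice_csv",
    "write_slice_h5ad",
    "write_outputs",
]


@dataclass
class STSlice:
    """One tissue section: spot×gene counts, 2-D coordinates, optional labels."""

    slice_id: str
    spot_ids: list[str]
    counts: np.ndarray
    coords: np.ndarray
    gene_ids: list[str]
    expr: np.ndarray | None = None
    labels: np.ndarray | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.float64)
        if self.counts.ndim != 2:
            raise ValueError(f"slice {self.slice_id}: counts must be 2-D")
        if not np.issubdtype(self.counts.dtype, np.number):
            raise TypeError(f"slice {self.slice_id}: counts must be numeric")
        if np.any(self.counts < 0):
            raise ValueError(f"slice {self.slice_id}: counts must be nonnegative")
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.shape != (self.counts.shape[0], 2):
            raise ValueError(
                f"slice {self.slice_id}: coords shape {self.coords.shape} does not "
                f"match {self.counts.shape[0]} spots × 2")
        check_finite(self.coords, f"slice {self.slice_id} coords")
        n = self.counts.shape[0]
        if len(self.spot_ids) != n:
            raise ValueError(f"slice {self.slice_id}: {len(self.spot_ids)} spot ids "
                             f"for {n} count rows")
        if len(self.gene_ids) != self.counts.shape[1]:
            raise ValueError(f"slice {self.slice_id}: gene_ids/columns mismatch")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError(f"slice {self.slice_id}: gene_ids not unique")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape[0] != n:
                raise ValueError(f"slice {self.slice_id}: labels length mismatch")
        if self.expr is not None:
            self.expr = np.asarray(self.expr, dtype=np.float64)

    @property
    def n_spots(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def to_anndata(self) -> ad.AnnData:
        adata = ad.AnnData(
            X=self.counts.copy(),
            obs=pd.DataFrame(index=pd.Index(self.spot_ids, name="spot_id")),
            var=pd.DataFrame(index=pd.Index(self.gene_ids, name="gene_id")),
        )
        adata.obsm["spatial"] = self.coords.copy()
        adata.uns["slice_id"] = self.slice_id
        if self.labels is not None:
            adata.obs["domain"] = pd.Categorical(self.labels.astype(str))
        if self.expr is not None:
            adata.layers["normalized"] = self.expr.copy()
        return adata


@dataclass
class MultiSliceGraph:
    """Undirected unit-weight graph over the spots of one or more slices.

    ``node_index[i] = (slice_id, spot_id)`` fixes the global node ordering;
    ``pairs`` holds unique undirected edges as rows ``(u, v)`` with
    ``u <= v`` (so self-edges appear as ``(u, u)``).
    """

    node_index: list[tuple[str, str]]
    pairs: np.ndarray
    slice_of: np.ndarray  # per-node slice_id, same order as node_index

    def __post_init__(self):
        self.pairs = np.asarray(self.pairs, dtype=np.intp)
        n = len(self.node_index)
        if self.pairs.size and (self.pairs.min() < 0 or self.pairs.max() >= n):
            raise ValueError("edge endpoint out of range")
        lo = np.minimum(self.pairs[:, 0], self.pairs[:, 1])
        hi = np.maximum(self.pairs[:, 0], self.pairs[:, 1])
        canon = np.unique(np.column_stack([lo, hi]), axis=0)
        if canon.shape[0] != self.pairs.shape[0]:
            raise ValueError("duplicate edges in graph")
        self.pairs = canon
        has_self = np.zeros(n, dtype=bool)
        self_rows = self.pairs[:, 0] == self.pairs[:, 1]
        has_self[self.pairs[self_rows, 0]] = True
        if not has_self.all():
            raise ValueError("every node must carry a self-edge")

    @property
    def n_nodes(self) -> int:
        return len(self.node_index)

    @property
    def edges(self) -> list[tuple[int, int, float]]:
        out = []
        for u, v in self.pairs:
            out.append((int(u), int(v), 1.0))
            if u != v:
                out.append((int(v), int(u), 1.0))
        return out

    def directed_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays (dst, src): src ∈ N(dst), both directions plus self loops."""
        u, v = self.pairs[:, 0], self.pairs[:, 1]
        nonself = u != v
        dst = np.concatenate([u, v[nonself]])
        src = np.concatenate([v, u[nonself]])
        order = np.lexsort((src, dst))
        return dst[order], src[order]

    def neighbor_sets(self) -> list[set[int]]:
        sets: list[set[int]] = [set() for _ in range(self.n_nodes)]
        for u, v in self.pairs:
            sets[u].add(int(v))
            sets[v].add(int(u))
        return sets


@dataclass
class PreprocessConfig:
    """Normalization / feature-selection settings.

    n_hvgs: per-slice number of highly variable genes ("all" keeps every
        shared gene); target_sum: per-spot total after count normalization;
        hvg_flavor: dispersion ranking flavor passed to scanpy.
    """

    n_hvgs: int | str = "all"
    target_sum: float = 1e4
    log1p: bool = True
    hvg_flavor: str = "seurat"

    def __post_init__(self):
        if isinstance(self.n_hvgs, str):
            if self.n_hvgs != "all":
                raise ValueError("n_hvgs must be a positive int or 'all'")
        elif int(self.n_hvgs) < 1:
            raise ValueError("n_hvgs must be ≥ 1")
        if self.target_sum <= 0:
            raise ValueError("target_sum must be positive")


def _normalize_log(counts: np.ndarray, cfg: PreprocessConfig) -> np.ndarray:
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        expr = np.where(totals > 0, counts / totals * cfg.target_sum, 0.0)
    if cfg.log1p:
        expr = np.log1p(expr)
    return expr


def _hvg_set(expr: np.ndarray, gene_ids: list[str], cfg: PreprocessConfig) -> set[str]:
    if cfg.n_hvgs == "all" or int(cfg.n_hvgs) >= len(gene_ids):
        return set(gene_ids)
    if len(gene_ids) < 50:
        # binned dispersion z-scores are meaningless on tiny panels;
        # rank by raw dispersion (variance/mean of normalized counts)
        vals = np.expm1(expr) if cfg.log1p else expr
        mean = vals.mean(axis=0)
        disp = np.where(mean > 0, vals.var(axis=0) / np.maximum(mean, 1e-12), 0.0)
        top = np.argsort(-disp, kind="stable")[:int(cfg.n_hvgs)]
        return {gene_ids[j] for j in top}
    adata = ad.AnnData(X=expr.copy(),
                      var=pd.DataFrame(index=pd.Index(gene_ids, name="gene_id")))
    sc.pp.highly_variable_genes(adata, n_top_genes=int(cfg.n_hvgs),
                                flavor=cfg.hvg_flavor)
    return set(adata.var.index[adata.var["highly_variable"]])


def preprocess(slices: list[STSlice],
               cfg: PreprocessConfig | None = None) -> list[STSlice]:
    """Normalize, log-transform, and restrict to the shared HVG intersection.

    Every returned slice carries ``expr`` (spots × shared genes) with an
    identical gene order across slices.  HVGs are ranked per slice on the
    normalized log data, then intersected.
    """
    cfg = cfg or PreprocessConfig()
    if len(slices) < 2:
        raise ValueError("preprocess requires at least two slices")
    shared = set(slices[0].gene_ids)
    for s in slices[1:]:
        shared &= set(s.gene_ids)
    if not shared:
        names = ", ".join(s.slice_id for s in slices)
        raise ValueError(f"no genes shared across slices {names}")

    hvg_inter: set[str] | None = None
    normalized: list[np.ndarray] = []
    for s in slices:
        expr = _normalize_log(s.counts, cfg)
        normalized.append(expr)
        hvgs = _hvg_set(expr, s.gene_ids, cfg) & shared
        hvg_inter = hvgs if hvg_inter is None else (hvg_inter & hvgs)
    if not hvg_inter:
        names = ", ".join(s.slice_id for s in slices)
        raise ValueError(
            f"highly-variable-gene intersection across slices {names} is empty; "
            f"increase n_hvgs or use n_hvgs='all'")

    # deterministic shared gene order: order of appearance in slice 1
    order = [g for g in slices[0].gene_ids if g in hvg_inter]
    out = []
    for s, expr in zip(slices, normalized):
        col = {g: i for i, g in enumerate(s.gene_ids)}
        idx = np.array([col[g] for g in order], dtype=np.intp)
        out.append(STSlice(
            slice_id=s.slice_id,
            spot_ids=list(s.spot_ids),
            counts=s.counts[:, idx],
            coords=s.coords.copy(),
            gene_ids=list(order),
            expr=expr[:, idx],
            labels=None if s.labels is None else s.labels.copy(),
        ))
    return out


_TIE_RTOL = 1e-6


def _knn_pairs(coords: np.ndarray, k: int) -> np.ndarray:
    """Union-symmetrized k-NN pairs over one coordinate cloud.

    Neighborhoods are tie-inclusive: every spot whose distance equals the
    k-th nearest distance (within a small relative tolerance) is kept, so
    the graph does not depend on spot ordering — important on lattice
    coordinates, where whole neighbor shells are exactly equidistant.
    Returns unique undirected pairs (u <= v) including self-edges.
    """
    n = coords.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of spots ({n})")
    us, vs = [], []
    if n <= 4096:
        d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        kth = np.partition(d, k - 1, axis=1)[:, k - 1]
        cutoff = kth * (1 + _TIE_RTOL) + 1e-12
        for i in range(n):
            nbr = np.flatnonzero(d[i] <= cutoff[i])
            us.append(np.full(len(nbr), i))
            vs.append(nbr)
    else:
        from sklearn.neighbors import NearestNeighbors
        nn = NearestNeighbors(n_neighbors=min(4 * k + 8, n)).fit(coords)
        dist, idx = nn.kneighbors(coords)
        for i in range(n):
            drow, irow = dist[i], idx[i]
            nonself = irow != i
            drow, irow = drow[nonself], irow[nonself]
            cutoff = drow[k - 1] * (1 + _TIE_RTOL) + 1e-12
            keep = drow <= cutoff
            us.append(np.full(int(keep.sum()), i))
            vs.append(irow[keep])
    u = np.concatenate(us)
    v = np.concatenate(vs)
    lo, hi = np.minimum(u, v), np.maximum(u, v)
    pairs = np.column_stack([lo, hi])
    selfp = np.column_stack([np.arange(n), np.arange(n)])
    return np.unique(np.vstack([pairs, selfp]), axis=0)


def build_intra_knn(sl: STSlice, k: int = 6) -> MultiSliceGraph:
    """Spatial k-NN graph within one slice (default k=6), self-edges included."""
    if k < 1:
        raise ValueError("k must be ≥ 1")
    pairs = _knn_pairs(sl.coords, k)
    node_index = [(sl.slice_id, sid) for sid in sl.spot_ids]
    return MultiSliceGraph(node_index=node_index, pairs=pairs,
                           slice_of=np.array([sl.slice_id] * sl.n_spots))


def union_graphs(graphs: list[MultiSliceGraph]) -> MultiSliceGraph:
    """Disjoint union of per-slice graphs with offset global node ids."""
    node_index: list[tuple[str, str]] = []
    slice_of: list[np.ndarray] = []
    pairs = []
    offset = 0
    for g in graphs:
        node_index.extend(g.node_index)
        slice_of.append(g.slice_of)
        pairs.append(g.pairs + offset)
        offset += g.n_nodes
    return MultiSliceGraph(node_index=node_index, pairs=np.vstack(pairs),
                           slice_of=np.concatenate(slice_of))


def build_unified_knn(slices: list[STSlice], k: int = 15,
                      extra_edges: list[tuple[int, int]] | None = None,
                      ) -> MultiSliceGraph:
    """k-NN over the pooled coordinate cloud of all slices, plus hard-links.

    Global node ids follow slice concatenation order.  ``extra_edges`` are
    merged into the edge set without duplication (hard-link edges, e.g.
    for horizontally adjacent sections that share no coordinate frame).
    """
    if not slices:
        raise ValueError("build_unified_knn requires at least one slice")
    coords = np.vstack([s.coords for s in slices])
    pairs = _knn_pairs(coords, k)
    if extra_edges:
        ee = np.asarray(extra_edges, dtype=np.intp).reshape(-1, 2)
        lo, hi = np.minimum(ee[:, 0], ee[:, 1]), np.maximum(ee[:, 0], ee[:, 1])
        pairs = np.unique(np.vstack([pairs, np.column_stack([lo, hi])]), axis=0)
    node_index = [(s.slice_id, sid) for s in slices for sid in s.spot_ids]
    slice_of = np.concatenate([np.array([s.slice_id] * s.n_spots) for s in slices])
    return MultiSliceGraph(node_index=node_index, pairs=pairs, slice_of=slice_of)


# -- input / output --------------------------------------------------------

def read_slice_h5ad(path: str, slice_id: str | None = None,
                    label_key: str | None = None) -> STSlice:
    adata = ad.read_h5ad(path)
    if "spatial" not in adata.obsm:
        raise KeyError(f"{path}: obsm['spatial'] (spot coordinates) is missing")
    X = adata.X
    X = np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)
    if label_key is None and "domain" in adata.obs:
        label_key = "domain"
    labels = None
    if label_key is not None:
        if label_key not in adata.obs:
            raise KeyError(f"{path}: obs['{label_key}'] not found")
        labels = adata.obs[label_key].to_numpy()
    sid = slice_id or str(adata.uns.get("slice_id",
                                        os.path.splitext(os.path.basename(path))[0]))
    expr = None
    if "normalized" in adata.layers:
        expr = np.asarray(adata.layers["normalized"])
    return STSlice(slice_id=sid, spot_ids=list(map(str, adata.obs_names)),
                   counts=X, coords=np.asarray(adata.obsm["spatial"], dtype=float),
                   gene_ids=list(map(str, adata.var_names)), expr=expr, labels=labels)


def read_slice_csv(expr_path: str, coords_path: str,
                   labels_path: str | None = None,
                   slice_id: str | None = None) -> STSlice:
    """Read a slice from (CSV or MatrixMarket counts) + coordinates CSV."""
    sid = slice_id or os.path.splitext(os.path.basename(expr_path))[0]
    coords_df = pd.read_csv(coords_path, index_col=0)
    if coords_df.shape[1] < 2:
        raise ValueError(f"{coords_path}: need two coordinate columns")
    if expr_path.endswith(".mtx"):
        mat = scipy.io.mmread(expr_path).toarray()
        spot_ids = list(map(str, coords_df.index))
        if mat.shape[0] != len(spot_ids):
            raise ValueError(f"{expr_path}: {mat.shape[0]} rows vs "
                             f"{len(spot_ids)} coordinate rows")
        gene_ids = [f"gene_{j}" for j in range(mat.shape[1])]
    else:
        df = pd.read_csv(expr_path, index_col=0)
        try:
            mat = df.to_numpy(dtype=float)
        except (TypeError, ValueError) as e:
            raise TypeError(f"{expr_path}: non-numeric counts") from e
        spot_ids = list(map(str, df.index))
        gene_ids = list(map(str, df.columns))
    labels = None
    if labels_path is not None:
        labels = pd.read_csv(labels_path, index_col=0).iloc[:, 0].to_numpy()
    return STSlice(slice_id=sid, spot_ids=spot_ids, counts=mat,
                   coords=coords_df.iloc[:, :2].to_numpy(dtype=float),
                   gene_ids=gene_ids, labels=labels)


def read_slices(path_specs: list) -> list[STSlice]:
    """Read several slices.  Each item is an h5ad path or a dict with keys
    ``expr``, ``coords`` and optionally ``labels`` / ``slice_id``."""
    out = []
    for spec in path_specs:
        if isinstance(spec, dict):
            out.append(read_slice_csv(spec["expr"], spec["coords"],
                                      spec.get("labels"), spec.get("slice_id")))
        else:
            out.append(read_slice_h5ad(str(spec)))
    return out


def write_slice_h5ad(sl: STSlice, path: str) -> None:
    sl.to_anndata().write_h5ad(path)


def write_outputs(embedding, clusters, mappings, outdir: str,
                  node_index: list[tuple[str, str]] | None = None) -> list[str]:
    """Write embeddings (CSV+NPY), cluster assignments (TSV) and per-pair
    spot mappings (TSV: anchor_slice, anchor_spot, aligned_spot, weight)."""
    os.makedirs(outdir, exist_ok=True)
    written = []
    emb = np.asarray(embedding, dtype=np.float64)
    npy = os.path.join(outdir, "embedding.npy")
    np.save(npy, emb)
    written.append(npy)
    if node_index is not None:
        idx = pd.MultiIndex.from_tuples(node_index, names=["slice_id", "spot_id"])
    else:
        idx = pd.RangeIndex(emb.shape[0])
    df = pd.DataFrame(emb, index=idx,
                      columns=[f"dim_{j}" for j in range(emb.shape[1])])
    csv = os.path.join(outdir, "embedding.csv")
    df.to_csv(csv)
    written.append(csv)
    if clusters is not None:
        cpath = os.path.join(outdir, "clusters.tsv")
        pd.Series(np.asarray(clusters), index=idx, name="cluster").to_csv(cpath, sep="\t")
        written.append(cpath)
    if mappings:
        for pair_name, rows in mappings.items():
            mpath = os.path.join(outdir, f"mapping_{pair_name}.tsv")
            pd.DataFrame(rows, columns=["anchor_slice", "anchor_spot",
                                        "aligned_spot", "weight"]).to_csv(
                mpath, sep="\t", index=False)
            written.append(mpath)
    return written
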