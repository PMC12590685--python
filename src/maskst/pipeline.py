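"""Five-step orchestration: initial integration → joint clustering →
cluster-wise alignment (hard-links) → coordinate unification → final
integration, with the ablation variants exposed as configuration.

Variants:
  full          — masked reconstruction + latent + triplet losses, hard-links
  mlp           — no graph aggregation, no masking/latent; recon + triplet
  gae           — graph autoencoder without masking or latent loss
  hardlink_only — no triplet loss (soft-links removed)
  mask_only     — masked reconstruction only (no triplet, no latent)
  softlink_only — final graph without hard-link edges (intra-slice only)
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.mixture import GaussianMixture

from ._utils import derive_seed, rng_for, check_finite
from .data_model import (STSlice, MultiSliceGraph, build_intra_knn,
                         build_unified_knn, union_graphs, write_outputs)
from .local_alignment import (TransportPlan, RigidTransform, align_pair,
                              best_counterparts, coordinate_replacement_sweep,
                              coordinate_transformation_optimize,
                              refined_pair_transform, transform_coordinates,
                              TransformOptConfig)
from .masked_gat import MaskedGraphAutoencoder, ModelConfig
from .softlinks import triplets_for_slices
from . import metrics as _metrics

logger = logging.getLogger("maskst")

__all__ = ["JointEmbedding", "PipelineConfig", "PipelineResult",
           "IntegrationPipeline", "initial_integration", "joint_cluster",
           "final_integration", "run", "VARIANTS", "UNIFICATIONS"]

VARIANTS = {
    "full": {},
    "mlp": {"use_graph": False, "use_mask": False, "use_latent": False},
    "gae": {"use_mask": False, "use_latent": False},
    "hardlink_only": {"use_triplet": False},
    "mask_only": {"use_triplet": False, "use_latent": False},
    "softlink_only": {},
}

UNIFICATIONS = ("auto", "procrustes", "replacement", "transformation",
                "horizontal")


@dataclass
class JointEmbedding:
    """Spots × d latent matrix with slice and cluster annotations."""

    matrix: np.ndarray
    node_index: list[tuple[str, str]]
    slice_of: np.ndarray
    cluster_of: np.ndarray | None = None

    def __post_init__(self):
        check_finite(self.matrix, "joint embedding")
        if self.matrix.shape[0] != len(self.node_index):
            raise ValueError("embedding rows must match the node index")

    def per_slice(self) -> dict[str, np.ndarray]:
        return {sid: self.matrix[self.slice_of == sid]
                for sid in dict.fromkeys(self.slice_of.tolist())}


@dataclass
class PipelineConfig:
    """Everything the five-step pipeline needs."""

    model: ModelConfig = field(default_factory=ModelConfig)
    n_clusters: int = 7
    intra_k: int = 6
    unified_k: int = 15
    unification: str = "auto"
    variant: str = "full"
    gw_tol: float = 1e-9
    gw_max_iter: int = 50
    # fused-GW weight on the geometric term: couplings minimize
    # (1-fuse_alpha)*<embedding cost, plan> + fuse_alpha*GW(plan).
    # 1.0 recovers pure (unfused) GW on the spatial distances alone.
    fuse_alpha: float = 0.1
    transform_opt: TransformOptConfig = field(default_factory=TransformOptConfig)
    seed: int = 0

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; "
                             f"choose from {sorted(VARIANTS)}")
        if self.unification not in UNIFICATIONS:
            raise ValueError(f"unknown unification {self.unification!r}; "
                             f"choose from {UNIFICATIONS}")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be ≥ 1")

    def model_for_stage(self, stage: str) -> ModelConfig:
        cfg = {**asdict(self.model), **VARIANTS[self.variant]}
        cfg["seed"] = derive_seed(self.seed, stage)
        return ModelConfig(**cfg)


@dataclass
class PipelineResult:
    embedding: JointEmbedding
    initial_embedding: JointEmbedding
    clusters: np.ndarray
    plans: list[TransportPlan]
    transforms: list[RigidTransform] | None
    slices_unified: list[STSlice]
    metrics_report: dict
    stage_seconds: dict


def _stack_expr(slices: list[STSlice]) -> np.ndarray:
    for s in slices:
        if s.expr is None:
            raise ValueError(f"slice {s.slice_id} is not preprocessed "
                             "(expr missing); call preprocess first")
    return np.vstack([s.expr for s in slices])


def _node_annotation(slices: list[STSlice]):
    node_index = [(s.slice_id, sid) for s in slices for sid in s.spot_ids]
    slice_of = np.concatenate([np.array([s.slice_id] * s.n_spots)
                               for s in slices])
    return node_index, slice_of


def _fit_model(slices: list[STSlice], graph: MultiSliceGraph,
               cfg: PipelineConfig, stage: str) -> tuple[np.ndarray, MaskedGraphAutoencoder]:
    X = _stack_expr(slices)
    mcfg = cfg.model_for_stage(stage)
    model = MaskedGraphAutoencoder(mcfg)
    sizes = [s.n_spots for s in slices]
    rng = rng_for(cfg.seed, stage + ".triplets")
    triplet_fn = None
    if mcfg.use_triplet and len(slices) > 1:
        def triplet_fn(embedding):
            return triplets_for_slices(embedding, sizes, k=mcfg.mnn_k, rng=rng)
    model.fit(X, graph, triplet_fn=triplet_fn)
    return model.embedding_, model


def initial_integration(slices: list[STSlice],
                        cfg: PipelineConfig) -> JointEmbedding:
    """Steps 1–2: train on the disjoint union of intra-slice k-NN graphs
    with the combined masked/latent loss plus triplet soft-links."""
    graph = union_graphs([build_intra_knn(s, cfg.intra_k) for s in slices])
    emb, _ = _fit_model(slices, graph, cfg, "initial")
    node_index, slice_of = _node_annotation(slices)
    return JointEmbedding(matrix=emb, node_index=node_index, slice_of=slice_of)


def _pc1_quantile_means(X: np.ndarray, n_clusters: int) -> np.ndarray:
    """Permutation-invariant GMM mean initialization: bin the first
    principal component into quantile groups and take group means."""
    Xc = X - X.mean(axis=0)
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    pc = vt[0]
    if pc[np.argmax(np.abs(pc))] < 0:  # deterministic sign
        pc = -pc
    score = Xc @ pc
    edges = np.quantile(score, np.linspace(0, 1, n_clusters + 1))
    means = []
    for k in range(n_clusters):
        inside = (score >= edges[k]) & (score <= edges[k + 1])
        means.append(X[inside].mean(axis=0) if inside.any() else X.mean(axis=0))
    return np.asarray(means)


def joint_cluster(embedding: np.ndarray, n_clusters: int,
                  seed: int = 0) -> np.ndarray:
    """Joint model-based clustering: full-covariance Gaussian-mixture EM on
    the embedding, with a deterministic, order-invariant initialization."""
    X = np.asarray(embedding, float)
    if n_clusters > X.shape[0]:
        raise ValueError(f"n_clusters={n_clusters} exceeds {X.shape[0]} spots")
    if n_clusters == 1:
        return np.zeros(X.shape[0], dtype=int)
    gmm = GaussianMixture(n_components=n_clusters, covariance_type="full",
                          random_state=seed, reg_covar=1e-4, max_iter=300,
                          means_init=_pc1_quantile_means(X, n_clusters))
    return gmm.fit_predict(X)


def _split_labels(labels: np.ndarray, slices: list[STSlice]) -> list[np.ndarray]:
    out, start = [], 0
    for s in slices:
        out.append(labels[start:start + s.n_spots])
        start += s.n_spots
    return out


def _hard_link_edges(plans: list[TransportPlan],
                     slices: list[STSlice]) -> list[tuple[int, int]]:
    """Global-id edges from each spot of slice h+1 to its highest-
    confidence counterpart on slice h."""
    offsets = np.concatenate([[0], np.cumsum([s.n_spots for s in slices])])
    edges = []
    for h, plan in enumerate(plans):
        cp = best_counterparts(plan)
        for j, i in enumerate(cp):
            if i >= 0:
                edges.append((int(offsets[h] + i), int(offsets[h + 1] + j)))
    return edges


def _unify(slices: list[STSlice], plans: list[TransportPlan],
           cfg: PipelineConfig):
    """Apply the configured coordinate-unification strategy.

    Returns (unified slices, per-slice transforms or None, extra hard-link
    edges for the final graph)."""
    mode = cfg.unification
    if mode == "auto":
        mode = "procrustes" if len(slices) == 2 else "replacement"
    hard_edges = (None if cfg.variant == "softlink_only"
                  else _hard_link_edges(plans, slices))
    if mode == "procrustes":
        unified = [slices[0]]
        transforms = [RigidTransform.identity()]
        for h, plan in enumerate(plans):
            T = refined_pair_transform(unified[h].coords,
                                       slices[h + 1].coords,
                                       plan.full_matrix())
            unified.append(transform_coordinates(slices[h + 1], T))
            transforms.append(T)
        return unified, transforms, hard_edges
    if mode == "replacement":
        return coordinate_replacement_sweep(slices, plans), None, hard_edges
    if mode == "transformation":
        offsets = np.concatenate([[0], np.cumsum([s.n_spots for s in slices])])
        links = []
        for h, plan in enumerate(plans):
            for j, i in enumerate(best_counterparts(plan)):
                if i >= 0:
                    links.append((h, int(i), h + 1, int(j)))
        tcfg = cfg.transform_opt
        tcfg.seed = derive_seed(cfg.seed, "transform_opt")
        transforms = coordinate_transformation_optimize(slices, links, tcfg)
        unified = [transform_coordinates(s, T)
                   for s, T in zip(slices, transforms)]
        return unified, transforms, hard_edges
    if mode == "horizontal":
        return list(slices), None, hard_edges
    raise AssertionError(mode)


def final_integration(slices_unified: list[STSlice],
                      hard_links: list[tuple[int, int]] | None,
                      cfg: PipelineConfig) -> JointEmbedding:
    """Steps 4–5: retrain on the unified k-NN graph (k=15 pooled spatial
    neighbors, hard-link edges merged in) — or, for the soft-link-only
    variant, on intra-slice graphs alone."""
    if cfg.variant == "softlink_only":
        graph = union_graphs([build_intra_knn(s, cfg.intra_k)
                              for s in slices_unified])
    else:
        graph = build_unified_knn(slices_unified, k=cfg.unified_k,
                                  extra_edges=hard_links)
    emb, _ = _fit_model(slices_unified, graph, cfg, "final")
    node_index, slice_of = _node_annotation(slices_unified)
    return JointEmbedding(matrix=emb, node_index=node_index, slice_of=slice_of)


def _default_metrics(embedding: JointEmbedding,
                     slices: list[STSlice], seed: int) -> dict:
    emb2d = _metrics.embed_2d(embedding.matrix, seed=seed)
    per_slice_2d, per_slice_coords = [], []
    for s in slices:
        rows = embedding.slice_of == s.slice_id
        per_slice_2d.append(emb2d[rows])
        per_slice_coords.append(s.coords)
    report = {
        "ilisi": _metrics.ilisi(embedding.matrix, embedding.slice_of),
        "isometry_correlation": _metrics.isometry_correlation(
            per_slice_coords, per_slice_2d),
        "procrustes_dissimilarity": _metrics.procrustes_dissimilarity(
            per_slice_coords, per_slice_2d),
    }
    if all(s.labels is not None for s in slices) and embedding.cluster_of is not None:
        truth = np.concatenate([np.asarray(s.labels) for s in slices])
        report["ari"] = _metrics.ari(embedding.cluster_of, truth)
    return report


def run(slices: list[STSlice], cfg: PipelineConfig | None = None,
        outdir: str | None = None) -> PipelineResult:
    """Execute the full five-step pipeline on preprocessed slices."""
    cfg = cfg or PipelineConfig()
    times: dict[str, float] = {}
    stage = "initial_integration"
    try:
        t0 = time.perf_counter()
        initial = initial_integration(slices, cfg)
        times[stage] = time.perf_counter() - t0

        stage = "joint_clustering"
        t0 = time.perf_counter()
        clusters = joint_cluster(initial.matrix, cfg.n_clusters,
                                 seed=derive_seed(cfg.seed, "cluster"))
        initial.cluster_of = clusters
        times[stage] = time.perf_counter() - t0

        stage = "local_alignment"
        t0 = time.perf_counter()
        # feature cost on normalized expression (PASTE-style): robust to
        # residual embedding noise, exact for expression-identical spots
        feats = [s.expr for s in slices] if cfg.fuse_alpha < 1.0 else None
        plans = align_pair(slices, _split_labels(clusters, slices),
                           tol=cfg.gw_tol, max_iter=cfg.gw_max_iter,
                           features=feats, fuse_alpha=cfg.fuse_alpha)
        times[stage] = time.perf_counter() - t0

        stage = "coordinate_unification"
        t0 = time.perf_counter()
        unified, transforms, hard_edges = _unify(slices, plans, cfg)
        times[stage] = time.perf_counter() - t0

        stage = "final_integration"
        t0 = time.perf_counter()
        # the soft-link-only variant ignores hard-links entirely, so it
        # trains on the original (non-unified) slice geometry
        final_slices = slices if cfg.variant == "softlink_only" else unified
        final = final_integration(final_slices, hard_edges, cfg)
        final.cluster_of = joint_cluster(final.matrix, cfg.n_clusters,
                                         seed=derive_seed(cfg.seed, "cluster2"))
        times[stage] = time.perf_counter() - t0

        stage = "metrics"
        t0 = time.perf_counter()
        report = _default_metrics(final, slices, seed=derive_seed(cfg.seed, "viz"))
        times[stage] = time.perf_counter() - t0
    except Exception as e:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {e}") from e

    for name, sec in times.items():
        logger.info("stage %s: %.2fs", name, sec)
    result = PipelineResult(embedding=final, initial_embedding=initial,
                            clusters=clusters, plans=plans,
                            transforms=transforms, slices_unified=unified,
                            metrics_report=report, stage_seconds=times)
    if outdir is not None:
        mappings = {}
        for plan in plans:
            cp = best_counterparts(plan)
            s1, s2 = slices[plan.pair[0]], slices[plan.pair[1]]
            M = plan.full_matrix()
            rows = [(s1.slice_id, s1.spot_ids[i], s2.spot_ids[j],
                     float(M[i, j])) for j, i in enumerate(cp) if i >= 0]
            mappings[f"{s1.slice_id}_{s2.slice_id}"] = rows
        write_outputs(final.matrix, final.cluster_of, mappings, outdir,
                      node_index=final.node_index)
    return result


class IntegrationPipeline:
    """Estimator-style wrapper: fit(slices) runs the five-step pipeline and
    exposes the results as fitted attributes."""

    def __init__(self, config: PipelineConfig | None = None):
        self.config = config or PipelineConfig()

    def get_params(self, deep: bool = True) -> dict:
        return {"config": self.config}

    def set_params(self, **params) -> "IntegrationPipeline":
        if "config" in params:
            self.config = params["config"]
        return self

    def fit(self, slices: list[STSlice], outdir: str | None = None
            ) -> "IntegrationPipeline":
        res = run(slices, self.config, outdir=outdir)
        self.result_ = res
        self.embedding_ = res.embedding.matrix
        self.clusters_ = res.embedding.cluster_of
        self.plans_ = res.plans
        self.metrics_report_ = res.metrics_report
        return self

    def fit_transform(self, slices: list[STSlice]) -> np.ndarray:
        return self.fit(slices).embedding_
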