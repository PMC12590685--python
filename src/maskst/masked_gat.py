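"""Masked graph-attention autoencoder.

The backbone has five components: a two-layer graph-attention encoder
(widths in→512→32), a mirrored decoder (32→512→in), a two-layer MLP
projector on the latent space, and a generator — an encoder+projector of
identical structure but independent parameters that runs on the unmasked
input to produce latent regression targets.

Per layer, node u aggregates h_u = ε(Σ_{v∈N(u)} α_uv W h_v) where the
attention α_uv = softmax_v(sigmoid(aᵀ[W h_u ⊕ W h_v])) is normalized over
u's neighborhood (which includes u itself).  Hidden activations are ELU;
encoder and decoder outputs are linear.

Training masks a random subset of spots (features zeroed), stochastically
re-masks their latent rows before decoding, and minimizes a scaled cosine
error on the masked reconstructions plus a latent consistency loss
against the generator targets; a triplet loss over cross-slice mutual
nearest neighbors can be added in a second phase.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from . import _autodiff as adf
from ._autodiff import Tensor, Adam
from .data_model import MultiSliceGraph
from ._utils import check_finite

__all__ = [
    "ModelConfig",
    "ModelState",
    "MaskPlan",
    "MaskedGraphAutoencoder",
    "attention_coefficients",
    "apply_mask",
    "apply_remask",
    "masked_loss",
    "latent_loss",
    "combined_loss",
    "sample_mask_plan",
]

_NORM_FLOOR = 1e-12


@dataclass
class ModelConfig:
    """Hyperparameters of the masked graph-attention autoencoder.

    Masking / re-masking rates default to 0.1/0.1 (large gene panels;
    0.5/0.5 is the alternative for small panels).  gamma scales the cosine
    error, lambda_latent balances the latent consistency term, and
    margin_alpha is the triplet margin; all three default to 1.
    """

    hidden_dim: int = 512
    latent_dim: int = 32
    projector_hidden: int = 64
    mask_rate: float = 0.1
    remask_rate: float = 0.1
    gamma: float = 1.0
    lambda_latent: float = 1.0
    margin_alpha: float = 1.0
    triplet_weight: float = 1.0
    epochs_phase1: int = 500
    epochs_phase2: int = 500
    triplet_refresh: int = 100
    lr: float = 1e-3
    weight_decay: float = 0.0
    seed: int = 0
    attention_heads: int = 1
    mnn_k: int = 5
    remask_within_mask: bool = False
    # ablation switches
    use_graph: bool = True
    use_mask: bool = True
    use_latent: bool = True
    use_triplet: bool = True

    def __post_init__(self):
        if not (0.0 <= self.mask_rate < 1.0) or not (0.0 <= self.remask_rate < 1.0):
            raise ValueError("mask/remask rates must lie in [0, 1)")
        if self.gamma < 1.0:
            raise ValueError("gamma must be ≥ 1")
        if self.lambda_latent < 0:
            raise ValueError("lambda_latent must be ≥ 0")
        if self.margin_alpha <= 0:
            raise ValueError("margin_alpha must be > 0")
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.attention_heads < 1:
            raise ValueError("attention_heads must be ≥ 1")


@dataclass
class MaskPlan:
    """Node sets selected for feature masking and latent re-masking."""

    masked_nodes: np.ndarray
    remasked_nodes: np.ndarray


def sample_mask_plan(n_nodes: int, cfg: ModelConfig,
                     rng: np.random.Generator) -> MaskPlan:
    n_mask = int(round(cfg.mask_rate * n_nodes))
    masked = rng.choice(n_nodes, size=n_mask, replace=False) if n_mask else \
        np.empty(0, dtype=np.intp)
    pool = masked if cfg.remask_within_mask else np.arange(n_nodes)
    n_re = int(round(cfg.remask_rate * len(pool)))
    remasked = rng.choice(pool, size=n_re, replace=False) if n_re else \
        np.empty(0, dtype=np.intp)
    return MaskPlan(masked_nodes=np.sort(masked), remasked_nodes=np.sort(remasked))


def apply_mask(X: np.ndarray, plan: MaskPlan) -> np.ndarray:
    """Zero the feature rows of the masked node set (Ṽ)."""
    Xm = X.copy()
    Xm[plan.masked_nodes] = 0.0
    return Xm


def apply_remask(H, plan: MaskPlan):
    """Zero latent rows of the re-mask set before decoding.

    Works on numpy arrays and on autodiff tensors (via a 0/1 row mask so
    gradients at re-masked rows are cut, matching the zeroed forward)."""
    if isinstance(H, Tensor):
        m = np.ones((H.shape[0], 1))
        m[plan.remasked_nodes] = 0.0
        return adf.mul(H, m)
    Hm = H.copy()
    Hm[plan.remasked_nodes] = 0.0
    return Hm


# -- losses ----------------------------------------------------------------

def _cosine_error(Xt: Tensor, Zt: Tensor, rows: np.ndarray | None,
                  gamma: float) -> Tensor:
    """Mean over `rows` of (1 − cos(x_i, z_i))^gamma; zero-norm rows get cos=0."""
    if rows is not None:
        Xt = adf.gather_rows(Xt, rows)
        Zt = adf.gather_rows(Zt, rows)
    dot = adf.row_sum(adf.mul(Xt, Zt))
    nx = adf.sqrt(adf.row_sum(adf.mul(Xt, Xt)))
    nz = adf.sqrt(adf.row_sum(adf.mul(Zt, Zt)))
    denom = adf.maximum_scalar(adf.mul(nx, nz), _NORM_FLOOR)
    cos = adf.div(dot, denom)
    err = adf.power(adf.sub(Tensor(1.0), cos), gamma)
    return adf.mean_all(err)


def _warn_zero_rows(X: np.ndarray, rows: np.ndarray | None, what: str) -> None:
    sub = X if rows is None else X[rows]
    if np.any((sub ** 2).sum(axis=1) < _NORM_FLOOR):
        warnings.warn(f"zero-norm {what} row(s): cosine defined as 0 there",
                      RuntimeWarning, stacklevel=3)


def masked_loss(X, Z, masked_nodes, gamma: float = 1.0):
    """Scaled cosine reconstruction error over the masked node set.

    Returns a float for numpy inputs, a differentiable tensor otherwise."""
    rows = np.asarray(masked_nodes, dtype=np.intp)
    if rows.size == 0:
        raise ValueError("masked node set must be nonempty")
    symbolic = isinstance(X, Tensor) or isinstance(Z, Tensor)
    Xt = X if isinstance(X, Tensor) else Tensor(np.asarray(X, float))
    Zt = Z if isinstance(Z, Tensor) else Tensor(np.asarray(Z, float))
    _warn_zero_rows(Xt.data, rows, "expression")
    out = _cosine_error(Xt, Zt, rows, gamma)
    return out if symbolic else float(out.data)


def latent_loss(Z_bar, X_bar, gamma: float = 1.0):
    """Scaled cosine error between projector outputs and generator targets,
    averaged over all spots."""
    symbolic = isinstance(Z_bar, Tensor) or isinstance(X_bar, Tensor)
    Zt = Z_bar if isinstance(Z_bar, Tensor) else Tensor(np.asarray(Z_bar, float))
    Xt = X_bar if isinstance(X_bar, Tensor) else Tensor(np.asarray(X_bar, float))
    if Zt.shape != Xt.shape:
        raise ValueError("projector and generator outputs must share a shape")
    out = _cosine_error(Xt, Zt, None, gamma)
    return out if symbolic else float(out.data)


def combined_loss(X, Z, masked_nodes, Z_bar, X_bar, gamma: float = 1.0,
                  lambda_latent: float = 1.0):
    """masked_loss + λ · latent_loss."""
    lm = masked_loss(X, Z, masked_nodes, gamma)
    if lambda_latent == 0:
        return lm
    ll = latent_loss(Z_bar, X_bar, gamma)
    if isinstance(lm, Tensor) or isinstance(ll, Tensor):
        return adf.add(lm, adf.mul(Tensor(lambda_latent), ll))
    return lm + lambda_latent * ll


# -- reference attention (numpy, used directly and as a test surface) ------

def attention_coefficients(h_prev: np.ndarray, W: np.ndarray, a: np.ndarray,
                           neighbors: list) -> np.ndarray:
    """Dense attention matrix for one layer: α_uv = softmax over N(u) of
    sigmoid(aᵀ[W h_u ⊕ W h_v]); rows sum to 1 over the neighborhood."""
    P = np.asarray(h_prev, float) @ np.asarray(W, float)
    a = np.asarray(a, float).ravel()
    d = P.shape[1]
    s_self, s_nbr = P @ a[:d], P @ a[d:]
    n = P.shape[0]
    alpha = np.zeros((n, n))
    for u, nbrs in enumerate(neighbors):
        nbrs = list(nbrs)
        if not nbrs:
            raise ValueError(f"node {u} has an empty neighborhood "
                             "(self-edge invariant violated)")
        scores = 1.0 / (1.0 + np.exp(-(s_self[u] + s_nbr[np.asarray(nbrs)])))
        e = np.exp(scores - scores.max())
        alpha[u, np.asarray(nbrs)] = e / e.sum()
    return alpha


# -- parameterized layers --------------------------------------------------

def _xavier(rng: np.random.Generator, shape) -> np.ndarray:
    bound = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-bound, bound, size=shape)


def _init_gat_layer(rng, d_in, d_out, heads):
    return [{"W": Tensor(_xavier(rng, (d_in, d_out)), requires_grad=True),
             "a_self": Tensor(_xavier(rng, (d_out, 1)), requires_grad=True),
             "a_nbr": Tensor(_xavier(rng, (d_out, 1)), requires_grad=True)}
            for _ in range(heads)]


def _init_mlp_layer(rng, d_in, d_out):
    return {"W": Tensor(_xavier(rng, (d_in, d_out)), requires_grad=True)}


def _gat_layer_forward(layer_heads, H, graph_ops, activate: bool):
    """One graph-attention layer; multi-head outputs are averaged.

    Edge-space arrays stay scalar (scores/attention); feature aggregation
    goes through the sparse attention-weighted adjacency."""
    tpl: adf.GraphTemplate = graph_ops
    outs = []
    for head in layer_heads:
        P = adf.matmul(H, head["W"])
        sc_self = adf.matmul(P, head["a_self"])
        sc_nbr = adf.matmul(P, head["a_nbr"])
        scores = adf.sigmoid(adf.add(adf.gather_rows(sc_self, tpl.dst),
                                     adf.gather_rows(sc_nbr, tpl.src)))
        ex = adf.exp(scores)
        denom = adf.gather_rows(adf.segment_sum(ex, tpl), tpl.dst)
        alpha = adf.div(ex, denom)
        outs.append(adf.edge_aggregate(alpha, P, tpl))
    out = outs[0]
    for o in outs[1:]:
        out = adf.add(out, o)
    if len(outs) > 1:
        out = adf.mul(out, Tensor(1.0 / len(outs)))
    return adf.elu(out) if activate else out


def _mlp_layer_forward(layer, H, activate: bool):
    out = adf.matmul(H, layer["W"])
    return adf.elu(out) if activate else out


def _stack_forward(layers, H, graph_ops, use_graph: bool):
    n = len(layers)
    for i, layer in enumerate(layers):
        activate = i < n - 1
        if use_graph:
            H = _gat_layer_forward(layer, H, graph_ops, activate)
        else:
            H = _mlp_layer_forward(layer[0] if isinstance(layer, list) else layer,
                                   H, activate)
    return H


@dataclass
class ModelState:
    """All trainable parameter sets plus optimizer and RNG state."""

    encoder: list
    decoder: list
    projector: list
    gen_encoder: list
    gen_projector: list
    optimizer: Adam | None = None
    rng: np.random.Generator | None = None
    epoch: int = 0
    loss_history: list = field(default_factory=list)

    def parameters(self) -> list[Tensor]:
        params = []
        for stack in (self.encoder, self.decoder, self.gen_encoder):
            for layer in stack:
                for head in layer:
                    params.extend(head.values())
        for stack in (self.projector, self.gen_projector):
            for layer in stack:
                params.extend(layer.values())
        return params


class MaskedGraphAutoencoder:
    """Estimator interface around the masked graph-attention autoencoder.

    fit(X, graph) trains on the full graph (no minibatching) and exposes
    ``embedding_`` (spots × latent_dim) plus ``loss_history_``.  A
    ``triplet_fn`` callback lets the caller refresh cross-slice triplets
    from the current embedding during phase 2.
    """

    def __init__(self, config: ModelConfig | None = None, **overrides):
        cfg = config or ModelConfig()
        if overrides:
            cfg = ModelConfig(**{**asdict(cfg), **overrides})
        self.config = cfg

    # sklearn-style parameter plumbing
    def get_params(self, deep: bool = True) -> dict:
        return dict(asdict(self.config))

    def set_params(self, **params) -> "MaskedGraphAutoencoder":
        self.config = ModelConfig(**{**asdict(self.config), **params})
        return self

    # -- construction ------------------------------------------------------
    def _init_state(self, n_features: int) -> ModelState:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        h, z, p = cfg.hidden_dim, cfg.latent_dim, cfg.projector_hidden
        heads = cfg.attention_heads
        enc = [_init_gat_layer(rng, n_features, h, heads),
               _init_gat_layer(rng, h, z, heads)]
        dec = [_init_gat_layer(rng, z, h, heads),
               _init_gat_layer(rng, h, n_features, heads)]
        proj = [_init_mlp_layer(rng, z, p), _init_mlp_layer(rng, p, z)]
        gen_enc = [_init_gat_layer(rng, n_features, h, heads),
                   _init_gat_layer(rng, h, z, heads)]
        gen_proj = [_init_mlp_layer(rng, z, p), _init_mlp_layer(rng, p, z)]
        state = ModelState(encoder=enc, decoder=dec, projector=proj,
                           gen_encoder=gen_enc, gen_projector=gen_proj, rng=rng)
        state.optimizer = Adam(state.parameters(), lr=cfg.lr,
                               weight_decay=cfg.weight_decay)
        return state

    @staticmethod
    def _graph_ops(graph: MultiSliceGraph) -> adf.GraphTemplate:
        dst, src = graph.directed_arrays()
        return adf.GraphTemplate(dst, src, graph.n_nodes)

    # -- forward passes ----------------------------------------------------
    def _encode(self, state: ModelState, Xt, graph_ops):
        return _stack_forward(state.encoder, Xt, graph_ops, self.config.use_graph)

    def _decode(self, state: ModelState, Ht, graph_ops):
        return _stack_forward(state.decoder, Ht, graph_ops, self.config.use_graph)

    def _project(self, layers, Ht):
        H = _mlp_layer_forward(layers[0], Ht, activate=True)
        return _mlp_layer_forward(layers[1], H, activate=False)

    def _generate(self, state: ModelState, Xt, graph_ops):
        H = _stack_forward(state.gen_encoder, Xt, graph_ops, self.config.use_graph)
        return self._project(state.gen_projector, H)

    # -- training ----------------------------------------------------------
    def train_epoch(self, state: ModelState, graph_ops, X: np.ndarray,
                    triplets, phase: int) -> float:
        """One full-graph gradient step; returns the epoch loss."""
        if phase not in (1, 2):
            raise ValueError("phase must be 1 or 2")
        cfg = self.config
        n = X.shape[0]
        if cfg.use_mask:
            plan = sample_mask_plan(n, cfg, state.rng)
            if plan.masked_nodes.size == 0:
                plan = MaskPlan(np.arange(n), plan.remasked_nodes)
            X_in = Tensor(apply_mask(X, plan))
            recon_rows = plan.masked_nodes
        else:
            plan = None
            X_in = Tensor(X)
            recon_rows = np.arange(n)

        H = self._encode(state, X_in, graph_ops)
        H_dec = apply_remask(H, plan) if (cfg.use_mask and plan is not None) else H
        Z = self._decode(state, H_dec, graph_ops)
        loss = _cosine_error(Tensor(X), Z, recon_rows, cfg.gamma)

        if cfg.use_latent and cfg.lambda_latent > 0:
            Z_bar = self._project(state.projector, H)
            X_bar = self._generate(state, Tensor(X), graph_ops)
            loss = adf.add(loss, adf.mul(Tensor(cfg.lambda_latent),
                                         _cosine_error(X_bar, Z_bar, None,
                                                       cfg.gamma)))
        if phase == 2 and cfg.use_triplet and triplets is not None and len(triplets):
            from .softlinks import triplet_loss
            loss = adf.add(loss, adf.mul(Tensor(cfg.triplet_weight),
                                         triplet_loss(H, triplets,
                                                      cfg.margin_alpha)))
        value = float(loss.data)
        if not np.isfinite(value):
            raise FloatingPointError(
                f"training loss diverged (non-finite) at epoch {state.epoch}")
        state.optimizer.zero_grad()
        loss.backward()
        state.optimizer.step()
        state.epoch += 1
        state.loss_history.append(value)
        return value

    def fit(self, X: np.ndarray, graph: MultiSliceGraph,
            triplet_fn=None) -> "MaskedGraphAutoencoder":
        """Two-phase training: combined masked+latent loss, then with
        triplet soft-links refreshed every ``triplet_refresh`` epochs."""
        X = np.asarray(X, dtype=np.float64)
        check_finite(X, "input features")
        cfg = self.config
        state = self._init_state(X.shape[1])
        graph_ops = self._graph_ops(graph)
        for _ in range(cfg.epochs_phase1):
            self.train_epoch(state, graph_ops, X, None, phase=1)
        triplets = None
        for ep in range(cfg.epochs_phase2):
            if (cfg.use_triplet and triplet_fn is not None
                    and ep % max(cfg.triplet_refresh, 1) == 0):
                triplets = triplet_fn(self._embed(state, X, graph_ops))
            self.train_epoch(state, graph_ops, X, triplets, phase=2)
        self.state_ = state
        self._graph_ops_ = graph_ops
        self.n_features_in_ = X.shape[1]
        self.embedding_ = self._embed(state, X, graph_ops)
        self.loss_history_ = list(state.loss_history)
        return self

    def _embed(self, state: ModelState, X: np.ndarray, graph_ops) -> np.ndarray:
        return self._encode(state, Tensor(X), graph_ops).data

    def transform(self, X: np.ndarray,
                  graph: MultiSliceGraph | None = None) -> np.ndarray:
        """Latent embedding of (unmasked) input on the training graph by
        default, or on a caller-provided graph."""
        if not hasattr(self, "state_"):
            raise RuntimeError("model is not fitted")
        ops = self._graph_ops(graph) if graph is not None else self._graph_ops_
        return self._embed(self.state_, np.asarray(X, float), ops)

    def fit_transform(self, X, graph, triplet_fn=None) -> np.ndarray:
        return self.fit(X, graph, triplet_fn=triplet_fn).embedding_

    # -- checkpointing -----------------------------------------------------
    def save_checkpoint(self, path: str) -> None:
        if not hasattr(self, "state_"):
            raise RuntimeError("model is not fitted")
        arrays, manifest = {}, []
        stacks = {"encoder": self.state_.encoder, "decoder": self.state_.decoder,
                  "gen_encoder": self.state_.gen_encoder,
                  "projector": self.state_.projector,
                  "gen_projector": self.state_.gen_projector}
        for name, stack in stacks.items():
            for i, layer in enumerate(stack):
                heads = layer if isinstance(layer, list) else [layer]
                for j, head in enumerate(heads):
                    for key, t in head.items():
                        tag = f"{name}.{i}.{j}.{key}"
                        arrays[tag] = t.data
                        manifest.append(tag)
        arrays["_config"] = np.frombuffer(
            json.dumps(asdict(self.config)).encode(), dtype=np.uint8)
        arrays["_rng"] = np.frombuffer(
            json.dumps(self.state_.rng.bit_generator.state).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load_checkpoint(cls, path: str, n_features: int) -> "MaskedGraphAutoencoder":
        data = np.load(path)
        cfg = ModelConfig(**json.loads(bytes(data["_config"]).decode()))
        model = cls(cfg)
        state = model._init_state(n_features)
        stacks = {"encoder": state.encoder, "decoder": state.decoder,
                  "gen_encoder": state.gen_encoder,
                  "projector": state.projector,
                  "gen_projector": state.gen_projector}
        for tag in data.files:
            if tag.startswith("_"):
                continue
            name, i, j, key = tag.split(".")
            layer = stacks[name][int(i)]
            head = layer[int(j)] if isinstance(layer, list) else layer
            head[key].data = data[tag]
        state.rng.bit_generator.state = json.loads(bytes(data["_rng"]).decode())
        model.state_ = state
        model.n_features_in_ = n_features
        return model
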