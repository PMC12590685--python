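"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the masked graph-attention autoencoder
needs: dense matmul, sparse-matrix × dense products (used for gather /
scatter along graph edges), elementwise arithmetic with broadcasting,
ELU / sigmoid / ReLU, powers, square roots and reductions.  Gradients
are accumulated by a topological backward sweep from a scalar loss.

Sparse matrices (scipy CSR) enter only as constants describing graph
incidence; their transpose implements the adjoint automatically, so a
single `spmm` primitive covers both neighbor gathering and scatter-add
aggregation.
"""

from __future__ import annotations

import numpy as np


class Tensor:
    """A node in the computation graph: value, gradient, backward rule."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # convenience operators --------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __sub__(self, other):
        return sub(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __neg__(self):
        return neg(self)

    def __matmul__(self, other):
        return matmul(self, other)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _needs_graph(*ts: Tensor) -> bool:
    return any(t.requires_grad or t._parents for t in ts)


def _accumulate(t: Tensor, g: np.ndarray) -> None:
    # grads are never mutated in place, so aliasing the first contribution
    # is safe and avoids allocating large zero buffers
    if not (t.requires_grad or t._parents):
        return
    t.grad = g if t.grad is None else t.grad + g


def _unbroadcast(g: np.ndarray, shape) -> np.ndarray:
    """Sum gradient `g` down to `shape` (inverse of numpy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g.reshape(shape)


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data, parents=parents)
    if _needs_graph(*parents):
        out._backward = backward
    else:
        out._parents = ()
    return out


# -- elementwise arithmetic ------------------------------------------------

def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data + b.data

    def backward(g):
        _accumulate(a, _unbroadcast(g, a.data.shape))
        _accumulate(b, _unbroadcast(g, b.data.shape))

    return _make(data, (a, b), backward)


def sub(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data - b.data

    def backward(g):
        _accumulate(a, _unbroadcast(g, a.data.shape))
        _accumulate(b, _unbroadcast(-g, b.data.shape))

    return _make(data, (a, b), backward)


def neg(a) -> Tensor:
    a = _as_tensor(a)

    def backward(g):
        _accumulate(a, -g)

    return _make(-a.data, (a,), backward)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data * b.data

    def backward(g):
        _accumulate(a, _unbroadcast(g * b.data, a.data.shape))
        _accumulate(b, _unbroadcast(g * a.data, b.data.shape))

    return _make(data, (a, b), backward)


def div(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data / b.data

    def backward(g):
        _accumulate(a, _unbroadcast(g / b.data, a.data.shape))
        _accumulate(b, _unbroadcast(-g * a.data / (b.data ** 2), b.data.shape))

    return _make(data, (a, b), backward)


# -- linear algebra --------------------------------------------------------

def matmul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data @ b.data

    def backward(g):
        _accumulate(a, g @ b.data.T)
        _accumulate(b, a.data.T @ g)

    return _make(data, (a, b), backward)


def spmm(S, x) -> Tensor:
    """Constant sparse matrix times dense tensor: out = S @ x.

    The adjoint is S.T @ grad, so the same primitive serves both the
    edge-gather (S: edges×nodes selection) and the scatter-add
    aggregation (S transpose) used by graph attention layers.
    """
    x = _as_tensor(x)
    ST = S.T.tocsr()
    data = S @ x.data

    def backward(g):
        _accumulate(x, ST @ g)

    return _make(data, (x,), backward)


# -- nonlinearities --------------------------------------------------------

def sigmoid(a) -> Tensor:
    a = _as_tensor(a)
    s = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        _accumulate(a, g * s * (1.0 - s))

    return _make(s, (a,), backward)


def elu(a, alpha: float = 1.0) -> Tensor:
    a = _as_tensor(a)
    neg_part = alpha * np.expm1(np.minimum(a.data, 0.0))
    data = np.where(a.data > 0, a.data, neg_part)

    def backward(g):
        _accumulate(a, g * np.where(a.data > 0, 1.0, neg_part + alpha))

    return _make(data, (a,), backward)


def relu(a) -> Tensor:
    a = _as_tensor(a)
    data = np.maximum(a.data, 0.0)

    def backward(g):
        _accumulate(a, g * (a.data > 0))

    return _make(data, (a,), backward)


def exp(a) -> Tensor:
    a = _as_tensor(a)
    data = np.exp(a.data)

    def backward(g):
        _accumulate(a, g * data)

    return _make(data, (a,), backward)


def sqrt(a) -> Tensor:
    a = _as_tensor(a)
    data = np.sqrt(a.data)

    def backward(g):
        _accumulate(a, g * 0.5 / np.maximum(data, 1e-300))

    return _make(data, (a,), backward)


def power(a, p: float) -> Tensor:
    a = _as_tensor(a)
    data = a.data ** p

    def backward(g):
        _accumulate(a, g * p * a.data ** (p - 1.0))

    return _make(data, (a,), backward)


def maximum_scalar(a, c: float) -> Tensor:
    """max(a, c) elementwise against a constant floor."""
    a = _as_tensor(a)
    data = np.maximum(a.data, c)

    def backward(g):
        _accumulate(a, g * (a.data > c))

    return _make(data, (a,), backward)


# -- reductions and indexing ----------------------------------------------

def row_sum(a, keepdims: bool = True) -> Tensor:
    a = _as_tensor(a)
    data = a.data.sum(axis=1, keepdims=keepdims)

    def backward(g):
        gg = g if keepdims else g[:, None]
        _accumulate(a, np.broadcast_to(gg, a.data.shape))

    return _make(data, (a,), backward)


def total_sum(a) -> Tensor:
    a = _as_tensor(a)

    def backward(g):
        _accumulate(a, np.full_like(a.data, float(g)))

    return _make(a.data.sum(), (a,), backward)


def mean_all(a) -> Tensor:
    a = _as_tensor(a)
    n = a.data.size

    def backward(g):
        _accumulate(a, np.full_like(a.data, float(g) / n))

    return _make(a.data.mean(), (a,), backward)


def gather_rows(a, idx) -> Tensor:
    a = _as_tensor(a)
    idx = np.asarray(idx, dtype=np.intp)
    data = a.data[idx]

    def backward(g):
        acc = np.zeros_like(a.data)
        np.add.at(acc, idx, g)
        _accumulate(a, acc)

    return _make(data, (a,), backward)


class GraphTemplate:
    """Precomputed sparse structure of a directed edge list sorted by
    destination node: CSR index arrays for the attention-weighted
    adjacency and its transpose, plus segment boundaries for per-node
    reductions over incoming edges.  Requires every node to have at least
    one incoming edge (guaranteed by the self-edge invariant)."""

    def __init__(self, dst: np.ndarray, src: np.ndarray, n_nodes: int):
        dst = np.asarray(dst, dtype=np.intp)
        src = np.asarray(src, dtype=np.intp)
        if np.any(np.diff(dst) < 0):
            raise ValueError("edges must be sorted by destination")
        if not np.array_equal(np.unique(dst), np.arange(n_nodes)):
            raise ValueError("every node needs an incoming edge (self-edge)")
        self.dst, self.src, self.n = dst, src, int(n_nodes)
        self.starts = np.flatnonzero(np.r_[True, dst[1:] != dst[:-1]])
        self.indptr = np.searchsorted(dst, np.arange(n_nodes + 1))
        self.perm_t = np.lexsort((dst, src))
        src_sorted = src[self.perm_t]
        self.indices_t = dst[self.perm_t]
        self.indptr_t = np.searchsorted(src_sorted, np.arange(n_nodes + 1))

    def csr(self, edge_vals: np.ndarray):
        import scipy.sparse as _sp
        return _sp.csr_matrix((edge_vals, self.src, self.indptr),
                              shape=(self.n, self.n))

    def csr_t(self, edge_vals: np.ndarray):
        import scipy.sparse as _sp
        return _sp.csr_matrix((edge_vals[self.perm_t], self.indices_t,
                               self.indptr_t), shape=(self.n, self.n))


def segment_sum(a, tpl: GraphTemplate) -> Tensor:
    """Sum edge values (E×1) over incoming-edge segments → (N×1)."""
    a = _as_tensor(a)
    data = np.add.reduceat(a.data, tpl.starts, axis=0)

    def backward(g):
        _accumulate(a, g[tpl.dst])

    return _make(data, (a,), backward)


def edge_aggregate(alpha, P, tpl: GraphTemplate) -> Tensor:
    """Attention aggregation out_u = Σ_{v∈N(u)} α_uv P_v without
    materializing edge-space feature arrays.

    alpha: (E×1) edge weights (sorted by destination); P: (N×d) node
    features.  Backward: ∂L/∂P = Aᵀg, ∂L/∂α_e = g[dst_e]·P[src_e]."""
    alpha, P = _as_tensor(alpha), _as_tensor(P)
    vals = alpha.data.ravel()
    A = tpl.csr(vals)
    data = A @ P.data

    def backward(g):
        _accumulate(P, tpl.csr_t(vals) @ g)
        ga = (g[tpl.dst] * P.data[tpl.src]).sum(axis=1, keepdims=True)
        _accumulate(alpha, ga)

    return _make(data, (alpha, P), backward)


class Adam:
    """Adam optimizer over a list of leaf tensors."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1.0 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1.0 - self.b2) * g * g
            p.data -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)

    def state_dict(self):
        return {"t": self.t, "m": [m.copy() for m in self.m],
                "v": [v.copy() for v in self.v]}

    def load_state_dict(self, state):
        self.t = state["t"]
        self.m = [m.copy() for m in state["m"]]
        self.v = [v.copy() for v in state["v"]]
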