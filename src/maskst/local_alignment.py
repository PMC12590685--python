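"""Cluster-wise optimal-transport alignment and coordinate unification.

For each adjacent slice pair and each cluster shared by both slices (the
clusters come from joint GMM clustering of the initial embedding), a
Gromov–Wasserstein (GW) problem couples the two intra-cluster spatial
distance structures.  The per-cluster plans form a block-diagonal
transport plan whose entries act as "hard-links" between slices.

Coordinates are unified either by a weighted Procrustes rigid projection
of slice h+1 onto slice h (pairwise case), by a backward replacement
sweep that gives every spot the coordinates of its highest-confidence
chain ancestor on slice 1, or by per-slice rigid transforms found with
differential evolution over correspondence distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.optimize import differential_evolution, linear_sum_assignment, linprog
from scipy.spatial.distance import cdist

from .data_model import STSlice

__all__ = [
    "ClusterSubproblem",
    "TransportPlan",
    "RigidTransform",
    "TransformOptConfig",
    "match_shared_clusters",
    "gw_align_cluster",
    "gw_cost",
    "assemble_block_plan",
    "weighted_procrustes",
    "transform_coordinates",
    "coordinate_replacement_sweep",
    "coordinate_transformation_optimize",
    "best_counterparts",
]


@dataclass
class ClusterSubproblem:
    """One shared cluster between adjacent slices h and h+1.

    ``C`` is an optional cross-slice feature-cost matrix (|I|×|J|, e.g.
    squared embedding distances); when present the solver minimizes the
    fused objective (1−α)·⟨C, Π⟩ + α·GW(Π), PASTE-style."""

    label: object
    idx1: np.ndarray  # spot indices in slice h
    idx2: np.ndarray  # spot indices in slice h+1
    D1: np.ndarray    # intra-cluster spatial distances, slice h
    D2: np.ndarray
    g1: np.ndarray    # uniform spot weights, sum to 1
    g2: np.ndarray
    C: np.ndarray | None = None

    def __post_init__(self):
        for g in (self.g1, self.g2):
            if np.any(g < 0) or not np.isclose(g.sum(), 1.0):
                raise ValueError("cluster weights must be a probability vector")
        if self.C is not None and self.C.shape != (len(self.g1), len(self.g2)):
            raise ValueError("feature cost matrix shape mismatch")


@dataclass
class TransportPlan:
    """Block-diagonal coupling between a slice pair, one block per shared
    cluster; each block carries unit mass (per-cluster normalization)."""

    pair: tuple[int, int]
    blocks: list  # list of (label, idx1, idx2, block_matrix)
    n1: int
    n2: int

    def full_matrix(self) -> np.ndarray:
        """Coupling in original spot order (off-block entries exactly 0)."""
        M = np.zeros((self.n1, self.n2))
        for _, i1, i2, B in self.blocks:
            M[np.ix_(i1, i2)] = B
        return M

    def sorted_matrix(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Block-diagonal layout with spots ordered by cluster label.

        Returns (matrix, row_order, col_order)."""
        row_order = np.concatenate([b[1] for b in self.blocks])
        col_order = np.concatenate([b[2] for b in self.blocks])
        M = np.zeros((len(row_order), len(col_order)))
        r = c = 0
        for _, i1, i2, B in self.blocks:
            M[r:r + len(i1), c:c + len(i2)] = B
            r += len(i1)
            c += len(i2)
        return M, row_order, col_order


@dataclass
class RigidTransform:
    """z ↦ R z + v with orthogonal R (RᵀR = I within 1e-8)."""

    R: np.ndarray
    v: np.ndarray

    def __post_init__(self):
        self.R = np.asarray(self.R, float).reshape(2, 2)
        self.v = np.asarray(self.v, float).reshape(2)
        if not np.allclose(self.R.T @ self.R, np.eye(2), atol=1e-8):
            raise ValueError("R must be orthogonal")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.R.T + self.v

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(R=np.eye(2), v=np.zeros(2))

    @classmethod
    def from_angle(cls, theta: float, v=(0.0, 0.0)) -> "RigidTransform":
        c, s = np.cos(theta), np.sin(theta)
        return cls(R=np.array([[c, -s], [s, c]]), v=np.asarray(v, float))


def match_shared_clusters(slices: list[STSlice], labels: list[np.ndarray],
                          features: list[np.ndarray] | None = None
                          ) -> list[list[ClusterSubproblem]]:
    """Per adjacent slice pair, one subproblem for each cluster label that
    is present on both slices; labels only on one side are skipped.

    ``features`` (per-slice spot feature matrices, e.g. the initial joint
    embedding) adds a squared-distance feature cost to each subproblem
    for the fused solve."""
    out: list[list[ClusterSubproblem]] = []
    for h in range(len(slices) - 1):
        l1, l2 = np.asarray(labels[h]), np.asarray(labels[h + 1])
        shared = sorted(set(l1.tolist()) & set(l2.tolist()))
        if not shared:
            raise ValueError(
                f"slices {slices[h].slice_id} and {slices[h + 1].slice_id} share "
                "no cluster label; rerun joint clustering with fewer clusters")
        skipped = (set(l1.tolist()) | set(l2.tolist())) - set(shared)
        if skipped:
            warnings.warn(
                f"pair ({h},{h + 1}): clusters {sorted(skipped)} present on one "
                "slice only; skipped", RuntimeWarning, stacklevel=2)
        subs = []
        for m in shared:
            i1 = np.flatnonzero(l1 == m)
            i2 = np.flatnonzero(l2 == m)
            c1 = slices[h].coords[i1]
            c2 = slices[h + 1].coords[i2]
            C = None
            if features is not None:
                C = cdist(features[h][i1], features[h + 1][i2],
                          "sqeuclidean")
            subs.append(ClusterSubproblem(
                label=m, idx1=i1, idx2=i2,
                D1=cdist(c1, c1), D2=cdist(c2, c2),
                g1=np.full(len(i1), 1.0 / len(i1)),
                g2=np.full(len(i2), 1.0 / len(i2)), C=C))
        out.append(subs)
    return out


# -- Gromov–Wasserstein (squared loss, conditional gradient) ---------------

def _solve_linear_ot(G: np.ndarray, g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    """Exact linear OT: min <G, T> under fixed marginals.

    Equal-size uniform marginals reduce to an assignment problem; the
    general case goes through the HiGHS LP solver."""
    n, m = G.shape
    uniform = (n == m and np.allclose(g1, 1.0 / n) and np.allclose(g2, 1.0 / m))
    if uniform:
        r, c = linear_sum_assignment(G)
        T = np.zeros_like(G)
        T[r, c] = 1.0 / n
        return T
    A_rows = sp.kron(sp.eye(n), np.ones((1, m)), format="csr")
    A_cols = sp.kron(np.ones((1, n)), sp.eye(m), format="csr")
    A_eq = sp.vstack([A_rows, A_cols[:-1]]).tocsr()  # drop one redundant row
    b_eq = np.concatenate([g1, g2[:-1]])
    res = linprog(G.ravel(), A_eq=A_eq, b_eq=b_eq, bounds=(0, None),
                  method="highs")
    if not res.success:
        raise RuntimeError(f"inner OT LP failed: {res.message}")
    return res.x.reshape(n, m)


def gw_cost(D1: np.ndarray, D2: np.ndarray, Pi: np.ndarray) -> float:
    """Σ_ijkl (D1_ik − D2_jl)² Π_ij Π_kl."""
    g1 = Pi.sum(axis=1)
    g2 = Pi.sum(axis=0)
    constC = (D1 ** 2) @ g1
    constC = constC[:, None] + ((D2 ** 2) @ g2)[None, :]
    return float(np.sum((constC - 2.0 * D1 @ Pi @ D2.T) * Pi))


def _profile_init(sub: ClusterSubproblem, n_q: int = 16) -> np.ndarray:
    """Initial plan from per-spot distance-profile signatures: spots whose
    distributions of intra-cluster distances match are coupled first."""
    qs = np.linspace(0.0, 1.0, n_q)
    f1 = np.quantile(sub.D1, qs, axis=1).T if sub.D1.shape[0] > 1 else \
        np.zeros((1, n_q))
    f2 = np.quantile(sub.D2, qs, axis=1).T if sub.D2.shape[0] > 1 else \
        np.zeros((1, n_q))
    return _solve_linear_ot(cdist(f1, f2), sub.g1, sub.g2)


def _conditional_gradient(sub: ClusterSubproblem, Pi: np.ndarray,
                          tol: float, max_iter: int,
                          fuse_alpha: float = 1.0,
                          g1: np.ndarray | None = None,
                          g2: np.ndarray | None = None
                          ) -> tuple[np.ndarray, float]:
    """Frank–Wolfe on (1−α)·⟨C, Π⟩ + α·GW(Π) with exact line search
    (α = 1 or C = None is pure GW).

    ``Pi`` (and the optional marginals) may carry one extra dummy row or
    column beyond the real cluster sizes; dummy entries have zero linear
    cost and are exempt from the geometric term (partial-OT device)."""
    D1, D2 = sub.D1, sub.D2
    n, m = D1.shape[0], D2.shape[0]
    g1 = sub.g1 if g1 is None else g1
    g2 = sub.g2 if g2 is None else g2
    a_w = fuse_alpha
    lin = (1.0 - a_w) * sub.C if (sub.C is not None and a_w < 1.0) else None

    def real(P):
        return P[:n, :m]

    def tens(P):
        R = real(P)
        constC = ((D1 ** 2) @ R.sum(axis=1))[:, None] + \
            ((D2 ** 2) @ R.sum(axis=0))[None, :]
        return constC - 2.0 * D1 @ R @ D2.T

    def objective(P):
        val = a_w * float(np.sum(tens(P) * real(P)))
        if lin is not None:
            val += float(np.sum(lin * real(P)))
        return val

    obj = objective(Pi)
    for _ in range(max_iter):
        G = np.zeros_like(Pi)
        G[:n, :m] = a_w * 2.0 * tens(Pi)
        if lin is not None:
            G[:n, :m] += lin
        T = _solve_linear_ot(G, g1, g2)
        Delta = T - Pi
        b = float(np.sum(G * Delta))             # directional derivative at 0
        Dr = real(Delta)
        quad = ((D1 ** 2) @ Dr.sum(axis=1))[:, None] + \
            ((D2 ** 2) @ Dr.sum(axis=0))[None, :] - 2.0 * D1 @ Dr @ D2.T
        a = a_w * float(np.sum(quad * Dr))
        if a > 0:
            t = min(1.0, max(0.0, -b / (2.0 * a)))
        else:
            t = 1.0 if a + b < 0 else 0.0
        if t <= 0:
            break
        Pi = Pi + t * Delta
        new_obj = objective(Pi)
        if obj - new_obj <= tol * max(abs(obj), 1.0):
            obj = new_obj
            break
        obj = new_obj
    return Pi, obj


def _best_permutation_plan(sub: ClusterSubproblem) -> np.ndarray:
    """Exhaustive minimum over permutation couplings (tiny equal-size
    uniform blocks only)."""
    import itertools
    n = len(sub.g1)
    D1, D2 = sub.D1, sub.D2
    best_perm, best_cost = None, np.inf
    for perm in itertools.permutations(range(n)):
        p = np.asarray(perm)
        cost = float(((D1 - D2[np.ix_(p, p)]) ** 2).sum()) / (n * n)
        if cost < best_cost - 1e-15:
            best_perm, best_cost = p, cost
    P = np.zeros((n, n))
    P[np.arange(n), best_perm] = 1.0 / n
    return P


def gw_align_cluster(sub: ClusterSubproblem, tol: float = 1e-9,
                     max_iter: int = 50,
                     fuse_alpha: float = 1.0) -> np.ndarray:
    """Coupling between the intra-cluster distance structures via
    conditional gradient with exact line search.

    With ``fuse_alpha = 1`` (or no feature cost on the subproblem) this is
    squared-loss GW; smaller values weigh in the cross-slice feature cost
    (fused objective), which disambiguates couplings when the two
    clusters cover the shared domain only partially.

    Several deterministic initializations are tried — the product
    measure, a distance-profile matching, and (for tiny equal-size
    uniform blocks) the exact best permutation coupling — and the
    lowest-cost solution is returned."""
    n, m = len(sub.g1), len(sub.g2)
    if n == 1 or m == 1:
        return np.outer(sub.g1, sub.g2)
    partial = sub.C is not None and fuse_alpha < 1.0 and n != m
    if partial:
        # partial fused OT: per-spot capacity 1/max(n,m) on both sides;
        # a zero-cost dummy on the smaller side absorbs the excess mass
        # of the larger side, so spots without a genuine counterpart are
        # not forced onto real spots.
        cap = 1.0 / max(n, m)
        if n > m:
            g1_eff = np.full(n, cap)
            g2_eff = np.concatenate([np.full(m, cap), [(n - m) * cap]])
            shape = (n, m + 1)
        else:
            g1_eff = np.concatenate([np.full(n, cap), [(m - n) * cap]])
            g2_eff = np.full(m, cap)
            shape = (n + 1, m)
        lin_cost = np.zeros(shape)
        lin_cost[:n, :m] = (1.0 - fuse_alpha) * sub.C
        inits = [np.outer(g1_eff, g2_eff),
                 _solve_linear_ot(lin_cost, g1_eff, g2_eff)]
        best_pi, best_obj = None, np.inf
        for Pi0 in inits:
            Pi, obj = _conditional_gradient(sub, Pi0, tol, max_iter,
                                            fuse_alpha, g1_eff, g2_eff)
            if obj < best_obj - 1e-15 or best_pi is None:
                best_pi, best_obj = Pi, obj
        return best_pi[:n, :m]
    best_pi, best_obj = None, np.inf
    inits = [np.outer(sub.g1, sub.g2), _profile_init(sub)]
    if sub.C is not None and fuse_alpha < 1.0:
        inits.append(_solve_linear_ot((1.0 - fuse_alpha) * sub.C,
                                      sub.g1, sub.g2))
    if (n == m and n <= 7 and np.allclose(sub.g1, 1.0 / n)
            and np.allclose(sub.g2, 1.0 / n)):
        inits.append(_best_permutation_plan(sub))
    for Pi0 in inits:
        Pi, obj = _conditional_gradient(sub, Pi0, tol, max_iter, fuse_alpha)
        if obj < best_obj - 1e-15 or best_pi is None:
            best_pi, best_obj = Pi, obj
    err1 = np.abs(best_pi.sum(axis=1) - sub.g1).max()
    err2 = np.abs(best_pi.sum(axis=0) - sub.g2).max()
    if max(err1, err2) > 1e-6:
        warnings.warn(f"GW marginal violation {max(err1, err2):.2e}",
                      RuntimeWarning, stacklevel=2)
    return best_pi


def assemble_block_plan(blocks, pair: tuple[int, int],
                        n1: int, n2: int) -> TransportPlan:
    """Assemble per-cluster couplings into one block-diagonal plan.

    `blocks` is a list of (label, idx1, idx2, block).  Index sets must not
    overlap across blocks."""
    seen1: set[int] = set()
    seen2: set[int] = set()
    for _, i1, i2, B in blocks:
        if B.shape != (len(i1), len(i2)):
            raise ValueError("block shape does not match its index sets")
        s1, s2 = set(map(int, i1)), set(map(int, i2))
        if seen1 & s1 or seen2 & s2:
            raise ValueError("overlapping spot index sets across blocks")
        seen1 |= s1
        seen2 |= s2
    return TransportPlan(pair=pair, blocks=list(blocks), n1=n1, n2=n2)


def align_pair(slices: list[STSlice], labels: list[np.ndarray],
               tol: float = 1e-9, max_iter: int = 50,
               features: list[np.ndarray] | None = None,
               fuse_alpha: float = 1.0) -> list[TransportPlan]:
    """Cluster-wise (optionally fused) GW alignment for every adjacent
    slice pair."""
    plans = []
    subs_per_pair = match_shared_clusters(slices, labels, features=features)
    for h, subs in enumerate(subs_per_pair):
        blocks = [(s.label, s.idx1, s.idx2,
                   gw_align_cluster(s, tol, max_iter, fuse_alpha))
                  for s in subs]
        plans.append(assemble_block_plan(
            blocks, (h, h + 1), slices[h].n_spots, slices[h + 1].n_spots))
    return plans


# -- coordinate unification ------------------------------------------------

def weighted_procrustes(Z: np.ndarray, Zp: np.ndarray,
                        Pi: np.ndarray) -> RigidTransform:
    """Closed-form solution of min_{RᵀR=I, v} Σ_ij π_ij ‖z_i − R z'_j − v‖²
    via weighted centering and SVD of the weighted cross-covariance."""
    Z, Zp, Pi = np.asarray(Z, float), np.asarray(Zp, float), np.asarray(Pi, float)
    if np.any(Pi < 0):
        raise ValueError("coupling must be nonnegative")
    mass = Pi.sum()
    if mass <= 0:
        raise ValueError("coupling has zero total mass")
    w1 = Pi.sum(axis=1)
    w2 = Pi.sum(axis=0)
    mu = (w1 @ Z) / mass
    mup = (w2 @ Zp) / mass
    S = (Z - mu).T @ Pi @ (Zp - mup)
    if np.linalg.norm(S) < 1e-15:
        # degenerate: all mass effectively on one pair — translation only
        return RigidTransform(R=np.eye(2), v=mu - mup)
    U, _, Vt = np.linalg.svd(S)
    R = U @ Vt
    v = mu - R @ mup
    return RigidTransform(R=R, v=v)


def refined_pair_transform(Z: np.ndarray, Zp: np.ndarray, Pi: np.ndarray,
                           n_refine: int = 3) -> RigidTransform:
    """Weighted Procrustes followed by trimmed re-fitting on the argmax
    correspondences: residual outliers (wrong or diffuse couplings) are
    dropped and the rigid fit repeated, so concentrated correct matches
    register exactly."""
    T = weighted_procrustes(Z, Zp, Pi)
    col_mass = Pi.sum(axis=0)
    j_idx = np.flatnonzero(col_mass > 0)
    i_idx = Pi[:, j_idx].argmax(axis=0)
    for _ in range(n_refine):
        resid = np.linalg.norm(Z[i_idx] - T.apply(Zp[j_idx]), axis=1)
        cut = max(2.0 * np.median(resid), 1e-9)
        keep = resid <= cut
        if keep.sum() < 3:
            break
        W = np.eye(int(keep.sum())) / int(keep.sum())
        T = weighted_procrustes(Z[i_idx[keep]], Zp[j_idx[keep]], W)
        if keep.all():
            break
    return T


def transform_coordinates(sl: STSlice, transform: RigidTransform) -> STSlice:
    """Return the slice with coordinates ẑ' = R z' + v (rigid: all pairwise
    distances preserved)."""
    return STSlice(slice_id=sl.slice_id, spot_ids=list(sl.spot_ids),
                   counts=sl.counts.copy(), coords=transform.apply(sl.coords),
                   gene_ids=list(sl.gene_ids),
                   expr=None if sl.expr is None else sl.expr.copy(),
                   labels=None if sl.labels is None else sl.labels.copy())


def best_counterparts(plan: TransportPlan) -> np.ndarray:
    """For each spot of the second slice of a pair, the highest-confidence
    counterpart on the first slice: argmax of the row-normalized plan
    column, ties toward the lower index.  −1 where the spot has no mass."""
    out = np.full(plan.n2, -1, dtype=np.intp)
    M = plan.full_matrix()
    col_mass = M.sum(axis=0)
    for j in range(plan.n2):
        if col_mass[j] > 0:
            out[j] = int(np.argmax(M[:, j]))  # argmax takes the lowest index on ties
    return out


def coordinate_replacement_sweep(slices: list[STSlice],
                                 plans: list[TransportPlan]) -> list[STSlice]:
    """Give every spot of slice i>1 the coordinates of its highest-
    confidence chain ancestor on slice 1 (counterpart maps composed
    backward from the last slice to the first).  Spots without any
    transport mass keep their own coordinates."""
    if len(plans) != len(slices) - 1:
        raise ValueError("need one transport plan per adjacent slice pair")
    counterparts = [best_counterparts(p) for p in plans]
    out = [slices[0]]
    # ancestor_on_first[i][j]: spot of slice 0 reached by chaining counterparts
    chain = None
    for i in range(1, len(slices)):
        cp = counterparts[i - 1]
        if chain is None:
            anc = cp.copy()
        else:
            anc = np.where(cp >= 0, chain[np.maximum(cp, 0)], -1)
        orphan = anc < 0
        if orphan.any():
            warnings.warn(
                f"slice {slices[i].slice_id}: {int(orphan.sum())} spot(s) have no "
                "transport mass; keeping their own coordinates",
                RuntimeWarning, stacklevel=2)
        coords = slices[i].coords.copy()
        coords[~orphan] = slices[0].coords[anc[~orphan]]
        sl = slices[i]
        out.append(STSlice(slice_id=sl.slice_id, spot_ids=list(sl.spot_ids),
                           counts=sl.counts.copy(), coords=coords,
                           gene_ids=list(sl.gene_ids),
                           expr=None if sl.expr is None else sl.expr.copy(),
                           labels=None if sl.labels is None else sl.labels.copy()))
        chain = anc
    return out


@dataclass
class TransformOptConfig:
    """Differential-evolution settings for coordinate transformation."""

    popsize: int = 30
    maxiter: int = 200
    overlap_penalty: float = 1.0
    overlap_radius: float | None = None  # default: 2× median NN spacing
    seed: int = 0


def coordinate_transformation_optimize(slices: list[STSlice], links,
                                       cfg: TransformOptConfig | None = None
                                       ) -> list[RigidTransform]:
    """Per-slice rigid transforms (slice 1 fixed) minimizing the mean
    distance between correspondence-linked spots, with a penalty for the
    fraction of spots left without a nearby counterpart.

    `links` is a list of (slice_a, idx_a, slice_b, idx_b) correspondences
    (e.g. embedding-space MNNs or hard-link argmaxes).  Slices are placed
    sequentially with seeded differential evolution."""
    cfg = cfg or TransformOptConfig()
    H = len(slices)
    coords = [s.coords.copy() for s in slices]
    diag = np.linalg.norm(np.vstack(coords).max(0) - np.vstack(coords).min(0))
    if cfg.overlap_radius is None:
        c0 = coords[0]
        d = cdist(c0, c0)
        np.fill_diagonal(d, np.inf)
        radius = 2.0 * float(np.median(d.min(axis=1)))
    else:
        radius = cfg.overlap_radius
    transforms = [RigidTransform.identity()]
    placed = coords[0]
    for i in range(1, H):
        pair_links = [(a, ia, ib) for a, ia, b, ib in links if b == i and a < i]
        own = coords[i]

        def objective(params, _links=pair_links, _own=own):
            tx, ty, th = params
            T = RigidTransform.from_angle(th, (tx, ty))
            moved = T.apply(_own)
            if _links:
                src = np.array([transforms[a].apply(coords[a][ia])
                                for a, ia, _ in _links])
                dst = moved[[ib for _, _, ib in _links]]
                link_cost = float(np.linalg.norm(src - dst, axis=1).mean())
            else:
                link_cost = 0.0
            near = cdist(moved, placed).min(axis=1) <= radius
            return link_cost + cfg.overlap_penalty * (1.0 - near.mean())

        res = differential_evolution(
            objective, bounds=[(-diag, diag), (-diag, diag), (-np.pi, np.pi)],
            popsize=cfg.popsize, maxiter=cfg.maxiter, tol=1e-8,
            seed=cfg.seed + i, polish=True, init="sobol")
        if not res.success and res.message != "Maximum number of iterations has been exceeded.":
            warnings.warn(f"slice {slices[i].slice_id}: transform optimizer "
                          f"stopped early ({res.message}); using best iterate",
                          RuntimeWarning, stacklevel=2)
        tx, ty, th = res.x
        T = RigidTransform.from_angle(th, (tx, ty))
        transforms.append(T)
        placed = np.vstack([placed, T.apply(own)])
    return transforms
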