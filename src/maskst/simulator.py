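"""Synthetic spatial-transcriptomics slices with alignment ground truth.

Slices emulate a Visium-like capture array: spots on a hexagonal lattice
(unit pitch), ordered layer domains as horizontal bands (7 by default,
cortex-like), and per-layer gene programs — each layer up-regulates a
disjoint gene block — with negative-binomial count noise and an optional
slice-specific batch shift.

Partially overlapping partners are built by the rotation-and-crop
construction: the coordinates are rotated, spots whose rotated position
falls within half a lattice pitch of an original lattice site are snapped
onto that site (inheriting the site's expression), and all others are
dropped.  The retained-site map is the spot-to-spot ground truth.  The
20–100% overlap series uses the lattice's own 60° symmetry about
lattice-site pivots so the overlap region stays contiguous; the pivot
displacement is the coarse overlap knob and a crop margin the fine one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .data_model import STSlice

__all__ = [
    "SimulatedPair",
    "generate_hex_slice",
    "rotate_and_crop",
    "make_overlap_series",
]

_PITCH = 1.0  # nearest-neighbor spacing of the lattice


@dataclass
class SimulatedPair:
    """A reference slice and its rotation-and-crop partner.

    ``truth_map[s]`` is the reference spot index matched to simulated spot
    s (injective); matched spots share their expression vector by
    construction."""

    reference: STSlice
    simulated: STSlice
    truth_map: np.ndarray
    nominal_overlap: float
    rotation_deg: float

    @property
    def achieved_overlap(self) -> float:
        return len(self.truth_map) / self.reference.n_spots


def hex_lattice(n_rows: int, n_cols: int) -> np.ndarray:
    """Hexagonal lattice coordinates: odd rows offset by half a pitch,
    rows spaced √3/2 apart, so all nearest-neighbor distances equal 1."""
    r, c = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    x = c + 0.5 * (r % 2)
    y = r * (np.sqrt(3.0) / 2.0)
    return np.column_stack([x.ravel() * _PITCH, y.ravel() * _PITCH])


def hex_patch(radius: int) -> np.ndarray:
    """Hexagon-shaped patch of the triangular lattice: all sites within
    ``radius`` lattice steps of a central site (3R²+3R+1 spots).  The
    footprint is 6-fold symmetric, so a ±60° rotation about the center
    maps the patch exactly onto itself."""
    a1 = np.array([1.0, 0.0])
    a2 = np.array([0.5, np.sqrt(3.0) / 2.0])
    pts = []
    for i in range(-radius, radius + 1):
        for j in range(max(-radius, -i - radius),
                       min(radius, -i + radius) + 1):
            pts.append(i * a1 + j * a2)
    pts = np.array(pts) * _PITCH
    order = np.lexsort((pts[:, 0], pts[:, 1]))
    return pts[order]


def generate_hex_slice(n_rows: int = 28, n_cols: int = 29, n_layers: int = 7,
                       n_genes: int = 200, seed: int = 0,
                       slice_id: str = "ref", base_mean: float = 0.5,
                       program_mean: float = 5.0, dispersion: float = 2.0,
                       batch_shift: float = 0.0,
                       footprint: str = "rectangle",
                       radius: int = 16) -> STSlice:
    """Layered hexagonal slice with per-layer gene programs.

    Genes are split into ``n_layers`` disjoint blocks; block k has
    negative-binomial mean ``program_mean`` inside layer k and
    ``base_mean`` elsewhere (``dispersion`` is the NB shape).  A nonzero
    ``batch_shift`` draws a per-gene log-scale offset ~N(0, batch_shift)
    applied to all means, emulating a slice-level batch effect.

    ``footprint`` is "rectangle" (n_rows × n_cols) or "hexagon" (all
    sites within ``radius`` steps of a center site; 6-fold symmetric,
    which the partial-overlap construction exploits).  Layers are
    horizontal row bands in either case.
    """
    rng = np.random.default_rng(seed)
    if footprint == "rectangle":
        if n_layers > n_rows:
            raise ValueError(f"n_layers={n_layers} exceeds n_rows={n_rows}")
        coords = hex_lattice(n_rows, n_cols)
        row_of = np.repeat(np.arange(n_rows), n_cols)
        n_bands = n_rows
    elif footprint == "hexagon":
        coords = hex_patch(radius)
        ys, row_of = np.unique(np.round(coords[:, 1], 9), return_inverse=True)
        n_bands = len(ys)
        if n_layers > n_bands:
            raise ValueError(f"n_layers={n_layers} exceeds {n_bands} rows")
    else:
        raise ValueError(f"unknown footprint {footprint!r}")
    n_spots = coords.shape[0]
    layer = np.floor(row_of * n_layers / n_bands).astype(int)
    block = n_genes // n_layers
    means = np.full((n_spots, n_genes), base_mean)
    for k in range(n_layers):
        genes = slice(k * block, (k + 1) * block)
        means[layer == k, genes] = program_mean
    if batch_shift > 0:
        means = means * np.exp(rng.normal(0.0, batch_shift, size=n_genes))
    p = dispersion / (dispersion + means)
    counts = rng.negative_binomial(dispersion, p).astype(float)
    labels = np.array([f"L{k + 1}" for k in layer])
    return STSlice(
        slice_id=slice_id,
        spot_ids=[f"{slice_id}_{i}" for i in range(n_spots)],
        counts=counts, coords=coords,
        gene_ids=[f"g{j}" for j in range(n_genes)],
        labels=labels)


def rotate_and_crop(reference: STSlice, angle_deg: float, seed: int = 0,
                    snap_tol: float = _PITCH / 2.0, pivot="centroid",
                    crop_x: float | None = None,
                    slice_id: str | None = None) -> SimulatedPair:
    """Rotate the reference coordinates about a pivot, snap spots that
    still fall within ``snap_tol`` of an original lattice site onto that
    site, and drop the rest.  The simulated slice therefore consists of
    the reference spots at the retained sites (identical expression), and
    the truth map is the retained-site index list.

    ``pivot`` is "centroid" (in-place rotation), "corner" (the lower-left
    lattice corner) or an explicit 2-D point.  When ``crop_x`` is given,
    retained sites with x-coordinate above it are cropped away (the fine
    overlap-ratio knob of the series construction)."""
    theta = np.deg2rad(angle_deg)
    R = np.array([[np.cos(theta), -np.sin(theta)],
                  [np.sin(theta), np.cos(theta)]])
    if isinstance(pivot, str) and pivot == "centroid":
        center = reference.coords.mean(axis=0)
    elif isinstance(pivot, str) and pivot == "corner":
        center = reference.coords.min(axis=0)
    else:
        center = np.asarray(pivot, float).reshape(2)
    rotated = (reference.coords - center) @ R.T + center
    tree = cKDTree(reference.coords)
    dist, site = tree.query(rotated)
    hit = dist <= snap_tol
    # several rotated spots may snap to one site: keep each site once
    sites = np.unique(site[hit])
    if crop_x is not None:
        sites = sites[reference.coords[sites, 0] <= crop_x]
    if sites.size == 0:
        raise ValueError(
            f"rotation by {angle_deg}° leaves no spot on the lattice; "
            "use a smaller angle")
    sid = slice_id or f"{reference.slice_id}_rot{angle_deg:g}"
    simulated = STSlice(
        slice_id=sid,
        spot_ids=[f"{sid}_{i}" for i in sites],
        counts=reference.counts[sites].copy(),
        coords=reference.coords[sites].copy(),
        gene_ids=list(reference.gene_ids),
        expr=None if reference.expr is None else reference.expr[sites].copy(),
        labels=None if reference.labels is None else reference.labels[sites].copy())
    overlap = sites.size / reference.n_spots
    return SimulatedPair(reference=reference, simulated=simulated,
                         truth_map=sites, nominal_overlap=overlap,
                         rotation_deg=angle_deg)


def _pivot_candidates(radius_extent: float) -> np.ndarray:
    """Triangular-lattice sites (rotation centers of the 60° symmetry)
    sorted by distance from the origin."""
    a1 = np.array([1.0, 0.0])
    a2 = np.array([0.5, np.sqrt(3.0) / 2.0])
    m = int(np.ceil(radius_extent)) + 1
    pts = []
    for i in range(-m, m + 1):
        for j in range(-m, m + 1):
            p = i * a1 + j * a2
            if np.linalg.norm(p) <= radius_extent:
                pts.append(p)
    pts = np.array(pts) * _PITCH
    return pts[np.argsort(np.linalg.norm(pts, axis=1), kind="stable")]


def make_overlap_series(reference: STSlice,
                        targets=(0.2, 0.4, 0.6, 0.8, 1.0),
                        tol: float = 0.02, seed: int = 0,
                        snap_tol: float = _PITCH / 2.0,
                        angle_deg: float = 60.0) -> list[SimulatedPair]:
    """Rotation-and-crop partners dialed to the requested overlap ratios,
    with contiguous overlap regions.

    The reference must be a 6-fold-symmetric hexagonal patch (see
    ``generate_hex_slice(footprint="hexagon")``).  Each partner is built
    by the 60° lattice-symmetry rotation about a lattice-site pivot:
    rotated spots coincide exactly with original sites, and the overlap
    region — the intersection of the footprint with its displaced image —
    is a contiguous lens whose size shrinks as the pivot moves away from
    the patch center.  The pivot displacement is the coarse overlap knob;
    a crop margin (guillotine cut along x on the retained sites) is
    bisected for fine adjustment to within ``tol`` of each target.
    Unreachable targets are skipped with a warning."""
    center = reference.coords.mean(axis=0)
    extent = np.linalg.norm(reference.coords - center, axis=1).max()
    pivots = _pivot_candidates(2.5 * extent)
    pairs = []
    for target in targets:
        if target >= 1.0 - 1e-12:
            pairs.append(rotate_and_crop(reference, 0.0, seed=seed,
                                         snap_tol=snap_tol))
            continue
        chosen, chosen_pivot = None, None
        for p in pivots:
            try:
                cand = rotate_and_crop(reference, angle_deg, seed=seed,
                                       snap_tol=snap_tol, pivot=center + p)
            except ValueError:
                break
            if cand.achieved_overlap >= target:
                chosen, chosen_pivot = cand, center + p  # smallest lens ≥ target
            else:
                break
        if chosen is None:
            warnings.warn(f"target overlap {target} unreachable; skipped",
                          RuntimeWarning, stacklevel=2)
            continue
        if chosen.achieved_overlap - target > 1e-12:
            # fine knob: guillotine crop along x, bisected on the threshold
            xs = reference.coords[chosen.truth_map, 0]
            lo, hi = xs.min() - 1.0, xs.max() + 1.0
            for _ in range(50):
                mid = (lo + hi) / 2.0
                frac = (xs <= mid).sum() / reference.n_spots
                if frac >= target:
                    hi = mid
                else:
                    lo = mid
            chosen = rotate_and_crop(reference, chosen.rotation_deg, seed=seed,
                                     snap_tol=snap_tol, pivot=chosen_pivot,
                                     crop_x=hi)
        if abs(chosen.achieved_overlap - target) > tol:
            warnings.warn(f"target overlap {target}: best achievable differs "
                          f"by {abs(chosen.achieved_overlap - target):.3f} "
                          f"(> tol {tol}); skipped", RuntimeWarning,
                          stacklevel=2)
            continue
        chosen.nominal_overlap = target
        pairs.append(chosen)
    return pairs
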