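"""Voronoi-treemap layout of the drug dendrogram ("drug atlas").

The cluster tree is flattened onto a 2D container by recursively applying a
weighted centroidal Voronoi tessellation: the tree is first cut at a branch
grouping threshold, the resulting groups partition the container, and each
group's convex region is partitioned again following the binary splits of
its subtree down to one convex cell per drug.  Cell areas are driven toward
weight-proportional targets by iterating an additively weighted Voronoi
diagram (power diagram) with Lloyd centroid moves and per-cell weight
adaptation.  Borders between cells are annotated with the cophenetic
distance of the separating split, so thick borders mark deep splits.

The power diagram of sites p_i with additive weights w_i assigns to cell i
the points x with |x - p_i|^2 - w_i minimal; each cell is the intersection
of the container with the half-planes

    2 (p_j - p_i) . x  <=  |p_j|^2 - |p_i|^2 + w_i - w_j      for all j != i,

which is how it is computed here (equivalent to the classical lift of the
plane to a 3D convex hull; the contract is the diagram, not the algorithm).
All randomness is drawn from a seeded generator, so layouts are fully
deterministic given (inputs, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster import hierarchy
from scipy.stats import qmc
from shapely.geometry import Point, Polygon

from .distance import ClusterTree, cophenetic_distance

_HALF_R = 1e3  # extent of the half-plane proxy polygons


@dataclass
class AtlasLayout:
    """Result of the treemap layout: one convex cell per drug.

    ``border_weight`` maps canonical (drug_a, drug_b) adjacency keys to the
    cophenetic distance (raw merge height) of the split separating them.
    """

    container: Polygon
    cells: dict
    sites: dict
    weights: dict = field(default_factory=dict)
    border_weight: dict = field(default_factory=dict)
    threshold: float | None = None
    group_of: dict = field(default_factory=dict)
    group_regions: dict = field(default_factory=dict)
    converged: bool = True
    achieved_tol: float = 0.0

    def area_fractions(self) -> dict:
        total = self.container.area
        return {d: c.area / total for d, c in self.cells.items()}


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

def circle_container(radius: float = 1.0, n_vertices: int = 96) -> Polygon:
    """Regular-polygon approximation of a disc (the default map outline)."""
    theta = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    return Polygon(np.c_[radius * np.cos(theta), radius * np.sin(theta)])


def rect_container(width: float = 2.0, height: float = 2.0) -> Polygon:
    w, h = width / 2, height / 2
    return Polygon([(-w, -h), (w, -h), (w, h), (-w, h)])


# ---------------------------------------------------------------------------
# Branch grouping threshold
# ---------------------------------------------------------------------------

def branch_threshold(tree: ClusterTree, depth_fraction: float = 0.25) -> float:
    """Merge height at which the cumulative fraction of merges (counted from
    the leaves upward) first reaches ``depth_fraction``.

    Branches merging strictly below the returned threshold are grouped into
    one top-level region each.
    """
    if not (0 < depth_fraction < 1) and depth_fraction != 1:
        raise ValueError("depth_fraction must lie in (0, 1]")
    heights = np.sort(tree.merge_heights)
    if heights.size == 0:
        return 0.0
    if heights.size == 1:
        return float(heights[0])
    if np.allclose(heights, heights[0]):
        warnings.warn("degenerate tree: all merge heights equal", stacklevel=2)
        return float(heights[0])
    m = heights.size
    idx = min(max(int(np.ceil(depth_fraction * m)) - 1, 0), m - 1)
    return float(heights[idx])


# ---------------------------------------------------------------------------
# Power diagram by half-plane clipping
# ---------------------------------------------------------------------------

def _halfplane(a: np.ndarray, b: float) -> Polygon:
    """Large polygon covering {x : a . x <= b} (|a| > 0)."""
    norm = np.linalg.norm(a)
    u = a / norm
    c = b / norm
    t = np.array([-u[1], u[0]])
    p0 = c * u
    return Polygon([
        p0 + _HALF_R * t,
        p0 - _HALF_R * t,
        p0 - _HALF_R * t - 2 * _HALF_R * u,
        p0 + _HALF_R * t - 2 * _HALF_R * u,
    ])


def power_diagram(region: Polygon, sites: np.ndarray, weights: np.ndarray) -> list:
    """Clip the additively weighted Voronoi diagram of ``sites`` to ``region``.

    Returns one (possibly empty) polygon per site.  ``region`` must be
    convex, so every cell is convex.
    """
    sites = np.asarray(sites, float)
    weights = np.asarray(weights, float)
    k = len(sites)
    cells = []
    sq = np.einsum("ij,ij->i", sites, sites)
    for i in range(k):
        cell = region
        order = np.argsort(np.einsum("ij,ij->i", sites - sites[i], sites - sites[i]))
        for j in order:
            if j == i:
                continue
            a = 2.0 * (sites[j] - sites[i])
            if np.linalg.norm(a) < 1e-12:
                continue  # coincident sites: leave to the other's half-plane
            b = sq[j] - sq[i] + weights[i] - weights[j]
            cell = cell.intersection(_halfplane(a, b))
            if cell.is_empty or cell.area < 1e-14:
                cell = Polygon()
                break
        if not isinstance(cell, Polygon):
            cell = max(cell.geoms, key=lambda g: g.area) if hasattr(cell, "geoms") else Polygon()
        cells.append(cell)
    return cells


def _low_discrepancy_sites(region: Polygon, k: int, rng: np.random.Generator) -> np.ndarray:
    """k well-spread points inside a convex region (scrambled Halton)."""
    minx, miny, maxx, maxy = region.bounds
    sampler = qmc.Halton(d=2, scramble=True, seed=int(rng.integers(2**31)))
    pts = []
    while len(pts) < k:
        cand = sampler.random(4 * k)
        cand = np.c_[minx + cand[:, 0] * (maxx - minx),
                     miny + cand[:, 1] * (maxy - miny)]
        for p in cand:
            if region.contains(Point(p)):
                pts.append(p)
                if len(pts) == k:
                    break
    return np.array(pts)


def _weighted_cvt(region: Polygon, targets: np.ndarray, rng: np.random.Generator,
                  init_sites=None, init_weights=None,
                  max_iter: int = 200, area_tol: float = 0.02):
    """Iterate (power diagram, centroid move, weight adaptation) until every
    cell area is within ``area_tol`` of its weight-proportional target.

    Returns (cells, sites, weights, achieved_err, converged); the best
    configuration seen is kept, so extra iterations never degrade the layout.
    """
    k = len(targets)
    area = region.area
    targets = np.asarray(targets, float)
    targets = targets / targets.sum() * area
    if k == 1:
        c = region.centroid
        return [region], np.array([[c.x, c.y]]), np.zeros(1), 0.0, True

    sites = (np.asarray(init_sites, float) if init_sites is not None
             else _low_discrepancy_sites(region, k, rng))
    w = np.zeros(k) if init_weights is None else np.asarray(init_weights, float).copy()
    best = None
    best_err = np.inf
    for _ in range(max_iter):
        cells = power_diagram(region, sites, w)
        areas = np.array([c.area for c in cells])
        err = float(np.max(np.abs(areas - targets) / targets))
        if err < best_err:
            best_err, best = err, (cells, sites.copy(), w.copy())
        if err <= area_tol:
            break
        # Lloyd step: move non-empty cells to their centroids
        new_sites = sites.copy()
        for i, c in enumerate(cells):
            if not c.is_empty and c.area > 0:
                new_sites[i] = [c.centroid.x, c.centroid.y]
            else:
                # nudge a vanished site toward the region centre
                rc = region.centroid
                new_sites[i] = 0.7 * sites[i] + 0.3 * np.array([rc.x, rc.y])
        sites = new_sites
        # additive weight adaptation: grow under-sized cells
        w = w + 0.7 * (targets - areas)
        w -= w.mean()
        # keep weights from exceeding squared site spacing (cells vanish)
        spread = max(region.bounds[2] - region.bounds[0],
                     region.bounds[3] - region.bounds[1])
        np.clip(w, -(spread ** 2), spread ** 2, out=w)
    cells, sites, w = best
    return cells, sites, w, best_err, best_err <= area_tol


# ---------------------------------------------------------------------------
# Recursive treemap
# ---------------------------------------------------------------------------

def _group_roots(root, b: float):
    """Maximal subtree nodes whose merge height is strictly below b,
    together with the height at which each attaches to the rest."""
    out = []

    def rec(nd, parent_height):
        if nd.is_leaf() or nd.dist < b:
            out.append((nd, parent_height))
        else:
            rec(nd.left, nd.dist)
            rec(nd.right, nd.dist)

    rec(root, root.dist)
    return out


def _leaf_ids(nd) -> list:
    return nd.pre_order(lambda x: x.id)


def _boundary_points(container: Polygon, m: int, rng: np.random.Generator) -> np.ndarray:
    """m maximally separated points on the container boundary, pulled
    slightly inward, starting at a seeded offset."""
    ring = container.exterior
    L = ring.length
    off = rng.uniform(0, L)
    pts = []
    c = container.centroid
    for i in range(m):
        p = ring.interpolate((off + i * L / m) % L)
        pts.append([c.x + 0.8 * (p.x - c.x), c.y + 0.8 * (p.y - c.y)])
    return np.array(pts)


def layout_voronoi_treemap(
    tree: ClusterTree,
    b: float | None = None,
    container: Polygon | None = None,
    weights: dict | None = None,
    seed: int = 0,
    max_iter: int = 400,
    area_tol: float = 0.02,
    depth_fraction: float = 0.25,
) -> AtlasLayout:
    """Lay the cluster tree out as a weighted centroidal Voronoi treemap.

    Parameters
    ----------
    b : float, optional
        Branch grouping threshold; computed from ``depth_fraction`` when
        omitted.
    container : shapely Polygon, optional
        Convex container (unit-circle disc by default).
    weights : dict drug -> positive weight, optional
        Target cell areas are proportional to these (uniform by default).
    area_tol : float
        Relative area tolerance for the final leaf cells (default 2%).
        Because the recursion nests tessellations, each inner tessellation
        is iterated to a tighter tolerance (``area_tol`` divided by the
        recursion depth, at least 8x tighter) so that errors compounding
        down a root-to-leaf path stay inside ``area_tol`` globally; the
        reported ``achieved_tol`` is the measured worst leaf error.

    Early-diverging top-level groups are seeded at maximally separated
    container boundary points (deepest split closest to the rim), then each
    group region is split recursively along the binary tree.  A final
    smoothing relaxation re-runs the bottom-level tessellations from their
    converged state with the site-to-region assignment frozen.
    """
    rng = np.random.default_rng(seed)
    if container is None:
        container = circle_container()
    labels = tree.labels
    if weights is None:
        weights = {d: 1.0 for d in labels}
    wvec = np.array([weights[d] for d in labels], float)
    if np.any(wvec <= 0):
        raise ValueError("cell weights must be strictly positive")

    if tree.n_leaves == 1:
        c = container.centroid
        return AtlasLayout(container, {labels[0]: container},
                           {labels[0]: (c.x, c.y)}, dict(weights),
                           threshold=0.0, group_of={labels[0]: 0},
                           group_regions={0: container})

    if b is None:
        b = branch_threshold(tree, depth_fraction)
    root = hierarchy.to_tree(tree.Z)

    def _depth(nd):
        return 0 if nd.is_leaf() else 1 + max(_depth(nd.left), _depth(nd.right))

    inner_tol = area_tol / max(8, _depth(root) + 1)

    # --- top level: grouped tree partitions the container -----------------
    groups = _group_roots(root, b)
    # deepest-splitting groups toward the rim ("corners")
    groups.sort(key=lambda g: (-g[1], min(_leaf_ids(g[0]))))
    g_targets = np.array([sum(wvec[i] for i in _leaf_ids(nd)) for nd, _ in groups])
    init = _boundary_points(container, len(groups), rng)
    g_cells, g_sites, _gw, g_err, g_conv = _weighted_cvt(
        container, g_targets, rng, init_sites=init,
        max_iter=max_iter, area_tol=inner_tol)

    cells: dict = {}
    sites: dict = {}
    group_of: dict = {}
    group_regions: dict = {}
    worst = g_err
    converged = g_conv
    bottom_runs = []  # (region, node_list, sites) for the smoothing pass

    def descend(nd, region):
        nonlocal worst, converged
        if nd.is_leaf():
            lab = labels[nd.id]
            cells[lab] = region
            c = region.centroid
            sites[lab] = (c.x, c.y)
            return
        kids = [nd.left, nd.right]
        t = np.array([sum(wvec[i] for i in _leaf_ids(k)) for k in kids])
        sub_cells, sub_sites, sub_w, err, conv = _weighted_cvt(
            region, t, rng, max_iter=max_iter, area_tol=inner_tol)
        worst = max(worst, err)
        converged = converged and conv
        if all(k.is_leaf() for k in kids):
            bottom_runs.append((region, kids, sub_cells, sub_sites, sub_w, err))
        for k_nd, c_poly in zip(kids, sub_cells):
            descend(k_nd, c_poly)

    for gid, ((nd, _h), region) in enumerate(zip(groups, g_cells)):
        group_regions[gid] = region
        for i in _leaf_ids(nd):
            group_of[labels[i]] = gid
        descend(nd, region)

    # --- smoothing: re-relax bottom tessellations, assignment frozen ------
    # Continues each bottom-level tessellation from its converged state
    # (sites and weights carried over); the relaxed result is kept only when
    # it does not worsen that region's area error.
    for region, kids, c0, s0, w0, err0 in bottom_runs:
        t = np.array([wvec[k.id] for k in kids])
        sub_cells, sub_sites, _w, err, _ = _weighted_cvt(
            region, t, rng, init_sites=s0, init_weights=w0,
            max_iter=10, area_tol=inner_tol)
        if err > err0:
            sub_cells, sub_sites = c0, s0
        for k_nd, c_poly, sp in zip(kids, sub_cells, sub_sites):
            lab = labels[k_nd.id]
            cells[lab] = c_poly
            sites[lab] = tuple(sp)

    # measured end-to-end proportionality of the leaf cells
    total = container.area
    target_frac = wvec / wvec.sum()
    leaf_err = max(
        abs(cells[d].area / total - target_frac[i]) / target_frac[i]
        for i, d in enumerate(labels)
    )
    converged = converged and leaf_err <= area_tol
    if not converged:
        warnings.warn(
            f"treemap did not reach area tolerance {area_tol:.3g} within "
            f"{max_iter} iterations (worst leaf error {leaf_err:.3g})",
            stacklevel=2)

    layout = AtlasLayout(
        container=container, cells=cells, sites=sites, weights=dict(weights),
        threshold=b, group_of=group_of, group_regions=group_regions,
        converged=converged, achieved_tol=float(leaf_err),
    )
    return border_weights(layout, tree)


def border_weights(layout: AtlasLayout, tree: ClusterTree) -> AtlasLayout:
    """Annotate each shared cell boundary with the cophenetic distance (raw
    merge height) of the split separating the two drugs.

    Sibling cells merged low in the tree therefore get thin borders, cells
    separated only at the root get the thickest.
    """
    coph = cophenetic_distance(tree, normalize=False).matrix
    drugs = list(layout.cells)
    bw = {}
    for i, a in enumerate(drugs):
        pa = layout.cells[a]
        if pa.is_empty:
            continue
        grown = pa.buffer(1e-7)
        for b in drugs[i + 1:]:
            pb = layout.cells[b]
            if pb.is_empty:
                continue
            contact = grown.intersection(pb)
            if contact.area > 1e-10:  # touching along a segment, not a point
                key = tuple(sorted((a, b)))
                bw[key] = float(coph.loc[a, b])
    layout.border_weight = bw
    return layout
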