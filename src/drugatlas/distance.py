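"""Drug-effect dissimilarity and dendrogram distances.

The dissimilarity between two drugs is one minus the cosine similarity of
their effect vectors (1 - AUC per cell line, restricted to shared cell
lines).  The dissimilarity matrix is clustered hierarchically (Ward.D2 or
average linkage) and pairwise drug distances are then read off the tree as
cophenetic distances: the merge height of the pair's lowest common ancestor,
optionally normalized by the root height so the farthest pair sits at 1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .io import Annotation, ResponseMatrix

logger = logging.getLogger("drugatlas")


@dataclass
class DistanceMatrix:
    """Symmetric item x item dissimilarity matrix with a metric tag.

    ``zero_diag=False`` admits target-level matrices whose diagonal holds
    the mean within-target cross-drug distance rather than 0.
    """

    matrix: pd.DataFrame
    metric: str = "cosine"
    zero_diag: bool = True

    def __post_init__(self):
        m = self.matrix
        if list(m.index) != list(m.columns):
            raise ValueError("distance matrix must have identical row/column items")
        vals = m.to_numpy(float)
        if self.zero_diag and np.any(np.diag(vals) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        with np.errstate(invalid="ignore"):
            if np.nanmin(vals) < -1e-12:
                raise ValueError("distances must be non-negative")
        if not np.allclose(vals, vals.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")

    @property
    def items(self) -> list:
        return list(self.matrix.index)

    def condensed(self, impute_median: bool = True) -> np.ndarray:
        """Condensed upper-triangle vector; missing entries imputed by the
        matrix median (count logged) so linkage can run."""
        vals = self.matrix.to_numpy(float).copy()
        iu = np.triu_indices_from(vals, k=1)
        cond = vals[iu]
        n_missing = int(np.isnan(cond).sum())
        if n_missing:
            if not impute_median:
                raise ValueError(f"{n_missing} missing pairwise distances")
            med = np.nanmedian(cond)
            logger.warning("imputing %d missing pairwise distances by median %.4g",
                           n_missing, med)
            cond = np.where(np.isnan(cond), med, cond)
        return cond


class ClusterTree:
    """Binary dendrogram over drugs: scipy linkage matrix + leaf labels.

    Leaves are sorted lexicographically before linkage so the merge set is
    invariant under permutation of the input rows (deterministic tie-break).
    """

    def __init__(self, labels, linkage_matrix, method: str):
        self.labels = list(labels)
        self.Z = np.asarray(linkage_matrix, float) if linkage_matrix is not None else None
        self.method = method
        if self.Z is not None:
            n = len(self.labels)
            if self.Z.shape[0] != n - 1:
                raise ValueError("a binary tree over n leaves has n-1 merges")
            h = self.Z[:, 2]
            if np.any(np.diff(h) < -1e-12):
                raise ValueError("merge heights must be non-decreasing toward the root")

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    @property
    def root_height(self) -> float:
        if self.Z is None or len(self.Z) == 0:
            return 0.0
        return float(self.Z[-1, 2])

    @property
    def merge_heights(self) -> np.ndarray:
        return self.Z[:, 2].copy() if self.Z is not None else np.empty(0)

    def cophenetic_matrix(self, normalize: bool = True) -> DistanceMatrix:
        return cophenetic_distance(self, normalize=normalize)

    def cut(self, height: float) -> dict:
        """Group leaves by cutting merges at strictly < ``height``.

        Returns mapping leaf -> group id (0-based, ordered by first leaf).
        """
        if self.Z is None or len(self.Z) == 0:
            return {self.labels[0]: 0}
        t = np.nextafter(height, -np.inf)
        flat = hierarchy.fcluster(self.Z, t=t, criterion="distance")
        order, remap = [], {}
        for lab, g in zip(self.labels, flat):
            if g not in remap:
                remap[g] = len(order)
                order.append(g)
        return {lab: remap[g] for lab, g in zip(self.labels, flat)}

    def to_newick(self) -> str:
        """Newick string, branch lengths = parent height - child height."""
        if self.n_leaves == 1:
            return f"{self.labels[0]};"
        node = hierarchy.to_tree(self.Z)

        def rec(nd, parent_height):
            if nd.is_leaf():
                return f"{self.labels[nd.id]}:{parent_height - 0.0:.10g}"
            left = rec(nd.left, nd.dist)
            right = rec(nd.right, nd.dist)
            bl = parent_height - nd.dist
            return f"({left},{right}):{bl:.10g}"

        body = rec(node, node.dist)
        # strip the root's zero-length branch
        return body.rsplit(":", 1)[0] + ";"


@dataclass
class CopheneticReport:
    """Cophenetic correlation diagnostic.

    ``c`` is the Pearson correlation between the original pairwise
    dissimilarities x(i,j) and the dendrogrammatic (cophenetic) distances
    t(i,j) over all i < j, computed directly as

        c = sum (x - xbar)(t - tbar) / sqrt( sum (x-xbar)^2 * sum (t-tbar)^2 )
    """

    c: float
    x_pairs: np.ndarray
    t_pairs: np.ndarray
    x_mean: float = field(init=False)
    t_mean: float = field(init=False)

    def __post_init__(self):
        self.x_mean = float(np.mean(self.x_pairs))
        self.t_mean = float(np.mean(self.t_pairs))


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def cosine_dissimilarity(m: ResponseMatrix, min_overlap: int = 5) -> DistanceMatrix:
    """1 - cosine similarity between drugs' effect vectors (1 - AUC).

    Each pair is evaluated on the cell lines where both drugs have values;
    pairs sharing fewer than ``min_overlap`` lines get a missing entry (with
    a warning).  A drug whose effect vector is identically zero has no
    direction and raises.
    """
    if m.value_kind != "auc":
        raise ValueError("cosine dissimilarity is defined on AUC panels")
    eff = m.one_minus_auc()
    drugs = list(eff.index)
    X = eff.to_numpy(float)
    n = len(drugs)
    for i, d in enumerate(drugs):
        v = X[i]
        obs = v[~np.isnan(v)]
        if obs.size and np.allclose(obs, 0):
            raise ValueError(f"drug {d!r} has an all-zero effect vector")
    out = np.zeros((n, n))
    n_short = 0
    for i in range(n):
        for j in range(i + 1, n):
            mask = ~np.isnan(X[i]) & ~np.isnan(X[j])
            if mask.sum() < min_overlap:
                out[i, j] = out[j, i] = np.nan
                n_short += 1
                continue
            a, b = X[i, mask], X[j, mask]
            na, nb = np.linalg.norm(a), np.linalg.norm(b)
            if na == 0 or nb == 0:
                out[i, j] = out[j, i] = np.nan
                n_short += 1
                continue
            d = 1.0 - float(a @ b) / (na * nb)
            out[i, j] = out[j, i] = max(d, 0.0)
    if n_short:
        warnings.warn(f"{n_short} drug pair(s) below min_overlap={min_overlap}; "
                      "entries left missing", stacklevel=2)
    return DistanceMatrix(pd.DataFrame(out, index=drugs, columns=drugs),
                          metric="cosine")


def cluster_drugs(d: DistanceMatrix, method: str = "ward_d2") -> ClusterTree:
    """Hierarchical clustering of the dissimilarity matrix.

    ``ward_d2`` maps to scipy's 'ward' on the condensed distance matrix
    (the distance-input Ward variant); ``average`` is UPGMA.  Leaves are
    sorted lexicographically first, making the result independent of input
    row order.
    """
    scipy_method = {"ward_d2": "ward", "average": "average"}.get(method)
    if scipy_method is None:
        raise ValueError(f"unknown linkage method {method!r}")
    items = d.items
    if len(items) < 2:
        raise ValueError("clustering needs at least two items")
    order = np.argsort(np.asarray(items, dtype=object))
    labels = [items[i] for i in order]
    mat = d.matrix.iloc[order, order]
    cond = DistanceMatrix(mat, d.metric).condensed()
    Z = hierarchy.linkage(cond, method=scipy_method)
    Z[:, 2] = np.maximum.accumulate(Z[:, 2])  # guard FP monotonicity
    return ClusterTree(labels, Z, method)


def cophenetic_distance(tree: ClusterTree, normalize: bool = True) -> DistanceMatrix:
    """Pairwise cophenetic distances: LCA merge height for each leaf pair.

    With ``normalize`` the heights are divided by the root height so the
    maximum distance is exactly 1 (bounded covariate for regression).  The
    result is ultrametric: d(i,k) <= max(d(i,j), d(j,k)) for every triple.
    """
    if tree.n_leaves == 1:
        mat = pd.DataFrame([[0.0]], index=tree.labels, columns=tree.labels)
        return DistanceMatrix(mat, metric="cophenetic")
    cond = hierarchy.cophenet(tree.Z)
    if normalize and tree.root_height > 0:
        cond = cond / tree.root_height
    full = squareform(cond)
    mat = pd.DataFrame(full, index=tree.labels, columns=tree.labels)
    return DistanceMatrix(mat, metric="cophenetic")


def cophenetic_correlation(input_d: DistanceMatrix, tree: ClusterTree) -> CopheneticReport:
    """Cophenetic correlation between input dissimilarities and tree distances.

    Computed by the explicit product-moment formula over all i < j pairs
    (algebraically the Pearson correlation of the two condensed vectors).
    Returns ``c = nan`` with a warning when the tree distances are constant.
    """
    if set(input_d.items) != set(tree.labels):
        raise ValueError("distance matrix and tree cover different item sets")
    mat = input_d.matrix.loc[tree.labels, tree.labels]
    x = DistanceMatrix(mat, input_d.metric).condensed()
    t = hierarchy.cophenet(tree.Z)
    xb, tb = x.mean(), t.mean()
    st = np.sum((t - tb) ** 2)
    sx = np.sum((x - xb) ** 2)
    if st == 0 or sx == 0:
        warnings.warn("constant distances: cophenetic correlation undefined",
                      stacklevel=2)
        return CopheneticReport(float("nan"), x, t)
    c = float(np.sum((x - xb) * (t - tb)) / np.sqrt(sx * st))
    return CopheneticReport(c, x, t)


def target_distance(tree: ClusterTree, ann: Annotation,
                    normalize: bool = True) -> DistanceMatrix:
    """Target-level distances: mean cophenetic distance over cross drug pairs.

    Several drugs can share a target, so the distance between targets u and v
    averages the drug-level cophenetic distance over every (drug with u,
    drug with v) pair, excluding identical-drug pairs.  The diagonal holds
    the mean within-target cross-drug distance (0 for a single-drug target).
    A target pair with no valid cross pair gets a missing entry.
    """
    coph = cophenetic_distance(tree, normalize=normalize).matrix
    drugs_in_tree = set(tree.labels)
    target_drugs: dict = {}
    for drug, targets in ann.targets_of.items():
        if drug not in drugs_in_tree:
            continue
        for t in targets:
            target_drugs.setdefault(t, set()).add(drug)
    targets = sorted(target_drugs)
    n = len(targets)
    out = np.zeros((n, n))
    for i, u in enumerate(targets):
        for j in range(i, n):
            v = targets[j]
            pairs = [(a, b) for a in target_drugs[u] for b in target_drugs[v]
                     if a != b]
            if not pairs:
                val = 0.0 if i == j else np.nan
            else:
                val = float(np.mean([coph.loc[a, b] for a, b in pairs]))
            out[i, j] = out[j, i] = val
    return DistanceMatrix(pd.DataFrame(out, index=targets, columns=targets),
                          metric="cophenetic-target", zero_diag=False)


def pathway_distance_sets(tree: ClusterTree, ann: Annotation,
                          normalize: bool = True):
    """Split cophenetic distances into within- and between-pathway sets.

    Drugs flagged cross-reactive (active over multiple pathways) are
    excluded before pairing; drugs without a pathway label are skipped.
    """
    if not ann.pathway_of:
        raise ValueError("no pathway labels available")
    coph = cophenetic_distance(tree, normalize=normalize).matrix
    drugs = [d for d in tree.labels
             if d in ann.pathway_of and d not in ann.cross_reactive]
    within, between = [], []
    for i, a in enumerate(drugs):
        for b in drugs[i + 1:]:
            d = float(coph.loc[a, b])
            (within if ann.pathway_of[a] == ann.pathway_of[b] else between).append(d)
    return within, between
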