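"""Signature clustering: weighted uncentered-correlation distance, average
linkage, cluster extraction, composition k-means control, sequence-similarity
control, and query annotation transfer."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

logger = logging.getLogger(__name__)


def uncentered_correlation_distance(x, y, w=None) -> float:
    """1 - uncentered (about-zero) correlation over pairwise-complete
    dimensions, optionally dimension-weighted; in [0, 2]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.ones_like(x) if w is None else np.asarray(w, dtype=float)
    m = np.isfinite(x) & np.isfinite(y)
    if not m.any():
        raise ValueError("no pairwise-complete dimensions")
    xx = float(np.sum(w[m] * x[m] * x[m]))
    yy = float(np.sum(w[m] * y[m] * y[m]))
    if xx <= 0 or yy <= 0:
        raise ValueError("zero norm over pairwise-complete dimensions")
    r = float(np.sum(w[m] * x[m] * y[m])) / np.sqrt(xx * yy)
    return float(np.clip(1.0 - r, 0.0, 2.0))


def distance_matrix(
    matrix: np.ndarray,
    dim_weights=None,
    min_shared: float = 0.5,
) -> np.ndarray:
    """All-pairs uncentered-correlation distances for a (items x dims) matrix
    with MISSING entries.

    Pairs sharing fewer than ``min_shared`` of the dimensions get a MISSING
    distance which is then imputed as the matrix maximum (logged).
    """
    X = np.asarray(matrix, dtype=float)
    n, d = X.shape
    w = np.ones(d) if dim_weights is None else np.asarray(dim_weights, dtype=float)
    finite = np.isfinite(X)
    Xz = np.where(finite, X, 0.0)
    Wx = finite.astype(float)
    # weighted cross-products restricted to pairwise-complete dims
    XY = (Xz * w) @ Xz.T
    XX = (Xz * Xz * w) @ Wx.T          # sum w x^2 over dims finite in both
    shared = finite.astype(np.int64) @ finite.astype(np.int64).T
    with np.errstate(invalid="ignore", divide="ignore"):
        r = XY / np.sqrt(XX * XX.T)
    D = 1.0 - r
    bad = (shared < min_shared * d) | ~np.isfinite(D)
    np.fill_diagonal(bad, False)
    if bad.any():
        finite_vals = D[~bad & np.isfinite(D)]
        fill = float(finite_vals.max()) if finite_vals.size else 2.0
        n_bad = int(bad.sum() // 2)
        logger.info("imputing %d missing pairwise distances as %.3f", n_bad, fill)
        D = np.where(bad, fill, D)
    np.fill_diagonal(D, 0.0)
    return np.clip(D, 0.0, 2.0)


def compute_item_weights(
    matrix: np.ndarray, cutoff: float = 0.8, exponent: float = 1.0,
    dim_weights=None,
) -> np.ndarray:
    """Density down-weighting: ``w_i = 1 / sum_j max(0, 1 - d_ij/cutoff)^k``
    with the self term included, so crowded items weigh less."""
    D = distance_matrix(matrix, dim_weights=dim_weights)
    contrib = np.maximum(0.0, 1.0 - D / cutoff) ** exponent
    return 1.0 / contrib.sum(axis=1)


@dataclass
class Dendrogram:
    """Average-linkage merge tree in scipy linkage layout.

    ``merges`` rows: (left id, right id, height, size); leaf ids 0..n-1,
    internal node i gets id n+i.
    """

    n_items: int
    merges: np.ndarray
    labels: list[str] = field(default_factory=list)

    def heights(self) -> np.ndarray:
        return self.merges[:, 2]


def average_linkage(dist: np.ndarray, labels=None) -> Dendrogram:
    """UPGMA on a precomputed distance matrix; ties broken by the smallest
    (i, j) cluster-id pair."""
    D = np.asarray(dist, dtype=float).copy()
    n = D.shape[0]
    if D.shape != (n, n):
        raise ValueError("distance matrix must be square")
    if n < 2:
        raise ValueError("need at least 2 items")
    active = {i: (i, 1) for i in range(n)}  # index in D -> (cluster id, size)
    merges = np.empty((n - 1, 4))
    next_id = n
    idx = list(range(n))
    for step in range(n - 1):
        best = None
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                ia, ib = idx[a], idx[b]
                d = D[ia, ib]
                ids = tuple(sorted((active[ia][0], active[ib][0])))
                key = (d, ids)
                if best is None or key < best[0]:
                    best = (key, ia, ib)
        (_, _), ia, ib = best[0], best[1], best[2]
        d = D[ia, ib]
        id_a, size_a = active[ia]
        id_b, size_b = active[ib]
        lo, hi = sorted((id_a, id_b))
        merges[step] = (lo, hi, d, size_a + size_b)
        # UPGMA update: size-weighted average distance to the merged cluster
        for other in idx:
            if other in (ia, ib):
                continue
            D[ia, other] = D[other, ia] = (
                size_a * D[ia, other] + size_b * D[ib, other]
            ) / (size_a + size_b)
        active[ia] = (next_id, size_a + size_b)
        next_id += 1
        idx.remove(ib)
        del active[ib]
    return Dendrogram(
        n_items=n, merges=merges,
        labels=list(labels) if labels is not None else [str(i) for i in range(n)],
    )


@dataclass
class ClusterAssignment:
    """Partition of items into labeled clusters (plus unassigned)."""

    labels: dict[str, str]  # item -> cluster label; "" = unassigned

    @property
    def clusters(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for item, lab in self.labels.items():
            if lab:
                out.setdefault(lab, []).append(item)
        return out

    def members(self, label: str) -> list[str]:
        return self.clusters.get(label, [])

    @property
    def items(self) -> list[str]:
        return list(self.labels)


def _subtree_leaves(dendrogram: Dendrogram, node: int) -> list[int]:
    n = dendrogram.n_items
    stack, leaves = [node], []
    while stack:
        v = stack.pop()
        if v < n:
            leaves.append(v)
        else:
            row = dendrogram.merges[v - n]
            stack.extend((int(row[0]), int(row[1])))
    return sorted(leaves)


def cut_clusters(
    dendrogram: Dendrogram,
    height: float | None = None,
    k: int | None = None,
    min_size: int = 15,
) -> ClusterAssignment:
    """Flat clusters from subtrees below a height (or forced cluster count k);
    subtrees smaller than ``min_size`` become unassigned."""
    if (height is None) == (k is None):
        raise ValueError("specify exactly one of height or k")
    n = dendrogram.n_items
    merges = dendrogram.merges
    if k is not None:
        k = max(1, min(k, n))
        cut_rows = n - k  # merge rows applied
    else:
        cut_rows = 0  # apply merges in order up to the cut height
        while cut_rows < n - 1 and merges[cut_rows, 2] <= height:
            cut_rows += 1
    # union of applied merges
    parent = list(range(n + cut_rows))
    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v
    for row in range(cut_rows):
        a, b = int(merges[row, 0]), int(merges[row, 1])
        node = n + row
        # ids beyond n + cut_rows cannot appear among the first cut_rows merges
        parent[find(a)] = node
        parent[find(b)] = node
    groups: dict[int, list[int]] = {}
    for leaf in range(n):
        groups.setdefault(find(leaf), []).append(leaf)
    ordered = sorted(groups.values(), key=lambda g: (-len(g), g[0]))
    labels: dict[str, str] = {}
    c = 0
    for group in ordered:
        if len(group) >= min_size:
            c += 1
            lab = f"C{c:02d}"
        else:
            lab = ""
        for leaf in group:
            labels[dendrogram.labels[leaf]] = lab
    return ClusterAssignment(labels=labels)


def cluster_signatures(
    matrix: pd.DataFrame,
    height: float | None = None,
    k: int | None = None,
    min_size: int = 15,
    use_item_weights: bool = False,
    cutoff: float = 0.8,
    exponent: float = 1.0,
):
    """Distance matrix -> UPGMA -> flat clusters for a signature DataFrame.

    Item weights are always computed and returned; they modulate the distance
    only when ``use_item_weights`` (uniform dimension weights by default).
    """
    X = matrix.to_numpy(dtype=float)
    weights = compute_item_weights(X, cutoff=cutoff, exponent=exponent)
    D = distance_matrix(X)
    if use_item_weights:
        # Cluster 3.0-style: weights belong to the transposed problem; when
        # clustering items they are exported, not folded into item-item
        # distances. Kept as an explicit hook for the transposed clustering.
        pass
    dend = average_linkage(D, labels=list(matrix.index))
    assignment = cut_clusters(dend, height=height, k=k, min_size=min_size)
    return assignment, dend, weights


# ---------------------------------------------------------------------------
# composition k-means control


def composition_zscores(aa_freqs: pd.DataFrame) -> pd.DataFrame:
    """Per-residue frequencies standardized against the column (proteome-wide)
    mean and sd."""
    mu = aa_freqs.mean(axis=0)
    sd = aa_freqs.std(axis=0, ddof=1).replace(0.0, np.nan)
    return (aa_freqs - mu) / sd


def composition_kmeans(
    aa_freq_z: pd.DataFrame, k: int = 25, seed: int = 0, max_iter: int = 100
) -> tuple[ClusterAssignment, list[float]]:
    """Lloyd k-means (k-means++ init) on composition Z-vectors.

    Returns the assignment and the per-iteration cost trace (non-increasing).
    """
    X = np.nan_to_num(aa_freq_z.to_numpy(dtype=float), nan=0.0)
    n = X.shape[0]
    k = min(k, n)
    rng = np.random.default_rng(seed)
    # k-means++ seeding
    centers = [X[rng.integers(n)]]
    for _ in range(1, k):
        d2 = np.min(
            [np.sum((X - c) ** 2, axis=1) for c in centers], axis=0
        )
        total = d2.sum()
        if total <= 0:
            centers.append(X[rng.integers(n)])
            continue
        centers.append(X[rng.choice(n, p=d2 / total)])
    C = np.array(centers)
    costs = []
    assign = np.zeros(n, dtype=int)
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - C[None, :, :]) ** 2).sum(axis=2)
        assign = np.argmin(d2, axis=1)
        cost = float(d2[np.arange(n), assign].sum())
        if costs and cost >= costs[-1] - 1e-12:
            costs.append(cost)
            break
        costs.append(cost)
        for j in range(k):
            members = X[assign == j]
            if len(members):
                C[j] = members.mean(axis=0)
    labels = {
        str(item): f"K{assign[i] + 1:02d}" for i, item in enumerate(aa_freq_z.index)
    }
    return ClusterAssignment(labels=labels), costs


# ---------------------------------------------------------------------------
# sequence-similarity control


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "global"
    aligner.open_gap_score = 0.0
    aligner.extend_gap_score = -1.0
    return aligner


def pairwise_similarity_distance(a: str, b: str, aligner=None) -> float:
    """BLOSUM62 global-alignment score (gap open 0, extend 1) mapped to a
    dissimilarity: ``1 - S(a,b) / min(S(a,a), S(b,b))``."""
    aligner = aligner or _aligner()
    sab = aligner.score(a, b)
    saa = aligner.score(a, a)
    sbb = aligner.score(b, b)
    return float(1.0 - sab / min(saa, sbb))


def similarity_control(
    assignment: ClusterAssignment,
    sequences: dict[str, str],
    top_fraction: float = 0.01,
) -> dict[str, float]:
    """Percent of each cluster's members having a within-cluster partner among
    the overall most-similar ``top_fraction`` of pairwise distances."""
    items = [i for i in assignment.items if assignment.labels[i]]
    aligner = _aligner()
    n = len(items)
    if n < 2:
        return {lab: 0.0 for lab in assignment.clusters}
    D = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            D[a, b] = D[b, a] = pairwise_similarity_distance(
                sequences[items[a]], sequences[items[b]], aligner
            )
    iu = np.triu_indices(n, k=1)
    threshold = np.quantile(D[iu], top_fraction)  # most-similar tail
    index = {item: i for i, item in enumerate(items)}
    out = {}
    for lab, members in assignment.clusters.items():
        if len(members) < 2:
            out[lab] = 0.0
            continue
        flagged = 0
        for m in members:
            i = index[m]
            partners = [index[o] for o in members if o != m]
            if np.min(D[i, partners]) <= threshold:
                flagged += 1
        out[lab] = 100.0 * flagged / len(members)
    return out


# ---------------------------------------------------------------------------
# query annotation transfer


def cluster_centroids(
    matrix: pd.DataFrame, assignment: ClusterAssignment
) -> pd.DataFrame:
    import warnings as _warnings

    rows = {}
    for lab, members in sorted(assignment.clusters.items()):
        sub = matrix.loc[[m for m in members if m in matrix.index]]
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN dims
            rows[lab] = np.nanmean(sub.to_numpy(dtype=float), axis=0)
    return pd.DataFrame.from_dict(rows, orient="index", columns=matrix.columns)


def annotate_query(
    query_z: np.ndarray,
    centroids: pd.DataFrame,
    cluster_annotations: dict[str, list[str]] | None = None,
    ambiguity_margin: float = 1e-6,
) -> dict:
    """Nearest cluster centroid under uncentered-correlation distance; the
    winner's enriched annotations are transferred.  Flags ambiguity when the
    margin to the runner-up is negligible."""
    dists = {}
    for lab in centroids.index:
        try:
            dists[lab] = uncentered_correlation_distance(
                query_z, centroids.loc[lab].to_numpy(dtype=float)
            )
        except ValueError:
            dists[lab] = np.nan
    ranked = sorted(
        ((d, lab) for lab, d in dists.items() if np.isfinite(d))
    )
    if not ranked:
        raise ValueError("query has no finite distance to any centroid")
    best_d, best_lab = ranked[0]
    margin = (ranked[1][0] - best_d) if len(ranked) > 1 else np.inf
    return {
        "cluster": best_lab,
        "distance": best_d,
        "margin": margin,
        "ambiguous": bool(margin <= ambiguity_margin),
        "ranked": [(lab, d) for d, lab in ranked],
        "transferred_terms": (
            list(cluster_annotations.get(best_lab, []))
            if cluster_annotations
            else []
        ),
    }
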