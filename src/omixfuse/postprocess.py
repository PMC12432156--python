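"""Post-training utilities: cross-batch embedding alignment and clustering.

Alignment never moves the reference batch.  Two methods:

* ``rpca_mnn_align`` — PCA is fit on each batch separately and each batch
  is projected into the other's component space; anchor pairs are mutual
  k-nearest neighbours in both reciprocal projections; every moving sample
  is corrected by a Gaussian-kernel weighted average of anchor
  displacement vectors.
* ``ot_align`` — optimal transport with squared-Euclidean cost; exact plan
  (assignment / linear program) at regularization 0, Sinkhorn iterations
  otherwise; moving samples mapped by barycentric projection.

Clustering: k-means or Louvain over a candidate grid, the winner chosen
by silhouette score; adjusted mutual information quantifies concordance
between partitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment, linprog
from scipy.sparse import coo_matrix
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_mutual_info_score, silhouette_score
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)

__all__ = ["AlignmentResult", "ClusteringResult", "rpca_mnn_align", "ot_align",
           "cluster_embeddings", "adjusted_mutual_information", "plot_embeddings"]


@dataclass
class AlignmentResult:
    method: str
    aligned: np.ndarray                   # moving batch after correction
    anchors: list[tuple[int, int]] | None = None   # (ref idx, mov idx)
    transport_plan: np.ndarray | None = None
    marginal_error: float | None = None
    parameters: dict | None = None


@dataclass
class ClusteringResult:
    method: str
    labels: np.ndarray
    chosen: float          # k or resolution
    silhouettes: dict      # candidate -> score (NaN = skipped)


def _mutual_pairs(a: np.ndarray, b: np.ndarray, k: int) -> set[tuple[int, int]]:
    """(i in a, j in b) pairs that are mutually within each other's kNN."""
    k_ab = min(k, len(b))
    k_ba = min(k, len(a))
    nn_b = NearestNeighbors(n_neighbors=k_ab).fit(b)
    _, ab = nn_b.kneighbors(a)
    nn_a = NearestNeighbors(n_neighbors=k_ba).fit(a)
    _, ba = nn_a.kneighbors(b)
    fwd = {(i, j) for i in range(len(a)) for j in ab[i]}
    return {(i, j) for j in range(len(b)) for i in ba[j] if (i, j) in fwd}


def rpca_mnn_align(emb_ref: np.ndarray, emb_mov: np.ndarray,
                   n_pcs: int = 20, k_anchors: int = 5) -> AlignmentResult:
    """Reciprocal-PCA mutual-nearest-neighbour alignment of ``emb_mov``
    onto ``emb_ref`` (the reference is never moved)."""
    ref = np.asarray(emb_ref, dtype=float)
    mov = np.asarray(emb_mov, dtype=float)
    n_pcs = min(n_pcs, ref.shape[1], ref.shape[0] - 1, mov.shape[0] - 1)
    if n_pcs < 1:
        raise ValueError("batches too small for any principal component")
    pca_ref = PCA(n_components=n_pcs).fit(ref)
    pca_mov = PCA(n_components=n_pcs).fit(mov)

    def project(X, pca):
        # center each batch by its OWN mean before projecting onto the other
        # batch's components: constant batch offsets then cancel, which is
        # what makes the reciprocal projection robust for anchor finding
        return (X - X.mean(axis=0)) @ pca.components_.T

    # projection 1: both batches in the reference's component space
    pairs1 = _mutual_pairs(project(ref, pca_ref), project(mov, pca_ref), k_anchors)
    # projection 2: both batches in the moving batch's component space
    pairs2 = _mutual_pairs(project(ref, pca_mov), project(mov, pca_mov), k_anchors)
    anchors = sorted(pairs1 & pairs2)
    if not anchors:
        raise ValueError("no mutual nearest neighbours found; increase k_anchors")
    ref_i = np.array([i for i, _ in anchors])
    mov_j = np.array([j for _, j in anchors])
    disp = ref[ref_i] - mov[mov_j]          # anchor displacement in embedding space
    # locality weights over the pair midpoint: a mismatched pair (i,j) and its
    # mirror (j,i) then get equal weights and opposite displacements, so for
    # identical batches the correction cancels to exactly zero
    mid = 0.5 * (ref[ref_i] + mov[mov_j])
    d = cdist(mov, mid)
    bw = np.median(d)
    bw = bw if bw > 0 else 1.0
    w = np.exp(-(d ** 2) / (2 * bw ** 2))
    w /= w.sum(axis=1, keepdims=True)
    aligned = mov + w @ disp
    return AlignmentResult("rpca_mnn", aligned, anchors=anchors,
                           parameters={"n_pcs": n_pcs, "k_anchors": k_anchors})


def _sinkhorn(C, a, b, reg, max_iter=5000, tol=1e-9):
    K = np.exp(-C / reg)
    u = np.ones_like(a)
    v = np.ones_like(b)
    for _ in range(max_iter):
        u_new = a / (K @ v)
        v_new = b / (K.T @ u_new)
        if np.max(np.abs(u_new - u)) < tol and np.max(np.abs(v_new - v)) < tol:
            u, v = u_new, v_new
            break
        u, v = u_new, v_new
    plan = u[:, None] * K * v[None, :]
    err = max(np.abs(plan.sum(1) - a).max(), np.abs(plan.sum(0) - b).max())
    if err > 1e-4:
        raise RuntimeError(f"Sinkhorn did not converge; marginal error {err:.2e}")
    return plan, err


def _exact_ot(C, a, b):
    n, m = C.shape
    if n == m and np.allclose(a, 1 / n) and np.allclose(b, 1 / m):
        r, c = linear_sum_assignment(C)
        plan = np.zeros_like(C)
        plan[r, c] = 1.0 / n
        return plan
    # generic LP: vec(P) row-major; marginal constraints
    rows_i = np.repeat(np.arange(n), m)
    cols_i = np.tile(np.arange(m), n)
    var = np.arange(n * m)
    A_eq = coo_matrix(
        (np.ones(2 * n * m),
         (np.concatenate([rows_i, n + cols_i]), np.concatenate([var, var]))),
        shape=(n + m, n * m),
    )
    res = linprog(C.ravel(), A_eq=A_eq, b_eq=np.concatenate([a, b]),
                  bounds=(0, None), method="highs")
    if not res.success:
        raise RuntimeError(f"exact OT solver failed: {res.message}")
    return res.x.reshape(n, m)


def ot_align(emb_ref: np.ndarray, emb_mov: np.ndarray,
             weights: tuple[np.ndarray, np.ndarray] | None = None,
             regularization: float | None = None) -> AlignmentResult:
    """Map the moving batch onto the reference by barycentric projection of
    the optimal transport plan (moving = source, reference = target).

    Cost is squared Euclidean distance; regularization ``None`` picks the
    exact solver for n <= 500 and entropic (reg 0.05 on the normalized
    cost) above."""
    ref = np.asarray(emb_ref, dtype=float)
    mov = np.asarray(emb_mov, dtype=float)
    if len(ref) == 0 or len(mov) == 0:
        raise ValueError("batches must be non-empty")
    n, m = len(mov), len(ref)
    if weights is None:
        a, b = np.full(n, 1 / n), np.full(m, 1 / m)
    else:
        a, b = (np.asarray(w, dtype=float) for w in weights)
        if abs(a.sum() - 1) > 1e-8 or abs(b.sum() - 1) > 1e-8:
            raise ValueError("weights must sum to 1 per side")
    C = cdist(mov, ref, "sqeuclidean")
    if regularization is None:
        regularization = 0.0 if max(n, m) <= 500 else 0.05
    if regularization == 0:
        plan = _exact_ot(C, a, b)
        err = float(max(np.abs(plan.sum(1) - a).max(), np.abs(plan.sum(0) - b).max()))
    else:
        scale = C.max() if C.max() > 0 else 1.0
        plan, err = _sinkhorn(C / scale, a, b, regularization)
    row = plan.sum(axis=1, keepdims=True)
    aligned = np.where(row > 0, plan @ ref / np.where(row > 0, row, 1.0), mov)
    return AlignmentResult("optimal_transport", aligned, transport_plan=plan,
                           marginal_error=float(err),
                           parameters={"regularization": regularization})


def _louvain_labels(emb: np.ndarray, resolution: float, seed: int,
                    k: int = 15) -> np.ndarray:
    import igraph as ig

    n = len(emb)
    k = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(emb)
    _, idx = nn.kneighbors(emb)
    neigh = [set(row[1:]) for row in idx]
    edges, ws = [], []
    for i in range(n):
        for j in idx[i][1:]:
            if j > i or i not in neigh[j]:
                inter = len(neigh[i] & neigh[j])
                union = len(neigh[i] | neigh[j])
                edges.append((i, int(j)))
                ws.append(inter / union if union else 0.0)
    g = ig.Graph(n=n, edges=edges)
    g.es["weight"] = ws
    np.random.seed(seed % 2**31)  # igraph draws from numpy's legacy global state
    part = g.community_multilevel(weights="weight", resolution=resolution)
    return np.array(part.membership)


def cluster_embeddings(emb: np.ndarray, method: str = "kmeans",
                       candidates=None, seed: int = 0) -> ClusteringResult:
    """Fit each candidate (k for k-means, resolution for Louvain), score by
    silhouette, return the best.  Degenerate candidates (one cluster, or
    only singletons) are skipped."""
    emb = np.asarray(emb, dtype=float)
    if method == "kmeans":
        candidates = list(candidates) if candidates is not None else list(range(2, 11))
        if max(candidates) + 1 > len(emb):
            raise ValueError("need at least max(k)+1 samples")
    elif method == "louvain":
        candidates = list(candidates) if candidates is not None else [0.25, 0.5, 1.0, 2.0]
    else:
        raise ValueError("method must be 'kmeans' or 'louvain'")
    sils: dict = {}
    labels_by_cand: dict = {}
    for c in candidates:
        if method == "kmeans":
            labels = KMeans(n_clusters=int(c), n_init=10,
                            random_state=seed).fit_predict(emb)
        else:
            labels = _louvain_labels(emb, float(c), seed)
        uniq, counts = np.unique(labels, return_counts=True)
        if len(uniq) < 2 or len(uniq) >= len(emb) or (counts == 1).all():
            sils[c] = np.nan
            continue
        try:
            sils[c] = float(silhouette_score(emb, labels))
        except ValueError:
            sils[c] = np.nan
            continue
        labels_by_cand[c] = labels
    valid = {c: s for c, s in sils.items() if np.isfinite(s)}
    if not valid:
        raise ValueError("no candidate produced a valid clustering")
    best = max(valid, key=valid.get)
    return ClusteringResult(method, labels_by_cand[best], best, sils)


def adjusted_mutual_information(labels_a, labels_b) -> float:
    """Chance-corrected agreement between two partitions (1 = identical)."""
    a = np.asarray(labels_a).ravel()
    b = np.asarray(labels_b).ravel()
    if len(a) != len(b):
        raise ValueError("label vectors differ in length")
    return float(adjusted_mutual_info_score(a, b))


def plot_embeddings(emb: np.ndarray, labels, path) -> None:
    """2-D PCA scatter of an embedding, colored by labels (visual aid only)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xy = PCA(n_components=2).fit_transform(np.asarray(emb, dtype=float))
    labels = np.asarray(labels)
    fig, ax = plt.subplots(figsize=(5, 4))
    for lv in np.unique(labels):
        m = labels == lv
        ax.scatter(xy[m, 0], xy[m, 1], s=8, label=str(lv))
    ax.legend(fontsize=6, markerscale=2)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
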