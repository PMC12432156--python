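"""Unsupervised feature ranking by Laplacian score, redundancy pruning,
and restriction of feature sets to an interaction graph.

The Laplacian score favours features that respect the local geometry of
the sample k-nearest-neighbour graph: for feature r with heat-kernel
weight matrix W, degree D, Laplacian L = D - W and the weighted-mean
removed f̃ = f - (fᵀD1 / 1ᵀD1)·1, the score is

    L_r = (f̃ᵀ L f̃) / (f̃ᵀ D f̃)          (lower = more informative)

Constant features get a +inf sentinel and are never selected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform, pdist
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)

__all__ = ["FeatureRanking", "laplacian_score", "select_features",
           "restrict_to_graph", "read_edge_list", "rank_and_select"]


@dataclass
class FeatureRanking:
    modality_name: str
    scores: np.ndarray
    selected: list[str]
    parameters: dict


def _knn_heat_graph(X: np.ndarray, n_neighbors: int, bandwidth: float | None):
    n = X.shape[0]
    k = min(n_neighbors, n - 1)
    sq = squareform(pdist(X, "sqeuclidean"))
    if bandwidth is None:
        iu = np.triu_indices(n, 1)
        bandwidth = float(np.median(sq[iu]))
        if bandwidth <= 0:
            bandwidth = 1.0
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    _, idx = nn.kneighbors(X)
    adj = np.zeros((n, n), dtype=bool)
    rows = np.repeat(np.arange(n), k)
    adj[rows, idx[:, 1:].ravel()] = True
    adj |= adj.T  # symmetrize: edge if either direction is a kNN link
    W = np.where(adj, np.exp(-sq / bandwidth), 0.0)
    return W, bandwidth


def laplacian_score(
    X: np.ndarray, n_neighbors: int = 10, bandwidth: float | None = None,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Scores for each column of a samples x features matrix (lower = better).

    ``weights`` optionally supplies a precomputed sample-graph weight matrix
    (e.g. to score features on a graph built from other data); by default
    the kNN heat-kernel graph is built from ``X`` itself.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise ValueError("need a 2-D matrix with >= 3 samples")
    if not np.isfinite(X).all():
        raise ValueError("X must be finite")
    if weights is not None:
        W = np.asarray(weights, dtype=float)
    else:
        W, _ = _knn_heat_graph(X, n_neighbors, bandwidth)
    d = W.sum(axis=1)
    D_tot = d.sum()
    # weighted mean removal per feature
    f_mean = (X.T @ d) / D_tot           # (p,)
    F = X - f_mean[None, :]
    # fᵀLf = fᵀDf - fᵀWf
    fDf = (F ** 2 * d[:, None]).sum(axis=0)
    fWf = np.einsum("ip,ij,jp->p", F, W, F, optimize=True)
    fLf = fDf - fWf
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = fLf / fDf
    scores = np.where(fDf <= 1e-12, np.inf, scores)
    return scores


def select_features(
    X: np.ndarray,
    scores: np.ndarray,
    feature_ids: list[str],
    top_fraction: float = 0.2,
    min_features: int = 10,
    redundancy_threshold: float = 0.8,
) -> list[str]:
    """Keep the best-scoring ceil(top_fraction*p) features (at least
    min_features), then greedily drop features too correlated (|Pearson| >
    threshold) with an already-kept better-scoring feature.  Score ties
    break lexicographically on feature id."""
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    if len(scores) != p or len(feature_ids) != p:
        raise ValueError("scores/feature_ids must align with columns of X")
    if min_features > p:
        logger.warning("min_features=%d > %d available; keeping all", min_features, p)
    n_keep = max(int(np.ceil(top_fraction * p)), min(min_features, p))
    order = sorted(range(p), key=lambda i: (scores[i], feature_ids[i]))
    top = [i for i in order if np.isfinite(scores[i])][:n_keep]
    if redundancy_threshold >= 1.0 or len(top) <= 1:
        return [feature_ids[i] for i in top]
    kept: list[int] = []
    sd = X.std(axis=0)
    Z = (X - X.mean(axis=0)) / np.where(sd == 0, 1.0, sd)
    for i in top:
        ok = True
        for j in kept:
            r = float(Z[:, i] @ Z[:, j]) / X.shape[0]
            if abs(r) > redundancy_threshold:
                ok = False
                break
        if ok:
            kept.append(i)
    if len(kept) < len(top):
        logger.info("redundancy pruning dropped %d features", len(top) - len(kept))
    return [feature_ids[i] for i in kept]


def rank_and_select(
    modality_name: str,
    X: np.ndarray,
    feature_ids: list[str],
    n_neighbors: int = 10,
    bandwidth: float | None = None,
    top_fraction: float = 0.2,
    min_features: int = 10,
    redundancy_threshold: float = 0.8,
) -> FeatureRanking:
    """Convenience wrapper: score then select; plugs into
    :func:`omixfuse.data_io.harmonize` as the ``feature_selector`` hook."""
    scores = laplacian_score(X, n_neighbors, bandwidth)
    selected = select_features(X, scores, feature_ids, top_fraction,
                               min_features, redundancy_threshold)
    return FeatureRanking(modality_name, scores, selected, {
        "n_neighbors": n_neighbors, "bandwidth": bandwidth,
        "top_fraction": top_fraction, "min_features": min_features,
        "redundancy_threshold": redundancy_threshold,
    })


def read_edge_list(path: str | Path) -> list[tuple[str, str]]:
    """Two-column (comma or tab separated) feature-id pairs; an optional
    third weight column is ignored."""
    sep = "\t" if "\t" in Path(path).read_text().splitlines()[0] else ","
    df = pd.read_csv(path, sep=sep, header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need at least two columns")
    return list(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def restrict_to_graph(
    X: np.ndarray, feature_ids: list[str], edge_list: list[tuple[str, str]]
) -> tuple[np.ndarray, list[str], list[tuple[int, int]]]:
    """Drop features absent from the graph node set; return the restricted
    matrix, kept feature ids, and induced edges as index pairs into them."""
    if not edge_list:
        raise ValueError("empty edge list")
    nodes = {a for a, _ in edge_list} | {b for _, b in edge_list}
    keep = [i for i, f in enumerate(feature_ids) if f in nodes]
    if not keep:
        raise ValueError("no feature overlaps the interaction graph")
    kept_ids = [feature_ids[i] for i in keep]
    pos = {f: i for i, f in enumerate(kept_ids)}
    edges = sorted({
        (pos[a], pos[b]) for a, b in edge_list
        if a in pos and b in pos and a != b
    })
    return np.asarray(X)[:, keep], kept_ids, edges
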