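"""Proportional thresholding and node-level graph metrics.

The connectivity matrix convention throughout is C[target, source]: the
entry (i, j) is the directed edge j -> i.  Thresholding keeps a fixed
fraction of the strongest off-diagonal entries so every trial's graph has
the same density.  Nine node metrics are computed and averaged within each
region to give the fixed-order 27-value feature vector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .connectivity import BandConnectivity
from .defs import FEATURE_NAMES, METRIC_ORDER, REGION_ORDER

__all__ = [
    "ThresholdedGraph",
    "proportional_threshold",
    "degree_metrics",
    "strength_metrics",
    "clustering_coefficient",
    "betweenness_centrality",
    "eigenvector_centrality",
    "compute_node_metrics",
    "aggregate_regions",
]

#: Default proportional-threshold operating range (fraction kept).
PTH_DEFAULT_RANGE = tuple(np.round(np.arange(0.06, 0.201, 0.01), 2))
#: Full exploratory scan range.
PTH_FULL_RANGE = tuple(np.round(np.arange(0.01, 0.501, 0.01), 2))


@dataclass
class ThresholdedGraph:
    weights: np.ndarray  # k x k, sub-threshold and diagonal entries zeroed
    mask: np.ndarray  # binary adjacency, mask[i, j] = 1 iff edge j -> i kept
    pth: float
    density: float


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def proportional_threshold(
    C: BandConnectivity | np.ndarray, pth: float
) -> ThresholdedGraph:
    """Keep the round(pth * k(k-1)) largest off-diagonal entries.

    Ties at the cutoff are broken deterministically by (value descending,
    source index ascending, target index ascending).
    """
    W = C.C if isinstance(C, BandConnectivity) else np.asarray(C, dtype=float)
    k = W.shape[0]
    if W.shape != (k, k) or k < 2:
        raise ValueError("need a square matrix with k >= 2")
    if not 0 < pth <= 1:
        raise ValueError("pth must lie in (0, 1]")
    n_possible = k * (k - 1)
    n_keep = _round_half_away(pth * n_possible)
    if n_keep < 1:
        raise ValueError(
            f"pth={pth} retains zero of {n_possible} edges; increase pth"
        )
    targets, sources = np.nonzero(~np.eye(k, dtype=bool))
    order = sorted(
        range(n_possible),
        key=lambda e: (-W[targets[e], sources[e]], sources[e], targets[e]),
    )
    keep = order[:n_keep]
    mask = np.zeros((k, k), dtype=int)
    mask[targets[keep], sources[keep]] = 1
    weights = np.where(mask.astype(bool), W, 0.0)
    np.fill_diagonal(weights, 0.0)
    return ThresholdedGraph(
        weights=weights, mask=mask, pth=pth, density=n_keep / n_possible
    )


def degree_metrics(g: ThresholdedGraph) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(in_degree, out_degree, degree) per node."""
    in_degree = g.mask.sum(axis=1)
    out_degree = g.mask.sum(axis=0)
    return in_degree, out_degree, in_degree + out_degree


def strength_metrics(
    g: ThresholdedGraph,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(in_strength, out_strength, strength) per node."""
    in_strength = g.weights.sum(axis=1)
    out_strength = g.weights.sum(axis=0)
    return in_strength, out_strength, in_strength + out_strength


def clustering_coefficient(g: ThresholdedGraph) -> np.ndarray:
    """Watts-Strogatz clustering on the binarized, symmetrized graph.

    An undirected link exists if either direction was retained; a node with
    fewer than two neighbors scores 0.
    """
    A = ((g.mask + g.mask.T) > 0).astype(float)
    np.fill_diagonal(A, 0.0)
    deg = A.sum(axis=1)
    triangles = np.diagonal(A @ A @ A)  # = 2 x triangles through each node
    cc = np.zeros_like(deg)
    valid = deg >= 2
    cc[valid] = triangles[valid] / (deg[valid] * (deg[valid] - 1.0))
    return cc


def betweenness_centrality(g: ThresholdedGraph) -> np.ndarray:
    """Directed shortest-path betweenness on the binary mask, unit edge
    lengths, raw (unnormalized); ordered pairs with no path contribute 0.

    Brandes' accumulation over BFS shortest-path DAGs.
    """
    # successors of node u are nodes v with an edge u -> v, i.e. mask[v, u]
    k = g.mask.shape[0]
    succ = [np.nonzero(g.mask[:, u])[0] for u in range(k)]
    bc = np.zeros(k)
    for s in range(k):
        sigma = np.zeros(k)
        sigma[s] = 1.0
        dist = np.full(k, -1)
        dist[s] = 0
        preds: list[list[int]] = [[] for _ in range(k)]
        stack: list[int] = []
        queue = [s]
        head = 0
        while head < len(queue):
            u = queue[head]
            head += 1
            stack.append(u)
            for v in succ[u]:
                if dist[v] < 0:
                    dist[v] = dist[u] + 1
                    queue.append(v)
                if dist[v] == dist[u] + 1:
                    sigma[v] += sigma[u]
                    preds[v].append(u)
        delta = np.zeros(k)
        for v in reversed(stack):
            for u in preds[v]:
                delta[u] += sigma[u] / sigma[v] * (1.0 + delta[v])
            if v != s:
                bc[v] += delta[v]
    return bc


def eigenvector_centrality(g: ThresholdedGraph) -> np.ndarray:
    """Principal-eigenvector centrality of the symmetrized weighted matrix
    (W + W^T)/2, entrywise non-negative, unit Euclidean norm.

    A zero matrix yields all zeros with a warning rather than an error.
    """
    S = (g.weights + g.weights.T) / 2.0
    if not S.any():
        warnings.warn("zero connectivity matrix: eigenvector centrality is 0")
        return np.zeros(S.shape[0])
    eigvals, eigvecs = np.linalg.eigh(S)
    v = eigvecs[:, -1]  # S is non-negative => top eigenvalue is the largest
    if v[np.argmax(np.abs(v))] < 0:
        v = -v
    v = np.clip(v, 0.0, None)
    norm = np.linalg.norm(v)
    return v / norm if norm > 0 else v


def compute_node_metrics(g: ThresholdedGraph) -> dict[str, np.ndarray]:
    """All nine node metrics keyed by their fixed metric names."""
    in_degree, out_degree, degree = degree_metrics(g)
    in_strength, out_strength, strength = strength_metrics(g)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ec = eigenvector_centrality(g)
    metrics = {
        "degree": degree.astype(float),
        "in_degree": in_degree.astype(float),
        "out_degree": out_degree.astype(float),
        "strength": strength,
        "in_strength": in_strength,
        "out_strength": out_strength,
        "clustering_coefficient": clustering_coefficient(g),
        "betweenness_centrality": betweenness_centrality(g),
        "eigenvector_centrality": ec,
    }
    assert set(metrics) == set(METRIC_ORDER)
    return metrics


def aggregate_regions(
    metrics: dict[str, np.ndarray], channel_regions: list[str]
) -> np.ndarray:
    """Average each metric over the channels of each region.

    Returns the 27-value vector in fixed (region x metric) order matching
    ``FEATURE_NAMES``.
    """
    regions = np.asarray(channel_regions)
    unknown = set(regions) - set(REGION_ORDER)
    if unknown:
        raise ValueError(f"unknown region labels {sorted(unknown)}")
    values = []
    for region in REGION_ORDER:
        members = regions == region
        if not members.any():
            raise ValueError(f"region {region} has no channels")
        for metric in METRIC_ORDER:
            values.append(float(np.mean(metrics[metric][members])))
    out = np.array(values)
    if not np.all(np.isfinite(out)):
        raise ValueError("non-finite feature value")
    assert out.shape == (len(FEATURE_NAMES),)
    return out
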