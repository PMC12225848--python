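"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's code paths: transfer matrices are
assembled and inverted per frequency from first principles, betweenness
enumerates every simple shortest path, eigenvector centrality uses plain
power iteration, and binomial tails are summed term by term with exact
integer binomial coefficients.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def dtf_bruteforce(coeffs: np.ndarray, freqs: np.ndarray, fs: float) -> np.ndarray:
    """DTF^2 per frequency from a VAR coefficient stack, scalar loops only."""
    p, k, _ = coeffs.shape
    out = np.empty((len(freqs), k, k))
    for fi, f in enumerate(freqs):
        A = np.eye(k, dtype=complex)
        for m in range(1, p + 1):
            A = A - coeffs[m - 1] * np.exp(-2j * np.pi * f * m / fs)
        H = np.linalg.inv(A)
        for i in range(k):
            denom = sum(abs(H[i, m]) ** 2 for m in range(k))
            for j in range(k):
                out[fi, i, j] = abs(H[i, j]) ** 2 / denom
    return out


def _shortest_paths(mask: np.ndarray, src: int, dst: int) -> list[tuple[int, ...]]:
    """All shortest directed paths src -> dst by exhaustive BFS enumeration."""
    k = mask.shape[0]
    if src == dst:
        return []
    best: list[tuple[int, ...]] = []
    frontier = [(src,)]
    while frontier and not best:
        nxt = []
        for path in frontier:
            u = path[-1]
            for v in range(k):
                if mask[v, u] and v not in path:
                    new = path + (v,)
                    if v == dst:
                        best.append(new)
                    else:
                        nxt.append(new)
        frontier = nxt
    return best


def betweenness_bruteforce(mask: np.ndarray) -> np.ndarray:
    k = mask.shape[0]
    bc = np.zeros(k)
    for i, j in itertools.permutations(range(k), 2):
        paths = _shortest_paths(mask, i, j)
        if not paths:
            continue
        for v in range(k):
            if v in (i, j):
                continue
            through = sum(1 for path in paths if v in path[1:-1])
            bc[v] += through / len(paths)
    return bc


def eigenvector_power_iteration(weights: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    S = (weights + weights.T) / 2.0
    if not S.any():
        return np.zeros(S.shape[0])
    # Gershgorin shift makes S PSD so iteration cannot oscillate between
    # eigenvalues of equal magnitude; eigenvectors are unchanged.
    S = S + np.abs(S).sum(axis=1).max() * np.eye(S.shape[0])
    v = np.ones(S.shape[0]) / np.sqrt(S.shape[0])
    for _ in range(100_000):
        nv = S @ v
        norm = np.linalg.norm(nv)
        if norm == 0:
            return np.zeros_like(v)
        nv = nv / norm
        if np.linalg.norm(nv - v) < tol:
            v = nv
            break
        v = nv
    v = np.clip(v, 0.0, None)
    norm = np.linalg.norm(v)
    return v / norm if norm > 0 else v


def clustering_bruteforce(mask: np.ndarray) -> np.ndarray:
    k = mask.shape[0]
    und = ((mask + mask.T) > 0) & ~np.eye(k, dtype=bool)
    cc = np.zeros(k)
    for i in range(k):
        neighbors = np.nonzero(und[i])[0]
        n_i = len(neighbors)
        if n_i < 2:
            continue
        links = sum(
            1
            for a, b in itertools.combinations(neighbors, 2)
            if und[a, b]
        )
        cc[i] = 2.0 * links / (n_i * (n_i - 1))
    return cc


def binomial_upper_tail_exact(k: int, n: int, p: float) -> float:
    """P(X >= k) by direct summation with exact integer coefficients."""
    return sum(
        math.comb(n, x) * p**x * (1 - p) ** (n - x) for x in range(k, n + 1)
    )
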