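"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — explicit path enumeration, truncated
series, exhaustive pairwise comparisons — and shares no code with the
package's own computation paths.
"""

from itertools import permutations

import numpy as np


def pathsim_by_enumeration(M: np.ndarray) -> np.ndarray:
    """PathSim via explicit enumeration of drug-attribute-drug path instances."""
    n, m = M.shape
    counts = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            c = 0
            for a in range(m):
                if M[i, a] and M[j, a]:
                    c += 1  # one path instance i -> a -> j
            counts[i, j] = c
    S = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            denom = counts[i, i] + counts[j, j]
            S[i, j] = 2.0 * counts[i, j] / denom if denom > 0 else 0.0
    return S


def jaccard_by_sets(A: np.ndarray) -> np.ndarray:
    """Jaccard of neighbour sets, computed with Python set operations."""
    n = A.shape[0]
    nbrs = [set(np.flatnonzero(A[i])) for i in range(n)]
    S = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            union = nbrs[i] | nbrs[j]
            S[i, j] = len(nbrs[i] & nbrs[j]) / len(union) if union else 0.0
    return S


def katz_by_series(P: np.ndarray, mu: float, terms: int = 200) -> np.ndarray:
    """Truncated geometric series sum_{m=1}^{terms} (mu P)^m, dense."""
    n = P.shape[0]
    K = np.zeros((n, n))
    term = np.eye(n)
    for _ in range(terms):
        term = term @ (mu * P)
        K += term
    return K


def supervision_loss_pairwise(E: np.ndarray, S: np.ndarray) -> float:
    """sum_ij S_ij ||e_i - e_j||^2 with explicit double loop."""
    n = E.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(n):
            d = E[i] - E[j]
            total += S[i, j] * float(d @ d)
    return total


def ap_at_k_by_definition(ranking, relevant, K, as_printed=False) -> float:
    """AP@K from first principles, rank by rank."""
    L = len(relevant)
    if L == 0:
        return 0.0
    acc = 0.0
    hits = 0
    for k in range(1, min(K, len(ranking)) + 1):
        item = ranking[k - 1]
        if item in relevant:
            hits += 1
        if as_printed or item in relevant:
            acc += hits / k
    return acc / min(L, K)


def auc_by_pair_counting(scores, labels) -> float:
    """Mann-Whitney AUC by exhaustive positive-negative pair comparison."""
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel()
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def best_ap_over_permutations(items, relevant, K):
    """Exhaustively score every ranking of ``items``; returns dict ranking->AP."""
    return {
        perm: ap_at_k_by_definition(list(perm), relevant, K)
        for perm in permutations(items)
    }


def hops_by_bfs(adj: dict, start) -> dict:
    """Unweighted BFS hop distances from ``start`` over an adjacency dict."""
    dist = {start: 0}
    frontier = [start]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj.get(u, ()):
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist
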