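"""Independent brute-force oracles used only by the test suite.

Each oracle recomputes a quantity by exhaustive enumeration, staying
deliberately independent of the production code paths it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from gec.graphlets import classify_induced, graphlet_size
from gec.network import Network


def connected_subset(adj: list[set[int]], subset: tuple[int, ...]) -> bool:
    sub = set(subset)
    seen = {subset[0]}
    stack = [subset[0]]
    while stack:
        u = stack.pop()
        for v in adj[u] & sub:
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return len(seen) == len(subset)


def brute_force_counts(net: Network, g: int):
    """Pair counts and degrees by enumerating *all* C(n, k) subsets."""
    k = graphlet_size(g)
    adj = net.adjacency_sets()
    n = net.n_nodes
    pair = np.zeros((n, n), dtype=int)
    deg = np.zeros(n, dtype=int)
    for subset in itertools.combinations(range(n), k):
        sub = set(subset)
        degs = [len(adj[u] & sub) for u in subset]
        n_edges = sum(degs) // 2
        if n_edges < k - 1 or not connected_subset(adj, subset):
            continue
        if classify_induced(k, n_edges, max(degs)) != g:
            continue
        for i, u in enumerate(subset):
            deg[u] += 1
            for v in subset[i + 1:]:
                pair[u, v] += 1
                pair[v, u] += 1
    return pair, deg


def brute_force_occurrences(net: Network, g: int) -> set[frozenset[str]]:
    k = graphlet_size(g)
    adj = net.adjacency_sets()
    out = set()
    for subset in itertools.combinations(range(net.n_nodes), k):
        sub = set(subset)
        degs = [len(adj[u] & sub) for u in subset]
        n_edges = sum(degs) // 2
        if n_edges < k - 1 or not connected_subset(adj, subset):
            continue
        if classify_induced(k, n_edges, max(degs)) == g:
            out.add(frozenset(net.nodes[i] for i in subset))
    return out


def analytic_power_iteration_limit(net: Network, g: int) -> np.ndarray:
    """Closed-form limit of uniform-start power iteration on A~_Gi.

    The eigenvalue-1 eigenspace of the symmetrically normalised graphlet
    adjacency is spanned, per connected component of the support, by the
    restriction of sqrt(graphlet degree).  The limit from the uniform
    start is the orthogonal projection onto that space: on component C
    the vector (sum_C sqrt(d) / sum_C d) * sqrt(d), L2-normalised
    globally.  On a connected support this reduces to the global
    normalised sqrt-degree vector.
    """
    from gec.graphlets import graphlet_adjacency

    adj = graphlet_adjacency(net, g)
    d = adj.degrees.astype(float)
    if d.sum() == 0:
        raise ValueError("empty support")
    # components of the graphlet-adjacency graph on the support
    mat = adj.pair_counts.tocoo()
    nbrs: dict[int, set[int]] = {}
    for i, j in zip(mat.row, mat.col):
        nbrs.setdefault(i, set()).add(j)
    out = np.zeros_like(d)
    seen: set[int] = set()
    for start in np.flatnonzero(d > 0):
        start = int(start)
        if start in seen:
            continue
        comp = {start}
        stack = [start]
        while stack:
            u = stack.pop()
            for v in nbrs.get(u, ()):
                if v not in comp:
                    comp.add(v)
                    stack.append(v)
        seen |= comp
        idx = sorted(comp)
        coeff = np.sqrt(d[idx]).sum() / d[idx].sum()
        out[idx] = coeff * np.sqrt(d[idx])
    return out / np.linalg.norm(out)


def brute_force_average_precision(scores, labels) -> float:
    """Average precision by explicit threshold sweep (O(n^2) loops)."""
    scores = list(map(float, scores))
    labels = list(map(int, labels))
    n_pos = sum(labels)
    if n_pos == 0:
        return float("nan")
    ap = 0.0
    prev_recall = 0.0
    for thr in sorted(set(scores), reverse=True):
        tp = sum(1 for s, y in zip(scores, labels) if s >= thr and y == 1)
        npred = sum(1 for s in scores if s >= thr)
        precision = tp / npred
        recall = tp / n_pos
        ap += precision * (recall - prev_recall)
        prev_recall = recall
    return ap


def brute_force_roc_auc(scores, labels) -> float:
    """Pairwise probability that a positive outscores a negative."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    if not pos or not neg:
        return float("nan")
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def brute_force_max_f1_positives(scores: dict, labels: dict):
    """Max-F1 threshold sweep with explicit loops, highest-threshold ties."""
    n_pos = sum(labels.values())
    if n_pos == 0:
        return frozenset()
    best_f1, best_thr = -1.0, None
    for thr in sorted(set(scores.values()), reverse=True):
        tp = sum(1 for k in scores if scores[k] >= thr and labels[k] == 1)
        npred = sum(1 for k in scores if scores[k] >= thr)
        if tp == 0:
            f1 = 0.0
        else:
            prec, rec = tp / npred, tp / n_pos
            f1 = 2 * prec * rec / (prec + rec)
        if f1 > best_f1:  # strict: first (highest) threshold wins ties
            best_f1, best_thr = f1, thr
    return frozenset(
        k for k in scores if scores[k] >= best_thr and labels[k] == 1
    )


def hypergeom_tail_by_enumeration(k: int, M: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(M, K, N) from binomial coefficients."""
    total = math.comb(M, N)
    acc = 0
    for x in range(k, min(K, N) + 1):
        acc += math.comb(K, x) * math.comb(M - K, N - x)
    return acc / total


def benjamini_hochberg(pvals):
    """Step-up BH adjusted p-values, straight from the definition."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_end, i in enumerate(reversed(order)):
        rank = m - rank_from_end
        val = min(prev, pvals[i] * m / rank)
        adj[i] = val
        prev = val
    return adj
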