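"""Independent brute-force reference implementations for tests.

Everything here is deliberately naive — explicit loops, Floyd-Warshall,
exhaustive path and partition enumeration — and shares no code with the
package implementations it cross-checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def floyd_warshall(lengths: np.ndarray) -> np.ndarray:
    """All-pairs shortest path distances; 0 entries mean no edge."""
    n = lengths.shape[0]
    d = np.where(lengths > 0, lengths, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def path_length_mean(weights: np.ndarray) -> float:
    """Characteristic path length over finite pairs, edge length 1/w."""
    lengths = np.where(weights > 0, 1.0 / np.where(weights > 0, weights, 1.0), 0.0)
    d = floyd_warshall(lengths)
    vals = [d[i, j] for i in range(len(d)) for j in range(i + 1, len(d)) if np.isfinite(d[i, j])]
    return float(np.mean(vals))


def global_efficiency(weights: np.ndarray) -> float:
    lengths = np.where(weights > 0, 1.0 / np.where(weights > 0, weights, 1.0), 0.0)
    d = floyd_warshall(lengths)
    n = len(d)
    vals = [
        (1.0 / d[i, j]) if np.isfinite(d[i, j]) else 0.0
        for i in range(n)
        for j in range(i + 1, n)
    ]
    return float(np.mean(vals))


def local_efficiency(weights: np.ndarray) -> float:
    n = len(weights)
    effs = []
    for v in range(n):
        nbrs = [u for u in range(n) if weights[v, u] > 0]
        if len(nbrs) < 2:
            effs.append(0.0)
            continue
        sub = weights[np.ix_(nbrs, nbrs)]
        effs.append(global_efficiency(sub))
    return float(np.mean(effs))


def clustering_onnela(weights: np.ndarray) -> np.ndarray:
    """Per-node Onnela weighted clustering with weights rescaled by max."""
    wmax = weights.max()
    wn = weights / wmax if wmax > 0 else weights
    n = len(weights)
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if weights[i, j] > 0]
        k = len(nbrs)
        if k < 2:
            continue
        total = 0.0
        for a in range(k):
            for b in range(a + 1, k):
                j, h = nbrs[a], nbrs[b]
                if weights[j, h] > 0:
                    total += (wn[i, j] * wn[i, h] * wn[j, h]) ** (1.0 / 3.0)
        out[i] = 2.0 * total / (k * (k - 1))
    return out


def betweenness(weights: np.ndarray) -> np.ndarray:
    """Unnormalized betweenness via exhaustive simple-path enumeration."""
    n = len(weights)
    lengths = {(i, j): 1.0 / weights[i, j] for i in range(n) for j in range(n) if weights[i, j] > 0}
    bc = np.zeros(n)

    def all_paths(s, t):
        stack = [(s, [s], 0.0)]
        found = []
        while stack:
            node, path, dist = stack.pop()
            if node == t:
                found.append((dist, path))
                continue
            for nxt in range(n):
                if (node, nxt) in lengths and nxt not in path:
                    stack.append((nxt, path + [nxt], dist + lengths[(node, nxt)]))
        return found

    for s in range(n):
        for t in range(s + 1, n):
            paths = all_paths(s, t)
            if not paths:
                continue
            dmin = min(d for d, _ in paths)
            shortest = [p for d, p in paths if abs(d - dmin) < 1e-12]
            sigma = len(shortest)
            for v in range(n):
                if v in (s, t):
                    continue
                through = sum(1 for p in shortest if v in p)
                bc[v] += through / sigma
    return bc


def modularity_value(weights: np.ndarray, partition: list[set[int]]) -> float:
    """Newman weighted modularity of a given partition."""
    m2 = weights.sum()  # = 2m for symmetric matrices
    strength = weights.sum(axis=1)
    q = 0.0
    for comm in partition:
        for i in comm:
            for j in comm:
                q += weights[i, j] - strength[i] * strength[j] / m2
    return q / m2


def best_modularity(weights: np.ndarray) -> float:
    """Maximum modularity over all partitions (feasible for n <= 8)."""
    n = len(weights)

    def partitions(elements):
        if not elements:
            yield []
            return
        first, rest = elements[0], elements[1:]
        for part in partitions(rest):
            for k in range(len(part)):
                yield part[:k] + [part[k] | {first}] + part[k + 1 :]
            yield part + [{first}]

    return max(modularity_value(weights, p) for p in partitions(list(range(n))))


def assortativity_binary(weights: np.ndarray) -> float:
    """Degree-degree Pearson correlation over directed edge stubs (binary)."""
    a = (weights > 0).astype(int)
    deg = a.sum(axis=1)
    xs, ys = [], []
    n = len(a)
    for i in range(n):
        for j in range(n):
            if a[i, j]:
                xs.append(deg[i])
                ys.append(deg[j])
    xs, ys = np.asarray(xs, float), np.asarray(ys, float)
    return float(
        ((xs * ys).mean() - xs.mean() * ys.mean())
        / math.sqrt((xs**2).mean() - xs.mean() ** 2)
        / math.sqrt((ys**2).mean() - ys.mean() ** 2)
    )


def hierarchy_exponent(weights: np.ndarray) -> float:
    """-slope of the least-squares line log C(i) vs log k(i), k>1, C>0."""
    clus = clustering_onnela(weights)
    deg = (weights > 0).sum(axis=1)
    pts = [(math.log(k), math.log(c)) for k, c in zip(deg, clus) if k > 1 and c > 0]
    xs = np.array([p[0] for p in pts])
    ys = np.array([p[1] for p in pts])
    xbar, ybar = xs.mean(), ys.mean()
    slope = ((xs - xbar) * (ys - ybar)).sum() / ((xs - xbar) ** 2).sum()
    return -float(slope)


def pooled_t(a, b):
    """Textbook pooled two-sample t and two-sided p via the t CDF."""
    from scipy.stats import t as tdist

    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    sp2 = (((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()) / (na + nb - 2)
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    p = 2 * (1 - tdist.cdf(abs(t), na + nb - 2))
    return t, p


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Step-up BH adjusted p-values: min over k>=rank of m p_(k)/k."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running = min(running, m * p[idx] / rank_from_top)
        adj[idx] = running
    return adj


def trapezoid_auc(values, xs) -> float:
    v, x = np.asarray(values, float), np.asarray(xs, float)
    total = 0.0
    for k in range(len(v) - 1):
        total += 0.5 * (v[k] + v[k + 1]) * (x[k + 1] - x[k])
    return total / (x[-1] - x[0])


def discrete_symmetric_kl(p, q) -> float:
    return float(
        sum(pi * math.log(pi / qi) + qi * math.log(qi / pi) for pi, qi in zip(p, q))
    )
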