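"""Independent brute-force oracles used to cross-check the implementation.

Everything here enumerates exhaustively at tiny n and shares no code with
the package's computational paths.
"""

from __future__ import annotations

import itertools

import numpy as np


def pearson_direct(x, y) -> float:
    """Direct formula evaluation: sum of cross-deviations over root products."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xm, ym = x.mean(), y.mean()
    num = np.sum((x - xm) * (y - ym))
    den = np.sqrt(np.sum((x - xm) ** 2) * np.sum((y - ym) ** 2))
    return float(num / den)


def threshold_scan(pairs, roi_labels, grid_step):
    """Descending scan of the grid, applying criteria I/II literally.

    ``pairs`` is a list of (roi_a, roi_b, voxel_a, voxel_b, r).  Returns the
    largest feasible grid value, or None.
    """
    n_levels = int(round(1.0 / grid_step)) - 1
    for k in range(n_levels, 0, -1):
        t = k * grid_step
        effective: dict[int, set] = {int(l): set() for l in roi_labels}
        for ra, rb, va, vb, r in pairs:
            if r > 0 and r >= t - 1e-12:
                effective[int(ra)].add(va)
                effective[int(rb)].add(vb)
        if all(len(v) >= 1 for v in effective.values()):
            return round(t, 12)
    return None


def all_spanning_trees_max_weight(weights) -> float:
    """Exhaustive maximum spanning-tree weight over all edge subsets."""
    w = np.asarray(weights, float)
    n = w.shape[0]
    edges = [(i, j, w[i, j]) for i in range(n) for j in range(i + 1, n) if w[i, j] > 0]
    best = -np.inf
    for combo in itertools.combinations(edges, n - 1):
        parent = list(range(n))

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        acyclic = True
        for i, j, _ in combo:
            ri, rj = find(i), find(j)
            if ri == rj:
                acyclic = False
                break
            parent[ri] = rj
        if acyclic and len({find(i) for i in range(n)}) == 1:
            best = max(best, sum(e[2] for e in combo))
    return best


def betweenness_exhaustive(weights, length="inv") -> np.ndarray:
    """Betweenness by enumerating every simple path between every pair.

    Shortest-path lengths and tie counts come from direct path enumeration;
    interior nodes of tied shortest paths get fractional credit.
    """
    w = np.asarray(weights, float)
    n = w.shape[0]
    adj = {i: [j for j in range(n) if w[i, j] > 0] for i in range(n)}

    def edge_len(i, j):
        return 1.0 / w[i, j] if length == "inv" else 1.0 - w[i, j]

    def simple_paths(s, t):
        stack = [(s, [s])]
        while stack:
            node, path = stack.pop()
            if node == t:
                yield path
                continue
            for nb in adj[node]:
                if nb not in path:
                    stack.append((nb, path + [nb]))

    bc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            paths = list(simple_paths(s, t))
            if not paths:
                continue
            lengths = [sum(edge_len(p[i], p[i + 1]) for i in range(len(p) - 1)) for p in paths]
            dmin = min(lengths)
            shortest = [p for p, l in zip(paths, lengths) if l <= dmin + 1e-12]
            for p in shortest:
                for v in p[1:-1]:
                    bc[v] += 1.0 / len(shortest)
    return bc


def onnela_clustering_direct(weights) -> np.ndarray:
    """Onnela coefficient from the definition, triple loop."""
    w = np.asarray(weights, float)
    n = w.shape[0]
    wmax = w.max()
    if wmax == 0:
        return np.zeros(n)
    wh = w / wmax
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if w[i, j] > 0]
        k = len(nbrs)
        if k < 2:
            continue
        s = 0.0
        for a in range(k):
            for b in range(a + 1, k):
                j, h = nbrs[a], nbrs[b]
                if w[j, h] > 0:
                    s += (wh[i, j] * wh[i, h] * wh[j, h]) ** (1.0 / 3.0)
        out[i] = 2.0 * s / (k * (k - 1))
    return out


def watts_strogatz_clustering(adj) -> np.ndarray:
    """Classic binary local clustering coefficient."""
    a = (np.asarray(adj) > 0).astype(int)
    n = a.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(a[i])
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(
            a[u, v] for u, v in itertools.combinations(nbrs, 2)
        )
        out[i] = 2.0 * links / (k * (k - 1))
    return out


def _positive_graph_connected(w) -> bool:
    n = w.shape[0]
    seen = {0}
    stack = [0]
    while stack:
        i = stack.pop()
        for j in np.flatnonzero(w[i] > 0):
            if j not in seen:
                seen.add(int(j))
                stack.append(int(j))
    return len(seen) == n


def random_correlation_graph(n, rng, t=40):
    """Random correlation network via random signals; resampled (rarely, for
    small n) until the positive-weight graph is connected."""
    while True:
        base = rng.standard_normal(t)
        sig = 0.5 * base + rng.standard_normal((n, t))
        w = np.corrcoef(sig)
        np.fill_diagonal(w, 0.0)
        w = np.clip(w, 0.0, 1.0)
        if _positive_graph_connected(w):
            return w
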