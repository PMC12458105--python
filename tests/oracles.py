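"""Independent brute-force implementations of the graph descriptors.

Deliberately naive (explicit loops, Floyd-Warshall, exhaustive path
enumeration) so they share no code path with the package; used to verify
the production implementations on small random graphs.
"""

import numpy as np


def floyd_warshall(w):
    """All-pairs shortest paths on lengths 1/w via triple-loop relaxation."""
    d = w.shape[0]
    dist = np.full((d, d), np.inf)
    np.fill_diagonal(dist, 0.0)
    for i in range(d):
        for j in range(d):
            if w[i, j] > 0:
                dist[i, j] = 1.0 / w[i, j]
    for k in range(d):
        for i in range(d):
            for j in range(d):
                if dist[i, k] + dist[k, j] < dist[i, j]:
                    dist[i, j] = dist[i, k] + dist[k, j]
    return dist


def global_efficiency(w):
    dist = floyd_warshall(w)
    d = w.shape[0]
    acc = 0.0
    for i in range(d):
        for j in range(d):
            if i != j and np.isfinite(dist[i, j]):
                acc += 1.0 / dist[i, j]
    return acc / (d * (d - 1))


def characteristic_path_length(w):
    dist = floyd_warshall(w)
    d = w.shape[0]
    vals = [dist[i, j] for i in range(d) for j in range(d) if i != j]
    return float(np.mean(vals))


def clustering_coefficient(w):
    """Onnela weighted clustering by exhaustive triangle enumeration."""
    d = w.shape[0]
    wmax = w.max()
    if wmax == 0:
        return 0.0
    wn = w / wmax
    per_node = []
    for i in range(d):
        k = int((w[i] > 0).sum())
        if k < 2:
            per_node.append(0.0)
            continue
        acc = 0.0
        for j in range(d):
            for h in range(d):
                if j != i and h != i and j != h:
                    acc += (wn[i, j] * wn[i, h] * wn[j, h]) ** (1.0 / 3.0)
        per_node.append(acc / (k * (k - 1)))
    return float(np.mean(per_node))


def local_efficiency(w):
    d = w.shape[0]
    per_node = []
    for i in range(d):
        nbrs = [j for j in range(d) if w[i, j] > 0]
        if len(nbrs) < 2:
            per_node.append(0.0)
            continue
        sub = w[np.ix_(nbrs, nbrs)]
        per_node.append(global_efficiency(sub))
    return float(np.mean(per_node))


def betweenness(w, tol=1e-12):
    """Brandes-free betweenness: enumerate every simple path per pair.

    Exponential; only usable for d <= 9 or so.  Normalized by
    (d-1)(d-2)/2.
    """
    d = w.shape[0]
    lengths = {
        (i, j): 1.0 / w[i, j] for i in range(d) for j in range(d) if w[i, j] > 0
    }

    def all_paths(s, t):
        paths = []

        def extend(path, total):
            last = path[-1]
            if last == t:
                paths.append((total, tuple(path)))
                return
            for nxt in range(d):
                if (last, nxt) in lengths and nxt not in path:
                    extend(path + [nxt], total + lengths[(last, nxt)])

        extend([s], 0.0)
        return paths

    bc = np.zeros(d)
    for s in range(d):
        for t in range(s + 1, d):
            paths = all_paths(s, t)
            if not paths:
                continue
            best = min(p[0] for p in paths)
            shortest = [p for p in paths if p[0] <= best + tol]
            sigma = len(shortest)
            for _, path in shortest:
                for v in path[1:-1]:
                    bc[v] += 1.0 / sigma
    return bc / ((d - 1) * (d - 2) / 2.0)


def eigenvector(w, iters=20000):
    """Principal eigenvector by shifted power iteration.

    The shift w + s*I (s > spectral radius) keeps the eigenvectors but
    makes the Perron eigenvalue strictly dominant, so iteration converges
    even on bipartite-like graphs with a symmetric spectrum.
    """
    d = w.shape[0]
    shifted = w + (1.0 + w.sum(axis=1).max()) * np.eye(d)
    v = np.ones(d) / np.sqrt(d)
    for _ in range(iters):
        nv = shifted @ v
        nv /= np.linalg.norm(nv)
        if np.abs(nv - v).max() < 1e-15:
            v = nv
            break
        v = nv
    return v


def nodal_strength(w):
    return np.array([sum(w[i, j] for j in range(w.shape[0])) for i in range(w.shape[0])])


def lobe_sums(w, lobes, hemis):
    """Exhaustive double-loop edge grouping by lobe pair and hemisphere."""
    out = {}
    d = w.shape[0]
    for i in range(d):
        for j in range(i + 1, d):
            if w[i, j] == 0:
                continue
            key = (*sorted((lobes[i], lobes[j])),
                   "intra" if hemis[i] == hemis[j] else "inter")
            out[key] = out.get(key, 0.0) + w[i, j]
    return out
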