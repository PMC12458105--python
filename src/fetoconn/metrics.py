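"""Weighted graph-theoretic descriptors of a connectome.

Conventions, stated once and used everywhere:

* weight -> length transform: ``l = 1 / w`` (stronger connections are
  shorter), absent edges have infinite length;
* clustering is the Onnela geometric-mean formulation with weights
  normalized by the graph maximum;
* the small-world index normalizes clustering and path length by a
  degree-preserving Maslov-Sneppen null ensemble with weights shuffled
  among the rewired edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import connected_components, shortest_path

from .io import Connectome, NodeTable

__all__ = [
    "MetricsReport",
    "NullModelConfig",
    "nodal_strength",
    "total_strength",
    "shortest_path_lengths",
    "global_efficiency",
    "characteristic_path_length",
    "clustering_coefficient",
    "local_efficiency",
    "small_world_index",
    "betweenness_centrality",
    "eigenvector_centrality",
    "identify_hubs",
    "hub_overlap",
    "lobe_connectivity",
    "compute_metrics",
]


@dataclass
class NullModelConfig:
    """Null ensemble for small-world normalization.

    ``rewiring_iterations_per_edge`` Maslov-Sneppen double-edge swaps are
    attempted per edge; with 0 iterations the null is the graph itself.
    """

    n_nulls: int = 100
    rewiring_iterations_per_edge: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nulls < 1:
            raise ValueError("n_nulls must be >= 1")


@dataclass
class MetricsReport:
    global_efficiency: float
    local_efficiency: float
    characteristic_path_length: float
    clustering_coefficient: float
    small_world_index: float
    total_strength: float
    nodal_strength: np.ndarray = field(repr=False)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["nodal_strength"] = list(map(float, self.nodal_strength))
        return d


def _weights(c: Connectome | np.ndarray) -> np.ndarray:
    if isinstance(c, Connectome):
        return c.weights
    return np.asarray(c, dtype=float)


def nodal_strength(c: Connectome | np.ndarray) -> np.ndarray:
    """Strength of each node: the sum of connection weights to its neighbors."""
    return _weights(c).sum(axis=1)


def total_strength(c: Connectome | np.ndarray) -> float:
    """Sum of nodal strengths across all regions (each edge counted twice)."""
    return float(nodal_strength(c).sum())


def _length_matrix(w: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    return lengths


def shortest_path_lengths(c: Connectome | np.ndarray) -> np.ndarray:
    """All-pairs shortest path distances on edge lengths 1/w.

    Unreachable pairs get ``inf``; the diagonal is 0.
    """
    w = _weights(c)
    lengths = _length_matrix(w)
    # dense csgraph input: zeros mean "no edge"
    return shortest_path(lengths, method="D", directed=False)


def global_efficiency(c: Connectome | np.ndarray) -> float:
    """Mean over ordered node pairs of the inverse shortest path length."""
    w = _weights(c)
    d = w.shape[0]
    if d < 2:
        raise ValueError("need at least 2 nodes")
    dist = shortest_path_lengths(w)
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (d * (d - 1)))


def _components(w: np.ndarray) -> tuple[int, np.ndarray]:
    return connected_components((w > 0).astype(int), directed=False)


def characteristic_path_length(c: Connectome | np.ndarray) -> float:
    """Mean shortest path length over ordered pairs; errors if disconnected."""
    w = _weights(c)
    n_comp, labels = _components(w)
    if n_comp > 1:
        sizes = np.bincount(labels)
        raise ValueError(
            f"graph is disconnected ({n_comp} components, sizes {sizes.tolist()})"
        )
    dist = shortest_path_lengths(w)
    d = w.shape[0]
    off = ~np.eye(d, dtype=bool)
    return float(dist[off].mean())


def clustering_coefficient(c: Connectome | np.ndarray) -> float:
    """Mean Onnela weighted clustering (weights normalized by graph max).

    c_i = (1 / k_i(k_i-1)) * sum_{j,h} (w'_ij w'_ih w'_jh)^(1/3) with
    w' = w / max(w); nodes of degree < 2 contribute 0.
    """
    w = _weights(c)
    wmax = w.max()
    if wmax == 0:
        return 0.0
    cw = np.cbrt(w / wmax)
    triangles = np.diagonal(cw @ cw @ cw)  # 2 * sum of cube-root triangle weights
    k = (w > 0).sum(axis=1)
    denom = k * (k - 1)
    per_node = np.where(denom > 0, triangles / np.where(denom > 0, denom, 1), 0.0)
    return float(per_node.mean())


def local_efficiency(c: Connectome | np.ndarray) -> float:
    """Mean over nodes of the global efficiency of the neighborhood subgraph.

    The neighborhood of node i is the subgraph induced on its neighbors
    (node i removed); nodes with degree < 2 contribute 0.
    """
    w = _weights(c)
    d = w.shape[0]
    vals = np.zeros(d)
    for i in range(d):
        nbrs = np.flatnonzero(w[i] > 0)
        if nbrs.size < 2:
            continue
        sub = w[np.ix_(nbrs, nbrs)]
        vals[i] = global_efficiency(sub)
    return float(vals.mean())


def _null_graph(w: np.ndarray, n_swaps: int, rng: np.random.Generator) -> np.ndarray:
    """Degree-preserving rewiring with weights shuffled among surviving edges.

    Resamples until the rewired graph is connected.  ``n_swaps == 0``
    returns the graph unchanged (identity null, so SWI self-normalizes to 1).
    """
    if n_swaps == 0:
        return w.copy()
    d = w.shape[0]
    iu = np.triu_indices(d, k=1)
    edge_weights = w[iu][w[iu] > 0]
    g = nx.from_numpy_array((w > 0).astype(int))
    for _ in range(50):
        g2 = g.copy()
        try:
            nx.double_edge_swap(
                g2, nswap=n_swaps, max_tries=100 * n_swaps,
                seed=int(rng.integers(2**31)),
            )
        except nx.NetworkXException:
            # dense graphs admit few swaps; the partially rewired graph is
            # still a valid degree-preserving null
            pass
        if not nx.is_connected(g2):
            continue
        null = np.zeros_like(w)
        edges = sorted(g2.edges())
        perm = rng.permutation(len(edge_weights))
        for (i, j), wi in zip(edges, edge_weights[perm]):
            null[i, j] = null[j, i] = wi
        return null
    raise RuntimeError("could not produce a connected rewired null graph")


def small_world_index(
    c: Connectome | np.ndarray, null: NullModelConfig | None = None
) -> float:
    """SWI = (CC / <CC_null>) / (CPL / <CPL_null>) against a rewired ensemble."""
    if null is None:
        null = NullModelConfig()
    w = _weights(c)
    n_comp, _ = _components(w)
    if n_comp > 1:
        raise ValueError("small_world_index requires a connected graph")
    m = int((w > 0).sum() // 2)
    n_swaps = null.rewiring_iterations_per_edge * m
    rng = np.random.default_rng(null.seed)
    cc_nulls = np.empty(null.n_nulls)
    cpl_nulls = np.empty(null.n_nulls)
    for b in range(null.n_nulls):
        nw = _null_graph(w, n_swaps, rng)
        cc_nulls[b] = clustering_coefficient(nw)
        cpl_nulls[b] = characteristic_path_length(nw)
    cc = clustering_coefficient(w)
    cpl = characteristic_path_length(w)
    return float((cc / cc_nulls.mean()) / (cpl / cpl_nulls.mean()))


def betweenness_centrality(c: Connectome | np.ndarray) -> np.ndarray:
    """Weighted betweenness on lengths 1/w, normalized by (d-1)(d-2)/2."""
    w = _weights(c)
    lengths = _length_matrix(w)
    g = nx.from_numpy_array(lengths)
    bc = nx.betweenness_centrality(g, weight="weight", normalized=True)
    return np.array([bc[i] for i in range(w.shape[0])])


def eigenvector_centrality(
    c: Connectome | np.ndarray, max_iter: int = 1000
) -> np.ndarray:
    """Principal eigenvector of the weight matrix (non-negative, unit l2 norm)."""
    w = _weights(c)
    n_comp, _ = _components(w)
    if n_comp > 1:
        raise ValueError("eigenvector centrality requires a connected graph")
    vals, vecs = np.linalg.eigh(w)
    v = vecs[:, -1]
    # Perron-Frobenius: the leading eigenvector of a connected non-negative
    # matrix has one sign; orient it non-negative.
    if v.sum() < 0:
        v = -v
    v = np.clip(v, 0.0, None)
    return v / np.linalg.norm(v)


_CENTRALITIES = {
    "strength": nodal_strength,
    "betweenness": betweenness_centrality,
    "eigenvector": eigenvector_centrality,
}


def identify_hubs(
    c: Connectome, metric: str = "strength", k: int = 10
) -> list[str]:
    """Top-k nodes by a centrality measure; ties broken by node id order."""
    if metric not in _CENTRALITIES:
        raise ValueError(
            f"unknown metric {metric!r}; choose from {sorted(_CENTRALITIES)}"
        )
    if k > c.n_nodes:
        raise ValueError(f"k={k} exceeds number of nodes {c.n_nodes}")
    scores = _CENTRALITIES[metric](c)
    order = np.argsort(-scores, kind="stable")
    return [c.node_ids[i] for i in order[:k]]


def hub_overlap(a, b) -> float:
    """Fraction of shared nodes between two equal-size hub sets."""
    a, b = set(a), set(b)
    if len(a) != len(b):
        raise ValueError(f"hub set sizes differ ({len(a)} vs {len(b)})")
    return len(a & b) / len(a)


def lobe_connectivity(c: Connectome, nt: NodeTable):
    """Sum of edge weights per (lobe pair, same/cross hemisphere) cell.

    Each undirected edge is counted exactly once, so the cells sum to the
    total edge weight of the graph.  Returns a pandas DataFrame indexed by
    (lobe_a, lobe_b) with columns ``intra_hemisphere`` / ``inter_hemisphere``.
    """
    import pandas as pd

    if nt.node_ids != c.node_ids:
        raise ValueError("node table does not match connectome")
    lobes = nt.lobes
    hemis = nt.hemispheres
    if any(not l or (isinstance(l, float) and np.isnan(l)) for l in lobes):
        raise ValueError("node with missing lobe")
    lobe_names = sorted(set(lobes))
    cells: dict[tuple[str, str, str], float] = {}
    d = c.n_nodes
    for i in range(d):
        for j in range(i + 1, d):
            w = c.weights[i, j]
            if w == 0:
                continue
            la, lb = sorted((lobes[i], lobes[j]))
            kind = (
                "intra_hemisphere" if hemis[i] == hemis[j] else "inter_hemisphere"
            )
            cells[(la, lb, kind)] = cells.get((la, lb, kind), 0.0) + w
    pairs = [
        (a, b)
        for ai, a in enumerate(lobe_names)
        for b in lobe_names[ai:]
    ]
    df = pd.DataFrame(
        0.0,
        index=pd.MultiIndex.from_tuples(pairs, names=["lobe_a", "lobe_b"]),
        columns=["intra_hemisphere", "inter_hemisphere"],
    )
    for (a, b, kind), v in cells.items():
        df.loc[(a, b), kind] = v
    return df


def compute_metrics(
    c: Connectome, null: NullModelConfig | None = None
) -> MetricsReport:
    """All scalar descriptors of one connectome in a single report."""
    ns = nodal_strength(c)
    return MetricsReport(
        global_efficiency=global_efficiency(c),
        local_efficiency=local_efficiency(c),
        characteristic_path_length=characteristic_path_length(c),
        clustering_coefficient=clustering_coefficient(c),
        small_world_index=small_world_index(c, null),
        total_strength=float(ns.sum()),
        nodal_strength=ns,
    )
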