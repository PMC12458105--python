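"""Age-specific connectome template construction by connectome aggregation.

A template set is one representative connectome per gestational week,
found by minimizing a three-term objective over the M template matrices
C_T jointly:

    L(C_T) = L_repr + lambda_cons * L_cons + lambda_dist * L_dist

* ``L_repr``  pulls each weekly template toward the individual connectomes
  of similar-age subjects: sum_i sum_j G(t_i, t_j) * GED(C_s^i, C_T^j),
  where GED is the l1 distance between weighted adjacency matrices (the
  graph edit distance when nodes are fixed and edit costs are weight
  differences) and G(t1, t2) = exp(-(t1-t2)^2 / 2 sigma^2) is a Gaussian
  kernel in gestational age (sigma = 1 week by default).
* ``L_cons``  penalizes GED between templates of nearby weeks, giving a
  temporally smooth template sequence.
* ``L_dist``  matches the distance-wise distribution of connection weights
  between subjects and templates via the Jensen-Shannon divergence of
  20-bin histograms, counteracting the short-range bias of consensus
  averaging so long-range connections are proportionally preserved.

The objective is minimized with stochastic (sub)gradient descent from a
per-week-average initialization.  Two standard aggregation baselines are
also provided: consensus thresholding and distance-preserved averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import rel_entr

from .io import Cohort, Connectome, node_distances

__all__ = [
    "KernelParams",
    "TemplateLossConfig",
    "TemplateSet",
    "DistanceDistribution",
    "gaussian_kernel",
    "graph_edit_distance",
    "histogram_bin_edges",
    "distance_weight_histogram",
    "js_divergence",
    "template_losses",
    "init_templates",
    "fit_templates",
    "consensus_threshold_template",
    "distance_preserved_template",
    "ConnectomeTemplateModel",
    "ConnectomeTemplateResults",
]

LN2 = float(np.log(2.0))


@dataclass
class KernelParams:
    """Gaussian age-similarity kernel G(t1,t2)=exp(-(t1-t2)^2/2 sigma^2)."""

    sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")


@dataclass
class TemplateLossConfig:
    """Weights and optimizer settings for the template objective.

    ``lambda_cons`` and ``lambda_dist`` weight the temporal-consistency and
    distance-distribution terms relative to the representation loss.  The
    learning rate defaults to 1e-5, small enough for a stable l1
    subgradient descent.
    """

    lambda_cons: float = 1.0
    lambda_dist: float = 1.0
    n_bins: int = 20
    learning_rate: float = 1e-5
    n_epochs: int = 200
    convergence_tol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.lambda_cons < 0 or self.lambda_dist < 0:
            raise ValueError("loss weights must be >= 0")


@dataclass
class DistanceDistribution:
    """Histogram of connection weight mass as a function of edge length."""

    bin_edges: np.ndarray
    mass: np.ndarray

    def __post_init__(self) -> None:
        e = np.asarray(self.bin_edges, dtype=float)
        m = np.asarray(self.mass, dtype=float)
        if len(e) != len(m) + 1:
            raise ValueError("need n_bins+1 edges for n_bins masses")
        if not np.all(np.diff(e) > 0):
            raise ValueError("bin edges must be strictly increasing")
        if (m < 0).any():
            raise ValueError("negative mass")
        if abs(m.sum() - 1.0) > 1e-12:
            raise ValueError(f"mass sums to {m.sum()!r}, not 1")
        self.bin_edges, self.mass = e, m


@dataclass
class TemplateSet:
    """One template connectome per gestational week, with fit diagnostics."""

    weeks: list[int]
    templates: list[Connectome]
    loss_trace: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.weeks:
            raise ValueError("empty template set")
        if len(self.weeks) != len(self.templates):
            raise ValueError("one template per week required")
        if not all(b > a for a, b in zip(self.weeks, self.weeks[1:])):
            raise ValueError("weeks must be strictly increasing")

    def __len__(self) -> int:
        return len(self.weeks)

    def __iter__(self):
        return iter(zip(self.weeks, self.templates))

    @property
    def node_ids(self) -> list[str]:
        return self.templates[0].node_ids

    def edge_matrix(self) -> np.ndarray:
        return np.array([t.upper_triangle() for t in self.templates])


def gaussian_kernel(t1, t2, kp: KernelParams | None = None) -> float:
    """Age-similarity kernel value in (0, 1]."""
    if kp is None:
        kp = KernelParams()
    t1, t2 = np.asarray(t1, dtype=float), np.asarray(t2, dtype=float)
    out = np.exp(-((t1 - t2) ** 2) / (2.0 * kp.sigma**2))
    return float(out) if out.ndim == 0 else out


def graph_edit_distance(c1: Connectome, c2: Connectome) -> float:
    """l1 distance between two connectomes over a shared node set.

    With fixed nodes, edge edits (insert/delete/substitute) costed by the
    weight change make the graph edit distance the l1 matrix distance; it
    is accumulated over the upper triangle (each undirected edge once).
    """
    if c1.node_ids != c2.node_ids:
        raise ValueError("node sets differ")
    iu = np.triu_indices(c1.n_nodes, k=1)
    return float(np.abs(c1.weights[iu] - c2.weights[iu]).sum())


def histogram_bin_edges(D: np.ndarray, n_bins: int = 20) -> np.ndarray:
    """Shared equal-width bin edges spanning [0, max inter-node distance]."""
    dmax = float(np.max(D))
    if dmax <= 0:
        raise ValueError("degenerate distance matrix (max distance 0)")
    return np.linspace(0.0, dmax, n_bins + 1)


def _soft_assignment(dists: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """(n_pairs, n_bins) soft (linear) assignment of each edge length to bins.

    Mass is split linearly between the two adjacent bin centers; lengths
    beyond the first/last center are clamped to the end bin.  Rows sum to 1.
    """
    centers = 0.5 * (edges[:-1] + edges[1:])
    n_bins = len(centers)
    A = np.zeros((len(dists), n_bins))
    idx = np.searchsorted(centers, dists)  # first center >= dist
    lo_clamp = idx == 0
    hi_clamp = idx == n_bins
    A[lo_clamp, 0] = 1.0
    A[hi_clamp, -1] = 1.0
    mid = ~(lo_clamp | hi_clamp)
    k = idx[mid]
    frac = (dists[mid] - centers[k - 1]) / (centers[k] - centers[k - 1])
    rows = np.flatnonzero(mid)
    A[rows, k - 1] = 1.0 - frac
    A[rows, k] = frac
    return A


def _histogram_mass(
    edge_w: np.ndarray, A: np.ndarray, hard: bool = False,
    dists: np.ndarray | None = None, edges: np.ndarray | None = None,
) -> np.ndarray:
    if hard:
        mass, _ = np.histogram(dists, bins=edges, weights=edge_w)
    else:
        mass = edge_w @ A
    total = mass.sum()
    if total <= 0:
        raise ValueError("all-zero connectome: no mass to normalize")
    return mass / total


def distance_weight_histogram(
    c: Connectome,
    D: np.ndarray,
    edges: np.ndarray,
    hard: bool = False,
) -> DistanceDistribution:
    """Distance-wise distribution of connection weights for one connectome.

    Each edge (i<j) contributes mass proportional to its weight at its
    length D[i,j].  By default the mass is split linearly between the two
    adjacent bin centers (differentiable soft binning); ``hard=True`` uses
    conventional histogram binning (evaluation only).
    """
    iu = np.triu_indices(c.n_nodes, k=1)
    w = c.weights[iu]
    dists = np.asarray(D, dtype=float)[iu]
    A = _soft_assignment(dists, np.asarray(edges, dtype=float))
    mass = _histogram_mass(w, A, hard=hard, dists=dists, edges=np.asarray(edges))
    return DistanceDistribution(np.asarray(edges, dtype=float), mass)


def js_divergence(p: DistanceDistribution, q: DistanceDistribution) -> float:
    """D_JS(p, q) = KL(p || m) + KL(q || m), m = (p+q)/2, natural log.

    Symmetric, zero iff p == q, and at most 2 ln 2 (disjoint supports).
    """
    if not np.array_equal(p.bin_edges, q.bin_edges):
        raise ValueError("bin edges differ")
    return _js_mass(p.mass, q.mass)


def _js_mass(p: np.ndarray, q: np.ndarray) -> float:
    m = 0.5 * (p + q)
    return float(rel_entr(p, m).sum() + rel_entr(q, m).sum())


# ---------------------------------------------------------------------------
# losses and optimization (flat upper-triangle representation throughout)


def _cohort_arrays(cohort: Cohort):
    S = cohort.edge_matrix()  # (N, n_pairs)
    t_s = cohort.ages
    return S, t_s


def _pair_distances(D: np.ndarray, d: int) -> np.ndarray:
    iu = np.triu_indices(d, k=1)
    return np.asarray(D, dtype=float)[iu]


def _losses_flat(
    T: np.ndarray, t_w: np.ndarray, S: np.ndarray, t_s: np.ndarray,
    A: np.ndarray, P_subj: np.ndarray, kp: KernelParams,
) -> tuple[float, float, float]:
    G_sw = gaussian_kernel(t_s[:, None], t_w[None, :], kp)  # (N, M)
    G_ww = gaussian_kernel(t_w[:, None], t_w[None, :], kp)  # (M, M)
    # L_repr: sum_ij G_ij * ||S_i - T_j||_1
    ged_sw = np.abs(S[:, None, :] - T[None, :, :]).sum(axis=2)
    l_repr = float((G_sw * ged_sw).sum())
    ged_ww = np.abs(T[:, None, :] - T[None, :, :]).sum(axis=2)
    l_cons = float((G_ww * ged_ww).sum())
    Q = _template_hists(T, A)
    M_half = 0.5 * (P_subj[:, None, :] + Q[None, :, :])
    js = (
        rel_entr(P_subj[:, None, :], M_half).sum(axis=2)
        + rel_entr(Q[None, :, :], M_half).sum(axis=2)
    )
    l_dist = float((G_sw * js).sum())
    return l_repr, l_cons, l_dist


def _template_hists(T: np.ndarray, A: np.ndarray) -> np.ndarray:
    mass = T @ A  # (M, n_bins)
    totals = mass.sum(axis=1, keepdims=True)
    if (totals <= 0).any():
        raise ValueError("all-zero template: no mass to normalize")
    return mass / totals


def template_losses(
    ts: TemplateSet,
    cohort: Cohort,
    D: np.ndarray,
    kp: KernelParams | None = None,
    cfg: TemplateLossConfig | None = None,
) -> tuple[float, float, float]:
    """(L_repr, L_cons, L_dist) of a template set against a cohort."""
    kp = kp or KernelParams()
    cfg = cfg or TemplateLossConfig()
    S, t_s = _cohort_arrays(cohort)
    d = cohort.n_nodes
    edges = histogram_bin_edges(D, cfg.n_bins)
    dists = _pair_distances(D, d)
    A = _soft_assignment(dists, edges)
    P_subj = np.array([_histogram_mass(s, A) for s in S])
    T = ts.edge_matrix()
    t_w = np.asarray(ts.weeks, dtype=float)
    return _losses_flat(T, t_w, S, t_s, A, P_subj, kp)


def _flat_to_templates(
    T: np.ndarray, weeks: Sequence[int], node_ids: list[str],
    loss_trace: pd.DataFrame | None = None,
) -> TemplateSet:
    d = len(node_ids)
    iu = np.triu_indices(d, k=1)
    templates = []
    for row in T:
        w = np.zeros((d, d))
        w[iu] = row
        w = w + w.T
        templates.append(Connectome(w, node_ids))
    return TemplateSet(list(weeks), templates, loss_trace=loss_trace)


def init_templates(
    cohort: Cohort, weeks: Sequence[int] | None = None
) -> TemplateSet:
    """Per-week element-wise average initialization.

    Week t averages subjects with age in [t-0.5, t+0.5).  A week with no
    subject widens its window symmetrically in 0.5-week increments until at
    least one subject falls inside.
    """
    if weeks is None:
        weeks = list(range(22, 38))
    weeks = list(weeks)
    S, t_s = _cohort_arrays(cohort)
    T = np.empty((len(weeks), S.shape[1]))
    for j, t in enumerate(weeks):
        half = 0.5
        while True:
            sel = (t_s >= t - half) & (t_s < t + half)
            if sel.any():
                break
            half += 0.5
        T[j] = S[sel].mean(axis=0)
    return _flat_to_templates(T, weeks, cohort.node_ids)


def fit_templates(
    cohort: Cohort,
    weeks: Sequence[int] | None = None,
    D: np.ndarray | None = None,
    kp: KernelParams | None = None,
    cfg: TemplateLossConfig | None = None,
    init: TemplateSet | None = None,
) -> TemplateSet:
    """Minimize the three-term template objective with seeded SGD.

    Each iteration samples one subject uniformly at random, takes a
    subgradient step on that subject's representation and distance terms
    for all templates plus 1/N of the consistency term, then projects
    template weights to be non-negative.  One epoch is N iterations; the
    full loss is evaluated at each epoch end and the run stops early when
    its relative change falls below ``convergence_tol``.
    """
    kp = kp or KernelParams()
    cfg = cfg or TemplateLossConfig()
    if weeks is None:
        weeks = list(range(22, 38))
    weeks = list(weeks)
    if D is None:
        if cohort.node_table is None:
            raise ValueError("need a node table or explicit distance matrix")
        D = node_distances(cohort.node_table)

    S, t_s = _cohort_arrays(cohort)
    N = len(cohort)
    d = cohort.n_nodes
    t_w = np.asarray(weeks, dtype=float)
    edges = histogram_bin_edges(D, cfg.n_bins)
    A = _soft_assignment(_pair_distances(D, d), edges)
    P_subj = np.array([_histogram_mass(s, A) for s in S])
    G_sw = gaussian_kernel(t_s[:, None], t_w[None, :], kp)  # (N, M)
    G_ww = gaussian_kernel(t_w[:, None], t_w[None, :], kp)  # (M, M)

    if init is None:
        init = init_templates(cohort, weeks)
    T = init.edge_matrix().copy()

    rng = np.random.default_rng(cfg.seed)
    lr = cfg.learning_rate
    eps = 1e-12

    trace = [(-1, *_losses_flat(T, t_w, S, t_s, A, P_subj, kp))]
    init_total = (
        trace[0][1] + cfg.lambda_cons * trace[0][2] + cfg.lambda_dist * trace[0][3]
    )
    prev_total = init_total

    for epoch in range(cfg.n_epochs):
        for i in rng.integers(0, N, size=N):
            grad = G_sw[i][:, None] * np.sign(T - S[i][None, :])
            if cfg.lambda_dist > 0:
                if (T.sum(axis=1) <= 0).any():
                    raise RuntimeError(
                        "optimization collapsed a template to zero; "
                        "try a smaller learning rate"
                    )
                Q = _template_hists(T, A)  # (M, n_bins)
                denom = P_subj[i][None, :] + Q
                # dDJS/dq_b = log(2q/(p+q)); at p=q=0 the one-sided limit is log 2
                ratio = np.where(denom > eps, 2.0 * Q / np.maximum(denom, eps), 2.0)
                g_bins = np.log(np.maximum(ratio, eps))
                totals = (T @ A).sum(axis=1, keepdims=True)
                # dq_b/dw_e = (A_eb - q_b) / total weight
                g_edges = (g_bins @ A.T - (g_bins * Q).sum(axis=1, keepdims=True)) / totals
                grad += cfg.lambda_dist * G_sw[i][:, None] * g_edges
            if cfg.lambda_cons > 0:
                diff_sign = np.sign(T[:, None, :] - T[None, :, :])
                g_cons = 2.0 * (G_ww[:, :, None] * diff_sign).sum(axis=1)
                grad += (cfg.lambda_cons / N) * g_cons
            T -= lr * grad
            np.clip(T, 0.0, None, out=T)
        l_repr, l_cons, l_dist = _losses_flat(T, t_w, S, t_s, A, P_subj, kp)
        total = l_repr + cfg.lambda_cons * l_cons + cfg.lambda_dist * l_dist
        trace.append((epoch, l_repr, l_cons, l_dist))
        if total > 10.0 * init_total:
            raise RuntimeError(
                "optimization diverged (loss grew >10x the initial value); "
                "try a smaller learning rate"
            )
        if abs(prev_total - total) < cfg.convergence_tol * abs(prev_total):
            break
        prev_total = total

    df = pd.DataFrame(trace, columns=["epoch", "L_repr", "L_cons", "L_dist"])
    df["total"] = (
        df["L_repr"] + cfg.lambda_cons * df["L_cons"] + cfg.lambda_dist * df["L_dist"]
    )
    return _flat_to_templates(T, weeks, cohort.node_ids, loss_trace=df)


# ---------------------------------------------------------------------------
# baseline aggregators


def _binary_density(w_flat: np.ndarray) -> float:
    return float((w_flat > 0).mean())


def consensus_threshold_template(group: Sequence[Connectome]) -> Connectome:
    """Mean matrix thresholded to the group's average binary density.

    The threshold keeps the strongest mean-weight edges so that the
    template's density is as close as possible to the mean subject density;
    surviving entries keep their mean weights.
    """
    group = list(group)
    if not group:
        raise ValueError("empty group")
    node_ids = group[0].node_ids
    S = np.array([c.upper_triangle() for c in group])
    mean_w = S.mean(axis=0)
    target = round(np.mean([_binary_density(s) for s in S]) * S.shape[1])
    keep = np.argsort(-mean_w, kind="stable")[:target]
    out = np.zeros_like(mean_w)
    out[keep] = mean_w[keep]
    return _flat_to_templates(out[None, :], [0], node_ids).templates[0]


def distance_preserved_template(
    group: Sequence[Connectome], D: np.ndarray, n_bins: int = 20
) -> Connectome:
    """Consensus thresholding applied separately within edge-length bins.

    Within each length bin the most frequently present edges are kept until
    the bin holds the rounded mean per-bin edge count of the subjects, so
    long-range connections are proportionally retained.  Kept edges take
    mean weights; presence ties are broken by higher mean weight.
    """
    group = list(group)
    if not group:
        raise ValueError("empty group")
    node_ids = group[0].node_ids
    d = group[0].n_nodes
    S = np.array([c.upper_triangle() for c in group])
    dists = _pair_distances(D, d)
    edges = histogram_bin_edges(D, n_bins)
    bin_idx = np.clip(np.digitize(dists, edges) - 1, 0, n_bins - 1)
    mean_w = S.mean(axis=0)
    consensus = (S > 0).mean(axis=0)
    out = np.zeros_like(mean_w)
    for b in range(n_bins):
        members = np.flatnonzero(bin_idx == b)
        if members.size == 0:
            continue
        per_subj = (S[:, members] > 0).sum(axis=1)
        target = round(per_subj.mean())
        if target == 0:
            continue
        order = np.lexsort((-mean_w[members], -consensus[members]))
        keep = members[order[:target]]
        out[keep] = mean_w[keep]
    return _flat_to_templates(out[None, :], [0], node_ids).templates[0]


# ---------------------------------------------------------------------------
# model / results interface


class ConnectomeTemplateModel:
    """Age-specific template model for a cohort of weighted connectomes.

    Parameters
    ----------
    cohort : Cohort
        Subject connectomes with gestational ages and a shared node set.
    weeks : sequence of int, optional
        Template weeks (default 22..37).
    distances : (d, d) ndarray, optional
        Inter-node connection lengths in mm; defaults to Euclidean
        centroid distances from the cohort's node table.
    sigma : float
        Width (weeks) of the Gaussian age kernel.

    Examples
    --------
    >>> model = ConnectomeTemplateModel(cohort, weeks=range(22, 38))
    >>> res = model.fit(seed=7)
    >>> res.templates  # TemplateSet
    >>> print(res.summary())
    """

    def __init__(
        self,
        cohort: Cohort,
        weeks: Sequence[int] | None = None,
        distances: np.ndarray | None = None,
        sigma: float = 1.0,
    ):
        self.cohort = cohort
        self.weeks = list(weeks) if weeks is not None else list(range(22, 38))
        if distances is None:
            if cohort.node_table is None:
                raise ValueError("need a node table or explicit distances")
            distances = node_distances(cohort.node_table)
        self.distances = np.asarray(distances, dtype=float)
        self.kernel = KernelParams(sigma=sigma)

    def fit(
        self,
        method: str = "aggregate",
        lambda_cons: float = 1.0,
        lambda_dist: float = 1.0,
        n_bins: int = 20,
        learning_rate: float = 1e-5,
        n_epochs: int = 200,
        convergence_tol: float = 1e-6,
        seed: int = 0,
    ) -> "ConnectomeTemplateResults":
        """Fit templates.

        ``method`` is one of ``aggregate`` (the three-term objective),
        ``weekly_mean`` (per-week element-wise average), ``consensus``
        (per-week consensus thresholding), or ``distance_preserved``
        (per-week distance-preserved averaging).
        """
        cfg = TemplateLossConfig(
            lambda_cons=lambda_cons, lambda_dist=lambda_dist, n_bins=n_bins,
            learning_rate=learning_rate, n_epochs=n_epochs,
            convergence_tol=convergence_tol, seed=seed,
        )
        if method == "aggregate":
            ts = fit_templates(
                self.cohort, self.weeks, self.distances, self.kernel, cfg
            )
        elif method == "weekly_mean":
            ts = init_templates(self.cohort, self.weeks)
        elif method in ("consensus", "distance_preserved"):
            ts = self._per_week_baseline(method, cfg)
        else:
            raise ValueError(f"unknown method {method!r}")
        return ConnectomeTemplateResults(self, ts, method, cfg)

    def _per_week_baseline(self, method: str, cfg: TemplateLossConfig) -> TemplateSet:
        t_s = self.cohort.ages
        templates = []
        for t in self.weeks:
            half = 0.5
            while True:
                sel = (t_s >= t - half) & (t_s < t + half)
                if sel.any():
                    break
                half += 0.5
            group = [s for s, m in zip(self.cohort.subjects, sel) if m]
            if method == "consensus":
                tpl = consensus_threshold_template(group)
            else:
                tpl = distance_preserved_template(group, self.distances, cfg.n_bins)
            templates.append(tpl)
        return TemplateSet(self.weeks, templates)


class ConnectomeTemplateResults:
    """Fitted template set plus its diagnostics."""

    def __init__(
        self,
        model: ConnectomeTemplateModel,
        templates: TemplateSet,
        method: str,
        config: TemplateLossConfig,
    ):
        self.model = model
        self.templates = templates
        self.method = method
        self.config = config

    @property
    def loss_trace(self) -> pd.DataFrame | None:
        return self.templates.loss_trace

    def losses(self) -> tuple[float, float, float]:
        """(L_repr, L_cons, L_dist) of the fitted templates."""
        return template_losses(
            self.templates, self.model.cohort, self.model.distances,
            self.model.kernel, self.config,
        )

    def summary(self) -> str:
        l_repr, l_cons, l_dist = self.losses()
        total = (
            l_repr
            + self.config.lambda_cons * l_cons
            + self.config.lambda_dist * l_dist
        )
        lines = [
            "Connectome template fit",
            "=" * 47,
            f"method:            {self.method}",
            f"subjects:          {len(self.model.cohort)}",
            f"nodes:             {self.model.cohort.n_nodes}",
            f"weeks:             {self.templates.weeks[0]}-{self.templates.weeks[-1]}"
            f" ({len(self.templates)} templates)",
            f"sigma (weeks):     {self.model.kernel.sigma:g}",
            f"lambda_cons:       {self.config.lambda_cons:g}",
            f"lambda_dist:       {self.config.lambda_dist:g}",
            "-" * 47,
            f"L_repr:            {l_repr:.4f}",
            f"L_cons:            {l_cons:.4f}",
            f"L_dist:            {l_dist:.4f}",
            f"total loss:        {total:.4f}",
        ]
        if self.loss_trace is not None and len(self.loss_trace) > 1:
            lines.append(f"epochs run:        {len(self.loss_trace) - 1}")
            lines.append(
                f"initial total:     {self.loss_trace['total'].iloc[0]:.4f}"
            )
        return "\n".join(lines)

    def plot_loss(self, ax=None):
        """Per-epoch loss trace (aggregate method only)."""
        import matplotlib.pyplot as plt

        if self.loss_trace is None:
            raise ValueError(f"no loss trace for method {self.method!r}")
        if ax is None:
            _, ax = plt.subplots()
        tr = self.loss_trace
        for col in ("L_repr", "L_cons", "L_dist", "total"):
            ax.plot(np.arange(len(tr)), tr[col], label=col)
        ax.set_xlabel("epoch")
        ax.set_ylabel("loss")
        ax.legend()
        return ax
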