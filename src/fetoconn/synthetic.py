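"""Seeded generator of developmental connectome cohorts.

The generator emulates the statistical structure that the analyses in this
package assume about the fetal brain between 22 and 37 gestational weeks:

* a bilateral parcellation (default 88 regions, 44 per hemisphere) with
  mirrored centroids and lobe labels;
* distance-dependent edge sparsity (short-range connections are more
  likely to exist than long-range ones);
* per-edge sigmoid growth w(t) = b + L / (1 + exp(-k (t - t0))) with
  inflection times t0 clustered near 28.6 +/- 0.44 weeks, a planted set of
  consistently increasing edges and a small planted set of decreasing,
  predominantly interhemispheric edges (162 and 12 by default, echoing the
  cohort dimensions the analyses were designed for);
* subject-level noise: a subject scalar effect, multiplicative log-normal
  edge noise, and additive Gaussian noise, truncated at zero.

All outputs are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import Cohort, Connectome, NodeTable, node_distances
from .templates import TemplateSet, _flat_to_templates

__all__ = [
    "GrowthFieldParams",
    "NoiseModel",
    "GrowthField",
    "make_node_table",
    "sample_growth_field",
    "generate_cohort",
    "ground_truth_templates",
    "generate_split_half",
    "default_study",
    "sigmoid_node_samples",
]

LOBES = ("frontal", "parietal", "temporal", "occipital", "limbic", "insula")


@dataclass
class NoiseModel:
    """Noise decomposition on top of the noiseless growth field.

    A subject's *true* connectome deviates from the population field via a
    stable per-subject scalar effect (``subject_effect_sd``, log-normal)
    and a stable per-subject, per-edge deviation (``subject_edge_sd``,
    log-normal) -- the individual topology that makes connectomes
    fingerprintable.  Each *measurement* of that true connectome adds
    multiplicative log-normal (``multiplicative_sd``) and additive
    Gaussian (``additive_sd``) noise.  Split-half pairs share the stable
    terms and draw the measurement terms independently.
    """

    multiplicative_sd: float = 0.13
    additive_sd: float = 0.05
    subject_effect_sd: float = 0.10
    subject_edge_sd: float = 0.15

    def __post_init__(self) -> None:
        sds = (self.multiplicative_sd, self.additive_sd,
               self.subject_effect_sd, self.subject_edge_sd)
        if min(sds) < 0:
            raise ValueError("noise SDs must be >= 0")


@dataclass
class GrowthFieldParams:
    """Population-level parameters of the synthetic growth field.

    Edge presence decays exponentially with centroid distance
    (``exp(-dist / distance_decay_mm)`` scaled by ``presence_scale``); a
    nearest-neighbor backbone guarantees connectivity.  ``n_increasing``
    edges get a strong sigmoid increase, ``n_decreasing`` (interhemispheric
    where possible) a sigmoid decrease; remaining present edges are flat.
    """

    presence_scale: float = 0.9
    distance_decay_mm: float = 60.0
    n_increasing: int = 162
    n_decreasing: int = 12
    baseline_range: tuple[float, float] = (0.5, 2.0)
    amplitude_range: tuple[float, float] = (2.0, 5.0)
    rate_range: tuple[float, float] = (0.8, 2.0)
    t0_mean: float = 28.6
    t0_sd: float = 0.44
    t0_window: tuple[float, float] = (27.7, 30.5)
    left_t0_offset: float = -0.2


@dataclass
class GrowthField:
    """Noiseless per-edge sigmoid trajectories over a fixed node table."""

    node_table: NodeTable
    present: np.ndarray = field(repr=False)  # (n_pairs,) bool
    b: np.ndarray = field(repr=False)
    L: np.ndarray = field(repr=False)
    k: np.ndarray = field(repr=False)
    t0: np.ndarray = field(repr=False)
    sign: np.ndarray = field(repr=False)  # +1 increasing, -1 decreasing, 0 flat
    params: GrowthFieldParams = field(default_factory=GrowthFieldParams)

    @property
    def n_nodes(self) -> int:
        return len(self.node_table)

    @property
    def n_pairs(self) -> int:
        return self.present.size

    def evaluate(self, t: float) -> np.ndarray:
        """Noiseless upper-triangle edge weights at gestational age t."""
        s = 1.0 / (1.0 + np.exp(-self.k * (t - self.t0)))
        rising = self.b + self.L * s
        falling = self.b + self.L * (1.0 - s)
        w = np.where(self.sign >= 0, rising, falling)
        return np.where(self.present, w, 0.0)

    def evaluate_matrix(self, t: float) -> np.ndarray:
        d = self.n_nodes
        iu = np.triu_indices(d, k=1)
        w = np.zeros((d, d))
        w[iu] = self.evaluate(t)
        return w + w.T


def scaled_field_params(d: int) -> GrowthFieldParams:
    """Planted-trend counts scaled to graph size.

    The full-size field (88 nodes, 3828 pairs) plants 162 increasing and
    12 decreasing edges; smaller graphs get counts proportional to their
    number of node pairs, floored so a trend analysis stays meaningful.
    """
    pairs = d * (d - 1) // 2
    frac = pairs / (88 * 87 // 2)
    return GrowthFieldParams(
        n_increasing=max(4, round(162 * frac)),
        n_decreasing=max(1, round(12 * frac)),
    )


def make_node_table(d: int = 88, seed: int = 0) -> NodeTable:
    """Bilateral node table: d/2 mirrored centroids per hemisphere.

    Centroids lie on a Fibonacci spiral over a brain-sized half-ellipsoid
    (x lateral, y anterior-posterior, z inferior-superior, mm); lobes are
    contiguous angular sectors in the sagittal (y, z) plane.
    """
    if d < 4 or d % 2:
        raise ValueError("d must be an even integer >= 4")
    half = d // 2
    rng = np.random.default_rng(seed)
    i = np.arange(half)
    golden = (1 + 5**0.5) / 2
    theta = 2 * np.pi * i / golden  # azimuth in the sagittal plane
    u = (i + 0.5) / half  # controls laterality
    x = 15.0 + 45.0 * u  # right hemisphere: x in [15, 60]
    r = 65.0 * np.sqrt(np.clip(1 - u**2, 0.05, 1.0))
    y = r * np.cos(theta)
    z = 0.7 * r * np.sin(theta) + 10.0
    # small deterministic jitter keeps centroids distinct and irregular
    jitter = rng.normal(scale=1.5, size=(half, 3))
    xyz_r = np.column_stack([x, y, z]) + jitter
    ang = np.mod(np.arctan2(xyz_r[:, 2] - 10.0, xyz_r[:, 1]), 2 * np.pi)
    sector = np.floor(ang / (2 * np.pi) * len(LOBES)).astype(int)
    lobes = [LOBES[s] for s in sector]
    rows = []
    for h, sgn in (("right", 1.0), ("left", -1.0)):
        for n in range(half):
            cx, cy, cz = sgn * xyz_r[n, 0], xyz_r[n, 1], xyz_r[n, 2]
            rows.append(
                (f"{h[0].upper()}{n + 1:03d}", f"{lobes[n]}_{h}_{n + 1}",
                 h, lobes[n], cx, cy, cz)
            )
    return NodeTable(pd.DataFrame(
        rows,
        columns=["node_id", "label", "hemisphere", "lobe", "x_mm", "y_mm", "z_mm"],
    ))


def _pair_index(d: int):
    return np.triu_indices(d, k=1)


def sample_growth_field(
    nt: NodeTable,
    params: GrowthFieldParams | None = None,
    seed: int = 0,
) -> GrowthField:
    """Draw per-edge presence and sigmoid growth parameters."""
    params = params or GrowthFieldParams()
    rng = np.random.default_rng(seed)
    d = len(nt)
    iu = _pair_index(d)
    D = node_distances(nt)
    dists = D[iu]
    n_pairs = dists.size

    prob = params.presence_scale * np.exp(-dists / params.distance_decay_mm)
    present = rng.random(n_pairs) < prob
    # nearest-neighbor backbone guarantees a connected graph
    flat = np.zeros((d, d), dtype=bool)
    flat[iu] = present
    order = np.argsort(D + np.where(np.eye(d, dtype=bool), np.inf, 0.0), axis=1)
    for i in range(d):
        j = order[i, 0]
        flat[min(i, j), max(i, j)] = True
    present = flat[iu]

    present_idx = np.flatnonzero(present)
    hemi = np.array(nt.hemispheres)
    inter = hemi[iu[0]] != hemi[iu[1]]
    both_left = (hemi[iu[0]] == "left") & (hemi[iu[1]] == "left")

    n_dec = min(params.n_decreasing, present_idx.size)
    inter_present = present_idx[inter[present_idx]]
    pool_dec = inter_present if inter_present.size >= n_dec else present_idx
    dec_idx = rng.choice(pool_dec, size=n_dec, replace=False)
    remaining = np.setdiff1d(present_idx, dec_idx)
    n_inc = min(params.n_increasing, remaining.size)
    if n_inc < params.n_increasing or n_dec < params.n_decreasing:
        raise ValueError("infeasible planted edge counts for this graph size")
    inc_idx = rng.choice(remaining, size=n_inc, replace=False)

    sign = np.zeros(n_pairs, dtype=int)
    sign[inc_idx] = 1
    sign[dec_idx] = -1

    b = rng.uniform(*params.baseline_range, size=n_pairs)
    L = np.where(sign != 0, rng.uniform(*params.amplitude_range, size=n_pairs), 0.0)
    k = rng.uniform(*params.rate_range, size=n_pairs)
    t0 = np.clip(
        rng.normal(params.t0_mean, params.t0_sd, size=n_pairs), *params.t0_window
    )
    t0 = t0 + np.where(both_left, params.left_t0_offset, 0.0)
    return GrowthField(nt, present, b, L, k, t0, sign, params)


def generate_cohort(
    field: GrowthField,
    n: int = 198,
    age_range: tuple[float, float] = (22.0, 37.0),
    noise: NoiseModel | None = None,
    seed: int = 0,
    subject_prefix: str = "S",
) -> Cohort:
    """Sample n subjects with uniform ages and seeded subject-level noise.

    w_ij = max(0, f_ij(t) * exp(eps_subj_edge) * exp(eps_meas) * s_subj + eps_add).
    """
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)
    ages = np.sort(rng.uniform(*age_range, size=n))
    d = field.n_nodes
    iu = _pair_index(d)
    subjects = []
    for idx, t in enumerate(ages):
        truth = field.evaluate(float(t))
        s_subj = float(np.exp(rng.normal(0.0, noise.subject_effect_sd)))
        edge_dev = np.exp(rng.normal(0.0, noise.subject_edge_sd, size=truth.size))
        mult = np.exp(rng.normal(0.0, noise.multiplicative_sd, size=truth.size))
        add = rng.normal(0.0, noise.additive_sd, size=truth.size)
        w_flat = np.clip(truth * edge_dev * mult * s_subj + add, 0.0, None)
        w = np.zeros((d, d))
        w[iu] = w_flat
        subjects.append(Connectome(
            w + w.T, field.node_table.node_ids,
            age_weeks=float(t), subject_id=f"{subject_prefix}{idx + 1:03d}",
        ))
    return Cohort(subjects, node_table=field.node_table, age_range=age_range)


def ground_truth_templates(field: GrowthField, weeks) -> TemplateSet:
    """Noiseless field evaluated at integer weeks (recovery oracle)."""
    weeks = list(weeks)
    T = np.array([field.evaluate(float(t)) for t in weeks])
    return _flat_to_templates(T, weeks, field.node_table.node_ids)


def generate_split_half(
    field: GrowthField,
    n: int = 198,
    age_range: tuple[float, float] = (22.0, 37.0),
    noise: NoiseModel | None = None,
    seed: int = 0,
) -> tuple[Cohort, Cohort]:
    """Two cohorts sharing subject-level truths with independent noise draws.

    Emulates connectomes reconstructed from two mutually exclusive subsets
    of each subject's measurements: the per-subject truth (age, scalar
    effect, stable edge-level deviation) is shared between the halves,
    while the measurement noise is drawn independently per half.
    """
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)
    ages = np.sort(rng.uniform(*age_range, size=n))
    d = field.n_nodes
    iu = _pair_index(d)
    halves: tuple[list, list] = ([], [])
    for idx, t in enumerate(ages):
        base = field.evaluate(float(t))
        s_subj = float(np.exp(rng.normal(0.0, noise.subject_effect_sd)))
        edge_dev = np.exp(rng.normal(0.0, noise.subject_edge_sd, size=base.size))
        truth = base * edge_dev * s_subj
        for half in halves:
            mult = np.exp(rng.normal(0.0, noise.multiplicative_sd, size=truth.size))
            add = rng.normal(0.0, noise.additive_sd, size=truth.size)
            w_flat = np.clip(truth * mult + add, 0.0, None)
            w = np.zeros((d, d))
            w[iu] = w_flat
            half.append(Connectome(
                w + w.T, field.node_table.node_ids,
                age_weeks=float(t), subject_id=f"S{idx + 1:03d}",
            ))
    nt = field.node_table
    return (
        Cohort(halves[0], node_table=nt, age_range=age_range),
        Cohort(halves[1], node_table=nt, age_range=age_range),
    )


def default_study(
    seed: int = 0,
    d: int = 30,
    n: int = 60,
    weeks=range(22, 38),
    n_increasing: int = 40,
    n_decreasing: int = 6,
    noise: NoiseModel | None = None,
) -> tuple[GrowthField, Cohort, TemplateSet]:
    """Desk-scale default study: (growth field, cohort, truth templates).

    The defaults (30 nodes, 60 subjects, 16 weeks, 40/6 planted trending
    edges) scale the full study dimensions (88 nodes, 198 subjects, 162/12
    trending edges) down to a size every analysis can run on in seconds
    while keeping the same statistical structure.
    """
    params = GrowthFieldParams(
        n_increasing=n_increasing, n_decreasing=n_decreasing
    )
    nt = make_node_table(d=d, seed=seed)
    field = sample_growth_field(nt, params, seed=seed + 1)
    cohort = generate_cohort(field, n=n, noise=noise, seed=seed + 2)
    truth = ground_truth_templates(field, weeks)
    return field, cohort, truth


def sigmoid_node_samples(
    n: int = 198,
    b: float = 10.0,
    L: float = 40.0,
    k: float = 1.2,
    t0: float = 28.6,
    noise_sd: float = 3.0,
    age_range: tuple[float, float] = (22.0, 37.0),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """(ages, values) for one noisy sigmoid nodal-strength trajectory."""
    rng = np.random.default_rng(seed)
    ages = np.sort(rng.uniform(*age_range, size=n))
    values = b + L / (1.0 + np.exp(-k * (ages - t0))) + rng.normal(
        0.0, noise_sd, size=n
    )
    return ages, values
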