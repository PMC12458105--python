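"""Developmental-trajectory statistics for connectome strength data.

Fits linear and sigmoid growth models of connectivity strength against
gestational age.  The sigmoid model is

    f(t) = b + L / (1 + exp(-k (t - t0)))

with baseline ``b``, amplitude ``L``, rate ``k`` (1/week) and inflection
point ``t0`` (weeks), the age of fastest increase; the slope at the
inflection is L*k/4.  Robustness machinery follows the resampling designs
used for cohort studies at this scale: bootstrapped sigmoid ensembles
(75% subsamples without replacement), Bonferroni screening across
regions, and edge-wise trend retention across repeated subsampled
regressions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

import statsmodels.api as sm

from .io import Cohort

__all__ = [
    "LinearFit",
    "SigmoidFit",
    "BootstrapEnsemble",
    "fit_linear",
    "bonferroni_screen",
    "sigmoid",
    "fit_sigmoid",
    "bootstrap_sigmoid",
    "edge_trend_resampling",
    "compare_hemispheres",
    "SigmoidGrowth",
    "SigmoidGrowthResults",
]


@dataclass
class LinearFit:
    slope: float
    intercept: float
    p_slope: float
    adj_r2: float

    def predict(self, t: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(t, dtype=float)


@dataclass
class SigmoidFit:
    b: float
    L: float
    k: float
    t0: float
    adj_r2: float
    converged: bool

    @property
    def slope_at_t0(self) -> float:
        return self.L * self.k / 4.0

    def predict(self, t: np.ndarray) -> np.ndarray:
        return sigmoid(np.asarray(t, dtype=float), self.b, self.L, self.k, self.t0)


@dataclass
class BootstrapEnsemble:
    fits: list[SigmoidFit] = field(repr=False)
    n_boot: int = 1000
    subsample_fraction: float = 0.75
    seed: int = 0
    n_nonconverged: int = 0
    age_grid: np.ndarray = field(default=None, repr=False)
    mean_curve: np.ndarray = field(default=None, repr=False)
    band_lower: np.ndarray = field(default=None, repr=False)
    band_upper: np.ndarray = field(default=None, repr=False)
    t0_mean: float = float("nan")
    t0_sd: float = float("nan")
    low_convergence: bool = False


def fit_linear(ages: np.ndarray, values: np.ndarray) -> LinearFit:
    """OLS of value on age: slope, intercept, two-sided slope p, adjusted R2."""
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    if ages.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(ages) == 0:
        raise ValueError("constant ages: slope is not identifiable")
    if np.ptp(values) == 0:
        return LinearFit(slope=0.0, intercept=float(values[0]), p_slope=1.0,
                         adj_r2=0.0)
    X = sm.add_constant(ages)
    res = sm.OLS(values, X).fit()
    return LinearFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        p_slope=float(res.pvalues[1]),
        adj_r2=float(res.rsquared_adj),
    )


def bonferroni_screen(p_values: np.ndarray, alpha: float = 0.01) -> np.ndarray:
    """Significance flags at the Bonferroni-corrected threshold alpha/m."""
    p = np.asarray(p_values, dtype=float)
    if p.size < 1:
        raise ValueError("empty p-value vector")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values outside [0, 1]")
    return p < alpha / p.size


def sigmoid(t, b, L, k, t0):
    return b + L / (1.0 + np.exp(-k * (t - t0)))


def _sigmoid_jac(theta, t, y):
    b, L, k, t0 = theta
    e = np.exp(-k * (t - t0))
    s = 1.0 / (1.0 + e)
    ds = s * (1 - s)
    J = np.empty((t.size, 4))
    J[:, 0] = 1.0
    J[:, 1] = s
    J[:, 2] = L * (t - t0) * ds
    J[:, 3] = -L * k * ds
    return J


def fit_sigmoid(ages: np.ndarray, values: np.ndarray) -> SigmoidFit:
    """Least-squares sigmoid fit with deterministic initialization.

    Initialization: b0 = min(values), L0 = range(values), k0 = 1, t0_0 =
    age of the value closest to midrange.  Bounds: L >= 0, k in
    [0.01, 10], t0 within the observed age range +/- 2 weeks.  Optimizer
    failure is reported via ``converged=False``, never an exception.
    """
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    if ages.size < 5:
        raise ValueError("need at least 5 observations for a 4-parameter fit")
    n = ages.size
    b0 = float(values.min())
    L0 = float(np.ptp(values)) or 1e-6
    mid = b0 + L0 / 2.0
    t00 = float(ages[np.argmin(np.abs(values - mid))])
    lo = [-np.inf, 0.0, 0.01, float(ages.min() - 2.0)]
    hi = [np.inf, np.inf, 10.0, float(ages.max() + 2.0)]
    x0 = np.clip([b0, L0, 1.0, t00], lo, hi)
    try:
        res = least_squares(
            lambda th: sigmoid(ages, *th) - values,
            x0=x0, jac=lambda th: _sigmoid_jac(th, ages, values),
            bounds=(lo, hi), method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14,
            max_nfev=2000,
        )
        params = res.x
        converged = bool(res.success)
    except Exception:
        params, converged = x0, False
    resid = sigmoid(ages, *params) - values
    ss_res = float(resid @ resid)
    ss_tot = float(((values - values.mean()) ** 2).sum())
    if ss_tot == 0:
        adj_r2 = 1.0 if ss_res == 0 else -np.inf
    else:
        r2 = 1.0 - ss_res / ss_tot
        adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - 4 - 1) if n > 5 else r2
    return SigmoidFit(*map(float, params), adj_r2=float(adj_r2), converged=converged)


def bootstrap_sigmoid(
    ages: np.ndarray,
    values: np.ndarray,
    n_boot: int = 1000,
    frac: float = 0.75,
    seed: int = 0,
    grid_size: int = 100,
) -> BootstrapEnsemble:
    """Sigmoid ensemble over seeded 75% subsamples without replacement.

    Returns per-fit parameters, the mean fitted curve with +/- 2 SD bands
    on a uniform age grid, and inflection-point summary statistics over
    the converged fits.  Fewer than 50% converged fits sets
    ``low_convergence`` and emits a warning.
    """
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    m = int(np.floor(frac * ages.size))
    if m < 5:
        raise ValueError("subsample too small for a sigmoid fit")
    rng = np.random.default_rng(seed)
    fits = []
    grid = np.linspace(ages.min(), ages.max(), grid_size)
    curves = np.empty((n_boot, grid_size))
    for rep in range(n_boot):
        idx = rng.choice(ages.size, size=m, replace=False)
        fit = fit_sigmoid(ages[idx], values[idx])
        fits.append(fit)
        curves[rep] = fit.predict(grid)
    conv = np.array([f.converged for f in fits])
    n_bad = int((~conv).sum())
    low = n_bad > n_boot // 2
    if low:
        warnings.warn(
            f"only {n_boot - n_bad}/{n_boot} bootstrap fits converged",
            RuntimeWarning,
        )
    use = conv if conv.any() else np.ones(n_boot, dtype=bool)
    mean_curve = curves[use].mean(axis=0)
    sd_curve = curves[use].std(axis=0, ddof=1) if use.sum() > 1 else np.zeros(grid_size)
    t0s = np.array([f.t0 for f, c in zip(fits, use) if c])
    return BootstrapEnsemble(
        fits=fits, n_boot=n_boot, subsample_fraction=frac, seed=seed,
        n_nonconverged=n_bad, age_grid=grid, mean_curve=mean_curve,
        band_lower=mean_curve - 2 * sd_curve, band_upper=mean_curve + 2 * sd_curve,
        t0_mean=float(t0s.mean()), t0_sd=float(t0s.std(ddof=1)) if t0s.size > 1 else 0.0,
        low_convergence=low,
    )


def _vectorized_slope_pvalues(
    ages: np.ndarray, V: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(slopes, two-sided p) of OLS per column of V regressed on ages."""
    n = ages.size
    x = ages - ages.mean()
    sxx = float(x @ x)
    slopes = (x @ V) / sxx
    intercepts = V.mean(axis=0)
    resid = V - intercepts[None, :] - np.outer(ages - ages.mean(), slopes)
    dof = n - 2
    s2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(s2 / sxx)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, slopes / np.where(se > 0, se, 1.0), np.inf * np.sign(slopes))
    p = 2.0 * stats.t.sf(np.abs(tstat), dof)
    return slopes, p


def edge_trend_resampling(
    cohort: Cohort,
    n_reps: int = 100,
    frac: float = 0.75,
    alpha: float = 0.01,
    retain_pct: float = 95.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Edge-wise trend retention across repeated subsampled regressions.

    For each repetition, 75% of subjects are drawn without replacement and
    every edge is tested for a significant linear age association
    (two-sided, level ``alpha``; 0.01 by default, matching the level used
    for the nodal regressions -- at 0.05 the correlated subsamples retain
    chance edges at about 2 per 1000).  An edge is retained as increasing
    (decreasing) when it is significantly positive (negative) in at least
    ``retain_pct`` percent of repetitions.

    Returns a DataFrame with one row per node pair: node_i, node_j,
    pct_significant_up, pct_significant_down, retained_up, retained_down.
    """
    ages = cohort.ages
    V = cohort.edge_matrix()  # (n_subjects, n_pairs)
    n, n_pairs = V.shape
    m = int(np.floor(frac * n))
    if m < 3:
        raise ValueError("cohort too small for subsampled regression")
    rng = np.random.default_rng(seed)
    up = np.zeros(n_pairs, dtype=int)
    down = np.zeros(n_pairs, dtype=int)
    for _ in range(n_reps):
        idx = rng.choice(n, size=m, replace=False)
        slopes, p = _vectorized_slope_pvalues(ages[idx], V[idx])
        sig = p < alpha
        up += sig & (slopes > 0)
        down += sig & (slopes < 0)
    pct_up = 100.0 * up / n_reps
    pct_down = 100.0 * down / n_reps
    d = cohort.n_nodes
    iu = np.triu_indices(d, k=1)
    ids = cohort.node_ids
    return pd.DataFrame({
        "node_i": [ids[i] for i in iu[0]],
        "node_j": [ids[j] for j in iu[1]],
        "pct_significant_up": pct_up,
        "pct_significant_down": pct_down,
        "retained_up": pct_up >= retain_pct,
        "retained_down": pct_down >= retain_pct,
    })


def _paired_t(a: np.ndarray, b: np.ndarray) -> dict:
    diff = a - b
    if np.allclose(diff, 0.0):
        return {"t": 0.0, "p": 1.0, "degenerate": False,
                "mean_diff": 0.0, "sd_diff": 0.0}
    sd = diff.std(ddof=1)
    if sd == 0:
        # constant nonzero difference: the paired t statistic is unbounded
        return {"t": float(np.inf * np.sign(diff.mean())), "p": 0.0,
                "degenerate": True, "mean_diff": float(diff.mean()), "sd_diff": 0.0}
    t, p = stats.ttest_rel(a, b)
    return {"t": float(t), "p": float(p), "degenerate": False,
            "mean_diff": float(diff.mean()), "sd_diff": float(sd)}


def compare_hemispheres(
    fits_left: list[SigmoidFit], fits_right: list[SigmoidFit]
) -> pd.DataFrame:
    """Paired tests of growth timing and rate between homologous node pairs.

    Rows: t0 (inflection age), slope_at_t0 (= L*k/4) and inv_k (= 1/k, the
    rate parameter's inverse, reported separately so either reading of
    "growth rate" is recoverable).  Columns include per-hemisphere mean/SD
    and the paired t statistic and p-value.
    """
    if len(fits_left) != len(fits_right):
        raise ValueError("paired fit lists must have equal length")
    rows = []
    for name, get in (
        ("t0", lambda f: f.t0),
        ("slope_at_t0", lambda f: f.slope_at_t0),
        ("inv_k", lambda f: 1.0 / f.k),
    ):
        a = np.array([get(f) for f in fits_left])
        b = np.array([get(f) for f in fits_right])
        r = _paired_t(a, b)
        rows.append({
            "quantity": name,
            "left_mean": float(a.mean()), "left_sd": float(a.std(ddof=1)),
            "right_mean": float(b.mean()), "right_sd": float(b.std(ddof=1)),
            "t": r["t"], "p": r["p"], "degenerate": r["degenerate"],
        })
    return pd.DataFrame(rows).set_index("quantity")


# ---------------------------------------------------------------------------
# model / results interface


class SigmoidGrowth:
    """Sigmoid growth model of a strength trajectory against age.

    Examples
    --------
    >>> model = SigmoidGrowth(ages, nodal_strength_values)
    >>> res = model.fit()
    >>> res.params.t0          # inflection age, weeks
    >>> ens = res.bootstrap(n_boot=1000, seed=7)
    >>> print(res.summary())
    """

    def __init__(self, ages: np.ndarray, values: np.ndarray):
        self.ages = np.asarray(ages, dtype=float)
        self.values = np.asarray(values, dtype=float)
        if self.ages.shape != self.values.shape:
            raise ValueError("ages and values must have equal length")

    def fit(self) -> "SigmoidGrowthResults":
        return SigmoidGrowthResults(self, fit_sigmoid(self.ages, self.values))


class SigmoidGrowthResults:
    def __init__(self, model: SigmoidGrowth, params: SigmoidFit):
        self.model = model
        self.params = params

    @property
    def linear_fit(self) -> LinearFit:
        return fit_linear(self.model.ages, self.model.values)

    def bootstrap(
        self, n_boot: int = 1000, frac: float = 0.75, seed: int = 0
    ) -> BootstrapEnsemble:
        return bootstrap_sigmoid(
            self.model.ages, self.model.values, n_boot=n_boot, frac=frac, seed=seed
        )

    def summary(self) -> str:
        p = self.params
        lin = self.linear_fit
        return "\n".join([
            "Sigmoid growth fit  f(t) = b + L / (1 + exp(-k (t - t0)))",
            "=" * 58,
            f"n observations:   {self.model.ages.size}",
            f"b  (baseline):    {p.b:.4f}",
            f"L  (amplitude):   {p.L:.4f}",
            f"k  (rate, 1/wk):  {p.k:.4f}",
            f"t0 (inflection):  {p.t0:.4f} weeks",
            f"slope at t0:      {p.slope_at_t0:.4f} per week",
            f"adj. R2 sigmoid:  {p.adj_r2:.4f}",
            f"adj. R2 linear:   {lin.adj_r2:.4f}",
            f"converged:        {p.converged}",
        ])

    def plot(self, ax=None, ensemble: BootstrapEnsemble | None = None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self.model.ages, self.model.values, s=8, color="k", alpha=0.5)
        grid = np.linspace(self.model.ages.min(), self.model.ages.max(), 200)
        ax.plot(grid, self.params.predict(grid), color="C3", label="sigmoid fit")
        if ensemble is not None:
            ax.plot(ensemble.age_grid, ensemble.mean_curve, color="C0",
                    label="bootstrap mean")
            ax.fill_between(ensemble.age_grid, ensemble.band_lower,
                            ensemble.band_upper, color="C0", alpha=0.2,
                            label="+/- 2 SD")
        ax.set_xlabel("gestational age (weeks)")
        ax.set_ylabel("strength")
        ax.legend()
        return ax
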