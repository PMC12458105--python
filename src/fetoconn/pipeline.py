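"""End-to-end pipeline orchestration and run configuration.

A single :class:`RunConfig` carries every stage's parameters plus one
global seed; per-stage seeds are derived deterministically from the
global seed (``seed + fixed per-stage offset``, documented below) so each
stage is independently reproducible.  Every run writes the resolved
configuration and a provenance record next to its outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .io import load_cohort, node_distances, write_cohort, write_connectome
from .metrics import NullModelConfig, compute_metrics
from .prediction import evaluate_age_prediction
from .reproducibility import split_half_ged
from .growth import bootstrap_sigmoid, edge_trend_resampling, fit_linear
from .metrics import nodal_strength
from .synthetic import (
    GrowthFieldParams,
    NoiseModel,
    generate_cohort,
    generate_split_half,
    make_node_table,
    sample_growth_field,
)
from .templates import ConnectomeTemplateModel

log = logging.getLogger("fetoconn")

#: fixed per-stage seed offsets (derived seed = global seed + offset)
STAGE_SEEDS = {
    "synth": 11,
    "templates": 23,
    "metrics": 31,
    "trajectories": 41,
    "edge_trends": 53,
    "predict_age": 61,
    "split_half": 71,
}

ALL_STAGES = (
    "synth", "templates", "metrics", "trajectories",
    "edge_trends", "predict_age", "split_half",
)


@dataclass
class RunConfig:
    """All pipeline parameters plus the global seed and output directory."""

    out_dir: str = "fetoconn_run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    # synthesis
    d: int = 88
    n_subjects: int = 198
    age_min: float = 22.0
    age_max: float = 37.0
    n_increasing: int = 162
    n_decreasing: int = 12
    multiplicative_sd: float = 0.13
    additive_sd: float = 0.05
    subject_effect_sd: float = 0.10
    subject_edge_sd: float = 0.15
    # manifest inputs (used instead of synthesis when given)
    manifest: str | None = None
    node_table: str | None = None
    # kernel / template loss
    sigma: float = 1.0
    week_min: int = 22
    week_max: int = 37
    lambda_cons: float = 1.0
    lambda_dist: float = 1.0
    n_bins: int = 20
    learning_rate: float = 1e-5
    n_epochs: int = 200
    convergence_tol: float = 1e-6
    # metrics nulls
    n_nulls: int = 100
    rewiring_iterations_per_edge: int = 10
    # bootstrap / resampling
    n_boot: int = 1000
    boot_frac: float = 0.75
    n_reps: int = 100
    rep_frac: float = 0.75
    rep_alpha: float = 0.01
    retain_pct: float = 95.0
    # classifier
    folds: int = 10

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["stages"] = list(self.stages)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    def stage_seed(self, stage: str) -> int:
        return int(self.seed) + STAGE_SEEDS[stage]


def _provenance(cfg: RunConfig, stage: str, inputs: dict) -> dict:
    return {
        "stage": stage,
        "fetoconn_version": __version__,
        "seed": cfg.stage_seed(stage),
        "inputs": inputs,
    }


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, default=float) + "\n")


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the requested stages in dependency order.

    Returns the run directory.  No stage mutates its inputs; rerunning
    with an identical config and seed reproduces identical outputs.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    weeks = list(range(cfg.week_min, cfg.week_max + 1))

    cohort, split_pair = _get_cohort(cfg, out)
    D = node_distances(cohort.node_table)
    templates = None

    for stage in cfg.stages:
        if stage == "synth":
            continue  # handled by _get_cohort
        log.info("stage %s", stage)
        sdir = out / stage
        sdir.mkdir(exist_ok=True)
        seed = cfg.stage_seed(stage)
        if stage == "templates":
            model = ConnectomeTemplateModel(cohort, weeks, D, sigma=cfg.sigma)
            res = model.fit(
                method="aggregate", lambda_cons=cfg.lambda_cons,
                lambda_dist=cfg.lambda_dist, n_bins=cfg.n_bins,
                learning_rate=cfg.learning_rate, n_epochs=cfg.n_epochs,
                convergence_tol=cfg.convergence_tol, seed=seed,
            )
            templates = res.templates
            for w, t in templates:
                write_connectome(t, sdir / f"template_week{w:02d}.csv")
            res.loss_trace.to_csv(sdir / "loss_trace.csv", index=False)
            _write_json(sdir / "provenance.json", _provenance(cfg, stage, {
                "n_subjects": len(cohort), "weeks": weeks,
            }))
        elif stage == "metrics":
            null = NullModelConfig(
                n_nulls=cfg.n_nulls,
                rewiring_iterations_per_edge=cfg.rewiring_iterations_per_edge,
                seed=seed,
            )
            reports = {
                s.subject_id: compute_metrics(s, null).to_dict() for s in cohort
            }
            _write_json(sdir / "metrics.json", reports)
            _write_json(sdir / "provenance.json", _provenance(cfg, stage, {
                "n_subjects": len(cohort),
            }))
        elif stage == "trajectories":
            ages = cohort.ages
            strengths = np.array([nodal_strength(s) for s in cohort])
            rows = {}
            for i, nid in enumerate(cohort.node_ids):
                lin = fit_linear(ages, strengths[:, i])
                ens = bootstrap_sigmoid(
                    ages, strengths[:, i], n_boot=cfg.n_boot,
                    frac=cfg.boot_frac, seed=seed + i,
                )
                rows[nid] = {
                    "slope": lin.slope, "p_slope": lin.p_slope,
                    "adj_r2_linear": lin.adj_r2,
                    "t0_mean": ens.t0_mean, "t0_sd": ens.t0_sd,
                    "n_nonconverged": ens.n_nonconverged,
                }
            _write_json(sdir / "trajectories.json", rows)
            _write_json(sdir / "provenance.json", _provenance(cfg, stage, {
                "n_boot": cfg.n_boot, "frac": cfg.boot_frac,
            }))
        elif stage == "edge_trends":
            df = edge_trend_resampling(
                cohort, n_reps=cfg.n_reps, frac=cfg.rep_frac,
                alpha=cfg.rep_alpha, retain_pct=cfg.retain_pct, seed=seed,
            )
            df.to_csv(sdir / "edge_trends.tsv", sep="\t", index=False)
            _write_json(sdir / "provenance.json", _provenance(cfg, stage, {
                "n_reps": cfg.n_reps, "frac": cfg.rep_frac,
            }))
        elif stage == "predict_age":
            if templates is None:
                raise RuntimeError(
                    "predict_age requires the templates stage in this run"
                )
            mean, sd, table = evaluate_age_prediction(cohort, templates)
            table.to_csv(sdir / "ged_nn_predictions.tsv", sep="\t", index=False)
            _write_json(sdir / "summary.json", {
                "ged_nn_mean_abs_error": mean, "ged_nn_sd_abs_error": sd,
            })
            _write_json(sdir / "provenance.json", _provenance(cfg, stage, {
                "method": "ged-nn",
            }))
        elif stage == "split_half":
            if split_pair is None:
                raise RuntimeError(
                    "split_half requires synthetic data (synth stage)"
                )
            half_a, half_b = split_pair
            rep = split_half_ged(half_a, half_b)
            _write_json(sdir / "split_half.json", {
                "intra_mean": rep.intra_mean, "intra_sd": rep.intra_sd,
                "inter_mean": rep.inter_mean, "inter_sd": rep.inter_sd,
                "welch_t": rep.welch_t, "welch_p": rep.welch_p,
                "fingerprint_rate": rep.fingerprint_rate,
            })
            _write_json(sdir / "provenance.json", _provenance(cfg, stage, {
                "n_subjects": len(half_a),
            }))
        else:
            raise ValueError(f"unknown stage {stage!r}")

    return out


def _get_cohort(cfg: RunConfig, out: Path):
    if cfg.manifest is not None:
        cohort = load_cohort(
            cfg.manifest, cfg.node_table, age_range=(cfg.age_min, cfg.age_max)
        )
        return cohort, None
    sdir = out / "synth"
    sdir.mkdir(exist_ok=True)
    seed = cfg.stage_seed("synth")
    params = GrowthFieldParams(
        n_increasing=cfg.n_increasing, n_decreasing=cfg.n_decreasing
    )
    noise = NoiseModel(
        multiplicative_sd=cfg.multiplicative_sd,
        additive_sd=cfg.additive_sd,
        subject_effect_sd=cfg.subject_effect_sd,
        subject_edge_sd=cfg.subject_edge_sd,
    )
    nt = make_node_table(d=cfg.d, seed=seed)
    fld = sample_growth_field(nt, params, seed=seed + 1)
    cohort = generate_cohort(
        fld, n=cfg.n_subjects, age_range=(cfg.age_min, cfg.age_max),
        noise=noise, seed=seed + 2,
    )
    write_cohort(cohort, sdir)
    _write_json(sdir / "ground_truth.json", {
        "present": fld.present.tolist(), "b": fld.b.tolist(),
        "L": fld.L.tolist(), "k": fld.k.tolist(), "t0": fld.t0.tolist(),
        "sign": fld.sign.tolist(),
    })
    _write_json(sdir / "provenance.json", _provenance(cfg, "synth", {
        "d": cfg.d, "n": cfg.n_subjects,
    }))
    split_pair = None
    if "split_half" in cfg.stages:
        split_pair = generate_split_half(
            fld, n=cfg.n_subjects, age_range=(cfg.age_min, cfg.age_max),
            noise=noise, seed=seed + 3,
        )
    return cohort, split_pair
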