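"""Reproducible end-to-end runs: simulate -> PSM -> sweep -> report.

A run is driven by one :class:`RunConfig` (loadable from YAML or JSON); every
stochastic stage derives its RNG stream from (global seed, stage name), so
re-running the same config reproduces every artifact byte-for-byte. Artifacts
are written under the configured output directory together with a config
snapshot, package/library versions and a structured log.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._rng import stage_seed
from .cohort import CohortTable, read_cohort, write_cohort
from .csrf import CSRFConfig
from .evaluation import (ALL_DATA, PSMConfig, SweepGrid, SweepResult, best_vs_all,
                         compute_fold_psm, make_folds, run_sweep)
from .schema import make_table1_schema
from .simulate import SimulationConfig, simulate_cohort

__all__ = ["RunConfig", "run_pipeline", "default_grid"]

log = logging.getLogger(__name__)

#: the reference grid geometry, defined at a training-fold size of ~15,500;
#: default_grid rescales it proportionally to the actual training-fold size
_REFERENCE_GRIDS = {
    "DC": (10, 15000, 10),
    "LR": (4000, 15000, 1000),
    "RF": (4000, 15000, 1000),
    "DT": (5000, 15000, 1000),
}
_REFERENCE_N_TRAIN = 15500


def default_grid(family: str, n_train: int) -> SweepGrid:
    """Scale the family's reference M-range proportionally to ``n_train``."""
    family = family.upper()
    if family == "CSRF":
        return SweepGrid("CSRF", ())
    lo, _, step = _REFERENCE_GRIDS[family]
    f = n_train / _REFERENCE_N_TRAIN
    raw_step = step * f
    if raw_step < 100:
        step_s = max(int(round(raw_step / 10.0)) * 10, 10)
    else:
        step_s = max(int(round(raw_step / 100.0)) * 100, 100)
    lo_s = max(int(np.floor(lo * f / step_s)) * step_s, step_s)
    values = tuple(range(lo_s, n_train + 1, step_s))
    if not values:
        raise ValueError(f"no feasible M grid for {family} at n_train={n_train}")
    return SweepGrid(family, values)


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "psmforest_run"
    cohort_path: str | None = None          # use an existing cohort instead of simulating
    simulate: dict = field(default_factory=dict)       # SimulationConfig overrides
    psm: dict = field(default_factory=dict)            # PSMConfig overrides
    families: tuple[str, ...] = ("DC", "LR", "DT", "RF", "CSRF")
    grids: dict = field(default_factory=dict)          # family -> list of M values
    folds: int = 10
    rf_trees: int = 500
    csrf_trees: int = 500
    max_test_per_fold: int | None = None
    write_plots: bool = True
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        doc = yaml.safe_load(text) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**doc)
        cfg.families = tuple(str(f).upper() for f in cfg.families)
        return cfg

    def validate(self) -> None:
        if self.cohort_path is not None and not Path(self.cohort_path).exists():
            raise FileNotFoundError(f"cohort file not found: {self.cohort_path}")
        for fam in self.families:
            if fam not in ("DC", "LR", "DT", "RF", "CSRF"):
                raise ValueError(f"unknown model family {fam!r}")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


def _versions() -> dict:
    import sklearn
    import scipy
    from . import __version__
    return {
        "psmforest": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "sklearn": sklearn.__version__,
    }


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=float))


def _plot_curves(summary: pd.DataFrame, outdir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for metric in ("auroc", "auprc"):
        fig, ax = plt.subplots(figsize=(7, 5))
        for family, grp in summary[summary["metric"] == metric].groupby("family"):
            grid = grp[grp["M"] != ALL_DATA].sort_values("M")
            if len(grid) == 0:
                continue
            ax.plot(grid["M"], grid["mean"], marker="o", ms=3, label=family)
            ax.fill_between(grid["M"], grid["lower"], grid["upper"], alpha=0.2)
        ax.set_xlabel("number of similar patients (M)")
        ax.set_ylabel(f"mean {metric.upper()} (95% CI)")
        ax.legend()
        fig.tight_layout()
        fig.savefig(outdir / f"sweep_{metric}.png", dpi=120)
        plt.close(fig)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline and return the output directory."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("psmforest")
    root.addHandler(handler)
    root.setLevel(getattr(logging, config.log_level.upper(), logging.INFO))
    try:
        _write_json(outdir / "config.json", dataclasses.asdict(config))
        _write_json(outdir / "versions.json", _versions())

        # -- stage: cohort -------------------------------------------------
        schema = make_table1_schema()
        if config.cohort_path is not None:
            cohort = read_cohort(config.cohort_path, schema)
            log.info("loaded cohort n=%d (%d rows excluded)", cohort.n, cohort.n_excluded)
        else:
            sim_cfg = SimulationConfig(
                seed=stage_seed(config.seed, "simulate"), **config.simulate
            )
            cohort, truth = simulate_cohort(sim_cfg, schema)
            write_cohort(cohort, outdir / "cohort.csv")
            _write_json(outdir / "truth.json", {
                "cluster_assignment": truth.cluster_assignment.tolist(),
                "cluster_intercepts": truth.cluster_intercepts.tolist(),
                "true_risk_mean": float(truth.true_risk.mean()),
                "prevalence": float(cohort.outcome.mean()),
            })

        # -- stage: psm ----------------------------------------------------
        psm_cfg = PSMConfig(**config.psm)
        fold_plan = make_folds(cohort.n, k=config.folds,
                               seed=stage_seed(config.seed, "folds"))
        fold_weights = compute_fold_psm(cohort, fold_plan, psm_cfg, seed=config.seed)
        _write_json(outdir / "psm_summary.json", {
            "n_trees": psm_cfg.n_trees, "mtry": psm_cfg.mtry,
            "nodesize": psm_cfg.nodesize, "scope": psm_cfg.scope,
            "folds": config.folds,
        })

        # -- stage: sweep ---------------------------------------------------
        n_train_min = cohort.n - int(np.ceil(cohort.n / config.folds))
        result: SweepResult | None = None
        for family in config.families:
            if family in config.grids:
                grid = SweepGrid(family, tuple(config.grids[family]))
            else:
                grid = default_grid(family, n_train_min)
            part = run_sweep(
                cohort, grid, psm_config=psm_cfg, fold_plan=fold_plan,
                seed=config.seed, rf_trees=config.rf_trees,
                csrf_config=CSRFConfig(n_trees=config.csrf_trees),
                max_test_per_fold=config.max_test_per_fold,
                fold_weights=fold_weights,
            )
            result = part if result is None else result.concat(part)
        result.records.to_csv(outdir / "results.csv", index=False)
        summary = result.summary()
        summary.to_csv(outdir / "summary.csv", index=False)

        comparisons = {}
        for family in config.families:
            if family == "CSRF":
                continue
            for metric in ("auroc", "auprc"):
                comparisons[f"{family}_{metric}"] = best_vs_all(result, family, metric)
        _write_json(outdir / "comparisons.json", comparisons)

        # -- stage: report --------------------------------------------------
        if config.write_plots:
            _plot_curves(summary, outdir)
        log.info("pipeline complete: %s", outdir)
        return outdir
    finally:
        root.removeHandler(handler)
        handler.close()
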