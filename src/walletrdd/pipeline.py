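"""End-to-end orchestration: data -> panel -> bandwidth -> RDD -> recovery.

A run is driven by a declarative :class:`RunConfig` (YAML-loadable), uses a
single seed for every stochastic stage, and writes a self-describing run
directory: panel summaries, a per-outcome effect table, the age-stratified
recovery table, bandwidth sensitivity scans, and a JSON log carrying the
seed and per-stage accounting counts so person-day and event totals can be
audited from the log alone.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .panel import (
    OUTCOMES,
    binarize,
    load_events,
    load_registry,
    summarize,
    validate_constraints,
)
from .rdd import PoissonRDD, sensitivity_scan
from .recovery import recovery_by_age
from .simulate import SimulationConfig, simulate_panel

__all__ = ["RunConfig", "validate_config", "run", "PipelineError"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    mode: str = "simulate"  # or "real-data"
    events_path: str | None = None
    registry_path: str | None = None
    policy_path: str | None = None
    output_dir: str = "runs/latest"
    start_date: dt.date = dt.date(2020, 1, 1)
    end_date: dt.date = dt.date(2020, 8, 27)
    cutoff_date: dt.date = dt.date(2020, 3, 23)
    bandwidth: str | int = "auto"
    sensitivity_delta: int = 20
    sensitivity_step: int = 5
    age_boundaries: tuple[int, int] = (25, 30)
    seed: int = 0
    cov_type: str = "HC0"  # HC0 | HC1 | cluster-by-user
    horizon_days: float = 999.0
    simulation: dict = field(default_factory=dict)

    @property
    def study_days(self) -> int:
        return (self.end_date - self.start_date).days + 1

    @property
    def cutoff_day(self) -> int:
        return (self.cutoff_date - self.start_date).days


_DATE_FIELDS = ("start_date", "end_date", "cutoff_date")


def validate_config(raw: dict) -> RunConfig:
    """Normalize a raw mapping: fill defaults, check calendar arithmetic,
    reject unknown keys and contradictions."""
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs = dict(raw)
    for f in _DATE_FIELDS:
        if f in kwargs and isinstance(kwargs[f], str):
            kwargs[f] = dt.date.fromisoformat(kwargs[f])
    if "age_boundaries" in kwargs:
        kwargs["age_boundaries"] = tuple(kwargs["age_boundaries"])
    cfg = RunConfig(**kwargs)
    if cfg.mode not in ("simulate", "real-data"):
        raise ValueError(f"unknown mode {cfg.mode!r}")
    if cfg.study_days <= 0:
        raise ValueError("end_date precedes start_date")
    if not (cfg.start_date <= cfg.cutoff_date <= cfg.end_date):
        raise ValueError("cutoff date outside the study period")
    if cfg.bandwidth != "auto":
        if int(cfg.bandwidth) <= 0:
            raise ValueError("negative or zero bandwidth")
        cfg.bandwidth = int(cfg.bandwidth)
        if cfg.bandwidth - cfg.sensitivity_delta < 2:
            raise ValueError(
                f"sensitivity delta {cfg.sensitivity_delta} leaves bandwidth "
                f"{cfg.bandwidth - cfg.sensitivity_delta} below the minimum of 2 days"
            )
    if cfg.cov_type not in ("HC0", "HC1", "cluster-by-user"):
        raise ValueError(f"unknown variance flavor {cfg.cov_type!r}")
    if cfg.mode == "real-data":
        for name in ("events_path", "registry_path"):
            p = getattr(cfg, name)
            if p is None or not Path(p).exists():
                raise ValueError(f"{name} missing or nonexistent in real-data mode")
    return cfg


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh) or {})


def _build_panels(cfg: RunConfig, counts: dict):
    if cfg.mode == "simulate":
        sim_raw = dict(cfg.simulation)
        sim_raw.setdefault("n_users", 3416)
        sim_raw["study_days"] = cfg.study_days
        sim_raw["cutoff_day"] = cfg.cutoff_day
        sim_raw["seed"] = cfg.seed
        sim_raw["start_date"] = cfg.start_date
        sim_cfg = SimulationConfig.from_dict(sim_raw)
        panels, truth = simulate_panel(sim_cfg)
        counts["simulated_users"] = sim_cfg.n_users
        return panels
    events = load_events(cfg.events_path, start_date=cfg.start_date,
                         study_days=cfg.study_days)
    counts["events_parsed"] = len(events)
    events, violations = validate_constraints(events)
    counts["constraint_violations"] = len(violations)
    users = load_registry(cfg.registry_path)
    counts["registry_users"] = len(users)
    return {
        outcome: binarize(events, users, study_days=cfg.study_days, outcome=outcome,
                          cutoff_day=cfg.cutoff_day, start_date=cfg.start_date)
        for outcome in OUTCOMES
    }


def run(config: RunConfig | dict) -> Path:
    """Execute the full analysis; returns the run directory."""
    cfg = config if isinstance(config, RunConfig) else validate_config(config)
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict = {}
    stage = "config"
    try:
        stage = "panel"
        panels = _build_panels(cfg, counts)
        summaries = {name: summarize(p) for name, p in panels.items()}
        counts["person_days_per_outcome"] = {
            k: s["person_days"] for k, s in summaries.items()
        }
        counts["events_per_outcome"] = {k: s["events_total"] for k, s in summaries.items()}
        _dump_json(summaries, out / "panel_summary.json")

        stage = "rdd"
        table_rows = []
        bandwidths: dict[str, int] = {}
        results = {}
        cov = "HC0" if cfg.cov_type == "cluster-by-user" else cfg.cov_type
        for name, panel in panels.items():
            model = PoissonRDD(panel, bandwidth=cfg.bandwidth)
            if cfg.bandwidth == "auto":
                model.bandwidth = model.select_bandwidth().h_opt
            res = model.fit(cov_type=cov)
            bandwidths[name] = res.bandwidth_days
            results[name] = res
            table_rows.append(res.to_dict())
        _dump_json(table_rows, out / "effects.json")
        _effects_table(table_rows).to_csv(out / "effects.csv", index=False)

        stage = "recovery"
        rec = recovery_by_age(panels, bandwidths=bandwidths,
                              horizon_days=cfg.horizon_days, cov_type=cov)
        rec.to_csv(out / "recovery.csv", index=False)

        stage = "sensitivity"
        for name, panel in panels.items():
            scan = sensitivity_scan(panel, h_opt=bandwidths[name],
                                    delta=cfg.sensitivity_delta,
                                    step=cfg.sensitivity_step, cov_type=cov)
            scan.to_csv(out / f"sensitivity_{name}.csv", index=False)

        stage = "log"
        _dump_json(
            {
                "package_version": __version__,
                "seed": cfg.seed,
                "mode": cfg.mode,
                "study_days": cfg.study_days,
                "cutoff_day": cfg.cutoff_day,
                "bandwidths": bandwidths,
                "cov_type": cfg.cov_type,
                "counts": counts,
            },
            out / "run_log.json",
        )
    except Exception as exc:
        _dump_json({"failed_stage": stage, "error": str(exc), "counts": counts},
                   out / "run_log.json")
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, str(exc)) from exc
    return out


def _effects_table(rows: list[dict]) -> pd.DataFrame:
    recs = []
    for r in rows:
        recs.append(
            {
                "outcome": r["outcome"],
                "bandwidth_days": r["bandwidth_days"],
                "irr_baseline": r["irr_baseline"]["irr"],
                "irr_baseline_ci": _ci(r["irr_baseline"]),
                "irr_jump": r["irr_jump"]["irr"],
                "irr_jump_ci": _ci(r["irr_jump"]),
                "irr_jump_p": r["irr_jump"]["p"],
                "irr_pre_trend": r["irr_pre_trend"]["irr"],
                "irr_pre_trend_ci": _ci(r["irr_pre_trend"]),
                "irr_post_trend": r["irr_post_trend"]["irr"],
                "irr_post_trend_ci": _ci(r["irr_post_trend"]),
                "p_trend_change": r["p_trend_change"],
                "percent_change_at_lockdown": r["percent_change_at_lockdown"],
            }
        )
    return pd.DataFrame(recs)


def _ci(w: dict) -> str:
    return f"{w['ci_low']:.4f}-{w['ci_high']:.4f}"


def _dump_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
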