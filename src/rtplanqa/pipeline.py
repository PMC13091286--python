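"""End-to-end orchestration: simulate/evaluate a cohort, summarize, test, report.

The report bundle mirrors clinical-audit tables: per-patient evaluation CSV
(full precision), a DVH-parameter summary and a TCP/risk summary formatted
``median (Q1–Q3)``, goal-pass percentages, route counts with the projected
workflow time savings, and the statistics report.  Every number is a pure
function of the run configuration and seed, so a rerun is bit-identical.

Evaluation reference: all metrics are computed on the reference (clinical /
simulated-truth) structures regardless of which structures fed planning —
the structure set used for planning affects only the dose.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dvh import DEFAULT_GOALS, GoalSet, PlanMetrics
from .radbio import (
    DEFAULT_RISK_REGISTRY,
    DEFAULT_TCP_PARAMS,
    ENDPOINTS,
    RiskEstimate,
    TCPParams,
)
from .synthetic import CohortData, CohortSimConfig, generate_cohort
from .workflow import (
    DEFAULT_ROUTE_TIMES,
    RISK_KEYS,
    SETUPS,
    SUMMARY_KEYS,
    CohortSummary,
    PatientEval,
    RouteTimes,
    compare_setups,
    metric_table,
    summarize_cohort,
    time_saving,
)

__all__ = [
    "RunConfig",
    "RunResult",
    "run_pipeline",
    "render_summary",
    "write_cohort_csv",
    "read_cohort_csv",
    "load_run_config",
]

log = logging.getLogger("rtplanqa")

COHORT_COLUMNS = [
    "patient_id", "setup",
    "ptv_dmean", "ptv_d98", "ptv_d2",
    "lungs_dmean", "heart_dmean", "breastcl_dmean",
    "goals_met", "tcp",
    "aer_w", "aer_wo", "aemr_cardiac_w", "aemr_cardiac_wo", "aemr_lung_w", "aemr_lung_wo",
    "route",
]


@dataclass(frozen=True)
class RunConfig:
    """Fully serializable description of one pipeline run."""

    seed: int = 0
    n_patients: int = 101
    mode: str = "dvh"  # dvh | voxel
    alpha: float = 0.05
    goals: GoalSet = DEFAULT_GOALS
    tcp_params: TCPParams = DEFAULT_TCP_PARAMS
    risk_registry: Mapping[str, object] = field(
        default_factory=lambda: dict(DEFAULT_RISK_REGISTRY)
    )
    route_times: RouteTimes = DEFAULT_ROUTE_TIMES
    sim: CohortSimConfig | None = None
    stat_metrics: tuple[str, ...] = SUMMARY_KEYS

    def resolved_sim(self) -> CohortSimConfig:
        if self.sim is not None:
            return self.sim
        return CohortSimConfig(n_patients=self.n_patients, seed=self.seed)


@dataclass
class RunResult:
    cohort: CohortData
    summary: CohortSummary
    route_counts: dict[str, int]
    dt_active_min: float
    dt_inter_h: float
    stats: dict[str, object]
    files: list[Path]


def _risk_map(m: PlanMetrics) -> dict[str, float]:
    return {k: float(r.value) for k, r in zip(RISK_KEYS, m.risks)}


def write_cohort_csv(evals: Sequence[PatientEval], path) -> None:
    """Per-patient evaluation CSV: one row per patient x setup (bit-exact)."""
    rows = []
    for p in evals:
        for s in SETUPS:
            m = p.metrics[s]
            row = {
                "patient_id": p.patient_id,
                "setup": s,
                **{k: getattr(m, k) for k in COHORT_COLUMNS[2:8]},
                "goals_met": m.goals_met,
                "tcp": m.tcp,
                **_risk_map(m),
                "route": p.route or "",
            }
            rows.append(row)
    df = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.9g")


def read_cohort_csv(path) -> list[PatientEval]:
    """Inverse of :func:`write_cohort_csv` (goal flags are not round-tripped)."""
    df = pd.read_csv(path)
    evals = []
    for pid, grp in df.groupby("patient_id", sort=False):
        metrics = {}
        route = None
        for _, row in grp.iterrows():
            risks = []
            for endpoint, (kw, kwo) in zip(
                ENDPOINTS,
                [("aer_w", "aer_wo"), ("aemr_cardiac_w", "aemr_cardiac_wo"),
                 ("aemr_lung_w", "aemr_lung_wo")],
            ):
                risks.append(RiskEstimate(endpoint, True, float(row[kw])))
                risks.append(RiskEstimate(endpoint, False, float(row[kwo])))
            metrics[row["setup"]] = PlanMetrics(
                ptv_dmean=row["ptv_dmean"], ptv_d98=row["ptv_d98"], ptv_d2=row["ptv_d2"],
                lungs_dmean=row["lungs_dmean"], heart_dmean=row["heart_dmean"],
                breastcl_dmean=row["breastcl_dmean"],
                goals_met=int(row["goals_met"]), tcp=float(row["tcp"]),
                risks=tuple(risks),
            )
            if isinstance(row["route"], str) and row["route"]:
                route = row["route"]
        evals.append(PatientEval(patient_id=str(pid), metrics=metrics, route=route))
    return evals


_METRIC_LABELS = {
    "ptv_dmean": "PTVp-Skin05 - Dmean [Gy]",
    "ptv_d98": "PTVp-Skin05 - D98 [Gy]",
    "ptv_d2": "PTVp-Skin05 - D2 [Gy]",
    "lungs_dmean": "Lungs - Dmean [Gy]",
    "heart_dmean": "Heart - Dmean [Gy]",
    "breastcl_dmean": "Breast CL - Dmean [Gy]",
    "tcp": "TCP [%]",
    "aer_w": "AER acute coronary events, with RF [%]",
    "aer_wo": "AER acute coronary events, without RF [%]",
    "aemr_cardiac_w": "AEMR cardiac disease, with RF [%]",
    "aemr_cardiac_wo": "AEMR cardiac disease, without RF [%]",
    "aemr_lung_w": "AEMR secondary lung cancer, with RF [%]",
    "aemr_lung_wo": "AEMR secondary lung cancer, without RF [%]",
}


def _cell(triple, percent: bool) -> str:
    med, q1, q3 = triple
    if any(not np.isfinite(v) for v in triple):
        warnings.warn("empty metric column rendered as em-dash", stacklevel=2)
        return "—"
    if percent:
        med, q1, q3 = 100.0 * med, 100.0 * q1, 100.0 * q3
    return f"{med:.1f} ({q1:.1f}–{q3:.1f})"


def render_summary(summary: CohortSummary) -> pd.DataFrame:
    """Summary table: one row per metric, one column per setup.

    Gy metrics show one decimal; TCP and the risk panel are percentages
    with one decimal (TCP is stored as a probability and scaled here).
    """
    rows = {}
    for key in SUMMARY_KEYS:
        label = _METRIC_LABELS[key]
        rows[label] = {
            s: _cell(summary.quartiles[s][key], percent=(key == "tcp")) for s in SETUPS
        }
    return pd.DataFrame(rows).T[list(SETUPS)]


def render_goals_met(summary: CohortSummary) -> pd.DataFrame:
    """Percent of patients meeting at least k of the six goals, per setup."""
    rows = {
        f"{k}/6 goals": {s: summary.goals_met_pct[s][k] for s in SETUPS}
        for k in (6, 5, 4, 3)
    }
    return pd.DataFrame(rows).T[list(SETUPS)]


def _stats_to_jsonable(sc) -> dict:
    return {
        "metric": sc.metric,
        "n": sc.n,
        "friedman_stat": sc.friedman_stat,
        "friedman_p": sc.friedman_p,
        "friedman_method": sc.friedman_method,
        "alpha": sc.alpha,
        "shapiro_p": {f"{a}|{b}": p for (a, b), p in sc.shapiro_p.items()},
        "posthoc": {
            f"{a}|{b}": {"w": w, "p": p, "p_bonferroni": pb}
            for (a, b), (w, p, pb) in sc.posthoc.items()
        },
    }


def _config_to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _config_to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, Mapping):
        return {str(k): _config_to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_config_to_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def run_pipeline(config: RunConfig, out_dir) -> RunResult:
    """Run simulate -> evaluate -> route -> summarize -> test -> report.

    Writes the report bundle into ``out_dir``; any stage error removes the
    partial outputs and re-raises with a stage tag.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "simulate"
    try:
        sim = dataclasses.replace(
            config.resolved_sim(), n_patients=config.n_patients, seed=config.seed
        )
        cohort = generate_cohort(
            sim, mode=config.mode, goals=config.goals,
            tcp_params=config.tcp_params, risk_registry=config.risk_registry,
        )
        log.info("stage=simulate patients_in=%d patients_out=%d", sim.n_patients, len(cohort.evals))

        stage = "summarize"
        summary = summarize_cohort(cohort.evals)
        log.info("stage=summarize patients_in=%d patients_out=%d",
                 len(cohort.evals), summary.n_patients)

        stage = "route"
        dt_active, dt_inter = time_saving(summary.route_counts, config.route_times)
        log.info("stage=route patients_in=%d patients_out=%d",
                 summary.n_patients, sum(summary.route_counts.values()))

        stage = "statistics"
        stats = {}
        for key in config.stat_metrics:
            values = metric_table(cohort.evals, key)
            stats[key] = _stats_to_jsonable(
                compare_setups(values, SETUPS, alpha=config.alpha, metric=key)
            )
        log.info("stage=statistics patients_in=%d metrics=%d", summary.n_patients, len(stats))

        stage = "report"
        p = out_dir / "cohort_eval.csv"
        write_cohort_csv(cohort.evals, p)
        written.append(p)

        p = out_dir / "summary_metrics.csv"
        render_summary(summary).to_csv(p, index_label="metric")
        written.append(p)

        p = out_dir / "goals_met.csv"
        render_goals_met(summary).to_csv(p, index_label="goals")
        written.append(p)

        p = out_dir / "routes.json"
        p.write_text(json.dumps({
            "route_counts": summary.route_counts,
            "n_patients": summary.n_patients,
            "dt_active_min": dt_active,
            "dt_inter_h": dt_inter,
        }, indent=2, sort_keys=True) + "\n")
        written.append(p)

        p = out_dir / "stats.json"
        p.write_text(json.dumps(stats, indent=2, sort_keys=True) + "\n")
        written.append(p)

        p = out_dir / "provenance.json"
        p.write_text(json.dumps(_config_to_jsonable(config), indent=2, sort_keys=True) + "\n")
        written.append(p)
        log.info("stage=report files=%d", len(written))
    except Exception as exc:
        for f in written:
            try:
                f.unlink()
            except OSError:
                pass
        raise RuntimeError(f"pipeline failed in stage '{stage}': {exc}") from exc

    return RunResult(
        cohort=cohort, summary=summary, route_counts=summary.route_counts,
        dt_active_min=dt_active, dt_inter_h=dt_inter, stats=stats, files=written,
    )


def load_run_config(path) -> RunConfig:
    """Build a RunConfig from a TOML file (missing blocks use defaults)."""
    import tomllib

    from .dvh import Goal
    from .radbio import RiskModelParams

    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    kwargs = {}
    for key in ("seed", "n_patients", "mode", "alpha"):
        if key in cfg:
            kwargs[key] = cfg[key]
    if "goal" in cfg:
        kwargs["goals"] = GoalSet(tuple(
            Goal(
                structure=g["structure"], metric=g["metric"], comparator=g["comparator"],
                threshold=float(g["threshold"]),
                threshold_high=float(g["threshold_high"]) if "threshold_high" in g else None,
                key=g.get("key", ""),
            )
            for g in cfg["goal"]
        ))
    if "tcp" in cfg:
        kwargs["tcp_params"] = dataclasses.replace(DEFAULT_TCP_PARAMS, **cfg["tcp"])
    if "risk_model" in cfg:
        registry = dict(DEFAULT_RISK_REGISTRY)
        for block in cfg["risk_model"]:
            model = RiskModelParams(**block)
            registry[model.endpoint] = model
        kwargs["risk_registry"] = registry
    if "route_times" in cfg:
        kwargs["route_times"] = RouteTimes(
            t_active_min=cfg["route_times"].get(
                "t_active_min", DEFAULT_ROUTE_TIMES.t_active_min
            ),
            t_inter_h=cfg["route_times"].get("t_inter_h", DEFAULT_ROUTE_TIMES.t_inter_h),
        )
    if "sim" in cfg:
        kwargs["sim"] = CohortSimConfig(**cfg["sim"])
    return RunConfig(**kwargs)
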