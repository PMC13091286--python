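"""Workflow route decisions, time savings, cohort summaries and statistics.

Four plan setups are evaluated per patient: CS-CP (clinical structures,
clinically approved plan — the gold standard), DLS-DLP (deep-learning
structures and plan, untouched), CS-DLP (clinical structures, DL plan) and
PS-DLP (DL structures with a corrected target, DL plan).  In the candidate
automated workflow a patient follows

* route A if DLS-DLP already meets all six clinical goals (no edits),
* route B if not, but PS-DLP does (target contour edit + replan),
* route C otherwise (edit + manual plan optimisation; the worst case of the
  indistinguishable C/D pair, so D is never auto-assigned).

Each route has an estimated hands-on staff time (t_active, minutes) and an
elapsed between-steps time (t_inter, working hours); the average saving is
measured against the current manual workflow.  TCP/NTCP never enter the
route decision — they are reporting-only.

Paired differences between setups are tested with a Shapiro-Wilk normality
gate (descriptive), a Friedman omnibus test across the four setups, and —
only when the omnibus is significant — all six pairwise Wilcoxon
signed-rank tests with Bonferroni correction.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .dvh import METRIC_KEYS, PlanMetrics

__all__ = [
    "SETUPS",
    "ROUTES",
    "PatientEval",
    "RouteTimes",
    "CohortSummary",
    "SetupComparison",
    "assign_route",
    "time_saving",
    "summarize_cohort",
    "friedman_test",
    "wilcoxon_signed_rank",
    "bonferroni",
    "compare_setups",
]

SETUPS = ("CS_CP", "DLS_DLP", "CS_DLP", "PS_DLP")
ROUTES = ("A", "B", "C")

#: summary columns: the six goal metrics plus TCP and the six risk values
SUMMARY_KEYS = METRIC_KEYS + (
    "tcp",
    "aer_w",
    "aer_wo",
    "aemr_cardiac_w",
    "aemr_cardiac_wo",
    "aemr_lung_w",
    "aemr_lung_wo",
)

RISK_KEYS = SUMMARY_KEYS[-6:]


@dataclass
class PatientEval:
    """The four evaluated plan setups of one patient, plus its route."""

    patient_id: str
    metrics: dict[str, PlanMetrics]
    route: str | None = None

    def require_setups(self, setups: Sequence[str] = SETUPS) -> None:
        missing = [s for s in setups if s not in self.metrics]
        if missing:
            raise KeyError(f"patient {self.patient_id} missing setup(s): {missing}")


@dataclass(frozen=True)
class RouteTimes:
    """Hands-on minutes and between-steps hours per workflow route."""

    t_active_min: Mapping[str, float] = field(
        default_factory=lambda: {"current": 85.0, "A": 20.0, "B": 25.0, "C": 75.0, "D": 70.0}
    )
    t_inter_h: Mapping[str, float] = field(
        default_factory=lambda: {"current": 37.0, "A": 16.0, "B": 24.0, "C": 36.0, "D": 36.0}
    )

    def __post_init__(self):
        for table in (self.t_active_min, self.t_inter_h):
            if any(v < 0 for v in table.values()):
                raise ValueError("route times must be >= 0")
        if self.t_active_min["A"] > self.t_active_min["current"]:
            raise ValueError("route A cannot take more active time than the current workflow")


DEFAULT_ROUTE_TIMES = RouteTimes()


def assign_route(p: PatientEval) -> str:
    """Apply the route decision rules to one patient's goal counts."""
    p.require_setups(("DLS_DLP", "PS_DLP"))
    if p.metrics["DLS_DLP"].goals_met == 6:
        return "A"
    if p.metrics["PS_DLP"].goals_met == 6:
        return "B"
    return "C"


def time_saving(
    route_counts: Mapping[str, int],
    times: RouteTimes = DEFAULT_ROUTE_TIMES,
) -> tuple[float, float]:
    """Average (t_active minutes, t_inter hours) saved per patient.

    The saving is the current-workflow time minus the count-weighted mean
    route time.  C/D patients are expected under the 'C' key (worst case).
    """
    total = sum(route_counts.values())
    if total <= 0:
        raise ValueError("route counts must total > 0")
    if any(c < 0 for c in route_counts.values()):
        raise ValueError("route counts must be >= 0")
    avg_active = sum(times.t_active_min[r] * c for r, c in route_counts.items()) / total
    avg_inter = sum(times.t_inter_h[r] * c for r, c in route_counts.items()) / total
    return (
        times.t_active_min["current"] - avg_active,
        times.t_inter_h["current"] - avg_inter,
    )


@dataclass
class CohortSummary:
    """Median (Q1-Q3) per setup and metric, goal-pass rates and routes."""

    n_patients: int
    quartiles: dict[str, dict[str, tuple[float, float, float]]]  # setup -> key -> (med, q1, q3)
    goals_met_pct: dict[str, dict[int, int]]  # setup -> k -> % patients with >= k of 6 goals
    route_counts: dict[str, int]

    def __post_init__(self):
        for setup, table in self.goals_met_pct.items():
            vals = [table[k] for k in sorted(table)]
            if any(not 0 <= v <= 100 for v in vals):
                raise ValueError("percentages must lie in [0, 100]")
            if any(a < b for a, b in zip(vals, vals[1:])):
                raise ValueError(f"goal-pass rates must be non-increasing in k ({setup})")


def _metric_value(m: PlanMetrics, key: str) -> float:
    if key in METRIC_KEYS or key == "tcp":
        return float(getattr(m, key))
    idx = RISK_KEYS.index(key)
    if idx >= len(m.risks):
        return math.nan
    return float(m.risks[idx].value)


def metric_table(evals: Sequence[PatientEval], key: str) -> np.ndarray:
    """n_patients x 4 array of one metric across the four setups."""
    return np.array(
        [[_metric_value(p.metrics[s], key) for s in SETUPS] for p in evals], dtype=np.float64
    )


def summarize_cohort(evals: Sequence[PatientEval]) -> CohortSummary:
    """Cohort-level summary: quartiles, goal-pass percentages, route counts.

    Quartiles use linear interpolation; percentages are rounded to integers
    for the report tables (raw CSVs keep full precision).
    """
    if not evals:
        raise ValueError("empty cohort")
    for p in evals:
        p.require_setups()
        if p.route is None:
            p.route = assign_route(p)
    n = len(evals)
    quart: dict[str, dict[str, tuple[float, float, float]]] = {}
    pct: dict[str, dict[int, int]] = {}
    for s in SETUPS:
        quart[s] = {}
        for key in SUMMARY_KEYS:
            vals = np.array([_metric_value(p.metrics[s], key) for p in evals])
            if np.all(np.isnan(vals)):
                quart[s][key] = (math.nan, math.nan, math.nan)
            else:
                med, q1, q3 = np.percentile(vals, [50, 25, 75])
                quart[s][key] = (float(med), float(q1), float(q3))
        counts = np.array([p.metrics[s].goals_met for p in evals])
        pct[s] = {k: int(round(100.0 * np.count_nonzero(counts >= k) / n)) for k in (3, 4, 5, 6)}
    routes = {r: sum(1 for p in evals if p.route == r) for r in ROUTES}
    return CohortSummary(n_patients=n, quartiles=quart, goals_met_pct=pct, route_counts=routes)


# ---------------------------------------------------------------------------
# Statistics chain


def _plain_friedman_stat(rank_sums: np.ndarray, n: int, k: int) -> float:
    rbar = rank_sums / n
    return float(12.0 * n / (k * (k + 1)) * np.sum((rbar - (k + 1) / 2.0) ** 2))


def _friedman_exact_p(ranks: np.ndarray, observed: float) -> float:
    """Exact permutation p for the Friedman statistic.

    Within-row permutations are iid uniform under the null; the statistic
    depends only on the column rank sums, so the null distribution is built
    by dynamic-programming convolution of per-row rank vectors (doubled to
    stay integer under mid-ranks).
    """
    n, k = ranks.shape
    scaled = np.round(ranks * 2).astype(np.int64)
    perms = list(itertools.permutations(range(k)))
    dist: dict[tuple, float] = {tuple([0] * k): 1.0}
    w = 1.0 / len(perms)
    for i in range(n):
        row = scaled[i]
        new: dict[tuple, float] = {}
        for state, prob in dist.items():
            for perm in perms:
                key = tuple(state[j] + row[perm[j]] for j in range(k))
                new[key] = new.get(key, 0.0) + prob * w
        dist = new
    p = 0.0
    for state, prob in dist.items():
        stat = _plain_friedman_stat(np.asarray(state) / 2.0, n, k)
        if stat >= observed - 1e-9:
            p += prob
    return min(1.0, p)


def friedman_test(data: np.ndarray, exact_max_n: int = 8) -> tuple[float, float, str]:
    """Friedman test on an ``n x k`` block of paired measurements.

    Mid-ranks within each row; the classic statistic
    ``12 n / (k (k+1)) * sum_j (Rbar_j - (k+1)/2)^2`` with the standard tie
    correction; p from the chi-square approximation with k-1 df, or from the
    exact permutation distribution when ``n <= exact_max_n``.  Returns
    (statistic, p, method).  Fully tied data give statistic 0 and p 1.
    """
    data = np.asarray(data, dtype=np.float64)
    if data.ndim != 2 or data.shape[1] < 2:
        raise ValueError("need an n x k array with k >= 2")
    n, k = data.shape
    ranks = sps.rankdata(data, axis=1)
    rank_sums = ranks.sum(axis=0)
    stat = _plain_friedman_stat(rank_sums, n, k)
    # tie correction: 1 - sum(t^3 - t) / (n k (k^2 - 1)) over within-row ties
    tie_sum = 0.0
    for i in range(n):
        _, counts = np.unique(data[i], return_counts=True)
        tie_sum += float(np.sum(counts**3 - counts))
    correction = 1.0 - tie_sum / (n * k * (k**2 - 1))
    if correction <= 0:
        return 0.0, 1.0, "degenerate"
    stat_c = stat / correction
    if n <= exact_max_n:
        return stat_c, _friedman_exact_p(ranks, stat), "exact"
    return stat_c, float(sps.chi2.sf(stat_c, k - 1)), "chi2"


def wilcoxon_signed_rank(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped; mid-ranks for tied magnitudes; exact null
    for n <= 25 without ties, otherwise the normal approximation with tie
    correction.  Returns (W statistic, p).
    """
    d = np.asarray(x, dtype=np.float64) - np.asarray(y, dtype=np.float64)
    d = d[d != 0]
    if d.size == 0:
        return 0.0, 1.0
    has_ties = np.unique(np.abs(d)).size < d.size
    method = "exact" if (d.size <= 25 and not has_ties) else "approx"
    res = sps.wilcoxon(d, zero_method="wilcox", correction=False, method=method)
    return float(res.statistic), float(res.pvalue)


def bonferroni(p: float, family: int = 6) -> float:
    """Bonferroni-adjusted p: min(1, family * p)."""
    return min(1.0, family * p)


@dataclass
class SetupComparison:
    """Shapiro-Wilk gate, Friedman omnibus and optional Wilcoxon post-hocs."""

    metric: str
    n: int
    labels: tuple[str, ...]
    shapiro_p: dict[tuple[str, str], float]
    friedman_stat: float
    friedman_p: float
    friedman_method: str
    posthoc: dict[tuple[str, str], tuple[float, float, float]]  # (W, p, p_bonf)
    alpha: float


def compare_setups(
    values: np.ndarray,
    labels: Sequence[str] = SETUPS,
    alpha: float = 0.05,
    metric: str = "",
    bonferroni_family: int | None = None,
) -> SetupComparison:
    """The full paired-comparison chain for one metric across setups.

    ``values`` is n_patients x k.  Shapiro-Wilk on every pairwise difference
    is reported descriptively (the protocol found no metric normal across
    all pairs, hence the non-parametric chain).  Pairwise Wilcoxon tests are
    run only when the Friedman omnibus is significant at ``alpha``, with
    Bonferroni correction over the pairs.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.ndim != 2 or values.shape[1] != len(labels):
        raise ValueError("values must be n x k with one column per label")
    n, k = values.shape
    if n < 5:
        raise ValueError("need at least 5 patients for the comparison chain")
    pairs = list(itertools.combinations(range(k), 2))
    family = bonferroni_family if bonferroni_family is not None else len(pairs)

    shapiro_p = {}
    for i, j in pairs:
        diff = values[:, i] - values[:, j]
        if np.ptp(diff) == 0:
            shapiro_p[(labels[i], labels[j])] = math.nan
        else:
            shapiro_p[(labels[i], labels[j])] = float(sps.shapiro(diff).pvalue)

    stat, p, method = friedman_test(values)

    posthoc = {}
    if p < alpha:
        for i, j in pairs:
            w, praw = wilcoxon_signed_rank(values[:, i], values[:, j])
            posthoc[(labels[i], labels[j])] = (w, praw, bonferroni(praw, family))

    return SetupComparison(
        metric=metric,
        n=n,
        labels=tuple(labels),
        shapiro_p=shapiro_p,
        friedman_stat=stat,
        friedman_p=p,
        friedman_method=method,
        posthoc=posthoc,
        alpha=alpha,
    )
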