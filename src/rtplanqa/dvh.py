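"""Cumulative dose-volume histograms and clinical-goal evaluation.

A cumulative DVH gives, for every dose level d, the fraction of a
structure's volume receiving at least d.  Six DVH parameters drive plan
scoring for the left-breast protocol (40.05 Gy in 15 fractions of 2.67 Gy):

* PTV D_mean within [39.65, 40.45] Gy (99-101 % of prescription)
* PTV D_98  >= 38.05 Gy (95 %)   -- minimum dose to the coldest 98 %
* PTV D_2   <= 42.85 Gy (107 %)  -- near-maximum dose
* mean lung dose        <= 6 Gy
* mean heart dose       <= 3 Gy
* mean contralateral-breast dose <= 1 Gy

D_mean is computed on raw voxels (exact); D_98/D_2 come from the binned
curve with linear interpolation (default bin width 0.01 Gy, i.e. cGy
resolution).  Goal comparisons are inclusive at the thresholds.  Only
relative-volume DVHs are supported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .grids import DoseGrid, StructMask, require_aligned

__all__ = [
    "DVHCurve",
    "Goal",
    "GoalSet",
    "PlanMetrics",
    "DEFAULT_GOALS",
    "METRIC_KEYS",
    "compute_dvh",
    "dvh_from_doses",
    "d_mean",
    "d_percent",
    "evaluate_goals",
    "write_dvh_csv",
    "read_dvh_csv",
    "load_goalset",
]

DEFAULT_BIN_WIDTH_GY = 0.01

#: canonical keys for the six scored DVH parameters
METRIC_KEYS = (
    "ptv_dmean",
    "ptv_d98",
    "ptv_d2",
    "lungs_dmean",
    "heart_dmean",
    "breastcl_dmean",
)


@dataclass(frozen=True)
class DVHCurve:
    """Cumulative DVH sampled on increasing bin edges (uniform when binned
    from voxels; fraction-conversion transforms may make them non-uniform).

    ``cum_volume[i]`` is the fraction of the structure receiving at least
    ``bin_edges[i]`` Gy; it starts at 1, is non-increasing, and ends at 0
    beyond the maximum dose.
    """

    structure: str
    bin_edges: np.ndarray
    cum_volume: np.ndarray

    def __post_init__(self):
        edges = np.asarray(self.bin_edges, dtype=np.float64)
        cum = np.asarray(self.cum_volume, dtype=np.float64)
        if edges.ndim != 1 or edges.shape != cum.shape:
            raise ValueError("bin_edges and cum_volume must be 1-D and equal length")
        if edges.size < 2:
            raise ValueError("a DVH needs at least two bin edges")
        widths = np.diff(edges)
        if np.any(widths <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.any(np.diff(cum) > 1e-12):
            raise ValueError("cum_volume must be non-increasing")
        if cum[0] != 1.0 or not np.isclose(cum[-1], 0.0, atol=1e-12):
            raise ValueError("cum_volume must start at 1 and end at 0")
        if cum.min() < -1e-12 or cum.max() > 1 + 1e-12:
            raise ValueError("volume fractions must lie in [0, 1]")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "cum_volume", cum)

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def is_uniform(self) -> bool:
        w = np.diff(self.bin_edges)
        return bool(np.allclose(w, w[0], rtol=1e-6, atol=1e-12))

    def differential(self) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(v_i, D_i)`` pairs: volume fraction per bin, bin-centre dose."""
        v = -np.diff(self.cum_volume)
        d = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
        keep = v > 0
        return v[keep], d[keep]


def dvh_from_doses(
    doses: np.ndarray,
    structure: str = "",
    bin_width: float = DEFAULT_BIN_WIDTH_GY,
) -> DVHCurve:
    """Cumulative DVH of a flat array of (equally weighted) voxel doses."""
    doses = np.asarray(doses, dtype=np.float64).ravel()
    if doses.size == 0:
        raise ValueError("cannot build a DVH from zero doses")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    dmax = float(doses.max())
    n_edges = int(np.floor(dmax / bin_width)) + 2
    edges = np.arange(n_edges, dtype=np.float64) * bin_width
    order = np.sort(doses)
    # fraction of voxels with dose >= edge
    cum = 1.0 - np.searchsorted(order, edges, side="left") / doses.size
    cum[0] = 1.0
    cum[-1] = 0.0
    return DVHCurve(structure=structure, bin_edges=edges, cum_volume=cum)


def compute_dvh(
    dose: DoseGrid,
    mask: StructMask,
    bin_width: float = DEFAULT_BIN_WIDTH_GY,
) -> DVHCurve:
    """Cumulative DVH of ``dose`` over the member voxels of ``mask``."""
    require_aligned(dose, mask)
    if mask.is_empty:
        raise ValueError(f"mask '{mask.name}' is empty; DVH undefined")
    return dvh_from_doses(dose.values[mask.values], mask.name, bin_width)


def d_mean(dose: DoseGrid, mask: StructMask) -> float:
    """Mean member-voxel dose in Gy, computed on raw voxels (not binned)."""
    require_aligned(dose, mask)
    if mask.is_empty:
        raise ValueError(f"mask '{mask.name}' is empty; mean dose undefined")
    return float(dose.values[mask.values].mean())


def d_percent(curve: DVHCurve, p: float) -> float:
    """D_p: the dose received by at least p % of the volume.

    Linear interpolation between the bracketing bin edges of the cumulative
    curve; D_98 is a cold-spot (near-minimum) metric, D_2 a hot-spot one.
    """
    if not 0.0 < p < 100.0:
        raise ValueError("p must be in (0, 100)")
    edges, cum = curve.bin_edges, curve.cum_volume
    if edges.size == 2:
        warnings.warn("degenerate single-bin DVH; returning its bin dose", stacklevel=2)
        return float(edges[0])
    target = p / 100.0
    # last edge still receiving >= target volume, interpolated into the
    # bracketing bin (cum is non-increasing with flat plateaus, so a plain
    # np.interp would be ambiguous there)
    j = int(np.nonzero(cum >= target)[0][-1])
    if j == cum.size - 1:
        return float(edges[-1])
    c1, c2 = cum[j], cum[j + 1]
    if c1 == target or c1 == c2:
        return float(edges[j])
    return float(edges[j] + (c1 - target) / (c1 - c2) * (edges[j + 1] - edges[j]))


_COMPARATORS = ("le", "ge", "range")


@dataclass(frozen=True)
class Goal:
    structure: str
    metric: str  # Dmean | D98 | D2
    comparator: str  # le | ge | range
    threshold: float
    threshold_high: float | None = None
    key: str = ""  # PlanMetrics key this goal reads

    def __post_init__(self):
        if self.comparator not in _COMPARATORS:
            raise ValueError(f"comparator must be one of {_COMPARATORS}")
        if self.threshold <= 0:
            raise ValueError("goal thresholds must be strictly positive")
        if self.comparator == "range":
            if self.threshold_high is None or self.threshold_high <= self.threshold:
                raise ValueError("range goal needs threshold < threshold_high")

    def is_met(self, value: float) -> bool:
        if self.comparator == "le":
            return value <= self.threshold
        if self.comparator == "ge":
            return value >= self.threshold
        return self.threshold <= value <= self.threshold_high

    def describe(self) -> str:
        if self.comparator == "range":
            return f"{self.threshold} Gy <= {self.structure} {self.metric} <= {self.threshold_high} Gy"
        op = "<=" if self.comparator == "le" else ">="
        return f"{self.structure} {self.metric} {op} {self.threshold} Gy"


@dataclass(frozen=True)
class GoalSet:
    goals: tuple[Goal, ...]

    def __post_init__(self):
        object.__setattr__(self, "goals", tuple(self.goals))

    def __iter__(self):
        return iter(self.goals)

    def __len__(self):
        return len(self.goals)


#: the six protocol goals (Dutch national consensus PTV criteria + OAR means)
DEFAULT_GOALS = GoalSet(
    goals=(
        Goal("PTVp-Skin05", "Dmean", "range", 39.65, 40.45, key="ptv_dmean"),
        Goal("PTVp-Skin05", "D98", "ge", 38.05, key="ptv_d98"),
        Goal("PTVp-Skin05", "D2", "le", 42.85, key="ptv_d2"),
        Goal("Lungs", "Dmean", "le", 6.0, key="lungs_dmean"),
        Goal("Heart", "Dmean", "le", 3.0, key="heart_dmean"),
        Goal("BreastCL", "Dmean", "le", 1.0, key="breastcl_dmean"),
    )
)


def evaluate_goals(
    metrics: Mapping[str, float],
    goals: GoalSet = DEFAULT_GOALS,
) -> tuple[tuple[bool, ...], int]:
    """Evaluate each goal against its DVH parameter.

    Returns (per-goal flags, number of goals met).  Boundary values count as
    met.  A missing or non-finite parameter raises, naming the goal.
    """
    flags = []
    for g in goals:
        if g.key not in metrics:
            raise KeyError(f"missing DVH parameter '{g.key}' for goal: {g.describe()}")
        v = float(metrics[g.key])
        if not np.isfinite(v):
            raise ValueError(f"non-finite DVH parameter '{g.key}' for goal: {g.describe()}")
        flags.append(g.is_met(v))
    return tuple(flags), int(sum(flags))


@dataclass(frozen=True)
class PlanMetrics:
    """Everything evaluated for one plan setup of one patient."""

    ptv_dmean: float
    ptv_d98: float
    ptv_d2: float
    lungs_dmean: float
    heart_dmean: float
    breastcl_dmean: float
    goal_flags: tuple[bool, ...] = ()
    goals_met: int = 0
    tcp: float = float("nan")
    risks: tuple = ()

    def __post_init__(self):
        if self.goal_flags and self.goals_met != sum(self.goal_flags):
            raise ValueError("goals_met must equal the count of true goal_flags")
        if not (self.ptv_d98 <= self.ptv_dmean + 1e-9 and self.ptv_dmean <= self.ptv_d2 + 1e-9):
            raise ValueError(
                "PTV metrics must satisfy D98 <= Dmean <= D2, got "
                f"({self.ptv_d98}, {self.ptv_dmean}, {self.ptv_d2})"
            )

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in METRIC_KEYS}


# ---------------------------------------------------------------------------
# DVH CSV dialect: header `dose_gy,<structure1>,...`, one row per ascending
# bin edge, fractions with 6 decimals; '#' lines are comments.

def write_dvh_csv(curves: Sequence[DVHCurve], path) -> None:
    curves = list(curves)
    if not curves:
        raise ValueError("no curves to write")
    n = max(c.bin_edges.size for c in curves)
    w = curves[0].bin_width
    for c in curves:
        if not c.is_uniform or not np.isclose(c.bin_width, w):
            raise ValueError("all curves in one file must share a uniform bin width")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("dose_gy," + ",".join(c.structure for c in curves) + "\n")
        for i in range(n):
            vals = [
                f"{(c.cum_volume[i] if i < c.cum_volume.size else 0.0):.6f}"
                for c in curves
            ]
            fh.write(f"{i * w:.6f}," + ",".join(vals) + "\n")


def read_dvh_csv(path) -> dict[str, DVHCurve]:
    path = Path(path)
    rows = []
    header = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if header is None:
                header = line.split(",")
                continue
            rows.append([float(x) for x in line.split(",")])
    if header is None or header[0] != "dose_gy":
        raise ValueError(f"{path} is not a DVH CSV (missing 'dose_gy' header)")
    data = np.asarray(rows, dtype=np.float64)
    edges = data[:, 0]
    out = {}
    for j, name in enumerate(header[1:], start=1):
        cum = data[:, j]
        out[name] = DVHCurve(structure=name, bin_edges=edges, cum_volume=cum)
    return out


def load_goalset(path) -> GoalSet:
    """Read a GoalSet from a TOML file with ``[[goal]]`` tables."""
    import tomllib

    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    goals = []
    for g in cfg.get("goal", []):
        goals.append(
            Goal(
                structure=g["structure"],
                metric=g["metric"],
                comparator=g["comparator"],
                threshold=float(g["threshold"]),
                threshold_high=float(g["threshold_high"]) if "threshold_high" in g else None,
                key=g.get("key", ""),
            )
        )
    if len(goals) != 6:
        warnings.warn(f"goal set has {len(goals)} goals (protocol default is 6)", stacklevel=2)
    return GoalSet(goals=tuple(goals))
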