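"""Synthetic left-breast cohort generator.

No patient data ships with this package, so every downstream stage is
exercised on virtual patients that mimic the statistical shape of a
left-sided node-negative breast cohort treated with 15 x 2.67 Gy:

* a voxel phantom (body, ipsilateral breast CTVp, PTVp-Skin05, lungs,
  heart, contralateral breast) built from ellipsoids, with the PTV formed
  by a 5 mm isotropic CTV expansion kept >= 5 mm from the skin;
* plan-like dose fields: a plateau at prescription inside the planning PTV
  with multiplicative Gaussian heterogeneity, and an exponential
  distance-driven falloff outside, calibrated by bisection to a requested
  mean lung dose;
* deep-learning-like contour differences: a smooth random radial
  displacement of the mask boundary whose amplitude is solved by bisection
  to hit a requested volumetric Dice, plus a localised boundary bump that
  sets the 95th-percentile Hausdorff distance;
* a fast DVH-level sampler that draws the six scored DVH parameters per
  setup from distributions matched to published cohort quartiles (normal
  for PTV metrics, log-normal for the right-skewed OAR mean doses), with a
  shared per-patient latent factor inducing inter-setup correlation, and a
  'clinically relevant target defect' mixture: a configurable fraction of
  patients receive a cold spot in the fully automatic setup (DLS-DLP) that
  is absent once the target contour is corrected (PS-DLP), which is what
  drags their TCP down.

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy import ndimage

from .dvh import (
    DEFAULT_GOALS,
    DVHCurve,
    GoalSet,
    PlanMetrics,
    compute_dvh,
    d_mean,
    d_percent,
    dvh_from_doses,
    evaluate_goals,
)
from .grids import DoseGrid, StructMask
from .radbio import (
    DEFAULT_RISK_REGISTRY,
    DEFAULT_TCP_PARAMS,
    TCPParams,
    risk_panel,
    tcp_from_curve,
)
from .segmetrics import vdsc
from .workflow import SETUPS, PatientEval, assign_route

__all__ = [
    "PhantomSpec",
    "PlanQuality",
    "CohortSimConfig",
    "DEFAULT_SETUP_DISTRIBUTIONS",
    "DEFAULT_CONTOUR_TARGETS",
    "build_phantom",
    "paint_dose",
    "perturb_mask",
    "sample_patient",
    "sample_dvh_params",
    "synthesize_ptv_curve",
    "generate_cohort",
]

STRUCTURES = ("Body", "CTVp", "PTVp-Skin05", "Lungs", "Heart", "BreastCL")


# ---------------------------------------------------------------------------
# Phantom


@dataclass(frozen=True)
class PhantomSpec:
    """Ellipsoid-based left-breast phantom geometry (all lengths in mm).

    Axes are (superior-inferior, anterior-posterior, right-left); centres
    are offsets from the body centre.  Defaults give structure volumes of
    the order reported for real cohorts (breast several hundred cm^3, lungs
    ~4 L, heart ~0.6 L).
    """

    spacing_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    extent_mm: tuple[float, float, float] = (260.0, 230.0, 360.0)
    body_semi_mm: tuple[float, float, float] = (120.0, 100.0, 170.0)
    ctv_center_mm: tuple[float, float, float] = (0.0, -70.0, -110.0)
    ctv_semi_mm: tuple[float, float, float] = (60.0, 55.0, 60.0)
    lung_center_mm: tuple[float, float, float] = (0.0, 25.0, 85.0)  # mirrored pair
    lung_semi_mm: tuple[float, float, float] = (112.0, 76.0, 68.0)
    heart_center_mm: tuple[float, float, float] = (-30.0, 25.0, -40.0)
    heart_semi_mm: tuple[float, float, float] = (60.0, 48.0, 48.0)
    mirror_breast_cl: bool = True
    ptv_margin_mm: float = 5.0
    skin_clearance_mm: float = 5.0

    def __post_init__(self):
        for name in ("spacing_mm", "extent_mm", "body_semi_mm", "ctv_semi_mm",
                     "lung_semi_mm", "heart_semi_mm"):
            if any(v <= 0 for v in getattr(self, name)):
                raise ValueError(f"{name} must be strictly positive")
        if self.ptv_margin_mm < 0 or self.skin_clearance_mm < 0:
            raise ValueError("PTV construction parameters must be >= 0")


def _ellipsoid(coords, center, semi) -> np.ndarray:
    acc = np.zeros(coords[0].shape)
    for c, c0, a in zip(coords, center, semi):
        acc = acc + ((c - c0) / a) ** 2
    return acc <= 1.0


def build_phantom(spec: PhantomSpec = PhantomSpec()) -> dict[str, StructMask]:
    """Build the six mutually consistent masks of one virtual patient.

    Structures are pairwise disjoint except PTV ^ CTV = CTV (up to the skin
    collar); the PTV is the CTV expanded by ``ptv_margin_mm`` (Euclidean,
    mm) intersected with the body eroded by ``skin_clearance_mm``.
    """
    spacing = spec.spacing_mm
    shape = tuple(int(round(e / s)) for e, s in zip(spec.extent_mm, spacing))
    coords = np.meshgrid(
        *[(np.arange(n) + 0.5) * s - e / 2.0 for n, s, e in zip(shape, spacing, spec.extent_mm)],
        indexing="ij",
    )

    body = _ellipsoid(coords, (0.0, 0.0, 0.0), spec.body_semi_mm)
    ctv = _ellipsoid(coords, spec.ctv_center_mm, spec.ctv_semi_mm) & body
    c0, c1, c2 = spec.lung_center_mm
    lungs = (
        _ellipsoid(coords, (c0, c1, -c2), spec.lung_semi_mm)
        | _ellipsoid(coords, (c0, c1, c2), spec.lung_semi_mm)
    ) & body
    heart = _ellipsoid(coords, spec.heart_center_mm, spec.heart_semi_mm) & body
    # enforce disjointness: the breast owns its voxels, heart beats lungs
    heart &= ~ctv
    lungs &= ~ctv & ~heart
    if spec.mirror_breast_cl:
        m0, m1, m2 = spec.ctv_center_mm
        breast_cl = _ellipsoid(coords, (m0, m1, -m2), spec.ctv_semi_mm) & body
    else:
        breast_cl = np.zeros_like(body)
    breast_cl &= ~ctv & ~heart & ~lungs

    ptv = _expand_to_ptv(ctv, body, spacing, spec.ptv_margin_mm, spec.skin_clearance_mm)
    if not ptv.any():
        raise ValueError("phantom spec produced an empty PTV")

    def mk(name, arr, allow_empty=False):
        return StructMask(name=name, values=arr, spacing=spacing, allow_empty=allow_empty)

    return {
        "Body": mk("Body", body),
        "CTVp": mk("CTVp", ctv),
        "PTVp-Skin05": mk("PTVp-Skin05", ptv),
        "Lungs": mk("Lungs", lungs),
        "Heart": mk("Heart", heart),
        "BreastCL": mk("BreastCL", breast_cl, allow_empty=not spec.mirror_breast_cl),
    }


def _expand_to_ptv(ctv, body, spacing, margin_mm, clearance_mm) -> np.ndarray:
    """CTV -> PTV: Euclidean dilation then skin-clearance erosion."""
    if margin_mm > 0:
        d_ctv = ndimage.distance_transform_edt(~ctv, sampling=spacing)
        ptv = d_ctv <= margin_mm
    else:
        ptv = ctv.copy()
    if clearance_mm > 0:
        d_skin = ndimage.distance_transform_edt(body, sampling=spacing)
        ptv &= d_skin >= clearance_mm
    else:
        ptv &= body
    return ptv


# ---------------------------------------------------------------------------
# Dose painting


@dataclass(frozen=True)
class PlanQuality:
    """Latent per-plan dose-shape parameters.

    ``plateau_gy`` is the target-mean dose level; ``heterogeneity_rel`` the
    relative sigma of the multiplicative Gaussian texture (controls the
    D98/D2 spread); ``lungs_dmean_gy`` the requested mean lung dose hit by
    calibrating the exponential falloff length; ``texture_corr_mm`` the
    correlation length of the texture.
    """

    plateau_gy: float = 40.4
    heterogeneity_rel: float = 0.022
    lungs_dmean_gy: float = 2.3
    texture_corr_mm: float = 12.0
    scatter_rel: float = 0.006  # long-range scatter floor, fraction of plateau


def _smooth_noise(shape, spacing, corr_mm, rng) -> np.ndarray:
    white = rng.standard_normal(shape)
    sigma = [max(corr_mm / s, 1e-6) for s in spacing]
    smooth = ndimage.gaussian_filter(white, sigma=sigma)
    sd = smooth.std()
    if sd < 1e-12:
        return np.zeros(shape)
    return smooth / sd


def paint_dose(
    phantom: Mapping[str, StructMask],
    quality: PlanQuality = PlanQuality(),
    seed: int | np.random.Generator = 0,
    planning_ptv: StructMask | None = None,
) -> DoseGrid:
    """Paint a tangential-plan-like dose field on a phantom.

    Plateau at ``plateau_gy`` inside the planning PTV, exponential falloff
    ``exp(-d/lambda)`` with distance outside it, all modulated by a
    multiplicative Gaussian texture.  The falloff length is solved by
    bisection so the mean lung dose matches ``lungs_dmean_gy``; a request at
    or above the plateau is unreachable and raises.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ptv = planning_ptv if planning_ptv is not None else phantom["PTVp-Skin05"]
    lungs = phantom["Lungs"]
    if quality.lungs_dmean_gy >= quality.plateau_gy:
        raise ValueError(
            f"requested mean lung dose {quality.lungs_dmean_gy} Gy is not below "
            f"the plateau {quality.plateau_gy} Gy"
        )
    spacing = ptv.spacing
    dist = ndimage.distance_transform_edt(~ptv.values, sampling=spacing)

    lung_dist = dist[lungs.values]
    scatter = quality.scatter_rel

    def lung_mean(lam: float) -> float:
        fall = np.minimum(np.exp(-lung_dist / lam) + scatter, 1.0)
        return float(quality.plateau_gy * fall.mean())

    lo, hi = 0.5, 1000.0
    if lung_mean(hi) < quality.lungs_dmean_gy:
        raise ValueError("requested mean lung dose unreachable even with flat falloff")
    if lung_mean(lo) > quality.lungs_dmean_gy:
        raise ValueError("requested mean lung dose unreachable: lungs too close to target")
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if lung_mean(mid) < quality.lungs_dmean_gy:
            lo = mid
        else:
            hi = mid
    lam = 0.5 * (lo + hi)

    base = quality.plateau_gy * np.minimum(np.exp(-dist / lam) + scatter, 1.0)
    base[ptv.values] = quality.plateau_gy
    if quality.heterogeneity_rel > 0:
        noise = _smooth_noise(ptv.shape, spacing, quality.texture_corr_mm, rng)
        # standardise over the planning PTV so the plateau mean stays exact
        inside = noise[ptv.values]
        if inside.size and inside.std() > 1e-12:
            noise = (noise - inside.mean()) / inside.std()
        texture = 1.0 + quality.heterogeneity_rel * noise
        base = base * np.clip(texture, 0.0, None)
    return DoseGrid(values=np.clip(base, 0.0, None), spacing=spacing, origin=ptv.origin)


# ---------------------------------------------------------------------------
# Contour perturbation


def perturb_mask(
    mask: StructMask,
    target: tuple[float, float],
    seed: int | np.random.Generator = 0,
    corr_mm: float = 15.0,
    vdsc_tol: float = 0.005,
    name: str | None = None,
) -> StructMask:
    """Deform a mask to a requested (VDSC, HD95) against the original.

    A band-limited random field displaces the boundary along its normal
    (implemented by thresholding the signed distance against the field);
    the field amplitude is solved by bisection so the volumetric Dice lands
    within ``vdsc_tol`` of the target.  A localised Gaussian boundary bump
    of depth ~ the HD95 target (covering ~12 % of the surface, so the 95th
    percentile sees it) sets the Hausdorff scale.  Targets (1, 0) return
    the mask unchanged.
    """
    vdsc_t, hd95_t = target
    if not 0.0 < vdsc_t <= 1.0 or hd95_t < 0:
        raise ValueError("need 0 < VDSC target <= 1 and HD95 target >= 0")
    if mask.is_empty:
        raise ValueError("cannot perturb an empty mask")
    out_name = name or mask.name
    if vdsc_t >= 1.0 - 1e-12 and hd95_t <= 0.0:
        return StructMask(out_name, mask.values.copy(), mask.spacing, mask.origin)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    spacing = np.asarray(mask.spacing)
    sd = ndimage.distance_transform_edt(~mask.values, sampling=mask.spacing).astype(np.float64)
    sd -= ndimage.distance_transform_edt(mask.values, sampling=mask.spacing)

    noise = _smooth_noise(mask.shape, mask.spacing, corr_mm, rng)

    bump = 0.0
    if hd95_t > 0:
        interior = ndimage.binary_erosion(mask.values, border_value=0)
        surf_idx = np.argwhere(mask.values & ~interior)
        pick = surf_idx[rng.integers(len(surf_idx))]
        # patch radius from ~12 % of the (voxelised) surface area
        voxel_face = float(np.cbrt(np.prod(spacing))) ** 2
        area = len(surf_idx) * voxel_face
        rb = math.sqrt(0.12 * area / math.pi)
        coords = np.meshgrid(
            *[(np.arange(n) - p) * s for n, p, s in zip(mask.shape, pick, spacing)],
            indexing="ij",
        )
        r2 = sum(c**2 for c in coords)
        sign = 1.0 if rng.uniform() < 0.5 else -1.0
        bump = sign * hd95_t * np.exp(-r2 / (2.0 * rb**2))

    def deformed(amp: float) -> np.ndarray:
        return sd <= amp * noise + bump

    def score(amp: float) -> float:
        new = deformed(amp)
        if not new.any():
            return 0.0
        inter = int(np.count_nonzero(new & mask.values))
        return 2.0 * inter / (int(np.count_nonzero(new)) + mask.n_voxels)

    lo, hi = 0.0, max(corr_mm, 2.0 * hd95_t, 4.0 * float(spacing.max()))
    if score(lo) < vdsc_t - vdsc_tol:
        raise ValueError(
            f"VDSC target {vdsc_t} unreachable: boundary bump alone gives {score(lo):.3f}"
        )
    tries = 0
    while score(hi) > vdsc_t and tries < 10:
        hi *= 2.0
        tries += 1
    if score(hi) > vdsc_t:
        raise ValueError(
            f"could not bracket VDSC target {vdsc_t}; achievable range "
            f"[{score(hi):.3f}, {score(lo):.3f}] with this noise field"
        )
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if score(mid) > vdsc_t:
            lo = mid
        else:
            hi = mid
        if abs(score(mid) - vdsc_t) <= vdsc_tol:
            lo = hi = mid
            break
    amp = 0.5 * (lo + hi)
    return StructMask(out_name, deformed(amp), mask.spacing, mask.origin)


# ---------------------------------------------------------------------------
# DVH-level sampler

def _deround(triple, min_gap=0.03):
    """Printed quartiles are rounded to 0.1 Gy; collapsed ones are offset by
    a sub-rounding spread so Q1 < median < Q3 always holds."""
    med, q1, q3 = triple
    if q1 >= med:
        q1 = med - min_gap
    if q3 <= med:
        q3 = med + min_gap
    return (med, q1, q3)


def _t(med, q1, q3):
    return _deround((med, q1, q3))


#: per-setup (median, Q1, Q3) of the six scored DVH parameters, matched to a
#: published 101-patient left-breast cohort (values in Gy, printed precision
#: 0.1 Gy; collapsed quartiles de-rounded by 0.03 Gy)
DEFAULT_SETUP_DISTRIBUTIONS: dict[str, dict[str, tuple[float, float, float]]] = {
    "CS_CP": {
        "ptv_dmean": _t(40.3, 40.2, 40.4),
        "ptv_d98": _t(38.1, 38.1, 38.3),
        "ptv_d2": _t(42.1, 41.9, 42.4),
        "lungs_dmean": _t(2.3, 1.9, 2.7),
        "heart_dmean": _t(1.1, 0.8, 1.4),
        "breastcl_dmean": _t(0.3, 0.2, 0.4),
    },
    "DLS_DLP": {
        "ptv_dmean": _t(40.4, 40.4, 40.4),
        "ptv_d98": _t(38.2, 37.9, 38.4),
        "ptv_d2": _t(42.2, 42.0, 42.4),
        "lungs_dmean": _t(2.5, 2.1, 2.9),
        "heart_dmean": _t(1.2, 0.9, 1.7),
        "breastcl_dmean": _t(0.4, 0.3, 0.5),
    },
    "CS_DLP": {
        "ptv_dmean": _t(40.4, 40.4, 40.4),
        "ptv_d98": _t(38.3, 38.1, 38.4),
        "ptv_d2": _t(42.2, 42.0, 42.4),
        "lungs_dmean": _t(2.3, 1.9, 2.7),
        "heart_dmean": _t(1.1, 0.9, 1.6),
        "breastcl_dmean": _t(0.3, 0.2, 0.5),
    },
    "PS_DLP": {
        "ptv_dmean": _t(40.4, 40.4, 40.4),
        "ptv_d98": _t(38.3, 38.1, 38.4),
        "ptv_d2": _t(42.2, 42.0, 42.4),
        "lungs_dmean": _t(2.3, 1.9, 2.7),
        "heart_dmean": _t(1.1, 0.8, 1.6),
        "breastcl_dmean": _t(0.3, 0.2, 0.5),
    },
}

#: (VDSC, HD95 mm) medians of DL-vs-clinical contours per structure
DEFAULT_CONTOUR_TARGETS: dict[str, tuple[float, float]] = {
    "PTVp-Skin05": (0.95, 6.0),
    "Lungs": (0.98, 1.2),
    "Heart": (0.95, 9.0),
    "BreastCL": (1.0, 0.0),
}

_PTV_KEYS = ("ptv_dmean", "ptv_d98", "ptv_d2")
_OAR_KEYS = ("lungs_dmean", "heart_dmean", "breastcl_dmean")
_Z_IQR = 1.3489795003921634  # Phi^-1(0.75) - Phi^-1(0.25)


@dataclass(frozen=True)
class CohortSimConfig:
    """Every distributional assumption of the synthetic cohort."""

    n_patients: int = 101
    seed: int = 0
    setup_distributions: Mapping[str, Mapping[str, tuple[float, float, float]]] = field(
        default_factory=lambda: DEFAULT_SETUP_DISTRIBUTIONS
    )
    rho: float = 0.9  # inter-setup correlation via a shared patient latent
    contour_targets: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: DEFAULT_CONTOUR_TARGETS
    )
    defect_fraction: float = 0.23  # clinically relevant DLS target defects
    defect_cold_volume: tuple[float, float] = (0.03, 0.12)  # fraction of PTV
    defect_cold_dose_gy: tuple[float, float] = (12.0, 28.0)
    dvh_bin_width_gy: float = 0.01
    phantom_spec: PhantomSpec = PhantomSpec()

    def __post_init__(self):
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")
        if not 0.0 <= self.defect_fraction <= 1.0:
            raise ValueError("defect_fraction must lie in [0, 1]")
        for setup, table in self.setup_distributions.items():
            for key, (med, q1, q3) in table.items():
                if not q1 < med < q3:
                    raise ValueError(
                        f"invalid quartile triple for {setup}/{key}: "
                        f"need Q1 < median < Q3, got ({q1}, {med}, {q3})"
                    )


def _marginal(triple, key, x):
    """Map a standard-normal draw through the configured marginal."""
    med, q1, q3 = triple
    if key in _OAR_KEYS:  # log-normal: positive and right-skewed
        sig = (math.log(q3) - math.log(q1)) / _Z_IQR
        return math.exp(math.log(med) + sig * x)
    sig = (q3 - q1) / _Z_IQR
    return med + sig * x


def sample_patient(
    config: CohortSimConfig, rng: np.random.Generator
) -> dict[str, dict[str, float]]:
    """Draw the six DVH parameters for all four setups of one patient.

    One latent standard-normal per metric is shared across setups with
    weight sqrt(rho); setup-specific noise carries the rest.  The PTV triple
    is re-drawn (up to 50 times, then sorted) until D98 <= Dmean <= D2.
    """
    setups = list(config.setup_distributions)
    keys = _PTV_KEYS + _OAR_KEYS
    z = {k: rng.standard_normal() for k in keys}
    w_shared = math.sqrt(config.rho)
    w_own = math.sqrt(1.0 - config.rho)
    for _ in range(50):
        eps = rng.standard_normal((len(keys), len(setups)))
        out = {}
        ok = True
        for j, s in enumerate(setups):
            table = config.setup_distributions[s]
            vals = {
                k: _marginal(table[k], k, w_shared * z[k] + w_own * eps[i, j])
                for i, k in enumerate(keys)
            }
            if not vals["ptv_d98"] <= vals["ptv_dmean"] <= vals["ptv_d2"]:
                ok = False
            out[s] = vals
        if ok:
            return out
    for s, vals in out.items():  # pathological config: fall back to sorting
        d98, dm, d2 = sorted([vals["ptv_d98"], vals["ptv_dmean"], vals["ptv_d2"]])
        vals.update(ptv_d98=d98, ptv_dmean=dm, ptv_d2=d2)
    return out


def sample_dvh_params(
    setup: str, config: CohortSimConfig, rng: np.random.Generator
) -> dict[str, float]:
    """One setup's six-metric vector (marginal of :func:`sample_patient`)."""
    return sample_patient(config, rng)[setup]


def synthesize_ptv_curve(
    dmean: float,
    d98: float,
    d2: float,
    cold: tuple[float, float] | None = None,
    n_points: int = 400,
    bin_width: float = 0.01,
) -> DVHCurve:
    """Build a plausible cumulative PTV DVH from its three summary doses.

    The voxel-dose quantile function is piecewise linear through
    (0.02, D98) and (0.98, D2) with short 0.3 Gy tails, and an interior knot
    placed so the distribution mean equals ``dmean``.  ``cold`` = (volume
    fraction, dose Gy) prepends a cold-spot segment, the signature of a
    target-delineation defect evaluated on the true target.
    """
    if not d98 <= dmean <= d2:
        raise ValueError("need D98 <= Dmean <= D2")
    tail = 0.3
    c = (dmean - 0.26 * (d98 + d2)) / 0.48
    c = min(max(c, d98), d2)
    p_nodes = np.array([0.0, 0.02, 0.5, 0.98, 1.0])
    d_nodes = np.array([d98 - tail, d98, c, d2, d2 + tail])
    p = (np.arange(n_points) + 0.5) / n_points
    if cold is not None:
        frac, cold_dose = cold
        if not 0.0 < frac < 1.0 or cold_dose <= 0:
            raise ValueError("cold spot needs 0 < fraction < 1 and dose > 0")
        doses = np.where(
            p < frac,
            cold_dose + (p / frac - 0.5),  # 1 Gy ramp across the cold segment
            np.interp((p - frac) / (1.0 - frac), p_nodes, d_nodes),
        )
    else:
        doses = np.interp(p, p_nodes, d_nodes)
    return dvh_from_doses(np.clip(doses, 0.0, None), "PTVp-Skin05", bin_width)


# ---------------------------------------------------------------------------
# Cohort generation


@dataclass
class CohortData:
    """A generated cohort: evaluated patients plus optional heavy payloads."""

    evals: list[PatientEval]
    config: CohortSimConfig
    defect_flags: list[bool]
    ptv_curves: dict[str, dict[str, DVHCurve]] | None = None  # patient -> setup
    volumes: dict[str, dict] | None = None  # voxel mode only


def _metrics_from_values(
    vals: Mapping[str, float],
    curve: DVHCurve,
    goals: GoalSet,
    tcp_params: TCPParams,
    registry,
) -> PlanMetrics:
    flags, met = evaluate_goals(vals, goals)
    return PlanMetrics(
        **{k: float(vals[k]) for k in _PTV_KEYS + _OAR_KEYS},
        goal_flags=flags,
        goals_met=met,
        tcp=tcp_from_curve(curve, tcp_params),
        risks=risk_panel(vals["heart_dmean"], vals["lungs_dmean"], registry),
    )


def generate_cohort(
    config: CohortSimConfig = CohortSimConfig(),
    mode: str = "dvh",
    goals: GoalSet = DEFAULT_GOALS,
    tcp_params: TCPParams = DEFAULT_TCP_PARAMS,
    risk_registry=DEFAULT_RISK_REGISTRY,
    keep_curves: bool = False,
) -> CohortData:
    """Generate and fully evaluate a virtual cohort.

    ``mode='dvh'`` samples DVH parameters directly (fast; used for cohort
    statistics).  ``mode='voxel'`` builds a phantom per patient, perturbs
    the clinical contours into DL-like ones, paints a dose per setup — the
    fully automatic setup is planned on the *perturbed* target — and
    evaluates everything on the clinical structures, mirroring gold-standard
    scoring.  Deterministic given ``config.seed``.
    """
    if mode not in ("dvh", "voxel"):
        raise ValueError("mode must be 'dvh' or 'voxel'")
    rng = np.random.default_rng(config.seed)
    if mode == "voxel":
        return _generate_voxel_cohort(config, rng, goals, tcp_params, risk_registry)

    evals = []
    flags = []
    curves: dict[str, dict[str, DVHCurve]] = {}
    for i in range(config.n_patients):
        pid = f"SYN{i + 1:03d}"
        params = sample_patient(config, rng)
        defect = bool(rng.uniform() < config.defect_fraction)
        flags.append(defect)
        per_setup = {}
        pcurves = {}
        for setup, vals in params.items():
            cold = None
            if defect and setup == "DLS_DLP":
                f_lo, f_hi = config.defect_cold_volume
                d_lo, d_hi = config.defect_cold_dose_gy
                cold = (rng.uniform(f_lo, f_hi), rng.uniform(d_lo, d_hi))
            curve = synthesize_ptv_curve(
                vals["ptv_dmean"], vals["ptv_d98"], vals["ptv_d2"],
                cold=cold, bin_width=config.dvh_bin_width_gy,
            )
            if cold is not None:
                # a real cold spot shows up in the reported DVH parameters
                v, d = curve.differential()
                vals = dict(vals)
                vals["ptv_dmean"] = float(np.sum(v * d) / np.sum(v))
                vals["ptv_d98"] = d_percent(curve, 98.0)
                vals["ptv_d2"] = d_percent(curve, 2.0)
            per_setup[setup] = _metrics_from_values(vals, curve, goals, tcp_params, risk_registry)
            pcurves[setup] = curve
        ev = PatientEval(patient_id=pid, metrics=per_setup)
        ev.route = assign_route(ev)
        evals.append(ev)
        if keep_curves:
            curves[pid] = pcurves
    return CohortData(
        evals=evals,
        config=config,
        defect_flags=flags,
        ptv_curves=curves if keep_curves else None,
    )


def _generate_voxel_cohort(config, rng, goals, tcp_params, risk_registry) -> CohortData:
    evals = []
    volumes: dict[str, dict] = {}
    for i in range(config.n_patients):
        pid = f"SYN{i + 1:03d}"
        spec = _jitter_spec(config.phantom_spec, rng)
        cs = build_phantom(spec)
        dls = {"Body": cs["Body"]}
        for name in ("CTVp", "Lungs", "Heart", "BreastCL"):
            key = "PTVp-Skin05" if name == "CTVp" else name
            target = config.contour_targets.get(key, (1.0, 0.0))
            if cs[name].is_empty or target[0] >= 1.0 and target[1] <= 0.0:
                dls[name] = cs[name]
            else:
                dls[name] = perturb_mask(cs[name], target, rng)
        dls["PTVp-Skin05"] = StructMask(
            "PTVp-Skin05",
            _expand_to_ptv(
                dls["CTVp"].values, cs["Body"].values, spec.spacing_mm,
                spec.ptv_margin_mm, spec.skin_clearance_mm,
            ),
            spec.spacing_mm,
        )
        params = sample_patient(config, rng)
        per_setup = {}
        doses = {}
        for setup, vals in params.items():
            planning_ptv = dls["PTVp-Skin05"] if setup == "DLS_DLP" else cs["PTVp-Skin05"]
            quality = PlanQuality(
                plateau_gy=vals["ptv_dmean"],
                heterogeneity_rel=(vals["ptv_d2"] - vals["ptv_d98"]) / (4.1 * vals["ptv_dmean"]),
                lungs_dmean_gy=vals["lungs_dmean"],
            )
            dose = paint_dose(cs, quality, rng, planning_ptv=planning_ptv)
            doses[setup] = dose
            # evaluation is always against the clinical structures
            curve = compute_dvh(dose, cs["PTVp-Skin05"], config.dvh_bin_width_gy)
            measured = {
                "ptv_dmean": d_mean(dose, cs["PTVp-Skin05"]),
                "ptv_d98": d_percent(curve, 98.0),
                "ptv_d2": d_percent(curve, 2.0),
                "lungs_dmean": d_mean(dose, cs["Lungs"]),
                "heart_dmean": d_mean(dose, cs["Heart"]),
                "breastcl_dmean": (
                    d_mean(dose, cs["BreastCL"]) if not cs["BreastCL"].is_empty else 0.0
                ),
            }
            per_setup[setup] = _metrics_from_values(
                measured, curve, goals, tcp_params, risk_registry
            )
        ev = PatientEval(patient_id=pid, metrics=per_setup)
        ev.route = assign_route(ev)
        evals.append(ev)
        volumes[pid] = {"masks_cs": cs, "masks_dls": dls, "doses": doses}
    return CohortData(evals=evals, config=config, defect_flags=[], volumes=volumes)


def _jitter_spec(spec: PhantomSpec, rng: np.random.Generator) -> PhantomSpec:
    """Per-patient anatomical variability: +-8 % on structure semi-axes."""
    def scale(axes):
        return tuple(a * rng.uniform(0.92, 1.08) for a in axes)

    return replace(
        spec,
        ctv_semi_mm=scale(spec.ctv_semi_mm),
        heart_semi_mm=scale(spec.heart_semi_mm),
        lung_semi_mm=scale(spec.lung_semi_mm),
    )
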