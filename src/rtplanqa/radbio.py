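"""Radiobiological plan scores: EUD-based TCP and linear excess-risk NTCP.

Tumour control probability follows the EUD logistic model

    EUD = (sum_i v_i D_i^a)^(1/a),      TCP = 1 / (1 + (TCD50/EUD)^(4*gamma50))

where ``a`` is the volume-effect exponent (negative for tumours, so cold
spots dominate), ``TCD50`` the uniform dose controlling half the tumours and
``gamma50`` the normalised slope at that point.  An optional per-bin EQD2
conversion re-expresses each DVH dose in 2-Gy-fraction equivalents under the
linear-quadratic model before the EUD is formed.

Normal-tissue risk uses zero-anchored linear excess models on mean organ
dose: an absolute excess risk of acute coronary events per Gy of mean heart
dose, and absolute excess mortality risks for cardiac disease (mean heart
dose) and secondary lung cancer (mean lung dose), each evaluated for a
stratum with and a stratum without the relevant risk factor (cardiac risk
factors, respectively smoking).  Six estimates per plan.

All model parameters are configuration, not constants.  The shipped
defaults are of the order published for breast radiotherapy (excess rates
0.074/Gy coronary events, 0.041/Gy cardiac mortality, 0.11/Gy lung-cancer
mortality, with lifetime baselines per stratum) and are meant to be
reviewed against local protocol before clinical-style use.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
from scipy.special import expit, logsumexp

from .dvh import DVHCurve

__all__ = [
    "TCPParams",
    "RiskModelParams",
    "RiskEstimate",
    "DEFAULT_TCP_PARAMS",
    "DEFAULT_RISK_REGISTRY",
    "ENDPOINTS",
    "eqd2_curve",
    "eud",
    "eud_from_bins",
    "tcp",
    "tcp_from_curve",
    "excess_risk",
    "risk_panel",
    "load_radbio_config",
]

#: doses below this (Gy) are clamped before a negative-exponent power mean,
#: so a cold volume at 0 Gy drives the EUD toward 0 instead of dividing by 0
EUD_COLD_CLAMP_GY = 1e-3

ENDPOINTS = (
    "acute_coronary_events",
    "cardiac_disease_mortality",
    "secondary_lung_cancer_mortality",
)


@dataclass(frozen=True)
class TCPParams:
    a: float = -7.2
    tcd50: float = 28.0
    gamma50: float = 2.5
    eqd2_enabled: bool = False
    alpha_beta: float = 10.0
    n_fractions: int = 15
    dose_per_fraction_ref: float = 2.0

    def __post_init__(self):
        if self.a == 0:
            raise ValueError("a must be nonzero (log-form EUD not supported)")
        if self.tcd50 <= 0 or self.gamma50 <= 0 or self.alpha_beta <= 0:
            raise ValueError("tcd50, gamma50 and alpha_beta must be positive")
        if self.n_fractions < 1:
            raise ValueError("n_fractions must be >= 1")


@dataclass(frozen=True)
class RiskModelParams:
    endpoint: str
    organ: str  # heart | lungs
    err_per_gy: float  # fractional excess per Gy of mean organ dose
    baseline_with_rf: float  # % lifetime risk, stratum with risk factor
    baseline_without_rf: float  # % without

    def __post_init__(self):
        if self.endpoint not in ENDPOINTS:
            raise ValueError(f"unknown endpoint {self.endpoint!r}")
        if self.organ not in ("heart", "lungs"):
            raise ValueError("organ must be 'heart' or 'lungs'")
        if self.err_per_gy < 0 or self.baseline_with_rf < 0 or self.baseline_without_rf < 0:
            raise ValueError("rates and baselines must be >= 0")
        if self.baseline_with_rf < self.baseline_without_rf:
            raise ValueError("baseline_with_rf must be >= baseline_without_rf")


@dataclass(frozen=True)
class RiskEstimate:
    endpoint: str
    with_risk_factor: bool
    value: float  # % absolute excess risk

    def __post_init__(self):
        if self.value < 0:
            raise ValueError("excess risk cannot be negative")


DEFAULT_RISK_REGISTRY: dict[str, RiskModelParams] = {
    "acute_coronary_events": RiskModelParams(
        "acute_coronary_events", "heart", 0.074, 9.6, 4.5
    ),
    "cardiac_disease_mortality": RiskModelParams(
        "cardiac_disease_mortality", "heart", 0.041, 8.0, 2.0
    ),
    "secondary_lung_cancer_mortality": RiskModelParams(
        "secondary_lung_cancer_mortality", "lungs", 0.11, 9.4, 0.5
    ),
}

DEFAULT_TCP_PARAMS = TCPParams()


def eqd2_dose(d: np.ndarray | float, params: TCPParams) -> np.ndarray | float:
    """LQ conversion of a total dose delivered in ``n_fractions`` to its
    2-Gy-per-fraction equivalent: D * (D/n + a/b) / (2 + a/b)."""
    d = np.asarray(d, dtype=np.float64)
    out = d * (d / params.n_fractions + params.alpha_beta) / (
        params.dose_per_fraction_ref + params.alpha_beta
    )
    return out if out.ndim else float(out)


def eqd2_curve(curve: DVHCurve, params: TCPParams) -> DVHCurve:
    """Map every bin dose of a DVH through the EQD2 conversion.

    Volume fractions are untouched; the map is monotone for positive doses,
    so edge ordering is preserved.  A dose of exactly 2 Gy per fraction is a
    fixed point.
    """
    edges = eqd2_dose(curve.bin_edges, params)
    return DVHCurve(structure=curve.structure, bin_edges=edges, cum_volume=curve.cum_volume)


def eud_from_bins(volumes: np.ndarray, doses: np.ndarray, a: float) -> float:
    """Generalised power mean (sum v_i D_i^a)^(1/a) over explicit bins.

    ``volumes`` are renormalised to sum to 1.  For negative ``a`` doses are
    clamped below EUD_COLD_CLAMP_GY so zero-dose bins act as the cold-spot
    limit rather than a division by zero.
    """
    if a == 0:
        raise ValueError("a must be nonzero")
    v = np.asarray(volumes, dtype=np.float64)
    d = np.asarray(doses, dtype=np.float64)
    if v.shape != d.shape or v.ndim != 1:
        raise ValueError("volumes and doses must be matching 1-D arrays")
    if np.any(v < 0) or v.sum() <= 0:
        raise ValueError("volumes must be non-negative with positive total")
    if np.any(d < 0):
        raise ValueError("doses must be non-negative")
    v = v / v.sum()
    if a < 0:
        d = np.maximum(d, EUD_COLD_CLAMP_GY)
    # log-sum-exp form keeps large |a| (near-max / near-min limits) finite
    with np.errstate(divide="ignore"):
        logd = np.log(d)
    return float(np.exp(logsumexp(a * logd, b=v) / a))


def eud(curve: DVHCurve, a: float) -> float:
    """EUD of a cumulative DVH (differential bins at bin-centre doses)."""
    v, d = curve.differential()
    return eud_from_bins(v, d, a)


def tcp(eud_gy: float, params: TCPParams = DEFAULT_TCP_PARAMS) -> float:
    """Logistic EUD-TCP; 0.5 at EUD = TCD50, 0 at EUD = 0, 1 in the limit."""
    if eud_gy < 0:
        raise ValueError("EUD must be >= 0")
    if eud_gy == 0.0:
        return 0.0
    k = 4.0 * params.gamma50
    # expit form avoids overflow of (tcd50/eud)**k far from the midpoint
    return float(expit(k * (np.log(eud_gy) - np.log(params.tcd50))))


def tcp_from_curve(curve: DVHCurve, params: TCPParams = DEFAULT_TCP_PARAMS) -> float:
    """TCP of a target DVH: optional EQD2 per bin, then EUD, then logistic."""
    c = eqd2_curve(curve, params) if params.eqd2_enabled else curve
    return tcp(eud(c, params.a), params)


def excess_risk(
    mean_dose: float, model: RiskModelParams, with_rf: bool
) -> RiskEstimate:
    """Absolute excess risk (%) = baseline(stratum) * err_per_gy * mean dose."""
    if mean_dose < 0:
        raise ValueError("mean dose must be >= 0")
    base = model.baseline_with_rf if with_rf else model.baseline_without_rf
    return RiskEstimate(
        endpoint=model.endpoint,
        with_risk_factor=with_rf,
        value=base * model.err_per_gy * mean_dose,
    )


def risk_panel(
    heart_dmean: float,
    lungs_dmean: float,
    registry: Mapping[str, RiskModelParams] = DEFAULT_RISK_REGISTRY,
) -> tuple[RiskEstimate, ...]:
    """The six per-plan risk estimates: three endpoints x {with, without} RF.

    Cardiac endpoints read the mean heart dose, the lung endpoint the mean
    lung dose.  Order is fixed: (coronary W, WO, cardiac-mortality W, WO,
    lung-cancer-mortality W, WO).
    """
    missing = [e for e in ENDPOINTS if e not in registry]
    if missing:
        raise KeyError(f"risk registry missing endpoint(s): {missing}")
    out = []
    for endpoint in ENDPOINTS:
        model = registry[endpoint]
        dose = heart_dmean if model.organ == "heart" else lungs_dmean
        out.append(excess_risk(dose, model, True))
        out.append(excess_risk(dose, model, False))
    return tuple(out)


def load_radbio_config(path) -> tuple[TCPParams, dict[str, RiskModelParams]]:
    """Read ``[tcp]`` and ``[[risk_model]]`` tables from a TOML file.

    Missing entries fall back to the shipped defaults.
    """
    import tomllib

    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    tcp_params = replace(DEFAULT_TCP_PARAMS, **cfg.get("tcp", {}))
    registry = dict(DEFAULT_RISK_REGISTRY)
    for block in cfg.get("risk_model", []):
        model = RiskModelParams(**block)
        registry[model.endpoint] = model
    return tcp_params, registry
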