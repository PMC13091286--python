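import numpy as np
import pytest
from scipy import ndimage

from rtplanqa.dvh import compute_dvh, d_mean, d_percent
from rtplanqa.segmetrics import hd95, vdsc
from rtplanqa.synthetic import (
    CohortSimConfig,
    PhantomSpec,
    PlanQuality,
    build_phantom,
    generate_cohort,
    paint_dose,
    perturb_mask,
    sample_patient,
    synthesize_ptv_curve,
)
from rtplanqa.workflow import SETUPS, summarize_cohort

COARSE = PhantomSpec(spacing_mm=(5.0, 5.0, 5.0))


# --- phantom -----------------------------------------------------------------

def test_phantom_masks_consistent(coarse_phantom):
    ph = coarse_phantom
    assert all(not ph[k].is_empty for k in ("Body", "CTVp", "PTVp-Skin05", "Lungs", "Heart"))
    ctv, ptv = ph["CTVp"].values, ph["PTVp-Skin05"].values
    # PTV covers the CTV except for the skin collar
    outside_ptv = ctv & ~ptv
    if outside_ptv.any():
        d_skin = ndimage.distance_transform_edt(ph["Body"].values, sampling=ph["Body"].spacing)
        assert d_skin[outside_ptv].max() < COARSE.skin_clearance_mm
    # organs pairwise disjoint
    for a, b in [("CTVp", "Lungs"), ("CTVp", "Heart"), ("Lungs", "Heart"),
                 ("CTVp", "BreastCL"), ("Heart", "BreastCL")]:
        assert not (ph[a].values & ph[b].values).any()


def test_phantom_zero_margins_gives_ptv_equal_ctv():
    spec = PhantomSpec(spacing_mm=(5.0, 5.0, 5.0), ptv_margin_mm=0.0, skin_clearance_mm=0.0)
    ph = build_phantom(spec)
    assert np.array_equal(ph["PTVp-Skin05"].values, ph["CTVp"].values)


def test_ptv_skin_clearance_distance_oracle(rng):
    # PTV voxel centres stay >= clearance from every non-body voxel centre
    for _ in range(3):
        spec = PhantomSpec(
            spacing_mm=(5.0, 5.0, 5.0),
            ctv_semi_mm=tuple(float(rng.uniform(45, 65)) for _ in range(3)),
        )
        ph = build_phantom(spec)
        d_skin = ndimage.distance_transform_edt(ph["Body"].values, sampling=spec.spacing_mm)
        assert d_skin[ph["PTVp-Skin05"].values].min() >= spec.skin_clearance_mm


# --- dose painting -----------------------------------------------------------

def test_paint_dose_step_limit():
    # negligible scatter and a steep falloff approach a pure step function
    # (PTV = CTV here, so the target is disjoint from every organ at risk)
    ph = build_phantom(PhantomSpec(spacing_mm=(5.0, 5.0, 5.0),
                                   ptv_margin_mm=0.0, skin_clearance_mm=0.0))
    q = PlanQuality(heterogeneity_rel=0.0, lungs_dmean_gy=0.02, scatter_rel=0.0)
    dose = paint_dose(ph, q, seed=1)
    ptv = ph["PTVp-Skin05"]
    assert d_mean(dose, ptv) == pytest.approx(q.plateau_gy, abs=1e-9)
    assert d_mean(dose, ph["Lungs"]) == pytest.approx(0.02, rel=0.05)
    assert d_mean(dose, ph["Heart"]) < 0.1


def test_paint_dose_hits_requested_targets(coarse_phantom):
    q = PlanQuality(plateau_gy=40.4, heterogeneity_rel=0.022, lungs_dmean_gy=2.5)
    dose = paint_dose(coarse_phantom, q, seed=2)
    assert d_mean(dose, coarse_phantom["Lungs"]) == pytest.approx(2.5, rel=0.05)
    assert d_mean(dose, coarse_phantom["PTVp-Skin05"]) == pytest.approx(40.4, abs=0.05)
    assert float(dose.values.min()) >= 0.0


def test_paint_dose_rejects_unreachable_target(coarse_phantom):
    with pytest.raises(ValueError, match="not below"):
        paint_dose(coarse_phantom, PlanQuality(lungs_dmean_gy=50.0), seed=0)


# --- contour perturbation ----------------------------------------------------

def test_perturb_identity_target(coarse_phantom):
    heart = coarse_phantom["Heart"]
    out = perturb_mask(heart, (1.0, 0.0), seed=0)
    assert np.array_equal(out.values, heart.values)


def test_perturb_hits_vdsc_target(coarse_phantom):
    ctv = coarse_phantom["CTVp"]
    out = perturb_mask(ctv, (0.95, 6.0), seed=3)
    assert 0.93 <= vdsc(ctv, out) <= 0.97


def test_perturb_heart_vdsc_and_hd95(coarse_phantom):
    heart = coarse_phantom["Heart"]
    for seed in (1, 5):
        out = perturb_mask(heart, (0.95, 9.0), seed=seed)
        assert vdsc(heart, out) == pytest.approx(0.95, abs=0.02)
        assert hd95(heart, out) == pytest.approx(9.0, abs=2.0)


def test_perturb_vdsc_target_across_seeds(coarse_phantom):
    heart = coarse_phantom["Heart"]
    for seed in range(8):
        out = perturb_mask(heart, (0.95, 9.0), seed=seed)
        assert vdsc(heart, out) == pytest.approx(0.95, abs=0.02)


# --- DVH-level sampler -------------------------------------------------------

def test_sampler_degenerate_config_returns_medians():
    eps = 1e-9
    dist = {
        s: {k: (m, m - eps, m + eps) for k, (m, _, _) in table.items()}
        for s, table in CohortSimConfig().setup_distributions.items()
    }
    cfg = CohortSimConfig(setup_distributions=dist, rho=1.0)
    vals = sample_patient(cfg, np.random.default_rng(0))
    for s, table in vals.items():
        for k, v in table.items():
            med = cfg.setup_distributions[s][k][0]
            assert v == pytest.approx(med, abs=1e-6)
    # rho = 1 with no residual scale: all setups see the same latent draw
    a, b = vals["CS_CP"], vals["PS_DLP"]
    for k in a:
        da = a[k] - cfg.setup_distributions["CS_CP"][k][0]
        db = b[k] - cfg.setup_distributions["PS_DLP"][k][0]
        assert da == pytest.approx(db, abs=1e-6)


def test_sampler_recovers_quartiles():
    cfg = CohortSimConfig(seed=11)
    rng = np.random.default_rng(cfg.seed)
    draws = [sample_patient(cfg, rng) for _ in range(2000)]
    lungs = np.array([d["DLS_DLP"]["lungs_dmean"] for d in draws])
    assert np.median(lungs) == pytest.approx(2.5, abs=0.1)
    for setup in SETUPS:
        for key in ("ptv_d98", "lungs_dmean", "heart_dmean"):
            med_t, q1_t, q3_t = cfg.setup_distributions[setup][key]
            vals = np.array([d[setup][key] for d in draws])
            assert np.median(vals) == pytest.approx(med_t, rel=0.10)
            assert np.percentile(vals, 25) == pytest.approx(q1_t, rel=0.10)
            assert np.percentile(vals, 75) == pytest.approx(q3_t, rel=0.10)


def test_sampler_orders_ptv_metrics():
    rng = np.random.default_rng(2)
    cfg = CohortSimConfig()
    for _ in range(200):
        vals = sample_patient(cfg, rng)
        for table in vals.values():
            assert table["ptv_d98"] <= table["ptv_dmean"] <= table["ptv_d2"]


def test_synthesized_curve_reproduces_parameters():
    c = synthesize_ptv_curve(40.4, 38.2, 42.2)
    v, d = c.differential()
    assert float(np.sum(v * d)) == pytest.approx(40.4, abs=0.02)
    assert d_percent(c, 98) == pytest.approx(38.2, abs=0.05)
    assert d_percent(c, 2) == pytest.approx(42.2, abs=0.05)
    cold = synthesize_ptv_curve(40.4, 38.2, 42.2, cold=(0.08, 20.0))
    assert d_percent(cold, 98) == pytest.approx(20.0, abs=1.0)


# --- cohort generation -------------------------------------------------------

def test_cohort_deterministic():
    cfg = CohortSimConfig(n_patients=15, seed=42)
    a = generate_cohort(cfg)
    b = generate_cohort(cfg)
    for pa, pb in zip(a.evals, b.evals):
        assert pa.route == pb.route
        for s in SETUPS:
            assert pa.metrics[s] == pb.metrics[s]


def test_cohort_end_to_end_smoke():
    data = generate_cohort(CohortSimConfig(n_patients=101, seed=1))
    summary = summarize_cohort(data.evals)
    assert summary.n_patients == 101
    assert sum(summary.route_counts.values()) == 101


def test_cohort_goal_rate_calibration():
    # the all-goals rate of the fully automatic setup tracks its configured
    # target (43 % of patients) within ten percentage points
    data = generate_cohort(CohortSimConfig(n_patients=800, seed=5))
    frac = np.mean([p.metrics["DLS_DLP"].goals_met == 6 for p in data.evals])
    assert abs(frac - 0.43) <= 0.10


def test_cohort_defect_mechanism():
    data = generate_cohort(CohortSimConfig(n_patients=400, seed=9))
    tcp_dls = np.array([p.metrics["DLS_DLP"].tcp for p in data.evals])
    tcp_ps = np.array([p.metrics["PS_DLP"].tcp for p in data.evals])
    defect = np.array(data.defect_flags)
    assert defect.mean() == pytest.approx(0.23, abs=0.06)
    # target-defect patients lose control probability in DLS-DLP only,
    # and correcting the target (PS-DLP) restores it
    assert np.median(tcp_dls[defect]) < np.median(tcp_dls[~defect])
    assert np.median(tcp_ps[defect]) > 0.95


def test_voxel_mode_smoke():
    cfg = CohortSimConfig(n_patients=1, seed=3, phantom_spec=COARSE)
    data = generate_cohort(cfg, mode="voxel")
    assert len(data.evals) == 1
    p = data.evals[0]
    assert p.route in ("A", "B", "C")
    for s in SETUPS:
        m = p.metrics[s]
        assert 35.0 < m.ptv_dmean < 45.0
        assert m.ptv_d98 <= m.ptv_dmean <= m.ptv_d2
        assert 0.0 <= m.tcp <= 1.0
        assert len(m.risks) == 6
    dose = data.volumes[p.patient_id]["doses"]["DLS_DLP"]
    masks = data.volumes[p.patient_id]["masks_cs"]
    curve = compute_dvh(dose, masks["PTVp-Skin05"], 0.05)
    assert d_percent(curve, 2) >= d_percent(curve, 98)


def test_config_validation():
    with pytest.raises(ValueError, match="rho"):
        CohortSimConfig(rho=1.5)
    bad = {s: dict(t) for s, t in CohortSimConfig().setup_distributions.items()}
    bad["CS_CP"] = dict(bad["CS_CP"], lungs_dmean=(2.3, 2.4, 2.7))
    with pytest.raises(ValueError, match="Q1 < median < Q3"):
        CohortSimConfig(setup_distributions=bad)
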