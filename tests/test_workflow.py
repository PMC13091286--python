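import itertools

import numpy as np
import pytest
from scipy import stats as sps

from rtplanqa.dvh import PlanMetrics
from rtplanqa.workflow import (
    DEFAULT_ROUTE_TIMES,
    SETUPS,
    PatientEval,
    RouteTimes,
    assign_route,
    bonferroni,
    compare_setups,
    friedman_test,
    summarize_cohort,
    time_saving,
    wilcoxon_signed_rank,
)


def plan_with_goals(k: int) -> PlanMetrics:
    flags = tuple([True] * k + [False] * (6 - k))
    return PlanMetrics(
        ptv_dmean=40.3, ptv_d98=38.1, ptv_d2=42.1,
        lungs_dmean=2.3, heart_dmean=1.1, breastcl_dmean=0.3,
        goal_flags=flags, goals_met=k, tcp=0.97,
    )


def patient(dls: int, ps: int, cs: int = 6, csdlp: int = 6, pid="p") -> PatientEval:
    return PatientEval(patient_id=pid, metrics={
        "CS_CP": plan_with_goals(cs),
        "DLS_DLP": plan_with_goals(dls),
        "CS_DLP": plan_with_goals(csdlp),
        "PS_DLP": plan_with_goals(ps),
    })


def test_route_rules():
    assert assign_route(patient(6, 5)) == "A"
    assert assign_route(patient(5, 6)) == "B"
    assert assign_route(patient(5, 5)) == "C"


def test_route_truth_table_exhaustive():
    for dls, ps in itertools.product(range(7), range(7)):
        expected = "A" if dls == 6 else ("B" if ps == 6 else "C")
        assert assign_route(patient(dls, ps)) == expected


def test_route_requires_setups():
    p = patient(6, 6)
    del p.metrics["PS_DLP"]
    with pytest.raises(KeyError, match="PS_DLP"):
        assign_route(p)


def test_time_saving_degenerate_cases():
    assert time_saving({"current": 10}) == (0.0, 0.0)
    dt_a, dt_i = time_saving({"A": 7})
    assert (dt_a, dt_i) == (65.0, 21.0)  # 85-20 min, 37-16 h


def test_time_saving_cohort_counts():
    dt_a, dt_i = time_saving({"A": 43, "B": 26, "C": 32})
    assert dt_a == pytest.approx(85 - 3910 / 101)
    assert dt_i == pytest.approx(37 - 2464 / 101)
    assert dt_a >= 45 and dt_i >= 12


def test_time_saving_affine_in_counts():
    c1 = {"A": 4, "B": 2, "C": 1}
    c2 = {"A": 8, "B": 4, "C": 2}  # scaling counts changes nothing
    assert time_saving(c1) == time_saving(c2)
    with pytest.raises(ValueError):
        time_saving({"A": 0})


def test_route_times_validation():
    with pytest.raises(ValueError, match="route A"):
        RouteTimes(t_active_min={"current": 10.0, "A": 20.0, "B": 1, "C": 1, "D": 1})


def test_summary_single_patient():
    s = summarize_cohort([patient(6, 6)])
    med, q1, q3 = s.quartiles["CS_CP"]["lungs_dmean"]
    assert med == q1 == q3 == 2.3
    assert s.route_counts == {"A": 1, "B": 0, "C": 0}


def test_summary_goal_percentages():
    cohort = [patient(6, 6, pid="a"), patient(6, 6, pid="b"), patient(5, 5, pid="c")]
    s = summarize_cohort(cohort)
    assert s.goals_met_pct["DLS_DLP"][6] == 67
    assert s.goals_met_pct["DLS_DLP"][5] == 100
    pct = s.goals_met_pct["DLS_DLP"]
    assert pct[3] >= pct[4] >= pct[5] >= pct[6]


def test_summary_quartiles_match_sort_oracle(rng):
    cohort = []
    doses = rng.uniform(1.5, 3.5, size=31)
    for i, d in enumerate(doses):
        p = patient(6, 6, pid=f"p{i}")
        for s in SETUPS:
            m = p.metrics[s]
            p.metrics[s] = PlanMetrics(
                **{**m.as_dict(), "lungs_dmean": float(d)},
                goal_flags=m.goal_flags, goals_met=m.goals_met, tcp=m.tcp,
            )
        cohort.append(p)
    s = summarize_cohort(cohort)
    med, q1, q3 = s.quartiles["CS_CP"]["lungs_dmean"]
    assert med == pytest.approx(np.percentile(doses, 50))
    assert q1 == pytest.approx(np.percentile(doses, 25))
    assert q3 == pytest.approx(np.percentile(doses, 75))


# --- statistics --------------------------------------------------------------

def test_friedman_identical_columns_degenerate():
    data = np.tile(np.arange(6.0)[:, None], (1, 4))
    stat, p, method = friedman_test(data)
    assert stat == 0.0 and p == 1.0


def test_friedman_statistic_matches_rank_formula():
    rng = np.random.default_rng(3)
    data = rng.normal(size=(6, 4))
    stat, _, _ = friedman_test(data)
    ranks = sps.rankdata(data, axis=1)
    rbar = ranks.mean(axis=0)
    n, k = data.shape
    expected = 12 * n / (k * (k + 1)) * np.sum((rbar - (k + 1) / 2) ** 2)
    assert stat == pytest.approx(expected, rel=1e-12)


def test_friedman_matches_scipy_on_tie_free_data():
    rng = np.random.default_rng(11)
    data = rng.normal(size=(20, 4))
    stat, p, method = friedman_test(data)
    ref = sps.friedmanchisquare(*data.T)
    assert method == "chi2"
    assert stat == pytest.approx(ref.statistic, rel=1e-10)
    assert p == pytest.approx(ref.pvalue, rel=1e-10)


def test_friedman_exact_close_to_chi2_in_decision_region():
    """The chi-square approximation tracks the exact permutation null to
    within 0.02 where test decisions live (small p); mid-range p can differ
    by up to ~0.05 at n = 8 because the null is discrete."""
    checked = 0
    for seed in range(30):
        rng = np.random.default_rng(seed)
        data = rng.normal(size=(8, 4)) + rng.normal(0, 0.6, size=(1, 4))
        stat, p_exact, method = friedman_test(data, exact_max_n=8)
        assert method == "exact"
        _, p_chi2, _ = friedman_test(data, exact_max_n=0)
        if p_exact < 0.2:
            assert abs(p_exact - p_chi2) < 0.02
            checked += 1
    assert checked >= 5


def test_friedman_exact_matches_monte_carlo():
    from rtplanqa.workflow import _plain_friedman_stat

    rng = np.random.default_rng(5)
    data = rng.normal(size=(8, 4))
    ranks = sps.rankdata(data, axis=1)
    n, k = data.shape
    obs = _plain_friedman_stat(ranks.sum(0), n, k)
    _, p_exact, _ = friedman_test(data, exact_max_n=8)
    mc = np.random.default_rng(0)
    hits = 0
    trials = 20000
    for _ in range(trials):
        r = np.array([mc.permutation(row) for row in ranks])
        if _plain_friedman_stat(r.sum(0), n, k) >= obs - 1e-9:
            hits += 1
    assert p_exact == pytest.approx(hits / trials, abs=0.015)


def exhaustive_wilcoxon_p(d):
    """Two-sided signed-rank p by enumerating all 2^n sign assignments."""
    d = np.asarray(d, dtype=float)
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    ew = n * (n + 1) / 4.0
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = ranks[np.array(signs, dtype=bool)].sum()
        if abs(w - ew) >= abs(w_obs - ew) - 1e-12:
            count += 1
    return count / 2**n


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_wilcoxon_matches_sign_flip_enumeration(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(5, 11))
    d = rng.normal(0.4, 1.0, size=n)
    d = np.where(d == 0, 0.1, d)
    _, p = wilcoxon_signed_rank(d, np.zeros(n))
    assert p == pytest.approx(exhaustive_wilcoxon_p(d), abs=1e-12)


def test_wilcoxon_all_zero_differences():
    x = np.ones(8)
    stat, p = wilcoxon_signed_rank(x, x)
    assert p == 1.0


def test_bonferroni_properties():
    assert bonferroni(0.01) == pytest.approx(0.06)
    assert bonferroni(0.3) == 1.0
    for p in (0.0, 1e-4, 0.2, 0.9):
        assert bonferroni(p) >= p


def test_compare_setups_chain(rng):
    n = 40
    base = rng.normal(40, 0.5, size=n)
    values = np.column_stack([base, base + 0.4, base + rng.normal(0, 0.01, n), base + 0.6])
    sc = compare_setups(values, SETUPS, alpha=0.05, metric="ptv_dmean")
    assert sc.friedman_p < 0.05 and len(sc.posthoc) == 6
    for (a, b), (w, p, pb) in sc.posthoc.items():
        assert pb == pytest.approx(min(1.0, 6 * p))
    assert len(sc.shapiro_p) == 6


def test_compare_setups_no_posthoc_when_null(rng):
    values = np.tile(rng.normal(size=20)[:, None], (1, 4)) + rng.normal(0, 1e-12, (20, 4))
    sc = compare_setups(values, SETUPS)
    if sc.friedman_p >= sc.alpha:
        assert sc.posthoc == {}


def test_compare_setups_input_validation(rng):
    with pytest.raises(ValueError, match="at least 5"):
        compare_setups(rng.normal(size=(3, 4)), SETUPS)
    with pytest.raises(ValueError, match="one column per label"):
        compare_setups(rng.normal(size=(10, 3)), SETUPS)
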