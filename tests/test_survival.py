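"""KM / log-rank / Cox / CCC against hand oracles and lifelines."""

import numpy as np
import pandas as pd
import pytest
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as ll_logrank

from ibris.survival import (clinical_codings, cox_fit, km_estimate, lin_ccc,
                            logrank_chi2, logrank_test, odx_categorize,
                            subgroup_analysis)


def test_km_no_events_survival_stays_one():
    km = km_estimate([5, 8, 12], [0, 0, 0])
    assert km.times.size == 0
    assert km.survival_at(100) == 1.0


def test_km_all_events_product_limit():
    km = km_estimate([1, 2, 3], [1, 1, 1])
    np.testing.assert_allclose(km.survival, [2 / 3, 1 / 3, 0.0])
    np.testing.assert_array_equal(km.at_risk, [3, 2, 1])


def test_km_tie_convention_events_before_censorings():
    # event and censoring both at t=1: the censored subject is still at risk
    km = km_estimate([1, 1], [1, 0])
    assert km.survival_at(1) == pytest.approx(0.5)


def test_km_matches_lifelines():
    rng = np.random.default_rng(0)
    t = rng.exponential(10, 60)
    e = rng.integers(0, 2, 60)
    e[0] = 1
    km = km_estimate(t, e)
    kmf = KaplanMeierFitter().fit(t, e)
    for tt, s in zip(km.times, km.survival):
        assert kmf.predict(tt) == pytest.approx(s, abs=1e-10)


def test_km_without_censoring_equals_empirical_survival():
    rng = np.random.default_rng(1)
    t = rng.exponential(10, 40)
    km = km_estimate(t, np.ones(40, dtype=int))
    for tt, s in zip(km.times, km.survival):
        assert s == pytest.approx(np.mean(t > tt))


def test_logrank_identical_groups_is_null():
    t = np.array([2.0, 5.0, 7.0, 9.0] * 2)
    e = np.array([1, 0, 1, 1] * 2)
    g = np.array([0] * 4 + [1] * 4)
    res = logrank_test(t, e, g)
    assert res["chi2"] == pytest.approx(0.0, abs=1e-12)
    assert res["p"] == pytest.approx(1.0)


def test_logrank_label_swap_symmetry():
    rng = np.random.default_rng(2)
    t = rng.exponential(10, 30)
    e = rng.integers(0, 2, 30)
    e[:3] = 1
    g = rng.integers(0, 2, 30).astype(bool)
    a, b = logrank_test(t, e, g), logrank_test(t, e, ~g)
    assert a["chi2"] == pytest.approx(b["chi2"], rel=1e-9)
    assert a["p"] == pytest.approx(b["p"], rel=1e-9)


def test_logrank_textbook_six_subjects_hand_oracle():
    """O-E computed by hand for {A: 1,3,5 events; B: 2,4+,6 (4 censored)}."""
    t = np.array([1.0, 3.0, 5.0, 2.0, 4.0, 6.0])
    e = np.array([1, 1, 1, 1, 0, 1])
    g = np.array([0, 0, 0, 1, 1, 1]).astype(bool)  # group B = True
    # risk sets at event times 1,2,3,5,6 (censor at 4):
    # t=1: n=6 nB=3 d=1 dB=0 -> E=1/2, V=(1*3*3*5)/(36*5)=1/4
    # t=2: n=5 nB=3 d=1 dB=1 -> E=3/5, V=(3*2*4)/(25*4)=6/25
    # t=3: n=4 nB=2 d=1 dB=0 -> E=1/2, V=(2*2*3)/(16*3)=1/4
    # t=5: n=2 nB=1 d=1 dB=0 -> E=1/2, V=1/4
    # t=6: n=1 nB=1 d=1 dB=1 -> E=1,  V=0
    o_minus_e = (0 - 0.5) + (1 - 0.6) + (0 - 0.5) + (0 - 0.5) + (1 - 1.0)
    var = 0.25 + 6 / 25 + 0.25 + 0.25
    assert logrank_chi2(t, e, g) == pytest.approx(o_minus_e ** 2 / var, abs=1e-12)


def test_logrank_matches_lifelines():
    rng = np.random.default_rng(3)
    t = rng.exponential(10, 50)
    e = rng.integers(0, 2, 50)
    e[:5] = 1
    g = rng.integers(0, 2, 50).astype(bool)
    mine = logrank_test(t, e, g)
    theirs = ll_logrank(t[g], t[~g], e[g], e[~g])
    assert mine["chi2"] == pytest.approx(theirs.test_statistic, rel=1e-9)
    assert mine["p"] == pytest.approx(theirs.p_value, rel=1e-9)


def test_cox_binary_covariate_matches_likelihood_scan():
    """No ties, no censoring: Newton fit equals the brute-force maximizer."""
    rng = np.random.default_rng(4)
    x = np.array([0.0] * 8 + [1.0] * 8)
    t = rng.exponential(np.where(x > 0, 4.0, 10.0))
    e = np.ones(16, dtype=int)
    res = cox_fit(t, e, pd.DataFrame({"x": x}))["x"]

    order = np.argsort(t)
    ts, xs = t[order], x[order]

    def pl(beta):
        lp = beta * xs
        out = 0.0
        for i in range(16):
            out += lp[i] - np.log(np.exp(lp[i:]).sum())
        return out

    grid = np.linspace(-4, 4, 20001)
    beta_star = grid[np.argmax([pl(b) for b in grid])]
    assert np.log(res.hr) == pytest.approx(beta_star, abs=1e-3)


def test_cox_wald_ci_coverage_near_nominal():
    """True HR = 2 two-group exponential data: ~95% CI coverage."""
    from ibris.model import univariable_cox

    rng = np.random.default_rng(5)
    cover = 0
    reps = 200
    for _ in range(reps):
        x = rng.integers(0, 2, 150).astype(float)
        t = rng.exponential(1.0 / (0.05 * np.exp(np.log(2.0) * x)))
        e = np.ones(150, dtype=int)
        r = univariable_cox(x[:, None], t, e)
        lo = r["beta"][0] - 1.96 * r["se"][0]
        hi = r["beta"][0] + 1.96 * r["se"][0]
        cover += lo <= np.log(2.0) <= hi
    assert 0.90 <= cover / reps <= 0.99


def test_cox_constant_covariate_is_rejected():
    with pytest.raises(ValueError, match="constant"):
        cox_fit([1, 2, 3, 4], [1, 1, 0, 1], pd.DataFrame({"x": [1.0] * 4}))


def test_cox_multivariable_reports_each_covariate():
    rng = np.random.default_rng(6)
    n = 120
    x1 = rng.normal(size=n)
    x2 = rng.integers(0, 2, n).astype(float)
    t = rng.exponential(1.0 / (0.05 * np.exp(0.7 * x1)))
    e = np.ones(n, dtype=int)
    res = cox_fit(t, e, pd.DataFrame({"x1": x1, "x2": x2}), multivariable=True)
    assert set(res) == {"x1", "x2"}
    assert res["x1"].ci_low <= res["x1"].hr <= res["x1"].ci_high
    assert res["x1"].p < 0.001 and res["x2"].p > 0.001


def test_lin_ccc_perfect_agreement_and_disagreement():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    assert lin_ccc(x, x)["ccc"] == pytest.approx(1.0)
    y = -(x - x.mean())
    assert lin_ccc(x - x.mean(), y)["ccc"] == pytest.approx(-1.0)


def test_lin_ccc_binary_agreement_table_matches_formula():
    # 2x2 agreement: 6 both-1, 5 both-0, 2 x-only, 3 y-only
    x = np.array([1] * 6 + [0] * 5 + [1] * 2 + [0] * 3, dtype=float)
    y = np.array([1] * 6 + [0] * 5 + [0] * 2 + [1] * 3, dtype=float)
    res = lin_ccc(x, y)
    sxy = np.mean((x - x.mean()) * (y - y.mean()))
    oracle = 2 * sxy / (x.var() + y.var() + (x.mean() - y.mean()) ** 2)
    assert res["ccc"] == pytest.approx(oracle, rel=1e-12)
    assert res["ci_low"] < res["ccc"] < res["ci_high"]


def test_lin_ccc_rejects_double_zero_variance():
    with pytest.raises(ValueError):
        lin_ccc([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])


@pytest.mark.parametrize("score,category", [
    (0, "low"), (17, "low"), (18, "intermediate"), (30, "intermediate"),
    (31, "high"), (50, "high"),
])
def test_odx_categorization_boundaries(score, category):
    assert odx_categorize(score) == category


def test_odx_negative_score_rejected():
    with pytest.raises(ValueError):
        odx_categorize(-1)


def _subgroup_frames(rng, n=240, effect=np.log(3.0)):
    group = rng.integers(0, 2, n)
    t = rng.exponential(1.0 / (0.02 * np.exp(effect * group)))
    preds = pd.DataFrame({"patient_id": [f"p{i}" for i in range(n)],
                          "score": group.astype(float),
                          "group": np.where(group == 1, "high", "low")})
    clinical = pd.DataFrame({
        "patient_id": [f"p{i}" for i in range(n)],
        "dfs_time": t, "event": np.ones(n, dtype=int),
        "odx_score": rng.integers(0, 50, n),
        "grade": rng.integers(1, 4, n),
        "her2_status": rng.choice(["neg", "pos", "unknown"], n),
        "age": rng.normal(55, 10, n), "tumor_size_mm": rng.normal(20, 5, n),
        "pr_status": rng.choice(["pos", "neg"], n),
    })
    return preds, clinical


def test_subgroup_random_strata_agree_with_pooled_effect():
    rng = np.random.default_rng(7)
    preds, clinical = _subgroup_frames(rng)
    pooled = cox_fit(clinical["dfs_time"], clinical["event"],
                     pd.DataFrame({"hi": (preds["group"] == "high").astype(float)})
                     )["hi"]
    strata = subgroup_analysis(preds, clinical, by="grade")
    assert set(strata) == {"low", "intermediate", "high"}
    for res in strata.values():
        assert res.evaluable
        # within ~3 SE of the pooled log-HR (random stratum = exchangeable)
        se = (np.log(res.hazard_ratio.ci_high) - np.log(res.hazard_ratio.hr)) / 1.96
        assert abs(np.log(res.hazard_ratio.hr) - np.log(pooled.hr)) < 3.5 * se


def test_subgroup_all_censored_stratum_flagged_non_evaluable():
    rng = np.random.default_rng(8)
    preds, clinical = _subgroup_frames(rng, n=60)
    clinical.loc[clinical["grade"] == 2, "event"] = 0
    strata = subgroup_analysis(preds, clinical, by="grade")
    assert not strata["intermediate"].evaluable
    assert strata["intermediate"].reason == "no events"


def test_subgroup_unknown_stratifier_errors():
    rng = np.random.default_rng(9)
    preds, clinical = _subgroup_frames(rng, n=30)
    with pytest.raises(ValueError, match="stratifier"):
        subgroup_analysis(preds, clinical, by="nottingham")


def test_subgroup_her2_filter_keeps_only_negative():
    rng = np.random.default_rng(10)
    preds, clinical = _subgroup_frames(rng)
    strata = subgroup_analysis(preds, clinical, by="her2_filter")
    assert set(strata) == {"her2_neg"}
    assert strata["her2_neg"].n == int((clinical["her2_status"] == "neg").sum())


def test_subgroup_missing_odx_excluded():
    rng = np.random.default_rng(11)
    preds, clinical = _subgroup_frames(rng, n=80)
    clinical.loc[:19, "odx_score"] = np.nan
    strata = subgroup_analysis(preds, clinical, by="odx_category")
    assert sum(r.n for r in strata.values()) == 60


def test_clinical_codings_follow_reporting_conventions():
    clinical = pd.DataFrame({
        "age": [45, 55], "tumor_size_mm": [15, 25], "pr_status": ["neg", "pos"],
        "her2_status": ["pos", "unknown"], "grade": [3, 1], "odx_score": [35, 10],
    })
    cod = clinical_codings(clinical)
    assert cod["age_ge50"].tolist() == [0.0, 1.0]
    assert cod["size_ge20"].tolist() == [0.0, 1.0]
    assert cod["pr_neg"].tolist() == [1.0, 0.0]
    assert cod["her2_pos"][0] == 1.0 and np.isnan(cod["her2_pos"][1])
    assert cod["grade_high_vs_rest"].tolist() == [1.0, 0.0]
    assert cod["odx_high_vs_rest"].tolist() == [1.0, 0.0]
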