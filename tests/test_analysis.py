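"""Study-level analyses: tertiles, comparisons, models, report plumbing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from tmemscore.analysis import (AnalysisConfig, CorrelationSummary,
                                correlation, group_compare, model_table,
                                power_by_simulation, rs_categorize,
                                run_full_analysis, run_models, subgroup_hr,
                                weighted_tertiles, MODEL_TERMS)
from tmemscore.cohort_sim import CohortParams, case_control_design


# ---------------------------------------------------------------------------
# weighted tertiles
# ---------------------------------------------------------------------------

def test_equal_weights_one_to_nine():
    spec = weighted_tertiles(np.arange(1, 10), np.ones(9))
    assert (spec.c1, spec.c2) == (3, 6)
    np.testing.assert_allclose(spec.fractions, [1 / 3, 1 / 3, 1 / 3])
    np.testing.assert_array_equal(spec.assign([1, 3, 4, 6, 7, 9]),
                                  [0, 0, 1, 1, 2, 2])


def test_heavy_ties_collapse_with_warning():
    scores = np.array([0, 0, 0, 0, 10, 20])
    with pytest.warns(UserWarning, match="tie"):
        spec = weighted_tertiles(scores, np.ones(6))
    assert (spec.c1, spec.c2) == (0, 10)
    np.testing.assert_allclose(spec.fractions, [4 / 6, 1 / 6, 1 / 6])
    assert spec.tie_collapsed


def test_degenerate_distribution_rejected():
    with pytest.raises(ValueError, match="degenerate"):
        weighted_tertiles(np.full(10, 7), np.ones(10))


@settings(max_examples=50, deadline=None)
@given(st.lists(st.integers(0, 40), min_size=6, max_size=60),
       st.integers(0, 10 ** 6))
def test_tertile_fractions_sum_to_one(scores, seed):
    scores = np.asarray(scores)
    if len(np.unique(scores)) < 3:
        return
    w = np.random.default_rng(seed).uniform(0.5, 4.0, len(scores))
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        try:
            spec = weighted_tertiles(scores, w)
        except ValueError:
            return
    assert sum(spec.fractions) == pytest.approx(1.0)
    assert spec.c1 < spec.c2


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------

def test_identical_groups_give_zero_statistic():
    x = np.tile([1.0, 2.0, 3.0], 2)
    g = np.repeat(["a", "b"], 3)
    t = group_compare(x, g, np.ones(6))
    assert t.statistic == 0.0
    assert t.pvalue == 1.0


def test_two_group_proportions_match_z_squared():
    rng = np.random.default_rng(0)
    x = (rng.random(200) < 0.4).astype(float)
    g = np.repeat(["a", "b"], 100)
    t = group_compare(x, g, np.ones(200), kind="proportion")
    pa, pb = x[:100].mean(), x[100:].mean()
    va = ((x[:100] - pa) ** 2).sum() / 100 ** 2
    vb = ((x[100:] - pb) ** 2).sum() / 100 ** 2
    z2 = (pa - pb) ** 2 / (va + vb)
    assert t.statistic == pytest.approx(z2, abs=1e-8)


def test_empty_group_and_bad_kind_rejected():
    with pytest.raises(ValueError):
        group_compare([1.0, 2.0], ["a", "a"], kind="mean")
    with pytest.raises(ValueError):
        group_compare([0.5, 1.0], ["a", "b"], kind="proportion")


def test_type_one_error_calibrated_under_equal_means():
    rng = np.random.default_rng(99)
    rej = 0
    reps = 1000
    for _ in range(reps):
        x = rng.normal(size=240)
        g = np.repeat(["a", "b", "c"], 80)
        w = rng.uniform(1, 3, 240)
        rej += group_compare(x, g, w).pvalue < 0.05
    assert abs(rej / reps - 0.05) < 0.02


# ---------------------------------------------------------------------------
# correlation and RS categories
# ---------------------------------------------------------------------------

def test_perfect_linear_correlation():
    x = np.arange(10.0)
    assert correlation(x, 2 * x + 1).r == pytest.approx(1.0)


def test_independent_pairs_have_near_zero_r():
    rng = np.random.default_rng(1)
    assert abs(correlation(rng.normal(size=10 ** 4),
                           rng.normal(size=10 ** 4)).r) < 0.05


def test_constant_vector_rejected_and_truncation_is_plot_only():
    with pytest.raises(ValueError):
        correlation(np.ones(5), np.arange(5.0))
    x = np.array([10.0, 60.0, 80.0])
    summ = correlation(x, x + 1.0, truncate_at=50)
    assert summ.r == pytest.approx(1.0)  # raw, untruncated
    np.testing.assert_array_equal(summ.truncated(x), [10.0, 50.0, 50.0])


@pytest.mark.parametrize("rs,scheme,label", [
    (17.9, "classical", "low"), (18, "classical", "mid"),
    (30, "classical", "mid"), (31, "classical", "high"),
    (10, "tailorx", "low"), (11, "tailorx", "mid"),
    (25, "tailorx", "mid"), (26, "tailorx", "high"),
])
def test_rs_boundaries(rs, scheme, label):
    assert rs_categorize(rs, scheme) == label


def test_rs_schemes_agree_on_extremes_and_reject_negatives():
    v = np.array([5, 8, 35, 60])
    np.testing.assert_array_equal(rs_categorize(v, "classical"),
                                  rs_categorize(v, "tailorx"))
    with pytest.raises(ValueError):
        rs_categorize(-1)
    with pytest.raises(ValueError):
        rs_categorize(5, "unknown")


# ---------------------------------------------------------------------------
# models / subgroups / power
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def hr_sample():
    from tmemscore.cohort_sim import generate_cohort, draw_subsample

    rng = np.random.default_rng(44)
    cohort = generate_cohort(CohortParams(n=2952, seed=44), rng=rng)
    return draw_subsample(cohort, case_control_design(0.25), rng=rng)


def test_model3_extends_model1_by_rs_categories(hr_sample):
    models = run_models(hr_sample, endpoint="rfi")
    t1 = list(models["model1"].params.index)
    t3 = list(models["model3"].params.index)
    assert set(t3) - set(t1) == {"rs_mid", "rs_high"}
    assert MODEL_TERMS["model3"][-1] == "score"
    table = model_table(models)
    assert set(table["model"]) == {"model1", "model2", "model3"}
    assert np.all((table["p"] >= 0) & (table["p"] <= 1))


def test_missing_covariates_named(hr_sample):
    with pytest.raises(ValueError, match="grade"):
        run_models(hr_sample.drop(columns=["grade"]))


def test_subgroup_hr_runs_and_flags_sparse_cells(hr_sample):
    from tmemscore.analysis import weighted_tertiles

    spec = weighted_tertiles(hr_sample["score"].to_numpy(),
                             hr_sample["weight"].to_numpy())
    hr_sub = hr_sample[hr_sample["subtype"] == "hr_her2neg"]
    tab = subgroup_hr(hr_sub, spec, "classical", "rfi")
    assert list(tab["rs_category"]) == ["low", "mid", "high"]
    est = tab[tab["estimable"]]
    assert np.all(est["ci_low"] <= est["hr"])
    assert np.all(est["hr"] <= est["ci_high"])
    flagged = tab[~tab["estimable"]]
    assert np.all(flagged["note"] != "")


def test_subgroup_ci_formula():
    """exp(beta +/- 1.96 se): beta=1, se=0.5 -> HR 2.72, CI (1.02, 7.24)."""
    hr = np.exp(1.0)
    lo, hi = np.exp(1.0 - 1.96 * 0.5), np.exp(1.0 + 1.96 * 0.5)
    assert hr == pytest.approx(2.718, abs=0.001)
    assert (round(lo, 2), round(hi, 2)) == (1.02, 7.24)


def test_power_validates_and_is_high_for_extreme_effect():
    params = CohortParams(n=500, covariate_log_hr={})
    design = case_control_design(0.5)
    with pytest.raises(ValueError):
        power_by_simulation(params, design, hr=0.0, nsim=10)
    p = power_by_simulation(params, design, hr=10.0, nsim=25, seed=7)
    assert p > 0.85


def test_power_monotone_in_hazard_ratio():
    params = CohortParams(n=500, covariate_log_hr={})
    design = case_control_design(0.5)
    powers = [power_by_simulation(params, design, hr, nsim=40, seed=11)
              for hr in (1.5, 3.0)]
    assert powers[1] >= powers[0]


# ---------------------------------------------------------------------------
# full report
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def report():
    return run_full_analysis(AnalysisConfig(seed=5))


def test_report_sections_present_and_nonempty(report):
    for name in report._TABLES:
        assert len(getattr(report, name)) > 0
    assert report.header["config_hash"]


def test_report_pvalues_and_cis_are_sane(report):
    for col in ("early_p", "late_p", "tv_overall_p", "tv_proportionality_p"):
        v = report.window_fits[col].dropna()
        assert np.all((v >= 0) & (v <= 1))
    est = report.subgroup_hrs[report.subgroup_hrs["estimable"]]
    assert np.all(est["ci_low"] <= est["hr"])
    assert np.all(est["hr"] <= est["ci_high"])


def test_report_subtype_means_track_configuration(report):
    """Generator round trip: weighted subtype means estimate the configured
    means within sampling tolerance (3 linearization SEs)."""
    cfg_means = CohortParams().score_mean
    tab = report.subtype_table.set_index("subtype")
    for s, mu in cfg_means.items():
        tol = 3 * tab.loc[s, "se_mean_score"] + 0.5
        assert abs(tab.loc[s, "weighted_mean_score"] - mu) < tol


def test_report_tables_are_deterministic(tmp_path, report):
    rep2 = run_full_analysis(AnalysisConfig(seed=5))
    a, b = tmp_path / "a", tmp_path / "b"
    report.to_dir(a, plots=False)
    rep2.to_dir(b, plots=False)
    for f in sorted(a.iterdir()):
        assert (b / f.name).read_bytes() == f.read_bytes()
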