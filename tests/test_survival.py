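"""Weighted Cox core: oracles, invariances, residuals, episode handling."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize, minimize_scalar

from tmemscore.survival import (ConvergenceError, WeightedCoxPH,
                                WeightedCoxResults, episode_split,
                                fit_time_varying, fit_weighted_cox,
                                restrict_window, robust_covariance,
                                score_residuals, weighted_km)

from conftest import breslow_loglik_reference, random_survival_frame


# ---------------------------------------------------------------------------
# weighted Kaplan-Meier
# ---------------------------------------------------------------------------

def test_km_four_events_quarter_steps():
    df = pd.DataFrame({"stop": [1, 2, 3, 4], "event": 1, "weight": 1.0})
    curve = weighted_km(df)
    np.testing.assert_allclose(curve.survival, [0.75, 0.5, 0.25, 0.0])


def test_km_weight_scale_invariance():
    rng = np.random.default_rng(3)
    df = pd.DataFrame({"stop": rng.exponential(2, 30) + 0.1,
                       "event": (rng.random(30) < 0.6).astype(int),
                       "weight": rng.choice([1.0, 2.0], 30)})
    a = weighted_km(df)
    df2 = df.assign(weight=df.weight * 2)
    b = weighted_km(df2)
    np.testing.assert_array_equal(a.survival, b.survival)


def test_km_weighted_risk_set():
    df = pd.DataFrame({"stop": [1.0, 5.0], "event": [1, 0],
                       "weight": [1.0, 3.0]})
    curve = weighted_km(df)
    assert curve.survival[0] == pytest.approx(0.75)


def test_km_rejects_negative_times():
    with pytest.raises(ValueError):
        weighted_km(pd.DataFrame({"stop": [-1.0], "event": [1],
                                  "weight": [1.0]}))


def test_km_invariants_on_random_data():
    rng = np.random.default_rng(9)
    for _ in range(5):
        df = random_survival_frame(rng, n=40, tie_grid=2)
        c = weighted_km(df)
        assert np.all(np.diff(c.survival) <= 1e-12)
        assert np.all((c.survival >= 0) & (c.survival <= 1))


# ---------------------------------------------------------------------------
# Cox fits: frozen R-survival oracle (weights + ties)
# ---------------------------------------------------------------------------

R_ORACLE = {
    # survival::coxph(Surv(stop,event)~x1+x2, weights=weight, robust=TRUE)
    "efron": {
        "coef": [-0.7428332557, 0.1277222939],
        "naive_se": [0.2036104400, 0.3009310052],
        "robust_se": [0.2841287730, 0.4068154289],
        "sr_first3": [[-0.73806183, -0.07023428], [-0.14832636, 0.48399722],
                      [-0.84259586, -0.66035886]],
    },
    "breslow": {
        "coef": [-0.7104785424, 0.0461950905],
        "naive_se": [0.2044675817, 0.3010065710],
        "robust_se": [0.2701578844, 0.3634764353],
        "sr_first3": [[-0.74316062, -0.04549482], [-0.12780272, 0.47225649],
                      [-0.77237934, -0.61631948]],
    },
}


@pytest.mark.parametrize("ties", ["efron", "breslow"])
def test_matches_r_survival_on_tied_weighted_data(tied_weighted_frame, ties):
    res = WeightedCoxPH(tied_weighted_frame, ["x1", "x2"], ties=ties).fit()
    ref = R_ORACLE[ties]
    np.testing.assert_allclose(res.params, ref["coef"], atol=1e-8)
    np.testing.assert_allclose(res.bse_naive, ref["naive_se"], atol=1e-8)
    np.testing.assert_allclose(res.bse, ref["robust_se"], atol=1e-8)
    np.testing.assert_allclose(
        res.score_residuals_[["x1", "x2"]].to_numpy()[:3],
        ref["sr_first3"], atol=1e-7)


def test_matches_lifelines_unweighted():
    from lifelines import CoxPHFitter

    rng = np.random.default_rng(8)
    df = random_survival_frame(rng, n=60, p=2, weighted=False)
    res = fit_weighted_cox(df, ["x0", "x1"], ties="efron")
    cph = CoxPHFitter().fit(df[["stop", "event", "x0", "x1"]],
                            duration_col="stop", event_col="event")
    np.testing.assert_allclose(res.params, cph.params_, atol=1e-5)
    np.testing.assert_allclose(res.bse_naive, cph.standard_errors_, atol=1e-5)


def test_breslow_beta_matches_brute_force_maximiser():
    rng = np.random.default_rng(12)
    for _ in range(5):
        df = random_survival_frame(rng, n=20, tie_grid=None)
        res = WeightedCoxPH(df, ["x0"], ties="breslow").fit()
        opt = minimize_scalar(
            lambda b: -breslow_loglik_reference([b], df, ["x0"]),
            bounds=(-4, 4), method="bounded",
            options={"xatol": 1e-10})
        assert abs(res.params.iloc[0] - opt.x) < 1e-4


def test_weight_scale_invariance_of_beta_and_sandwich():
    rng = np.random.default_rng(5)
    df = random_survival_frame(rng, n=40, p=2)
    a = fit_weighted_cox(df, ["x0", "x1"])
    b = fit_weighted_cox(df.assign(weight=df.weight * 10), ["x0", "x1"])
    np.testing.assert_allclose(a.params, b.params, atol=1e-10)
    np.testing.assert_allclose(a.cov_robust, b.cov_robust, atol=1e-8)


def test_unit_weights_equal_unweighted_fit():
    rng = np.random.default_rng(6)
    df = random_survival_frame(rng, n=30, weighted=False)
    with_w = fit_weighted_cox(df.assign(weight=1.0), ["x0"])
    without = fit_weighted_cox(df.drop(columns="weight"), ["x0"])
    np.testing.assert_array_equal(with_w.params.to_numpy(),
                                  without.params.to_numpy())


def test_separation_raises_convergence_error():
    df = pd.DataFrame({"stop": [1.0, 2.0], "event": [1, 0],
                       "x0": [1.0, 0.0]})
    with pytest.raises(ConvergenceError):
        fit_weighted_cox(df, ["x0"])


def test_constant_covariate_rejected():
    df = pd.DataFrame({"stop": [1.0, 2.0, 3.0], "event": [1, 1, 0],
                       "x0": [2.0, 2.0, 2.0]})
    with pytest.raises(ValueError, match="constant"):
        fit_weighted_cox(df, ["x0"])


# ---------------------------------------------------------------------------
# score residuals and robust covariance
# ---------------------------------------------------------------------------

def test_weighted_residuals_sum_to_zero_at_mle(tied_weighted_frame):
    res = WeightedCoxPH(tied_weighted_frame, ["x1", "x2"]).fit()
    sr = res.score_residuals_
    total = (sr[["x1", "x2"]].to_numpy()
             * sr["weight"].to_numpy()[:, None]).sum(0)
    np.testing.assert_allclose(total, 0.0, atol=1e-8)


def test_episode_splitting_preserves_subject_residuals():
    rng = np.random.default_rng(14)
    df = random_survival_frame(rng, n=25)
    res = fit_weighted_cox(df, ["x0"])
    cuts = np.unique(df["stop"].to_numpy()[df["event"] == 1])
    split = episode_split(df, cuts)
    res2 = WeightedCoxPH(split, ["x0"]).fit()
    np.testing.assert_allclose(res.params, res2.params, atol=1e-8)
    np.testing.assert_allclose(
        score_residuals(res).to_numpy(),
        score_residuals(res2).to_numpy(), atol=1e-10)


def test_robust_covariance_is_symmetric_psd(tied_weighted_frame):
    res = WeightedCoxPH(tied_weighted_frame, ["x1", "x2"]).fit()
    V = robust_covariance(res).to_numpy()
    np.testing.assert_allclose(V, V.T)
    assert np.all(np.linalg.eigvalsh(V) >= -1e-12)


@pytest.mark.parametrize("seed", [22, 23, 24, 25])
def test_robust_se_close_to_jackknife_unweighted(seed):
    rng = np.random.default_rng(seed)
    df = random_survival_frame(rng, n=80, weighted=False)
    res = fit_weighted_cox(df, ["x0"])
    jk = []
    for i in range(len(df)):
        sub = df.drop(index=i)
        if sub["event"].sum() == 0:
            continue
        jk.append(fit_weighted_cox(sub, ["x0"]).params.iloc[0])
    jk = np.asarray(jk)
    m = len(jk)
    jk_se = np.sqrt((m - 1) / m * ((jk - jk.mean()) ** 2).sum())
    assert abs(res.bse.iloc[0] - jk_se) / jk_se < 0.15


# ---------------------------------------------------------------------------
# episode splitting and window restriction
# ---------------------------------------------------------------------------

def test_split_example_and_cut_outside_range():
    df = pd.DataFrame({"id": [1], "start": [0.0], "stop": [5.0],
                       "event": [1], "weight": [2.0]})
    out = episode_split(df, [2.0])
    np.testing.assert_array_equal(out[["start", "stop", "event"]].to_numpy(),
                                  [[0, 2, 0], [2, 5, 1]])
    assert list(out["weight"]) == [2.0, 2.0]
    unchanged = episode_split(df, [7.0])
    np.testing.assert_array_equal(
        unchanged[["start", "stop", "event"]].to_numpy(), [[0, 5, 1]])


def test_window_restriction_rules():
    df = pd.DataFrame({"id": [1, 2, 3], "start": 0.0,
                       "stop": [8.0, 3.0, 7.0], "event": [1, 1, 0],
                       "weight": 1.0})
    early = restrict_window(df, 0, 5)
    assert early.loc[early.id == 1, "stop"].iloc[0] == 5.0
    assert early.loc[early.id == 1, "event"].iloc[0] == 0
    late = restrict_window(df, 5, 10)
    assert set(late["id"]) == {1, 3}
    row3 = late[late.id == 3].iloc[0]
    assert (row3["start"], row3["stop"], row3["event"]) == (5.0, 7.0, 0)
    with pytest.raises(ValueError):
        restrict_window(df, 5, 5)


# ---------------------------------------------------------------------------
# time-varying coefficient model
# ---------------------------------------------------------------------------

def test_wald_statistic_with_diagonal_covariance():
    res = WeightedCoxResults(
        model=None, params=pd.Series([0.5, -0.1], index=["v", "v_x_time"]),
        cov_naive=pd.DataFrame(np.diag([0.04, 0.0025]),
                               index=["v", "v_x_time"],
                               columns=["v", "v_x_time"]),
        cov_robust=pd.DataFrame(np.diag([0.04, 0.0025]),
                                index=["v", "v_x_time"],
                                columns=["v", "v_x_time"]),
        score_residuals_=pd.DataFrame(), loglik=0.0, n_iter=1,
        converged=True, ties="efron", weighted=True)
    t = res.wald_test(["v", "v_x_time"])
    assert t.statistic == pytest.approx(10.25)
    assert t.df == 2


def test_early_only_effect_gives_negative_interaction():
    from tmemscore.cohort_sim import CohortParams, generate_cohort
    from tmemscore.analysis import endpoint_frame

    base = CohortParams(
        n=500, covariate_log_hr={},
        baseline_hazard={s: 0.03 for s in
                         ("hr_her2neg", "triple_negative", "her2pos")},
        beta_early={s: 0.02 for s in
                    ("hr_her2neg", "triple_negative", "her2pos")},
        beta_late={s: 0.0 for s in
                   ("hr_her2neg", "triple_negative", "her2pos")})
    inters = []
    for ch in np.random.SeedSequence(55).spawn(20):
        c = generate_cohort(base, rng=np.random.default_rng(ch))
        res, _, _ = fit_time_varying(endpoint_frame(c, "rfi"), "score")
        inters.append(res.params["score_x_time"])
    assert np.mean(inters) < 0
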