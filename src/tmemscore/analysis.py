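"""Cohort-level weighted analyses and the full synthetic-study report.

Implements the study-layer statistics around the weighted survival core:
weighted tertile cutpoints of the MetaSite score, design-based (weighted)
group comparisons, the raw score/Recurrence-Score correlation, the three
multivariate Cox specifications, hazard ratios of high- vs low-tertile
score within Recurrence-Score categories, power by simulation, and a
report object that reproduces the study's table/figure structure on
synthetic cohorts.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_sim import (CohortParams, SamplingDesign, case_control_design,
                         draw_subsample, generate_cohort)
from .survival import (TestResult, WeightedCoxPH, WeightedCoxResults,
                       ConvergenceError, fit_weighted_cox, restrict_window,
                       fit_time_varying, weighted_km)

__all__ = [
    "TertileSpec",
    "weighted_tertiles",
    "group_compare",
    "CorrelationSummary",
    "correlation",
    "rs_categorize",
    "RS_SCHEMES",
    "endpoint_frame",
    "run_models",
    "model_table",
    "subgroup_hr",
    "power_by_simulation",
    "AnalysisConfig",
    "AnalysisReport",
    "run_full_analysis",
]

TERTILE_LABELS = ("low", "mid", "high")

#: Recurrence-Score category boundaries: label -> (low cut, high cut); a
#: value v is "low" if v < lo, "mid" if lo <= v <= hi, "high" if v > hi
RS_SCHEMES = {"classical": (18, 30), "tailorx": (11, 25)}


# ---------------------------------------------------------------------------
# weighted tertiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TertileSpec:
    """Integer tertile cutpoints of a weighted score distribution.

    Groups are [0, c1], (c1, c2], (c2, max]; the cutpoints are the
    smallest integers whose weighted CDF reaches 1/3 and 2/3.  When heavy
    ties force the two cutpoints together, the second is pushed to the
    next distinct value (``tie_collapsed`` is set) and the group fractions
    deviate from 1/3.
    """

    c1: int
    c2: int
    fractions: tuple
    tie_collapsed: bool = False

    def assign(self, scores) -> np.ndarray:
        """Tertile index per score: 0 = low, 1 = mid, 2 = high."""
        s = np.asarray(scores)
        return np.where(s <= self.c1, 0, np.where(s <= self.c2, 1, 2))

    def labels(self, scores) -> np.ndarray:
        return np.asarray(TERTILE_LABELS)[self.assign(scores)]


def weighted_tertiles(scores, weights=None) -> TertileSpec:
    """Empirical tertile cutpoints in the weighted score distribution."""
    s = np.asarray(scores)
    if np.any(s < 0) or not np.allclose(s, np.round(s)):
        raise ValueError("scores must be non-negative integers")
    w = np.ones_like(s, float) if weights is None else np.asarray(weights, float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    vals = np.unique(s)
    if len(vals) < 2:
        raise ValueError("degenerate score distribution (single value)")
    totals = np.array([w[s == v].sum() for v in vals])
    cdf = np.cumsum(totals) / totals.sum()
    c1 = int(vals[np.argmax(cdf >= 1 / 3)])
    c2 = int(vals[np.argmax(cdf >= 2 / 3)])
    collapsed = False
    if c2 <= c1:
        above = vals[vals > c1]
        if len(above) == 0:
            raise ValueError("cannot form three groups: ties swallow the top")
        c2 = int(above[0])
        collapsed = True
        warnings.warn("tertile cutpoints collapsed by ties; group fractions "
                      "deviate from 1/3", stacklevel=2)
    idx = np.where(s <= c1, 0, np.where(s <= c2, 1, 2))
    fr = tuple(w[idx == g].sum() / w.sum() for g in range(3))
    return TertileSpec(c1, c2, fr, collapsed)


# ---------------------------------------------------------------------------
# design-based comparisons / correlation / RS categories
# ---------------------------------------------------------------------------

def _weighted_mean_var(x, w):
    """Weighted mean and its Horvitz-Thompson linearization variance."""
    sw = w.sum()
    m = float((w * x).sum() / sw)
    v = float((w ** 2 * (x - m) ** 2).sum() / sw ** 2)
    return m, v


def group_compare(values, groups, weights=None, kind: str = "mean") -> TestResult:
    """Design-based Wald chi-square comparing weighted means or proportions.

    Each group's weighted estimate gets a linearization variance; the test
    contrasts all groups against the last, with df = (number of groups - 1).
    """
    if kind not in ("mean", "proportion"):
        raise ValueError("kind must be 'mean' or 'proportion'")
    x = np.asarray(values, float)
    g = np.asarray(groups)
    w = np.ones_like(x) if weights is None else np.asarray(weights, float)
    if kind == "proportion" and not np.all(np.isin(x, (0.0, 1.0))):
        raise ValueError("proportion comparison needs 0/1 indicators")
    labels = np.unique(g)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    means, var = [], []
    for lab in labels:
        m = g == lab
        if m.sum() == 0:
            raise ValueError(f"empty group {lab!r}")
        mu, v = _weighted_mean_var(x[m], w[m])
        means.append(mu)
        var.append(v)
    means, var = np.array(means), np.array(var)
    d = means[:-1] - means[-1]
    V = np.diag(var[:-1]) + var[-1]
    if np.allclose(d, 0):
        return TestResult(0.0, len(labels) - 1, 1.0)
    stat = float(d @ np.linalg.solve(V, d))
    df = len(labels) - 1
    return TestResult(stat, df, float(stats.chi2.sf(stat, df)))


@dataclass(frozen=True)
class CorrelationSummary:
    r: float
    n: int
    truncate_at: float | None = None

    def truncated(self, x):
        return np.minimum(np.asarray(x, float), self.truncate_at) \
            if self.truncate_at is not None else np.asarray(x, float)


def correlation(ms, rs, truncate_at: float | None = None) -> CorrelationSummary:
    """Raw (untruncated, unweighted) Pearson correlation.

    ``truncate_at`` only affects plotting helpers, never the statistic.
    """
    x = np.asarray(ms, float)
    y = np.asarray(rs, float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r = float(stats.pearsonr(x, y).statistic)
    return CorrelationSummary(r, len(x), truncate_at)


def rs_categorize(rs, scheme: str = "classical"):
    """Label Recurrence Scores low/mid/high under a cutpoint scheme."""
    if scheme not in RS_SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    v = np.asarray(rs, float)
    if np.any(v < 0):
        raise ValueError("Recurrence Score must be >= 0")
    lo, hi = RS_SCHEMES[scheme]
    out = np.where(v < lo, "low", np.where(v <= hi, "mid", "high"))
    return out if np.ndim(rs) else str(out)


# ---------------------------------------------------------------------------
# model specifications
# ---------------------------------------------------------------------------

_BASE_COLS = ("nodal_positive", "size_gt2cm", "grade")


def endpoint_frame(data: pd.DataFrame, endpoint: str,
                   window: tuple | None = None) -> pd.DataFrame:
    """Long-format episode frame (id/start/stop/event/weight + covariates)."""
    tcol, ecol = f"{endpoint}_time", f"{endpoint}_event"
    if tcol not in data.columns or ecol not in data.columns:
        raise ValueError(f"missing endpoint columns {tcol}/{ecol}")
    df = data.copy().reset_index(drop=True)
    df["start"] = 0.0
    df["stop"] = df[tcol].astype(float)
    df["event"] = df[ecol].astype(int)
    if "weight" not in df.columns:
        df["weight"] = 1.0
    if window is not None:
        df = restrict_window(df, *window)
    return df


def _design_columns(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _BASE_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"missing covariate columns: {missing}")
    out = df.copy()
    out["grade_mod"] = (df["grade"] == "intermediate").astype(float)
    out["grade_poor"] = (df["grade"] == "high").astype(float)
    cat = rs_categorize(df["rs"].to_numpy(), "classical")
    out["rs_mid"] = (cat == "mid").astype(float)
    out["rs_high"] = (cat == "high").astype(float)
    return out


MODEL_TERMS = {
    "model1": ["nodal_positive", "size_gt2cm", "grade_mod", "grade_poor",
               "score"],
    "model2": ["nodal_positive", "size_gt2cm", "grade_mod", "grade_poor",
               "rs"],
    "model3": ["nodal_positive", "size_gt2cm", "grade_mod", "grade_poor",
               "rs_mid", "rs_high", "score"],
}


def run_models(data: pd.DataFrame, endpoint: str = "drfi",
               window: tuple = (0.0, 5.0), ties: str = "efron",
               subset_subtype: str | None = "hr_her2neg") -> dict:
    """Fit the three multivariate specifications on the 0-5-year window.

    All models share nodal status, tumor size (> 2 cm) and grade (two
    dummies vs low); model 1 adds the continuous MetaSite score, model 2
    the continuous Recurrence Score instead, model 3 both the continuous
    MetaSite score and the categorical (classical) Recurrence Score.
    Robust covariance throughout.
    """
    df = data
    if subset_subtype is not None and "subtype" in df.columns:
        df = df[df["subtype"] == subset_subtype]
    df = _design_columns(df)
    rows = endpoint_frame(df, endpoint, window)
    out = {}
    for name, terms in MODEL_TERMS.items():
        out[name] = WeightedCoxPH(rows, terms, ties=ties).fit()
    return out


def model_table(models: dict) -> pd.DataFrame:
    """Tidy per-term table: LHR, robust SE, p (joint 2-df for grade/RS-cat)."""
    rows = []
    for name, res in models.items():
        summ = res.summary()
        grade_p = res.wald_test(["grade_mod", "grade_poor"]).pvalue
        for term in res.params.index:
            p = summ.loc[term, "p"]
            if term in ("grade_mod", "grade_poor"):
                p = grade_p
            if term in ("rs_mid", "rs_high"):
                p = res.wald_test(["rs_mid", "rs_high"]).pvalue
            rows.append({"model": name, "term": term,
                         "lhr": summ.loc[term, "coef"],
                         "se_robust": summ.loc[term, "se(robust)"],
                         "p": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# subgroup hazard ratios
# ---------------------------------------------------------------------------

def subgroup_hr(data: pd.DataFrame, tertiles: TertileSpec,
                scheme: str = "classical", endpoint: str = "drfi",
                window: tuple = (0.0, 5.0), ties: str = "efron") -> pd.DataFrame:
    """High- vs low-tertile score hazard ratio within each RS category.

    Cells where either exposure arm has no events are flagged "too few
    recurrences" instead of fitted.
    """
    df = data.copy()
    df["rs_cat"] = rs_categorize(df["rs"].to_numpy(), scheme)
    df["tertile"] = tertiles.assign(df["score"].to_numpy())
    rows = []
    for cat in ("low", "mid", "high"):
        sub = df[(df["rs_cat"] == cat) & (df["tertile"] != 1)].copy()
        sub["high_tertile"] = (sub["tertile"] == 2).astype(float)
        row = {"rs_scheme": scheme, "rs_category": cat,
               "n": len(sub), "estimable": False, "note": "",
               "hr": np.nan, "ci_low": np.nan, "ci_high": np.nan}
        if len(sub) == 0:
            row["note"] = "empty subgroup"
            rows.append(row)
            continue
        ep = endpoint_frame(sub, endpoint, window)
        ev = ep.groupby("high_tertile")["event"].sum() if len(ep) else None
        if ep.empty or ev.reindex([0.0, 1.0]).fillna(0).min() == 0:
            row["note"] = "too few recurrences"
            rows.append(row)
            continue
        try:
            res = WeightedCoxPH(ep, ["high_tertile"], ties=ties).fit()
        except (ConvergenceError, ValueError) as exc:
            row["note"] = f"not estimable ({exc})"
            rows.append(row)
            continue
        ci = res.conf_int().iloc[0]
        row.update(estimable=True, hr=float(np.exp(res.params.iloc[0])),
                   ci_low=float(np.exp(ci["lower"])),
                   ci_high=float(np.exp(ci["upper"])))
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# power by simulation
# ---------------------------------------------------------------------------

def power_by_simulation(params: CohortParams, design: SamplingDesign,
                        hr: float, nsim: int = 1000, alpha: float = 0.05,
                        endpoint: str = "drfi", window: tuple = (0.0, 5.0),
                        seed: int | None = None) -> float:
    """Fraction of simulated studies rejecting high- vs low-tertile HR = 1.

    Each replicate generates a cohort whose recurrence hazard carries the
    target high-vs-low tertile log hazard ratio, draws the case-enriched
    subsample, and tests the weighted high-vs-low coefficient with the
    robust Wald test at ``alpha``.
    """
    if hr <= 0:
        raise ValueError("hr must be positive")
    if nsim < 1:
        raise ValueError("nsim must be >= 1")
    ss = np.random.SeedSequence(params.seed if seed is None else seed)
    reject = 0
    for child in ss.spawn(nsim):
        rng = np.random.default_rng(child)
        pi = replace(params, tertile_log_hr=float(np.log(hr)))
        cohort = generate_cohort(pi, rng=rng)
        sample = draw_subsample(cohort, design, rng=rng)
        spec = weighted_tertiles(sample["score"].to_numpy(),
                                 sample["weight"].to_numpy())
        sub = sample[spec.assign(sample["score"].to_numpy()) != 1].copy()
        sub["high_tertile"] = (spec.assign(sub["score"].to_numpy()) == 2
                               ).astype(float)
        ep = endpoint_frame(sub, endpoint, window)
        try:
            res = WeightedCoxPH(ep, ["high_tertile"]).fit()
            p = res.summary().loc["high_tertile", "p"]
        except (ConvergenceError, ValueError):
            continue
        reject += p < alpha
    return reject / nsim


# ---------------------------------------------------------------------------
# full report
# ---------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    params: CohortParams = field(default_factory=CohortParams)
    design: SamplingDesign = field(default_factory=case_control_design)
    endpoints: tuple = ("drfi", "rfi")
    early_window: tuple = (0.0, 5.0)
    late_window: tuple = (5.0, 10.0)
    ties: str = "efron"
    seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps({
            "params": asdict(self.params),
            "design": {"strata_cols": list(self.design.strata_cols),
                       "fractions": {str(k): v for k, v
                                     in self.design.fractions.items()}},
            "endpoints": list(self.endpoints),
            "early_window": list(self.early_window),
            "late_window": list(self.late_window),
            "ties": self.ties, "seed": self.seed,
        }, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class AnalysisReport:
    """All tables of a full synthetic-study run, with provenance header."""

    header: dict
    subtype_table: pd.DataFrame
    tertile_spec: TertileSpec
    tertile_table: pd.DataFrame
    correlations: pd.DataFrame
    window_fits: pd.DataFrame
    model_fits: pd.DataFrame
    subgroup_hrs: pd.DataFrame
    km_curves: pd.DataFrame
    km_tests: pd.DataFrame

    _TABLES = ("subtype_table", "tertile_table", "correlations",
               "window_fits", "model_fits", "subgroup_hrs", "km_curves",
               "km_tests")

    def to_dir(self, out_dir, plots: bool = True) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps({
            **self.header,
            "tertiles": {"c1": self.tertile_spec.c1,
                         "c2": self.tertile_spec.c2,
                         "fractions": [round(f, 10) for f in
                                       self.tertile_spec.fractions]},
        }, indent=1, sort_keys=True))
        for name in self._TABLES:
            getattr(self, name).to_csv(out / f"{name}.csv", index=False,
                                       float_format="%.10g")
        if plots:
            self._write_plots(out)

    def _write_plots(self, out: Path) -> None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        for lab, grp in self.km_curves.groupby("tertile"):
            ax.step(np.r_[0, grp["time"]], np.r_[1.0, grp["survival"]],
                    where="post", label=f"tertile {lab}")
        ax.set_xlabel("years")
        ax.set_ylabel("event-free probability")
        ax.set_ylim(0, 1.02)
        ax.legend()
        fig.savefig(out / "km_by_tertile.png", dpi=120)
        plt.close(fig)


def _weighted_pct(ind, w):
    return 100.0 * float((w * ind).sum() / w.sum())


def run_full_analysis(config: AnalysisConfig) -> AnalysisReport:
    """Generate cohort -> subsample -> weighted study analysis."""
    rng = np.random.default_rng(config.seed)
    params = replace(config.params, seed=config.seed)
    cohort = generate_cohort(params, rng=rng)
    sample = draw_subsample(cohort, config.design, rng=rng)
    w = sample["weight"].to_numpy()
    score = sample["score"].to_numpy()

    # descriptives by subtype (weighted), score-mean comparison p-values
    rows = []
    for s in sorted(sample["subtype"].unique()):
        m = (sample["subtype"] == s).to_numpy()
        mu, var = _weighted_mean_var(score[m], w[m])
        rows.append({
            "subtype": s, "n": int(m.sum()),
            "weighted_mean_score": mu,
            "se_mean_score": float(np.sqrt(var)),
            "pct_node_positive": _weighted_pct(
                sample.loc[m, "nodal_positive"].to_numpy(), w[m]),
            "pct_size_gt2cm": _weighted_pct(
                sample.loc[m, "size_gt2cm"].to_numpy(), w[m]),
            "pct_grade_high": _weighted_pct(
                (sample.loc[m, "grade"] == "high").to_numpy(), w[m]),
        })
    score_p = group_compare(score, sample["subtype"].to_numpy(), w).pvalue
    subtype_table = pd.DataFrame(rows)
    subtype_table["p_score_across_subtypes"] = score_p

    # weighted tertiles + descriptives by tertile
    spec = weighted_tertiles(score, w)
    tert = spec.assign(score)
    rows = []
    for name, ind in (
        ("pct_age<=40", (sample["age_group"] == "<=40").to_numpy(float)),
        ("pct_node_positive", sample["nodal_positive"].to_numpy(float)),
        ("pct_size_gt2cm", sample["size_gt2cm"].to_numpy(float)),
        ("pct_grade_low", (sample["grade"] == "low").to_numpy(float)),
        ("pct_grade_high", (sample["grade"] == "high").to_numpy(float)),
    ):
        test = group_compare(ind, tert, w, kind="proportion")
        row = {"characteristic": name, "p": test.pvalue}
        for g, lab in enumerate(TERTILE_LABELS):
            row[f"{lab}_pct"] = _weighted_pct(ind[tert == g], w[tert == g])
        rows.append(row)
    tertile_table = pd.DataFrame(rows)

    # correlation, overall and in the HR+/HER2- subset (raw, unweighted)
    hr_m = (sample["subtype"] == "hr_her2neg").to_numpy()
    correlations = pd.DataFrame([
        {"subset": "overall",
         "pearson_r": correlation(score, sample["rs"].to_numpy()).r,
         "n": len(sample)},
        {"subset": "hr_her2neg",
         "pearson_r": correlation(score[hr_m],
                                  sample.loc[hr_m, "rs"].to_numpy()).r,
         "n": int(hr_m.sum())},
    ])

    # continuous-score window fits per subtype, plus time-varying tests
    wrows = []
    for s in ["overall"] + sorted(sample["subtype"].unique()):
        sub = sample if s == "overall" else sample[sample["subtype"] == s]
        for ep in config.endpoints:
            entry = {"subset": s, "endpoint": ep}
            for wname, win in (("early", config.early_window),
                               ("late", config.late_window)):
                frame = endpoint_frame(sub, ep, win)
                try:
                    res = WeightedCoxPH(frame, ["score"],
                                        ties=config.ties).fit()
                    entry[f"{wname}_coef"] = float(res.params.iloc[0])
                    entry[f"{wname}_p"] = float(res.summary()["p"].iloc[0])
                except (ConvergenceError, ValueError):
                    entry[f"{wname}_coef"] = np.nan
                    entry[f"{wname}_p"] = np.nan
            try:
                _, overall_t, prop_t = fit_time_varying(
                    endpoint_frame(sub, ep), "score", ties=config.ties)
                entry["tv_overall_p"] = overall_t.pvalue
                entry["tv_proportionality_p"] = prop_t.pvalue
            except (ConvergenceError, ValueError):
                entry["tv_overall_p"] = np.nan
                entry["tv_proportionality_p"] = np.nan
            wrows.append(entry)
    window_fits = pd.DataFrame(wrows)

    # the three multivariate models (HR+/HER2-, early window)
    mrows = []
    for ep in config.endpoints:
        models = run_models(sample, endpoint=ep, window=config.early_window,
                            ties=config.ties)
        tab = model_table(models)
        tab.insert(0, "endpoint", ep)
        mrows.append(tab)
    model_fits = pd.concat(mrows, ignore_index=True)

    # subgroup HRs under both RS schemes
    hr_sub = sample[sample["subtype"] == "hr_her2neg"]
    sub_tabs = []
    for scheme in RS_SCHEMES:
        for ep in config.endpoints:
            t = subgroup_hr(hr_sub, spec, scheme, ep, config.early_window,
                            config.ties)
            t.insert(0, "endpoint", ep)
            sub_tabs.append(t)
    subgroup_hrs = pd.concat(sub_tabs, ignore_index=True)

    # weighted KM by tertile in HR+/HER2-, truncated at 5 years
    km_rows, km_test_rows = [], []
    for ep in config.endpoints:
        frame = endpoint_frame(hr_sub, ep, (0.0, config.early_window[1]))
        tert_sub = spec.assign(frame["score"].to_numpy())
        for g, lab in enumerate(TERTILE_LABELS):
            grp = frame[tert_sub == g]
            if grp.empty:
                continue
            curve = weighted_km(grp, label=f"{ep}:{lab}")
            cf = curve.to_frame()
            cf.insert(0, "endpoint", ep)
            cf.insert(1, "tertile", lab)
            km_rows.append(cf)
        frame = frame.copy()
        frame["t_mid"] = (tert_sub == 1).astype(float)
        frame["t_high"] = (tert_sub == 2).astype(float)
        try:
            res = WeightedCoxPH(frame, ["t_mid", "t_high"],
                                ties=config.ties).fit()
            test = res.wald_test(["t_mid", "t_high"])
            km_test_rows.append({"endpoint": ep, "statistic": test.statistic,
                                 "df": test.df, "p": test.pvalue})
        except (ConvergenceError, ValueError):
            km_test_rows.append({"endpoint": ep, "statistic": np.nan,
                                 "df": 2, "p": np.nan})
    km_curves = pd.concat(km_rows, ignore_index=True)
    km_tests = pd.DataFrame(km_test_rows)

    header = {"config_hash": config.config_hash(), "seed": config.seed,
              "n_cohort": len(cohort), "n_sample": len(sample)}
    return AnalysisReport(header, subtype_table, spec, tertile_table,
                          correlations, window_fits, model_fits,
                          subgroup_hrs, km_curves, km_tests)
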