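"""Synthetic trial-like cohorts with known effects and two-phase sampling.

Generates patient-level data emulating the structure of an adjuvant
breast-cancer trial cohort: three subtypes (HR+/HER2-, triple negative,
HER2+) with different MetaSite-score distributions, a Recurrence Score
weakly correlated with the MetaSite score through a Gaussian copula,
clinicopathologic covariates, recurrence/death histories drawn from a
piecewise-constant proportional-hazards model (the score's log hazard can
differ before and after year 5), STEEP-style endpoint derivation (DRFI,
RFI, OS, BCSS), and case-enriched stratified subsampling with
inverse-sampling-fraction weights.

The cohort container is a :class:`pandas.DataFrame`; see
:data:`COHORT_COLUMNS` for the column dictionary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SUBTYPES",
    "CohortParams",
    "EventHistory",
    "SamplingDesign",
    "derive_endpoints",
    "generate_cohort",
    "draw_subsample",
    "case_control_design",
    "COHORT_COLUMNS",
]

SUBTYPES = ("hr_her2neg", "triple_negative", "her2pos")

COHORT_COLUMNS = {
    "id": "patient identifier (int)",
    "subtype": "hr_her2neg | triple_negative | her2pos",
    "age_group": "<=40 | 41-50 | 51-60 | >60",
    "nodal_positive": "1 if 1-3 positive axillary nodes, else 0",
    "size_gt2cm": "1 if tumor > 2 cm, else 0",
    "grade": "low | intermediate | high",
    "score": "MetaSite score (integer >= 0)",
    "rs": "Recurrence Score (integer 0-100)",
    "recurrence_time": "time of first recurrence (years; NaN if none)",
    "recurrence_type": "distant | locoregional | '' if none",
    "death_time": "death time (years; NaN if alive at cutoff)",
    "death_cause": "breast | other | '' if alive",
    "drfi_time/drfi_event": "distant relapse-free interval",
    "rfi_time/rfi_event": "relapse-free interval",
    "os_time/os_event": "overall survival",
    "bcss_time/bcss_event": "breast-cancer-specific survival",
    "stratum": "sampling stratum label (after subsampling)",
    "weight": "inverse sampling fraction (1.0 in the full cohort)",
}


@dataclass(frozen=True)
class CohortParams:
    """Generator settings; defaults emulate the target study's structure.

    Score means per subtype follow the reported weighted means (16.1 /
    23.8 / 26.2); the score's log hazard for first recurrence is
    ``beta_early`` up to ``window_break`` years and ``beta_late`` after,
    nonzero by default only in HR+/HER2-; 70% of first recurrences are
    distant.
    """

    n: int = 2952
    subtype_prevalence: dict = field(default_factory=lambda: {
        "hr_her2neg": 0.65, "triple_negative": 0.20, "her2pos": 0.15})
    score_mean: dict = field(default_factory=lambda: {
        "hr_her2neg": 16.1, "triple_negative": 23.8, "her2pos": 26.2})
    score_dispersion: float = 0.8       # negative-binomial size parameter
    score_zero_inflation: float = 0.12
    score_cap: int = 199
    rs_gamma: dict = field(default_factory=lambda: {
        # (shape, scale): HR+ centered low, TN almost all > 30, HER2+ high
        "hr_her2neg": (3.6, 5.3),
        "triple_negative": (25.0, 2.0),
        "her2pos": (7.4, 5.2)})
    copula_rho: float = 0.33            # latent normal corr between score and RS
    age_group_probs: dict = field(default_factory=lambda: {
        "hr_her2neg": (0.11, 0.33, 0.36, 0.20),
        "triple_negative": (0.23, 0.41, 0.24, 0.12),
        "her2pos": (0.13, 0.40, 0.28, 0.19)})
    nodal_positive_prob: dict = field(default_factory=lambda: {
        "hr_her2neg": 0.457, "triple_negative": 0.191, "her2pos": 0.321})
    size_gt2cm_prob: dict = field(default_factory=lambda: {
        "hr_her2neg": 0.456, "triple_negative": 0.560, "her2pos": 0.546})
    grade_probs: dict = field(default_factory=lambda: {
        "hr_her2neg": (0.277, 0.488, 0.235),
        "triple_negative": (0.011, 0.090, 0.899),
        "her2pos": (0.080, 0.309, 0.611)})
    baseline_hazard: dict = field(default_factory=lambda: {
        "hr_her2neg": 0.004, "triple_negative": 0.014, "her2pos": 0.009})
    beta_early: dict = field(default_factory=lambda: {
        "hr_her2neg": 0.015, "triple_negative": 0.0, "her2pos": 0.0})
    beta_late: dict = field(default_factory=lambda: {
        "hr_her2neg": 0.0, "triple_negative": 0.0, "her2pos": 0.0})
    window_break: float = 5.0
    covariate_log_hr: dict = field(default_factory=lambda: {
        "nodal_positive": 0.4, "size_gt2cm": 0.4,
        "grade_intermediate": 0.5, "grade_high": 1.0})
    distant_fraction: float = 0.70
    bc_death_rate: float = 0.35         # after distant recurrence (per year)
    other_death_rate: float = 0.012
    admin_censor_time: float = 10.0
    tertile_log_hr: float | None = None  # replaces the score effect if set
    seed: int = 0

    def __post_init__(self) -> None:
        pv = sum(self.subtype_prevalence.values())
        if abs(pv - 1.0) > 1e-9:
            raise ValueError("subtype prevalences must sum to 1")
        if any(h < 0 for h in self.baseline_hazard.values()):
            raise ValueError("hazards must be >= 0")
        if self.admin_censor_time <= 0:
            raise ValueError("censoring time must be positive")
        if not 0 <= self.score_zero_inflation < 1:
            raise ValueError("zero inflation must be in [0, 1)")


@dataclass(frozen=True)
class EventHistory:
    """Raw event history before endpoint derivation (times in years)."""

    recurrence_time: float | None
    recurrence_type: str | None        # "distant" | "locoregional" | None
    death_time: float | None
    death_cause: str | None            # "breast" | "other" | None
    followup_end: float


def derive_endpoints(history: EventHistory) -> dict:
    """Map an event history to STEEP-style (time, indicator) endpoints.

    * DRFI: time to first distant recurrence; censored at a first
      locoregional recurrence (subsequent distant events are not recorded)
      or at last follow-up.
    * RFI: time to first recurrence at any site, censored at last
      follow-up (death without recurrence censors).
    * OS: time to death from any cause.
    * BCSS: time to breast-cancer death; other-cause death censors.
    """
    rec_t, rec_type = history.recurrence_time, history.recurrence_type
    death_t, cause = history.death_time, history.death_cause
    fu = history.followup_end
    if fu <= 0:
        raise ValueError("follow-up end must be positive")
    if rec_t is not None and death_t is not None and rec_t > death_t:
        raise ValueError("recurrence recorded after death")
    # truncate anything beyond the follow-up cutoff
    if rec_t is not None and rec_t > fu:
        rec_t, rec_type = None, None
    if death_t is not None and death_t > fu:
        death_t, cause = None, None
    end = min(death_t, fu) if death_t is not None else fu

    if rec_t is not None:
        rfi = (rec_t, 1)
        drfi = (rec_t, 1) if rec_type == "distant" else (rec_t, 0)
    else:
        rfi = (end, 0)
        drfi = (end, 0)
    os_ = (death_t, 1) if death_t is not None else (fu, 0)
    if death_t is not None and cause == "breast":
        bcss = (death_t, 1)
    elif death_t is not None:
        bcss = (death_t, 0)
    else:
        bcss = (fu, 0)
    return {
        "drfi_time": drfi[0], "drfi_event": drfi[1],
        "rfi_time": rfi[0], "rfi_event": rfi[1],
        "os_time": os_[0], "os_event": os_[1],
        "bcss_time": bcss[0], "bcss_event": bcss[1],
    }


# ---------------------------------------------------------------------------
# marginals
# ---------------------------------------------------------------------------

def _zinb_ppf(u, mean, size, pi0, cap):
    """Quantile of a zero-inflated negative binomial with given overall mean."""
    mu = mean / (1.0 - pi0)
    p = size / (size + mu)
    out = np.zeros_like(u)
    tail = u > pi0
    q = (u[tail] - pi0) / (1.0 - pi0)
    out[tail] = stats.nbinom.ppf(q, size, p)
    return np.minimum(out, cap).astype(int)


def _piecewise_exp_time(E, rate1, rate2, brk):
    """Inverse-CDF draw from hazard rate1 on (0, brk], rate2 after."""
    H_brk = rate1 * brk
    t = np.where(E <= H_brk, E / np.maximum(rate1, 1e-300),
                 brk + (E - H_brk) / np.maximum(rate2, 1e-300))
    return np.where((rate1 == 0) & (rate2 == 0), np.inf, t)


def generate_cohort(params: CohortParams,
                    rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw a full cohort; deterministic given ``params.seed``."""
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n = params.n
    subtypes = rng.choice(SUBTYPES, size=n,
                          p=[params.subtype_prevalence[s] for s in SUBTYPES])

    age_labels = ("<=40", "41-50", "51-60", ">60")
    grade_labels = ("low", "intermediate", "high")
    age = np.empty(n, dtype=object)
    grade = np.empty(n, dtype=object)
    nodal = np.zeros(n, dtype=int)
    size2 = np.zeros(n, dtype=int)
    score = np.zeros(n, dtype=int)
    rs = np.zeros(n, dtype=int)

    # latent bivariate normal for the score-RS copula
    z = rng.multivariate_normal(
        [0, 0], [[1, params.copula_rho], [params.copula_rho, 1]], size=n)
    u_score, u_rs = stats.norm.cdf(z[:, 0]), stats.norm.cdf(z[:, 1])

    for s in SUBTYPES:
        m = subtypes == s
        k = int(m.sum())
        if k == 0:
            continue
        age[m] = rng.choice(age_labels, size=k, p=params.age_group_probs[s])
        grade[m] = rng.choice(grade_labels, size=k, p=params.grade_probs[s])
        nodal[m] = rng.random(k) < params.nodal_positive_prob[s]
        size2[m] = rng.random(k) < params.size_gt2cm_prob[s]
        score[m] = _zinb_ppf(u_score[m], params.score_mean[s],
                             params.score_dispersion,
                             params.score_zero_inflation, params.score_cap)
        shape, scale = params.rs_gamma[s]
        rs[m] = np.clip(np.round(stats.gamma.ppf(u_rs[m], shape, scale=scale)),
                        0, 100).astype(int)

    lhr = params.covariate_log_hr
    lp = (lhr.get("nodal_positive", 0.0) * nodal
          + lhr.get("size_gt2cm", 0.0) * size2
          + lhr.get("grade_intermediate", 0.0) * (grade == "intermediate")
          + lhr.get("grade_high", 0.0) * (grade == "high"))

    h0 = np.array([params.baseline_hazard[s] for s in subtypes])
    if params.tertile_log_hr is None:
        be = np.array([params.beta_early[s] for s in subtypes])
        bl = np.array([params.beta_late[s] for s in subtypes])
        eff_early, eff_late = be * score, bl * score
    else:
        # effect on the tertile-group index (0/1/2) of the realized scores:
        # high-vs-low log HR equals tertile_log_hr by construction
        from .analysis import weighted_tertiles
        spec = weighted_tertiles(score, np.ones(n))
        idx = spec.assign(score)
        eff_early = eff_late = params.tertile_log_hr / 2.0 * idx

    rate1 = h0 * np.exp(lp + eff_early)
    rate2 = h0 * np.exp(lp + eff_late)
    rec_time = _piecewise_exp_time(rng.exponential(size=n), rate1, rate2,
                                   params.window_break)
    distant = rng.random(n) < params.distant_fraction
    other_death = rng.exponential(1.0 / max(params.other_death_rate, 1e-300),
                                  size=n) if params.other_death_rate > 0 \
        else np.full(n, np.inf)
    bc_lag = rng.exponential(1.0 / max(params.bc_death_rate, 1e-300), size=n) \
        if params.bc_death_rate > 0 else np.full(n, np.inf)

    rows = []
    for i in range(n):
        if other_death[i] < rec_time[i]:
            hist = EventHistory(None, None, float(other_death[i]), "other",
                                params.admin_censor_time)
            rec_t, rec_ty, death_t, cause = np.nan, "", other_death[i], "other"
        else:
            rec_ty = "distant" if distant[i] else "locoregional"
            bc_death = rec_time[i] + bc_lag[i] if distant[i] else np.inf
            death = min(bc_death, other_death[i])
            cause = ("breast" if bc_death <= other_death[i] else "other") \
                if np.isfinite(death) else None
            hist = EventHistory(float(rec_time[i]), rec_ty,
                                float(death) if np.isfinite(death) else None,
                                cause, params.admin_censor_time)
            rec_t = rec_time[i]
            death_t = death if np.isfinite(death) else np.nan
            cause = cause or ""
        ends = derive_endpoints(hist)
        # blank out raw history beyond the administrative cutoff, matching
        # what the endpoints can see
        if np.isfinite(rec_t) and rec_t > params.admin_censor_time:
            rec_t, rec_ty = np.nan, ""
        if np.isfinite(death_t) and death_t > params.admin_censor_time:
            death_t, cause = np.nan, ""
        rows.append({
            "id": i, "subtype": subtypes[i], "age_group": age[i],
            "nodal_positive": int(nodal[i]), "size_gt2cm": int(size2[i]),
            "grade": grade[i], "score": int(score[i]), "rs": int(rs[i]),
            "recurrence_time": rec_t if np.isfinite(rec_t) else np.nan,
            "recurrence_type": rec_ty if np.isfinite(rec_t) else "",
            "death_time": death_t, "death_cause": cause,
            **ends,
        })
    df = pd.DataFrame(rows)
    df["stratum"] = ""
    df["weight"] = 1.0
    return df


# ---------------------------------------------------------------------------
# two-phase sampling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SamplingDesign:
    """Stratified fixed-size subsampling with known sampling fractions.

    ``strata_cols`` define the sampling groups (typically covariate strata
    crossed with recurrence status); ``fractions`` maps each group's key
    (a tuple of column values, or a scalar for one column) to its sampling
    fraction in (0, 1].  The analysis weight is the inverse fraction.
    """

    strata_cols: tuple = ("rfi_event",)
    fractions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, f in self.fractions.items():
            if not 0 < f <= 1:
                raise ValueError(f"sampling fraction for {key!r} must be in (0, 1]")

    def group_key(self, row) -> tuple:
        return tuple(row[c] for c in self.strata_cols)


def case_control_design(control_fraction: float = 0.2,
                        case_fraction: float = 1.0) -> SamplingDesign:
    """All recurrences kept, controls subsampled — the case-enriched design."""
    return SamplingDesign(("rfi_event",), {(0,): control_fraction,
                                           (1,): case_fraction})


def draw_subsample(cohort: pd.DataFrame, design: SamplingDesign,
                   rng: np.random.Generator | int | None = 0) -> pd.DataFrame:
    """Fixed-size sampling without replacement of round(f * N) per group.

    Each selected patient carries weight 1/f and a stratum label, so that
    weighted group totals reproduce the full-cohort group sizes exactly.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    keys = cohort[list(design.strata_cols)].apply(tuple, axis=1)
    picks = []
    for key, idx in cohort.groupby(keys, sort=True).groups.items():
        key_t = key if isinstance(key, tuple) else (key,)
        if key_t not in design.fractions:
            raise ValueError(f"no sampling fraction for stratum {key_t!r}")
        f = design.fractions[key_t]
        m = int(round(f * len(idx)))
        if m == 0:
            raise ValueError(
                f"stratum {key_t!r} is non-empty but round(f*N) = 0")
        chosen = rng.choice(np.asarray(idx), size=m, replace=False)
        sub = cohort.loc[np.sort(chosen)].copy()
        sub["stratum"] = "|".join(f"{c}={v}" for c, v in
                                  zip(design.strata_cols, key_t))
        sub["weight"] = 1.0 / f
        picks.append(sub)
    return pd.concat(picks).sort_index().reset_index(drop=True)
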