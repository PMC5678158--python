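"""Weighted survival estimation for two-phase (case-enriched) sampling designs.

The estimators here implement the weighted analysis used for cohorts sampled
with known, outcome-dependent sampling fractions: every subject carries a
weight equal to the inverse of the sampling fraction of their sampling group,
and estimation proceeds by

* weighted Kaplan-Meier product-limit curves,
* weighted Cox partial-likelihood fits over counting-process
  ``(start, stop]`` episodes, and
* a "corrected" (sandwich) covariance built from subject-level score
  residuals, which is the valid variance estimator when weights are not
  all 1 (the naive inverse-information variance is not).

The model layer follows the statsmodels convention: :class:`WeightedCoxPH`
is constructed from a long-format episode table and ``fit()`` returns a
:class:`WeightedCoxResults` carrying coefficients, both covariances, the
score-residual matrix and a ``summary()`` table.  The module-level functions
(:func:`fit_weighted_cox`, :func:`weighted_km`, :func:`episode_split`,
:func:`restrict_window`, :func:`fit_time_varying`, ...) are thin conveniences
over these objects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConvergenceError",
    "TestResult",
    "KMCurve",
    "WeightedCoxPH",
    "WeightedCoxResults",
    "WeightedKaplanMeier",
    "fit_weighted_cox",
    "weighted_km",
    "score_residuals",
    "robust_covariance",
    "episode_split",
    "restrict_window",
    "fit_time_varying",
]


class ConvergenceError(RuntimeError):
    """Raised when Newton-Raphson fails, e.g. under monotone likelihood."""


@dataclass(frozen=True)
class TestResult:
    """A Wald-type test: chi-square statistic, degrees of freedom, p-value."""

    statistic: float
    df: int
    pvalue: float
    family: str = "Wald"

    def __post_init__(self) -> None:
        if self.df < 1:
            raise ValueError("df must be >= 1")


# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------

def _prepare(
    data: pd.DataFrame,
    covariates: list[str],
    start_col: str | None,
    stop_col: str,
    event_col: str,
    weight_col: str | None,
    id_col: str | None,
):
    df = data.reset_index(drop=True)
    stop = df[stop_col].to_numpy(float)
    start = (
        df[start_col].to_numpy(float)
        if start_col is not None and start_col in df.columns
        else np.zeros_like(stop)
    )
    event = df[event_col].to_numpy(float).astype(bool)
    if weight_col is not None and weight_col in df.columns:
        w = df[weight_col].to_numpy(float)
    else:
        w = np.ones_like(stop)
    if id_col is not None and id_col in df.columns:
        ids = df[id_col].to_numpy()
    else:
        ids = np.arange(len(df))
    X = df[list(covariates)].to_numpy(float)
    if np.any(start < 0) or np.any(stop < 0):
        raise ValueError("negative times are not allowed")
    if np.any(start >= stop):
        raise ValueError("every episode must satisfy start < stop")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    if not np.all(np.isfinite(X)):
        raise ValueError("covariates must be finite")
    return start, stop, event, X, w, ids


# ---------------------------------------------------------------------------
# partial likelihood and derivatives
# ---------------------------------------------------------------------------

def _risk_set_sums(values, lo, hi, n_times):
    """Sum ``values`` (n,) over episodes at risk at each event time.

    Episode i is at risk at event-time indices j in [lo_i, hi_i); computed
    with a difference array + cumulative sum, O(n + T).
    """
    delta = np.zeros(n_times + 1)
    np.add.at(delta, lo, values)
    np.add.at(delta, hi, -values)
    return np.cumsum(delta)[:n_times]


def _event_structure(start, stop, event):
    """Shared index structure: event times, at-risk ranges, death groups."""
    ev_times = np.unique(stop[event])
    # episode i is at risk at time t iff start_i < t <= stop_i
    lo = np.searchsorted(ev_times, start, side="right")
    hi = np.searchsorted(ev_times, stop, side="right")
    death_idx = np.full(len(stop), -1)
    which = np.flatnonzero(event)
    death_idx[which] = np.searchsorted(ev_times, stop[which])
    return ev_times, lo, hi, death_idx


def _loglik_derivs(beta, start, stop, event, X, w, ties, structure=None):
    """Weighted log partial likelihood, gradient and Hessian.

    Risk sets are counting-process style: episode (start, stop] is at risk
    at event time t iff start < t <= stop.  Breslow treats tied events with
    the full-risk-set denominator; Efron down-weights the tied deaths'
    contribution to the denominator by k/d for the k-th of d tied events,
    with each log-denominator carrying the mean weight of the tied deaths.
    Risk-set sums are accumulated with difference arrays, so one
    evaluation costs O(n p^2 + T p^2).
    """
    n, p = X.shape
    eta = X @ beta
    if np.max(np.abs(eta)) > 500:
        raise ConvergenceError(
            "linear predictor overflow (|x'beta| > 500); the partial "
            "likelihood is likely monotone (separation)"
        )
    r = np.exp(eta)
    wr = w * r
    if structure is None:
        structure = _event_structure(start, stop, event)
    ev_times, lo, hi, death_idx = structure
    T = len(ev_times)
    dmask = event
    didx = death_idx[dmask]

    S0 = _risk_set_sums(wr, lo, hi, T)
    S1 = np.stack([_risk_set_sums(wr * X[:, j], lo, hi, T)
                   for j in range(p)], axis=1)                    # (T, p)
    S2 = np.stack([_risk_set_sums(wr * X[:, a] * X[:, b], lo, hi, T)
                   for a in range(p) for b in range(p)],
                  axis=1).reshape(T, p, p)

    # per-event-time death totals
    Wd = np.bincount(didx, weights=w[dmask], minlength=T)
    d_count = np.bincount(didx, minlength=T)
    ll = float(w[dmask] @ eta[dmask])
    grad = X[dmask].T @ w[dmask]

    if ties == "breslow":
        ll -= float(Wd @ np.log(S0))
        m1 = S1 / S0[:, None]
        grad -= Wd @ m1
        hess = -np.einsum("t,tab->ab", Wd, S2 / S0[:, None, None]
                          - np.einsum("ta,tb->tab", m1, m1))
        return ll, grad, hess

    # Efron: tied-death sums per time
    S0d = np.bincount(didx, weights=wr[dmask], minlength=T)
    S1d = np.stack([np.bincount(didx, weights=(wr * X[:, j])[dmask],
                                minlength=T) for j in range(p)], axis=1)
    S2d = np.stack([np.bincount(didx, weights=(wr * X[:, a] * X[:, b])[dmask],
                                minlength=T) for a in range(p)
                    for b in range(p)], axis=1).reshape(T, p, p)
    hess = np.zeros((p, p))
    # untied times contribute the Breslow form; vectorize those
    single = d_count == 1
    if np.any(single):
        s0, s1, s2 = S0[single], S1[single], S2[single]
        wd = Wd[single]
        ll -= float(wd @ np.log(s0))
        m1 = s1 / s0[:, None]
        grad -= wd @ m1
        hess -= np.einsum("t,tab->ab", wd, s2 / s0[:, None, None]
                          - np.einsum("ta,tb->tab", m1, m1))
    for t in np.flatnonzero(d_count > 1):
        d = int(d_count[t])
        wbar = Wd[t] / d
        for k in range(d):
            f = k / d
            denom = S0[t] - f * S0d[t]
            m1 = (S1[t] - f * S1d[t]) / denom
            ll -= wbar * np.log(denom)
            grad -= wbar * m1
            hess -= wbar * ((S2[t] - f * S2d[t]) / denom - np.outer(m1, m1))
    return ll, grad, hess


def _score_residual_matrix(beta, start, stop, event, X, w, ties):
    """Per-episode score residuals (own weight excluded).

    The residual is the martingale integral int (x_i - xbar(t)) dM_i(t) with
    the weighted risk-set mean xbar and the weighted Breslow/Efron baseline
    hazard increment; the subject's own sampling weight multiplies the
    residual only later, in the sandwich.
    """
    n, p = X.shape
    r = np.exp(X @ beta)
    wr = w * r
    ev_times, lo, hi, death_idx = _event_structure(start, stop, event)
    T = len(ev_times)
    dmask = event
    didx = death_idx[dmask]

    S0 = _risk_set_sums(wr, lo, hi, T)
    S1 = np.stack([_risk_set_sums(wr * X[:, j], lo, hi, T)
                   for j in range(p)], axis=1)
    Wd = np.bincount(didx, weights=w[dmask], minlength=T)
    d_count = np.bincount(didx, minlength=T)
    xbar = S1 / S0[:, None]

    # per-time hazard-increment totals for the at-risk integral, the mean
    # risk-set average seen by the deaths, and the tied-death correction
    # (all reduce to the Breslow forms at untied times)
    dL_tot = Wd / S0
    dLx_tot = dL_tot[:, None] * xbar
    xbar_mean = xbar.copy()
    corr_f = np.zeros(T)
    corr_fx = np.zeros((T, p))
    if ties == "efron" and np.any(d_count > 1):
        S0d = np.bincount(didx, weights=wr[dmask], minlength=T)
        S1d = np.stack([np.bincount(didx, weights=(wr * X[:, j])[dmask],
                                    minlength=T) for j in range(p)], axis=1)
        for t in np.flatnonzero(d_count > 1):
            d = int(d_count[t])
            wbar = Wd[t] / d
            dsum = np.zeros(p)
            dlt, dlx = 0.0, np.zeros(p)
            cf, cfx = 0.0, np.zeros(p)
            for k in range(d):
                f = k / d
                denom = S0[t] - f * S0d[t]
                xb_k = (S1[t] - f * S1d[t]) / denom
                dl_k = wbar / denom
                dsum += xb_k
                dlt += dl_k
                dlx += dl_k * xb_k
                cf += f * dl_k
                cfx += f * dl_k * xb_k
            dL_tot[t], dLx_tot[t] = dlt, dlx
            xbar_mean[t] = dsum / d
            corr_f[t], corr_fx[t] = cf, cfx

    Apad = np.concatenate([[0.0], np.cumsum(dL_tot)])
    Bpad = np.vstack([np.zeros(p), np.cumsum(dLx_tot, axis=0)])
    dA = Apad[hi] - Apad[lo]                       # (n,)
    dB = Bpad[hi] - Bpad[lo]                       # (n, p)
    resid = -r[:, None] * (X * dA[:, None] - dB)
    # dN terms at each episode's own death time (tied deaths are at risk
    # in the k-th pseudo risk set only with multiplicity 1 - k/d)
    resid[dmask] += X[dmask] - xbar_mean[didx]
    resid[dmask] += r[dmask, None] * (X[dmask] * corr_f[didx][:, None]
                                      - corr_fx[didx])
    return resid


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

class WeightedCoxPH:
    """Cox proportional-hazards model with sampling weights.

    Parameters
    ----------
    data
        Long-format episode table; one row per ``(start, stop]`` interval.
        A plain one-row-per-subject table works too (``start`` defaults
        to 0, ``weight`` to 1, ``id`` to the row number).
    covariates
        Column names entering the linear predictor.
    ties
        ``"efron"`` (default) or ``"breslow"``.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        covariates: list[str],
        *,
        start_col: str | None = "start",
        stop_col: str = "stop",
        event_col: str = "event",
        weight_col: str | None = "weight",
        id_col: str | None = "id",
        ties: str = "efron",
    ):
        if ties not in ("efron", "breslow"):
            raise ValueError(f"unknown ties method {ties!r}")
        self.covariates = list(covariates)
        self.ties = ties
        self.data = data
        arrs = _prepare(data, self.covariates, start_col, stop_col,
                        event_col, weight_col, id_col)
        self._start, self._stop, self._event, self._X, self._w, self._ids = arrs
        if self._event.sum() < 1:
            raise ValueError("at least one event is required")
        for j, name in enumerate(self.covariates):
            if np.ptp(self._X[:, j]) == 0:
                raise ValueError(f"covariate {name!r} is constant")

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, covariates: list[str],
                       **kwargs) -> "WeightedCoxPH":
        return cls(data, covariates, **kwargs)

    def loglik(self, beta: np.ndarray) -> float:
        ll, _, _ = _loglik_derivs(np.asarray(beta, float), self._start,
                                  self._stop, self._event, self._X, self._w,
                                  self.ties)
        return ll

    def fit(
        self,
        beta_init: np.ndarray | None = None,
        max_iter: int = 60,
        tol_score: float = 1e-8,
        tol_ll: float = 1e-10,
    ) -> "WeightedCoxResults":
        p = self._X.shape[1]
        # standardise covariates for numerical stability; estimates,
        # covariances and residuals are transformed back afterwards
        xmean = self._X.mean(axis=0)
        scale = self._X.std(axis=0)
        Xc = (self._X - xmean) / scale
        beta = np.zeros(p) if beta_init is None \
            else np.asarray(beta_init, float) * scale
        ll, grad, hess = _loglik_derivs(beta, self._start, self._stop,
                                        self._event, Xc, self._w, self.ties)
        n_iter = 0
        converged = False
        for n_iter in range(1, max_iter + 1):
            info = -hess
            try:
                step = np.linalg.solve(info, grad)
            except np.linalg.LinAlgError as exc:
                raise ConvergenceError(f"singular information matrix: {exc}")
            # step halving if the likelihood does not improve
            for _ in range(25):
                cand = beta + step
                try:
                    ll_new, grad_new, hess_new = _loglik_derivs(
                        cand, self._start, self._stop, self._event, Xc,
                        self._w, self.ties)
                except ConvergenceError:
                    step /= 2
                    continue
                if ll_new >= ll - 1e-12:
                    break
                step /= 2
            else:
                raise ConvergenceError("step halving failed to improve the "
                                       "partial likelihood")
            rel = abs(ll_new - ll) / (abs(ll) + 1e-300)
            beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
            if np.max(np.abs(grad)) < tol_score or rel < tol_ll:
                converged = True
                break
        if not converged:
            raise ConvergenceError(
                f"no convergence in {max_iter} iterations "
                f"(max |score| = {np.max(np.abs(grad)):.3g}); the likelihood "
                "may be monotone (separation)")
        if np.max(np.abs(beta)) > 8:
            # > 10 log hazard ratios per covariate SD: the likelihood is
            # monotone and the "optimum" is an artifact of the plateau
            raise ConvergenceError(
                "estimate diverged (|beta| > 8 per covariate SD); the "
                "partial likelihood is likely monotone (separation)")
        cov_naive = np.linalg.inv(-hess)
        resid_rows = _score_residual_matrix(beta, self._start, self._stop,
                                            self._event, Xc, self._w,
                                            self.ties)
        # back-transform to the original covariate scale
        beta = beta / scale
        cov_naive = cov_naive / np.outer(scale, scale)
        resid_rows = resid_rows * scale
        # aggregate episodes to subjects; a split subject's weight is the
        # (common) weight of its episodes
        rframe = pd.DataFrame(resid_rows, columns=self.covariates)
        rframe["_id"] = self._ids
        rframe["_w"] = self._w
        by = rframe.groupby("_id", sort=True)
        resid_subj = by[self.covariates].sum()
        w_subj = by["_w"].first()
        D = (resid_subj.to_numpy() * w_subj.to_numpy()[:, None]) @ cov_naive
        cov_robust = D.T @ D
        return WeightedCoxResults(
            model=self,
            params=pd.Series(beta, index=self.covariates),
            cov_naive=pd.DataFrame(cov_naive, index=self.covariates,
                                   columns=self.covariates),
            cov_robust=pd.DataFrame(cov_robust, index=self.covariates,
                                    columns=self.covariates),
            score_residuals_=resid_subj.assign(weight=w_subj),
            loglik=ll,
            n_iter=n_iter,
            converged=converged,
            ties=self.ties,
            weighted=bool(np.ptp(self._w) > 0 or self._w[0] != 1.0),
        )


@dataclass
class WeightedCoxResults:
    """Fitted weighted Cox model.

    ``cov_robust`` (the score-residual sandwich) is the default covariance
    for standard errors and Wald tests; it is required whenever weights
    differ from 1, and for unweighted data it is the ordinary robust
    (Lin-Wei) covariance.
    """

    model: WeightedCoxPH
    params: pd.Series
    cov_naive: pd.DataFrame
    cov_robust: pd.DataFrame
    score_residuals_: pd.DataFrame
    loglik: float
    n_iter: int
    converged: bool
    ties: str
    weighted: bool
    extra: dict = field(default_factory=dict)

    @property
    def bse_naive(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_naive)), index=self.params.index)

    @property
    def bse(self) -> pd.Series:
        """Robust (sandwich) standard errors."""
        return pd.Series(np.sqrt(np.diag(self.cov_robust)), index=self.params.index)

    @property
    def hazard_ratios(self) -> pd.Series:
        return np.exp(self.params)

    def conf_int(self, alpha: float = 0.05, robust: bool = True) -> pd.DataFrame:
        se = self.bse if robust else self.bse_naive
        z = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {"lower": self.params - z * se, "upper": self.params + z * se})

    def wald_test(self, terms: list[str] | None = None,
                  robust: bool = True) -> TestResult:
        """Joint Wald chi-square that the named coefficients are all zero."""
        terms = list(self.params.index) if terms is None else list(terms)
        cov = self.cov_robust if robust else self.cov_naive
        b = self.params[terms].to_numpy()
        V = cov.loc[terms, terms].to_numpy()
        stat = float(b @ np.linalg.solve(V, b))
        df = len(terms)
        return TestResult(stat, df, float(stats.chi2.sf(stat, df)))

    def summary(self) -> pd.DataFrame:
        se = self.bse
        z = self.params / se
        pvals = 2 * stats.norm.sf(np.abs(z))
        return pd.DataFrame({
            "coef": self.params,
            "HR": np.exp(self.params),
            "se(naive)": self.bse_naive,
            "se(robust)": se,
            "z": z,
            "p": pvals,
        })

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"<WeightedCoxResults ties={self.ties} "
                f"n_iter={self.n_iter} loglik={self.loglik:.4f}>")


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

@dataclass
class KMCurve:
    """Weighted product-limit curve: S(t) = prod over event times (1 - dw/nw)."""

    times: np.ndarray
    n_risk: np.ndarray
    n_event: np.ndarray
    survival: np.ndarray
    label: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.times,
            "n_risk_weighted": self.n_risk,
            "n_event_weighted": self.n_event,
            "survival": self.survival,
        })

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


class WeightedKaplanMeier:
    """Weighted Kaplan-Meier estimator with optional delayed entry."""

    def __init__(self, label: str = ""):
        self.label = label
        self.curve_: KMCurve | None = None

    def fit(self, data: pd.DataFrame, *, stop_col: str = "stop",
            event_col: str = "event", start_col: str | None = "start",
            weight_col: str | None = "weight") -> "WeightedKaplanMeier":
        stop = data[stop_col].to_numpy(float)
        start = (data[start_col].to_numpy(float)
                 if start_col is not None and start_col in data.columns
                 else np.zeros_like(stop))
        event = data[event_col].to_numpy(float).astype(bool)
        w = (data[weight_col].to_numpy(float)
             if weight_col is not None and weight_col in data.columns
             else np.ones_like(stop))
        if np.any(stop < 0) or np.any(start < 0):
            raise ValueError("negative times are not allowed")
        if np.any(w <= 0):
            raise ValueError("weights must be positive")
        times = np.unique(stop[event])
        n_risk = np.empty_like(times)
        n_event = np.empty_like(times)
        surv = np.empty_like(times)
        s = 1.0
        for i, t in enumerate(times):
            at_risk = (start < t) & (stop >= t)
            dead = at_risk & event & (stop == t)
            n_risk[i] = w[at_risk].sum()
            n_event[i] = w[dead].sum()
            s *= 1.0 - n_event[i] / n_risk[i]
            surv[i] = s
        self.curve_ = KMCurve(times, n_risk, n_event, surv, self.label)
        return self


# ---------------------------------------------------------------------------
# episode manipulation
# ---------------------------------------------------------------------------

def episode_split(data: pd.DataFrame, cut_times, *,
                  start_col: str = "start", stop_col: str = "stop",
                  event_col: str = "event") -> pd.DataFrame:
    """Split each episode at the given cut times.

    Each row ``(start, stop]`` is intersected with the cuts; only the
    terminal sub-episode keeps the event indicator; all other columns
    (weights, covariates, ids) are copied.  Cuts outside ``(start, stop)``
    leave a row unchanged.
    """
    cuts = np.unique(np.asarray(list(cut_times), float))
    df = data.reset_index(drop=True)
    s = df[start_col].to_numpy(float)
    t = df[stop_col].to_numpy(float)
    e = df[event_col].to_numpy()
    lo = np.searchsorted(cuts, s, side="right")   # first cut > start
    hi = np.searchsorted(cuts, t, side="left")    # first cut >= stop
    k = hi - lo                                   # inner cuts per episode
    reps = k + 1
    idx = np.repeat(np.arange(len(df)), reps)
    pos = np.arange(len(idx)) - np.repeat(np.cumsum(reps) - reps, reps)
    lo_r, k_r = lo[idx], k[idx]
    first = pos == 0
    last = pos == k_r
    new_start = np.where(first, s[idx], cuts[np.where(first, 0, lo_r + pos - 1)])
    new_stop = np.where(last, t[idx], cuts[np.minimum(lo_r + pos, len(cuts) - 1)])
    out = df.iloc[idx].reset_index(drop=True)
    out[start_col] = new_start
    out[stop_col] = new_stop
    out[event_col] = np.where(last, e[idx], 0)
    return out


def restrict_window(data: pd.DataFrame, t0: float, t1: float, *,
                    start_col: str = "start", stop_col: str = "stop",
                    event_col: str = "event") -> pd.DataFrame:
    """Restrict follow-up to the window (t0, t1].

    Episodes ending at or before t0 are dropped (their subjects were not at
    risk at t0), entry is delayed to max(start, t0), and anything after t1
    is administratively censored at t1.
    """
    if not 0 <= t0 < t1:
        raise ValueError("need 0 <= t0 < t1")
    df = data.copy()
    if start_col not in df.columns:
        df[start_col] = 0.0
    df = df[df[stop_col] > t0]
    df = df[df[start_col] < t1].copy()
    df[start_col] = df[start_col].clip(lower=t0)
    over = df[stop_col] > t1
    df.loc[over, event_col] = 0
    df.loc[over, stop_col] = t1
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# functional conveniences
# ---------------------------------------------------------------------------

def fit_weighted_cox(data: pd.DataFrame, covariates: list[str],
                     ties: str = "efron", **kwargs) -> WeightedCoxResults:
    """Fit a weighted Cox model; see :class:`WeightedCoxPH`."""
    return WeightedCoxPH(data, covariates, ties=ties, **kwargs).fit()


def weighted_km(data: pd.DataFrame, label: str = "", **kwargs) -> KMCurve:
    """Weighted Kaplan-Meier curve; see :class:`WeightedKaplanMeier`."""
    km = WeightedKaplanMeier(label).fit(data, **kwargs)
    assert km.curve_ is not None
    return km.curve_


def score_residuals(results: WeightedCoxResults) -> pd.DataFrame:
    """Subject-level score residual matrix of a converged fit."""
    if not results.converged:
        raise ConvergenceError("fit did not converge")
    return results.score_residuals_[list(results.params.index)]


def robust_covariance(results: WeightedCoxResults) -> pd.DataFrame:
    """Score-residual sandwich covariance of a converged fit."""
    if not results.converged:
        raise ConvergenceError("fit did not converge")
    return results.cov_robust


def fit_time_varying(
    data: pd.DataFrame,
    var: str,
    extra_covariates: list[str] | None = None,
    ties: str = "efron",
    **kwargs,
):
    """Fit a linear time-varying coefficient model for ``var``.

    Episodes are split at every event time, and the interaction covariate
    ``var_x_time = t * var`` (with t the stop time of each risk interval)
    is added, so the log hazard ratio of ``var`` is beta_var + t *
    beta_interaction.  Returns the fit, the joint 2-df Wald test that both
    coefficients are zero (the overall association test) and the 1-df Wald
    test on the interaction (the proportional-hazards test), both using the
    robust covariance.
    """
    stop_col = kwargs.get("stop_col", "stop")
    event_col = kwargs.get("event_col", "event")
    ev_times = np.unique(data.loc[data[event_col].astype(bool), stop_col])
    split = episode_split(data, ev_times,
                          start_col=kwargs.get("start_col", "start"),
                          stop_col=stop_col, event_col=event_col)
    inter = f"{var}_x_time"
    split[inter] = split[stop_col] * split[var]
    covs = [var, inter] + list(extra_covariates or [])
    res = WeightedCoxPH(split, covs, ties=ties, **kwargs).fit()
    overall = res.wald_test([var, inter], robust=True)
    prop = res.wald_test([inter], robust=True)
    return res, overall, prop
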