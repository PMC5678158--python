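import numpy as np
import pandas as pd
import pytest


@pytest.fixture(scope="session")
def tied_weighted_frame():
    """40-row weighted survival frame with heavy ties (seeded)."""
    rng = np.random.default_rng(42)
    n = 40
    df = pd.DataFrame({
        "stop": np.ceil(rng.exponential(5, n) * 2) / 2,
        "event": (rng.random(n) < 0.6).astype(int),
        "x1": rng.normal(size=n).round(2),
        "x2": (rng.random(n) < 0.4).astype(float),
        "weight": rng.choice([1.0, 2.0, 4.0], n),
    })
    return df


def random_survival_frame(rng, n=25, p=1, weighted=True, tie_grid=None):
    """Small random episode frame for oracle comparisons."""
    stop = rng.exponential(3.0, n) + 0.05
    if tie_grid:
        stop = np.ceil(stop * tie_grid) / tie_grid
    df = pd.DataFrame({
        "id": np.arange(n),
        "start": 0.0,
        "stop": stop,
        "event": (rng.random(n) < 0.6).astype(int),
        "weight": rng.choice([1.0, 2.0, 3.0], n) if weighted else 1.0,
    })
    for j in range(p):
        df[f"x{j}"] = rng.normal(size=n).round(2)
    if df["event"].sum() == 0:
        df.loc[df.index[0], "event"] = 1
    return df


def breslow_loglik_reference(beta, df, covs):
    """Independent weighted Breslow log partial likelihood (plain loops)."""
    beta = np.atleast_1d(np.asarray(beta, float))
    X = df[covs].to_numpy(float)
    w = df["weight"].to_numpy(float)
    stop = df["stop"].to_numpy(float)
    start = df["start"].to_numpy(float) if "start" in df else np.zeros_like(stop)
    event = df["event"].to_numpy().astype(bool)
    eta = X @ beta
    ll = 0.0
    for t in np.unique(stop[event]):
        dead = event & (stop == t)
        risk = (start < t) & (stop >= t)
        ll += float((w[dead] * eta[dead]).sum())
        ll -= w[dead].sum() * np.log((w[risk] * np.exp(eta[risk])).sum())
    return ll
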