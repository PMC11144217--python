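"""Independent brute-force oracles used to validate the package numerics.

These deliberately avoid the library code paths they check: OLS is done
with explicit normal equations, MAD/trimmed-mean with literal
sort-and-loop implementations, and CIs with resampling.
"""

import numpy as np


def ols_normal_equations(X, y):
    """Explicit normal-equations OLS with intercept.

    Returns dict with coefficients (intercept first), fitted values,
    residuals, rss, tss and r2.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    A = np.column_stack([np.ones(len(y)), X])
    beta = np.linalg.inv(A.T @ A) @ (A.T @ y)
    fitted = A @ beta
    resid = y - fitted
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    return {
        "beta": beta,
        "fitted": fitted,
        "resid": resid,
        "rss": rss,
        "tss": tss,
        "r2": 1.0 - rss / tss,
    }


def slope_closed_form(x, y):
    """Least-squares slope/intercept by the textbook sums."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xbar, ybar = x.mean(), y.mean()
    slope = np.sum((x - xbar) * (y - ybar)) / np.sum((x - xbar) ** 2)
    return slope, ybar - slope * xbar


def mad_brute(values):
    values = sorted(float(v) for v in values)
    n = len(values)
    med = (values[n // 2] if n % 2 else (values[n // 2 - 1] + values[n // 2]) / 2)
    devs = sorted(abs(v - med) for v in values)
    return devs[n // 2] if n % 2 else (devs[n // 2 - 1] + devs[n // 2]) / 2


def mad_mask_brute(values, k=3.0):
    values = [float(v) for v in values]
    srt = sorted(values)
    n = len(srt)
    med = srt[n // 2] if n % 2 else (srt[n // 2 - 1] + srt[n // 2]) / 2
    m = mad_brute(values)
    if m == 0:
        return [True] * n
    return [abs(v - med) <= k * m for v in values]


def trimmed_mean_brute(values, trim):
    srt = sorted(float(v) for v in values)
    g = int(np.floor(len(srt) * trim))
    kept = srt[g : len(srt) - g] if g else srt
    return sum(kept) / len(kept)


def vif_brute(X):
    """VIF via inversion of the predictor correlation matrix diagonal."""
    X = np.asarray(X, dtype=float)
    R = np.corrcoef(X, rowvar=False)
    return np.diag(np.linalg.inv(R))


def inclusion_count_brute(observed, min_obs):
    """Number of individuals with >= min_obs observed waves (bool matrix)."""
    return sum(1 for row in observed if sum(bool(v) for v in row) >= min_obs)


def dependent_corr_diff_bootstrap(x, y1, y2, n_boot=2000, seed=0, alpha=0.05):
    """Percentile-bootstrap CI for corr(x,y1) - corr(x,y2)."""
    rng = np.random.default_rng(seed)
    n = len(x)
    diffs = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        xb, y1b, y2b = x[idx], y1[idx], y2[idx]
        r1 = np.corrcoef(xb, y1b)[0, 1]
        r2 = np.corrcoef(xb, y2b)[0, 1]
        diffs[b] = r1 - r2
    lo, hi = np.percentile(diffs, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def exact_corr_pair(n, r, rng):
    """Two vectors whose *sample* correlation is exactly ``r``."""
    x = rng.standard_normal(n)
    e = rng.standard_normal(n)
    x = (x - x.mean()) / x.std(ddof=1)
    # orthogonalize e against x, standardize
    e = e - e.mean()
    e = e - (e @ x) / (x @ x) * x
    e = e / e.std(ddof=1)
    y = r * x + np.sqrt(1 - r**2) * e
    y = (y - y.mean()) / y.std(ddof=1)
    return x, y
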