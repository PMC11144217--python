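"""Univariate twin variance decomposition.

Monozygotic (MZ) pairs share all additive-genetic influences, dizygotic
(DZ) pairs half of them on average; both share the common-environment
component.  The ACE model exploits this contrast: the expected
within-pair covariance is ``a² + c²`` for MZ and ``0.5 a² + c²`` for DZ,
with total variance ``a² + c² + e²``.  Fitting maximizes the
bivariate-normal likelihood over nonnegative variance components, with
saturated (per-zygosity) means, profile-likelihood or bootstrap CIs, and
the Falconer closed form as a starting point and sanity oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import (
    ConvergenceError,
    DegenerateScaleError,
    InsufficientDataError,
    ValidationError,
)

__all__ = [
    "simulate_twin_pairs",
    "pairs_from_cohort",
    "intraclass_corr",
    "falconer",
    "fit_ace",
    "AceEstimate",
]

_LOG2PI = float(np.log(2.0 * np.pi))


def simulate_twin_pairs(
    n_mz: int,
    n_dz: int,
    a2: float,
    c2: float,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Simulate standardized twin-pair trait values with known ACE structure.

    Utility for parameter-recovery and power studies: each pair's trait is
    ``sqrt(a2)·A + sqrt(c2)·C + sqrt(e2)·E`` with the usual MZ/DZ genetic
    sharing, so MZ covariance is ``a2 + c2`` and DZ covariance
    ``0.5·a2 + c2`` exactly.

    Returns a DataFrame with columns ``family_id, zygosity, trait1, trait2``.
    """
    if a2 < 0 or c2 < 0 or a2 + c2 > 1:
        raise ValidationError("need a2 >= 0, c2 >= 0, a2 + c2 <= 1")
    rng = np.random.default_rng(rng)
    e2 = 1.0 - a2 - c2
    frames = []
    for zyg, n, rho_a in (("MZ", n_mz, 1.0), ("DZ", n_dz, 0.5)):
        a1 = rng.standard_normal(n)
        a2_ = rho_a * a1 + np.sqrt(1 - rho_a**2) * rng.standard_normal(n)
        c = rng.standard_normal(n)
        t1 = np.sqrt(a2) * a1 + np.sqrt(c2) * c + np.sqrt(e2) * rng.standard_normal(n)
        t2 = np.sqrt(a2) * a2_ + np.sqrt(c2) * c + np.sqrt(e2) * rng.standard_normal(n)
        frames.append(
            pd.DataFrame(
                {
                    "family_id": [f"{zyg}{i:05d}" for i in range(n)],
                    "zygosity": zyg,
                    "trait1": t1,
                    "trait2": t2,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def pairs_from_cohort(
    cohort: pd.DataFrame,
    trait: str,
    family_col: str = "family_id",
    zygosity_col: str = "zygosity",
) -> pd.DataFrame:
    """Reshape an individual-level cohort into complete twin pairs.

    Keeps only families with exactly two members both non-missing on
    ``trait``.  Twin order within a family follows row order.
    """
    cols = [family_col, zygosity_col, trait]
    df = cohort[cols].copy()
    df["_pos"] = df.groupby(family_col).cumcount() + 1
    wide = df.pivot_table(
        index=[family_col, zygosity_col], columns="_pos", values=trait, aggfunc="first"
    ).reset_index()
    wide.columns = [family_col, zygosity_col, "trait1", "trait2"][: len(wide.columns)]
    if "trait2" not in wide.columns:
        wide["trait2"] = np.nan
    wide = wide.dropna(subset=["trait1", "trait2"]).reset_index(drop=True)
    return wide.rename(columns={family_col: "family_id", zygosity_col: "zygosity"})


def intraclass_corr(
    pairs: pd.DataFrame, zygosity: str | None = None, alpha: float = 0.05
) -> tuple[float, tuple[float, float]]:
    """ANOVA intraclass correlation for twin pairs with a Fisher-z CI.

    For pairs (k = 2 members per family) the one-way ANOVA ICC equals the
    double-entry Pearson correlation.  The CI uses the Fisher transform
    with the number of *pairs* as the effective sample size, which is
    conservative.
    """
    df = pairs if zygosity is None else pairs[pairs["zygosity"] == zygosity]
    y = df[["trait1", "trait2"]].to_numpy(dtype=float)
    y = y[np.all(np.isfinite(y), axis=1)]
    n = y.shape[0]
    if n < 5:
        raise InsufficientDataError(f"need >= 5 complete pairs, got {n}")
    grand = y.mean()
    msb = 2.0 * np.sum((y.mean(axis=1) - grand) ** 2) / (n - 1)
    msw = np.sum((y[:, 0] - y[:, 1]) ** 2) / (2.0 * n)
    if msb + msw == 0:
        raise DegenerateScaleError("zero variance in pair data")
    r = float((msb - msw) / (msb + msw))
    zcrit = stats.norm.ppf(1 - alpha / 2)
    se = 1.0 / np.sqrt(n - 3)
    r_clip = np.clip(r, -0.999999, 0.999999)
    lo = float(np.tanh(np.arctanh(r_clip) - zcrit * se))
    hi = float(np.tanh(np.arctanh(r_clip) + zcrit * se))
    return r, (lo, hi)


def falconer(r_mz: float, r_dz: float) -> tuple[float, float, float, bool]:
    """Closed-form ACE estimates from twin correlations.

    ``a² = 2(r_mz − r_dz)``, ``c² = r_mz − a²``, ``e² = 1 − r_mz``;
    components are clipped to [0, 1] and a flag reports whether clipping
    occurred.  Serves as the optimizer's starting point and an
    independent oracle for the maximum-likelihood fit.
    """
    for name, r in (("r_mz", r_mz), ("r_dz", r_dz)):
        if not -1 < r < 1:
            raise ValidationError(f"{name} must lie in (-1, 1)")
    a2 = 2.0 * (r_mz - r_dz)
    c2 = r_mz - a2
    e2 = 1.0 - r_mz
    clipped = not (0 <= a2 <= 1 and 0 <= c2 <= 1 and 0 <= e2 <= 1)
    return (
        float(np.clip(a2, 0, 1)),
        float(np.clip(c2, 0, 1)),
        float(np.clip(e2, 0, 1)),
        clipped,
    )


# ---------------------------------------------------------------------------
# maximum-likelihood ACE


@dataclass(frozen=True)
class AceEstimate:
    """Standardized variance proportions with fit metadata."""

    a2: float
    c2: float
    e2: float
    ci: dict = field(default_factory=dict)  # component -> (lower, upper)
    loglik: float = np.nan
    converged: bool = False
    iterations: int = 0
    boundary: bool = False
    n_mz: int = 0
    n_dz: int = 0


def _suffstats(pairs: pd.DataFrame) -> tuple[int, np.ndarray]:
    y = pairs[["trait1", "trait2"]].to_numpy(dtype=float)
    y = y[np.all(np.isfinite(y), axis=1)]
    n = y.shape[0]
    if n < 2:
        raise InsufficientDataError("need >= 2 complete pairs per zygosity")
    yc = y - y.mean(axis=0)  # saturated per-zygosity means, profiled out
    return n, yc.T @ yc / n


def _group_nll(n: int, S: np.ndarray, v: float, cov: float) -> float:
    det = v * v - cov * cov
    if det <= 0 or v <= 0:
        return np.inf
    # tr(Sigma^-1 S) for 2x2 exchangeable Sigma
    tr = (v * (S[0, 0] + S[1, 1]) - 2.0 * cov * S[0, 1]) / det
    return 0.5 * n * (2.0 * _LOG2PI + np.log(det) + tr)


def _nll(var: np.ndarray, stats_mz, stats_dz) -> float:
    va, vc, ve = var
    if va < 0 or vc < 0 or ve <= 0:
        return np.inf
    v = va + vc + ve
    n1, S1 = stats_mz
    n2, S2 = stats_dz
    return _group_nll(n1, S1, v, va + vc) + _group_nll(n2, S2, v, 0.5 * va + vc)


def fit_ace(
    mz: pd.DataFrame,
    dz: pd.DataFrame,
    ci: str | None = "profile",
    alpha: float = 0.05,
    n_boot: int = 200,
    seed: int = 0,
    ci_components: tuple = ("a2", "c2", "e2"),
) -> AceEstimate:
    """Maximum-likelihood ACE fit from MZ and DZ pair tables.

    Parameters
    ----------
    mz, dz : DataFrame
        Pair tables with ``trait1``/``trait2`` columns (see
        :func:`pairs_from_cohort`); incomplete pairs are dropped.
    ci : {"profile", "bootstrap", None}
        Confidence-interval method.  Profile likelihood inverts the
        chi-square(1) likelihood-ratio bound for each standardized
        component; bootstrap resamples families within zygosity.

    Notes
    -----
    The optimizer works on raw variance components (bounded below by
    zero) from the Falconer starting point plus five jittered restarts;
    estimates are standardized afterwards so ``a2 + c2 + e2 = 1``.
    Boundary solutions (a² or c² at zero) are flagged.
    """
    stats_mz = _suffstats(mz)
    stats_dz = _suffstats(dz)

    r_mz, _ = intraclass_corr(mz)
    r_dz, _ = intraclass_corr(dz)
    a2_0, c2_0, e2_0, _ = falconer(np.clip(r_mz, -0.99, 0.99), np.clip(r_dz, -0.99, 0.99))
    start = np.array([max(a2_0, 1e-3), max(c2_0, 1e-3), max(e2_0, 1e-3)])

    rng = np.random.default_rng(seed)
    starts = [start] + [
        np.clip(start * np.exp(rng.normal(0, 0.5, 3)), 1e-4, 10.0) for _ in range(5)
    ]
    best = None
    total_iter = 0
    bounds = [(0.0, None), (0.0, None), (1e-10, None)]
    for x0 in starts:
        res = optimize.minimize(
            _nll, x0, args=(stats_mz, stats_dz), method="L-BFGS-B", bounds=bounds
        )
        total_iter += res.nit
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise ConvergenceError("ACE likelihood optimization failed", best)
    va, vc, ve = best.x
    v = va + vc + ve
    est = np.array([va, vc, ve]) / v
    boundary = bool(est[0] < 1e-6 or est[1] < 1e-6)

    cis: dict = {}
    if ci == "profile":
        llmax = -best.fun
        for comp, idx in (("a2", 0), ("c2", 1), ("e2", 2)):
            if comp not in ci_components:
                continue
            cis[comp] = _profile_ci(
                idx, est[idx], llmax, stats_mz, stats_dz, alpha=alpha
            )
    elif ci == "bootstrap":
        cis = _bootstrap_ci(mz, dz, n_boot=n_boot, alpha=alpha, seed=seed)
    elif ci is not None:
        raise ValidationError(f"unknown ci method {ci!r}")

    return AceEstimate(
        a2=float(est[0]),
        c2=float(est[1]),
        e2=float(est[2]),
        ci=cis,
        loglik=float(-best.fun),
        converged=bool(best.success),
        iterations=int(total_iter),
        boundary=boundary,
        n_mz=stats_mz[0],
        n_dz=stats_dz[0],
    )


def _constrained_nll(prop: float, idx: int, stats_mz, stats_dz) -> float:
    """Profile NLL with component ``idx`` fixed at proportion ``prop``."""

    def inner(x: np.ndarray) -> float:
        s, v = x  # s = other proportion, v = total variance
        if v <= 0 or s < 0 or s > 1 - prop:
            return 1e12  # finite penalty keeps Nelder-Mead well-behaved
        props = np.empty(3)
        props[idx] = prop
        other_idx = [i for i in range(3) if i != idx]
        props[other_idx[0]] = s
        props[other_idx[1]] = 1.0 - prop - s
        val = _nll(props * v, stats_mz, stats_dz)
        return val if np.isfinite(val) else 1e12

    best = np.inf
    for s0 in (0.05, 0.3, 0.6):
        res = optimize.minimize(
            inner,
            np.array([min(s0, max(1 - prop - 1e-6, 0.0)), 1.0]),
            method="Nelder-Mead",
            options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 400},
        )
        best = min(best, res.fun)
    return best


def _profile_ci(
    idx: int, mle: float, llmax: float, stats_mz, stats_dz, alpha: float
) -> tuple[float, float]:
    crit = stats.chi2.ppf(1 - alpha, df=1) / 2.0
    # re-anchor at the profile value of the MLE so the deficit is exactly
    # zero there even when the inner optimizer is slightly suboptimal
    ll_anchor = max(llmax, -_constrained_nll(mle, idx, stats_mz, stats_dz))

    def deficit(p: float) -> float:
        return (_constrained_nll(p, idx, stats_mz, stats_dz) + ll_anchor) - crit

    # lower bound
    if mle <= 1e-9 or deficit(0.0) <= 0:
        lo = 0.0
    else:
        try:
            lo = optimize.brentq(deficit, 0.0, mle, xtol=1e-5)
        except ValueError:
            lo = 0.0
    # upper bound
    if mle >= 1 - 1e-9 or deficit(1.0 - 1e-9) <= 0:
        hi = 1.0
    else:
        try:
            hi = optimize.brentq(deficit, mle, 1.0 - 1e-9, xtol=1e-5)
        except ValueError:
            hi = 1.0
    return float(lo), float(hi)


def _bootstrap_ci(
    mz: pd.DataFrame, dz: pd.DataFrame, n_boot: int, alpha: float, seed: int
) -> dict:
    rng = np.random.default_rng(seed)
    draws = {"a2": [], "c2": [], "e2": []}
    for _ in range(n_boot):
        bmz = mz.sample(n=len(mz), replace=True, random_state=rng.integers(2**31))
        bdz = dz.sample(n=len(dz), replace=True, random_state=rng.integers(2**31))
        est = fit_ace(bmz, bdz, ci=None)
        draws["a2"].append(est.a2)
        draws["c2"].append(est.c2)
        draws["e2"].append(est.e2)
    qs = (alpha / 2 * 100, (1 - alpha / 2) * 100)
    return {
        comp: tuple(np.percentile(vals, qs).astype(float)) for comp, vals in draws.items()
    }
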