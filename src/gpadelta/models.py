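"""Regression machinery: correlations with CIs, hierarchical OLS with
semi-partial R² and nested F-tests, SES-style moderation, VIF
diagnostics, repeated cross-validated multi-score weighting, and
dependent-correlation comparison.

All regressions are complete-case.  OLS fits are delegated to
statsmodels; every reported quantity is cross-checked in the test suite
against explicit normal-equations implementations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import LinearRegression
from sklearn.metrics import r2_score
from sklearn.model_selection import RepeatedKFold, RepeatedStratifiedKFold

from .errors import (
    CollinearityError,
    DegenerateScaleError,
    InsufficientDataError,
    ValidationError,
)

__all__ = [
    "pearson_ci",
    "CorrelationResult",
    "hierarchical_regression",
    "RegressionReport",
    "moderation_test",
    "ModerationResult",
    "vif",
    "multi_gps_weights",
    "CvWeights",
    "joint_delta_regression",
    "compare_correlations",
    "CorrelationComparison",
]


# ---------------------------------------------------------------------------
# correlations


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    ci_lower: float
    ci_upper: float
    p_value: float
    n: int


def pearson_ci(x, y, alpha: float = 0.05) -> CorrelationResult:
    """Pearson correlation with a Fisher-z confidence interval.

    The CI back-transforms ``atanh(r) ± z_{1-alpha/2} / sqrt(n-3)``.
    Missing entries are dropped pairwise; at least four complete pairs
    are required.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    mask = np.isfinite(xv) & np.isfinite(yv)
    n = int(mask.sum())
    if n < 4:
        raise InsufficientDataError(f"need >= 4 complete pairs, got {n}")
    xs, ys = xv[mask], yv[mask]
    if np.std(xs) == 0 or np.std(ys) == 0:
        raise DegenerateScaleError("constant input in pearson_ci")
    r, p = stats.pearsonr(xs, ys)
    zcrit = stats.norm.ppf(1 - alpha / 2)
    if abs(r) >= 1.0:
        lo, hi = r, r
    else:
        z = np.arctanh(r)
        se = 1.0 / np.sqrt(n - 3)
        lo, hi = np.tanh(z - zcrit * se), np.tanh(z + zcrit * se)
    return CorrelationResult(float(r), float(lo), float(hi), float(p), n)


# ---------------------------------------------------------------------------
# hierarchical regression


@dataclass(frozen=True)
class RegressionReport:
    """One fitted model within a hierarchical sequence."""

    formula: str
    coef: pd.DataFrame  # index: term; columns: estimate, beta, ci_lower, ci_upper, p
    r_squared: float
    semipartial_r2_focal: float
    partial_r2_focal: float
    nested_f: float | None = None
    nested_df: tuple[int, int] | None = None
    nested_p: float | None = None
    n: int = 0


def _complete_frame(data: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValidationError(f"columns not in data: {missing}")
    return data[cols].dropna()


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # identify offending columns via near-zero pivots of a pivoted QR proxy
        bad = []
        for j in range(1, X.shape[1]):
            sub = X[:, : j + 1]
            if np.linalg.matrix_rank(sub) < sub.shape[1]:
                bad.append(names[j - 1] if j <= len(names) else f"col{j}")
        raise CollinearityError(f"rank-deficient design; offending columns: {bad}")


def _fit_ols(df: pd.DataFrame, outcome: str, predictors: list[str]):
    X = sm.add_constant(df[predictors].to_numpy(dtype=float), has_constant="add")
    _check_rank(X, predictors)
    return sm.OLS(df[outcome].to_numpy(dtype=float), X).fit()


def _coef_table(
    fit, predictors: list[str], df: pd.DataFrame, outcome: str, alpha: float
) -> pd.DataFrame:
    ci = fit.conf_int(alpha=alpha)
    sd_y = df[outcome].std(ddof=1)
    rows = []
    for i, name in enumerate(["const"] + predictors):
        beta = np.nan
        if name != "const":
            beta = fit.params[i] * df[name].std(ddof=1) / sd_y
        rows.append(
            {
                "term": name,
                "estimate": fit.params[i],
                "beta": beta,
                "ci_lower": ci[i][0],
                "ci_upper": ci[i][1],
                "p": fit.pvalues[i],
            }
        )
    return pd.DataFrame(rows).set_index("term")


def hierarchical_regression(
    data: pd.DataFrame,
    outcome: str,
    focal: str,
    covariate_blocks: list[list[str]],
    alpha: float = 0.05,
) -> list[RegressionReport]:
    """Sequence of OLS models adding covariate blocks around a focal predictor.

    Model 1 regresses the outcome on the focal predictor alone; each
    subsequent model adds the next covariate block.  For every model the
    focal predictor's unique contribution is reported as the semi-partial
    R² — the drop in R² when the focal term is removed from that model —
    alongside the squared-partial-correlation variant.  Models after the
    first also carry a nested F-test against Model 1 computed from the
    residual sums of squares.

    Complete cases over *all* variables are used for every model so the
    sequence is comparable.
    """
    cols = [outcome, focal] + [c for block in covariate_blocks for c in block]
    df = _complete_frame(data, cols)
    n = len(df)
    if n < len(cols) + 2:
        raise InsufficientDataError(f"{n} complete rows for {len(cols)} variables")

    reports: list[RegressionReport] = []
    predictors: list[str] = [focal]
    base_fit = None
    for step in range(len(covariate_blocks) + 1):
        fit = _fit_ols(df, outcome, predictors)
        others = [p for p in predictors if p != focal]
        if others:
            reduced = _fit_ols(df, outcome, others)
            sp_r2 = fit.rsquared - reduced.rsquared
            partial = sp_r2 / (1.0 - reduced.rsquared) if reduced.rsquared < 1 else np.nan
        else:
            sp_r2 = fit.rsquared
            partial = fit.rsquared
        nested_f = nested_df = nested_p = None
        if step == 0:
            base_fit = fit
        else:
            df_num = int(base_fit.df_resid - fit.df_resid)
            df_den = int(fit.df_resid)
            if df_num > 0 and df_den > 0:
                f = ((base_fit.ssr - fit.ssr) / df_num) / (fit.ssr / df_den)
                nested_f = float(f)
                nested_df = (df_num, df_den)
                nested_p = float(stats.f.sf(f, df_num, df_den))
        reports.append(
            RegressionReport(
                formula=f"{outcome} ~ {' + '.join(predictors)}",
                coef=_coef_table(fit, predictors, df, outcome, alpha),
                r_squared=float(fit.rsquared),
                semipartial_r2_focal=float(sp_r2),
                partial_r2_focal=float(partial),
                nested_f=nested_f,
                nested_df=nested_df,
                nested_p=nested_p,
                n=n,
            )
        )
        if step < len(covariate_blocks):
            predictors = predictors + covariate_blocks[step]
    return reports


# ---------------------------------------------------------------------------
# moderation


@dataclass(frozen=True)
class ModerationResult:
    interaction_estimate: float
    interaction_beta: float
    ci_lower: float
    ci_upper: float
    p_value: float
    n: int
    coef: pd.DataFrame = field(repr=False, default=None)


def moderation_test(
    data: pd.DataFrame,
    outcome: str,
    focal: str,
    moderator: str,
    covariates: list[str] | None = None,
    alpha: float = 0.05,
) -> ModerationResult:
    """Test whether ``moderator`` moderates the focal→outcome association.

    Focal and moderator are z-scored on the complete-case sample before
    forming the product term, then the outcome is regressed on focal,
    moderator, covariates, and focal×moderator.  The reported quantity is
    the interaction coefficient with its CI and p-value.
    """
    covariates = covariates or []
    cols = [outcome, focal, moderator] + covariates
    df = _complete_frame(data, cols).copy()
    for c in (focal, moderator):
        sd = df[c].std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValidationError(f"{c} is constant; moderation not estimable")
        df[c] = (df[c] - df[c].mean()) / sd
    df["_interaction"] = df[focal] * df[moderator]
    predictors = [focal, moderator] + covariates + ["_interaction"]
    fit = _fit_ols(df, outcome, predictors)
    table = _coef_table(fit, predictors, df, outcome, alpha)
    row = table.loc["_interaction"]
    return ModerationResult(
        interaction_estimate=float(row["estimate"]),
        interaction_beta=float(row["beta"]),
        ci_lower=float(row["ci_lower"]),
        ci_upper=float(row["ci_upper"]),
        p_value=float(row["p"]),
        n=len(df),
        coef=table,
    )


# ---------------------------------------------------------------------------
# collinearity


def vif(design) -> np.ndarray:
    """Variance inflation factor per predictor, ``1 / (1 - R²_j)``.

    ``R²_j`` comes from regressing predictor j (with intercept) on all
    other predictors.  Perfectly collinear predictors yield ``inf`` with
    a warning rather than an exception.
    """
    if isinstance(design, pd.DataFrame):
        X = design.to_numpy(dtype=float)
    else:
        X = np.asarray(design, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValidationError("vif needs >= 2 predictor columns")
    if X.shape[0] <= X.shape[1]:
        raise InsufficientDataError("vif needs more rows than predictors")
    out = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        others = np.delete(X, j, axis=1)
        A = np.column_stack([np.ones(X.shape[0]), others])
        coef, *_ = np.linalg.lstsq(A, X[:, j], rcond=None)
        resid = X[:, j] - A @ coef
        tss = float(np.sum((X[:, j] - X[:, j].mean()) ** 2))
        if tss == 0:
            raise DegenerateScaleError(f"predictor {j} is constant")
        r2 = 1.0 - float(resid @ resid) / tss
        if r2 >= 1.0 - 1e-12:
            warnings.warn(f"predictor {j} is perfectly collinear; VIF is inf")
            out[j] = np.inf
        else:
            out[j] = 1.0 / (1.0 - r2)
    return out


# ---------------------------------------------------------------------------
# multi-score cross-validated weights


@dataclass(frozen=True)
class CvWeights:
    names: list[str]
    weights: np.ndarray  # full-sample OLS coefficients (no intercept entry)
    intercept: float
    cv_r2_mean: float
    cv_r2_sd: float
    full_r2: float
    vif: np.ndarray
    k: int
    repeats: int
    seed: int


def multi_gps_weights(
    gps_matrix,
    target,
    k: int = 10,
    repeats: int = 3,
    seed: int = 0,
    stratify: bool = True,
) -> CvWeights:
    """Weight multiple polygenic scores by repeated k-fold cross-validation.

    Runs a repeated k-fold cross-validation of the multiple regression of
    ``target`` on all score columns, reporting the mean and SD of the
    held-out R² across folds.  The returned weights are the coefficients
    of the full-sample fit, so a weighted-mean composite score can be
    formed as ``gps_matrix @ weights``.  Folds are stratified by target
    decile by default to stabilize small-fold variance.
    """
    if isinstance(gps_matrix, pd.DataFrame):
        names = list(gps_matrix.columns)
        X = gps_matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(gps_matrix, dtype=float)
        names = [f"gps{i + 1}" for i in range(X.shape[1])]
    y = np.asarray(target, dtype=float)
    mask = np.all(np.isfinite(X), axis=1) & np.isfinite(y)
    X, y = X[mask], y[mask]
    if k < 2:
        raise ValidationError("k must be >= 2")
    if len(y) < 10 * k:
        raise InsufficientDataError(f"need n >= {10 * k} rows, got {len(y)}")

    for attempt in range(5):
        rs = seed + attempt
        if stratify:
            bins = np.searchsorted(
                np.quantile(y, np.linspace(0.1, 0.9, 9)), y, side="right"
            )
            splitter = RepeatedStratifiedKFold(
                n_splits=k, n_repeats=repeats, random_state=rs
            )
            split_iter = splitter.split(X, bins)
        else:
            splitter = RepeatedKFold(n_splits=k, n_repeats=repeats, random_state=rs)
            split_iter = splitter.split(X)
        scores = []
        degenerate = False
        for train, test in split_iter:
            if np.std(y[train]) == 0:
                degenerate = True
                break
            model = LinearRegression().fit(X[train], y[train])
            scores.append(r2_score(y[test], model.predict(X[test])))
        if not degenerate:
            break
        warnings.warn(f"constant-target fold at seed {rs}; refolding")
    else:  # pragma: no cover - essentially unreachable with real data
        raise ValidationError("could not build non-degenerate folds")

    full = LinearRegression().fit(X, y)
    return CvWeights(
        names=names,
        weights=np.asarray(full.coef_, dtype=float),
        intercept=float(full.intercept_),
        cv_r2_mean=float(np.mean(scores)),
        cv_r2_sd=float(np.std(scores, ddof=1)),
        full_r2=float(full.score(X, y)),
        vif=vif(X),
        k=k,
        repeats=repeats,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# joint delta regression


def joint_delta_regression(
    data: pd.DataFrame,
    outcome: str = "slope_z",
    delta_a: str = "gpa_delta",
    delta_b: str = "cog_delta",
    alpha: float = 0.05,
) -> RegressionReport:
    """Two-predictor OLS of an outcome on both discrepancy measures.

    Reports standardized betas and the joint R².  If the two predictors
    are perfectly collinear the second is dropped and the fit reduces to
    the single-predictor model (flagged in the formula string).
    """
    df = _complete_frame(data, [outcome, delta_a, delta_b])
    predictors = [delta_a, delta_b]
    X = sm.add_constant(df[predictors].to_numpy(dtype=float), has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        warnings.warn(f"{delta_b} collinear with {delta_a}; dropping it")
        predictors = [delta_a]
    fit = _fit_ols(df, outcome, predictors)
    return RegressionReport(
        formula=f"{outcome} ~ {' + '.join(predictors)}",
        coef=_coef_table(fit, predictors, df, outcome, alpha),
        r_squared=float(fit.rsquared),
        semipartial_r2_focal=float(fit.rsquared),
        partial_r2_focal=float(fit.rsquared),
        n=len(df),
    )


# ---------------------------------------------------------------------------
# dependent overlapping correlations


@dataclass(frozen=True)
class CorrelationComparison:
    r1: float
    r2: float
    difference: float
    ci_lower: float
    ci_upper: float
    significant: bool


def compare_correlations(
    r1: float,
    r2: float,
    n: int,
    overlap: float,
    alpha: float = 0.05,
) -> CorrelationComparison:
    """Zou's CI for the difference of two dependent overlapping correlations.

    ``r1 = corr(x, y1)`` and ``r2 = corr(x, y2)`` share the variable
    ``x``; ``overlap = corr(y1, y2)``.  The method combines the
    individual Fisher-z CIs of r1 and r2 with the sampling correlation
    between the two estimates; a difference is declared when the CI of
    ``r1 - r2`` excludes zero.
    """
    for name, r in (("r1", r1), ("r2", r2), ("overlap", overlap)):
        if not -1 < r < 1:
            raise ValidationError(f"{name} must lie strictly inside (-1, 1)")
    if n < 4:
        raise InsufficientDataError("need n >= 4")
    zcrit = stats.norm.ppf(1 - alpha / 2)
    se = 1.0 / np.sqrt(n - 3)

    def fisher_ci(r: float) -> tuple[float, float]:
        z = np.arctanh(r)
        return float(np.tanh(z - zcrit * se)), float(np.tanh(z + zcrit * se))

    l1, u1 = fisher_ci(r1)
    l2, u2 = fisher_ci(r2)
    # sampling correlation between r1-hat and r2-hat (overlapping case)
    num = (overlap - 0.5 * r1 * r2) * (1 - r1**2 - r2**2 - overlap**2) + overlap**3
    den = (1 - r1**2) * (1 - r2**2)
    c = num / den
    diff = r1 - r2
    lo = diff - np.sqrt((r1 - l1) ** 2 + (u2 - r2) ** 2 - 2 * c * (r1 - l1) * (u2 - r2))
    hi = diff + np.sqrt((u1 - r1) ** 2 + (r2 - l2) ** 2 - 2 * c * (u1 - r1) * (r2 - l2))
    return CorrelationComparison(
        r1=float(r1),
        r2=float(r2),
        difference=float(diff),
        ci_lower=float(lo),
        ci_upper=float(hi),
        significant=bool(lo > 0 or hi < 0),
    )
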