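"""Regression toward prediction, achiever-group classification, and
trajectory summaries.

The central quantity is the per-individual regression percentage
``(1 - delta16/delta7) * 100``: 100 means the age-7 discrepancy from the
genomic prediction has vanished by age 16, 0 means it is unchanged, and
negative values mean it grew.  Because the denominator can be tiny, the
cohort summary is a symmetric trimmed mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptyInputError, ValidationError
from .scores import STANDARDIZED_TOL, check_standardized
from .slopes import fit_slope

__all__ = [
    "trimmed_mean",
    "regression_percentage",
    "classify_groups",
    "assign_deciles",
    "decile_trajectories",
    "group_trajectory_summary",
    "GROUP_LABELS",
]

GROUP_LABELS = (
    "absolute_underachiever",
    "relative_underachiever",
    "relative_overachiever",
    "absolute_overachiever",
)


def trimmed_mean(values, trim: float = 0.05) -> float:
    """Symmetric trimmed mean dropping ``floor(n*trim)`` values per tail.

    ``trim`` is the proportion removed from *each* tail (so ``trim=0.05``
    removes 10% of the data in total).  NaN entries are ignored.
    """
    if not 0 <= trim < 0.5:
        raise ValidationError(f"trim must be in [0, 0.5), got {trim}")
    x = np.asarray(values, dtype=float)
    x = np.sort(x[np.isfinite(x)])
    if x.size == 0:
        raise EmptyInputError("trimmed_mean of an empty vector")
    g = int(np.floor(x.size * trim))
    if x.size - 2 * g <= 0:
        raise EmptyInputError("nothing left after trimming")
    return float(x[g : x.size - g].mean())


def regression_percentage(
    delta_7,
    delta_16,
    trim: float = 0.05,
    eps: float = 0.0,
) -> tuple[np.ndarray, float]:
    """Per-individual regression-to-prediction percentages and their summary.

    Each individual's percentage is ``(1 - delta_16/delta_7) * 100``.
    Individuals whose age-7 delta is smaller than ``eps`` in magnitude
    (and any non-finite ratio) are excluded from the summary, which is
    the ``trim``-trimmed mean of the rest.

    Returns
    -------
    (percentages, summary)
        ``percentages`` has one entry per individual (NaN/inf where
        undefined); ``summary`` is the trimmed mean over included
        individuals.
    """
    d7 = np.asarray(delta_7, dtype=float)
    d16 = np.asarray(delta_16, dtype=float)
    if d7.shape != d16.shape:
        raise ValidationError("delta_7 and delta_16 must have equal length")
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = (1.0 - d16 / d7) * 100.0
    include = np.isfinite(pct) & (np.abs(d7) > eps)
    if not include.any():
        raise EmptyInputError("no individuals eligible for the summary")
    return pct, trimmed_mean(pct[include], trim)


def classify_groups(
    delta,
    achievement_7,
    delta_threshold: float = 1.0,
    achievement_threshold: float = 1.0,
    tol: float = STANDARDIZED_TOL,
) -> pd.DataFrame:
    """Label relative and absolute under/over-achievers.

    Relative groups lie beyond ``delta_threshold`` SDs of the delta mean
    on either side.  Absolute groups are the subset of relative members
    whose (standardized) age-7 achievement additionally lies beyond
    ``achievement_threshold`` on the matching side.

    Parameters
    ----------
    delta : array-like
        Discrepancy score at age 7 (any location/scale; thresholds are
        applied relative to its own mean and SD).
    achievement_7 : array-like
        Standardized age-7 achievement (validated to tolerance ``tol``).

    Returns
    -------
    pandas.DataFrame
        Columns ``relative_group`` and ``absolute_group`` with values in
        {"underachiever", "overachiever", "none"}; rows with missing
        inputs are "none".
    """
    d = np.asarray(delta, dtype=float)
    a = np.asarray(achievement_7, dtype=float)
    if d.shape != a.shape:
        raise ValidationError("delta and achievement_7 must have equal length")
    check_standardized(a, "achievement_7", tol)
    finite = np.isfinite(d)
    mu = float(np.mean(d[finite]))
    sd = float(np.std(d[finite], ddof=1))
    if sd == 0.0:
        raise ValidationError("delta has zero variance")
    lo = mu - delta_threshold * sd
    hi = mu + delta_threshold * sd

    rel_under = finite & (d <= lo)
    rel_over = finite & (d >= hi)
    ach_ok = np.isfinite(a)
    abs_under = rel_under & ach_ok & (a <= -achievement_threshold)
    abs_over = rel_over & ach_ok & (a >= achievement_threshold)

    relative = np.where(rel_under, "underachiever",
                        np.where(rel_over, "overachiever", "none"))
    absolute = np.where(abs_under, "underachiever",
                        np.where(abs_over, "overachiever", "none"))
    return pd.DataFrame({"relative_group": relative, "absolute_group": absolute})


def assign_deciles(delta, achievement_7, band: float = 0.5) -> np.ndarray:
    """Decile membership (1..10) among the mid-achievement band.

    Eligible individuals have standardized age-7 achievement within
    ``band`` SDs of the mean and a non-missing delta.  They are ranked by
    (delta, position) — a stable order — and split into 10 contiguous
    groups whose sizes differ by at most one.  Decile 1 holds the most
    negative deltas.  Ineligible individuals get 0.
    """
    d = np.asarray(delta, dtype=float)
    a = np.asarray(achievement_7, dtype=float)
    eligible = np.isfinite(d) & np.isfinite(a) & (np.abs(a) <= band)
    n_el = int(eligible.sum())
    if n_el < 10:
        raise EmptyInputError(f"only {n_el} eligible individuals for 10 deciles")
    idx = np.flatnonzero(eligible)
    order = idx[np.lexsort((idx, d[idx]))]
    deciles = np.zeros(d.size, dtype=int)
    for q, chunk in enumerate(np.array_split(order, 10), start=1):
        deciles[chunk] = q
    return deciles


def _mean_se(col: np.ndarray) -> tuple[float, float, int]:
    v = col[np.isfinite(col)]
    n = v.size
    if n == 0:
        return np.nan, np.nan, 0
    se = float(np.std(v, ddof=1) / np.sqrt(n)) if n > 1 else np.nan
    return float(v.mean()), se, n


def decile_trajectories(
    delta,
    achievement_by_age,
    ages,
    band: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-decile mean achievement trajectories within the average band.

    Restricts to individuals whose age-7 (first-column) achievement is
    within ``band`` SDs of the mean, stratifies them by delta decile, and
    summarizes achievement at each age per decile, together with an OLS
    line through each decile's per-age means.

    Returns
    -------
    (summary, fits)
        ``summary``: one row per decile × age with mean, SE and n.
        ``fits``: one row per decile with the fitted slope and intercept.
    """
    Y = np.asarray(achievement_by_age, dtype=float)
    x = np.asarray(ages, dtype=float)
    if Y.ndim != 2 or Y.shape[1] != x.size:
        raise ValidationError("achievement_by_age must be (n, n_ages)")
    deciles = assign_deciles(delta, Y[:, 0], band=band)
    rows, fit_rows = [], []
    for q in range(1, 11):
        members = deciles == q
        means = []
        for j, age in enumerate(x):
            m, se, n = _mean_se(Y[members, j])
            rows.append({"decile": q, "age": age, "mean": m, "se": se, "n": n})
            means.append(m)
        slope, intercept, _ = fit_slope(x, np.asarray(means), min_points=3)
        fit_rows.append(
            {"decile": q, "n_members": int(members.sum()),
             "fit_slope": slope, "fit_intercept": intercept}
        )
    return pd.DataFrame(rows), pd.DataFrame(fit_rows)


@dataclass(frozen=True)
class GroupRegression:
    """Regression percentages for one achiever group, both computation modes."""

    group: str
    n: int
    pct_trimmed_individual: float
    pct_from_group_means: float


def group_trajectory_summary(
    groups: pd.DataFrame,
    achievement_by_age,
    ages,
    delta_7,
    delta_16,
    trim: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean ± SE trajectory and regression percentage per achiever group.

    Empty groups yield rows of NaN rather than an error.  The regression
    percentage is reported two ways: the trimmed mean of individual
    percentages, and the percentage computed from the group-mean deltas
    ``(1 - mean(d16)/mean(d7)) * 100``.
    """
    Y = np.asarray(achievement_by_age, dtype=float)
    x = np.asarray(ages, dtype=float)
    d7 = np.asarray(delta_7, dtype=float)
    d16 = np.asarray(delta_16, dtype=float)
    masks = {
        "relative_underachiever": groups["relative_group"].to_numpy() == "underachiever",
        "relative_overachiever": groups["relative_group"].to_numpy() == "overachiever",
        "absolute_underachiever": groups["absolute_group"].to_numpy() == "underachiever",
        "absolute_overachiever": groups["absolute_group"].to_numpy() == "overachiever",
    }
    rows, pct_rows = [], []
    for label in GROUP_LABELS:
        members = masks[label]
        n_members = int(members.sum())
        for j, age in enumerate(x):
            if n_members:
                m, se, n = _mean_se(Y[members, j])
            else:
                m, se, n = np.nan, np.nan, 0
            rows.append({"group": label, "age": age, "mean": m, "se": se, "n": n})
        if n_members:
            try:
                _, pct_ind = regression_percentage(d7[members], d16[members], trim=trim)
            except EmptyInputError:
                pct_ind = np.nan
            pair = members & np.isfinite(d7) & np.isfinite(d16)
            m7 = float(np.mean(d7[pair])) if pair.any() else np.nan
            m16 = float(np.mean(d16[pair])) if pair.any() else np.nan
            pct_grp = (1.0 - m16 / m7) * 100.0 if pair.any() and m7 != 0 else np.nan
        else:
            pct_ind, pct_grp = np.nan, np.nan
        pct_rows.append(
            {"group": label, "n": n_members,
             "pct_trimmed_individual": pct_ind, "pct_from_group_means": pct_grp}
        )
    return pd.DataFrame(rows), pd.DataFrame(pct_rows)
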