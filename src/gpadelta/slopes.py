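"""Per-individual achievement slopes across assessment ages.

Each individual's standardized achievement is regressed on age with
ordinary least squares; the fitted slope summarizes the trajectory.
Outlying slopes are flagged with a median-absolute-deviation rule and the
retained slopes are re-standardized for analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateScaleError, EmptyInputError, InsufficientDataError

__all__ = [
    "fit_slope",
    "fit_cohort_slopes",
    "mad",
    "mad_filter",
    "standardize_slopes",
    "slope_table",
    "MadZeroWarning",
]

#: scale factor that makes the MAD a consistent estimator of the normal SD.
NORMAL_CONSISTENCY = 1.4826022185056018


class MadZeroWarning(UserWarning):
    """MAD is zero on non-constant data; no filtering is possible."""


def fit_slope(ages, scores, min_points: int = 3) -> tuple[float, float, int]:
    """OLS line of best fit of score on age for one individual.

    Parameters
    ----------
    ages : array-like of float
        Assessment ages (the x variable), in raw years.
    scores : array-like of float
        Standardized achievement at each age; NaN marks missing waves.
    min_points : int
        Minimum non-missing (age, score) pairs; individuals below this
        are excluded from slope analyses.

    Returns
    -------
    (slope, intercept, n_points)

    Raises
    ------
    InsufficientDataError
        Fewer than ``min_points`` complete pairs.
    DegenerateScaleError
        No variance in the observed ages.
    """
    x = np.asarray(ages, dtype=float)
    y = np.asarray(scores, dtype=float)
    if x.shape != y.shape:
        raise ValueError("ages and scores must have equal length")
    mask = np.isfinite(x) & np.isfinite(y)
    n = int(mask.sum())
    if n < min_points:
        raise InsufficientDataError(
            f"{n} observed ages < required minimum of {min_points}"
        )
    xm = x[mask]
    ym = y[mask]
    xc = xm - xm.mean()
    sxx = float(xc @ xc)
    if sxx == 0.0:
        raise DegenerateScaleError("zero variance in ages")
    slope = float(xc @ (ym - ym.mean())) / sxx
    intercept = float(ym.mean() - slope * xm.mean())
    return slope, intercept, n


def fit_cohort_slopes(
    score_matrix, ages, min_points: int = 3
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized :func:`fit_slope` over the rows of an (n, T) score matrix.

    Rows with fewer than ``min_points`` observed ages get NaN slope and
    intercept.  Rows sharing a missingness pattern are solved together,
    so complete cohorts reduce to a single matrix product.

    Returns
    -------
    (slopes, intercepts, n_points) : arrays of shape (n,)
    """
    Y = np.asarray(score_matrix, dtype=float)
    x = np.asarray(ages, dtype=float)
    if Y.ndim != 2 or Y.shape[1] != x.size:
        raise ValueError("score_matrix must be (n_individuals, n_ages)")
    n, T = Y.shape
    obs = np.isfinite(Y)
    n_points = obs.sum(axis=1)
    slopes = np.full(n, np.nan)
    intercepts = np.full(n, np.nan)

    # group rows by missingness pattern (at most 2**T patterns)
    codes = obs @ (1 << np.arange(T))
    for code in np.unique(codes):
        pattern = (code >> np.arange(T)) & 1 == 1
        k = int(pattern.sum())
        if k < min_points:
            continue
        rows = codes == code
        xm = x[pattern]
        xc = xm - xm.mean()
        sxx = float(xc @ xc)
        if sxx == 0.0:
            raise DegenerateScaleError("zero variance in observed ages")
        Ym = Y[np.ix_(rows, pattern)]
        ybar = Ym.mean(axis=1)
        slopes[rows] = (Ym - ybar[:, None]) @ xc / sxx
        intercepts[rows] = ybar - slopes[rows] * xm.mean()
    return slopes, intercepts, n_points


def mad(values) -> float:
    """Raw median absolute deviation, ``median(|x_i - median(x)|)``.

    No consistency constant is applied; multiply by
    :data:`NORMAL_CONSISTENCY` to estimate a normal SD.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise EmptyInputError("mad of an empty vector")
    med = float(np.median(x))
    return float(np.median(np.abs(x - med)))


def mad_filter(values, k: float = 3.0, consistency: bool = False) -> np.ndarray:
    """Boolean mask of entries retained by the k×MAD outlier rule.

    An entry is retained iff ``|x - median| <= k * MAD`` (strictly
    *exceeding* the threshold removes).  When the MAD is zero on
    non-constant data no filtering is possible: a :class:`MadZeroWarning`
    is emitted and all finite entries are retained.  NaN entries are
    never retained.

    Parameters
    ----------
    values : array-like of float
    k : float
        Threshold multiple, default 3.
    consistency : bool
        If True, scale the MAD by the normal-consistency constant 1.4826
        before thresholding.
    """
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    if not finite.any():
        raise EmptyInputError("mad_filter of an all-missing vector")
    xf = x[finite]
    med = float(np.median(xf))
    m = mad(xf)
    if consistency:
        m *= NORMAL_CONSISTENCY
    if m == 0.0:
        if np.any(xf != xf[0]):
            warnings.warn(
                "MAD is zero on non-constant data; retaining all entries",
                MadZeroWarning,
                stacklevel=2,
            )
        return finite
    keep = np.zeros_like(finite)
    keep[finite] = np.abs(xf - med) <= k * m
    return keep


def standardize_slopes(slopes, retained) -> np.ndarray:
    """Z-score slopes over the retained (post-filter) individuals.

    Entries not retained come back NaN.  Raises
    :class:`EmptyInputError` / :class:`DegenerateScaleError` when nothing
    (or only one value) survives the filter.
    """
    x = np.asarray(slopes, dtype=float)
    keep = np.asarray(retained, dtype=bool)
    if x.shape != keep.shape:
        raise ValueError("slopes and retained mask must have equal length")
    if not keep.any():
        raise EmptyInputError("no retained slopes to standardize")
    kept = x[keep]
    if kept.size < 2 or np.std(kept, ddof=1) == 0.0:
        raise DegenerateScaleError("retained slopes have no scale")
    out = np.full_like(x, np.nan)
    out[keep] = (kept - kept.mean()) / np.std(kept, ddof=1)
    return out


@dataclass(frozen=True)
class SlopeParams:
    """Knobs for :func:`slope_table` (defaults follow the analysis protocol)."""

    min_points: int = 3
    k_mad: float = 3.0
    consistency: bool = False
    filter_before_standardize: bool = True


def slope_table(
    individual_ids,
    score_matrix,
    ages,
    params: SlopeParams | None = None,
) -> pd.DataFrame:
    """Fit, filter, and standardize slopes for a whole cohort.

    Returns a DataFrame with columns ``individual_id``, ``slope``,
    ``intercept``, ``n_points``, ``outlier`` and ``slope_z``.  ``outlier``
    is True for fitted slopes removed by the MAD rule; ``slope_z`` is NaN
    for outliers and for individuals with too few observations.
    """
    p = params or SlopeParams()
    slopes, intercepts, n_points = fit_cohort_slopes(
        score_matrix, ages, min_points=p.min_points
    )
    fitted = np.isfinite(slopes)
    if not fitted.any():
        raise EmptyInputError("no individual has enough observations")
    if p.filter_before_standardize:
        keep = mad_filter(slopes, k=p.k_mad, consistency=p.consistency)
        slope_z = standardize_slopes(slopes, keep)
    else:  # standardize first, filter the z-scores
        prelim = standardize_slopes(slopes, fitted)
        keep = mad_filter(prelim, k=p.k_mad, consistency=p.consistency)
        slope_z = standardize_slopes(slopes, keep)
    return pd.DataFrame(
        {
            "individual_id": np.asarray(individual_ids),
            "slope": slopes,
            "intercept": intercepts,
            "n_points": n_points,
            "outlier": fitted & ~keep,
            "slope_z": slope_z,
        }
    )
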