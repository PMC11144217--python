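"""Standardization, achievement composites, and discrepancy (delta) scores.

A delta score is standardized observed achievement minus a standardized
prediction of achievement.  With a polygenic score as the predictor the
delta indexes genomically defined under/over-achievement (negative =
underachievement); with a cognitive-ability score it is the traditional
ability-achievement discrepancy.  Both a plain difference and a
residualized variant are supported.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import (
    DegenerateScaleError,
    EmptyInputError,
    InsufficientDataError,
    ValidationError,
)

__all__ = [
    "zscore",
    "composite",
    "delta",
    "residualize",
    "check_standardized",
]

#: tolerance used when asserting that an input vector is already z-scored.
#: Loose on purpose: listwise alignment of columns standardized on slightly
#: different non-missing subsets shifts means away from exactly zero.
STANDARDIZED_TOL = 0.1


def zscore(values) -> np.ndarray:
    """Z-score a vector, propagating missing values.

    Non-missing entries are centered and scaled to sample mean 0 and
    sample standard deviation 1 (denominator ``n - 1``).  NaN entries are
    preserved in place.

    Parameters
    ----------
    values : array-like of float
        Input vector; NaN marks missing.

    Returns
    -------
    numpy.ndarray
        Standardized copy of ``values``.

    Raises
    ------
    EmptyInputError
        If every entry is missing.
    DegenerateScaleError
        If fewer than two non-missing entries remain or their sample
        standard deviation is zero.
    """
    x = np.asarray(values, dtype=float).copy()
    mask = np.isfinite(x)
    n = int(mask.sum())
    if n == 0:
        raise EmptyInputError("cannot z-score an all-missing vector")
    if n < 2:
        raise DegenerateScaleError("need >= 2 non-missing values to z-score")
    sd = float(np.std(x[mask], ddof=1))
    if sd == 0.0:
        raise DegenerateScaleError("constant input has no scale")
    x[mask] = (x[mask] - float(np.mean(x[mask]))) / sd
    return x


def composite(subject_scores, min_subjects: int = 2) -> np.ndarray:
    """Row-wise mean of per-subject z-scores, re-standardized.

    Rows with fewer than ``min_subjects`` non-missing subjects become
    missing.  The resulting mean is re-standardized so the composite is
    again in z-units.

    Parameters
    ----------
    subject_scores : 2-D array-like or :class:`pandas.DataFrame`
        One column per subject, already standardized.
    min_subjects : int
        Minimum number of available subjects for a row to contribute.

    Returns
    -------
    numpy.ndarray
        Standardized composite, NaN where unavailable.
    """
    if isinstance(subject_scores, pd.DataFrame):
        mat = subject_scores.to_numpy(dtype=float)
    else:
        mat = np.asarray(subject_scores, dtype=float)
    if mat.ndim != 2 or mat.shape[1] == 0:
        raise EmptyInputError("composite requires at least one subject column")
    finite = np.isfinite(mat)
    available = finite.sum(axis=1)
    sums = np.where(finite, mat, 0.0).sum(axis=1)
    mean = np.where(
        available >= max(min_subjects, 1), sums / np.maximum(available, 1), np.nan
    )
    return zscore(mean)


def check_standardized(x: np.ndarray, name: str, tol: float = STANDARDIZED_TOL) -> None:
    """Raise :class:`ValidationError` unless ``x`` looks z-scored."""
    finite = x[np.isfinite(x)]
    if finite.size < 2:
        raise ValidationError(f"{name}: too few non-missing values")
    m = float(np.mean(finite))
    # accept either denominator convention so tiny vectors standardized by
    # hand (population SD) and z-scored samples (n-1) both pass
    sd1 = float(np.std(finite, ddof=1))
    sd0 = float(np.std(finite, ddof=0))
    if abs(m) > tol or min(abs(sd1 - 1.0), abs(sd0 - 1.0)) > tol:
        raise ValidationError(
            f"{name} is not standardized (mean={m:.3f}, sd={sd1:.3f}, tol={tol})"
        )


def residualize(values, covariates) -> np.ndarray:
    """Residualize ``values`` on one or more covariate columns via OLS.

    Optional pre-step for predictor columns that still carry nuisance
    structure (e.g. genotyping batch).  Residuals are re-standardized;
    rows with any missing input are NaN.
    """
    y = np.asarray(values, dtype=float)
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    mask = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    if mask.sum() < X.shape[1] + 2:
        raise InsufficientDataError(
            f"residualize needs >= {X.shape[1] + 2} complete rows, got {int(mask.sum())}"
        )
    design = np.column_stack([np.ones(int(mask.sum())), X[mask]])
    beta, *_ = np.linalg.lstsq(design, y[mask], rcond=None)
    out = np.full_like(y, np.nan, dtype=float)
    out[mask] = y[mask] - design @ beta
    return zscore(out)


def delta(
    achievement_z,
    predictor_z,
    method: str = "difference",
    tol: float = STANDARDIZED_TOL,
) -> np.ndarray:
    """Discrepancy between standardized achievement and a standardized predictor.

    ``difference`` returns the elementwise difference achievement − predictor,
    so the result has mean ≈ 0 and variance ``2(1 − r)`` where ``r`` is the
    correlation between the two inputs.  ``residualized`` instead regresses
    achievement on the predictor and re-standardizes the residual.  Under
    either method, negative values mean achievement below prediction
    (underachievement) and positive values above it.

    Missing values propagate: the delta is NaN wherever either input is NaN.

    Parameters
    ----------
    achievement_z, predictor_z : array-like of float
        Equal-length standardized vectors (checked to tolerance ``tol``).
    method : {"difference", "residualized"}

    Raises
    ------
    ValidationError
        On length mismatch, unknown method, or unstandardized inputs.
    """
    a = np.asarray(achievement_z, dtype=float)
    p = np.asarray(predictor_z, dtype=float)
    if a.shape != p.shape:
        raise ValidationError(
            f"length mismatch: achievement {a.shape} vs predictor {p.shape}"
        )
    check_standardized(a, "achievement_z", tol)
    check_standardized(p, "predictor_z", tol)
    if method == "difference":
        return a - p
    if method == "residualized":
        mask = np.isfinite(a) & np.isfinite(p)
        X = np.column_stack([np.ones(int(mask.sum())), p[mask]])
        beta, *_ = np.linalg.lstsq(X, a[mask], rcond=None)
        out = np.full_like(a, np.nan)
        out[mask] = a[mask] - X @ beta
        return zscore(out)
    raise ValidationError(f"unknown delta method: {method!r}")
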