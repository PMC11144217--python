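"""Synthetic twin-cohort generator.

Emulates the covariance structure a polygenic-discrepancy analysis
assumes: an ACE twin structure for a stable achievement propensity, a
polygenic score that is a noisy proxy of the additive-genetic factor
with an age-increasing phenotypic correlation, cross-age achievement
stability, a family SES composite correlated with achievement, a noisy
age-7 cognitive-ability proxy, and per-age attrition.

The model is a linear-Gaussian factor model, per family ``f`` with twins
``i ∈ {1, 2}``::

    A_1 ~ N(0,1);  A_2 = A_1 (MZ)  or  0.5·A_1 + sqrt(0.75)·η  (DZ)
    C_f ~ N(0,1) shared;  S_i ~ N(0,1) stable individual factor
    GPS_i   = kappa·A_i + sqrt(1 − kappa²)·ν_i
    Ach_i,t = g_t·A_i + sqrt(c2)·C_f + u·S_i + r_t·ε_i,t
              with g_t = validity_t / kappa, u = stability,
              r_t = sqrt(1 − g_t² − c2 − u²)
    SES_f   = l_g·(A_1 + A_2)/sqrt(2 + 2·corr(A_1, A_2)) + l_c·C_f + noise

so by construction ``corr(GPS, Ach_t) = validity_t`` exactly and every
column is standardized in expectation.  This is an *emulation* chosen as
the minimal model reproducing the moments the analysis is calibrated
against, not a claim about any real cohort.

Reproducibility: all variates for family ``i`` occupy row ``i`` of two
fixed-width random blocks drawn from a single seeded generator, so the
same seed is bit-identical and growing ``n_pairs`` leaves earlier
families unchanged.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError

__all__ = [
    "GeneratorConfig",
    "generate_cohort",
    "theoretical_covariance",
    "load_config",
    "write_cohort",
    "SUBJECTS",
]

SUBJECTS = ("english", "math", "science")

#: loadings of the optional extra polygenic scores on the genetic factor
EXTRA_GPS_KAPPA = (0.45, 0.40, 0.34, 0.30)
#: loading of the extra scores on a shared (per-individual) noise factor,
#: giving them realistic mutual correlations beyond genetic sharing
EXTRA_GPS_SHARED = 0.55


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic-cohort generative model.

    Defaults are calibrated so that, at scale, corr(GPS, achievement)
    matches ``gps_validity`` per age, corr(SES, age-7 achievement) ≈ 0.30,
    corr between the two discrepancy scores ≈ 0.38, and the stable
    propensity has heritability ``a2`` and shared environment ``c2``.
    """

    n_pairs: int = 2000
    prop_mz: float = 0.35
    ages: tuple = (7, 9, 12, 16)
    a2: float = 0.66
    c2: float = 0.12
    gps_validity: tuple = (0.28, 0.27, 0.26, 0.43)
    kappa: float = 0.55
    stability: float = 0.45
    ses_load_g: float = 0.42
    ses_load_c: float = 0.30
    g_load_a: float = 0.30
    g_load_s: float = 0.50
    attrition: tuple = (0.0, 0.0, 0.0, 0.0)
    subject_fidelity: float = 0.92
    n_gps: int = 1
    sex_effect: float = 0.0
    age_effect: float = 0.0
    seed: int = 0

    def __post_init__(self):
        self.validate()

    # -- derived loadings ---------------------------------------------------

    @property
    def genetic_loadings(self) -> np.ndarray:
        """Per-age loading of achievement on the additive-genetic factor."""
        return np.asarray(self.gps_validity, dtype=float) / self.kappa

    @property
    def residual_scales(self) -> np.ndarray:
        g = self.genetic_loadings
        r2 = 1.0 - g**2 - self.c2 - self.stability**2
        return np.sqrt(np.maximum(r2, 0.0))

    def validate(self) -> None:
        """Raise :class:`ConfigError` naming the first violated constraint."""
        c = self
        if c.n_pairs < 1:
            raise ConfigError(f"n_pairs must be >= 1, got {c.n_pairs}")
        if not 0 <= c.prop_mz <= 1:
            raise ConfigError(f"prop_mz must be in [0, 1], got {c.prop_mz}")
        ages = np.asarray(c.ages, dtype=float)
        if ages.size < 3 or np.any(np.diff(ages) <= 0):
            raise ConfigError("ages must be strictly increasing with length >= 3")
        if len(c.gps_validity) != ages.size:
            raise ConfigError("gps_validity must have one entry per age")
        if len(c.attrition) != ages.size:
            raise ConfigError("attrition must have one entry per age")
        v = np.asarray(c.gps_validity, dtype=float)
        if np.any(v <= 0) or np.any(v > 1):
            raise ConfigError("every gps_validity entry must lie in (0, 1]")
        att = np.asarray(c.attrition, dtype=float)
        if np.any(att < 0) or np.any(att >= 1):
            raise ConfigError("every attrition entry must lie in [0, 1)")
        if c.a2 < 0 or c.c2 < 0:
            raise ConfigError("a2 and c2 must be nonnegative")
        if c.a2 + c.c2 > 1:
            raise ConfigError(f"a2 + c2 must be <= 1, got {c.a2 + c.c2}")
        if not 0 < c.kappa <= 1:
            raise ConfigError(f"kappa must lie in (0, 1], got {c.kappa}")
        if c.a2 == 0:
            raise ConfigError("a2 must be positive (genetic loading undefined)")
        lam = v / (c.kappa * np.sqrt(c.a2))
        if np.any(lam > 1 + 1e-12):
            raise ConfigError(
                "implied genetic loading gps_validity/(kappa*sqrt(a2)) exceeds 1 "
                f"(max {lam.max():.4f})"
            )
        if c.stability < 0:
            raise ConfigError("stability must be nonnegative")
        g = v / c.kappa
        r2 = 1.0 - g**2 - c.c2 - c.stability**2
        if np.any(r2 < -1e-12):
            raise ConfigError(
                "implied residual variance of achievement is negative "
                f"(min {r2.min():.4f}); lower gps_validity, c2 or stability"
            )
        if c.ses_load_g**2 + c.ses_load_c**2 > 1:
            raise ConfigError("ses_load_g^2 + ses_load_c^2 must be <= 1")
        if c.g_load_a**2 + c.g_load_s**2 > 1:
            raise ConfigError("g_load_a^2 + g_load_s^2 must be <= 1")
        if not 0 < c.subject_fidelity <= 1:
            raise ConfigError("subject_fidelity must lie in (0, 1]")
        if not 1 <= c.n_gps <= 1 + len(EXTRA_GPS_KAPPA):
            raise ConfigError(f"n_gps must lie in 1..{1 + len(EXTRA_GPS_KAPPA)}")

    # -- (de)serialization --------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["ages"] = list(self.ages)
        d["gps_validity"] = list(self.gps_validity)
        d["attrition"] = list(self.attrition)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        for key in ("ages", "gps_validity", "attrition"):
            if key in d:
                d[key] = tuple(d[key])
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown generator config fields: {sorted(unknown)}")
        return cls(**d)


def load_config(path) -> GeneratorConfig:
    """Load a :class:`GeneratorConfig` from a YAML or JSON file."""
    with open(path) as fh:
        text = fh.read()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    return GeneratorConfig.from_dict(data or {})


def _gps_column_names(n_gps: int) -> list[str]:
    return ["gps"] + [f"gps{i}" for i in range(2, n_gps + 1)]


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Generate a wide cohort table, one row per individual.

    Columns: identifiers (``individual_id``, ``family_id``), ``zygosity``
    ("MZ"/"DZ"), ``sex`` (0/1), ``age_jitter`` (years, uniform ±0.5),
    family ``ses``, polygenic score column(s) ``gps[, gps2..]``, age-7
    cognitive proxy ``g_age7``, the stable ACE ``propensity``, composite
    achievement ``ach_<age>`` and per-subject scores
    ``english_<age>/math_<age>/science_<age>``.  Missing cells are NaN;
    science at age 7 is missing by design; attrition knocks out whole
    assessment waves i.i.d. per individual.
    """
    config.validate()
    c = config
    T = len(c.ages)
    n = c.n_pairs
    # two independent child streams so each block is row-major prefix-stable:
    # growing n_pairs appends families without reshuffling earlier ones
    child_z, child_u = np.random.SeedSequence(c.seed).spawn(2)
    rng_z = np.random.default_rng(child_z)
    rng_u = np.random.default_rng(child_u)

    # fixed-width per-family random blocks (row i == family i)
    m_norm = 20 + 8 * T
    Z = rng_z.standard_normal((n, m_norm))
    U = rng_u.random((n, 5 + 2 * T))

    A1 = Z[:, 0]
    is_mz = U[:, 0] < c.prop_mz
    A2 = np.where(is_mz, A1, 0.5 * A1 + np.sqrt(0.75) * Z[:, 1])
    C = Z[:, 2]
    S = Z[:, 3:5]  # per twin
    nu = Z[:, 5:7]
    ses_noise = Z[:, 7]
    g7_noise = Z[:, 8:10]
    xi = Z[:, 10:12]
    extra_resid = Z[:, 12:20].reshape(n, 2, 4)
    eps = Z[:, 20 : 20 + 2 * T].reshape(n, 2, T)
    deltas = Z[:, 20 + 2 * T :].reshape(n, 2, T, 3)

    sex1 = (U[:, 1] < 0.5).astype(int)
    sex2 = np.where(is_mz, sex1, (U[:, 2] < 0.5).astype(int))
    jitter = U[:, 3:5] - 0.5
    dropout = U[:, 5:].reshape(n, 2, T) < np.asarray(c.attrition, dtype=float)

    A = np.stack([A1, A2], axis=1)  # (n, 2)
    sex = np.stack([sex1, sex2], axis=1)

    gps = c.kappa * A + np.sqrt(1.0 - c.kappa**2) * nu

    g_t = c.genetic_loadings
    r_t = c.residual_scales
    u = c.stability
    c_load = np.sqrt(c.c2)
    ach = (
        g_t[None, None, :] * A[:, :, None]
        + c_load * C[:, None, None]
        + u * S[:, :, None]
        + r_t[None, None, :] * eps
    )
    if c.sex_effect != 0.0:
        ach = ach + c.sex_effect * (2 * sex[:, :, None] - 1)
    if c.age_effect != 0.0:
        ach = ach + c.age_effect * jitter[:, :, None]

    # subject scores: fidelity-weighted composite plus sum-zero subject noise,
    # so the mean of available subjects reproduces the composite exactly
    rho = c.subject_fidelity
    subj = np.full((n, 2, T, 3), np.nan)
    ages_arr = np.asarray(c.ages, dtype=float)
    for t in range(T):
        present = [j for j, s in enumerate(SUBJECTS) if not (s == "science" and ages_arr[t] == 7)]
        k = len(present)
        d = deltas[:, :, t, :k]
        d = d - d.mean(axis=2, keepdims=True)
        if k > 1:
            d = d * np.sqrt(k / (k - 1))
        subj[:, :, t, present] = rho * ach[:, :, t, None] + np.sqrt(1 - rho**2) * d

    ach = np.where(dropout, np.nan, ach)
    subj = np.where(dropout[:, :, :, None], np.nan, subj)

    rho_a = np.where(is_mz, 1.0, 0.5)
    abar = (A1 + A2) / np.sqrt(2.0 + 2.0 * rho_a)
    ses_resid = np.sqrt(max(1.0 - c.ses_load_g**2 - c.ses_load_c**2, 0.0))
    ses = c.ses_load_g * abar + c.ses_load_c * C + ses_resid * ses_noise

    g_resid = np.sqrt(max(1.0 - c.g_load_a**2 - c.g_load_s**2, 0.0))
    g_age7 = c.g_load_a * A + c.g_load_s * S + g_resid * g7_noise

    e2 = max(1.0 - c.a2 - c.c2, 0.0)
    propensity = (
        np.sqrt(c.a2) * A + np.sqrt(c.c2) * C[:, None] + np.sqrt(e2) * S
    )

    extra = []
    for j, kap in enumerate(EXTRA_GPS_KAPPA[: c.n_gps - 1]):
        resid = np.sqrt(1.0 - kap**2 - EXTRA_GPS_SHARED**2)
        extra.append(kap * A + EXTRA_GPS_SHARED * xi + resid * extra_resid[:, :, j])

    # assemble long-by-individual rows: family f twins 1 and 2
    fam_ids = np.array([f"F{i:06d}" for i in range(n)])
    records = {
        "individual_id": np.concatenate([fam_ids + "_1", fam_ids + "_2"]),
        "family_id": np.concatenate([fam_ids, fam_ids]),
        "zygosity": np.concatenate([np.where(is_mz, "MZ", "DZ")] * 2),
        "sex": np.concatenate([sex[:, 0], sex[:, 1]]),
        "age_jitter": np.concatenate([jitter[:, 0], jitter[:, 1]]),
        "ses": np.concatenate([ses, ses]),
        "gps": np.concatenate([gps[:, 0], gps[:, 1]]),
    }
    for j, col in enumerate(extra):
        records[f"gps{j + 2}"] = np.concatenate([col[:, 0], col[:, 1]])
    records["g_age7"] = np.concatenate([g_age7[:, 0], g_age7[:, 1]])
    records["propensity"] = np.concatenate([propensity[:, 0], propensity[:, 1]])
    for t, age in enumerate(c.ages):
        records[f"ach_{age}"] = np.concatenate([ach[:, 0, t], ach[:, 1, t]])
    for t, age in enumerate(c.ages):
        for j, s in enumerate(SUBJECTS):
            records[f"{s}_{age}"] = np.concatenate([subj[:, 0, t, j], subj[:, 1, t, j]])

    df = pd.DataFrame(records)
    # interleave twins so the two members of a family are adjacent
    order = np.arange(2 * n).reshape(2, n).T.ravel()
    return df.iloc[order].reset_index(drop=True)


def theoretical_covariance(config: GeneratorConfig) -> pd.DataFrame:
    """Closed-form correlation matrix implied by the generative model.

    Covers {GPS, achievement per age, SES} for a randomly drawn
    individual (zygosity-dependent SES terms are averaged over the MZ/DZ
    mix).  Exact when ``sex_effect`` and ``age_effect`` are zero.
    """
    config.validate()
    c = config
    if c.sex_effect != 0.0 or c.age_effect != 0.0:
        warnings.warn(
            "theoretical_covariance assumes zero sex/age effects; "
            "nonzero effects perturb the implied correlations slightly"
        )
    g = c.genetic_loadings
    T = len(c.ages)
    names = ["gps"] + [f"ach_{a}" for a in c.ages] + ["ses"]
    M = np.eye(T + 2)
    v = np.asarray(c.gps_validity, dtype=float)
    for t in range(T):
        M[0, 1 + t] = M[1 + t, 0] = v[t]
    for s in range(T):
        for t in range(s + 1, T):
            r = g[s] * g[t] + c.c2 + c.stability**2
            M[1 + s, 1 + t] = M[1 + t, 1 + s] = r
    # SES column: E over zygosity of corr(SES, A_i) = sqrt((1+rho)/2)
    wbar = c.prop_mz * 1.0 + (1.0 - c.prop_mz) * np.sqrt(0.75)
    M[0, T + 1] = M[T + 1, 0] = c.ses_load_g * wbar * c.kappa
    for t in range(T):
        r = c.ses_load_g * wbar * g[t] + c.ses_load_c * np.sqrt(c.c2)
        M[1 + t, T + 1] = M[T + 1, 1 + t] = r
    return pd.DataFrame(M, index=names, columns=names)


def write_cohort(df: pd.DataFrame, path) -> None:
    """Write a cohort table as CSV with empty fields for missing values."""
    df.to_csv(path, index=False, na_rep="")
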