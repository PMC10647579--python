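"""Synthetic clinical cohorts with the joint structure of a geriatric
arterial-stiffness study population.

The generator emulates a two-stratum (age < 70 vs >= 70) cohort of
adults aged 40--96 in which diastolic blood pressure declines with age
(target Pearson r = -0.464), pulse pressure widens with age, and body
composition, sex ratio and comorbidity prevalences differ by stratum.
Stiffness indexes are attached in one of two modes:

* ``regression`` -- CAVI0 and CAVI are drawn from fitted linear
  interaction models (index = b0 + b_age*age + b_dbp*DBP +
  b_int*age*DBP + noise), with the noise standard deviation either
  given directly or calibrated to a target model R^2.
* ``mechanistic`` -- heart-ankle PWV is drawn from a linear aging
  model, independent of DBP given age, and CAVI / CAVI0 are computed
  through the hemodynamic formula chain.  This mode embodies the
  physiological hypothesis that an age-declining DBP alone induces an
  age-by-DBP interaction on CAVI0 but only a much weaker one on CAVI.

All randomness flows through a single NumPy Generator keyed by the
config seed; columns are drawn in a fixed, documented order (age, sex,
BMI, waist, DBP noise, PP, comorbidity flags, then index/PWV noise) so
that a given seed yields the same cohort across runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from . import hemodynamics as hemo
from .errors import ConfigError
from .hemodynamics import HemoConstants, PressurePair

__all__ = [
    "StratumPair",
    "NoiseSpec",
    "InteractionCoefficients",
    "GeneratorConfig",
    "COHORT_COLUMNS",
    "truncated_age_sd",
    "calibrate_dbp_slope",
    "calibrate_noise_sd",
    "sample_covariates",
    "generate_regression_mode",
    "generate_mechanistic_mode",
    "generate_cohort",
    "linear_predictor",
]

logger = logging.getLogger(__name__)

#: Canonical column order of a generated cohort table.
COHORT_COLUMNS = [
    "id", "age", "sex", "bmi", "waist", "sbp", "dbp", "map", "pp",
    "pwv", "cavi", "cavi0",
    "hypertension", "diabetes", "dyslipidemia", "smoking",
]


@dataclass(frozen=True)
class StratumPair:
    """A (young, old) pair of per-stratum parameters."""

    young: float
    old: float


@dataclass(frozen=True)
class NoiseSpec:
    """Residual-noise specification for one index in regression mode.

    Exactly one of ``noise_sd`` (index units) or ``target_r2``
    (population R^2 of the generating model) must be set.
    """

    noise_sd: float | None = None
    target_r2: float | None = None

    def __post_init__(self):
        if (self.noise_sd is None) == (self.target_r2 is None):
            raise ConfigError("exactly one of noise_sd / target_r2 must be set")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        if self.target_r2 is not None and not 0 < self.target_r2 < 1:
            raise ConfigError("target_r2 must lie strictly between 0 and 1")


@dataclass(frozen=True)
class InteractionCoefficients:
    """Coefficients of index = b0 + b_age*age + b_dbp*DBP + b_int*age*DBP."""

    intercept: float
    age: float
    dbp: float
    interaction: float

    def as_array(self) -> np.ndarray:
        return np.array([self.intercept, self.age, self.dbp, self.interaction])


# Default generating planes: the fitted 3-term interaction models for
# CAVI0 and CAVI in the reference study population.
DEFAULT_CAVI0_COEFFS = InteractionCoefficients(-30.301, 0.682, 0.306, -0.005)
DEFAULT_CAVI_COEFFS = InteractionCoefficients(-4.16, 0.175, 0.072, -0.001)

#: Default population R^2 of the generating CAVI0 model.
DEFAULT_CAVI0_TARGET_R2 = 0.508

# The CAVI arm's default residual scale is tied to the CAVI0 arm's:
# both reference models share a design matrix, so the ratio of their
# residual SDs equals the ratio of any slope's reported standard
# errors, 0.062 / 0.176 for the age term.
CAVI_TO_CAVI0_RESIDUAL_RATIO = 0.062 / 0.176


@dataclass(frozen=True)
class GeneratorConfig:
    """Full specification of a synthetic cohort.

    Defaults reproduce the reference study conditions: n = 191
    subjects, ages truncated-normal (68.3, 14.4) on [40, 96], DBP
    declining with age at a slope calibrated to give Pearson
    r(DBP, age) = -0.464, and per-stratum anthropometrics, sex ratio
    and comorbidity prevalences matching the study's two age strata.
    """

    n: int = 191
    seed: int = 0
    mode: Literal["regression", "mechanistic"] = "regression"

    # Age model: truncated normal.
    age_mean: float = 68.3
    age_sd: float = 14.4
    age_range: tuple[float, float] = (40.0, 96.0)

    # DBP model: DBP = a0 + a1*age + N(0, sigma_eps), clipped to dbp_range.
    # a0/a1 default to None, meaning "calibrate from target_dbp_age_r and
    # dbp_mean using the truncated-normal age moments".
    dbp_intercept: float | None = None
    dbp_slope: float | None = None
    dbp_noise_sd: float = 9.48
    dbp_mean: float = 81.2
    target_dbp_age_r: float = -0.464
    dbp_range: tuple[float, float] = (55.0, 109.0)
    clip_dbp: bool = True

    # Pulse pressure: normal with mean/SD linearly interpolated in age
    # between the two stratum anchors (stratum mean ages 56.86 / 80.79).
    pp_mean: StratumPair = StratumPair(54.9, 60.07)
    pp_sd: StratumPair = StratumPair(13.18, 14.53)
    pp_anchor_ages: StratumPair = StratumPair(56.86, 80.79)
    pp_floor: float = 10.0

    # Per-stratum covariates (threshold 70 years).
    stratum_threshold: float = 70.0
    sex_male_prob: StratumPair = StratumPair(0.28, 0.44)
    bmi_mean: StratumPair = StratumPair(31.38, 25.84)
    bmi_sd: StratumPair = StratumPair(4.82, 5.68)
    waist_mean: StratumPair = StratumPair(103.6, 97.18)
    waist_sd: StratumPair = StratumPair(13.88, 15.19)
    prev_hypertension: StratumPair = StratumPair(0.62, 0.78)
    prev_diabetes: StratumPair = StratumPair(0.21, 0.29)
    prev_dyslipidemia: StratumPair = StratumPair(0.74, 0.58)
    prev_smoking: StratumPair = StratumPair(0.24, 0.35)

    # Regression mode.
    cavi0_coefficients: InteractionCoefficients = DEFAULT_CAVI0_COEFFS
    cavi_coefficients: InteractionCoefficients = DEFAULT_CAVI_COEFFS
    cavi0_noise: NoiseSpec = NoiseSpec(target_r2=DEFAULT_CAVI0_TARGET_R2)
    cavi_noise: NoiseSpec | None = None  # None -> residual-SD ratio rule
    pilot_n: int = 100_000
    pilot_seed: int = 202_311

    # Mechanistic mode: pwv = c0 + c1*age + N(0, sigma_pwv), m/s.
    pwv_intercept: float = 4.8
    pwv_slope: float = 0.045
    pwv_noise_sd: float = 0.6
    hemo: HemoConstants = field(default_factory=HemoConstants)

    def validate(self) -> None:
        if self.n <= 0:
            raise ConfigError("n must be positive")
        if self.age_range[0] >= self.age_range[1]:
            raise ConfigError("age_range must be (low, high) with low < high")
        if self.age_sd <= 0 or self.dbp_noise_sd < 0 or self.pwv_noise_sd < 0:
            raise ConfigError("standard deviations must be non-negative")
        if self.mode not in ("regression", "mechanistic"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        for name in ("sex_male_prob", "prev_hypertension", "prev_diabetes",
                     "prev_dyslipidemia", "prev_smoking"):
            pair: StratumPair = getattr(self, name)
            if not (0 <= pair.young <= 1 and 0 <= pair.old <= 1):
                raise ConfigError(f"{name} must lie in [0, 1]")
        if not abs(self.target_dbp_age_r) < 1:
            raise ConfigError("target_dbp_age_r must lie in (-1, 1)")


def truncated_age_sd(config: GeneratorConfig) -> float:
    """Standard deviation of the truncated-normal age distribution.

    Truncation to ``age_range`` shrinks the SD below the nominal
    ``age_sd``; slope calibration must use the realized (truncated)
    moments or the DBP-age correlation would overshoot its target.
    """
    lo, hi = config.age_range
    a = (lo - config.age_mean) / config.age_sd
    b = (hi - config.age_mean) / config.age_sd
    return float(stats.truncnorm.std(a, b, loc=config.age_mean, scale=config.age_sd))


def _truncated_age_mean(config: GeneratorConfig) -> float:
    lo, hi = config.age_range
    a = (lo - config.age_mean) / config.age_sd
    b = (hi - config.age_mean) / config.age_sd
    return float(stats.truncnorm.mean(a, b, loc=config.age_mean, scale=config.age_sd))


def calibrate_dbp_slope(target_r: float, sigma_eps: float, sigma_age: float) -> float:
    """Closed-form DBP-vs-age slope achieving a target correlation.

    For DBP = a0 + a1*age + eps with independent noise,
    corr(DBP, age) = a1*s_age / sqrt(a1^2 s_age^2 + s_eps^2); solving
    for a1 gives a1 = r * s_eps / (s_age * sqrt(1 - r^2)).
    """
    if not abs(target_r) < 1:
        raise ConfigError("target correlation must lie strictly inside (-1, 1)")
    if sigma_eps < 0 or sigma_age <= 0:
        raise ConfigError("sigma_eps must be >= 0 and sigma_age > 0")
    return target_r * sigma_eps / (sigma_age * np.sqrt(1.0 - target_r**2))


def calibrate_noise_sd(target_r2: float, linear_predictor_variance: float) -> float:
    """Residual SD giving a target population R^2.

    R^2 = Var(mu) / (Var(mu) + sigma^2)  =>
    sigma = sqrt(Var(mu) * (1 - R^2) / R^2).
    """
    if not 0 < target_r2 < 1:
        raise ConfigError("target_r2 must lie strictly between 0 and 1")
    if linear_predictor_variance <= 0:
        raise ConfigError("linear predictor variance must be positive")
    return float(np.sqrt(linear_predictor_variance * (1.0 - target_r2) / target_r2))


def _resolved_dbp_model(config: GeneratorConfig) -> tuple[float, float]:
    """(intercept, slope) of the DBP-vs-age model, calibrating defaults."""
    slope = config.dbp_slope
    if slope is None:
        slope = calibrate_dbp_slope(
            config.target_dbp_age_r, config.dbp_noise_sd, truncated_age_sd(config)
        )
    intercept = config.dbp_intercept
    if intercept is None:
        intercept = config.dbp_mean - slope * _truncated_age_mean(config)
    return intercept, slope


def _stratum_value(age: np.ndarray, pair: StratumPair, threshold: float) -> np.ndarray:
    return np.where(age < threshold, pair.young, pair.old)


def _interp_in_age(age: np.ndarray, pair: StratumPair, anchors: StratumPair) -> np.ndarray:
    clamped = np.clip(age, anchors.young, anchors.old)
    frac = (clamped - anchors.young) / (anchors.old - anchors.young)
    return pair.young + frac * (pair.old - pair.young)


def sample_covariates(
    config: GeneratorConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Draw the covariate block (everything except PWV and the indexes).

    Column draw order is fixed: age, sex, BMI, waist, DBP noise, PP,
    hypertension, diabetes, dyslipidemia, smoking.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n
    lo, hi = config.age_range
    a = (lo - config.age_mean) / config.age_sd
    b = (hi - config.age_mean) / config.age_sd
    age = stats.truncnorm.rvs(
        a, b, loc=config.age_mean, scale=config.age_sd, size=n, random_state=rng
    )

    thr = config.stratum_threshold
    sex_p = _stratum_value(age, config.sex_male_prob, thr)
    sex = np.where(rng.random(n) < sex_p, "M", "F")
    bmi = rng.normal(
        _stratum_value(age, config.bmi_mean, thr),
        _stratum_value(age, config.bmi_sd, thr),
    )
    waist = rng.normal(
        _stratum_value(age, config.waist_mean, thr),
        _stratum_value(age, config.waist_sd, thr),
    )

    a0, a1 = _resolved_dbp_model(config)
    dbp = a0 + a1 * age + rng.normal(0.0, config.dbp_noise_sd, size=n)
    if config.clip_dbp:
        dbp = np.clip(dbp, *config.dbp_range)

    pp_mu = _interp_in_age(age, config.pp_mean, config.pp_anchor_ages)
    pp_sd = _interp_in_age(age, config.pp_sd, config.pp_anchor_ages)
    pp = np.maximum(rng.normal(pp_mu, pp_sd), config.pp_floor)
    sbp = dbp + pp

    flags = {}
    for name, pair in (
        ("hypertension", config.prev_hypertension),
        ("diabetes", config.prev_diabetes),
        ("dyslipidemia", config.prev_dyslipidemia),
        ("smoking", config.prev_smoking),
    ):
        flags[name] = (rng.random(n) < _stratum_value(age, pair, thr)).astype(int)

    return pd.DataFrame(
        {
            "id": np.arange(1, n + 1),
            "age": age,
            "sex": sex,
            "bmi": bmi,
            "waist": waist,
            "sbp": sbp,
            "dbp": dbp,
            "map": dbp + pp / 3.0,
            "pp": pp,
            **flags,
        }
    )


def linear_predictor(
    coeffs: InteractionCoefficients, age: np.ndarray, dbp: np.ndarray
) -> np.ndarray:
    """Evaluate the 3-term interaction plane at (age, DBP)."""
    age = np.asarray(age, dtype=float)
    dbp = np.asarray(dbp, dtype=float)
    return (
        coeffs.intercept
        + coeffs.age * age
        + coeffs.dbp * dbp
        + coeffs.interaction * age * dbp
    )


def _pilot_predictor_variance(
    config: GeneratorConfig, coeffs: InteractionCoefficients
) -> float:
    """Var of the linear predictor on a large pilot covariate sample."""
    pilot = replace(config, n=config.pilot_n, seed=config.pilot_seed)
    cov = sample_covariates(pilot)
    return float(np.var(linear_predictor(coeffs, cov["age"], cov["dbp"]), ddof=1))


def _resolve_noise_sd(
    config: GeneratorConfig, which: Literal["cavi0", "cavi"]
) -> float:
    """Residual SD for one index arm, calibrating R^2 targets via pilot.

    The default CAVI residual SD is the CAVI0 residual SD scaled by
    the ratio of the two reference models' coefficient standard
    errors (they share a design matrix, so the SE ratio is the
    residual-SD ratio).
    """
    if which == "cavi0":
        spec = config.cavi0_noise
        if spec.noise_sd is not None:
            return spec.noise_sd
        var_mu = _pilot_predictor_variance(config, config.cavi0_coefficients)
        return calibrate_noise_sd(spec.target_r2, var_mu)
    spec = config.cavi_noise
    if spec is None:
        return _resolve_noise_sd(config, "cavi0") * CAVI_TO_CAVI0_RESIDUAL_RATIO
    if spec.noise_sd is not None:
        return spec.noise_sd
    var_mu = _pilot_predictor_variance(config, config.cavi_coefficients)
    return calibrate_noise_sd(spec.target_r2, var_mu)


def generate_regression_mode(config: GeneratorConfig) -> pd.DataFrame:
    """Cohort whose indexes are drawn from the fitted interaction models."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    table = sample_covariates(config, rng)
    sigma0 = _resolve_noise_sd(config, "cavi0")
    sigma_c = _resolve_noise_sd(config, "cavi")
    mu0 = linear_predictor(config.cavi0_coefficients, table["age"], table["dbp"])
    mu_c = linear_predictor(config.cavi_coefficients, table["age"], table["dbp"])
    table["cavi0"] = mu0 + rng.normal(0.0, sigma0, size=config.n)
    table["cavi"] = mu_c + rng.normal(0.0, sigma_c, size=config.n)
    return table[[c for c in COHORT_COLUMNS if c in table.columns]]


def generate_mechanistic_mode(config: GeneratorConfig) -> pd.DataFrame:
    """Cohort whose indexes arise from a PWV aging model via the formulas.

    PWV depends on age only (given age it is independent of DBP), so
    any fitted age-by-DBP interaction on the indexes is induced purely
    by the formulas' pressure dependence.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    table = sample_covariates(config, rng)
    pwv = (
        config.pwv_intercept
        + config.pwv_slope * table["age"].to_numpy()
        + rng.normal(0.0, config.pwv_noise_sd, size=config.n)
    )
    n_neg = int(np.sum(pwv < 0))
    if n_neg:
        logger.warning("PWV model produced %d negative speeds; clipped to 0", n_neg)
        pwv = np.maximum(pwv, 0.0)
    pressures = PressurePair(table["sbp"].to_numpy(), table["dbp"].to_numpy())
    table["pwv"] = pwv
    table["cavi"] = hemo.cavi_from_pwv(pressures, pwv, config.hemo)
    table["cavi0"] = hemo.cavi0_from_pwv(
        table["dbp"].to_numpy(), pwv, config.hemo.rho, config.hemo.pref
    )
    return table[[c for c in COHORT_COLUMNS if c in table.columns]]


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Dispatch to the configured generation mode."""
    if config.mode == "regression":
        return generate_regression_mode(config)
    return generate_mechanistic_mode(config)
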