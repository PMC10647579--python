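"""Statistical pipeline for stratified cohort description and
age-by-DBP effect-modification regression.

Covers the comparisons a clinical arterial-stiffness study reports:
two-group descriptive tables (t test, Mann-Whitney U, Yates-corrected
chi-square), Pearson correlations, ordinary least squares with an
age x DBP interaction term, sequential (Type I) ANOVA, Freedman-Lane
permutation inference, prediction surfaces over an (age, DBP) grid,
the crossover age at which the modeled DBP effect vanishes, and a
trend across decade age strata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import (
    CollinearityError,
    ConfigError,
    ContractError,
    DegenerateSampleError,
    StratificationError,
    UndefinedTableError,
)

__all__ = [
    "RegressionFit",
    "CrossoverResult",
    "GroupComparison",
    "TrendResult",
    "student_t_test",
    "mann_whitney_u",
    "chisq_2x2_yates",
    "pearson_correlation",
    "fit_interaction_model",
    "sequential_anova",
    "permutation_test",
    "predict_index",
    "prediction_grid",
    "crossover",
    "describe_by_age_group",
    "trend_across_strata",
]

CORE_TERMS = ("intercept", "age", "dbp", "age_dbp")
EXTRA_TERM_COLUMNS = {"sbp": "sbp", "sex": "sex_male", "bmi": "bmi"}


# ---------------------------------------------------------------------------
# elementary two-sample and correlation tests
# ---------------------------------------------------------------------------

def student_t_test(x, y, welch: bool = False) -> tuple[float, float]:
    """Two-sided unpaired t test; pooled variance unless ``welch``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise DegenerateSampleError("each sample needs at least two observations")
    if not welch and np.var(x, ddof=1) + np.var(y, ddof=1) == 0:
        raise DegenerateSampleError("zero pooled variance")
    res = stats.ttest_ind(x, y, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Uses the exact null distribution when the combined sample size is
    at most 20 and there are no ties; otherwise the normal
    approximation with tie and continuity corrections.  A completely
    tied comparison (zero rank variance) returns p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise DegenerateSampleError("both samples must be nonempty")
    combined = np.concatenate([x, y])
    no_ties = len(np.unique(combined)) == len(combined)
    method = "exact" if (len(combined) <= 20 and no_ties) else "asymptotic"
    if np.all(combined == combined[0]):
        # All observations equal: U at its midpoint, no evidence either way.
        return float(len(x) * len(y) / 2.0), 1.0
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    p = float(res.pvalue)
    if np.isnan(p):
        p = 1.0
    return float(res.statistic), p


def chisq_2x2_yates(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Yates-continuity-corrected chi-square on a 2x2 table [[a,b],[c,d]].

    The correction is clamped so |O-E| - 1/2 never goes negative;
    df = 1, two-sided.
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if np.any(table < 0):
        raise UndefinedTableError("counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise UndefinedTableError("a zero margin leaves the test undefined")
    stat, p, _, _ = stats.chi2_contingency(table, correction=True)
    return float(stat), float(p)


def pearson_correlation(x, y) -> tuple[float, float]:
    """Pearson r with a two-sided p from the t transform on n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise DegenerateSampleError("need paired samples of size >= 3")
    if np.var(x) == 0 or np.var(y) == 0:
        raise DegenerateSampleError("zero variance in one sample")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# interaction regression
# ---------------------------------------------------------------------------

@dataclass
class RegressionFit:
    """An ordinary-least-squares fit of an interaction model.

    Standard errors come from the classical homoskedastic covariance
    estimator; p-values are two-sided from the t distribution with
    n - p degrees of freedom.  ``perm_pvalues`` is populated by
    :func:`permutation_test`.
    """

    response: str
    terms: list[str]
    params: np.ndarray
    bse: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    residuals: np.ndarray
    fitted: np.ndarray
    rsquared: float
    nobs: int
    design: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    perm_pvalues: dict[str, float] | None = None

    def coef(self, term: str) -> float:
        if term not in self.terms:
            raise ContractError(f"fit has no term {term!r}")
        return float(self.params[self.terms.index(term)])

    def summary_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            {
                "estimate": self.params,
                "se": self.bse,
                "t": self.tvalues,
                "p": self.pvalues,
            },
            index=pd.Index(self.terms, name="term"),
        )
        if self.perm_pvalues is not None:
            out["perm_p"] = [self.perm_pvalues.get(t, np.nan) for t in self.terms]
        return out


@dataclass(frozen=True)
class CrossoverResult:
    """Age at which the modeled partial effect of DBP is exactly zero."""

    crossover_age: float
    crossover_value: float


def _design_matrix(
    table: pd.DataFrame, extra_terms: tuple[str, ...]
) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(table)), table["age"].to_numpy(float),
            table["dbp"].to_numpy(float),
            (table["age"] * table["dbp"]).to_numpy(float)]
    terms = list(CORE_TERMS)
    for extra in extra_terms:
        if extra not in EXTRA_TERM_COLUMNS:
            raise ConfigError(f"unknown extra term {extra!r}")
        if extra == "sex":
            col = (table["sex"].astype(str).str.upper() == "M").to_numpy(float)
        else:
            col = table[extra].to_numpy(float)
        cols.append(col)
        terms.append(EXTRA_TERM_COLUMNS[extra])
    return np.column_stack(cols), terms


def _check_rank(X: np.ndarray, terms: list[str]) -> None:
    if np.linalg.matrix_rank(X) == X.shape[1]:
        return
    offending = []
    rank = 0
    for j in range(X.shape[1]):
        new_rank = np.linalg.matrix_rank(X[:, : j + 1])
        if new_rank == rank:
            offending.append(terms[j])
        rank = new_rank
    raise CollinearityError(
        f"design matrix is rank deficient; collinear terms: {offending}"
    )


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """(coefs, residuals, rss) by least squares."""
    coefs, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coefs
    return coefs, resid, float(resid @ resid)


def fit_interaction_model(
    table: pd.DataFrame,
    response: str = "cavi0",
    extra_terms: tuple[str, ...] = (),
) -> RegressionFit:
    """OLS of an index on age, DBP and their interaction (plus extras).

    ``extra_terms`` may include any of ``"sbp"``, ``"sex"`` (coded
    male = 1) and ``"bmi"``, mirroring the extended adjustment model.
    """
    X, terms = _design_matrix(table, tuple(extra_terms))
    y = table[response].to_numpy(float)
    n, p = X.shape
    if n <= p:
        raise DegenerateSampleError("need more observations than model terms")
    _check_rank(X, terms)
    res = sm.OLS(y, X).fit()
    return RegressionFit(
        response=response,
        terms=terms,
        params=np.asarray(res.params),
        bse=np.asarray(res.bse),
        tvalues=np.asarray(res.tvalues),
        pvalues=np.asarray(res.pvalues),
        residuals=np.asarray(res.resid),
        fitted=np.asarray(res.fittedvalues),
        rsquared=float(res.rsquared),
        nobs=n,
        design=X,
        y=y,
    )


def sequential_anova(fit: RegressionFit) -> pd.DataFrame:
    """Type I (sequential) F tests, adding terms in model order."""
    X, y = fit.design, fit.y
    n, p = X.shape
    dof = n - p
    _, _, rss_full = _ols(X, y)
    mse = rss_full / dof
    rows = []
    prev_rss = float(np.sum((y - y.mean()) ** 2))
    for j in range(1, p):
        _, _, rss_j = _ols(X[:, : j + 1], y)
        ss = prev_rss - rss_j
        f = ss / mse
        rows.append(
            {
                "term": fit.terms[j],
                "df": 1,
                "sum_sq": ss,
                "F": f,
                "p": float(stats.f.sf(f, 1, dof)),
            }
        )
        prev_rss = rss_j
    rows.append({"term": "residual", "df": dof, "sum_sq": rss_full,
                 "F": np.nan, "p": np.nan})
    return pd.DataFrame(rows).set_index("term")


# ---------------------------------------------------------------------------
# permutation inference
# ---------------------------------------------------------------------------

def permutation_test(
    fit: RegressionFit,
    n_permutations: int = 999,
    seed: int | None = None,
    scheme: str = "freedman_lane",
    terms: list[str] | None = None,
) -> dict[str, float]:
    """Permutation p-values per coefficient of an OLS fit.

    The default Freedman-Lane scheme tests each term against the
    reduced model without it: the reduced-model residuals are
    permuted, added back to the reduced-model fitted values, the full
    model is refitted to each reconstructed response, and the
    permutation p-value is (1 + #{|t*| >= |t_obs|}) / (B + 1).  The
    simpler ``scheme="response"`` permutes the raw response instead.
    Results are attached to ``fit.perm_pvalues`` and returned.
    """
    if n_permutations < 99:
        raise ConfigError("need at least 99 permutations for usable resolution")
    if scheme not in ("freedman_lane", "response"):
        raise ConfigError(f"unknown permutation scheme {scheme!r}")
    rng = np.random.default_rng(seed)
    X, y = fit.design, fit.y
    n, p = X.shape
    dof = n - p
    pinv = np.linalg.pinv(X)
    diag_xtx_inv = np.diag(np.linalg.inv(X.T @ X))
    which = terms if terms is not None else fit.terms
    out: dict[str, float] = {}
    for term in which:
        j = fit.terms.index(term)
        if scheme == "freedman_lane":
            Z = np.delete(X, j, axis=1)
            gamma, resid_red, _ = _ols(Z, y)
            base = Z @ gamma
        else:
            base = np.zeros(n)
            resid_red = y
        # Build all permuted responses at once: n x B.
        perm_idx = np.argsort(rng.random((n_permutations, n)), axis=1)
        Ystar = base[:, None] + resid_red[perm_idx].T
        coefs = pinv @ Ystar                      # p x B
        resid = Ystar - X @ coefs
        sigma2 = np.einsum("ij,ij->j", resid, resid) / dof
        se_j = np.sqrt(sigma2 * diag_xtx_inv[j])
        tstar = np.abs(coefs[j] / se_j)
        t_obs = abs(fit.tvalues[j])
        out[term] = float((1 + np.sum(tstar >= t_obs)) / (n_permutations + 1))
    fit.perm_pvalues = dict(fit.perm_pvalues or {}, **out)
    return out


# ---------------------------------------------------------------------------
# prediction, crossover
# ---------------------------------------------------------------------------

def predict_index(
    fit: RegressionFit,
    age,
    dbp,
    extras: dict[str, float] | None = None,
):
    """Evaluate the fitted linear predictor at (age, DBP).

    Extra terms not supplied in ``extras`` are held at their sample
    means in the fitted design, so predictions are for a reference
    subject.  Vectorized over broadcastable age/dbp arrays.
    """
    age = np.asarray(age, dtype=float)
    dbp = np.asarray(dbp, dtype=float)
    extras = extras or {}
    pred = np.zeros(np.broadcast(age, dbp).shape)
    col_means = fit.design.mean(axis=0)
    for j, term in enumerate(fit.terms):
        beta = fit.params[j]
        if term == "intercept":
            pred = pred + beta
        elif term == "age":
            pred = pred + beta * age
        elif term == "dbp":
            pred = pred + beta * dbp
        elif term == "age_dbp":
            pred = pred + beta * age * dbp
        elif term in extras:
            pred = pred + beta * extras[term]
        else:
            pred = pred + beta * col_means[j]
    return pred if pred.ndim else float(pred)


def prediction_grid(
    fit: RegressionFit,
    ages=(40, 50, 60, 70, 80, 90),
    dbps=None,
    extras: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Tidy (age, dbp, predicted) table for plotting prediction lines."""
    if dbps is None:
        dbps = np.arange(50.0, 111.0, 5.0)
    rows = []
    for a in np.asarray(ages, dtype=float):
        preds = predict_index(fit, a, np.asarray(dbps, dtype=float), extras)
        for d, v in zip(np.asarray(dbps, dtype=float), np.atleast_1d(preds)):
            rows.append({"age": a, "dbp": d, "predicted": v})
    return pd.DataFrame(rows)


def crossover(fit: RegressionFit) -> CrossoverResult:
    """Age at which the DBP partial effect b_dbp + b_int*age is zero.

    At that age the prediction is DBP-independent; its value is
    intercept + b_age * age (extra terms at reference values are not
    included, matching the 3-term model this quantity describes).
    """
    for term in ("dbp", "age_dbp"):
        if term not in fit.terms:
            raise ContractError(f"fit lacks required term {term!r}")
    b_dbp = fit.coef("dbp")
    b_int = fit.coef("age_dbp")
    if b_int == 0:
        raise ContractError("zero interaction: DBP-effect lines are parallel")
    age_star = -b_dbp / b_int
    value = fit.coef("intercept") + fit.coef("age") * age_star
    return CrossoverResult(crossover_age=age_star, crossover_value=value)


# ---------------------------------------------------------------------------
# stratified description and trend
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupComparison:
    """Two-stratum descriptive comparison of a cohort table."""

    threshold: float
    n_young: int
    n_old: int
    continuous: pd.DataFrame
    binary: pd.DataFrame


DEFAULT_CONTINUOUS = ["age", "dbp", "sbp", "map", "pp", "cavi0", "cavi",
                      "pwv", "bmi", "waist"]
DEFAULT_BINARY = ["sex_male", "smoking", "hypertension", "diabetes",
                  "dyslipidemia"]


def _quartiles(x: np.ndarray) -> tuple[float, float, float]:
    q1, med, q3 = np.percentile(x, [25, 50, 75])  # inclusive-median (R type 7)
    return float(q1), float(med), float(q3)


def describe_by_age_group(
    table: pd.DataFrame,
    threshold: float = 70.0,
    continuous: list[str] | None = None,
    binary: list[str] | None = None,
) -> GroupComparison:
    """Per-variable two-group summary split at an age threshold.

    Continuous variables get mean, SD, median and quartiles per group
    plus t-test and Mann-Whitney p-values; binary variables get counts
    and percentages plus a Yates-corrected chi-square p-value.
    """
    work = table.copy()
    if "sex" in work.columns and "sex_male" not in work.columns:
        work["sex_male"] = (work["sex"].astype(str).str.upper() == "M").astype(int)
    young = work[work["age"] < threshold]
    old = work[work["age"] >= threshold]
    if len(young) == 0 or len(old) == 0:
        raise StratificationError("both age strata must be nonempty")

    cont_vars = [v for v in (continuous or DEFAULT_CONTINUOUS) if v in work.columns]
    bin_vars = [v for v in (binary or DEFAULT_BINARY) if v in work.columns]

    cont_rows = []
    for var in cont_vars:
        xy, xo = young[var].to_numpy(float), old[var].to_numpy(float)
        q1y, my, q3y = _quartiles(xy)
        q1o, mo, q3o = _quartiles(xo)
        _, t_p = student_t_test(xy, xo)
        _, mw_p = mann_whitney_u(xy, xo)
        cont_rows.append({
            "variable": var,
            "mean_young": xy.mean(), "sd_young": xy.std(ddof=1),
            "median_young": my, "q1_young": q1y, "q3_young": q3y,
            "mean_old": xo.mean(), "sd_old": xo.std(ddof=1),
            "median_old": mo, "q1_old": q1o, "q3_old": q3o,
            "t_p": t_p, "mw_p": mw_p,
        })

    bin_rows = []
    for var in bin_vars:
        ky = int(young[var].sum())
        ko = int(old[var].sum())
        _, chi_p = chisq_2x2_yates(ky, len(young) - ky, ko, len(old) - ko)
        bin_rows.append({
            "variable": var,
            "count_young": ky, "percent_young": 100.0 * ky / len(young),
            "count_old": ko, "percent_old": 100.0 * ko / len(old),
            "chi2_p": chi_p,
        })

    return GroupComparison(
        threshold=threshold,
        n_young=len(young),
        n_old=len(old),
        continuous=pd.DataFrame(cont_rows).set_index("variable"),
        binary=pd.DataFrame(bin_rows).set_index("variable"),
    )


@dataclass(frozen=True)
class TrendResult:
    """Linear trend of an index across ordinal decade age strata."""

    slope: float
    pvalue: float
    adjusted_for_dbp: bool
    stratum_means: pd.DataFrame


DECADE_EDGES = [40, 50, 60, 70, 80, 90, np.inf]
DECADE_LABELS = ["40-49", "50-59", "60-69", "70-79", "80-89", "90+"]


def trend_across_strata(
    table: pd.DataFrame,
    index: str = "cavi0",
    adjust_for_dbp: bool = False,
) -> TrendResult:
    """OLS of an index on an ordinal decade-stratum score.

    The score is 0 for ages 40-49 up to 5 for 90+; an optional DBP
    covariate tests whether the age trend survives pressure
    adjustment.  Per-stratum index means are returned for plotting.
    """
    score = pd.cut(
        table["age"], bins=DECADE_EDGES, right=False,
        labels=False, include_lowest=True,
    )
    mask = score.notna()
    if mask.sum() < len(table):
        raise StratificationError("ages outside 40+ cannot be assigned a stratum")
    score = score.astype(int)
    populated = np.unique(score)
    if len(populated) < 3:
        raise StratificationError("need at least 3 populated age strata")
    y = table.loc[mask, index].to_numpy(float)
    cols = [np.ones(mask.sum()), score.to_numpy(float)]
    if adjust_for_dbp:
        cols.append(table.loc[mask, "dbp"].to_numpy(float))
    X = np.column_stack(cols)
    coefs, resid, rss = _ols(X, y)
    dof = len(y) - X.shape[1]
    sigma2 = rss / dof
    se = np.sqrt(sigma2 * np.diag(np.linalg.inv(X.T @ X)))
    t = coefs[1] / se[1]
    p = 2.0 * stats.t.sf(abs(t), dof)
    means = (
        pd.DataFrame({"stratum": [DECADE_LABELS[s] for s in score], index: y})
        .groupby("stratum", sort=True)[index]
        .agg(["mean", "count"])
    )
    return TrendResult(
        slope=float(coefs[1]),
        pvalue=float(p),
        adjusted_for_dbp=adjust_for_dbp,
        stratum_means=means,
    )
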