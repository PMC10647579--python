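"""Tests for the statistical pipeline: elementary tests, interaction
regression, prediction, crossover, stratified description and trend."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from cavikit.analysis import (
    chisq_2x2_yates,
    crossover,
    describe_by_age_group,
    fit_interaction_model,
    mann_whitney_u,
    pearson_correlation,
    predict_index,
    prediction_grid,
    sequential_anova,
    student_t_test,
    trend_across_strata,
)
from cavikit.cohort import (
    GeneratorConfig,
    InteractionCoefficients,
    NoiseSpec,
    generate_regression_mode,
)
from cavikit.errors import (
    CollinearityError,
    ContractError,
    DegenerateSampleError,
    StratificationError,
    UndefinedTableError,
)


def plane_table(coeffs: InteractionCoefficients, n=60, seed=0) -> pd.DataFrame:
    """Noiseless table lying exactly on an interaction plane."""
    rng = np.random.default_rng(seed)
    age = rng.uniform(40, 96, n)
    dbp = rng.uniform(55, 109, n)
    return pd.DataFrame(
        {
            "age": age,
            "dbp": dbp,
            "cavi0": coeffs.intercept + coeffs.age * age + coeffs.dbp * dbp
            + coeffs.interaction * age * dbp,
        }
    )


# ---------------------------------------------------------------------------
# elementary tests
# ---------------------------------------------------------------------------

def test_student_t_pooled_reference():
    t, p = student_t_test([1, 2, 3], [2, 3, 4])
    assert t == pytest.approx(-1.2247, abs=5e-4)
    assert p == pytest.approx(0.288, abs=5e-3)


def test_student_t_identical_groups():
    t, p = student_t_test([1.0, 2.0, 5.0], [1.0, 2.0, 5.0])
    assert t == 0.0 and p == pytest.approx(1.0)


def test_student_t_zero_variance_errors():
    with pytest.raises(DegenerateSampleError):
        student_t_test([1.0, 1.0], [1.0, 1.0])


def test_mann_whitney_exact_reference_values():
    u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
    assert u == 0.0 and p == pytest.approx(0.1)
    u, p = mann_whitney_u([1, 2], [3, 4])
    assert p == pytest.approx(2 / 6)


def test_mann_whitney_complete_tie():
    u, p = mann_whitney_u([5.0], [5.0])
    assert u == 0.5 and p == 1.0


def brute_force_mw_p(x, y):
    """Exact two-sided Mann-Whitney p by enumerating all labelings."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    pooled = np.concatenate([x, y])
    n1 = len(x)

    def u_stat(xs, ys):
        return sum((xi > yj) + 0.5 * (xi == yj) for xi in xs for yj in ys)

    u_obs = u_stat(x, y)
    mean_u = n1 * len(y) / 2.0
    dev_obs = abs(u_obs - mean_u)
    count = total = 0
    for idx in combinations(range(len(pooled)), n1):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(idx)] = True
        u = u_stat(pooled[mask], pooled[~mask])
        total += 1
        if abs(u - mean_u) >= dev_obs - 1e-12:
            count += 1
    return count / total


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_mann_whitney_matches_enumeration(seed):
    """Tie-free small samples: implementation equals exhaustive enumeration."""
    rng = np.random.default_rng(seed)
    n1, n2 = rng.integers(2, 6, size=2)
    pooled = rng.permutation(np.arange(1.0, n1 + n2 + 1))
    x, y = pooled[:n1], pooled[n1:]
    _, p = mann_whitney_u(x, y)
    assert p == pytest.approx(brute_force_mw_p(x, y), abs=1e-12)


def test_chi_square_yates_reference_values():
    _, p = chisq_2x2_yates(74, 26, 53, 38)
    assert round(p, 3) == 0.031
    _, p = chisq_2x2_yates(21, 79, 27, 64)
    assert round(p, 3) == 0.225
    stat, p = chisq_2x2_yates(10, 10, 10, 10)
    assert stat == 0.0 and p == pytest.approx(1.0)


def test_chi_square_zero_margin_errors():
    with pytest.raises(UndefinedTableError):
        chisq_2x2_yates(0, 0, 5, 5)


def test_pearson_reference_values():
    assert pearson_correlation([1, 2, 3], [2, 4, 6])[0] == pytest.approx(1.0)
    assert pearson_correlation([1, 2, 3], [1, 3, 2])[0] == pytest.approx(0.5)
    assert pearson_correlation([1, 2, 3], [3, 2, 1])[0] == pytest.approx(-1.0)
    with pytest.raises(DegenerateSampleError):
        pearson_correlation([1, 1, 1], [1, 2, 3])


# ---------------------------------------------------------------------------
# interaction regression
# ---------------------------------------------------------------------------

def test_ols_matches_normal_equations_oracle(six_row_table):
    fit = fit_interaction_model(six_row_table, "cavi0")
    X = np.column_stack(
        [
            np.ones(6),
            six_row_table.age,
            six_row_table.dbp,
            six_row_table.age * six_row_table.dbp,
        ]
    )
    y = six_row_table["cavi0"].to_numpy()
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    assert np.allclose(fit.params, beta, atol=1e-9)
    resid = y - X @ beta
    sigma2 = resid @ resid / (6 - 4)
    se = np.sqrt(np.diag(sigma2 * np.linalg.inv(X.T @ X)))
    assert np.allclose(fit.bse, se, atol=1e-9)


def test_noiseless_fit_recovers_generating_plane():
    coeffs = InteractionCoefficients(-30.301, 0.682, 0.306, -0.005)
    fit = fit_interaction_model(plane_table(coeffs), "cavi0")
    assert np.allclose(fit.params, coeffs.as_array(), atol=1e-9)
    assert fit.rsquared == pytest.approx(1.0, abs=1e-12)


def test_collinear_design_raises_naming_terms():
    table = plane_table(InteractionCoefficients(0, 1, 1, 0))
    table["bmi"] = 2.0 * table["age"]  # exactly collinear with age
    with pytest.raises(CollinearityError, match="bmi"):
        fit_interaction_model(table, "cavi0", extra_terms=("bmi",))


def test_extended_model_terms_present():
    cfg = GeneratorConfig(n=500, seed=21)
    table = generate_regression_mode(cfg)
    fit = fit_interaction_model(table, "cavi0", extra_terms=("sbp", "sex", "bmi"))
    assert fit.terms == ["intercept", "age", "dbp", "age_dbp",
                         "sbp", "sex_male", "bmi"]
    assert 0 <= fit.rsquared <= 1


def test_sequential_anova_partitions_variance(six_row_table):
    fit = fit_interaction_model(six_row_table, "cavi0")
    table = sequential_anova(fit)
    y = fit.y
    tss = np.sum((y - y.mean()) ** 2)
    assert table["sum_sq"].sum() == pytest.approx(tss, rel=1e-10)
    # for the last term, the sequential F equals the squared t statistic
    assert table.loc["age_dbp", "F"] == pytest.approx(
        fit.tvalues[-1] ** 2, rel=1e-10
    )


# ---------------------------------------------------------------------------
# prediction and crossover
# ---------------------------------------------------------------------------

def test_predictions_from_printed_coefficients():
    coeffs = InteractionCoefficients(-30.301, 0.682, 0.306, -0.005)
    fit = fit_interaction_model(plane_table(coeffs), "cavi0")
    assert predict_index(fit, 70.0, 50.0) == pytest.approx(15.239, abs=1e-6)
    # OLS identity: prediction at covariate means equals mean fitted value
    mean_age = fit.design[:, 1].mean()
    mean_dbp = fit.design[:, 2].mean()
    # the interaction column mean is not the product of means, so check
    # the identity on the exact plane instead
    assert predict_index(fit, mean_age, mean_dbp) == pytest.approx(
        coeffs.intercept + coeffs.age * mean_age + coeffs.dbp * mean_dbp
        + coeffs.interaction * mean_age * mean_dbp
    )


def test_prediction_grid_shape_and_values():
    coeffs = InteractionCoefficients(0.0, 1.0, 0.0, 0.0)
    fit = fit_interaction_model(plane_table(coeffs), "cavi0")
    grid = prediction_grid(fit, ages=(40, 60), dbps=(60.0, 80.0))
    assert len(grid) == 4
    assert np.allclose(grid["predicted"], grid["age"], atol=1e-9)


def test_crossover_from_printed_coefficients():
    coeffs = InteractionCoefficients(-30.301, 0.682, 0.306, -0.005)
    fit = fit_interaction_model(plane_table(coeffs), "cavi0")
    result = crossover(fit)
    assert result.crossover_age == pytest.approx(61.2, abs=1e-6)
    assert result.crossover_value == pytest.approx(11.437, abs=5e-4)
    # at the crossover age the prediction is DBP-independent
    lo = predict_index(fit, result.crossover_age, 50.0)
    hi = predict_index(fit, result.crossover_age, 110.0)
    assert abs(lo - hi) < 1e-9
    assert lo == pytest.approx(result.crossover_value, abs=1e-9)


def test_crossover_simple_ratio_and_parallel_error():
    fit = fit_interaction_model(
        plane_table(InteractionCoefficients(0.0, 1.0, 1.0, -0.01)), "cavi0"
    )
    result = crossover(fit)
    assert result.crossover_age == pytest.approx(100.0, abs=1e-6)
    assert result.crossover_value == pytest.approx(100.0, abs=1e-6)

    parallel = fit_interaction_model(
        plane_table(InteractionCoefficients(0.0, 1.0, 1.0, 0.0)), "cavi0"
    )
    # interaction estimate is numerically ~0 but not exactly; force it
    parallel.params[parallel.terms.index("age_dbp")] = 0.0
    with pytest.raises(ContractError):
        crossover(parallel)


# ---------------------------------------------------------------------------
# stratified description and trend
# ---------------------------------------------------------------------------

def test_describe_by_age_group_hand_summary(six_row_table):
    comp = describe_by_age_group(six_row_table, threshold=70.0)
    assert comp.n_young == 3 and comp.n_old == 3
    row = comp.continuous.loc["dbp"]
    assert row["mean_young"] == pytest.approx((88 + 86 + 82) / 3)
    assert row["median_old"] == pytest.approx(72.0)
    assert row["q1_young"] <= row["median_young"] <= row["q3_young"]
    bin_row = comp.binary.loc["hypertension"]
    assert bin_row["count_young"] == 2 and bin_row["count_old"] == 2
    assert 0 <= bin_row["chi2_p"] <= 1


def test_describe_binary_matches_chisq_op():
    n_young, n_old = 100, 91
    rng = np.random.default_rng(0)
    table = pd.DataFrame(
        {
            "age": np.r_[rng.uniform(40, 69, n_young), rng.uniform(70, 96, n_old)],
            "dyslipidemia": np.r_[
                np.ones(74), np.zeros(26), np.ones(53), np.zeros(38)
            ].astype(int),
        }
    )
    comp = describe_by_age_group(table, continuous=[], binary=["dyslipidemia"])
    _, expected = chisq_2x2_yates(74, 26, 53, 38)
    assert comp.binary.loc["dyslipidemia", "chi2_p"] == pytest.approx(expected)


def test_describe_empty_stratum_errors(six_row_table):
    with pytest.raises(StratificationError):
        describe_by_age_group(six_row_table, threshold=200.0)


def test_trend_perfect_increase():
    rng = np.random.default_rng(1)
    age = rng.uniform(40, 96, 300)
    table = pd.DataFrame({"age": age, "dbp": rng.uniform(60, 100, 300),
                          "cavi0": age * 0.5})
    res = trend_across_strata(table, "cavi0")
    assert res.slope > 0 and res.pvalue < 1e-6
    assert list(res.stratum_means.index) == sorted(res.stratum_means.index)
    adj = trend_across_strata(table, "cavi0", adjust_for_dbp=True)
    assert adj.slope > 0 and adj.pvalue < 1e-6


def test_trend_requires_three_strata():
    table = pd.DataFrame({"age": [45.0, 46, 47, 55, 56], "cavi0": range(5)})
    with pytest.raises(StratificationError):
        trend_across_strata(table, "cavi0")
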