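import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from wormfit.metrics import add_fitness_columns
from wormfit.simulate import MethodError, full_design_config, simulate_assay
from wormfit.varmodel import (
    ConvergenceError,
    SingularDesignError,
    VarianceModelSpec,
    aicc,
    analyze_p,
    analyze_sd_logci,
    default_candidate_ladder,
    fit_model,
    model_search,
    type3_f_test,
)

LOG2PI = math.log(2 * math.pi)


def _frame(y, method=None, block=None, focal=None, competitor=None):
    n = len(y)
    return pd.DataFrame(
        {
            "y": y,
            "focal_strain": focal if focal is not None else ["a"] * n,
            "competitor_strain": competitor if competitor is not None else ["x"] * n,
            "method": method if method is not None else ["m1"] * n,
            "block_id": block if block is not None else ["B1"] * n,
        }
    )


def dense_reml_loglik(y, X, V):
    """Independent oracle: REML log-likelihood by dense matrix algebra."""
    n, p = X.shape
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    return -0.5 * (
        (n - p) * LOG2PI
        + np.linalg.slogdet(V)[1]
        + np.linalg.slogdet(XtViX)[1]
        + r @ Vi @ r
    )


def dense_ml_loglik(y, X, V):
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    return stats.multivariate_normal.logpdf(y, mean=X @ beta, cov=V)


def test_reml_intercept_only_equals_sample_variance(rng):
    y = rng.normal(3.0, 1.7, size=25)
    fit = fit_model(VarianceModelSpec(response="y"), _frame(y), "REML")
    assert fit.sigma2["all"] == pytest.approx(np.var(y, ddof=1), rel=1e-6)


def test_two_group_free_variances_match_closed_form(rng):
    y = np.concatenate([rng.normal(0, 1, 12), rng.normal(0.5, 2.5, 15)])
    method = ["m1"] * 12 + ["m2"] * 15
    spec = VarianceModelSpec(
        response="y", fixed_terms=("method",), residual_grouping=("method",)
    )
    fit = fit_model(spec, _frame(y, method=method), "REML")
    assert fit.sigma2["m1"] == pytest.approx(np.var(y[:12], ddof=1), rel=1e-6)
    assert fit.sigma2["m2"] == pytest.approx(np.var(y[12:], ddof=1), rel=1e-6)
    # REML logL against the dense-matrix oracle at the fitted variances
    V = np.diag([fit.sigma2["m1"]] * 12 + [fit.sigma2["m2"]] * 15)
    X = fit._X
    assert fit.loglik == pytest.approx(dense_reml_loglik(y, X, V), abs=1e-6)


def test_loglik_matches_dense_gaussian_with_block_random_effect(rng):
    """ML and REML likelihoods against brute-force dense MVN evaluation on a
    small instance with a block random intercept."""
    n_per, blocks = 5, ["B1", "B2", "B3"]
    y = rng.normal(1.0, 1.0, size=n_per * len(blocks))
    method = (["m1", "m1", "m2", "m2", "m2"]) * 3
    block = sum(([b] * n_per for b in blocks), [])
    d = _frame(y, method=method, block=block)
    spec = VarianceModelSpec(
        response="y", fixed_terms=("method",), random_block=True,
        residual_grouping=("method",),
    )
    for criterion, oracle in (("ML", dense_ml_loglik), ("REML", dense_reml_loglik)):
        fit = fit_model(spec, d, criterion)
        sig = np.array([fit.sigma2[m] for m in method])
        Z = np.asarray([[b == bb for bb in blocks] for b in block], dtype=float)
        V = np.diag(sig) + max(fit.sigma2_block, 1e-13) * Z @ Z.T
        assert fit.loglik == pytest.approx(oracle(y, fit._X, V), abs=1e-5)


def test_aicc_formula_and_limits():
    fit = fit_model(
        VarianceModelSpec(response="y"),
        _frame(np.arange(10.0)),
        "REML",
    )
    # formula check with synthetic inputs: logL=-10, k=2, n=10 -> 25.714
    fit2 = fit
    fit2.loglik, fit2.k, fit2.n = -10.0, 2, 10
    assert aicc(fit2) == pytest.approx(20 + 4 + 12 / 7, abs=1e-3)
    fit2.k = 0
    assert aicc(fit2) == pytest.approx(20.0)
    fit2.k, fit2.n = 9, 10
    assert math.isnan(aicc(fit2))


def test_useless_parameter_never_improves_ml_deviance(rng):
    y = rng.normal(0, 1, size=40)
    method = ["m1", "m2"] * 20
    d = _frame(y, method=method)
    small = fit_model(VarianceModelSpec(response="y"), d, "ML")
    big = fit_model(
        VarianceModelSpec(response="y", fixed_terms=("method",)), d, "ML"
    )
    assert -2 * big.loglik <= -2 * small.loglik + 1e-6
    assert big.aicc > small.aicc  # the useless term costs more than it buys


def test_satterthwaite_equals_welch_for_two_free_variances(rng):
    g1 = rng.normal(0.0, 1.0, size=11)
    g2 = rng.normal(0.8, 2.2, size=17)
    y = np.concatenate([g1, g2])
    spec = VarianceModelSpec(
        response="y", fixed_terms=("method",), residual_grouping=("method",)
    )
    fit = fit_model(spec, _frame(y, method=["m1"] * 11 + ["m2"] * 17), "REML")
    ft = type3_f_test(fit, "method")
    t, p = stats.ttest_ind(g1, g2, equal_var=False)
    v1, v2 = np.var(g1, ddof=1) / 11, np.var(g2, ddof=1) / 17
    welch_df = (v1 + v2) ** 2 / (v1**2 / 10 + v2**2 / 16)
    assert ft.f_value == pytest.approx(t**2, rel=1e-6)
    assert ft.denom_df == pytest.approx(welch_df, rel=1e-6)
    assert ft.p_value == pytest.approx(p, rel=1e-5)


def test_f_test_matches_textbook_anova_in_balanced_pooled_case(rng):
    groups = [rng.normal(mu, 1.0, size=8) for mu in (0.0, 0.3, -0.2)]
    y = np.concatenate(groups)
    method = ["m1"] * 8 + ["m2"] * 8 + ["m3"] * 8
    spec = VarianceModelSpec(response="y", fixed_terms=("method",))
    fit = fit_model(spec, _frame(y, method=method), "REML")
    ft = type3_f_test(fit, "method")
    F, p = stats.f_oneway(*groups)
    assert ft.f_value == pytest.approx(F, rel=1e-6)
    assert ft.denom_df == pytest.approx(21.0, rel=1e-6)  # n - 3 exactly
    assert ft.p_value == pytest.approx(p, rel=1e-6)
    with pytest.raises(ValueError, match="not among fitted"):
        type3_f_test(fit, "focal")


def test_variance_recovery_from_known_heteroscedastic_truth(rng):
    """3 methods with sigma = {1, 2, 3}, 50 obs each: each sigma-hat lands
    within 3 SEs of truth on average over 200 replicates."""
    sig = {"m1": 1.0, "m2": 2.0, "m3": 3.0}
    spec = VarianceModelSpec(
        response="y", fixed_terms=("method",), residual_grouping=("method",)
    )
    est = {m: [] for m in sig}
    n_rep = 200
    for _ in range(n_rep):
        y = np.concatenate([rng.normal(0, s, size=50) for s in sig.values()])
        method = ["m1"] * 50 + ["m2"] * 50 + ["m3"] * 50
        fit = fit_model(spec, _frame(y, method=method), "REML")
        for m in sig:
            est[m].append(fit.sigma2[m])
    for m, s in sig.items():
        e = np.asarray(est[m])
        se = e.std(ddof=1) / math.sqrt(n_rep)
        assert abs(e.mean() - s**2) < 3 * se


def test_model_search_ties_and_ranking_invariances(rng):
    y = rng.normal(0, 1, size=60)
    method = ["m1", "m2", "m3"] * 20
    d = _frame(y, method=method)
    spec = VarianceModelSpec(response="y", fixed_terms=("method",))
    table, best, _ = model_search(d, [spec, spec, VarianceModelSpec(response="y")])
    assert table.iloc[0]["aicc"] != table.iloc[1]["aicc"] or (
        table.iloc[0]["index"] < table.iloc[1]["index"]
    )
    tied = table[table["model"] == spec.label()]
    assert tied["aicc"].nunique() == 1
    assert list(tied["index"]) == sorted(tied["index"])  # stable input order

    # invariance to row order and to relabelled factor levels
    t1, b1, _ = model_search(d, [spec, VarianceModelSpec(response="y")])
    d_shuf = d.sample(frac=1.0, random_state=1).reset_index(drop=True)
    t2, b2, _ = model_search(d_shuf, [spec, VarianceModelSpec(response="y")])
    d_rec = d.replace({"method": {"m1": "zz", "m2": "aa", "m3": "mm"}})
    t3, b3, _ = model_search(d_rec, [spec, VarianceModelSpec(response="y")])
    for ta, tb in ((t1, t2), (t1, t3)):
        assert np.allclose(
            ta.sort_values("index")["aicc"], tb.sort_values("index")["aicc"],
            atol=1e-6,
        )


def test_model_search_flags_failed_candidates(rng):
    # one residual group has a single observation: free variance impossible
    y = rng.normal(0, 1, size=7)
    method = ["m1"] * 6 + ["m2"]
    d = _frame(y, method=method)
    bad = VarianceModelSpec(response="y", residual_grouping=("method",))
    ok = VarianceModelSpec(response="y")
    table, best, _ = model_search(d, [bad, ok])
    assert best == ok
    failed = table[~table["converged"]]
    assert len(failed) == 1 and "<2 observations" in failed.iloc[0]["error"]


def test_spec_validation_enforces_marginality():
    with pytest.raises(ValueError, match="margin"):
        VarianceModelSpec(response="y", fixed_terms=("focal:method",))
    with pytest.raises(SingularDesignError):
        # single-level factor aliased with the intercept
        fit_model(
            VarianceModelSpec(response="y", fixed_terms=("focal",)),
            _frame(np.arange(6.0)),
            "REML",
        )


def test_zero_block_variance_pins_at_boundary(rng):
    y = rng.normal(0.0, 1.0, size=60)
    block = ["B1", "B2", "B3"] * 20
    spec = VarianceModelSpec(response="y", random_block=True)
    fit = fit_model(spec, _frame(y, block=block), "REML")
    assert fit.sigma2_block == pytest.approx(0.0, abs=1e-4)


def test_analyze_sd_logci_names_missing_factor_levels(full_sim):
    est, _ = full_sim
    single = est[est["method"] == "sorter"]
    with pytest.raises(ValueError, match="method"):
        analyze_sd_logci(single)


def test_headline_analyses_run_on_full_design(full_sim):
    est, _ = full_sim
    rep = analyze_sd_logci(est)
    ft = rep["f_test"]
    assert ft.num_df == 2
    assert ft.denom_df > 2
    assert 0.0 < ft.p_value <= 1.0
    assert {"model", "aicc", "delta_aicc"} <= set(rep["model_table"].columns)

    rep_p = analyze_p(est)
    assert rep_p["f_test"].num_df == 2
    assert rep_p["best_fit"].sigma2_block is not None
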