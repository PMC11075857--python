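"""Tests for rule extraction, the chi-square screen, and the sparse linear
rule model."""

import itertools

import numpy as np
import pandas as pd
import pytest

import upliftrules as ur
from upliftrules.data import TrialDataset
from upliftrules.errors import ConfigError, UpliftRulesError, ValidationError
from upliftrules.rules import (Rule, fit_rule_model, extract_rules,
                               importance_scores, linear_design,
                               node_chi_square, rank_and_select,
                               rule_importance, rule_matrix, subgroup_ate)
from upliftrules.schema import FeatureSchema, FeatureSpec
from upliftrules.tree import NodeStats, SplitCondition


def two_feature_ds(xvals, yvals, t, y):
    schema = FeatureSchema([
        FeatureSpec("x"), FeatureSpec("y"),
        FeatureSpec("T", role="treatment", kind="binary"),
        FeatureSpec("Y", role="outcome", kind="binary")])
    return TrialDataset(X=pd.DataFrame({"x": xvals, "y": yvals}),
                        t=np.asarray(t), y=np.asarray(y), schema=schema)


# ---- chi-square -------------------------------------------------------------

def test_chi_square_closed_form_value():
    res = node_chi_square(NodeStats(n_t=50, n_c=50, s_t=30, s_c=10))
    assert res.statistic == pytest.approx(16.6667, abs=1e-3)
    assert res.p_value == pytest.approx(4.45e-5, rel=0.05)
    assert not res.degenerate


def test_chi_square_equal_rates_zero():
    res = node_chi_square(NodeStats(n_t=40, n_c=40, s_t=10, s_c=10))
    assert res.statistic == 0.0
    assert res.p_value == 1.0


def test_chi_square_degenerate_margin():
    res = node_chi_square(NodeStats(n_t=20, n_c=20, s_t=20, s_c=20))
    assert res.degenerate and res.p_value == 1.0


def test_chi_square_matches_scipy():
    from scipy.stats import chi2_contingency
    rng = np.random.default_rng(5)
    for _ in range(50):
        nt, nc = rng.integers(5, 60, 2)
        st, sc = rng.integers(1, nt), rng.integers(1, nc)
        res = node_chi_square(NodeStats(int(nt), int(nc), int(st), int(sc)))
        table = [[st, nt - st], [sc, nc - sc]]
        chi2, p, _, _ = chi2_contingency(table, correction=False)
        assert res.statistic == pytest.approx(chi2, abs=1e-9)
        assert res.p_value == pytest.approx(p, abs=1e-12)


# ---- interval merging / rule evaluation --------------------------------------

def test_rule_merges_same_feature_conditions():
    r = Rule(conditions=(SplitCondition("x", ">=", 70.0),
                         SplitCondition("x", ">=", 80.0)))
    assert r.describe() == "x >= 80"
    r2 = Rule(conditions=(SplitCondition("x", ">=", 70.0),
                          SplitCondition("x", "<", 147.0)))
    assert r2.describe() == "x >= 70 and x < 147"


def test_rule_matrix_boundary_semantics():
    ds = two_feature_ds([70.0, 69.0, 70.0], [214.0, 214.0, 215.0],
                        [0, 1, 0], [0, 1, 0])
    rule = Rule(conditions=(SplitCondition("x", ">=", 70.0),
                            SplitCondition("y", "<", 215.0)))
    R, s = rule_matrix([rule], ds.X)
    assert R[:, 0].tolist() == [1, 0, 0]
    assert s[0] == pytest.approx(1 / 3)


def test_rule_matrix_empty_and_full():
    ds = two_feature_ds([1.0, 2.0], [1.0, 2.0], [0, 1], [0, 1])
    R, s = rule_matrix([], ds.X)
    assert R.shape == (2, 0)
    rule = Rule(conditions=(SplitCondition("x", ">=", -1e9),))
    R, s = rule_matrix([rule], ds.X)
    assert R[:, 0].tolist() == [1, 1] and s[0] == 1.0


# ---- extract_rules -----------------------------------------------------------

def test_extract_rules_contracts(default_sim, small_forest):
    ds, _ = default_sim
    rules = extract_rules(small_forest, alpha=0.05, reference=ds)
    n_nonroot = sum(len(list(t.walk())) - 1 for t in small_forest.trees)
    assert 0 < len(rules) <= n_nonroot
    for r in rules:
        assert r.p_value < 0.05
        assert 1 <= r.depth <= small_forest.params.max_depth
        assert 0.0 <= r.support_frac <= 1.0
    # exact duplicates collapsed
    keys = [r.key() for r in rules]
    assert len(keys) == len(set(keys))


def test_extract_rules_single_leaf_forest(default_sim):
    ds, _ = default_sim
    from upliftrules.tree import TreeGrowthParams
    # min_node_samples above n forces single-leaf trees
    f = ur.grow_forest(ds, TreeGrowthParams(min_node_samples=10_000),
                       n_trees=3, seed=0)
    assert extract_rules(f, reference=ds) == []


def test_extract_rules_alpha_monotone(default_sim, small_forest):
    ds, _ = default_sim
    loose = extract_rules(small_forest, alpha=0.5, reference=ds)
    tight = extract_rules(small_forest, alpha=0.01, reference=ds)
    assert len(tight) <= len(loose)
    tight_keys = {r.key() for r in tight}
    assert tight_keys <= {r.key() for r in loose}


# ---- fit_rule_model ----------------------------------------------------------

def toy_design(n=60, m=3, seed=0):
    rng = np.random.default_rng(seed)
    R = (rng.random((n, m)) < 0.5).astype(float)
    schema = FeatureSchema([
        FeatureSpec("z"),
        FeatureSpec("T", role="treatment", kind="binary"),
        FeatureSpec("Y", role="outcome", kind="binary")])
    X = pd.DataFrame({"z": rng.normal(size=n)})
    return R, X, schema, rng


def test_lambda_large_full_shrinkage():
    R, X, schema, rng = toy_design()
    tau = rng.normal(0.1, 0.05, size=len(X))
    m = fit_rule_model(tau, R, linear_design(X, schema), lam=1e6)
    assert np.allclose(m.rule_coefs, 0.0)
    assert np.allclose(m.feature_coefs, 0.0)
    assert m.intercept == pytest.approx(tau.mean(), abs=1e-9)


def test_lambda_zero_matches_least_squares():
    R, X, schema, rng = toy_design(n=80)
    tau = rng.normal(size=80)
    Z = linear_design(X, schema)
    m = fit_rule_model(tau, R, Z, lam=0.0)
    D = np.column_stack([R, Z.values, np.ones(80)])
    beta, *_ = np.linalg.lstsq(D, tau, rcond=None)
    got = np.concatenate([m.rule_coefs, m.feature_coefs, [m.intercept]])
    assert np.allclose(got, beta, atol=1e-6)


def test_negative_lambda_rejected():
    R, X, schema, rng = toy_design()
    with pytest.raises((ValidationError, ConfigError, UpliftRulesError)):
        fit_rule_model(rng.normal(size=len(X)), R, linear_design(X, schema),
                       lam=-1.0)


def test_objective_matches_bruteforce_grid_minimum():
    """On a 2-coefficient toy (1 rule + intercept, no linear terms), the
    solver's objective is within 1e-6 of the best point on a fine grid."""
    rng = np.random.default_rng(3)
    n = 50
    R = (rng.random((n, 1)) < 0.5).astype(float)
    tau = 0.3 * R[:, 0] + rng.normal(0, 0.05, n)
    Z = pd.DataFrame(index=range(n))  # no linear terms
    lam = 0.5
    m = fit_rule_model(tau, R, Z, lam=lam)
    def objective(a, c):
        return np.sum((tau - (a * R[:, 0] + c)) ** 2) + lam * abs(a)
    got = objective(m.rule_coefs[0], m.intercept)
    best = min(objective(a, c)
               for a in np.linspace(-0.1, 0.5, 121)
               for c in np.linspace(-0.2, 0.3, 101))
    assert got <= best + 1e-6


def test_planted_rule_wins_against_noise_rules():
    """tau = 0.2*(planted indicator) + small noise, 10 noise rules: the
    planted rule gets the largest |a| in a clear majority of 20 seeds."""
    wins = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        n = 200
        R = (rng.random((n, 11)) < 0.5).astype(float)
        tau = 0.2 * R[:, 0] + rng.normal(0, 0.01, n)
        Z = pd.DataFrame(index=range(n))
        m = fit_rule_model(tau, R, Z, lam=0.5)
        if np.argmax(np.abs(m.rule_coefs)) == 0:
            wins += 1
    assert wins >= 15


def test_linear_coefficients_back_transformed():
    """Fitting on z-scored continuous terms must report original-scale
    coefficients: predictions reproduce the target for an exact linear tau."""
    rng = np.random.default_rng(9)
    n = 100
    schema = FeatureSchema([
        FeatureSpec("z"),
        FeatureSpec("T", role="treatment", kind="binary"),
        FeatureSpec("Y", role="outcome", kind="binary")])
    X = pd.DataFrame({"z": rng.normal(3.0, 10.0, n)})  # far from unit scale
    tau = 0.02 * X["z"].values + 0.1
    m = fit_rule_model(tau, np.zeros((n, 0)), linear_design(X, schema), lam=0.0)
    pred = m.predict(np.zeros((n, 0)), linear_design(X, schema))
    assert np.allclose(pred, tau, atol=1e-8)
    assert m.feature_coefs[0] == pytest.approx(0.02, abs=1e-8)


# ---- importance and ranking --------------------------------------------------

def test_rule_importance_arithmetic():
    assert round(rule_importance(0.0090, 0.8191), 4) == 0.0035
    assert round(rule_importance(-0.0063, 0.0913), 4) == 0.0018
    assert round(rule_importance(-0.0046, 0.4991), 4) == 0.0023
    assert rule_importance(0.0, 0.77) == 0.0


def test_importance_scores_match_formula(default_sim, small_forest):
    ds, _ = default_sim
    rules = extract_rules(small_forest, reference=ds)
    R, s = rule_matrix(rules, ds.X)
    Z = linear_design(ds.X, ds.schema)
    m = fit_rule_model(small_forest.predict_oob(ds), R, Z, lam=1.0, rules=rules)
    I_m, I_d = importance_scores(m)
    assert np.allclose(I_m, np.abs(m.rule_coefs) * np.sqrt(s * (1 - s)))
    sds = Z.values.std(axis=0)
    assert np.allclose(I_d, np.abs(m.feature_coefs) * sds)


def fitted_toy_model():
    rules = [Rule(conditions=(SplitCondition("x", ">=", float(i)),))
             for i in range(3)]
    return ur.RuleLinearModel(
        rules=rules, rule_coefs=np.array([0.009, 0.004, -0.006]),
        feature_names=[], feature_coefs=np.zeros(0), intercept=0.0, lam=1.0,
        rule_supports=np.array([0.8191, 0.5, 0.0913]), feature_sds=np.zeros(0))


def test_rank_and_select_threshold_semantics():
    m = fitted_toy_model()
    fav, unf = rank_and_select(m, threshold="coefficient", value=0.005)
    assert [r.coefficient for r in fav] == [pytest.approx(0.009)]
    assert [r.coefficient for r in unf] == [pytest.approx(-0.006)]
    fav, unf = rank_and_select(m, threshold="nonzero")
    assert len(fav) == 2 and len(unf) == 1
    fav, unf = rank_and_select(m, threshold="importance", value=0.002)
    kept = [r.importance for r in fav + unf]
    assert all(i > 0.002 for i in kept)


def test_rank_and_select_sorted_by_importance():
    m = fitted_toy_model()
    fav, unf = rank_and_select(m, threshold="nonzero")
    imps = [r.importance for r in fav]
    assert imps == sorted(imps, reverse=True)


def test_rank_and_select_unknown_threshold():
    with pytest.raises(ConfigError):
        rank_and_select(fitted_toy_model(), threshold="bogus")


def test_rank_and_select_empty_on_full_shrinkage():
    m = fitted_toy_model()
    m.rule_coefs = np.zeros(3)
    fav, unf = rank_and_select(m, threshold="nonzero")
    assert fav == [] and unf == []


# ---- subgroup ATE ------------------------------------------------------------

def test_subgroup_ate_arithmetic():
    t = np.array([1] * 10 + [0] * 10)
    y = np.array([1] * 6 + [0] * 4 + [1] * 4 + [0] * 6)
    ds = two_feature_ds(np.ones(20), np.ones(20), t, y)
    rule = Rule(conditions=(SplitCondition("x", ">=", 0.0),))
    ate, se, n_in = subgroup_ate(ds, rule)
    assert ate == pytest.approx(0.2)
    assert se == pytest.approx(np.sqrt(0.024 + 0.024), abs=1e-3)
    assert n_in == 20


def test_subgroup_ate_missing_arm_errors():
    ds = two_feature_ds([1.0, -1.0], [0.0, 0.0], [1, 0], [1, 0])
    rule = Rule(conditions=(SplitCondition("x", ">=", 0.0),))
    with pytest.raises(UpliftRulesError) as exc:
        subgroup_ate(ds, rule)
    assert "x >= 0" in str(exc.value)
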