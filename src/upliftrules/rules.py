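"""Rule extraction, significance screening, and sparse linear ranking.

A *rule* is the conjunction of split conditions on the path from a tree's
root to one of its nodes; it defines a candidate responsive subgroup. The
forest is flattened into all such rules, each screened by a Pearson
chi-square test on the node's 2x2 arm-by-outcome table; significant rules are
encoded as binary indicator columns and, together with the raw baseline
features, regressed onto the forest's per-subject effect estimates with an
L1 penalty (RuleFit-style). A rule's importance is |coefficient| *
sqrt(support * (1 - support)); a linear term's importance is |coefficient| *
SD(feature). Ranked rules are reported with their within-subgroup average
treatment effect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.linear_model import Lasso, LinearRegression

from .data import TrialDataset
from .errors import ConfigError, UpliftRulesError, ValidationError
from .forest import UpliftForest
from .tree import NodeStats, SplitCondition

logger = logging.getLogger(__name__)

__all__ = [
    "Rule", "RuleLinearModel", "SubgroupReport", "ChiSquareResult",
    "node_chi_square", "extract_rules", "rule_matrix", "fit_rule_model",
    "rule_importance", "importance_scores", "rank_and_select", "subgroup_ate",
    "linear_design",
]


# ---------------------------------------------------------------------------
# rules


def merge_conditions(conditions, schema) -> tuple:
    """Canonicalize a condition path: one interval / level set per feature.

    Repeated ">=" thresholds keep the largest, "<" thresholds the smallest;
    categorical memberships intersect. The result is sorted by feature name
    (then bound direction) so identical subgroups compare equal.
    """
    lower, upper, levels = {}, {}, {}
    order = []
    for c in conditions:
        if c.feature not in order:
            order.append(c.feature)
        if c.comparator == ">=":
            lower[c.feature] = max(lower.get(c.feature, -np.inf), c.threshold)
        elif c.comparator == "<":
            upper[c.feature] = min(upper.get(c.feature, np.inf), c.threshold)
        else:
            allowed = levels.get(c.feature, set(schema[c.feature].levels))
            if c.comparator == "in":
                allowed &= set(c.levels)
            else:
                allowed -= set(c.levels)
            levels[c.feature] = allowed
    out = []
    for feat in sorted(order):
        if feat in lower:
            out.append(SplitCondition(feat, ">=", lower[feat]))
        if feat in upper:
            out.append(SplitCondition(feat, "<", upper[feat]))
        if feat in levels:
            all_levels = list(schema[feat].levels)
            allowed = levels[feat]
            if allowed == set(all_levels):
                continue  # vacuous
            kept = tuple(lv for lv in all_levels if lv in allowed)
            if not kept:
                kept = ()  # contradictory path: matches nothing
            excluded = tuple(lv for lv in all_levels if lv not in allowed)
            # prefer the shorter description
            if kept and len(excluded) < len(kept):
                out.append(SplitCondition(feat, "not in", levels=excluded))
            elif kept:
                out.append(SplitCondition(feat, "in", levels=kept))
            else:
                out.append(SplitCondition(feat, "in", levels=("__none__",)))
    return tuple(out)


@dataclass
class Rule:
    """A conjunction of split conditions defining one candidate subgroup."""

    conditions: tuple
    tree_index: int = -1
    node_id: int = -1
    depth: int = 0
    statistic: float = np.nan
    p_value: float = np.nan
    support_count: int = 0
    support_frac: float = np.nan

    def __post_init__(self):
        # Type invariant: at most one interval per feature. Threshold
        # conditions are merged here; categorical level-set intersection needs
        # the schema and happens in merge_conditions at extraction time.
        lower, upper, passthrough = {}, {}, []
        order = []
        for c in self.conditions:
            if c.feature not in order:
                order.append(c.feature)
            if c.comparator == ">=":
                lower[c.feature] = max(lower.get(c.feature, -np.inf), c.threshold)
            elif c.comparator == "<":
                upper[c.feature] = min(upper.get(c.feature, np.inf), c.threshold)
            else:
                passthrough.append(c)
        out = []
        for feat in order:
            if feat in lower:
                out.append(SplitCondition(feat, ">=", lower[feat]))
            if feat in upper:
                out.append(SplitCondition(feat, "<", upper[feat]))
            out.extend(c for c in passthrough if c.feature == feat)
        self.conditions = tuple(out)

    def key(self) -> tuple:
        return tuple((c.feature, c.comparator, c.threshold, c.levels)
                     for c in self.conditions)

    def evaluate(self, X) -> np.ndarray:
        """Boolean membership vector on a covariate frame or dataset."""
        if isinstance(X, TrialDataset):
            X = X.X
        mask = np.ones(len(X), dtype=bool)
        for c in self.conditions:
            if c.levels == ("__none__",):
                return np.zeros(len(X), dtype=bool)
            mask &= c.evaluate(X)
        return mask

    def describe(self) -> str:
        return " and ".join(c.describe() for c in self.conditions) or "(everyone)"

    def to_dict(self) -> dict:
        return {
            "conditions": [c.to_dict() for c in self.conditions],
            "tree_index": self.tree_index, "node_id": self.node_id,
            "depth": self.depth, "statistic": self.statistic,
            "p_value": self.p_value, "support_count": self.support_count,
            "support_frac": self.support_frac,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Rule":
        return cls(conditions=tuple(SplitCondition.from_dict(c)
                                    for c in d["conditions"]),
                   tree_index=d.get("tree_index", -1),
                   node_id=d.get("node_id", -1), depth=d.get("depth", 0),
                   statistic=d.get("statistic", np.nan),
                   p_value=d.get("p_value", np.nan),
                   support_count=d.get("support_count", 0),
                   support_frac=d.get("support_frac", np.nan))


# ---------------------------------------------------------------------------
# chi-square screening


class ChiSquareResult(NamedTuple):
    statistic: float
    p_value: float
    degenerate: bool


def node_chi_square(stats: NodeStats) -> ChiSquareResult:
    """Pearson chi-square (1 df, no continuity correction) on the node's
    2x2 arm-by-outcome table; a zero margin returns p=1 with the degenerate
    flag set."""
    a, b = stats.s_t, stats.n_t - stats.s_t
    c, d = stats.s_c, stats.n_c - stats.s_c
    n = a + b + c + d
    margins = [a + b, c + d, a + c, b + d]
    if n == 0 or min(margins) == 0:
        return ChiSquareResult(0.0, 1.0, True)
    chi2 = n * (a * d - b * c) ** 2 / np.prod([float(m) for m in margins])
    return ChiSquareResult(float(chi2), float(sps.chi2.sf(chi2, df=1)), False)


def extract_rules(forest: UpliftForest, alpha: float = 0.05,
                  reference: TrialDataset = None) -> list:
    """Flatten the forest into significant candidate rules.

    Every non-root node of every tree contributes its root-to-node
    conjunction; rules whose node chi-square has p < alpha are kept,
    conditions on the same feature are merged, and exact duplicates are
    collapsed keeping the first occurrence. Supports are computed on the
    reference dataset when given.
    """
    rules = []
    seen = {}
    for ti, tree in enumerate(forest.trees):
        for node, path in tree.walk():
            if not path:
                continue  # root
            res = node_chi_square(node.stats)
            if res.degenerate or not (res.p_value < alpha):
                continue
            merged = merge_conditions(path, forest.schema)
            rule = Rule(conditions=merged, tree_index=ti, node_id=node.node_id,
                        depth=node.depth, statistic=res.statistic,
                        p_value=res.p_value)
            k = rule.key()
            if k in seen:
                continue
            seen[k] = rule
            rules.append(rule)
    if reference is not None:
        for rule in rules:
            member = rule.evaluate(reference)
            rule.support_count = int(member.sum())
            rule.support_frac = float(member.mean())
    return rules


def rule_matrix(rules: list, X) -> tuple:
    """Binary indicator matrix (n x M) and the column-mean support vector."""
    if isinstance(X, TrialDataset):
        X = X.X
    n = len(X)
    if not rules:
        return np.zeros((n, 0)), np.zeros(0)
    R = np.column_stack([rule.evaluate(X).astype(float) for rule in rules])
    return R, R.mean(axis=0)


# ---------------------------------------------------------------------------
# sparse linear model on the forest's effect estimates


def linear_design(X: pd.DataFrame, schema) -> pd.DataFrame:
    """Numeric design of the raw baseline features.

    Continuous and binary covariates enter as-is; categorical covariates are
    expanded into one indicator per level.
    """
    cols = {}
    for spec in schema.covariates:
        if spec.kind == "categorical":
            for lv in spec.levels:
                cols[f"{spec.name}={lv}"] = (X[spec.name] == lv).astype(float)
        else:
            cols[spec.name] = X[spec.name].astype(float)
    return pd.DataFrame(cols, index=X.index)


@dataclass
class RuleLinearModel:
    """L1-penalized linear model of tau-hat on rule indicators + raw features."""

    rules: list
    rule_coefs: np.ndarray        # a_m, on the 0/1 rule-indicator scale
    feature_names: list
    feature_coefs: np.ndarray     # b_d, on the original feature scale
    intercept: float              # c, on the original feature scale
    lam: float
    rule_supports: np.ndarray
    feature_sds: np.ndarray       # standardization scale used in the penalty
    feature_col_sds: np.ndarray = None  # actual column SDs, for importance
    rule_importances: np.ndarray = None
    feature_importances: np.ndarray = None

    def __post_init__(self):
        if self.feature_col_sds is None:
            self.feature_col_sds = np.asarray(self.feature_sds, dtype=float)

    def predict(self, R: np.ndarray, X_linear: pd.DataFrame) -> np.ndarray:
        return (self.intercept + R @ self.rule_coefs
                + X_linear[self.feature_names].to_numpy() @ self.feature_coefs)

    def objective(self, tau_hat, R, X_linear) -> float:
        resid = tau_hat - self.predict(R, X_linear)
        # penalty applies on the standardized-feature scale used in fitting
        pen = np.abs(self.rule_coefs).sum() + np.abs(
            self.feature_coefs * self.feature_sds).sum()
        return float(resid @ resid + self.lam * pen)


def fit_rule_model(tau_hat: np.ndarray, R: np.ndarray,
                   X_linear: pd.DataFrame, lam: float,
                   rules: list = None) -> RuleLinearModel:
    """Minimize  sum (tau_hat - [R a + X b + c])^2 + lam * (|a|_1 + |b|_1).

    Columns of ``X_linear`` with more than two distinct values are z-scored
    before fitting (the penalty acts on the standardized coefficients);
    reported coefficients are back-transformed to the original feature scale.
    The intercept is never penalized. ``lam = 0`` reduces to least squares.
    """
    if lam < 0:
        raise UpliftRulesError(f"penalty must be nonnegative, got {lam}")
    tau_hat = np.asarray(tau_hat, dtype=float)
    n = len(tau_hat)
    X_linear = X_linear.copy()
    feature_names = list(X_linear.columns)
    Z = X_linear.to_numpy(dtype=float)
    sds = np.ones(Z.shape[1])
    means = np.zeros(Z.shape[1])
    for j in range(Z.shape[1]):
        col = Z[:, j]
        uniq = np.unique(col)
        if len(uniq) > 2:
            sd = col.std(ddof=0)
            if sd > 0:
                means[j] = col.mean()
                sds[j] = sd
    Zs = (Z - means) / sds
    D = np.hstack([R, Zs]) if R.size or Zs.size else np.zeros((n, 0))
    M = R.shape[1]

    if D.shape[1] == 0:
        coefs = np.zeros(0)
        intercept = float(tau_hat.mean())
    elif lam == 0:
        fit = LinearRegression().fit(D, tau_hat)
        coefs, intercept = fit.coef_, float(fit.intercept_)
    else:
        # sklearn's Lasso minimizes (1/2n)||y - Dw - c||^2 + alpha ||w||_1,
        # so alpha = lam / (2n) matches the stated objective exactly.
        fit = Lasso(alpha=lam / (2.0 * n), fit_intercept=True,
                    max_iter=20000, tol=1e-8).fit(D, tau_hat)
        coefs, intercept = fit.coef_, float(fit.intercept_)

    a = coefs[:M]
    b_std = coefs[M:]
    b = b_std / sds
    intercept = intercept - float(b_std @ (means / sds))
    supports = R.mean(axis=0) if M else np.zeros(0)
    return RuleLinearModel(
        rules=list(rules) if rules is not None else [None] * M,
        rule_coefs=np.asarray(a, dtype=float), feature_names=feature_names,
        feature_coefs=np.asarray(b, dtype=float), intercept=intercept,
        lam=lam, rule_supports=supports, feature_sds=sds,
        feature_col_sds=Z.std(axis=0, ddof=0) if Z.size else np.zeros(Z.shape[1]))


def rule_importance(coef: float, support: float) -> float:
    """RuleFit-style rule importance: |coefficient| * sqrt(s * (1 - s))."""
    return abs(coef) * float(np.sqrt(support * (1.0 - support)))


def importance_scores(model: RuleLinearModel, supports: np.ndarray = None,
                      X_linear: pd.DataFrame = None) -> tuple:
    """Importance of every rule and raw feature in a fitted model.

    Rule importance is |a_m| sqrt(s_m (1 - s_m)); a linear term's importance
    is |b_d| * SD(X_d), so both live on the scale of the effect estimate.
    Results are stored on the model and returned.
    """
    s = model.rule_supports if supports is None else np.asarray(supports)
    I_m = np.array([rule_importance(a, sm)
                    for a, sm in zip(model.rule_coefs, s)])
    if X_linear is not None:
        sd = X_linear[model.feature_names].to_numpy(dtype=float).std(axis=0, ddof=0)
    else:
        sd = model.feature_col_sds
    I_d = np.abs(model.feature_coefs) * sd
    model.rule_importances = I_m
    model.feature_importances = I_d
    return I_m, I_d


# ---------------------------------------------------------------------------
# ranking and reporting


@dataclass
class SubgroupReport:
    """One ranked row of the subgroup table."""

    rule: str
    coefficient: float
    support_count: int
    support_frac: float
    importance: float
    ate: Optional[float] = None
    ate_se: Optional[float] = None
    n_in: Optional[int] = None
    dataset: str = ""
    rule_obj: Rule = None

    def row(self) -> dict:
        return {
            "rule": self.rule, "coefficient": self.coefficient,
            "support_count": self.support_count,
            "support_pct": 100.0 * self.support_frac,
            "importance": self.importance,
            "ate": self.ate, "ate_se": self.ate_se, "n_in": self.n_in,
        }


THRESHOLD_KINDS = ("nonzero", "coefficient", "importance")


def rank_and_select(model: RuleLinearModel, threshold: str = "nonzero",
                    value: float = 0.0, top_k: int = 5,
                    eval_ds: TrialDataset = None) -> tuple:
    """Partition rules by coefficient sign, filter, rank by importance.

    ``threshold`` is one of "nonzero" (a_m != 0), "coefficient" (|a_m| >
    value) or "importance" (I_m > value). Returns (favorable, unfavorable)
    lists of :class:`SubgroupReport`, each sorted by importance descending
    and truncated to ``top_k``; when ``eval_ds`` is given each report carries
    the within-subgroup ATE on that dataset.
    """
    if threshold not in THRESHOLD_KINDS:
        raise ConfigError(f"unknown threshold kind {threshold!r}; "
                          f"expected one of {THRESHOLD_KINDS}")
    if model.rule_importances is None:
        importance_scores(model)
    favorable, unfavorable = [], []
    for rule, a, s_frac, imp in zip(model.rules, model.rule_coefs,
                                    model.rule_supports,
                                    model.rule_importances):
        if a == 0:
            continue
        if threshold == "coefficient" and not (abs(a) > value):
            continue
        if threshold == "importance" and not (imp > value):
            continue
        rep = SubgroupReport(
            rule=rule.describe() if rule is not None else "?",
            coefficient=float(a),
            support_count=rule.support_count if rule is not None else 0,
            support_frac=float(s_frac), importance=float(imp), rule_obj=rule)
        if eval_ds is not None and rule is not None:
            try:
                rep.ate, rep.ate_se, rep.n_in = subgroup_ate(eval_ds, rule)
                rep.dataset = "eval"
            except ValidationError:
                pass  # subgroup missing an arm on the eval set
        (favorable if a > 0 else unfavorable).append(rep)
    favorable.sort(key=lambda r: -r.importance)
    unfavorable.sort(key=lambda r: -r.importance)
    return favorable[:top_k], unfavorable[:top_k]


def subgroup_ate(ds: TrialDataset, rule: Rule) -> tuple:
    """Average treatment effect within a rule's subgroup.

    Returns (ate, se, n_in) where ate = mean(Y | T=1, in) - mean(Y | T=0, in)
    and se is the binomial standard error of the difference.
    """
    member = rule.evaluate(ds)
    t_in = ds.t[member]
    y_in = ds.y[member]
    n1 = int(t_in.sum())
    n0 = int((1 - t_in).sum())
    if n1 == 0 or n0 == 0:
        raise ValidationError(
            f"subgroup {rule.describe()!r} lacks a treatment arm "
            f"(treated={n1}, control={n0})")
    p1 = float(y_in[t_in == 1].mean())
    p0 = float(y_in[t_in == 0].mean())
    se = float(np.sqrt(p1 * (1 - p1) / n1 + p0 * (1 - p0) / n0))
    return p1 - p0, se, int(member.sum())
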