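"""Model / results layer tying the forest and the rule ensemble together.

:class:`RuleUpliftModel` is constructed from a :class:`~upliftrules.data.TrialDataset`
(or a DataFrame plus schema) and fixed hyperparameters; :meth:`RuleUpliftModel.fit`
grows the bootstrapped uplift forest, extracts and screens candidate rules,
chooses the L1 penalty by cross-validation when not given, fits the sparse
linear ranking model on the forest's out-of-bag effect estimates, and returns
a :class:`RuleUpliftResults` carrying estimates, diagnostics and a
``summary()`` table of the ranked subgroups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import TrialDataset
from .errors import ConfigError
from .evaluate import qini_curve, stratified_folds
from .forest import UpliftForest, grow_forest
from .rules import (RuleLinearModel, extract_rules, fit_rule_model,
                    importance_scores, linear_design, rank_and_select,
                    rule_matrix, subgroup_ate)
from .tree import TreeGrowthParams

__all__ = ["RuleUpliftModel", "RuleUpliftResults"]

DEFAULT_LAMBDA_GRID = (0.05, 0.2, 1.0, 5.0, 20.0)


class RuleUpliftModel:
    """Interpretable uplift model: KL forest + chi-square-screened rule lasso.

    Parameters
    ----------
    data : TrialDataset
        Training cohort (may include matched historical/synthetic rows).
    n_trees : int
        Bootstrap ensemble size.
    tree_params : TreeGrowthParams, optional
        Growth limits; defaults cap depth at 3 so rules keep at most
        two-feature interactions plus one refinement.
    alpha : float
        Chi-square significance level for rule screening.
    lam : float, optional
        L1 penalty of the rule ranking model. ``None`` selects it by
        ``cv_folds``-fold cross-validated pseudo-label MSE over ``lam_grid``.
    use_oob : bool
        Regress on out-of-bag forest estimates (default) rather than in-bag.
    """

    def __init__(self, data: TrialDataset, n_trees: int = 100,
                 tree_params: TreeGrowthParams = None, alpha: float = 0.05,
                 lam: float = None, lam_grid=DEFAULT_LAMBDA_GRID,
                 cv_folds: int = 4, use_oob: bool = True):
        if not (0.0 < alpha < 1.0):
            raise ConfigError(f"alpha must lie in (0,1), got {alpha}")
        self.data = data
        self.n_trees = n_trees
        self.tree_params = tree_params or TreeGrowthParams()
        self.alpha = alpha
        self.lam = lam
        self.lam_grid = tuple(lam_grid)
        self.cv_folds = cv_folds
        self.use_oob = use_oob

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, schema, **kwargs) -> "RuleUpliftModel":
        """Build from a raw table: columns typed and validated per ``schema``."""
        t = df[schema.treatment].to_numpy()
        y = df[schema.outcome].to_numpy()
        X = df[schema.covariate_names].copy()
        source = (df["_source"].to_numpy(dtype=object)
                  if "_source" in df.columns else None)
        ds = TrialDataset(X=X, t=t, y=y, schema=schema, source=source)
        return cls(ds, **kwargs)

    # ------------------------------------------------------------------

    def _select_lambda(self, tau_hat, R, Z, seed) -> float:
        """Pick the L1 penalty by k-fold CV of the pseudo-label regression MSE."""
        rng = np.random.default_rng(np.random.SeedSequence((seed, 4)))
        fold = stratified_folds(self.data.t, self.cv_folds, rng)
        mse = []
        for lam in self.lam_grid:
            errs = []
            for f in range(self.cv_folds):
                tr, va = fold != f, fold == f
                m = fit_rule_model(tau_hat[tr], R[tr], Z.loc[tr], lam)
                pred = m.predict(R[va], Z.loc[va])
                errs.append(float(np.mean((tau_hat[va] - pred) ** 2)))
            mse.append(float(np.mean(errs)))
        return self.lam_grid[int(np.argmin(mse))]

    def fit(self, seed: int = 0) -> "RuleUpliftResults":
        forest = grow_forest(self.data, self.tree_params, n_trees=self.n_trees,
                             seed=seed)
        tau_hat = (forest.predict_oob(self.data) if self.use_oob
                   else forest.predict(self.data))
        rules = extract_rules(forest, alpha=self.alpha, reference=self.data)
        R, supports = rule_matrix(rules, self.data)
        Z = linear_design(self.data.X, self.data.schema)
        lam = self.lam
        if lam is None:
            lam = self._select_lambda(tau_hat, R, Z, seed)
        rule_model = fit_rule_model(tau_hat, R, Z, lam, rules=rules)
        importance_scores(rule_model)
        return RuleUpliftResults(model=self, forest=forest, rules=rules,
                                 rule_model=rule_model, tau_hat=tau_hat,
                                 lam=lam, seed=seed)


@dataclass
class RuleUpliftResults:
    """Fitted forest + ranked rule ensemble."""

    model: RuleUpliftModel
    forest: UpliftForest
    rules: list
    rule_model: RuleLinearModel
    tau_hat: np.ndarray
    lam: float
    seed: int = 0

    # ---- estimates -----------------------------------------------------

    def predict_tau(self, X) -> np.ndarray:
        """Forest treatment-effect estimate for new subjects."""
        return self.forest.predict(X)

    def predict_tau_linear(self, X) -> np.ndarray:
        """Effect estimate from the sparse rule model (the interpretable surrogate)."""
        if isinstance(X, TrialDataset):
            X = X.X
        R, _ = rule_matrix(self.rules, X)
        Z = linear_design(X, self.model.data.schema)
        return self.rule_model.predict(R, Z)

    def qini(self, eval_ds: TrialDataset, use_linear: bool = False):
        """Qini curve of the fitted scores on a (held-out) dataset."""
        scores = (self.predict_tau_linear(eval_ds) if use_linear
                  else self.predict_tau(eval_ds))
        return qini_curve(eval_ds.y, eval_ds.t, scores)

    def subgroups(self, threshold: str = "nonzero", value: float = 0.0,
                  top_k: int = 5, eval_ds: TrialDataset = None):
        """(favorable, unfavorable) ranked subgroup reports."""
        return rank_and_select(self.rule_model, threshold, value, top_k,
                               eval_ds=eval_ds if eval_ds is not None else self.model.data)

    def subgroup_table(self, threshold: str = "nonzero", value: float = 0.0,
                       top_k: int = 5, eval_ds: TrialDataset = None) -> pd.DataFrame:
        fav, unf = self.subgroups(threshold, value, top_k, eval_ds)
        rows = ([dict(direction="favorable", **r.row()) for r in fav]
                + [dict(direction="unfavorable", **r.row()) for r in unf])
        return pd.DataFrame(rows)

    def summary(self, threshold: str = "nonzero", value: float = 0.0,
                top_k: int = 5, eval_ds: TrialDataset = None) -> str:
        """Human-readable account of the fit and the top-ranked subgroups."""
        m = self.rule_model
        nz = int(np.count_nonzero(m.rule_coefs))
        lines = [
            "Rule-ensemble uplift model",
            "=" * 66,
            f"subjects: {self.model.data.n}  "
            f"(treated {self.model.data.n_treated}, "
            f"control {self.model.data.n_control})",
            f"trees: {self.forest.n_trees}  max depth: "
            f"{self.forest.params.max_depth}",
            f"significant candidate rules (p < {self.model.alpha}): "
            f"{len(self.rules)}",
            f"L1 penalty lambda: {self.lam:g}   rules with nonzero "
            f"coefficient: {nz}",
            "",
        ]
        fav, unf = self.subgroups(threshold, value, top_k, eval_ds)
        for title, group in (("Favorable treatment effects", fav),
                             ("Unfavorable treatment effects", unf)):
            lines.append(title)
            lines.append("-" * 66)
            if not group:
                lines.append("  (none selected)")
            for r in group:
                ate = (f"  ATE {r.ate:+.4f} +/- {r.ate_se:.4f} (n={r.n_in})"
                       if r.ate is not None else "")
                lines.append(
                    f"  {r.rule}\n    coef {r.coefficient:+.4f}  support "
                    f"{r.support_count} ({100 * r.support_frac:.2f}%)  "
                    f"importance {r.importance:.4f}{ate}")
            lines.append("")
        return "\n".join(lines)
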