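"""End-to-end orchestration: data -> augmentation -> forest -> rules -> Qini.

A :class:`PipelineConfig` (YAML-loadable) names either input files (trial CSV
+ schema sidecar, optional historical-pool CSV) or a built-in simulation
fixture, plus the augmentation, forest, selection and evaluation settings.
:func:`run_pipeline` executes the stages and writes every artifact (augmented
cohort, forest JSON, rules JSON, subgroup table, balance report, Qini report,
run manifest) into an output directory; :func:`make_experiment` wraps the
same stages as a per-seed callable for repeated experiments.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .augment import (SmoothedBootstrapGenerator, arm_auc, borrow_historical,
                      match_synthetic, smd_report)
from .data import TrialDataset, load_trial_table, save_trial_table
from .errors import ConfigError, UpliftRulesError
from .evaluate import qini_curve, stratified_folds
from .model import RuleUpliftModel
from .schema import FeatureSchema
from .simulate import (confounded_fixture_config, default_fixture_config,
                       null_fixture_config, simulate_observational_pool,
                       simulate_rct)
from .tree import TreeGrowthParams

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "make_experiment",
           "PipelineStageError"]

FIXTURES = {
    "default": default_fixture_config,
    "null": null_fixture_config,
    "confounded": confounded_fixture_config,
}


class PipelineStageError(UpliftRulesError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """All settings of one pipeline run."""

    # data: either a fixture name or file paths
    fixture: str = "confounded"
    rct_path: str = None
    pool_path: str = None
    schema_path: str = None
    test_fraction: float = 0.25

    # augmentation
    augment: bool = True
    use_historical: bool = True
    use_synthetic: bool = True
    caliper_sd: float = 0.2
    n_synthetic_treated: int = 500
    n_synthetic_control: int = 500
    bandwidth_scale: float = 1.0

    # forest
    n_trees: int = 100
    max_depth: int = 3
    min_node_samples: int = 100
    min_treated_samples: int = 25
    k_thresholds: int = 10

    # selection
    alpha: float = 0.05
    lam: float = None            # None -> cross-validated
    cv_folds: int = 4
    threshold: str = "nonzero"
    threshold_value: float = 0.0
    top_k: int = 5

    # evaluation
    n_seeds: int = 30
    seed: int = 0

    def __post_init__(self):
        if self.max_depth < 1:
            raise ConfigError("max_depth must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ConfigError("alpha must lie in (0,1)")
        if self.rct_path is None and self.fixture not in FIXTURES:
            raise ConfigError(f"unknown fixture {self.fixture!r}; "
                              f"choose from {sorted(FIXTURES)} or give rct_path")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def tree_params(self) -> TreeGrowthParams:
        return TreeGrowthParams(max_depth=self.max_depth,
                                min_node_samples=self.min_node_samples,
                                min_treated_samples=self.min_treated_samples,
                                k_thresholds=self.k_thresholds)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


# ---------------------------------------------------------------------------
# stages


def _load_inputs(config: PipelineConfig, seed: int):
    """Return (rct, pool-or-None, ground-truth-or-None)."""
    if config.rct_path is not None:
        if config.schema_path is None:
            raise ConfigError("schema_path is required with rct_path")
        schema = FeatureSchema.from_yaml(config.schema_path)
        rct = load_trial_table(config.rct_path, schema)
        pool = (load_trial_table(config.pool_path, schema)
                if config.pool_path else None)
        return rct, pool, None
    sim = FIXTURES[config.fixture](seed=seed)
    rct, truth = simulate_rct(sim)
    pool = simulate_observational_pool(sim) if config.use_historical else None
    return rct, pool, truth


def _train_test_split(rct: TrialDataset, fraction: float, seed: int):
    if not (0.0 < fraction < 1.0):
        return rct, None
    rng = np.random.default_rng(np.random.SeedSequence((seed, 5)))
    k = max(2, round(1.0 / fraction))
    fold = stratified_folds(rct.t, k, rng)
    return rct.subset(fold != 0), rct.subset(fold == 0)


def _augment(train: TrialDataset, pool, config: PipelineConfig, seed: int):
    cohort = train
    if config.use_historical and pool is not None and pool.n:
        cohort = borrow_historical(cohort, pool, caliper_sd=config.caliper_sd,
                                   seed=seed)
    if config.use_synthetic:
        gen = SmoothedBootstrapGenerator(bandwidth_scale=config.bandwidth_scale)
        synthetic = gen.fit(cohort).sample(config.n_synthetic_treated,
                                           config.n_synthetic_control,
                                           seed=seed)
        cohort = match_synthetic(cohort, synthetic,
                                 caliper_sd=config.caliper_sd, seed=seed)
    return cohort


def _fit(cohort: TrialDataset, config: PipelineConfig, seed: int):
    model = RuleUpliftModel(cohort, n_trees=config.n_trees,
                            tree_params=config.tree_params(),
                            alpha=config.alpha, lam=config.lam,
                            cv_folds=config.cv_folds)
    return model.fit(seed=seed)


# ---------------------------------------------------------------------------
# per-seed experiment


def make_experiment(config: PipelineConfig):
    """Build a (seed) -> metrics-dict callable running the full pipeline.

    Held-out evaluation uses only real trial rows; augmented rows enter
    training only. The returned metrics carry the held-out Qini of the
    forest and of the rule surrogate, and the selected-rule counts under the
    three threshold kinds.
    """

    def experiment(seed: int) -> dict:
        rct, pool, truth = _load_inputs(config, seed)
        train, test = _train_test_split(rct, config.test_fraction, seed)
        cohort = _augment(train, pool, config, seed) if config.augment else train
        results = _fit(cohort, config, seed)
        eval_ds = test if test is not None else train
        q_forest = results.qini(eval_ds).coefficient
        q_linear = results.qini(eval_ds, use_linear=True).coefficient
        m = results.rule_model
        out = {
            "qini": q_forest,
            "qini_rule_model": q_linear,
            "rules_significant": len(results.rules),
            "rules_nonzero": int(np.count_nonzero(m.rule_coefs)),
            "rules_coefficient": int((np.abs(m.rule_coefs) > 0.005).sum()),
            "rules_importance": int((m.rule_importances > 0.002).sum()),
            "lambda": results.lam,
        }
        if truth is not None and truth.membership.shape[1]:
            from .simulate import recovery_score
            fav, _ = results.subgroups(top_k=1)
            out["recovery_top_favorable"] = recovery_score(
                [r.rule_obj for r in fav if r.rule_obj is not None],
                truth, rct)
        return out

    return experiment


# ---------------------------------------------------------------------------
# artifact-writing pipeline


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Execute every stage and write artifacts; returns the output directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except UpliftRulesError:
            raise
        except Exception as exc:
            raise PipelineStageError(name, exc) from exc

    rct, pool, truth = stage("load", _load_inputs, config, seed)
    train, test = stage("split", _train_test_split, rct, config.test_fraction, seed)

    balance = {"n_train": train.n}
    if config.augment:
        naive = train.concat(pool) if pool is not None and pool.n else train
        balance["before"] = {"mean_smd": smd_report(naive).mean_abs,
                             "arm_auc": arm_auc(naive, seed=seed),
                             "n": naive.n}
        cohort = stage("augment", _augment, train, pool, config, seed)
        balance["after"] = {"mean_smd": smd_report(cohort).mean_abs,
                            "arm_auc": arm_auc(cohort, seed=seed),
                            "n": cohort.n}
    else:
        cohort = train
    save_trial_table(cohort, out / "cohort.csv")
    with open(out / "balance.json", "w") as fh:
        json.dump(balance, fh, indent=1)

    results = stage("fit", _fit, cohort, config, seed)
    results.forest.to_json(out / "forest.json")
    with open(out / "rules.json", "w") as fh:
        json.dump([dict(r.to_dict(),
                        coefficient=float(a), importance=float(i))
                   for r, a, i in zip(results.rules,
                                      results.rule_model.rule_coefs,
                                      results.rule_model.rule_importances)],
                  fh, indent=1)

    eval_ds = test if test is not None else train
    table = results.subgroup_table(config.threshold, config.threshold_value,
                                   config.top_k, eval_ds=eval_ds)
    table.to_csv(out / "subgroups.csv", index=False)
    (out / "summary.txt").write_text(
        results.summary(config.threshold, config.threshold_value,
                        config.top_k, eval_ds=eval_ds))

    q = stage("evaluate", results.qini, eval_ds)
    with open(out / "qini.json", "w") as fh:
        json.dump({"coefficient": q.coefficient,
                   "fractions": q.fractions.tolist(),
                   "curve": q.curve.tolist(),
                   "baseline_end": q.baseline_end}, fh, indent=1)

    manifest = {"config": asdict(config), "config_digest": config.digest(),
                "seed": seed, "version": __version__}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    logger.info("pipeline artifacts written to %s", out)
    return out
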