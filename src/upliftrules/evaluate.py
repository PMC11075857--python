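"""Qini-based evaluation of uplift rankings and multi-seed experiments.

The Qini curve plots, against the fraction of the population targeted in
descending order of predicted effect, the cumulative incremental gain

    g = sum(Y_treated) - sum(Y_control) * (n_treated / n_control)

accumulated over the targeted prefix, normalized by the total subject count.
The Qini coefficient is the trapezoidal area between this curve and the
random-targeting chord from (0, 0) to (1, g_total / n); tied scores are
grouped into a single block so the coefficient is invariant to the order
within ties and to strictly monotone transformations of the scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .data import TrialDataset
from .errors import ConfigError, ValidationError

logger = logging.getLogger(__name__)

__all__ = ["QiniResult", "ExperimentSummary", "qini_curve", "qini_coefficient",
           "cross_validate", "repeat_experiment", "stratified_folds"]


@dataclass
class QiniResult:
    """Incremental-gain curve and its area-based coefficient."""

    fractions: np.ndarray   # includes the leading 0
    curve: np.ndarray       # normalized incremental gain, starts at 0
    baseline_end: float     # random-targeting gain at fraction 1
    coefficient: float

    def baseline(self) -> np.ndarray:
        return self.fractions * self.baseline_end


def qini_curve(y, t, scores) -> QiniResult:
    """Qini curve and coefficient of an uplift score.

    Subjects are sorted by score descending with ties grouped as one block.
    At each prefix the incremental gain is sum(y_t) - sum(y_c) * (n_t/n_c)
    over the prefix (or plain sum(y_t) while the prefix has no controls),
    normalized by the total number of subjects. The coefficient is the
    trapezoidal area between the curve and the chord to its endpoint.
    """
    y = np.asarray(y, dtype=float)
    t = np.asarray(t, dtype=float)
    s = np.asarray(scores, dtype=float)
    n = len(y)
    if n == 0 or t.min() == t.max():
        raise ValidationError("Qini evaluation requires both arms present")

    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    t_sorted = t[order]
    # block boundaries: last position of each distinct score value
    boundary = np.flatnonzero(np.diff(s_sorted) != 0)
    ends = np.append(boundary, n - 1)

    cum_yt = np.cumsum(y_sorted * t_sorted)[ends]
    cum_yc = np.cumsum(y_sorted * (1 - t_sorted))[ends]
    cum_nt = np.cumsum(t_sorted)[ends]
    cum_nc = np.cumsum(1 - t_sorted)[ends]

    with np.errstate(divide="ignore", invalid="ignore"):
        g = np.where(cum_nc > 0, cum_yt - cum_yc * (cum_nt / cum_nc), cum_yt)
    fractions = np.concatenate([[0.0], (ends + 1) / n])
    curve = np.concatenate([[0.0], g / n])

    auc = float(np.trapezoid(curve, fractions))
    baseline_end = float(curve[-1])
    coefficient = auc - baseline_end / 2.0
    return QiniResult(fractions=fractions, curve=curve,
                      baseline_end=baseline_end, coefficient=coefficient)


def qini_coefficient(y, t, scores) -> float:
    return qini_curve(y, t, scores).coefficient


# ---------------------------------------------------------------------------
# cross-validation


def stratified_folds(t: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Fold labels 0..k-1, stratified by arm."""
    t = np.asarray(t)
    fold = np.empty(len(t), dtype=int)
    for arm in (0, 1):
        idx = np.flatnonzero(t == arm)
        rng.shuffle(idx)
        fold[idx] = np.arange(len(idx)) % k
    return fold


def cross_validate(ds: TrialDataset, param_grid: list, k: int = 4,
                   metric=None, seed: int = 0, max_retries: int = 10):
    """Pick the best hyperparameters by k-fold cross-validation.

    ``param_grid`` is an ordered list of parameter dicts; ``metric`` is a
    callable (params, train_ds, val_ds) -> float to be maximized, defaulting
    to the validation Qini of a forest grown with the given parameters.
    Folds are stratified by arm; a fold that still ends up single-arm
    triggers refolding with a new stream (up to ``max_retries``). Ties take
    the first grid entry.
    """
    if k < 2:
        raise ConfigError("cross-validation needs k >= 2")
    if not param_grid:
        raise ConfigError("empty parameter grid")
    if metric is None:
        metric = _forest_qini_metric

    rng = np.random.default_rng(np.random.SeedSequence((seed, 3)))
    for attempt in range(max_retries):
        fold = stratified_folds(ds.t, k, rng)
        ok = all(len(np.unique(ds.t[fold == f])) == 2 for f in range(k))
        if ok:
            break
    else:
        raise ValidationError(f"could not build {k} two-arm folds in "
                              f"{max_retries} attempts")

    fold_scores = []
    for params in param_grid:
        scores = []
        for f in range(k):
            train = ds.subset(fold != f)
            val = ds.subset(fold == f)
            scores.append(float(metric(params, train, val)))
        fold_scores.append(scores)
    means = [float(np.mean(s)) for s in fold_scores]
    best = int(np.argmax(means))  # argmax takes the first maximizer
    return param_grid[best], {"means": means, "folds": fold_scores,
                              "best_index": best}


def _forest_qini_metric(params: dict, train: TrialDataset, val: TrialDataset) -> float:
    from .forest import grow_forest
    from .tree import TreeGrowthParams
    p = dict(params)
    n_trees = p.pop("n_trees", 100)
    seed = p.pop("seed", 0)
    forest = grow_forest(train, TreeGrowthParams(**p), n_trees=n_trees, seed=seed)
    return qini_coefficient(val.y, val.t, forest.predict(val))


# ---------------------------------------------------------------------------
# repeated experiments


@dataclass
class ExperimentSummary:
    """Multi-seed pipeline results: Qini values and selected-rule counts."""

    seeds: list
    qini: list
    mean: float
    sd: float
    rule_counts: dict         # threshold kind -> list of counts per seed
    failures: list = field(default_factory=list)
    single_seed: bool = False # SD is 0 by construction, not evidence

    def as_dict(self) -> dict:
        return {"seeds": list(self.seeds), "qini": list(self.qini),
                "mean": self.mean, "sd": self.sd,
                "rule_counts": {k: list(v) for k, v in self.rule_counts.items()},
                "failures": list(self.failures),
                "single_seed": self.single_seed}


def repeat_experiment(experiment, n_seeds: int = 30, seeds=None) -> ExperimentSummary:
    """Run one pipeline experiment across seeds and summarize.

    ``experiment`` is a callable (seed) -> dict with a "qini" entry and
    optional "rules_nonzero" / "rules_coefficient" / "rules_importance"
    counts (see :func:`upliftrules.pipeline.make_experiment`). A failing seed
    is recorded and skipped.
    """
    if seeds is None:
        seeds = list(range(n_seeds))
    seeds = list(seeds)
    qini, failures = [], []
    counts = {"nonzero": [], "coefficient": [], "importance": []}
    for seed in seeds:
        try:
            res = experiment(seed)
        except Exception as exc:  # record and continue per contract
            logger.warning("experiment seed %s failed: %s", seed, exc)
            failures.append({"seed": seed, "error": str(exc)})
            continue
        qini.append(float(res["qini"]))
        for kind in counts:
            key = f"rules_{kind}"
            if key in res:
                counts[kind].append(int(res[key]))
    mean = float(np.mean(qini)) if qini else float("nan")
    sd = float(np.std(qini, ddof=1)) if len(qini) > 1 else 0.0
    return ExperimentSummary(seeds=seeds, qini=qini, mean=mean, sd=sd,
                             rule_counts={k: v for k, v in counts.items() if v},
                             failures=failures, single_seed=len(qini) == 1)
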