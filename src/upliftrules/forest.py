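"""Bootstrapped ensembles of KL uplift trees.

Each tree is grown on an n-out-of-n bootstrap resample drawn within arm
(stratified), so every resample keeps the trial's arm ratio. The forest's
per-subject treatment-effect estimate is the weighted mean over trees of the
leaf risk difference the subject falls into; tree weights are uniform by
default. Out-of-bag estimates average only the trees whose bootstrap missed
the subject, which decouples the rule-selection regression target from each
tree's own training rows.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import TrialDataset
from .errors import ValidationError
from .tree import (FeatureMatrix, TreeGrowthParams, UpliftTreeNode,
                   global_threshold_grid, grow_tree)

logger = logging.getLogger(__name__)

__all__ = ["UpliftForest", "grow_forest", "predict_tau"]


@dataclass
class UpliftForest:
    """Ensemble of uplift trees with uniform (or supplied) weights."""

    trees: list
    params: TreeGrowthParams
    schema: object  # FeatureSchema of the training data
    weights: np.ndarray = None
    seed: int = 0
    n_trees: int = None
    bootstrap_indices: list = None  # per-tree training row positions
    n_train: int = None

    def __post_init__(self):
        if self.n_trees is None:
            self.n_trees = len(self.trees)
        if self.weights is None:
            self.weights = np.full(len(self.trees), 1.0 / len(self.trees))
        self.weights = np.asarray(self.weights, dtype=float)
        if (self.weights < 0).any():
            raise ValidationError("tree weights must be nonnegative")
        s = self.weights.sum()
        if not np.isclose(s, 1.0):
            self.weights = self.weights / s
        self._warned_unseen = False

    # ---- prediction ------------------------------------------------------

    def _encode(self, X) -> np.ndarray:
        if isinstance(X, TrialDataset):
            X = X.X
        return FeatureMatrix.from_frame(X, self.schema)

    def _feature_pos(self):
        return {s.name: i for i, s in enumerate(self.schema.covariates)}

    def _tree_leaf_tau(self, tree: UpliftTreeNode, V: np.ndarray, pos: dict) -> np.ndarray:
        """Vector of leaf risk differences for every row of encoded matrix V."""
        out = np.empty(len(V))
        stack = [(tree, np.arange(len(V)))]
        while stack:
            node, idx = stack.pop()
            if node.is_leaf:
                out[idx] = node.tau
                continue
            cond = node.split
            j = pos[cond.feature]
            col = V[idx, j]
            if cond.comparator == ">=":
                right = col >= cond.threshold
            else:  # "in"
                levels = list(self.schema[cond.feature].levels)
                codes = [levels.index(lv) for lv in cond.levels]
                right = np.isin(col, codes)
            unseen = np.isnan(col)
            if unseen.any():
                if not self._warned_unseen:
                    logger.warning(
                        "unseen or missing values on %r at prediction; routing to "
                        "the larger child", cond.feature)
                    self._warned_unseen = True
                to_right = node.right.stats.n >= node.left.stats.n
                right = np.where(unseen, to_right, right)
            stack.append((node.right, idx[right]))
            stack.append((node.left, idx[~right]))
        return out

    def predict(self, X) -> np.ndarray:
        """Weighted-average treatment-effect estimate for each row of X."""
        V = self._encode(X)
        pos = self._feature_pos()
        acc = np.zeros(len(V))
        for w, tree in zip(self.weights, self.trees):
            acc += w * self._tree_leaf_tau(tree, V, pos)
        return acc

    def predict_oob(self, ds: TrialDataset) -> np.ndarray:
        """Out-of-bag estimate on the training data.

        Each subject is averaged over trees whose bootstrap excluded it; rows
        in every bag fall back to the full-forest average.
        """
        if self.bootstrap_indices is None:
            return self.predict(ds)
        V = self._encode(ds)
        pos = self._feature_pos()
        acc = np.zeros(ds.n)
        wsum = np.zeros(ds.n)
        full = np.zeros(ds.n)
        for w, tree, bag in zip(self.weights, self.trees, self.bootstrap_indices):
            leaf = self._tree_leaf_tau(tree, V, pos)
            full += w * leaf
            oob = np.ones(ds.n, dtype=bool)
            oob[np.asarray(bag)] = False
            acc[oob] += w * leaf[oob]
            wsum[oob] += w
        out = np.where(wsum > 0, acc / np.where(wsum > 0, wsum, 1.0), full)
        return out

    # ---- serialization ---------------------------------------------------

    def to_json(self, path=None):
        d = {
            "params": {
                "max_depth": self.params.max_depth,
                "min_node_samples": self.params.min_node_samples,
                "min_treated_samples": self.params.min_treated_samples,
                "k_thresholds": self.params.k_thresholds,
                "threshold_scope": self.params.threshold_scope,
            },
            "seed": self.seed,
            "n_train": self.n_train,
            "weights": self.weights.tolist(),
            "schema": self.schema.to_dict(),
            "trees": [t.to_dict() for t in self.trees],
            "bootstrap_indices": (
                [list(map(int, b)) for b in self.bootstrap_indices]
                if self.bootstrap_indices is not None else None),
        }
        if path is None:
            return json.dumps(d)
        with open(path, "w") as fh:
            json.dump(d, fh)

    @classmethod
    def from_json(cls, src) -> "UpliftForest":
        from .schema import FeatureSchema
        if isinstance(src, (str, bytes)) and str(src).lstrip().startswith("{"):
            d = json.loads(src)
        else:
            with open(src) as fh:
                d = json.load(fh)
        return cls(
            trees=[UpliftTreeNode.from_dict(t) for t in d["trees"]],
            params=TreeGrowthParams(**d["params"]),
            schema=FeatureSchema.from_dict(d["schema"]),
            weights=np.asarray(d["weights"]),
            seed=d["seed"],
            n_train=d.get("n_train"),
            bootstrap_indices=(
                [np.asarray(b) for b in d["bootstrap_indices"]]
                if d.get("bootstrap_indices") is not None else None),
        )


def _stratified_bootstrap(t: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """n-out-of-n bootstrap drawn separately within each arm."""
    treated = np.flatnonzero(t == 1)
    control = np.flatnonzero(t == 0)
    idx = np.concatenate([
        rng.choice(treated, size=len(treated), replace=True),
        rng.choice(control, size=len(control), replace=True),
    ])
    return np.sort(idx)


def grow_forest(ds: TrialDataset, params: TreeGrowthParams = None,
                n_trees: int = 100, seed: int = 0,
                bootstrap: bool = True) -> UpliftForest:
    """Grow a bootstrapped uplift forest.

    Per-tree random streams are spawned deterministically from the master
    seed, so the same (data, params, seed) triple regrows the same forest.
    With ``bootstrap=False`` every tree sees the full sample (useful only for
    testing: all trees are then identical).
    """
    params = params or TreeGrowthParams()
    if ds.n_treated == 0 or ds.n_control == 0:
        raise ValidationError("forest training data must contain both arms")
    fm = FeatureMatrix(ds)
    grids = (global_threshold_grid(fm, params.k_thresholds)
             if params.threshold_scope == "global" else None)
    seq = np.random.SeedSequence(seed)
    children = seq.spawn(n_trees)
    trees = []
    bags = []
    for child in children:
        rng = np.random.default_rng(child)
        idx = _stratified_bootstrap(ds.t, rng) if bootstrap else np.arange(ds.n)
        trees.append(grow_tree(ds, params, indices=idx, _fm=fm, grids=grids))
        bags.append(idx)
    return UpliftForest(trees=trees, params=params, schema=ds.schema,
                        seed=seed, n_train=ds.n,
                        bootstrap_indices=bags if bootstrap else None)


def predict_tau(forest: UpliftForest, X) -> np.ndarray:
    """Functional alias for :meth:`UpliftForest.predict`."""
    return forest.predict(X)
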