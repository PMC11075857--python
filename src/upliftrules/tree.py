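"""KL-divergence uplift trees.

Each tree recursively partitions the covariate space to maximize the gain in
Kullback-Leibler divergence between the treatment-arm and control-arm outcome
distributions. For binary outcomes the arm distributions are Bernoulli, so
the divergence at a node is the binary KL between the (smoothed) arm success
rates. A split's gain is the sample-weighted child divergence minus the
parent divergence; growth stops at a depth cap, at minimum node / treated
sample counts, or when no candidate split has positive gain. Leaves carry the
unsmoothed risk difference p_t - p_c as the local treatment-effect estimate.

Rates entering the KL are Jeffreys-smoothed, p = (s + 1/2)/(n + 1), which
keeps the divergence finite when an arm has no successes or no failures
without materially shifting rates in large nodes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .data import TrialDataset
from .errors import UpliftRulesError, ValidationError

__all__ = [
    "NodeStats", "SplitCondition", "UpliftTreeNode", "TreeGrowthParams",
    "binary_kl", "split_gain", "candidate_splits", "find_best_split",
    "grow_tree", "FeatureMatrix", "global_threshold_grid",
]


# ---------------------------------------------------------------------------
# numeric design used by the growth loop


class FeatureMatrix:
    """Numeric view of a dataset's covariates for fast tree growth.

    Continuous and binary features are used as floats; categorical features
    are mapped to integer level codes (the schema's level order).
    """

    def __init__(self, ds: TrialDataset):
        cov = ds.schema.covariates
        self.names = [s.name for s in cov]
        self.kinds = [s.kind for s in cov]
        self.levels = [list(s.levels) for s in cov]
        cols = []
        for spec in cov:
            v = ds.X[spec.name]
            if spec.kind == "categorical":
                code = {lv: i for i, lv in enumerate(spec.levels)}
                cols.append(v.map(code).to_numpy(dtype=float))
            else:
                cols.append(v.to_numpy(dtype=float))
        self.values = np.column_stack(cols) if cols else np.empty((ds.n, 0))
        self.t = ds.t
        self.y = ds.y

    @classmethod
    def from_frame(cls, X: pd.DataFrame, schema) -> np.ndarray:
        """Encode a covariate frame with the training schema (no arm columns)."""
        cols = []
        for spec in schema.covariates:
            v = X[spec.name]
            if spec.kind == "categorical":
                code = {lv: i for i, lv in enumerate(spec.levels)}
                cols.append(v.map(code).to_numpy(dtype=float))  # unseen -> NaN
            else:
                cols.append(v.to_numpy(dtype=float))
        return np.column_stack(cols) if cols else np.empty((len(X), 0))


# ---------------------------------------------------------------------------
# node statistics and divergence


@dataclass(frozen=True)
class NodeStats:
    """Per-arm sample and success counts of one node."""

    n_t: int
    n_c: int
    s_t: int
    s_c: int

    def __post_init__(self):
        if not (0 <= self.s_t <= self.n_t and 0 <= self.s_c <= self.n_c):
            raise ValidationError("success counts must satisfy 0 <= s <= n per arm")

    @property
    def n(self) -> int:
        return self.n_t + self.n_c

    @property
    def p_t(self) -> float:
        """Jeffreys-smoothed treated success rate, in (0,1)."""
        return (self.s_t + 0.5) / (self.n_t + 1.0)

    @property
    def p_c(self) -> float:
        """Jeffreys-smoothed control success rate, in (0,1)."""
        return (self.s_c + 0.5) / (self.n_c + 1.0)

    @property
    def tau(self) -> float:
        """Unsmoothed risk difference; NaN when an arm is empty."""
        if self.n_t == 0 or self.n_c == 0:
            return float("nan")
        return self.s_t / self.n_t - self.s_c / self.n_c

    def divergence(self) -> float:
        return binary_kl(self.p_t, self.p_c)

    def __add__(self, other: "NodeStats") -> "NodeStats":
        return NodeStats(self.n_t + other.n_t, self.n_c + other.n_c,
                         self.s_t + other.s_t, self.s_c + other.s_c)


def binary_kl(p: float, q: float) -> float:
    """KL divergence between Bernoulli(p) and Bernoulli(q), natural log.

    Defined for p, q strictly inside (0,1); callers smooth empirical rates
    first. Nonnegative, zero iff p == q, and asymmetric in its arguments.
    """
    if not (0.0 < p < 1.0 and 0.0 < q < 1.0):
        raise UpliftRulesError(f"binary_kl requires rates in (0,1); got p={p}, q={q}")
    return p * math.log(p / q) + (1.0 - p) * math.log((1.0 - p) / (1.0 - q))


def split_gain(parent: NodeStats, left: NodeStats, right: NodeStats):
    """KL gain of a candidate split; ``None`` when a child misses an arm.

    gain = (n_L/n) KL(p_t^L, p_c^L) + (n_R/n) KL(p_t^R, p_c^R) - KL(p_t, p_c),
    with all rates Jeffreys-smoothed and n counting both arms.
    """
    if left + right != parent:
        raise ValidationError("children must partition the parent's samples")
    if min(left.n_t, left.n_c, right.n_t, right.n_c) == 0:
        return None  # candidate rejected, not an error
    n = parent.n
    return (left.n / n) * left.divergence() + (right.n / n) * right.divergence() \
        - parent.divergence()


# ---------------------------------------------------------------------------
# split conditions


@dataclass(frozen=True)
class SplitCondition:
    """One decision boundary on a single feature.

    Continuous: ``feature >= threshold`` (comparator ">=") or its complement
    "<". Categorical: ``feature in levels`` ("in") or "not in".
    """

    feature: str
    comparator: str  # "<", ">=", "in", "not in"
    threshold: Optional[float] = None
    levels: tuple = ()

    def __post_init__(self):
        if self.comparator in ("<", ">="):
            if self.threshold is None or not math.isfinite(self.threshold):
                raise ValidationError(f"threshold must be finite for {self.feature!r}")
        elif self.comparator in ("in", "not in"):
            if not self.levels:
                raise ValidationError(f"level set must be nonempty for {self.feature!r}")
            object.__setattr__(self, "levels", tuple(self.levels))
        else:
            raise ValidationError(f"unknown comparator {self.comparator!r}")

    def negate(self) -> "SplitCondition":
        comp = {"<": ">=", ">=": "<", "in": "not in", "not in": "in"}[self.comparator]
        return SplitCondition(self.feature, comp, self.threshold, self.levels)

    def evaluate(self, X: pd.DataFrame) -> np.ndarray:
        v = X[self.feature]
        if self.comparator == ">=":
            return (v.to_numpy(dtype=float) >= self.threshold)
        if self.comparator == "<":
            return (v.to_numpy(dtype=float) < self.threshold)
        mask = v.isin(list(self.levels)).to_numpy()
        return mask if self.comparator == "in" else ~mask

    def describe(self) -> str:
        if self.comparator in ("<", ">="):
            return f"{self.feature} {self.comparator} {self.threshold:g}"
        joined = " or ".join(str(l) for l in self.levels)
        if self.comparator == "in":
            return f"{self.feature} in {{{joined}}}"
        return f"{self.feature} not in {{{joined}}}"

    def to_dict(self) -> dict:
        d = {"feature": self.feature, "comparator": self.comparator}
        if self.comparator in ("<", ">="):
            d["threshold"] = self.threshold
        else:
            d["levels"] = list(self.levels)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SplitCondition":
        return cls(d["feature"], d["comparator"], d.get("threshold"),
                   tuple(d.get("levels", ())))


def candidate_splits(values: np.ndarray, kind: str, feature: str, k: int = 10,
                     levels=()) -> list:
    """Candidate split conditions for one feature within a node.

    Continuous features: ">= t" at up to ``k`` interior empirical quantiles
    (levels i/(k+1), i = 1..k) of the in-node values, deduplicated and
    restricted to thresholds that actually separate the node. Binary and
    categorical features: one-vs-rest level splits ("in {level}"), with the
    mirrored split dropped for two-level features. Constant features yield no
    candidates.
    """
    values = np.asarray(values, dtype=float)
    finite = values[~np.isnan(values)]
    if finite.size == 0 or np.all(finite == finite[0]):
        return []
    if kind == "continuous":
        qs = np.arange(1, k + 1) / (k + 1.0)
        thresholds = np.unique(np.quantile(finite, qs))
        lo = finite.min()
        out = []
        for th in thresholds:
            if lo < th <= finite.max():  # both sides nonempty under ">= th"
                out.append(SplitCondition(feature, ">=", float(th)))
        return out
    if kind == "binary":
        # both levels present (constant case handled above): single split at 0.5
        return [SplitCondition(feature, ">=", 0.5)]
    # categorical: one-vs-rest per observed level code
    present = np.unique(finite).astype(int)
    if len(present) == 2:
        present = present[-1:]  # complement split is the mirror image
    return [SplitCondition(feature, "in", levels=(levels[int(code)],))
            for code in present]


# ---------------------------------------------------------------------------
# tree structure


@dataclass
class UpliftTreeNode:
    """One node of an uplift tree.

    The right child holds subjects satisfying the split condition
    (">= threshold" / "in levels"); the left child holds the complement.
    """

    stats: NodeStats
    depth: int
    split: Optional[SplitCondition] = None
    left: Optional["UpliftTreeNode"] = None
    right: Optional["UpliftTreeNode"] = None
    node_id: int = 0

    @property
    def is_leaf(self) -> bool:
        return self.split is None

    @property
    def tau(self) -> float:
        return self.stats.tau

    def walk(self):
        """Yield (node, path) pairs in preorder; path is the condition list."""
        stack = [(self, [])]
        while stack:
            node, path = stack.pop()
            yield node, path
            if not node.is_leaf:
                stack.append((node.right, path + [node.split]))
                stack.append((node.left, path + [node.split.negate()]))

    def to_dict(self) -> dict:
        d = {
            "node_id": self.node_id,
            "depth": self.depth,
            "stats": [self.stats.n_t, self.stats.n_c, self.stats.s_t, self.stats.s_c],
        }
        if not self.is_leaf:
            d["split"] = self.split.to_dict()
            d["left"] = self.left.to_dict()
            d["right"] = self.right.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "UpliftTreeNode":
        node = cls(stats=NodeStats(*d["stats"]), depth=d["depth"],
                   node_id=d["node_id"])
        if "split" in d:
            node.split = SplitCondition.from_dict(d["split"])
            node.left = cls.from_dict(d["left"])
            node.right = cls.from_dict(d["right"])
        return node


@dataclass(frozen=True)
class TreeGrowthParams:
    """Growth hyperparameters.

    max_depth caps root-to-leaf splits (3 keeps rules to at most two-feature
    interactions plus a refinement); min_node_samples / min_treated_samples
    are the stopping counts; k_thresholds is the per-feature candidate
    quantile count. threshold_scope picks where candidate thresholds are
    computed: "global" (default) anchors every tree to the k empirical
    quantiles of the full training sample, so identical subgroups recur
    across bootstrap trees and collapse during rule deduplication; "node"
    recomputes quantiles from the in-node values at every split.
    """

    max_depth: int = 3
    min_node_samples: int = 100
    min_treated_samples: int = 25
    k_thresholds: int = 10
    threshold_scope: str = "global"


def global_threshold_grid(fm: "FeatureMatrix", k: int) -> dict:
    """Per-feature candidate thresholds from the full training sample."""
    grid = {}
    qs = np.arange(1, k + 1) / (k + 1.0)
    for j, (name, kind) in enumerate(zip(fm.names, fm.kinds)):
        if kind == "continuous":
            v = fm.values[:, j]
            v = v[~np.isnan(v)]
            if v.size and not np.all(v == v[0]):
                grid[name] = np.unique(np.quantile(v, qs))
    return grid


def _node_stats(t, y, idx) -> NodeStats:
    ti = t[idx]
    yi = y[idx]
    n_t = int(ti.sum())
    return NodeStats(n_t=n_t, n_c=len(idx) - n_t,
                     s_t=int(yi[ti == 1].sum()), s_c=int(yi[ti == 0].sum()))


def find_best_split(fm: FeatureMatrix, idx: np.ndarray, params: TreeGrowthParams,
                    grids: dict = None):
    """Best (condition, gain, right-mask) over all features' candidates.

    Continuous candidates come from ``grids`` (the training-sample quantile
    grid) when given, restricted to thresholds that separate the node;
    otherwise from the in-node quantiles of :func:`candidate_splits`. Ties
    break to the lowest feature index, then the smallest threshold / first
    level, matching candidate enumeration order. Returns ``None`` if no
    candidate attains positive gain.
    """
    parent = _node_stats(fm.t, fm.y, idx)
    t_idx = fm.t[idx]
    y_idx = fm.y[idx]
    best = None  # (gain, feature_pos, cand_pos, condition, mask)
    for j, (name, kind) in enumerate(zip(fm.names, fm.kinds)):
        col = fm.values[idx, j]
        if kind == "continuous" and grids is not None:
            finite = col[~np.isnan(col)]
            if finite.size == 0:
                continue
            lo, hi = finite.min(), finite.max()
            cands = [SplitCondition(name, ">=", float(th))
                     for th in grids.get(name, ()) if lo < th <= hi]
        else:
            cands = candidate_splits(col, kind, name, k=params.k_thresholds,
                                     levels=fm.levels[j])
        for ci, cond in enumerate(cands):
            if cond.comparator == ">=":
                mask = col >= cond.threshold
            else:  # "in" on a single level set, encoded values are codes
                codes = [fm.levels[j].index(lv) for lv in cond.levels]
                mask = np.isin(col, codes)
            n_t_r = int(t_idx[mask].sum())
            s_t_r = int(y_idx[mask & (t_idx == 1)].sum())
            n_r = int(mask.sum())
            s_c_r = int(y_idx[mask & (t_idx == 0)].sum())
            right = NodeStats(n_t_r, n_r - n_t_r, s_t_r, s_c_r)
            left = NodeStats(parent.n_t - right.n_t, parent.n_c - right.n_c,
                             parent.s_t - right.s_t, parent.s_c - right.s_c)
            gain = split_gain(parent, left, right)
            if gain is None or gain <= 0.0:
                continue
            key = (-gain, j, ci)
            if best is None or key < best[0]:
                best = (key, cond, mask)
    if best is None:
        return None
    (neg_gain, _, _), cond, mask = best
    return cond, -neg_gain, mask


def grow_tree(ds: TrialDataset, params: TreeGrowthParams = None,
              indices: np.ndarray = None, _fm: FeatureMatrix = None,
              grids: dict = None) -> UpliftTreeNode:
    """Grow one uplift tree on ``ds`` (optionally a bootstrap index vector).

    The root must contain both arms. Recursion stops when a node falls below
    the minimum sample or minimum treated-sample counts, reaches max_depth,
    or when no candidate split has positive KL gain; a root that already
    violates the stopping rule becomes a single leaf. With the default
    "global" threshold scope, continuous candidates come from the quantile
    grid of the full dataset (not the bootstrap resample).
    """
    params = params or TreeGrowthParams()
    fm = _fm or FeatureMatrix(ds)
    if grids is None and params.threshold_scope == "global":
        grids = global_threshold_grid(fm, params.k_thresholds)
    idx = np.arange(ds.n) if indices is None else np.asarray(indices)
    root_stats = _node_stats(fm.t, fm.y, idx)
    if root_stats.n_t == 0 or root_stats.n_c == 0:
        raise ValidationError("tree root must contain both treatment arms")

    counter = [0]

    def build(node_idx: np.ndarray, depth: int) -> UpliftTreeNode:
        stats = _node_stats(fm.t, fm.y, node_idx)
        node = UpliftTreeNode(stats=stats, depth=depth, node_id=counter[0])
        counter[0] += 1
        if (depth >= params.max_depth
                or stats.n < params.min_node_samples
                or stats.n_t < params.min_treated_samples):
            return node
        found = find_best_split(fm, node_idx, params, grids=grids)
        if found is None:
            return node
        cond, _gain, mask = found
        node.split = cond
        node.left = build(node_idx[~mask], depth + 1)
        node.right = build(node_idx[mask], depth + 1)
        return node

    return build(idx, 0)
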