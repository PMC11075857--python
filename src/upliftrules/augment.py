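"""Cohort augmentation with matched historical controls and synthetic subjects.

Augmenting a randomized trial with external controls or generated subjects
re-introduces confounding, so every borrowed or synthetic row is admitted
only through 1:1 propensity-score matching against the real cohort:

* historical controls (all T=0) are eligibility-filtered and matched to the
  trial's *treated* arm on elastic-net propensity scores;
* synthetic controls are matched to the real treated subjects and synthetic
  treated subjects to the real control side, each stage with its own
  freshly fitted propensity model.

Real subjects are never dropped: unmatched real rows stay in the cohort.
Matching is greedy 1:1 nearest-neighbor without replacement on the logit of
the propensity score with a caliper of ``caliper_sd`` pooled logit standard
deviations. Balance is diagnosed with standardized mean differences and with
the in-sample AUC of a propensity model at separating the two arms; synthetic
fidelity with per-variable Kolmogorov-Smirnov / total-variation similarity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from .data import TrialDataset, eligibility_mask
from .errors import ValidationError
from .rules import linear_design

logger = logging.getLogger(__name__)

__all__ = [
    "PropensityModel", "MatchResult", "GeneratorInterface",
    "SmoothedBootstrapGenerator", "BalanceReport", "fit_propensity",
    "nn_match", "borrow_historical", "baseline_generator_fit_sample",
    "match_synthetic", "smd_report", "arm_auc", "similarity_report",
]


# ---------------------------------------------------------------------------
# propensity model


@dataclass
class PropensityModel:
    """Elastic-net logistic regression of group membership on covariates."""

    clf: LogisticRegression
    feature_names: list
    means: np.ndarray
    sds: np.ndarray
    schema: object
    train_auc: float = np.nan
    train_scores: np.ndarray = None

    def _design(self, ds: TrialDataset) -> np.ndarray:
        Z = linear_design(ds.X, self.schema)[self.feature_names].to_numpy(dtype=float)
        return (Z - self.means) / self.sds

    def predict(self, ds: TrialDataset) -> np.ndarray:
        """Propensity scores in (0,1) for every row."""
        return self.clf.predict_proba(self._design(ds))[:, 1]

    @property
    def coefficients(self) -> np.ndarray:
        return self.clf.coef_.ravel()


def _fit_group_model(ds: TrialDataset, labels: np.ndarray, seed: int,
                     l1_ratio: float, C: float) -> PropensityModel:
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValidationError("propensity fitting requires both classes present")
    Z = linear_design(ds.X, ds.schema)
    names = list(Z.columns)
    V = Z.to_numpy(dtype=float)
    if np.isnan(V).any():
        raise ValidationError("covariates must be imputed before propensity fitting")
    means = V.mean(axis=0)
    sds = V.std(axis=0, ddof=0)
    sds[sds == 0] = 1.0
    Vs = (V - means) / sds
    clf = LogisticRegression(solver="saga", l1_ratio=l1_ratio, C=C,
                             max_iter=2000, random_state=seed)
    clf.fit(Vs, labels)
    scores = clf.predict_proba(Vs)[:, 1]
    return PropensityModel(clf=clf, feature_names=names, means=means, sds=sds,
                           schema=ds.schema,
                           train_auc=float(roc_auc_score(labels, scores)),
                           train_scores=scores)


def fit_propensity(ds_combined: TrialDataset, seed: int = 0,
                   l1_ratio: float = 0.5, C: float = 1.0) -> PropensityModel:
    """Fit a treatment-propensity model P(T=1 | X) on the combined cohort."""
    return _fit_group_model(ds_combined, ds_combined.t, seed, l1_ratio, C)


# ---------------------------------------------------------------------------
# nearest-neighbor matching


@dataclass
class MatchResult:
    """1:1 greedy nearest-neighbor matching outcome.

    ``pairs`` holds (index_a, index_b) positions into the two score vectors;
    each index appears in at most one pair and every pair distance (on the
    logit scale) is within the caliper.
    """

    pairs: list
    caliper: float
    distances: list = field(default_factory=list)
    n_a: int = 0
    n_b: int = 0

    @property
    def n_matched(self) -> int:
        return len(self.pairs)

    @property
    def matched_a(self) -> np.ndarray:
        return np.array([p[0] for p in self.pairs], dtype=int)

    @property
    def matched_b(self) -> np.ndarray:
        return np.array([p[1] for p in self.pairs], dtype=int)

    @property
    def unmatched_a(self) -> np.ndarray:
        return np.setdiff1d(np.arange(self.n_a), self.matched_a)

    @property
    def unmatched_b(self) -> np.ndarray:
        return np.setdiff1d(np.arange(self.n_b), self.matched_b)


def _logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(np.asarray(p, dtype=float), 1e-12, 1 - 1e-12)
    return np.log(p / (1.0 - p))


def nn_match(scores_a, scores_b, caliper_sd: float = 0.2) -> MatchResult:
    """Greedy 1:1 nearest-neighbor matching on logit propensity scores.

    Side A is iterated in descending score order; each A subject takes the
    nearest still-available B subject within the caliper. The caliper is
    ``caliper_sd`` times the pooled standard deviation of all logit scores;
    a zero caliper admits no pairs.
    """
    la = _logit(scores_a)
    lb = _logit(scores_b)
    if len(la) == 0 or len(lb) == 0:
        raise ValidationError("both sides of the matching must be nonempty")
    pooled_sd = float(np.concatenate([la, lb]).std(ddof=1))
    if pooled_sd == 0 and caliper_sd > 0:
        raise ValidationError("zero pooled score variance: caliper undefined")
    caliper = caliper_sd * pooled_sd
    result = MatchResult(pairs=[], caliper=caliper, n_a=len(la), n_b=len(lb))
    if caliper <= 0:
        return result

    order_b = np.argsort(lb, kind="stable")
    sorted_b = lb[order_b]
    available = np.ones(len(lb), dtype=bool)
    for ia in np.argsort(-la, kind="stable"):
        target = la[ia]
        lo = np.searchsorted(sorted_b, target - caliper, side="left")
        hi = np.searchsorted(sorted_b, target + caliper, side="right")
        best_j, best_d = -1, np.inf
        for j in range(lo, hi):
            if not available[j]:
                continue
            d = abs(sorted_b[j] - target)
            if d < best_d - 1e-15:
                best_j, best_d = j, d
        if best_j >= 0 and best_d <= caliper:
            available[best_j] = False
            result.pairs.append((int(ia), int(order_b[best_j])))
            result.distances.append(float(best_d))
    return result


# ---------------------------------------------------------------------------
# historical-control borrowing


def borrow_historical(rct: TrialDataset, pool: TrialDataset, criteria=None,
                      caliper_sd: float = 0.2, seed: int = 0) -> TrialDataset:
    """Enlarge the trial's control arm with matched historical controls.

    The pool (all control) is filtered by the trial's eligibility criteria; a
    treatment-propensity model is fitted on trial + filtered pool, and pool
    subjects are matched 1:1 to the trial's *treated* subjects. Matched pool
    rows are appended; every real trial row is kept whether matched or not.
    """
    if (pool.t != 0).any():
        raise ValidationError("historical pool must be control-only")
    if criteria is not None and len(criteria):
        mask = eligibility_mask(pool, criteria)
        if not mask.any():
            logger.warning("historical pool empty after eligibility filtering; "
                           "returning the trial unchanged")
            return rct
        pool = pool.subset(mask)
    combined = rct.concat(pool)
    model = fit_propensity(combined, seed=seed)
    scores = model.train_scores
    treated_pos = np.flatnonzero(rct.t == 1)
    pool_pos = np.arange(rct.n, rct.n + pool.n)
    match = nn_match(scores[treated_pos], scores[pool_pos], caliper_sd)
    logger.info("borrowed %d of %d historical controls (%d treated to match)",
                match.n_matched, pool.n, len(treated_pos))
    if match.n_matched == 0:
        return rct
    borrowed = pool.subset(match.matched_b)
    return rct.concat(borrowed)


# ---------------------------------------------------------------------------
# synthetic-subject generation


class GeneratorInterface:
    """Contract for pluggable synthetic-data generators.

    Implementations learn the joint distribution of the real cohort in
    ``fit`` and emit schema-conforming rows (source="synthetic") from
    ``sample``. Deep tabular generators can be plugged in here; the built-in
    baseline is a smoothed bootstrap.
    """

    def fit(self, real: TrialDataset) -> "GeneratorInterface":
        raise NotImplementedError

    def sample(self, n_treated: int, n_control: int, seed: int = 0) -> TrialDataset:
        raise NotImplementedError


class SmoothedBootstrapGenerator(GeneratorInterface):
    """Arm-conditional smoothed bootstrap generator.

    Rows are resampled with replacement within each treatment arm (keeping
    each row's own outcome, so (T,Y) cell frequencies are preserved in
    expectation). Continuous features are jittered with Gaussian kernel noise
    at the Silverman bandwidth of their (T,Y) cell; categorical features are
    resampled from the within-cell level frequencies. Cells with fewer than
    two subjects fall back to arm-level statistics (logged). With
    ``bandwidth_scale=0`` and ``freeze_categoricals=True`` samples are exact
    copies of real rows.
    """

    def __init__(self, bandwidth_scale: float = 1.0,
                 freeze_categoricals: bool = False):
        self.bandwidth_scale = bandwidth_scale
        self.freeze_categoricals = freeze_categoricals
        self.real_ = None

    def fit(self, real: TrialDataset) -> "SmoothedBootstrapGenerator":
        if real.X.isna().any().any():
            raise ValidationError("real data must be imputed before generator fitting")
        self.real_ = real
        return self

    @staticmethod
    def _silverman(v: np.ndarray) -> float:
        m = len(v)
        if m < 2:
            return 0.0
        sd = v.std(ddof=1)
        iqr = np.subtract(*np.percentile(v, [75, 25]))
        spread = min(sd, iqr / 1.34) if iqr > 0 else sd
        return 0.9 * spread * m ** (-0.2)

    def _cell(self, arm: int, y: int):
        real = self.real_
        cell = (real.t == arm) & (real.y == y)
        if cell.sum() < 2:
            logger.info("(T=%d, Y=%d) cell too small in real data; "
                        "falling back to arm-level statistics", arm, y)
            cell = real.t == arm
        return np.flatnonzero(cell)

    def _sample_arm(self, arm: int, n: int, rng: np.random.Generator) -> TrialDataset:
        real = self.real_
        arm_rows = np.flatnonzero(real.t == arm)
        if len(arm_rows) == 0:
            raise ValidationError(f"real data has no subjects with T={arm}")
        picks = rng.choice(arm_rows, size=n, replace=True)
        X = real.X.iloc[picks].reset_index(drop=True)
        y = real.y[picks].copy()
        for spec in real.schema.covariates:
            if spec.kind == "continuous" and self.bandwidth_scale > 0:
                col = X[spec.name].to_numpy(dtype=float)
                for yv in np.unique(y):
                    rows = np.flatnonzero(y == yv)
                    src = real.X[spec.name].to_numpy(dtype=float)[self._cell(arm, yv)]
                    bw = self.bandwidth_scale * self._silverman(src)
                    if bw > 0:
                        col[rows] = col[rows] + rng.normal(0.0, bw, size=len(rows))
                X[spec.name] = col
            elif spec.kind != "continuous" and not self.freeze_categoricals:
                col = X[spec.name].to_numpy(dtype=object)
                for yv in np.unique(y):
                    rows = np.flatnonzero(y == yv)
                    src = real.X[spec.name].iloc[self._cell(arm, yv)]
                    freq = src.value_counts(normalize=True)
                    col[rows] = rng.choice(freq.index.to_numpy(), size=len(rows),
                                           p=freq.to_numpy())
                X[spec.name] = pd.Series(col).astype(real.X[spec.name].dtype)
        return TrialDataset(
            X=X, t=np.full(n, arm, dtype=np.int64), y=y, schema=real.schema,
            source=np.full(n, "synthetic", dtype=object))

    def sample(self, n_treated: int, n_control: int, seed: int = 0) -> TrialDataset:
        if self.real_ is None:
            raise ValidationError("generator must be fitted before sampling")
        rng = np.random.default_rng(np.random.SeedSequence((seed, 2)))
        parts = []
        if n_treated > 0:
            parts.append(self._sample_arm(1, n_treated, rng))
        if n_control > 0:
            parts.append(self._sample_arm(0, n_control, rng))
        if not parts:
            raise ValidationError("requested zero synthetic subjects")
        out = parts[0]
        for p in parts[1:]:
            out = out.concat(p)
        return out


def baseline_generator_fit_sample(real: TrialDataset, n_t: int, n_c: int,
                                  seed: int = 0, bandwidth_scale: float = 1.0,
                                  freeze_categoricals: bool = False) -> TrialDataset:
    """Fit the built-in smoothed-bootstrap generator and draw one sample."""
    gen = SmoothedBootstrapGenerator(bandwidth_scale, freeze_categoricals)
    return gen.fit(real).sample(n_t, n_c, seed=seed)


# ---------------------------------------------------------------------------
# synthetic matching


def match_synthetic(real_cohort: TrialDataset, synthetic: TrialDataset,
                    caliper_sd: float = 0.2, seed: int = 0) -> TrialDataset:
    """Admit synthetic subjects into the cohort through two 1:1 matchings.

    Stage 1 matches the real treated subjects with the synthetic controls;
    stage 2 matches the real control side (trial controls plus any matched
    borrowed controls) with the synthetic treated subjects. Each stage fits
    its own propensity model on the rows it compares. Matched synthetic rows
    are appended; all real rows are kept. A synthetic arm that is absent
    skips its stage with a warning.
    """
    if synthetic is None or synthetic.n == 0:
        return real_cohort
    admitted = []
    stages = [
        ("treated-vs-synthetic-control", real_cohort.t == 1, synthetic.t == 0),
        ("control-vs-synthetic-treated", real_cohort.t == 0, synthetic.t == 1),
    ]
    for si, (name, real_mask, synth_mask) in enumerate(stages):
        if not synth_mask.any():
            logger.warning("synthetic data missing an arm; skipping stage %s", name)
            continue
        if not real_mask.any():
            logger.warning("real cohort missing an arm; skipping stage %s", name)
            continue
        real_side = real_cohort.subset(real_mask)
        synth_side = synthetic.subset(synth_mask)
        combined = real_side.concat(synth_side)
        labels = np.concatenate([np.ones(real_side.n), np.zeros(synth_side.n)])
        model = _fit_group_model(combined, labels, seed=seed + si,
                                 l1_ratio=0.5, C=1.0)
        scores = model.train_scores
        match = nn_match(scores[:real_side.n], scores[real_side.n:], caliper_sd)
        logger.info("stage %s admitted %d of %d synthetic subjects",
                    name, match.n_matched, synth_side.n)
        if match.n_matched:
            admitted.append(synth_side.subset(match.matched_b))
    out = real_cohort
    for part in admitted:
        out = out.concat(part)
    return out


# ---------------------------------------------------------------------------
# balance and similarity diagnostics


@dataclass
class BalanceReport:
    """Per-feature standardized mean differences between arms."""

    per_feature: dict
    mean_abs: float
    flagged: list = field(default_factory=list)  # zero-variance, unequal means


def smd_report(ds: TrialDataset) -> BalanceReport:
    """Standardized mean difference of every covariate between arms.

    Continuous and binary features use (m1 - m0) / sqrt((v1 + v0) / 2);
    categorical features contribute one entry per level indicator. The
    summary is the unweighted mean of absolute per-entry SMDs.
    """
    if ds.n_treated == 0 or ds.n_control == 0:
        raise ValidationError("SMD requires both arms present")
    treated = ds.t == 1
    Z = linear_design(ds.X, ds.schema)
    out = {}
    flagged = []
    for name in Z.columns:
        v = Z[name].to_numpy(dtype=float)
        m1, m0 = v[treated].mean(), v[~treated].mean()
        v1, v0 = v[treated].var(ddof=0), v[~treated].var(ddof=0)
        pooled = np.sqrt((v1 + v0) / 2.0)
        if pooled == 0:
            if m1 == m0:
                out[name] = 0.0
            else:
                out[name] = np.inf
                flagged.append(name)
        else:
            out[name] = float((m1 - m0) / pooled)
    finite = [abs(x) for x in out.values() if np.isfinite(x)]
    return BalanceReport(per_feature=out,
                         mean_abs=float(np.mean(finite)) if finite else 0.0,
                         flagged=flagged)


def arm_auc(ds: TrialDataset, seed: int = 0) -> float:
    """In-sample AUC of a fresh propensity model at separating the arms.

    A balance diagnostic, not a generalization estimate: values near 0.5 mean
    the covariates cannot tell the arms apart.
    """
    model = fit_propensity(ds, seed=seed)
    return model.train_auc


def similarity_report(real: TrialDataset, synth: TrialDataset,
                      schema=None) -> dict:
    """Per-variable similarity of synthetic to real data, each in [0,1].

    Continuous variables score 1 - KS statistic (two-sample sup distance of
    the empirical CDFs); categorical and binary variables score 1 - TVD with
    TVD = 0.5 * sum_level |p_level - q_level|.
    """
    schema = schema or real.schema
    out = {}
    for spec in schema.covariates:
        if spec.name not in real.X.columns or spec.name not in synth.X.columns:
            logger.warning("variable %r absent on one side; skipped", spec.name)
            continue
        a = real.X[spec.name].dropna()
        b = synth.X[spec.name].dropna()
        if spec.kind == "continuous":
            ks = sps.ks_2samp(a.to_numpy(dtype=float), b.to_numpy(dtype=float),
                              method="asymp").statistic
            out[spec.name] = float(1.0 - ks)
        else:
            levels = spec.levels if spec.kind == "categorical" else (0, 1)
            p = a.value_counts(normalize=True)
            q = b.value_counts(normalize=True)
            tvd = 0.5 * sum(abs(p.get(lv, 0.0) - q.get(lv, 0.0)) for lv in levels)
            out[spec.name] = float(1.0 - tvd)
    return out
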