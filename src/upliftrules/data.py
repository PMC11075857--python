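"""Trial dataset container, file I/O and preprocessing.

The central container is :class:`TrialDataset`: a covariate table ``X`` typed
per a :class:`~upliftrules.schema.FeatureSchema`, a binary treatment vector
``t``, a binary outcome vector ``y``, and a per-subject ``source`` label
(``rct`` / ``historical`` / ``synthetic``). Historical rows are by definition
control-only. Ordinal disability scores (modified Rankin Scale, 0-6) are
binarized to a favorable-outcome indicator before entering the container, so
responsive subgroups correspond to a positive risk difference.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError
from .schema import EligibilityCriteria, FeatureSchema, FeatureSpec, Predicate

logger = logging.getLogger(__name__)

SOURCES = ("rct", "historical", "synthetic")


@dataclass
class TrialDataset:
    """Subject-level trial data.

    Attributes
    ----------
    X : pandas.DataFrame
        Covariates, one row per subject, columns typed per ``schema``.
    t : numpy.ndarray of {0,1}
        Treatment indicator.
    y : numpy.ndarray of {0,1}
        Binary outcome (1 = favorable).
    source : numpy.ndarray of str
        Provenance of every row: "rct", "historical" or "synthetic".
    ids : numpy.ndarray
        Subject identifiers (opaque).
    schema : FeatureSchema
    """

    X: pd.DataFrame
    t: np.ndarray
    y: np.ndarray
    schema: FeatureSchema
    source: np.ndarray = None
    ids: np.ndarray = None

    def __post_init__(self):
        n = len(self.X)
        if n < 1:
            raise ValidationError("dataset must contain at least one subject")
        self.t = np.asarray(self.t)
        self.y = np.asarray(self.y)
        if self.source is None:
            self.source = np.full(n, "rct", dtype=object)
        self.source = np.asarray(self.source, dtype=object)
        if self.ids is None:
            self.ids = np.arange(n)
        self.ids = np.asarray(self.ids)
        for name, v in (("treatment", self.t), ("outcome", self.y)):
            if len(v) != n:
                raise ValidationError(f"{name} length {len(v)} != {n} rows")
            if pd.isna(v).any():
                raise ValidationError(f"{name} contains missing values")
            bad = ~np.isin(v, (0, 1))
            if bad.any():
                row = int(np.flatnonzero(bad)[0])
                raise ValidationError(
                    f"{name} must be 0/1; row {row} has value {v[bad][0]!r}")
        self.t = self.t.astype(np.int64)
        self.y = self.y.astype(np.int64)
        bad_src = ~np.isin(self.source, SOURCES)
        if bad_src.any():
            raise ValidationError(f"unknown source labels: {set(self.source[bad_src])}")
        hist_treated = (self.source == "historical") & (self.t == 1)
        if hist_treated.any():
            raise ValidationError("historical rows must be controls (T=0)")
        self.X = self.X.reset_index(drop=True)

    # ---- basic views ---------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.X)

    def __len__(self) -> int:
        return self.n

    @property
    def n_treated(self) -> int:
        return int(self.t.sum())

    @property
    def n_control(self) -> int:
        return int((1 - self.t).sum())

    def subset(self, index) -> "TrialDataset":
        """Row subset (boolean mask or integer positions); order preserved."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return TrialDataset(
            X=self.X.iloc[index].reset_index(drop=True),
            t=self.t[index],
            y=self.y[index],
            schema=self.schema,
            source=self.source[index],
            ids=self.ids[index],
        )

    def concat(self, other: "TrialDataset") -> "TrialDataset":
        """Stack two datasets sharing a schema (this dataset's rows first)."""
        if set(self.X.columns) != set(other.X.columns):
            raise SchemaError("cannot concatenate datasets with different columns")
        return TrialDataset(
            X=pd.concat([self.X, other.X[self.X.columns]], ignore_index=True),
            t=np.concatenate([self.t, other.t]),
            y=np.concatenate([self.y, other.y]),
            schema=self.schema,
            source=np.concatenate([self.source, other.source]),
            ids=np.concatenate([self.ids, other.ids]),
        )

    def to_frame(self) -> pd.DataFrame:
        df = self.X.copy()
        df.insert(0, "_id", self.ids)
        df[self.schema.treatment] = self.t
        df[self.schema.outcome] = self.y
        df["_source"] = self.source
        return df


# ---- I/O ----------------------------------------------------------------


def load_trial_table(path, schema: FeatureSchema) -> TrialDataset:
    """Read a delimited text file (CSV with header) into a typed dataset.

    Rows with a missing treatment or outcome are dropped with a logged count.
    Missing covariates are preserved (imputation is a separate step).
    """
    df = pd.read_csv(path)
    required = set(schema.covariate_names) | {schema.treatment, schema.outcome}
    missing_cols = sorted(required - set(df.columns))
    if missing_cols:
        raise SchemaError(f"input file missing required columns: {missing_cols}")

    complete = df[schema.treatment].notna() & df[schema.outcome].notna()
    dropped = int((~complete).sum())
    if dropped:
        logger.info("dropped %d rows with missing treatment or outcome", dropped)
        df = df.loc[complete]
    df = df.reset_index(drop=True)

    t = df[schema.treatment].to_numpy()
    bad = ~np.isin(t, (0, 1))
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValidationError(
            f"treatment column {schema.treatment!r} must be 0/1; "
            f"row {row} has value {t[bad][0]!r}")

    X = df[schema.covariate_names].copy()
    for spec in schema.covariates:
        if spec.kind == "categorical":
            observed = set(X[spec.name].dropna().unique())
            unknown = observed - set(spec.levels)
            if unknown:
                raise ValidationError(
                    f"feature {spec.name!r} has undeclared levels {sorted(map(str, unknown))}")
        else:
            X[spec.name] = pd.to_numeric(X[spec.name])

    source = (df["_source"].to_numpy(dtype=object) if "_source" in df.columns
              else None)
    id_col = schema.id_column or ("_id" if "_id" in df.columns else None)
    ids = df[id_col].to_numpy() if id_col and id_col in df.columns else None
    return TrialDataset(X=X, t=t, y=df[schema.outcome].to_numpy(),
                        schema=schema, source=source, ids=ids)


def save_trial_table(ds: TrialDataset, path) -> None:
    """Write the dataset back to CSV (inverse of :func:`load_trial_table`)."""
    ds.to_frame().to_csv(path, index=False)


# ---- derived features and outcome coding --------------------------------


def binarize_outcome(mrs_scores) -> np.ndarray:
    """Binarize modified Rankin Scale scores: 1 if mRS <= 2, else 0.

    mRS 0-2 denotes functional independence, the favorable outcome.
    """
    scores = np.asarray(mrs_scores)
    if pd.isna(scores).any():
        raise ValidationError("mRS scores contain missing values")
    scores = scores.astype(np.int64)
    if ((scores < 0) | (scores > 6)).any():
        raise ValidationError("mRS scores must lie in 0..6")
    return (scores <= 2).astype(np.int64)


def derive_bp_features(ds: TrialDataset, sbp: str = "SBP", dbp: str = "DBP") -> TrialDataset:
    """Append mean arterial pressure and pulse pressure.

    MAP = SBP/3 + DBP*2/3 and PP = SBP - DBP; original columns are unchanged.
    """
    for col in (sbp, dbp):
        if col not in ds.schema:
            raise SchemaError(f"cannot derive blood-pressure features: {col!r} missing")
    X = ds.X.copy()
    X["MAP"] = X[sbp] / 3.0 + X[dbp] * 2.0 / 3.0
    X["PP"] = X[sbp] - X[dbp]
    schema = ds.schema
    for name in ("MAP", "PP"):
        schema = schema.with_feature(FeatureSpec(name=name, kind="continuous"))
    return replace(ds, X=X, schema=schema)


# ---- preprocessing -------------------------------------------------------


@dataclass
class Preprocessor:
    """Log/z-normalization transforms with parameters frozen on training data.

    ``fit_transform`` learns per-feature means and SDs (after any log step)
    and marks the returned data as transformed; ``transform`` re-applies the
    stored parameters to held-out data. Re-transforming already transformed
    data is rejected.
    """

    params: dict = field(default_factory=dict)

    def fit_transform(self, ds: TrialDataset) -> TrialDataset:
        X = ds.X.copy()
        self.params = {}
        for spec in ds.schema.covariates:
            if not (spec.log or spec.znorm):
                continue
            v = X[spec.name].astype(float)
            entry = {"log": spec.log, "znorm": spec.znorm, "shift": spec.log_shift}
            if spec.log:
                v = _apply_log(v, spec)
            if spec.znorm:
                entry["mean"] = float(v.mean())
                sd = float(v.std(ddof=0))
                entry["sd"] = sd if sd > 0 else 1.0
                v = (v - entry["mean"]) / entry["sd"]
            X[spec.name] = v
            self.params[spec.name] = entry
        out = replace(ds, X=X)
        out._preprocessed = True
        return out

    def transform(self, ds: TrialDataset) -> TrialDataset:
        if not self.params and not any(s.log or s.znorm for s in ds.schema.covariates):
            return ds
        if getattr(ds, "_preprocessed", False):
            raise ValidationError("dataset already carries the fitted transforms")
        if not self.params:
            raise ValidationError("preprocessor has not been fitted")
        X = ds.X.copy()
        for name, entry in self.params.items():
            v = X[name].astype(float)
            if entry["log"]:
                v = _apply_log(v, ds.schema[name])
            if entry["znorm"]:
                v = (v - entry["mean"]) / entry["sd"]
            X[name] = v
        out = replace(ds, X=X)
        out._preprocessed = True
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.params, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "Preprocessor":
        with open(path) as fh:
            return cls(params=json.load(fh))


def _apply_log(v: pd.Series, spec: FeatureSpec) -> pd.Series:
    shifted = v + spec.log_shift
    if (shifted <= 0).any():
        raise ValidationError(
            f"log transform of {spec.name!r}: non-positive values after shift "
            f"{spec.log_shift}; configure a larger log_shift")
    return np.log(shifted)


def preprocess(ds: TrialDataset) -> tuple:
    """Fit the schema-flagged transforms on ``ds``; returns (dataset, preprocessor)."""
    pp = Preprocessor()
    return pp.fit_transform(ds), pp


# ---- eligibility ----------------------------------------------------------

_OPS = {
    "<": np.less, "<=": np.less_equal, ">": np.greater, ">=": np.greater_equal,
    "==": np.equal,
}


def _predicate_mask(pred: Predicate, ds: TrialDataset) -> np.ndarray:
    if pred.feature not in ds.schema:
        raise SchemaError(f"eligibility predicate references unknown feature {pred.feature!r}")
    v = ds.X[pred.feature]
    if pred.comparator == "in":
        return v.isin(list(pred.value)).to_numpy()
    if pred.comparator == "not in":
        return (~v.isin(list(pred.value))).to_numpy()
    return _OPS[pred.comparator](v.to_numpy(), pred.value)


def eligibility_mask(ds: TrialDataset, criteria: EligibilityCriteria) -> np.ndarray:
    """Boolean mask of subjects satisfying every predicate."""
    mask = np.ones(ds.n, dtype=bool)
    for pred in criteria:
        mask &= _predicate_mask(pred, ds)
    return mask


def apply_eligibility(ds: TrialDataset, criteria: EligibilityCriteria) -> TrialDataset:
    """Keep subjects satisfying every predicate; order preserved."""
    mask = eligibility_mask(ds, criteria)
    removed = int((~mask).sum())
    if removed:
        logger.info("eligibility filtering removed %d of %d subjects", removed, ds.n)
    if mask.all():
        return ds
    return ds.subset(mask)


# ---- imputation ------------------------------------------------------------


class MedianModeImputer:
    """Deterministic baseline imputer: median (continuous), mode (categorical/binary).

    Statistics are learned once on a training partition and reused unchanged
    on new data; ties in the mode break toward the smaller value.
    """

    def __init__(self):
        self.fill_ = {}

    def fit(self, ds: TrialDataset) -> "MedianModeImputer":
        self.fill_ = {}
        for spec in ds.schema.covariates:
            v = ds.X[spec.name]
            observed = v.dropna()
            if len(observed) == 0:
                raise ValidationError(f"feature {spec.name!r} is 100% missing; cannot impute")
            if spec.kind == "continuous":
                self.fill_[spec.name] = float(observed.median())
            else:
                counts = observed.value_counts()
                top = counts[counts == counts.max()].index
                self.fill_[spec.name] = sorted(top, key=lambda x: str(x))[0]
        return self

    def transform(self, ds: TrialDataset) -> TrialDataset:
        if not ds.X.isna().any().any():
            return ds
        X = ds.X.copy()
        for name, value in self.fill_.items():
            if X[name].isna().any():
                X[name] = X[name].fillna(value)
        return replace(ds, X=X)


def impute_baseline(ds: TrialDataset, imputer=None) -> TrialDataset:
    """Impute missing covariates; default imputer is :class:`MedianModeImputer`."""
    imputer = imputer or MedianModeImputer()
    if hasattr(imputer, "fit"):
        imputer.fit(ds)
    return imputer.transform(ds)
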