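"""Feature schema for subject-level trial tables.

A :class:`FeatureSchema` declares, for every column of a trial table, its
statistical kind (continuous, binary, categorical with enumerated levels),
its role (covariate, treatment, outcome, id, source) and optional transform
flags (log-transform, z-normalize). Eligibility criteria are conjunctive
predicates over schema covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import yaml

from .errors import SchemaError

KINDS = ("continuous", "binary", "categorical")
ROLES = ("covariate", "treatment", "outcome", "id", "source")


@dataclass(frozen=True)
class FeatureSpec:
    """Declaration of a single column.

    Parameters
    ----------
    name : str
        Column name in the table.
    kind : {"continuous", "binary", "categorical"}
    role : {"covariate", "treatment", "outcome", "id", "source"}
    levels : tuple, optional
        Closed set of admissible levels; required for categorical features.
    log : bool
        Apply a (shifted) natural-log transform during preprocessing.
    znorm : bool
        Z-normalize (after any log transform) during preprocessing.
    log_shift : float
        Constant added before the log transform; with a positive shift the
        transform is log(x + shift), so zero values are admissible.
    """

    name: str
    kind: str = "continuous"
    role: str = "covariate"
    levels: tuple = ()
    log: bool = False
    znorm: bool = False
    log_shift: float = 0.0

    def __post_init__(self):
        if self.kind not in KINDS:
            raise SchemaError(f"unknown feature kind {self.kind!r} for {self.name!r}")
        if self.role not in ROLES:
            raise SchemaError(f"unknown role {self.role!r} for {self.name!r}")
        if self.kind == "categorical" and not self.levels:
            raise SchemaError(f"categorical feature {self.name!r} must enumerate levels")
        object.__setattr__(self, "levels", tuple(self.levels))


@dataclass(frozen=True)
class Predicate:
    """One eligibility predicate: feature <comparator> threshold / level set."""

    feature: str
    comparator: str  # one of <, <=, >, >=, ==, in, not in
    value: object

    _COMPARATORS = ("<", "<=", ">", ">=", "==", "in", "not in")

    def __post_init__(self):
        if self.comparator not in self._COMPARATORS:
            raise SchemaError(f"unknown comparator {self.comparator!r}")


@dataclass
class EligibilityCriteria:
    """Ordered conjunction of predicates over schema covariates."""

    predicates: list = field(default_factory=list)

    def __iter__(self):
        return iter(self.predicates)

    def __len__(self):
        return len(self.predicates)


class FeatureSchema:
    """Typed description of a trial table.

    Exactly one column must carry the treatment role and one the outcome
    role; no feature name may appear twice.
    """

    def __init__(self, specs: Iterable[FeatureSpec]):
        specs = list(specs)
        names = [s.name for s in specs]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise SchemaError(f"duplicate feature names: {dup}")
        for role in ("treatment", "outcome"):
            k = sum(1 for s in specs if s.role == role)
            if k != 1:
                raise SchemaError(f"schema needs exactly one {role} column, found {k}")
        self.specs = specs
        self._by_name = {s.name: s for s in specs}

    def __contains__(self, name):
        return name in self._by_name

    def __getitem__(self, name) -> FeatureSpec:
        try:
            return self._by_name[name]
        except KeyError:
            raise SchemaError(f"feature {name!r} not in schema") from None

    def __iter__(self):
        return iter(self.specs)

    @property
    def treatment(self) -> str:
        return next(s.name for s in self.specs if s.role == "treatment")

    @property
    def outcome(self) -> str:
        return next(s.name for s in self.specs if s.role == "outcome")

    @property
    def id_column(self):
        return next((s.name for s in self.specs if s.role == "id"), None)

    @property
    def source_column(self):
        return next((s.name for s in self.specs if s.role == "source"), None)

    @property
    def covariates(self) -> list:
        return [s for s in self.specs if s.role == "covariate"]

    @property
    def covariate_names(self) -> list:
        return [s.name for s in self.covariates]

    def with_feature(self, spec: FeatureSpec) -> "FeatureSchema":
        """Return a new schema with one extra covariate appended."""
        return FeatureSchema(self.specs + [spec])

    # ---- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        feats = []
        for s in self.specs:
            d = {"name": s.name, "kind": s.kind, "role": s.role}
            if s.levels:
                d["levels"] = list(s.levels)
            if s.log:
                d["log"] = True
            if s.znorm:
                d["znorm"] = True
            if s.log_shift:
                d["log_shift"] = s.log_shift
            feats.append(d)
        return {"features": feats}

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSchema":
        specs = []
        for f in d.get("features", []):
            specs.append(FeatureSpec(
                name=f["name"],
                kind=f.get("kind", "continuous"),
                role=f.get("role", "covariate"),
                levels=tuple(f.get("levels", ())),
                log=bool(f.get("log", False)),
                znorm=bool(f.get("znorm", False)),
                log_shift=float(f.get("log_shift", 0.0)),
            ))
        return cls(specs)

    @classmethod
    def from_yaml(cls, path) -> "FeatureSchema":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def criteria_from_dicts(items: Sequence[dict]) -> EligibilityCriteria:
    """Build eligibility criteria from config entries like
    ``{"feature": "SBP", "comparator": ">", "value": 180}``."""
    return EligibilityCriteria(
        [Predicate(i["feature"], i["comparator"], i["value"]) for i in items]
    )
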