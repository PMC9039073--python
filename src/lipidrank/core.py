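"""Core domain types and file I/O for case-control lipidomics tables.

The package works on three plain-text inputs: a wide abundance table
(subjects x lipid features, linear concentration scale), a species-to-class
taxonomy, and per-subject metadata (case/control group, age, sex).  Missing
measurements (undetectable peaks) are carried as NaN and excluded from all
statistics unless imputed explicitly.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

SPECIES = "species"
CLASS = "class"

CASE = "case"
CONTROL = "control"

#: Covariate encoding: sex is carried as a 0/1 indicator, female = 1.
SEX_FEMALE_COLUMN = "sex_female"
AGE_COLUMN = "age"


class LipidDataError(ValueError):
    """Raised for malformed or inconsistent input tables."""


@dataclass(frozen=True)
class LipidTaxonomy:
    """Mapping of lipid species to lipid classes.

    Species names follow the dotted dialect ``CLASS.carbons.doublebonds``
    (e.g. ``PC.38.5``); the loader treats them as opaque strings and the
    taxonomy alone supplies class membership.
    """

    class_of: dict[str, str]

    def __post_init__(self) -> None:
        if not self.class_of:
            raise LipidDataError("taxonomy is empty")

    @property
    def species_ids(self) -> list[str]:
        return list(self.class_of)

    @property
    def class_ids(self) -> list[str]:
        """Class names in order of first appearance among species."""
        seen: dict[str, None] = {}
        for cls in self.class_of.values():
            seen.setdefault(cls)
        return list(seen)

    @property
    def n_species(self) -> int:
        return len(self.class_of)

    @property
    def n_classes(self) -> int:
        return len(self.class_ids)

    def members(self, class_id: str) -> list[str]:
        return [s for s, c in self.class_of.items() if c == class_id]

    @classmethod
    def from_csv(cls, path: str | Path) -> "LipidTaxonomy":
        """Read a two-column CSV ``species_id,class_id`` with header."""
        df = pd.read_csv(path, dtype=str)
        if df.shape[1] < 2:
            raise LipidDataError(f"taxonomy CSV needs two columns, got {df.shape[1]}")
        species = df.iloc[:, 0].tolist()
        dupes = [s for s, n in pd.Series(species).value_counts().items() if n > 1]
        if dupes:
            raise LipidDataError(f"duplicate species in taxonomy: {dupes}")
        return cls(dict(zip(species, df.iloc[:, 1].tolist())))

    @classmethod
    def from_json(cls, path: str | Path) -> "LipidTaxonomy":
        with open(path) as fh:
            return cls(dict(json.load(fh)))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"species_id": self.species_ids,
             "class_id": [self.class_of[s] for s in self.species_ids]}
        ).to_csv(path, index=False)


@dataclass
class AbundanceMatrix:
    """Subjects x features concentration table on the linear scale.

    ``data`` holds NaN where a measurement is missing; ``level`` records
    whether columns are individual species or aggregated classes.
    """

    data: pd.DataFrame
    level: str = SPECIES

    def __post_init__(self) -> None:
        if self.level not in (SPECIES, CLASS):
            raise LipidDataError(f"unknown level {self.level!r}")
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise LipidDataError(f"duplicate subject ids: {dupes}")
        if self.data.columns.has_duplicates:
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise LipidDataError(f"duplicate feature ids: {dupes}")
        neg = self.data.lt(0)
        if neg.any().any():
            r, c = next(zip(*np.nonzero(neg.to_numpy())))
            raise LipidDataError(
                "negative concentration at subject "
                f"{self.data.index[r]!r}, feature {self.data.columns[c]!r}"
            )

    @property
    def subject_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def feature_ids(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.data.isna()

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index_label="subject_id", na_rep="NA")


def load_abundance_table(path: str | Path, level: str = SPECIES) -> AbundanceMatrix:
    """Load a wide CSV abundance table (first column subject_id).

    Empty cells and the sentinel ``NA`` become missing entries.  Duplicate
    subject or feature names, and negative concentrations, are hard errors.
    """
    with open(path, newline="") as fh:
        header = next(csv.reader(fh))
    features = header[1:]
    counts = pd.Series(features).value_counts()
    dupes = counts[counts > 1].index.tolist()
    if dupes:
        raise LipidDataError(f"duplicate feature columns: {dupes}")
    df = pd.read_csv(path, index_col=0, na_values=["NA"], keep_default_na=False)
    df.columns = features  # undo pandas' dedup renaming guard, names checked above
    df = df.apply(pd.to_numeric, errors="coerce")
    df.index = df.index.astype(str)
    df.index.name = None
    return AbundanceMatrix(df, level=level)


@dataclass
class SubjectMetadata:
    """Per-subject group label, age (years) and sex."""

    table: pd.DataFrame  # index subject_id; columns group, age, sex

    def __post_init__(self) -> None:
        required = {"group", "age", "sex"}
        missing = required - set(self.table.columns)
        if missing:
            raise LipidDataError(f"metadata missing columns: {sorted(missing)}")
        if self.table.index.has_duplicates:
            raise LipidDataError("duplicate subject ids in metadata")
        bad = set(self.table["group"]) - {CASE, CONTROL}
        if bad:
            raise LipidDataError(f"unknown group labels: {sorted(bad)}")
        bad = set(self.table["sex"]) - {"female", "male"}
        if bad:
            raise LipidDataError(f"unknown sex labels: {sorted(bad)}")

    @property
    def subject_ids(self) -> list[str]:
        return self.table.index.tolist()

    @property
    def group(self) -> pd.Series:
        return self.table["group"]

    @classmethod
    def from_csv(cls, path: str | Path) -> "SubjectMetadata":
        df = pd.read_csv(path, index_col=0)
        df.index = df.index.astype(str)
        return cls(df)

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index_label="subject_id")


@dataclass
class FeatureTable:
    """Design matrix for classification: lipid features plus encoded covariates.

    ``X`` columns are lipid features followed by ``age`` and ``sex_female``
    (female = 1, male = 0) when covariates are included; ``y`` is 1 for cases.
    """

    X: pd.DataFrame
    y: np.ndarray
    covariates: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y)
        if len(self.y) != len(self.X):
            raise LipidDataError("outcome length does not match design matrix")
        if len(np.unique(self.y)) < 2:
            raise LipidDataError("outcome must contain both cases and controls")

    @property
    def lipid_features(self) -> list[str]:
        cov = set(self.covariates)
        return [c for c in self.X.columns if c not in cov]

    @property
    def n_subjects(self) -> int:
        return len(self.X)

    def subset(self, features: list[str]) -> "FeatureTable":
        """Restrict to the given lipid features, keeping covariates."""
        cols = list(features) + [c for c in self.covariates if c not in features]
        return FeatureTable(self.X[cols], self.y, list(self.covariates))


def build_feature_table(
    m: AbundanceMatrix, meta: SubjectMetadata, include_covariates: bool = True
) -> FeatureTable:
    """Join abundances with encoded covariates and the binary outcome."""
    missing = set(m.subject_ids) - set(meta.subject_ids)
    if missing:
        raise LipidDataError(f"subjects without metadata: {sorted(missing)}")
    meta_aligned = meta.table.loc[m.subject_ids]
    X = m.data.copy()
    covariates: list[str] = []
    if include_covariates:
        X[AGE_COLUMN] = meta_aligned["age"].to_numpy(dtype=float)
        X[SEX_FEMALE_COLUMN] = (meta_aligned["sex"] == "female").to_numpy(dtype=float)
        covariates = [AGE_COLUMN, SEX_FEMALE_COLUMN]
    y = (meta_aligned["group"] == CASE).to_numpy(dtype=int)
    return FeatureTable(X, y, covariates)


def aggregate_to_classes(m: AbundanceMatrix, tax: LipidTaxonomy) -> AbundanceMatrix:
    """Sum member-species concentrations into class-level concentrations.

    A class value is the sum of the subject's non-missing member species and
    is missing only when every member species is missing.  This summation
    convention preserves mass: per subject, the class totals add up to the
    species totals.
    """
    if m.level != SPECIES:
        raise LipidDataError("aggregate_to_classes expects a species-level matrix")
    orphans = [f for f in m.feature_ids if f not in tax.class_of]
    if orphans:
        raise LipidDataError(f"species absent from taxonomy: {orphans}")
    groups = pd.Series({f: tax.class_of[f] for f in m.feature_ids})
    # min_count=1 turns an all-missing group into NaN rather than 0
    agg = m.data.T.groupby(groups, sort=False).sum(min_count=1).T
    present = [c for c in tax.class_ids if c in agg.columns]
    return AbundanceMatrix(agg[present], level=CLASS)


@dataclass
class MissingReport:
    dropped: list[str]
    n_imputed: int


def handle_missing(
    m: AbundanceMatrix, drop_frac: float = 0.2, impute: str = "half_min"
) -> tuple[AbundanceMatrix, MissingReport]:
    """Drop mostly-missing features, then impute the rest.

    Features missing in more than ``drop_frac`` of subjects are removed (a
    fully undetectable feature is always removed under half-min imputation:
    no observed minimum exists).  Remaining missing cells are set to half the
    feature's observed minimum when ``impute='half_min'``, a standard
    stand-in for below-detection-limit abundances; ``impute='none'`` leaves
    them missing.
    """
    if not 0 <= drop_frac <= 1:
        raise LipidDataError("drop_frac must be in [0, 1]")
    if impute not in ("half_min", "none"):
        raise LipidDataError(f"unknown imputation {impute!r}")
    frac_missing = m.missing_mask.mean(axis=0)
    drop = frac_missing > drop_frac
    if impute == "half_min":
        drop |= frac_missing == 1.0
    dropped = m.data.columns[drop].tolist()
    data = m.data.drop(columns=dropped)
    n_imputed = 0
    if impute == "half_min":
        n_imputed = int(data.isna().to_numpy().sum())
        if n_imputed:
            data = data.fillna(data.min(axis=0) / 2.0)
    return AbundanceMatrix(data, level=m.level), MissingReport(dropped, n_imputed)
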