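"""Domain types and the dataset contract shared by all PU-learning stages.

A :class:`FeatureTable` holds samples × typed features (numeric or
categorical, missing cells allowed); :class:`PULabels` partitions the sample
ids into high-confidence positives ``P`` and unlabeled ``U``;
:class:`PlatoConfig` collects every tunable of the PU loop.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: strings treated as missing in tab-separated input
MISSING_SENTINELS = ("", "NA", "NaN", "nan", "na", "N/A")

#: truthy / falsy spellings accepted for the positive-flag column
_TRUE = {"1", "true", "t", "yes", "y"}
_FALSE = {"0", "false", "f", "no", "n"}


class FeatureTable:
    """Samples × typed features with an explicit missingness mask.

    Parameters
    ----------
    data:
        DataFrame indexed by unique sample id (string).  Numeric columns are
        stored as float64 with NaN for missing; categorical columns as
        object with NaN for missing.
    numeric, categorical:
        Names of the numeric and categorical columns.  Every column of
        ``data`` must be declared in exactly one of the two lists.
    """

    def __init__(self, data: pd.DataFrame, numeric: list[str], categorical: list[str]):
        numeric = list(numeric)
        categorical = list(categorical)
        declared = set(numeric) | set(categorical)
        if set(numeric) & set(categorical):
            raise ValueError(f"columns declared both numeric and categorical: "
                             f"{sorted(set(numeric) & set(categorical))}")
        if declared != set(data.columns):
            raise ValueError("every column must be declared exactly once; "
                             f"mismatch: {sorted(declared ^ set(data.columns))}")
        if data.index.has_duplicates:
            dupes = data.index[data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dupes[:5]}")
        data = data.copy()
        data.index = data.index.astype(str)
        for c in numeric:
            data[c] = pd.to_numeric(data[c], errors="raise").astype(float)
        for c in categorical:
            col = data[c].astype(object)
            col = col.where(~pd.isna(col), np.nan)
            # normalize non-missing levels to str so equality is well defined
            data[c] = col.map(lambda v: v if (isinstance(v, float) and np.isnan(v)) else str(v))
        self.data = data
        self.numeric = numeric
        self.categorical = categorical

    # -- basic introspection -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return len(self.data)

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    def missing_mask(self) -> pd.DataFrame:
        return self.data.isna()

    def has_missing(self) -> bool:
        return bool(self.data.isna().any().any())

    def column_type(self, name: str) -> str:
        if name in self.numeric:
            return "numeric"
        if name in self.categorical:
            return "categorical"
        raise KeyError(name)

    # -- subsetting ----------------------------------------------------------
    def subset(self, ids) -> "FeatureTable":
        ids = list(ids)
        return FeatureTable(self.data.loc[ids], self.numeric, self.categorical)

    def select_columns(self, cols) -> "FeatureTable":
        cols = list(cols)
        return FeatureTable(
            self.data[cols],
            [c for c in cols if c in self.numeric],
            [c for c in cols if c in self.categorical],
        )

    def equals(self, other: "FeatureTable") -> bool:
        if self.numeric != other.numeric or self.categorical != other.categorical:
            return False
        if list(self.data.index) != list(other.data.index):
            return False
        if not self.missing_mask().equals(other.missing_mask()):
            return False
        a, b = self.data.fillna(0), other.data.fillna(0)
        for c in self.numeric:
            if not np.allclose(a[c].to_numpy(), b[c].to_numpy(), equal_nan=True):
                return False
        for c in self.categorical:
            if not (a[c] == b[c]).all():
                return False
        return True

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"FeatureTable({self.n_samples} samples × {self.n_features} features: "
                f"{len(self.numeric)} numeric, {len(self.categorical)} categorical)")

    # -- I/O -----------------------------------------------------------------
    def to_tsv(self, path, schema_path=None) -> None:
        """Write as tab-separated text, missing cells as ``NA``.

        ``schema_path``, if given, receives a two-column sidecar declaring
        each column's type, so a re-read does not depend on inference.
        """
        out = self.data.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t", na_rep="NA")
        if schema_path is not None:
            with open(schema_path, "w") as fh:
                for c in self.feature_names:
                    fh.write(f"{c}\t{self.column_type(c)}\n")


def read_schema(path) -> dict[str, str]:
    schema = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            name, kind = line.split("\t")
            if kind not in ("numeric", "categorical"):
                raise ValueError(f"unknown column type {kind!r} for {name!r}")
            schema[name] = kind
    return schema


def _infer_type(col: pd.Series) -> str:
    """All non-missing cells parseable as numbers → numeric, else categorical."""
    obs = col.dropna()
    if obs.empty:
        return "numeric"
    try:
        pd.to_numeric(obs, errors="raise")
        return "numeric"
    except (ValueError, TypeError):
        return "categorical"


def read_feature_table(path, schema: dict[str, str] | str | None = None,
                       positive_column: str | None = "is_positive"):
    """Read a tab-separated candidate table.

    First column is the sample id; a designated boolean column (default
    ``is_positive``) defines the positive set P and is not kept as a
    feature.  Column types come from ``schema`` (a mapping or a sidecar
    path) when declared, else are inferred: a column whose non-missing
    cells all parse as numbers is numeric, anything else categorical.

    Returns ``(FeatureTable, PULabels)`` when a positive column is present,
    else ``(FeatureTable, None)``.
    """
    if isinstance(schema, str):
        schema = read_schema(schema)
    schema = dict(schema or {})
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                      na_values=list(MISSING_SENTINELS))
    if raw.shape[1] < 1:
        raise ValueError("empty table")
    id_col = raw.columns[0]
    raw = raw.set_index(id_col)
    if raw.index.has_duplicates:
        raise ValueError("duplicate sample ids in input file")

    labels = None
    if positive_column is not None and positive_column in raw.columns:
        flags = raw[positive_column]
        pos, uns = set(), set()
        for sid, v in flags.items():
            s = str(v).strip().lower()
            if s in _TRUE:
                pos.add(str(sid))
            elif s in _FALSE or pd.isna(v):
                uns.add(str(sid))
            else:
                raise ValueError(f"unparseable positive flag {v!r} for sample {sid!r}")
        labels = PULabels(P=frozenset(pos), U=frozenset(uns))
        raw = raw.drop(columns=[positive_column])

    numeric, categorical = [], []
    for c in raw.columns:
        kind = schema.get(c) or _infer_type(raw[c])
        (numeric if kind == "numeric" else categorical).append(c)
    data = raw.copy()
    for c in numeric:
        data[c] = pd.to_numeric(data[c], errors="raise")
    table = FeatureTable(data, numeric, categorical)
    return table, labels


@dataclass(frozen=True)
class PULabels:
    """Partition of the sample ids into positives P and unlabeled U."""

    P: frozenset
    U: frozenset

    def __post_init__(self):
        object.__setattr__(self, "P", frozenset(str(x) for x in self.P))
        object.__setattr__(self, "U", frozenset(str(x) for x in self.U))
        if self.P & self.U:
            raise ValueError(f"P and U overlap on {len(self.P & self.U)} ids, "
                             f"e.g. {sorted(self.P & self.U)[:3]}")

    @property
    def all_ids(self) -> frozenset:
        return self.P | self.U

    def ratio(self) -> float:
        """Unlabeled-to-positive skew |U| / |P|."""
        if not self.P:
            raise ValueError("P is empty")
        return len(self.U) / len(self.P)


@dataclass(frozen=True)
class PlatoConfig:
    """All tunables of the PU loop.

    Attributes
    ----------
    b, m:
        Informed-undersampling batch count and batch size.  ``m=None``
        means ``m = |P|`` (the published default, together with ``b=10``).
    N:
        Number of bootstrap runs.
    spy_fraction:
        Fraction of P held out of training as spies; the minimum spy score
        becomes the run's classification threshold.
    support_fraction:
        Minimum fraction of positive bootstrap votes for a final positive
        call.
    threshold_mode:
        ``"spies"`` (threshold = min spy score, strict >) or ``"fixed"``
        (threshold = ``fixed_threshold``, ≥).
    classifier_mode:
        ``"automl_lite"`` (local model search + voting/stacking ensembles)
        or ``"random_forest"`` (single random forest baseline).
    feature_selection:
        Per-bootstrap random-forest median-rank feature selection (on for
        SNV-style tables, off for MS/MS).
    likely_negative_vote:
        What a run records for unlabeled samples it consumed as training
        likely-negatives: ``"negative"`` (default) or ``"abstain"``.
    """

    b: int = 10
    m: int | None = None
    N: int = 20
    spy_fraction: float = 0.10
    support_fraction: float = 0.50
    threshold_mode: str = "spies"
    fixed_threshold: float = 0.5
    cv_folds: int = 10
    search_iterations: int = 10
    classifier_mode: str = "automl_lite"
    feature_selection: bool = True
    likely_negative_vote: str = "negative"
    n_jobs: int = 1
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.spy_fraction < 1):
            raise ValueError("spy_fraction must be in (0, 1)")
        if not (0 < self.support_fraction <= 1):
            raise ValueError("support_fraction must be in (0, 1]")
        if self.b < 1 or self.N < 1:
            raise ValueError("b and N must be ≥ 1")
        if self.m is not None and self.m < 1:
            raise ValueError("m must be ≥ 1 (or None for m = |P|)")
        if self.threshold_mode not in ("spies", "fixed"):
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")
        if self.classifier_mode not in ("automl_lite", "random_forest"):
            raise ValueError(f"unknown classifier_mode {self.classifier_mode!r}")
        if self.likely_negative_vote not in ("negative", "abstain"):
            raise ValueError(f"unknown likely_negative_vote {self.likely_negative_vote!r}")

    def replace(self, **kw) -> "PlatoConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class DatasetReport:
    """Diagnostics from :func:`validate_dataset`."""

    n_positives: int
    n_unlabeled: int
    ratio: float
    column_types: dict[str, str]
    missing_fraction: dict[str, float]

    def to_text(self) -> str:
        buf = io.StringIO()
        buf.write(f"positives (P):  {self.n_positives}\n")
        buf.write(f"unlabeled (U):  {self.n_unlabeled}\n")
        buf.write(f"U:P ratio:      {self.ratio:.1f}:1\n")
        buf.write("columns:\n")
        for c, t in self.column_types.items():
            buf.write(f"  {c}\t{t}\tmissing={self.missing_fraction[c]:.3f}\n")
        return buf.getvalue()


MIN_POSITIVES = 10  # a 10% spy split must be non-empty


def validate_dataset(table: FeatureTable, labels: PULabels) -> DatasetReport:
    """Check the PU dataset invariants and report per-column diagnostics.

    Raises on duplicate ids, id-set mismatch between table and labels, and
    ``|P| < 10`` (a 10% spy split would be empty).
    """
    ids = set(table.sample_ids)
    if labels.all_ids != ids:
        extra = sorted(labels.all_ids - ids)[:3]
        missing = sorted(ids - labels.all_ids)[:3]
        raise ValueError(f"labels and table disagree on sample ids "
                         f"(labels-only: {extra}, table-only: {missing})")
    if len(labels.P) < MIN_POSITIVES:
        raise ValueError(f"|P| < {MIN_POSITIVES}: got {len(labels.P)} positives")
    miss = table.missing_mask().mean(axis=0)
    return DatasetReport(
        n_positives=len(labels.P),
        n_unlabeled=len(labels.U),
        ratio=labels.ratio(),
        column_types={c: table.column_type(c) for c in table.feature_names},
        missing_fraction={c: float(miss[c]) for c in table.feature_names},
    )
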