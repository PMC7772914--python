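"""Missing-value filtering, iterative tree-based imputation, and
random-forest median-rank feature selection.

The upstream candidate tables carry a large fraction of missing values
(typically from low read coverage in one sequencing technology).  The
pipeline drops features and samples that are more than half missing, fills
the rest with a missForest-style iterative random-forest imputer, and —
independently inside every bootstrap — keeps the half of the features a
random forest ranks above the median by importance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from .datasets import FeatureTable

log = logging.getLogger(__name__)


@dataclass
class FilterReport:
    dropped_features: list[str] = field(default_factory=list)
    dropped_samples: list[str] = field(default_factory=list)


def filter_missing(table: FeatureTable, max_missing: float = 0.5):
    """Drop features, then samples, that are more than half missing.

    The threshold is strict: a column (row) exactly ``max_missing`` missing
    is kept.  Columns are filtered first so that near-empty features do not
    drag otherwise well-covered samples below the row threshold.

    Returns ``(filtered FeatureTable, FilterReport)``; raises if every
    column would be dropped.  Idempotent.
    """
    report = FilterReport()
    col_miss = table.missing_mask().mean(axis=0)
    keep_cols = [c for c in table.feature_names if col_miss[c] <= max_missing]
    report.dropped_features = [c for c in table.feature_names if c not in keep_cols]
    if not keep_cols:
        raise ValueError("all feature columns exceed the missingness threshold")
    reduced = table.select_columns(keep_cols)
    row_miss = reduced.missing_mask().mean(axis=1)
    keep_rows = [s for s in reduced.sample_ids if row_miss[s] <= max_missing]
    report.dropped_samples = [s for s in reduced.sample_ids if s not in keep_rows]
    if report.dropped_features:
        log.info("filter_missing: dropped %d features: %s",
                 len(report.dropped_features), report.dropped_features)
    if report.dropped_samples:
        log.info("filter_missing: dropped %d samples", len(report.dropped_samples))
    return reduced.subset(keep_rows), report


def _encode_predictors(df: pd.DataFrame, numeric: list[str], categorical: list[str],
                       exclude: str) -> pd.DataFrame:
    cols = [c for c in df.columns if c != exclude]
    num = [c for c in cols if c in numeric]
    cat = [c for c in cols if c in categorical]
    parts = []
    if num:
        parts.append(df[num].astype(float))
    if cat:
        parts.append(pd.get_dummies(df[cat].astype(object), dummy_na=False))
    if not parts:
        raise ValueError("no predictor columns available for imputation")
    return pd.concat(parts, axis=1)


@dataclass
class ImputationModel:
    """Record of a fitted iterative imputation: per-column initial fill,
    iteration count and the convergence deltas observed."""

    initial_fill: dict[str, object]
    iterations: int
    deltas: list[float]


def impute(table: FeatureTable, seed: int = 0, max_iter: int = 5,
           tol: float = 1e-3, n_estimators: int = 50):
    """Fill every missing cell by iterative random-forest imputation.

    Columns are initialized from their median (numeric) or mode
    (categorical), then revisited in order of increasing missingness: a
    random forest trained on the rows where the column is observed predicts
    the missing cells from all other (currently filled) columns.  Sweeps
    repeat until the normalized change of the imputed values falls below
    ``tol`` or ``max_iter`` sweeps have run.  Imputed numeric values are
    clipped to the column's observed min/max; imputed categorical values
    are observed levels by construction.  Deterministic given ``seed``.

    Imputation is unsupervised (labels are never consulted) so no label
    information can leak into the unlabeled set.

    Returns ``(complete FeatureTable, ImputationModel)``.
    """
    mask = table.missing_mask()
    for c in table.feature_names:
        if mask[c].all():
            raise ValueError(f"column {c!r} has no observed values; run filter_missing first")
    if not table.has_missing():
        return table, ImputationModel(initial_fill={}, iterations=0, deltas=[])

    df = table.data.copy()
    initial: dict[str, object] = {}
    for c in table.numeric:
        if mask[c].any():
            initial[c] = float(df[c].median())
            df[c] = df[c].fillna(initial[c])
    for c in table.categorical:
        if mask[c].any():
            initial[c] = df[c].mode(dropna=True).sort_values().iloc[0]
            df[c] = df[c].fillna(initial[c])

    miss_frac = mask.mean(axis=0)
    targets = sorted([c for c in table.feature_names if mask[c].any()],
                     key=lambda c: (miss_frac[c], c))
    rng = np.random.default_rng(seed)
    deltas: list[float] = []
    it = 0
    for it in range(1, max_iter + 1):
        sq_change = 0.0
        sq_scale = 0.0
        for c in targets:
            obs = ~mask[c]
            X = _encode_predictors(df, table.numeric, table.categorical, exclude=c)
            rs = int(rng.integers(0, 2**31 - 1))
            if c in table.numeric:
                model = RandomForestRegressor(n_estimators=n_estimators,
                                              random_state=rs, n_jobs=1)
                model.fit(X[obs.values], df.loc[obs, c].astype(float))
                pred = model.predict(X[~obs.values])
                lo, hi = table.data[c].min(), table.data[c].max()
                pred = np.clip(pred, lo, hi)
                old = df.loc[~obs, c].to_numpy(dtype=float)
                scale = float(table.data[c].var(ddof=0)) or 1.0
                sq_change += float(((pred - old) ** 2).sum()) / scale
                sq_scale += len(pred)
                df.loc[~obs, c] = pred
            else:
                model = RandomForestClassifier(n_estimators=n_estimators,
                                               random_state=rs, n_jobs=1)
                model.fit(X[obs.values], df.loc[obs, c].astype(str))
                pred = model.predict(X[~obs.values])
                old = df.loc[~obs, c].to_numpy(dtype=object)
                sq_change += float((pred != old).sum())
                sq_scale += len(pred)
                df.loc[~obs, c] = pred
        delta = sq_change / max(sq_scale, 1)
        deltas.append(delta)
        if delta < tol:
            break

    out = FeatureTable(df, table.numeric, table.categorical)
    return out, ImputationModel(initial_fill=initial, iterations=it, deltas=deltas)


def select_features(table: FeatureTable, labels, seed: int = 0,
                    n_estimators: int = 200) -> list[str]:
    """Keep the above-median-importance half of the features.

    A random forest is fit on the (balanced, complete) training table;
    categorical features are one-hot encoded internally and their dummy
    importances summed back onto the original column.  Exactly ``⌈d/2⌉``
    column names are returned, ordered and tie-broken by
    (importance descending, name ascending).  Deterministic given ``seed``.
    """
    if table.has_missing():
        raise ValueError("select_features requires a complete table; impute first")
    d = table.n_features
    if d < 2:
        log.warning("select_features: fewer than 2 features; returning all")
        return list(table.feature_names)

    y = np.asarray([labels[s] if isinstance(labels, dict) else labels[i]
                    for i, s in enumerate(table.sample_ids)])
    parts = []
    origin: list[str] = []
    if table.numeric:
        parts.append(table.data[table.numeric].astype(float))
        origin += list(table.numeric)
    if table.categorical:
        dummies = pd.get_dummies(table.data[table.categorical].astype(object))
        parts.append(dummies)
        for col in dummies.columns:
            src = max((c for c in table.categorical if col.startswith(c + "_")), key=len)
            origin.append(src)
    X = pd.concat(parts, axis=1)

    rf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed, n_jobs=1)
    rf.fit(X, y)
    imp: dict[str, float] = {c: 0.0 for c in table.feature_names}
    for col, w in zip(origin, rf.feature_importances_):
        imp[col] += float(w)
    k = math.ceil(d / 2)
    ranked = sorted(table.feature_names, key=lambda c: (-imp[c], c))
    return ranked[:k]
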