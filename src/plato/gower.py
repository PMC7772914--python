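"""Gower distance on mixed-type feature vectors and informed undersampling.

The Gower dissimilarity between two samples is the mean, over features
where both values are present, of a per-feature score: range-normalized
absolute difference for numeric features, 0/1 mismatch for categorical
ones.  Informed undersampling selects likely negatives from the unlabeled
set as the samples farthest, on average, from the positives — drawn in
``b`` random batches of size ``m`` so heterogeneous regions of the majority
class all get a chance to contribute.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import FeatureTable

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FeatureMetadata:
    """Per-dataset normalization constants for the Gower distance.

    Numeric ranges (max − min over all of P ∪ U) are computed once per
    dataset, before any batch sampling, so distances are comparable across
    batches and bootstrap runs.  Zero-range numeric features contribute 0.
    """

    numeric: tuple[str, ...]
    categorical: tuple[str, ...]
    ranges: dict[str, float]

    @classmethod
    def fit(cls, table: FeatureTable) -> "FeatureMetadata":
        ranges = {}
        for c in table.numeric:
            col = table.data[c]
            if col.notna().any():
                r = float(col.max() - col.min())
            else:
                r = 0.0
            ranges[c] = r
        return cls(numeric=tuple(table.numeric),
                   categorical=tuple(table.categorical),
                   ranges=ranges)


def _split_arrays(tab: FeatureTable, meta: FeatureMetadata):
    num = tab.data[list(meta.numeric)].to_numpy(dtype=float) if meta.numeric \
        else np.empty((tab.n_samples, 0))
    cat = tab.data[list(meta.categorical)].to_numpy(dtype=object) if meta.categorical \
        else np.empty((tab.n_samples, 0), dtype=object)
    return num, cat


def gower_matrix(a: FeatureTable, b: FeatureTable, meta: FeatureMetadata) -> np.ndarray:
    """Pairwise Gower distances, shape (len(a), len(b)), values in [0, 1].

    Missing values are handled by pairwise deletion: each pair's distance
    is renormalized over the features present in both samples.  A pair
    with no mutually present feature raises.
    """
    a_num, a_cat = _split_arrays(a, meta)
    b_num, b_cat = _split_arrays(b, meta)
    na, nb = a.n_samples, b.n_samples
    total = np.zeros((na, nb))
    count = np.zeros((na, nb))

    for j, c in enumerate(meta.numeric):
        x = a_num[:, j][:, None]
        y = b_num[:, j][None, :]
        present = ~(np.isnan(x) | np.isnan(y))
        r = meta.ranges[c]
        if r > 0:
            d = np.abs(x - y) / r
            d = np.where(present, np.clip(d, 0.0, 1.0), 0.0)
            total += d
        count += present

    for j in range(len(meta.categorical)):
        x = a_cat[:, j][:, None]
        y = b_cat[:, j][None, :]
        x_miss = pd.isna(x)
        y_miss = pd.isna(y)
        present = ~(x_miss | y_miss)
        total += np.where(present, x != y, False).astype(float)
        count += present

    if (count == 0).any():
        raise ValueError("no comparable features for at least one sample pair")
    return total / count


def gower_distance(x, y, meta: FeatureMetadata, table: FeatureTable | None = None) -> float:
    """Gower distance between two samples.

    ``x`` and ``y`` may be sample ids (with ``table`` given) or single-row
    :class:`FeatureTable` objects.
    """
    if table is not None:
        x = table.subset([x])
        y = table.subset([y])
    return float(gower_matrix(x, y, meta)[0, 0])


def avg_distance_to_positives(u, P, table: FeatureTable,
                              meta: FeatureMetadata) -> float:
    """Mean Gower distance from unlabeled sample ``u`` to every id in P."""
    P = sorted(P)
    if not P:
        raise ValueError("P is empty")
    if u in set(P):
        raise ValueError(f"sample {u!r} is itself in P")
    d = gower_matrix(table.subset([u]), table.subset(P), meta)
    return float(d.mean())


def informed_undersample(table: FeatureTable, P, U, n_required: int,
                         b: int, m: int, rng: np.random.Generator,
                         meta: FeatureMetadata | None = None,
                         debug_dump: list | None = None) -> list[str]:
    """Select ``n_required`` likely negatives from U, farthest from P.

    ``b`` batches of ``m`` candidates are drawn without replacement from
    the not-yet-selected part of U; each batch keeps its
    ``ceil(remaining / batches_remaining)`` candidates with the greatest
    average Gower distance to P (ties broken by ascending sample id).

    Returns a sorted list of exactly ``n_required`` distinct ids.
    """
    P = sorted(set(P))
    available = sorted(set(U))
    if set(P) & set(available):
        raise ValueError("P and U overlap")
    if n_required > len(available):
        raise ValueError(f"n_required={n_required} exceeds |U|={len(available)}")
    if n_required == 0:
        return []
    if b < 1:
        raise ValueError("b must be ≥ 1")
    if meta is None:
        meta = FeatureMetadata.fit(table)

    ref = table.subset(P)
    selected: list[str] = []
    for i in range(b):
        remaining = n_required - len(selected)
        if remaining <= 0:
            break
        quota = math.ceil(remaining / (b - i))
        batch_size = min(m, len(available))
        if batch_size < m:
            log.warning("batch %d: m=%d exceeds remaining |U|=%d; clipped",
                        i, m, len(available))
        idx = rng.choice(len(available), size=batch_size, replace=False)
        batch = [available[k] for k in sorted(idx)]
        d = gower_matrix(table.subset(batch), ref, meta).mean(axis=1)
        order = sorted(range(len(batch)), key=lambda k: (-d[k], batch[k]))
        keep = [batch[k] for k in order[:min(quota, len(batch))]]
        if debug_dump is not None:
            debug_dump.append([(batch[k], float(d[k])) for k in order])
        selected.extend(keep)
        chosen = set(keep)
        available = [s for s in available if s not in chosen]

    if len(selected) < n_required:
        # possible only if batches were clipped; top up from what is left
        d = gower_matrix(table.subset(available), ref, meta).mean(axis=1)
        order = sorted(range(len(available)), key=lambda k: (-d[k], available[k]))
        selected.extend(available[k] for k in order[: n_required - len(selected)])
    return sorted(selected)
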