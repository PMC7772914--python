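"""Synthetic fixtures with known ground truth for every pipeline stage.

Two generators: (i) PU tabular data emulating somatic-SNV candidate tables
— a small positive set, a heavily skewed unlabeled set (unlabeled:positive
ratios up to 1000:1) hiding some true positives, mixed numeric/categorical
features, and completely-at-random missingness; (ii) target/decoy PSM
score tables in PIN format in which decoy scores are exchangeable with
false-target scores, the core assumption of target-decoy competition.
Both are pure functions of their parameters, seed included.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import FeatureTable, PULabels
from .msms import PSMTable, write_pin

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the PU tabular generator.

    ``class_separation`` is the Euclidean distance between the positive and
    negative class centroids in units of the (unit) within-class spread,
    spread evenly over the ``n_informative_numeric`` informative numeric
    features; the remaining numeric features are pure noise, as in real
    candidate tables where only a subset of the extracted features carries
    the class signal.
    """

    n_positives: int = 100
    n_unlabeled: int = 100_000
    n_hidden_positives: int = 100
    d_numeric: int = 8
    n_informative_numeric: int = 5
    d_categorical: int = 4
    class_separation: float = 5.0
    missing_rate: float = 0.0
    n_categorical_levels: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.n_hidden_positives > self.n_unlabeled:
            raise ValueError("n_hidden_positives cannot exceed n_unlabeled")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.d_numeric < 1:
            raise ValueError("need at least one numeric feature")
        if not (1 <= self.n_informative_numeric <= self.d_numeric):
            raise ValueError("n_informative_numeric must be in [1, d_numeric]")
        if min(self.n_positives, self.n_unlabeled) < 1:
            raise ValueError("need positives and unlabeled samples")


def gen_pu_tabular(spec: SyntheticSpec):
    """Generate ``(FeatureTable, PULabels, truth)``.

    Positives (labeled and hidden) are drawn from one class distribution,
    true negatives from another: numeric features are Gaussian clusters
    whose centroids are ``class_separation`` apart; categorical features
    use class-conditional level frequencies drawn from a flat Dirichlet.
    ``truth`` maps every sample id to its hidden class (True = positive);
    ids in P are True by construction.  Missingness is applied completely
    at random over feature cells at ``missing_rate``.
    """
    rng = np.random.default_rng(spec.seed)
    n_pos_total = spec.n_positives + spec.n_hidden_positives
    n_neg = spec.n_unlabeled - spec.n_hidden_positives
    n = n_pos_total + n_neg

    shift = spec.class_separation / np.sqrt(spec.n_informative_numeric)
    shifts = np.r_[np.full(spec.n_informative_numeric, shift),
                   np.zeros(spec.d_numeric - spec.n_informative_numeric)]
    X_pos = rng.normal(0.0, 1.0, size=(n_pos_total, spec.d_numeric)) + shifts
    X_neg = rng.normal(0.0, 1.0, size=(n_neg, spec.d_numeric))
    X = np.vstack([X_pos, X_neg])
    is_positive = np.r_[np.ones(n_pos_total, bool), np.zeros(n_neg, bool)]

    data = {f"num_{j:02d}": X[:, j] for j in range(spec.d_numeric)}
    levels = list(string.ascii_uppercase[: spec.n_categorical_levels])
    # categorical informativeness scales with class separation: each class
    # tilts a shared Dirichlet base distribution in opposite directions, so
    # separation 0 yields exchangeable classes on every feature
    tilt = spec.class_separation / 10.0
    for j in range(spec.d_categorical):
        base = rng.dirichlet(np.ones(len(levels)))
        g = rng.normal(size=len(levels))
        p_pos = base * np.exp(tilt * g)
        p_neg = base * np.exp(-tilt * g)
        p_pos /= p_pos.sum()
        p_neg /= p_neg.sum()
        col = np.where(
            is_positive,
            rng.choice(levels, size=n, p=p_pos),
            rng.choice(levels, size=n, p=p_neg),
        )
        data[f"cat_{j:02d}"] = col

    # ids: labeled positives first, then the unlabeled pool with the hidden
    # positives shuffled uniformly into it
    p_ids = [f"P{i:06d}" for i in range(spec.n_positives)]
    u_ids = [f"U{i:06d}" for i in range(spec.n_unlabeled)]
    u_slot = rng.permutation(spec.n_unlabeled)
    ids = np.empty(n, dtype=object)
    ids[: spec.n_positives] = p_ids
    # rows n_positives .. n_pos_total-1 are hidden positives; remaining rows
    # are true negatives; both are scattered over the U id space
    u_rows = np.arange(spec.n_positives, n)
    for row, slot in zip(u_rows, u_slot):
        ids[row] = u_ids[slot]

    df = pd.DataFrame(data, index=pd.Index(ids, name="sample_id"))
    numeric = [c for c in df.columns if c.startswith("num_")]
    categorical = [c for c in df.columns if c.startswith("cat_")]

    if spec.missing_rate > 0:
        mask = rng.random(size=df.shape) < spec.missing_rate
        for j, c in enumerate(df.columns):
            df.loc[mask[:, j], c] = np.nan

    table = FeatureTable(df.sort_index(), numeric, categorical)
    labels = PULabels(P=frozenset(p_ids), U=frozenset(u_ids))
    truth = {str(sid): bool(t) for sid, t in zip(ids, is_positive)}
    return table, labels, truth


def gen_psm_fixture(n_true_targets: int = 300, n_false_targets: int = 300,
                    n_decoys: int = 300, score_shift: float = 3.0,
                    n_informative_features: int = 4,
                    n_noise_features: int = 3, seed: int = 0,
                    path=None):
    """Generate a concatenated-search PSM table (one best PSM per spectrum).

    False-target and decoy search scores are i.i.d. draws from the same
    standard-normal null — the exchangeability assumption under which
    target-decoy competition controls the FDR — while true-target scores
    are shifted up by ``score_shift``.  Informative auxiliary features
    carry an independent copy of the class signal (so a rescorer can beat
    the raw search score); noise features are pure N(0,1).

    Returns ``(PSMTable, truth)`` where truth maps spec_id → True for true
    targets.  When ``path`` is given the table is also written as PIN.
    """
    rng = np.random.default_rng(seed)
    n = n_true_targets + n_false_targets + n_decoys
    is_true = np.r_[np.ones(n_true_targets, bool), np.zeros(n - n_true_targets, bool)]
    is_decoy = np.r_[np.zeros(n_true_targets + n_false_targets, bool),
                     np.ones(n_decoys, bool)]

    score = rng.normal(0.0, 1.0, size=n) + np.where(is_true, score_shift, 0.0)
    feats = {"lnEValue": score}
    for k in range(n_informative_features):
        feats[f"feat_info_{k}"] = rng.normal(0.0, 1.0, size=n) + \
            np.where(is_true, score_shift * 0.8, 0.0)
    for k in range(n_noise_features):
        feats[f"feat_noise_{k}"] = rng.normal(0.0, 1.0, size=n)

    peptides = []
    seen = set()
    for i in range(n):
        core = "".join(rng.choice(list(_AA), size=9))
        while core in seen:
            core = "".join(rng.choice(list(_AA), size=9))
        seen.add(core)
        peptides.append(core)

    order = rng.permutation(n)  # interleave classes over spectrum ids
    df = pd.DataFrame({
        "spec_id": [f"spec_{i:06d}" for i in range(n)],
        "scan": np.arange(1, n + 1),
        "is_decoy": is_decoy[order],
        "peptide_raw": [f"K.{peptides[j]}.A" for j in order],
        "peptide": [peptides[j] for j in order],
        "proteins": [("decoy_prot" if is_decoy[j] else "prot") for j in order],
    })
    for cname, vals in feats.items():
        df[cname] = vals[order]
    df["score"] = df["lnEValue"]
    psms = PSMTable(df, feature_columns=list(feats), score_column="lnEValue")
    truth = {sid: bool(is_true[j]) for sid, j in zip(df.spec_id, order)}
    if path is not None:
        write_pin(psms, path)
    return psms, truth
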