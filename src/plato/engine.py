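"""The PU-learning loop: per-bootstrap informed undersampling, training,
spy-threshold scoring, and cross-bootstrap vote aggregation.

Each bootstrap run (1) selects likely negatives — as many as there are
training positives — by informed undersampling, (2) trains the configured
classifier on 90% of P plus those likely negatives, (3) scores the held-out
10% of P (the "spies") and every unlabeled sample not consumed for
training, and (4) votes an unlabeled sample positive when its score
strictly exceeds the minimum spy score (or meets a fixed threshold).  A
sample's final call is positive when its fraction of positive votes over
the N runs reaches the configured bootstrap support.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .datasets import FeatureTable, PULabels, PlatoConfig, validate_dataset
from .gower import FeatureMetadata, informed_undersample
from .models import fit_best
from .preprocess import select_features

log = logging.getLogger(__name__)


@dataclass
class BootstrapResult:
    """Everything one bootstrap run decided."""

    run_index: int
    train_positive_ids: frozenset
    spy_ids: frozenset
    likely_negative_ids: frozenset
    selected_features: list[str]
    spy_threshold: float
    scores: dict[str, float]          # spies + unlabeled samples not used in training
    votes: dict[str, bool]            # unlabeled ids only; True = positive
    model_summary: dict = field(default_factory=dict)
    feature_importance: dict[str, float] = field(default_factory=dict)


def _run_seed(seed: int, run_index: int) -> np.random.SeedSequence:
    # spawn-key derivation: reproducible and independent of execution order
    return np.random.SeedSequence(entropy=seed, spawn_key=(run_index,))


def run_bootstrap(table: FeatureTable, labels: PULabels, config: PlatoConfig,
                  run_index: int = 0,
                  meta: FeatureMetadata | None = None) -> BootstrapResult:
    """Execute one bootstrap run; deterministic given (config.seed, run_index)."""
    if table.has_missing():
        raise ValueError("table has missing cells; impute first (SNV mode) or "
                         "provide complete features (MS/MS mode)")
    ss = _run_seed(config.seed, run_index)
    rng = np.random.default_rng(ss)
    sk_seed = int(ss.generate_state(1, dtype=np.uint64)[0] % (2**31 - 1))
    if meta is None:
        meta = FeatureMetadata.fit(table)

    P = sorted(labels.P)
    U = sorted(labels.U)
    n_spies = max(1, int(round(config.spy_fraction * len(P))))
    spy_idx = rng.choice(len(P), size=n_spies, replace=False)
    spies = sorted(P[i] for i in spy_idx)
    train_pos = sorted(set(P) - set(spies))
    if not train_pos:
        raise ValueError("spy split consumed every positive")

    # likely negatives: as many as there are training positives
    m = config.m if config.m is not None else len(P)
    likely_neg = informed_undersample(table, train_pos, U, n_required=len(train_pos),
                                      b=config.b, m=m, rng=rng, meta=meta)

    train_ids = train_pos + likely_neg
    y_train = np.array([1] * len(train_pos) + [0] * len(likely_neg))
    train_tab = table.subset(train_ids)

    if config.feature_selection and train_tab.n_features >= 2:
        selected = select_features(train_tab, dict(zip(train_ids, y_train)),
                                   seed=sk_seed)
    else:
        selected = list(table.feature_names)
    train_sel = train_tab.select_columns(selected)

    model = fit_best(train_sel, y_train, mode=config.classifier_mode,
                     iterations=config.search_iterations, folds=config.cv_folds,
                     seed=sk_seed)

    to_score = spies + [u for u in U if u not in set(likely_neg)]
    proba = model.predict_proba(table.subset(to_score).select_columns(selected).data)[:, 1]
    scores = {sid: float(p) for sid, p in zip(to_score, proba)}

    if config.threshold_mode == "spies":
        threshold = min(scores[s] for s in spies)
        def is_pos(p): return p > threshold        # strictly higher than min spy
    else:
        threshold = float(config.fixed_threshold)
        def is_pos(p): return p >= threshold

    votes: dict[str, bool] = {}
    for u in U:
        if u in scores:
            votes[u] = bool(is_pos(scores[u]))
        elif config.likely_negative_vote == "negative":
            votes[u] = False                        # consumed as training negative
        # "abstain": leave the id out of this run's votes

    importance = model.feature_importance(train_sel.data, y_train, seed=sk_seed)
    return BootstrapResult(
        run_index=run_index,
        train_positive_ids=frozenset(train_pos),
        spy_ids=frozenset(spies),
        likely_negative_ids=frozenset(likely_neg),
        selected_features=selected,
        spy_threshold=threshold,
        scores=scores,
        votes=votes,
        model_summary=model.summary(),
        feature_importance=importance,
    )


@dataclass
class PlatoRunReport:
    """Aggregated outcome of N bootstrap runs over the unlabeled set."""

    results: list[BootstrapResult]
    support: dict[str, float]
    final_calls: dict[str, bool]
    mean_score: dict[str, float]
    mean_feature_importance: dict[str, float]
    threshold_distribution: list[float]
    config: PlatoConfig | None = None

    @property
    def n_runs(self) -> int:
        return len(self.results)

    def positive_ids(self) -> list[str]:
        return sorted(i for i, c in self.final_calls.items() if c)

    def calls_frame(self) -> pd.DataFrame:
        ids = sorted(self.final_calls)
        return pd.DataFrame({
            "sample_id": ids,
            "support": [self.support[i] for i in ids],
            "final_call": ["positive" if self.final_calls[i] else "negative" for i in ids],
            "mean_score": [self.mean_score[i] for i in ids],
        })

    def write_calls(self, path) -> None:
        self.calls_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")

    def manifest(self) -> dict:
        return {
            "config": self.config.to_dict() if self.config else None,
            "n_runs": self.n_runs,
            "thresholds": [round(t, 6) for t in self.threshold_distribution],
            "n_final_positive": len(self.positive_ids()),
            "models": [r.model_summary for r in self.results],
            "selected_features": [r.selected_features for r in self.results],
        }

    def write_manifest(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.manifest(), fh, indent=2)


def aggregate(results: list[BootstrapResult], support_fraction: float,
              config: PlatoConfig | None = None) -> PlatoRunReport:
    """Combine N bootstrap votes into final calls.

    ``support(id)`` is the fraction of positive votes over all N runs; a
    run that consumed the sample as a training likely-negative contributes
    a negative vote (unless configured to abstain, in which case the run
    still counts in the denominator).  Final call is positive iff support
    ≥ ``support_fraction``.
    """
    if not results:
        raise ValueError("no bootstrap results to aggregate")
    N = len(results)
    # spies are positives and are never re-called: only voted-on ids matter
    unlabeled = sorted({u for r in results for u in r.votes})
    support, mean_score, calls = {}, {}, {}
    for u in unlabeled:
        pos_votes = sum(1 for r in results if r.votes.get(u, False))
        support[u] = pos_votes / N
        run_scores = [r.scores[u] for r in results if u in r.scores]
        mean_score[u] = float(np.mean(run_scores)) if run_scores else 0.0
        calls[u] = support[u] >= support_fraction

    importance: dict[str, float] = {}
    all_feats = sorted({f for r in results for f in r.feature_importance})
    for f in all_feats:
        importance[f] = float(np.mean([r.feature_importance.get(f, 0.0) for r in results]))

    return PlatoRunReport(
        results=results,
        support=support,
        final_calls=calls,
        mean_score=mean_score,
        mean_feature_importance=importance,
        threshold_distribution=[r.spy_threshold for r in results],
        config=config,
    )


def feature_importance_summary(results: list[BootstrapResult]) -> dict[str, float]:
    """Per-feature mean importance over runs; runs that did not select a
    feature contribute 0 for it."""
    out: dict[str, float] = {}
    feats = sorted({f for r in results for f in r.feature_importance})
    for f in feats:
        out[f] = float(np.mean([r.feature_importance.get(f, 0.0) for r in results]))
    return out


def run_plato(table: FeatureTable, labels: PULabels, config: PlatoConfig,
              validate: bool = True) -> PlatoRunReport:
    """Run the full PU loop: N independent bootstrap runs + aggregation.

    Per-run seeds are derived from ``config.seed`` and the run index, so
    results are reproducible and independent of execution order (including
    parallel execution with ``config.n_jobs > 1``).
    """
    if validate:
        validate_dataset(table, labels)
    meta = FeatureMetadata.fit(table)
    if config.n_jobs != 1:
        results = Parallel(n_jobs=config.n_jobs)(
            delayed(run_bootstrap)(table, labels, config, i, meta)
            for i in range(config.N))
    else:
        results = [run_bootstrap(table, labels, config, i, meta)
                   for i in range(config.N)]
    results = sorted(results, key=lambda r: r.run_index)
    for r in results:
        log.info("run %d: threshold=%.4f, %d features, %d positive votes",
                 r.run_index, r.spy_threshold, len(r.selected_features),
                 sum(r.votes.values()))
    return aggregate(results, config.support_fraction, config=config)
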