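"""Local model search with cross-validation, plus soft-voting and stacking
ensembles built by greedy forward selection.

The search draws configurations from a fixed pool spanning five classifier
families — Bernoulli naive Bayes, extremely randomized trees, gradient
boosted trees (LightGBM), random forests and linear SGD — scores each by
k-fold cross-validated accuracy, and assembles the best (up to five models
within 5% of the top score) into a weighted soft-voting ensemble and a
two-layer stack with a logistic-regression meta-model, Caruana-style:
starting from the single best model, a model joins the ensemble (re-adding
allowed) only if it improves cross-validated accuracy; accuracy ties —
the norm when the balanced training set is separable — are broken by
cross-validated log-loss, so calibration decides where accuracy cannot.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier
from sklearn.base import clone
from sklearn.compose import ColumnTransformer
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.linear_model import LogisticRegression, SGDClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import BernoulliNB
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import Binarizer, OneHotEncoder, StandardScaler

from .datasets import FeatureTable

log = logging.getLogger(__name__)

FAMILIES = ("bernoulli_naive_bayes", "extremely_randomized_trees",
            "gradient_boosted_trees", "random_forest", "linear_sgd")

#: fixed hyperparameter pool: 2–3 configurations per family, small enough
#: that ~10 search iterations cover most of it
PARAMETER_POOL: tuple[tuple[str, dict], ...] = (
    ("bernoulli_naive_bayes", {"alpha": 1.0}),
    ("bernoulli_naive_bayes", {"alpha": 0.1}),
    ("extremely_randomized_trees", {"n_estimators": 50, "max_features": "sqrt"}),
    ("extremely_randomized_trees", {"n_estimators": 50, "max_features": 0.5}),
    ("gradient_boosted_trees", {"n_estimators": 100, "learning_rate": 0.1,
                                "min_child_samples": 5}),
    ("gradient_boosted_trees", {"n_estimators": 200, "learning_rate": 0.05,
                                "min_child_samples": 5}),
    ("random_forest", {"n_estimators": 50, "max_features": "sqrt"}),
    ("random_forest", {"n_estimators": 50, "max_features": 0.5,
                       "min_samples_leaf": 2}),
    ("linear_sgd", {"alpha": 1e-4}),
    ("linear_sgd", {"alpha": 1e-3}),
    ("random_forest", {"n_estimators": 50, "min_samples_leaf": 3}),
)

_TREE_FAMILIES = {"extremely_randomized_trees", "gradient_boosted_trees", "random_forest"}


def _make_pipeline(family: str, params: dict, numeric: list[str],
                   categorical: list[str], seed: int) -> Pipeline:
    scale = family in ("bernoulli_naive_bayes", "linear_sgd")
    transformers = []
    if numeric:
        transformers.append(("num", StandardScaler() if scale else "passthrough", numeric))
    if categorical:
        transformers.append(("cat", OneHotEncoder(handle_unknown="ignore",
                                                  sparse_output=False), categorical))
    pre = ColumnTransformer(transformers)
    if family == "bernoulli_naive_bayes":
        steps = [("pre", pre), ("bin", Binarizer(threshold=0.0)),
                 ("clf", BernoulliNB(**params))]
    elif family == "extremely_randomized_trees":
        steps = [("pre", pre), ("clf", ExtraTreesClassifier(random_state=seed,
                                                            n_jobs=1, **params))]
    elif family == "gradient_boosted_trees":
        steps = [("pre", pre), ("clf", LGBMClassifier(random_state=seed, n_jobs=1,
                                                      verbose=-1, **params))]
    elif family == "random_forest":
        steps = [("pre", pre), ("clf", RandomForestClassifier(random_state=seed,
                                                              n_jobs=1, **params))]
    elif family == "linear_sgd":
        steps = [("pre", pre), ("clf", SGDClassifier(loss="log_loss", max_iter=2000,
                                                     random_state=seed, **params))]
    else:
        raise ValueError(f"unknown family {family!r}")
    pipe = Pipeline(steps)
    # keep transformed frames as pandas so feature names stay consistent
    # between fit and predict for every estimator in the pool
    pipe.set_output(transform="pandas")
    return pipe


@dataclass
class CandidateModel:
    """One evaluated configuration: family, hyperparameters, pipeline and
    its cross-validated accuracy (mean over held-out folds)."""

    family: str
    params: dict
    pipeline: Pipeline
    cv_accuracy: float = float("nan")
    oof_logloss: float = float("nan")
    oof_proba: np.ndarray | None = field(default=None, repr=False)

    def fit(self, X: pd.DataFrame, y: np.ndarray) -> "CandidateModel":
        self.pipeline.fit(X, y)
        return self

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        return self.pipeline.predict_proba(X)

    def summary(self) -> dict:
        return {"family": self.family, "params": dict(self.params),
                "cv_accuracy": round(float(self.cv_accuracy), 4)}


def _fold_accuracy(proba_pos: np.ndarray, y: np.ndarray, folds: list[np.ndarray]) -> float:
    """Mean over folds of the accuracy of thresholding OOF probabilities at 0.5."""
    accs = [float(((proba_pos[f] >= 0.5).astype(int) == y[f]).mean()) for f in folds]
    return float(np.mean(accs))


def _logloss(proba_pos: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(proba_pos, 1e-12, 1 - 1e-12)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def search_models(X: pd.DataFrame, y, numeric: list[str], categorical: list[str],
                  iterations: int = 10, folds: int = 10, seed: int = 0) -> list[CandidateModel]:
    """Evaluate ``iterations`` configurations from the fixed pool by k-fold CV.

    Each candidate's out-of-fold positive-class probabilities are retained
    so ensembles can be scored on honestly held-out predictions.  Returns
    candidates sorted by cv_accuracy descending; deterministic given seed.
    """
    y = np.asarray(y).astype(int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training labels contain a single class")
    if counts.min() < folds:
        raise ValueError(f"cv_folds={folds} exceeds the minority class count "
                         f"({counts.min()}); stratified folds are infeasible")

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(PARAMETER_POOL))[: min(iterations, len(PARAMETER_POOL))]
    skf = StratifiedKFold(n_splits=folds, shuffle=True,
                          random_state=int(rng.integers(0, 2**31 - 1)))
    fold_test = [test for _, test in skf.split(X, y)]

    candidates: list[CandidateModel] = []
    for pick in order:
        family, params = PARAMETER_POOL[pick]
        model_seed = int(rng.integers(0, 2**31 - 1))
        pipe = _make_pipeline(family, params, numeric, categorical, model_seed)
        oof = np.empty(len(y))
        for test in fold_test:
            train = np.setdiff1d(np.arange(len(y)), test)
            fitted = clone(pipe)
            fitted.fit(X.iloc[train], y[train])
            proba = fitted.predict_proba(X.iloc[test])
            pos_col = list(fitted.classes_).index(1)
            oof[test] = proba[:, pos_col]
        cand = CandidateModel(family=family, params=params, pipeline=pipe,
                              cv_accuracy=_fold_accuracy(oof, y, fold_test),
                              oof_logloss=_logloss(oof, y),
                              oof_proba=oof)
        candidates.append(cand)
    # primary metric accuracy; ties (common on separable training sets) are
    # broken by OOF log-loss so the better-calibrated model ranks first
    candidates.sort(key=lambda c: (-c.cv_accuracy, c.oof_logloss, c.family,
                                   repr(sorted(c.params.items()))))
    for c in candidates:
        c._folds = fold_test  # shared fold structure, reused by the ensembles
    return candidates


@dataclass
class EnsembleModel:
    """Weighted soft-voting or two-layer stacking ensemble."""

    kind: str  # "voting" | "stacking"
    members: list[CandidateModel]
    weights: np.ndarray | None = None
    meta_model: LogisticRegression | None = None
    cv_accuracy: float = float("nan")

    def fit(self, X: pd.DataFrame, y) -> "EnsembleModel":
        y = np.asarray(y).astype(int)
        for m in self.members:
            m.fit(X, y)
        return self

    def _member_proba(self, X: pd.DataFrame) -> np.ndarray:
        cols = []
        for m in self.members:
            proba = m.predict_proba(X)
            pos = list(m.pipeline.classes_).index(1)
            cols.append(proba[:, pos])
        return np.column_stack(cols)

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        P = self._member_proba(X)
        if self.kind == "voting":
            pos = P @ (self.weights / self.weights.sum())
        else:
            pos = self.meta_model.predict_proba(P)[:, list(self.meta_model.classes_).index(1)]
        pos = np.clip(pos, 0.0, 1.0)
        return np.column_stack([1.0 - pos, pos])

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def summary(self) -> dict:
        out = {"kind": self.kind, "cv_accuracy": round(float(self.cv_accuracy), 4),
               "members": [m.summary() for m in self.members]}
        if self.weights is not None:
            out["weights"] = [round(float(w), 4) for w in self.weights / self.weights.sum()]
        return out

    def feature_importance(self, X: pd.DataFrame, y, seed: int = 0) -> dict[str, float]:
        return _ensemble_importance(self, X, np.asarray(y).astype(int), seed)


def _shortlist(candidates: list[CandidateModel], max_members: int = 5) -> list[CandidateModel]:
    """Up to five best models within 5% of the top score.

    Accuracy ties are pervasive when the balanced training set is
    separable, so among eligible candidates the shortlist prefers family
    diversity (one configuration per family first), which is what a
    heterogeneous-ensemble search converges to; remaining slots are filled
    in rank order.
    """
    best = candidates[0].cv_accuracy
    pool = [c for c in candidates if c.cv_accuracy >= 0.95 * best]
    picked: list[CandidateModel] = []
    seen_families: set[str] = set()
    for c in pool:
        if len(picked) >= max_members:
            break
        if c.family not in seen_families:
            picked.append(c)
            seen_families.add(c.family)
    for c in pool:
        if len(picked) >= max_members:
            break
        if c not in picked:
            picked.append(c)
    # keep rank order: best first (greedy + fallback rely on it)
    picked.sort(key=lambda c: (-c.cv_accuracy, c.oof_logloss, c.family,
                               repr(sorted(c.params.items()))))
    return picked


def _greedy_weights(pool: list[CandidateModel], y: np.ndarray,
                    folds: list[np.ndarray], max_rounds: int = 10):
    """Caruana-style forward selection with replacement on OOF probabilities.

    The ensemble is initialized with the whole shortlist (the up-to-five
    best models within 5% of the top score), one vote each; each
    subsequent round adds whichever member most improves the ensemble's
    cross-validated accuracy — ties in accuracy (the norm on separable
    training sets) broken by the largest reduction in OOF log-loss —
    stopping when no addition improves either.  Returns selection counts
    and the final OOF accuracy.
    """
    counts = np.ones(len(pool), dtype=int)
    stack = np.column_stack([c.oof_proba for c in pool])
    current = stack.mean(axis=1)
    acc = _fold_accuracy(current, y, folds)
    loss = _logloss(current, y)
    for _ in range(max_rounds):
        best_key, best_j, best_mix = None, None, None
        total = counts.sum()
        for j in range(len(pool)):
            mix = (current * total + stack[:, j]) / (total + 1)
            acc_gain = _fold_accuracy(mix, y, folds) - acc
            loss_gain = loss - _logloss(mix, y)
            # strict: ties in accuracy add nothing (an OOF-separable training
            # set cannot rank members, so the equal-weight shortlist stands)
            improves = acc_gain > 1e-12
            key = (acc_gain, loss_gain)
            if improves and (best_key is None or key > best_key):
                best_key, best_j, best_mix = key, j, mix
        if best_j is None:
            break
        counts[best_j] += 1
        current = best_mix
        acc = max(acc, acc + best_key[0])
        loss -= best_key[1]
    return counts, current, acc


def build_voting_ensemble(candidates: list[CandidateModel], y) -> EnsembleModel:
    """Soft-voting ensemble over the ≤5 best candidates within 5% of the top
    score, weighted by greedy selection counts."""
    y = np.asarray(y).astype(int)
    pool = _shortlist(candidates)
    folds = candidates[0]._folds
    counts, _, acc = _greedy_weights(pool, y, folds)
    if acc < pool[0].cv_accuracy - 1e-12:
        # the averaged shortlist must never score below its best member;
        # degenerate to that member if greedy additions could not recover
        counts = np.zeros(len(pool), dtype=int)
        counts[0] = 1
        acc = pool[0].cv_accuracy
    members = [c for c, k in zip(pool, counts) if k > 0]
    weights = np.array([k for k in counts if k > 0], dtype=float)
    return EnsembleModel(kind="voting", members=members, weights=weights, cv_accuracy=acc)


def build_stack_ensemble(candidates: list[CandidateModel], y,
                         seed: int = 0) -> EnsembleModel:
    """Two-layer stack: the voting ensemble's member set feeds a logistic
    regression meta-model trained on out-of-fold member probabilities.

    The reported cv_accuracy refits the meta-model per fold on the OOF
    probability matrix, so the meta-layer is also scored out of fold.
    """
    y = np.asarray(y).astype(int)
    voting = build_voting_ensemble(candidates, y)
    members = voting.members
    folds = candidates[0]._folds
    Z = np.column_stack([m.oof_proba for m in members])
    oof_meta = np.empty(len(y))
    for test in folds:
        train = np.setdiff1d(np.arange(len(y)), test)
        lr = LogisticRegression(max_iter=1000, random_state=seed)
        lr.fit(Z[train], y[train])
        oof_meta[test] = lr.predict_proba(Z[test])[:, list(lr.classes_).index(1)]
    acc = _fold_accuracy(oof_meta, y, folds)
    meta = LogisticRegression(max_iter=1000, random_state=seed)
    meta.fit(Z, y)
    return EnsembleModel(kind="stacking", members=members, meta_model=meta, cv_accuracy=acc)


def fit_best(table: FeatureTable, y, mode: str = "automl_lite", iterations: int = 10,
             folds: int = 10, seed: int = 0):
    """Train the configured classifier on a balanced training table.

    ``automl_lite`` runs the model search, builds both ensembles, and
    returns the one with higher cv_accuracy (tie → voting), fully refit on
    the training data.  ``random_forest`` returns a single fitted random
    forest pipeline wrapped as a one-member voting ensemble so both modes
    expose the same predict_proba / feature_importance surface.
    """
    X = table.data
    y = np.asarray(y).astype(int)
    if mode == "random_forest":
        pipe = _make_pipeline("random_forest", {"n_estimators": 200}, table.numeric,
                              table.categorical, seed)
        cand = CandidateModel(family="random_forest", params={"n_estimators": 200},
                              pipeline=pipe, cv_accuracy=float("nan"))
        model = EnsembleModel(kind="voting", members=[cand], weights=np.array([1.0]))
        return model.fit(X, y)
    candidates = search_models(X, y, table.numeric, table.categorical,
                               iterations=iterations, folds=folds, seed=seed)
    voting = build_voting_ensemble(candidates, y)
    stacking = build_stack_ensemble(candidates, y, seed=seed)
    chosen = stacking if stacking.cv_accuracy > voting.cv_accuracy else voting
    log.debug("fit_best: voting=%.4f stacking=%.4f chose %s",
              voting.cv_accuracy, stacking.cv_accuracy, chosen.kind)
    return chosen.fit(X, y)


# -- feature importance ------------------------------------------------------

def _origin_of_transformed(pipeline: Pipeline) -> list[str]:
    """Map each transformed column back to its source feature name."""
    pre: ColumnTransformer = pipeline.named_steps["pre"]
    origin: list[str] = []
    for name, trans, cols in pre.transformers_:
        if name == "remainder":
            continue
        if isinstance(trans, OneHotEncoder):
            for col, cats in zip(cols, trans.categories_):
                origin.extend([col] * len(cats))
        else:
            origin.extend(cols)
    return origin


def _member_importance(member: CandidateModel, X: pd.DataFrame, y: np.ndarray,
                       seed: int) -> dict[str, float]:
    clf = member.pipeline.named_steps["clf"]
    imp: dict[str, float] = {c: 0.0 for c in X.columns}
    if member.family in _TREE_FAMILIES:
        raw = np.asarray(clf.feature_importances_, dtype=float)
        if raw.sum() > 0:
            raw = raw / raw.sum()
        for col, w in zip(_origin_of_transformed(member.pipeline), raw):
            imp[col] += float(w)
    else:
        res = permutation_importance(member.pipeline, X, y, n_repeats=3,
                                     random_state=seed, n_jobs=1)
        raw = np.clip(res.importances_mean, 0.0, None)
        if raw.sum() > 0:
            raw = raw / raw.sum()
        for col, w in zip(X.columns, raw):
            imp[col] += float(w)
    return imp


def _ensemble_importance(model: EnsembleModel, X: pd.DataFrame, y: np.ndarray,
                         seed: int = 0) -> dict[str, float]:
    """Weighted member average: impurity importance for tree members,
    permutation importance for the rest; normalized to sum to 1."""
    if model.weights is not None:
        w = model.weights / model.weights.sum()
    else:
        w = np.full(len(model.members), 1.0 / len(model.members))
    total: dict[str, float] = {c: 0.0 for c in X.columns}
    for weight, member in zip(w, model.members):
        mi = _member_importance(member, X, y, seed)
        for c, v in mi.items():
            total[c] += weight * v
    s = sum(total.values())
    if s > 0:
        total = {c: v / s for c, v in total.items()}
    return total
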