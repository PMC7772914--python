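# Methods

## The positive-unlabeled rescoring loop

The package addresses a recurring situation in variant calling and
proteomics: a model-based pipeline produces a large list of candidate
calls, a stringent filter certifies a small subset P of them as
high-confidence positives, and everything else is an unlabeled pool U
with a typical U:P skew of 100:1 to 1000:1, almost all of it true
negatives. No confirmed negatives exist, so ordinary supervised training
is not possible. The loop implemented here trains a discriminative
classifier anyway, by manufacturing likely negatives and calibrating the
decision threshold with held-out positives:

1. **Spy split.** A fraction `spy_fraction` (default 10%) of P is held
   out of training entirely ("spies"); the remaining 90% are the training
   positives.
2. **Informed undersampling.** As many likely negatives as there are
   training positives are drawn from U: `b` batches (default 10) of `m`
   candidates (default `m = |P|`) are sampled without replacement, and
   each batch keeps its candidates with the greatest *average Gower
   distance* to the training positives. Batching matters because the
   majority class is rarely homogeneous (sequencing errors and germline
   variants occupy different regions of feature space); batches give
   every region a chance to contribute far-from-P representatives.
3. **Balanced training.** A classifier is fit on training positives vs.
   likely negatives (one random forest, or the model search described
   below). For SNV-style tables a per-run random-forest median-rank
   feature selection precedes the fit; MS/MS tables skip selection.
4. **Spy threshold.** The fitted classifier scores the spies and every
   unlabeled sample not consumed for training. A sample votes positive in
   this run iff its score is *strictly greater* than the minimum spy
   score (mode `spies`), or ≥ a fixed cutoff (mode `fixed`, default 0.5).
5. **Bootstrap aggregation.** Steps 1–4 repeat N times (default 20) with
   independent spy splits and batches. A sample's support is its fraction
   of positive votes over all N runs; its final call is positive iff
   support ≥ `support_fraction` (default 50%). A run that consumed a
   sample as a training likely-negative records a negative vote for it
   (configurable to abstain instead).

The Gower distance is used because the feature tables mix numeric and
categorical columns: per feature, the dissimilarity is |x−y|/range for
numeric (ranges computed once over P ∪ U; zero-range features contribute
0) and a 0/1 mismatch for categorical, averaged over the features present
in both samples (pairwise deletion with renormalization). Ties in average
distance break by ascending sample id, so the undersampler is a pure
function of its RNG.

### Why the spy minimum, and what it costs

With negatives vastly over-represented in U, a fixed 0.5 cutoff
over-calls. The minimum spy score adapts per run: it estimates the score
of the *weakest* true positive, and on skewed data it settles well above
0.5 (observable in the per-run threshold distributions the engine
reports). The price is variance: one unusually weak spy lowers a run's
threshold and floods that run with false votes, while a run whose spies
all saturate at probability 1.0 can accept nothing (the strict-> rule
makes a threshold of 1.0 unbeatable). Bootstrap aggregation dampens both
failure modes but does not remove them; see *Limitations*.

## The model search and ensembles

Instead of a hosted AutoML service, `model_search` draws up to
`search_iterations` (default 10) configurations from a fixed pool spanning
five families — Bernoulli naive Bayes (on standardized, mean-binarized
features), extremely randomized trees, gradient-boosted trees (LightGBM),
random forests, and logistic SGD — and scores each by stratified k-fold
cross-validated accuracy (default 10 folds), retaining out-of-fold
probabilities. Two ensembles are built from the up-to-five best models
within 5% of the top score:

- **Voting**: weighted soft-vote. The ensemble is initialized with the
  whole shortlist, one vote each, then grown greedily (re-adding allowed):
  a model is added only if it strictly improves cross-validated accuracy,
  and weights are proportional to selection counts. If the greedy result
  ever scores below the best single member, it degenerates to that member.
- **Stacking**: the same member set feeding a logistic-regression
  meta-model trained on out-of-fold member probabilities (the meta layer
  is itself scored out of fold).

The better ensemble by cross-validated accuracy is used; ties go to
voting. Two details deserve comment because the balanced 180-sample
training sets are usually linearly separable:

- *Every* candidate then reaches cross-validated accuracy 1.0, so
  accuracy alone cannot rank them. Candidate ranking breaks ties by
  out-of-fold log-loss; shortlist composition prefers family diversity
  (one configuration per family before second configurations), because a
  homogeneous shortlist of the most overconfident family produces badly
  calibrated vote averages.
- Greedy additions are accepted on strict accuracy improvement only. On a
  separable training set nothing improves, and the equal-weight vote of
  the diverse shortlist stands — which is the desired behavior: the
  member probabilities are averaged, and miscalibration of any single
  family is diluted.

Feature importance is reported per run as the weight-averaged member
importance (impurity importance for tree members, permutation importance
for the others, each normalized to sum to 1), and per dataset as the mean
over runs, with runs that did not select a feature contributing 0.

## Preprocessing

SNV-style candidate tables arrive with substantial missingness (low read
coverage in one technology). `filter_missing` drops features, then
samples, that are *more than half* missing (exactly half is kept;
columns first, so near-empty features do not drag otherwise well-covered
samples under the row threshold). `impute` is a missForest-style
iterative imputer: columns initialize from their median/mode and are
revisited in order of increasing missingness, each fitted with a
50-tree random forest on the currently completed other columns, for up
to 5 sweeps or until the normalized change of imputed values drops below
1e-3. Imputed numeric values are clipped to the observed column range;
imputed categorical values are observed levels by construction.
Imputation is deliberately unsupervised — the labels are never shown to
the imputer — so no label information can leak into U.

`select_features` fits a 200-tree random forest on the balanced training
set, sums one-hot importances back onto their source columns, and keeps
the ⌈d/2⌉ columns of above-median importance (ties by name). It runs
independently inside every bootstrap, which both regularizes (different
runs may keep different features) and keeps any selection bias out of the
spy scores.

## MS/MS adapter

PIN (Percolator-input) files from a concatenated target-decoy search are
parsed as tab-separated text (`SpecId, Label ∈ {1,−1}, ScanNr,
features…, Peptide, Proteins`; an optional DefaultDirection row is
skipped; flanking residues are stripped for peptide identity). The
adapter applies, in order: best PSM per spectrum (ties: target beats
decoy, then lexicographic peptide); FDR by target-decoy competition,

    FDR(t) = (1 + #decoys with score ≥ t) / (#targets with score ≥ t),

with q(s) = min over thresholds t ≤ s of FDR(t), computed in one
descending sweep (ties share the counts of their full tie group, which is
the conservative direction); acceptance at level Q means *q strictly
below Q*. Peptide-level control first keeps the best-scoring PSM per
distinct peptide (targets and decoys separately), then reapplies the same
q-value machinery.

For rescoring, P is the stage-1 target set at 1% FDR and U is everything
else, decoys included — decoys are legitimate likely-negative material.
The PU loop runs without imputation or feature selection; each PSM's new
score is its mean predicted positive probability over the runs that
scored it (P keeps 1.0; a PSM consumed as a likely negative in every run
scores 0), and peptide counting at the cutoff repeats on the new score.
FDR values above 1 are capped for reporting only.

## Synthetic data

`gen_pu_tabular` emulates the PU tabular regime: positives and hidden
positives are one Gaussian class, true negatives another, with the
centroid distance `class_separation` (default 5, in units of the unit
within-class spread) spread evenly over `n_informative_numeric` (default
5) of the `d_numeric` (default 8) numeric features — the remainder are
pure noise, mirroring real candidate tables where most extracted features
carry little signal. Categorical features (default 4, with 4 levels) tilt
a shared Dirichlet base distribution in opposite directions per class,
with tilt magnitude proportional to `class_separation`, so separation 0
yields exchangeable classes on *every* feature (a true null).
Missingness is completely at random at `missing_rate`. Defaults are
n_positives = 100 and n_unlabeled up to 100,000, reaching the 1000:1
skew regime.

`gen_psm_fixture` draws false-target and decoy scores i.i.d. from the
same standard normal — the exchangeability assumption under which
target-decoy competition controls FDR — and shifts true-target scores up
by `score_shift` (default 3). Informative auxiliary features carry an
independent copy of the class signal, so a feature-based rescorer can
genuinely beat the raw score; noise features are N(0,1).

What the generators do **not** emulate: structured missingness (real
missingness concentrates in low-coverage regions and correlates across
features), heavy-tailed or multimodal negatives (sequencing artifacts
cluster), feature correlations, and score distributions with the skew of
real search engines. Passing tests on this data therefore demonstrate
the mechanics and calibration of the pipeline, not clinical performance.

## Numerical and protocol choices

- Per-run seeds derive from `SeedSequence(seed, spawn_key=(run_index,))`,
  so results are bit-identical regardless of execution order, including
  parallel bootstraps (`n_jobs > 1`).
- The spy count is `round(spy_fraction·|P|)`, floored at 1; `|P| ≥ 10`
  is enforced so the default split is non-empty.
- The likely-negative quota equals the number of *training* positives
  (90% of P), and the distance reference set is also the training
  positives: spies are hidden from every stage of a run.
- Per-batch quota is ⌈remaining/batches-remaining⌉; a batch larger than
  the remaining pool is clipped with a warning; selection is without
  replacement across batches, so exactly the requested number of
  distinct ids returns.
- The 90% positive subsets are subsampling runs (without replacement),
  not classical with-replacement bootstraps.
- "More than half missing" is strict; "above median rank" keeps ⌈d/2⌉.
- Metric reporting rounds half-up to 2 decimals on the 0–100 scale;
  internal values are unrounded. Zero-denominator metrics report as
  not-available, never as silent zeros.

## Problem sizes used in the test and acceptance runs

The shipped test suite and acceptance script exercise the recovery
protocol at 100 positives, 100 hidden positives, 50,000 unlabeled,
separation 5, N = 20 bootstraps, 50% support, with the single-forest
classifier mode (the model-search mode is exercised at smaller n and in
the determinism checks); FDR calibration uses 100 replicates of
900-PSM fixtures. These sizes keep a full run in minutes while staying
in the heavily skewed regime the method targets.

## Limitations

- **A precision ceiling governs hidden-positive recovery at extreme
  skew.** With ~50,000 true negatives and 100 hidden positives, the
  false-positive count at any score threshold t (measured in within-class
  standard deviations above the negative centroid along the discriminant)
  is ≈ 50,000·Φ(−t), while recall is Φ(d′−t) for centroid distance d′.
  At d′ = 5 even the *oracle* likelihood-ratio classifier maximizes F1
  around 0.91–0.93, and the spy-minimum threshold (the weakest of ~10
  spies sits ≈1.5 sd below the positive centroid) lands near, not at,
  that optimum with run-to-run variance. Measured mean F1 over ten seeds
  is ≈0.6–0.7 in both classifier modes (individual seeds range from
  ≈0.35 to ≈0.87; recall is consistently 88–98 while precision swings
  with the weakest spy) — far above the naive treat-everything-unlabeled-
  as-negative baseline, which calls nothing and scores 0 on every seed,
  but below the oracle ceiling. Recovering F1 ≥ 0.9 in this regime
  requires stronger separation, fewer unlabeled negatives, or an
  essentially-oracle classifier with a lower-variance threshold rule.
- Spy-threshold variance: a single aberrant spy can dominate a run in
  either direction; the minimum is deliberately conservative but noisy.
  Aggregation over N runs is the only mitigation implemented.
- Probability saturation: tree ensembles emit exact 0/1 probabilities on
  separable data; a run whose spies all score exactly 1.0 accepts
  nothing under the strict-> rule. The family-diverse vote makes exact
  ties rare but cannot exclude them.
- The imputer is O(sweeps × columns × forest); it is meant for
  ~10⁵ × ~10² tables, not larger.
- The model-search pool is small and fixed by design; it is a stand-in
  for a full hyperparameter search and will not track a hosted AutoML
  service on hard datasets.
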