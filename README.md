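# plato-pu

Positive-unlabeled (PU) learning for rescoring model-based calls, with
adapters for somatic-SNV candidate tables and MS/MS peptide-spectrum-match
(PSM) rescoring under target-decoy FDR control.

## The problem

Model-based callers — somatic variant callers on tumor/normal exomes,
database search engines on immunopeptidomic spectra — emit a long list of
candidates. A stringent consensus filter certifies a small subset *P* of
high-confidence positives; the remaining candidates form a huge unlabeled
pool *U* (U:P skews of 1000:1 are typical) that is mostly, but not
entirely, negative. There are no confirmed negatives to train on, and
patient-to-patient variation defeats classifiers trained on other
samples. The PU loop implemented here learns from each dataset itself:

1. hold out 10% of *P* as **spies**;
2. select likely negatives from *U* by **informed undersampling** — `b`
   random batches, keeping the candidates with the greatest average
   **Gower distance** (mixed numeric/categorical dissimilarity in [0,1])
   to the training positives;
3. train a classifier (a seeded model search over five families with
   10-fold cross-validation and Caruana-style voting/stacking ensembles,
   or a plain random forest) on the balanced set, with per-run
   random-forest median-rank feature selection for SNV-style tables;
4. vote a sample positive when its score strictly exceeds the **minimum
   spy score**;
5. repeat for *N* = 20 bootstraps and call positive every sample with
   ≥ 50% **bootstrap support**.

Evaluation uses TPR = TP/(TP+FN), PPV = TP/(TP+FP) and
F1 = 2·TPR·PPV/(TPR+PPV) over ground-truthed samples. The MS/MS adapter
estimates FDR by target-decoy competition,
FDR(t) = (1 + #decoys ≥ t)/(#targets ≥ t), with q-values and
peptide-level uniquification.

## A worked example

```python
from plato import metrics
from plato.datasets import PlatoConfig
from plato.engine import run_plato
from plato.synthetic import SyntheticSpec, gen_pu_tabular

spec = SyntheticSpec(n_positives=50, n_unlabeled=3000, n_hidden_positives=30,
                     class_separation=5.0, seed=42)
table, labels, truth = gen_pu_tabular(spec)
result = run_plato(table, labels,
                   PlatoConfig(N=10, classifier_mode="random_forest", seed=42))
c = metrics.confusion(result.final_calls, {u: truth[u] for u in labels.U})
print(len(result.positive_ids()), metrics.tpr(c), metrics.ppv(c), metrics.f1(c))
```

Running `python examples/snv_rescoring.py` (the same pipeline plus
missing-value filtering and imputation at 5% missingness) prints:

```
candidates: |P|=50, |U|=3000, 12 features, 5.1% cells missing
final positive calls: 25 of 3000 unlabeled
spy thresholds per bootstrap: [0.79, 0.97, 0.86, 0.82, 0.79, 0.93, 0.84, 0.82, 0.91, 0.93]
TPR=73.33%  PPV=88.0%  F1=80.0%
```

Thirty true variants hide among the 3000 unlabeled candidates; the loop
calls 25 candidates, 22 of them correct. Note the spy thresholds all sit
above the 0.5 default — the skewed unlabeled pool pushes them up, which
is exactly what keeps the false-positive count low. `python
examples/msms_rescoring.py` shows the proteomics side: on a 900-PSM
fixture the raw search score accepts 243 peptides at 1% FDR and PU
rescoring with auxiliary features lifts that to 299 at an actual
false-discovery proportion of 0.003.

There is also a thin CLI exposing the same pipelines
(`plato run-snv`, `plato run-msms`, `plato fdr-filter`,
`plato simulate`, `plato metrics`); every run writes a manifest with the
config, seed and per-bootstrap thresholds needed to reproduce it.

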