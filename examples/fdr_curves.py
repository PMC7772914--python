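"""Target-decoy competition FDR and q-values from first principles.

Builds a small score table, prints the estimated FDR at a few thresholds
and the q-value of each PSM, illustrating the +1-corrected estimator
FDR(t) = (1 + #decoys ≥ t) / (#targets ≥ t) and the monotone q transform.
"""

import numpy as np
import pandas as pd

from plato.msms import PSMTable, fdr_at_threshold, qvalues

scores = [5.0, 4.5, 4.0, 3.5, 3.0, 2.5, 2.0, 1.5, 1.0, 0.5]
decoy = [False, False, False, True, False, False, True, False, True, True]
df = pd.DataFrame({
    "spec_id": [f"sp{i}" for i in range(10)],
    "scan": range(10),
    "is_decoy": decoy,
    "peptide": [f"PEPTIDE{i}" for i in range(10)],
    "peptide_raw": [f"K.PEPTIDE{i}.A" for i in range(10)],
    "proteins": "prot",
    "s": scores,
    "score": scores,
})
psms = PSMTable(df, feature_columns=["s"], score_column="s")

for t in (4.0, 3.0, 1.0):
    print(f"FDR at t={t}: {fdr_at_threshold(psms, t):.3f}")

scored = qvalues(psms).df
print(scored[["spec_id", "score", "is_decoy", "fdr", "q"]].to_string(index=False))
# Every target's q is the best (smallest) FDR achievable by any threshold
# at or below its score; q never increases as the score grows.
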