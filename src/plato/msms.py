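"""MS/MS peptide-spectrum-match rescoring under target-decoy FDR control.

Ingests Percolator-input (PIN) tab-separated search results from a
concatenated target-decoy search, keeps the best PSM per spectrum, and
estimates FDR by target-decoy competition:

    FDR(t) = (1 + #decoy PSMs with score ≥ t) / (#target PSMs with score ≥ t)

q-values are the usual min-over-lower-thresholds transform; the accepted
set at level Q is the target PSMs with q strictly below Q.  Peptide-level
control first keeps only the best-scoring PSM per distinct peptide
(targets and decoys separately) and then applies the same q-value cutoff.
The PU loop rescoring uses the 1%-FDR targets as P and everything else
(weak targets and decoys) as U; no imputation and no feature selection are
applied to MS/MS feature tables.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import FeatureTable, PULabels, PlatoConfig
from .engine import run_plato

log = logging.getLogger(__name__)

_FLANK = re.compile(r"^(?:[A-Z-]\.)?(.*?)(?:\.[A-Z-])?$")


def strip_flanks(peptide: str) -> str:
    """Drop flanking residues from ``K.PEPTIDER.A``-style notation."""
    m = _FLANK.match(peptide.strip())
    core = m.group(1) if m else peptide
    if not core:
        raise ValueError(f"empty peptide after stripping flanks: {peptide!r}")
    return core


@dataclass
class PSMTable:
    """Peptide-spectrum matches with target/decoy labels and features.

    ``df`` columns: ``spec_id``, ``scan``, ``is_decoy``, ``peptide``
    (flanks stripped), ``peptide_raw``, ``proteins``, ``score``, plus the
    numeric feature columns listed in ``feature_columns``.
    """

    df: pd.DataFrame
    feature_columns: list[str] = field(default_factory=list)
    score_column: str = "score"

    def __len__(self) -> int:
        return len(self.df)

    @property
    def targets(self) -> pd.DataFrame:
        return self.df[~self.df.is_decoy]

    @property
    def decoys(self) -> pd.DataFrame:
        return self.df[self.df.is_decoy]

    def copy(self) -> "PSMTable":
        return PSMTable(self.df.copy(), list(self.feature_columns), self.score_column)


PIN_FIXED = ("SpecId", "Label", "ScanNr")


def read_pin(path, score_column: str | None = None) -> PSMTable:
    """Read a Percolator-input (PIN) file.

    Expected header: ``SpecId  Label  ScanNr  <feature...>  Peptide
    Proteins`` with Label ∈ {1, −1}.  An optional second ``DefaultDirection``
    row is skipped.  Flanking residues are stripped for peptide identity
    but the raw string is retained.  ``score_column`` names the feature
    used as the stage-1 search score (default: the first feature column).
    """
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:3]) != list(PIN_FIXED):
        raise ValueError(f"malformed PIN header: expected leading columns "
                         f"{PIN_FIXED}, got {list(df.columns[:3])}")
    if "Peptide" not in df.columns or "Proteins" not in df.columns:
        raise ValueError("malformed PIN header: missing Peptide/Proteins columns")
    if len(df) and str(df.iloc[0]["SpecId"]).lower() == "defaultdirection":
        df = df.iloc[1:].reset_index(drop=True)

    labels = pd.to_numeric(df["Label"], errors="raise")
    bad = ~labels.isin([1, -1])
    if bad.any():
        raise ValueError(f"PIN Label must be 1 or -1; found {sorted(labels[bad].unique())}")

    features = [c for c in df.columns if c not in PIN_FIXED + ("Peptide", "Proteins")]
    for c in features:
        try:
            df[c] = pd.to_numeric(df[c], errors="raise").astype(float)
        except (ValueError, TypeError) as exc:
            raise ValueError(f"non-numeric cell in PIN feature column {c!r}") from exc
    if not features:
        raise ValueError("PIN file has no feature columns")
    score_column = score_column or features[0]
    if score_column not in features:
        raise ValueError(f"score column {score_column!r} not among PIN features")

    out = pd.DataFrame({
        "spec_id": df["SpecId"].astype(str),
        "scan": pd.to_numeric(df["ScanNr"], errors="raise").astype(int),
        "is_decoy": (labels == -1).to_numpy(),
        "peptide_raw": df["Peptide"].astype(str),
        "peptide": df["Peptide"].astype(str).map(strip_flanks),
        "proteins": df["Proteins"].astype(str),
    })
    for c in features:
        out[c] = df[c].to_numpy()
    out["score"] = out[score_column]
    return PSMTable(out, feature_columns=features, score_column=score_column)


def write_pin(psms: PSMTable, path) -> None:
    """Write back to PIN format (round-trip partner of :func:`read_pin`)."""
    df = psms.df
    out = pd.DataFrame({
        "SpecId": df.spec_id,
        "Label": np.where(df.is_decoy, -1, 1),
        "ScanNr": df.scan,
    })
    for c in psms.feature_columns:
        out[c] = df[c]
    out["Peptide"] = df.peptide_raw
    out["Proteins"] = df.proteins
    out.to_csv(path, sep="\t", index=False)


def best_psm_per_spectrum(psms: PSMTable) -> PSMTable:
    """Keep one PSM per spectrum: highest score; ties prefer a target over
    a decoy, then the lexicographically smallest peptide."""
    df = psms.df.copy()
    ranked = df.sort_values(["spec_id", "score", "is_decoy", "peptide"],
                            ascending=[True, False, True, True],
                            kind="mergesort")
    best = ranked.drop_duplicates("spec_id", keep="first").reset_index(drop=True)
    return PSMTable(best, psms.feature_columns, psms.score_column)


def fdr_at_threshold(psms: PSMTable, t: float, score_col: str = "score",
                     cap: bool = True) -> float | None:
    """Target-decoy competition FDR estimate at score threshold ``t``.

    Returns None (not-available) when no target scores at or above ``t``.
    Values above 1 are capped at 1 unless ``cap`` is False.
    """
    s = psms.df[score_col].to_numpy()
    decoy = psms.df.is_decoy.to_numpy()
    n_target = int(((s >= t) & ~decoy).sum())
    if n_target == 0:
        return None
    v = (1 + int(((s >= t) & decoy).sum())) / n_target
    return min(v, 1.0) if cap else v


def qvalues(psms: PSMTable, score_col: str = "score") -> PSMTable:
    """Attach TDC FDR and q-value columns by a single descending-score sweep.

    q(psm) = min over thresholds t ≤ score(psm) of FDR(t), evaluated on the
    distinct observed scores; non-increasing as score increases.  At a tied
    score, decoys and targets are counted together (both ≥ t), which is the
    conservative direction.  The attached ``fdr`` column is capped at 1;
    the q computation uses uncapped values internally.
    """
    df = psms.df.copy()
    s = df[score_col].to_numpy(dtype=float)
    decoy = df.is_decoy.to_numpy()
    order = np.argsort(-s, kind="mergesort")
    s_sorted = s[order]
    decoy_sorted = decoy[order]
    cum_decoy = np.cumsum(decoy_sorted)
    cum_target = np.cumsum(~decoy_sorted)
    # collapse ties: FDR is defined per distinct threshold, using all PSMs ≥ t
    is_last_of_tie = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    with np.errstate(divide="ignore"):
        fdr_sorted = np.where(cum_target > 0,
                              (1.0 + cum_decoy) / np.maximum(cum_target, 1),
                              np.inf)
    # propagate each tie group's final counts (all PSMs ≥ t) to its members
    idx_last = np.empty(len(s), dtype=int)
    last = len(s) - 1
    for i in range(len(s) - 1, -1, -1):
        if is_last_of_tie[i]:
            last = i
        idx_last[i] = last
    fdr_sorted = fdr_sorted[idx_last]
    qs = np.minimum.accumulate(fdr_sorted[::-1])[::-1]
    q = np.empty(len(s))
    q[order] = qs
    fdr_col = np.empty(len(s))
    fdr_col[order] = np.minimum(fdr_sorted, 1.0)
    df["fdr"] = fdr_col
    df["q"] = np.minimum(q, 1.0)
    return PSMTable(df, psms.feature_columns, psms.score_column)


def accepted_at(psms: PSMTable, q_cutoff: float = 0.01) -> pd.DataFrame:
    """Target PSMs accepted at level Q: q strictly below the cutoff."""
    df = psms.df
    if "q" not in df.columns:
        df = qvalues(psms).df
    return df[(~df.is_decoy) & (df.q < q_cutoff)]


def uniquify_peptides(psms: PSMTable, score_col: str = "score") -> PSMTable:
    """One PSM per distinct peptide (targets and decoys uniquified within
    their own class), keeping the best score; ties broken by spec_id."""
    df = psms.df.copy()
    ranked = df.sort_values(["is_decoy", "peptide", score_col, "spec_id"],
                            ascending=[True, True, False, True], kind="mergesort")
    best = ranked.drop_duplicates(["is_decoy", "peptide"], keep="first")
    return PSMTable(best.reset_index(drop=True), psms.feature_columns, psms.score_column)


def count_peptides_at_fdr(psms: PSMTable, q_cutoff: float = 0.01,
                          score_col: str = "score") -> int:
    """Distinct target peptides accepted at peptide-level FDR ``q_cutoff``."""
    uni = uniquify_peptides(psms, score_col=score_col)
    uni = qvalues(uni, score_col=score_col)
    return int(len(accepted_at(uni, q_cutoff)))


def build_pu_from_psms(psms: PSMTable, q_cutoff: float = 0.01):
    """PU construction: P = targets accepted at stage-1 FDR ``q_cutoff``,
    U = everything else (weak targets and decoys).

    Returns ``(FeatureTable, PULabels, PSMTable-with-q)``.  The feature
    table carries the PIN features unchanged: no imputation, no feature
    selection for MS/MS data.  Raises when |P| < 10.
    """
    scored = qvalues(psms)
    df = scored.df
    if df.spec_id.duplicated().any():
        raise ValueError("duplicate spectrum ids; run best_psm_per_spectrum first")
    p_ids = set(df.loc[(~df.is_decoy) & (df.q < q_cutoff), "spec_id"])
    if len(p_ids) < 10:
        raise ValueError(f"|P| < 10 at q < {q_cutoff} (got {len(p_ids)}); "
                         f"cannot train the PU loop")
    u_ids = set(df.spec_id) - p_ids
    feats = df.set_index("spec_id")[scored.feature_columns].astype(float)
    table = FeatureTable(feats, numeric=list(scored.feature_columns), categorical=[])
    labels = PULabels(P=frozenset(p_ids), U=frozenset(u_ids))
    return table, labels, scored


def rescore_and_count(psms: PSMTable, config: PlatoConfig, q_cutoff: float = 0.01):
    """Rescore PSMs with the PU loop and count peptides at ``q_cutoff``.

    The stage-1 accepted targets form P; the PU loop scores U and each
    PSM's new score is its mean predicted positive probability over the
    bootstrap runs in which it was scored (members of P keep score 1.0; a
    sample consumed as a likely negative in every run scores 0).  Peptide
    uniquification and the q-value sweep are then applied to the new score.
    Feature selection is always disabled here (MS/MS mode).

    Returns ``(n_peptides_accepted, rescored PSMTable, PlatoRunReport)``.
    """
    table, labels, scored = build_pu_from_psms(psms, q_cutoff=q_cutoff)
    cfg = config.replace(feature_selection=False)
    report = run_plato(table, labels, cfg)

    df = scored.df.copy()
    new_score = np.empty(len(df))
    for i, sid in enumerate(df.spec_id):
        if sid in labels.P:
            new_score[i] = 1.0
        else:
            new_score[i] = report.mean_score.get(sid, 0.0)
    df["stage1_score"] = df["score"]
    df["plato_score"] = new_score
    df["score"] = new_score
    rescored = PSMTable(df, scored.feature_columns, "plato_score")
    rescored = qvalues(rescored)
    rescored.df.rename(columns={"q": "psm_q", "fdr": "psm_fdr"}, inplace=True)

    uni = uniquify_peptides(rescored)
    uni = qvalues(uni)
    pep_q = dict(zip(uni.df.set_index(["is_decoy", "peptide"]).index, uni.df.q))
    rescored.df["peptide_q"] = [
        pep_q.get((d, p), np.nan)
        for d, p in zip(rescored.df.is_decoy, rescored.df.peptide)
    ]
    n_accepted = int(len(accepted_at(uni, q_cutoff)))
    log.info("rescoring: |P|=%d, |U|=%d, peptides at q<%g: %d",
             len(labels.P), len(labels.U), q_cutoff, n_accepted)
    return n_accepted, rescored, report


def write_rescored(psms: PSMTable, path) -> None:
    """Tab-separated rescored PSM table."""
    cols = ["spec_id", "is_decoy", "peptide", "stage1_score", "plato_score",
            "psm_q", "peptide_q"]
    out = psms.df[[c for c in cols if c in psms.df.columns]].copy()
    out.insert(1, "Label", np.where(psms.df.is_decoy, -1, 1))
    out.drop(columns=["is_decoy"]).to_csv(path, sep="\t", index=False,
                                          float_format="%.6g")
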