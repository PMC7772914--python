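import numpy as np
import pandas as pd
import pytest

from plato.datasets import PlatoConfig
from plato.msms import (PSMTable, accepted_at, best_psm_per_spectrum,
                        build_pu_from_psms, count_peptides_at_fdr,
                        fdr_at_threshold, qvalues, read_pin, rescore_and_count,
                        strip_flanks, uniquify_peptides, write_pin)
from plato.synthetic import gen_psm_fixture


def brute_force_qvalues(scores, is_decoy):
    """Quadratic oracle: q(s) = min over thresholds t ≤ s of
    (1 + #decoys ≥ t) / (#targets ≥ t), evaluated on observed scores."""
    scores = np.asarray(scores, float)
    is_decoy = np.asarray(is_decoy, bool)
    thresholds = np.unique(scores)
    q = np.empty(len(scores))
    for i, s in enumerate(scores):
        fdrs = []
        for t in thresholds[thresholds <= s]:
            n_t = int(((scores >= t) & ~is_decoy).sum())
            n_d = int(((scores >= t) & is_decoy).sum())
            if n_t > 0:
                fdrs.append((1 + n_d) / n_t)
        q[i] = min(fdrs) if fdrs else np.inf
    return np.minimum(q, 1.0)


def _psms_from(scores, is_decoy, peptides=None):
    n = len(scores)
    peptides = peptides or [f"PEP{i:03d}" for i in range(n)]
    df = pd.DataFrame({
        "spec_id": [f"sp{i:03d}" for i in range(n)],
        "scan": np.arange(n),
        "is_decoy": np.asarray(is_decoy, bool),
        "peptide": peptides,
        "peptide_raw": [f"K.{p}.A" for p in peptides],
        "proteins": "prot",
        "s": np.asarray(scores, float),
        "score": np.asarray(scores, float),
    })
    return PSMTable(df, feature_columns=["s"], score_column="s")


class TestPinIO:
    def test_strip_flanks(self):
        assert strip_flanks("K.PEPTIDER.A") == "PEPTIDER"
        assert strip_flanks("-.PEPTIDER.-") == "PEPTIDER"
        assert strip_flanks("PEPTIDER") == "PEPTIDER"

    def test_round_trip(self, psm_table, tmp_path):
        psms, _ = psm_table
        path = tmp_path / "f.pin"
        write_pin(psms, path)
        back = read_pin(path, score_column="lnEValue")
        assert len(back) == len(psms)
        assert list(back.df.spec_id) == list(psms.df.spec_id)
        assert list(back.df.is_decoy) == list(psms.df.is_decoy)
        assert list(back.df.peptide) == list(psms.df.peptide)
        for c in psms.feature_columns:
            np.testing.assert_allclose(back.df[c], psms.df[c])

    def test_invalid_label_rejected(self, tmp_path):
        path = tmp_path / "bad.pin"
        path.write_text("SpecId\tLabel\tScanNr\tscore\tPeptide\tProteins\n"
                        "s1\t0\t1\t2.5\tK.PEPTIDE.R\tp1\n")
        with pytest.raises(ValueError, match="Label"):
            read_pin(path)

    def test_malformed_header_rejected(self, tmp_path):
        path = tmp_path / "bad.pin"
        path.write_text("id\tLabel\tScanNr\tscore\tPeptide\tProteins\ns1\t1\t1\t2\tA.B.C\tp\n")
        with pytest.raises(ValueError, match="header"):
            read_pin(path)

    def test_non_numeric_feature_rejected(self, tmp_path):
        path = tmp_path / "bad.pin"
        path.write_text("SpecId\tLabel\tScanNr\tscore\tPeptide\tProteins\n"
                        "s1\t1\t1\toops\tK.PEP.R\tp1\n")
        with pytest.raises(ValueError, match="non-numeric"):
            read_pin(path)

    def test_default_direction_row_skipped(self, tmp_path):
        path = tmp_path / "dd.pin"
        path.write_text("SpecId\tLabel\tScanNr\tscore\tPeptide\tProteins\n"
                        "DefaultDirection\t1\t0\t1\t-\t-\n"
                        "s1\t1\t1\t2.5\tK.PEP.R\tp1\n")
        assert len(read_pin(path)) == 1


class TestBestPerSpectrum:
    def test_unique_spectra_unchanged(self, psm_table):
        psms, _ = psm_table
        assert len(best_psm_per_spectrum(psms)) == len(psms)

    def test_highest_score_wins(self):
        p = _psms_from([2.0, 5.0], [False, False])
        p.df.loc[:, "spec_id"] = "same"
        best = best_psm_per_spectrum(p)
        assert len(best) == 1 and best.df.iloc[0]["s"] == 5.0

    def test_matches_group_by_max_oracle(self):
        rng = np.random.default_rng(2)
        n = 200
        p = _psms_from(rng.normal(size=n), rng.random(n) < 0.5)
        p.df["spec_id"] = [f"sp{int(i)}" for i in rng.integers(0, 60, size=n)]
        best = best_psm_per_spectrum(p)
        expected = p.df.groupby("spec_id")["s"].max()
        assert len(best) == len(expected)
        got = best.df.set_index("spec_id")["s"]
        for sid, smax in expected.items():
            assert got[sid] == smax

    def test_tie_prefers_target_over_decoy(self):
        p = _psms_from([1.0, 1.0], [True, False], peptides=["AAA", "BBB"])
        p.df.loc[:, "spec_id"] = "same"
        best = best_psm_per_spectrum(p)
        assert not best.df.iloc[0]["is_decoy"]


class TestFdr:
    def test_forced_example_no_decoys(self):
        scores = list(np.linspace(1, 2, 99)) + [0.5]
        decoy = [False] * 99 + [True]
        p = _psms_from(scores, decoy)
        assert fdr_at_threshold(p, 1.0) == pytest.approx(1 / 99)

    def test_equal_counts_capped_at_one(self):
        p = _psms_from([1.0, 1.0], [False, True])
        assert fdr_at_threshold(p, 1.0) == 1.0
        assert fdr_at_threshold(p, 1.0, cap=False) == pytest.approx(2.0)

    def test_no_targets_above_threshold_not_available(self):
        p = _psms_from([1.0, 5.0], [False, True])
        assert fdr_at_threshold(p, 2.0) is None

    def test_matches_brute_force_counting(self):
        rng = np.random.default_rng(3)
        s = rng.normal(size=80)
        d = rng.random(80) < 0.4
        p = _psms_from(s, d)
        for t in rng.choice(s, size=10, replace=False):
            n_t = int(((s >= t) & ~d).sum())
            expect = min(1.0, (1 + int(((s >= t) & d).sum())) / n_t)
            assert fdr_at_threshold(p, t) == pytest.approx(expect)


class TestQValues:
    def test_separated_classes_all_targets_share_min_q(self):
        # all decoys strictly below all targets → every target q = 1/n
        p = _psms_from(list(range(10, 30)) + list(range(10)),
                       [False] * 20 + [True] * 10)
        q = qvalues(p).df
        assert np.allclose(q.loc[~q.is_decoy, "q"], 1 / 20)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_quadratic_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 50
        s = np.round(rng.normal(size=n), 2)  # rounding forces score ties
        d = rng.random(n) < 0.5
        got = qvalues(_psms_from(s, d)).df["q"].to_numpy()
        np.testing.assert_allclose(got, brute_force_qvalues(s, d))

    def test_monotone_non_increasing_in_score(self):
        rng = np.random.default_rng(9)
        s = rng.normal(size=200)
        d = rng.random(200) < 0.5
        q = qvalues(_psms_from(s, d)).df
        order = np.argsort(s)
        qs = q["q"].to_numpy()[order]
        assert (np.diff(qs) <= 1e-12).all()


class TestUniquify:
    def test_distinct_peptides_unchanged(self, psm_table):
        psms, _ = psm_table
        assert len(uniquify_peptides(psms)) == len(psms)

    def test_repeated_peptide_keeps_best(self):
        p = _psms_from([1.0, 3.0, 2.0], [False] * 3, peptides=["AAA"] * 3)
        uni = uniquify_peptides(p)
        assert len(uni) == 1 and uni.df.iloc[0]["s"] == 3.0

    def test_matches_group_by_max_on_peptide(self):
        rng = np.random.default_rng(4)
        n = 150
        peps = [f"P{int(i)}" for i in rng.integers(0, 40, size=n)]
        p = _psms_from(rng.normal(size=n), rng.random(n) < 0.5, peptides=peps)
        uni = uniquify_peptides(p)
        expected = p.df.groupby(["is_decoy", "peptide"])["s"].max()
        assert len(uni) == len(expected)
        for (d, pep), smax in expected.items():
            row = uni.df[(uni.df.is_decoy == d) & (uni.df.peptide == pep)]
            assert row.iloc[0]["s"] == smax

    def test_peptide_level_count_never_exceeds_psm_level(self, psm_table):
        psms, _ = psm_table
        best = best_psm_per_spectrum(psms)
        scored = qvalues(best)
        n_psm = len(accepted_at(scored, 0.05))
        uni = qvalues(uniquify_peptides(best))
        n_pep = len(accepted_at(uni, 0.05))
        assert n_pep <= n_psm


class TestPuConstruction:
    def test_dominating_targets_form_p(self, psm_table):
        psms, truth = psm_table
        table, labels, scored = build_pu_from_psms(best_psm_per_spectrum(psms))
        assert len(labels.P) >= 10
        # P members are all true targets in a well-separated fixture
        assert all(truth[sid] for sid in labels.P)

    def test_decoys_never_in_p(self, psm_table):
        psms, _ = psm_table
        _, labels, scored = build_pu_from_psms(best_psm_per_spectrum(psms))
        decoy_ids = set(scored.df.loc[scored.df.is_decoy, "spec_id"])
        assert not (labels.P & decoy_ids)
        assert decoy_ids <= labels.U

    def test_zero_cutoff_rejected(self, psm_table):
        psms, _ = psm_table
        with pytest.raises(ValueError, match=r"\|P\| < 10"):
            build_pu_from_psms(best_psm_per_spectrum(psms), q_cutoff=0.0)


class TestRescoring:
    def test_end_to_end_improves_or_matches_stage1(self, psm_table):
        """With informative auxiliary features the PU rescoring must not
        lose peptides relative to the stage-1 search score."""
        psms, truth = psm_table
        best = best_psm_per_spectrum(psms)
        n_stage1 = count_peptides_at_fdr(best, 0.01)
        cfg = PlatoConfig(N=3, classifier_mode="random_forest", seed=1)
        n_plato, rescored, report = rescore_and_count(best, cfg, q_cutoff=0.01)
        assert n_plato >= n_stage1
        assert {"stage1_score", "plato_score", "psm_q", "peptide_q"} <= \
            set(rescored.df.columns)
        # P members keep probability 1.0
        assert (rescored.df.plato_score == 1.0).sum() >= 10

    def test_single_bootstrap_smoke(self, psm_table):
        psms, _ = psm_table
        best = best_psm_per_spectrum(psms)
        cfg = PlatoConfig(N=1, classifier_mode="random_forest", seed=2)
        n, rescored, _ = rescore_and_count(best, cfg)
        assert n >= 0 and len(rescored) == len(best)
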