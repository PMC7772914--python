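import numpy as np
import pandas as pd
import pytest

from plato.datasets import FeatureTable
from plato.preprocess import filter_missing, impute, select_features


def _ft(df, numeric=None, categorical=None):
    numeric = numeric if numeric is not None else list(df.columns)
    categorical = categorical or []
    return FeatureTable(df, numeric, categorical)


class TestFilterMissing:
    def test_complete_table_unchanged(self, mixed_table):
        filtered, report = filter_missing(mixed_table)
        assert filtered.n_samples == mixed_table.n_samples
        assert not report.dropped_features and not report.dropped_samples

    def test_mostly_missing_column_dropped(self):
        df = pd.DataFrame({
            "good": [1.0, 2.0, 3.0, 4.0],
            "bad": [1.0, np.nan, np.nan, np.nan],   # 3/4 missing
        }, index=list("abcd"))
        filtered, report = filter_missing(_ft(df))
        assert report.dropped_features == ["bad"]
        assert filtered.feature_names == ["good"]

    def test_exactly_half_missing_is_kept(self):
        df = pd.DataFrame({"x": [1.0, np.nan], "y": [1.0, 2.0]}, index=["a", "b"])
        filtered, report = filter_missing(_ft(df))
        assert "x" in filtered.feature_names
        assert not report.dropped_samples

    def test_columns_dropped_before_rows(self):
        # hand-applied rule on a crafted 10x10: columns c7..c9 are >50%
        # missing and must go first; afterwards only row r9 exceeds 50%
        rng = np.random.default_rng(0)
        data = rng.normal(size=(10, 10))
        df = pd.DataFrame(data, index=[f"r{i}" for i in range(10)],
                          columns=[f"c{i}" for i in range(10)])
        for c in ("c7", "c8", "c9"):
            df.loc[df.index[:6], c] = np.nan          # 6/10 missing → drop
        df.loc["r9", ["c0", "c1", "c2", "c3"]] = np.nan  # 4/7 of surviving cols
        filtered, report = filter_missing(_ft(df))
        assert report.dropped_features == ["c7", "c8", "c9"]
        assert report.dropped_samples == ["r9"]
        # had rows been dropped first, r9 (4/10 missing) would have survived
        # with all 10 columns; the column-first order is what rescues it only
        # when its missingness is concentrated in surviving columns
        assert filtered.n_samples == 9 and filtered.n_features == 7

    def test_idempotent(self):
        df = pd.DataFrame({
            "good": [1.0, 2.0, 3.0, 4.0],
            "bad": [1.0, np.nan, np.nan, np.nan],
        }, index=list("abcd"))
        once, _ = filter_missing(_ft(df))
        twice, report = filter_missing(once)
        assert twice.equals(once)
        assert not report.dropped_features and not report.dropped_samples

    def test_all_columns_dropped_is_error(self):
        df = pd.DataFrame({"x": [np.nan, np.nan, 1.0]}, index=list("abc"))
        with pytest.raises(ValueError, match="all feature columns"):
            filter_missing(_ft(df))


class TestImpute:
    def test_complete_table_identical(self, mixed_table):
        complete = mixed_table.subset(["s0", "s1", "s5"])
        out, model = impute(complete, seed=0)
        assert out.equals(complete)
        assert model.iterations == 0

    def test_constant_column_filled_with_constant(self):
        df = pd.DataFrame({
            "const": [7.0, 7.0, 7.0, np.nan],
            "other": [1.0, 2.0, 3.0, 4.0],
        }, index=list("abcd"))
        out, _ = impute(_ft(df), seed=0)
        assert out.data.loc["d", "const"] == pytest.approx(7.0)

    def test_deterministic_function_recovered_within_tolerance(self):
        """A masked column that is a deterministic function of two others
        must be recovered with mean abs error below the column's sd."""
        rng = np.random.default_rng(1)
        n = 120
        a, b = rng.normal(size=n), rng.normal(size=n)
        target = 2.0 * a - b
        df = pd.DataFrame({"a": a, "b": b, "t": target},
                          index=[f"s{i}" for i in range(n)])
        mask = rng.random(n) < 0.2
        truth = df.loc[mask, "t"].copy()
        df.loc[mask, "t"] = np.nan
        out, _ = impute(_ft(df), seed=2)
        mae = (out.data.loc[truth.index, "t"] - truth).abs().mean()
        assert mae < np.std(target)

    def test_numeric_fill_within_observed_range_and_levels_observed(self):
        rng = np.random.default_rng(3)
        n = 60
        df = pd.DataFrame({
            "x": rng.uniform(10, 20, size=n),
            "c": rng.choice(["u", "v"], size=n),
            "z": rng.normal(size=n),
        }, index=[f"s{i}" for i in range(n)])
        df.loc[df.index[:10], "x"] = np.nan
        df.loc[df.index[10:20], "c"] = np.nan
        t = FeatureTable(df, ["x", "z"], ["c"])
        out, _ = impute(t, seed=4)
        assert not out.has_missing()
        filled = out.data.loc[df.index[:10], "x"]
        assert (filled >= df["x"].min()).all() and (filled <= df["x"].max()).all()
        assert set(out.data["c"]) <= {"u", "v"}

    def test_fully_missing_column_is_error(self):
        df = pd.DataFrame({"x": [np.nan, np.nan], "y": [1.0, 2.0]}, index=["a", "b"])
        with pytest.raises(ValueError, match="no observed values"):
            impute(_ft(df), seed=0)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"x": rng.normal(size=40), "y": rng.normal(size=40)},
                          index=[f"s{i}" for i in range(40)])
        df.loc[df.index[:8], "x"] = np.nan
        a, _ = impute(_ft(df), seed=9)
        b, _ = impute(_ft(df), seed=9)
        assert a.equals(b)


class TestSelectFeatures:
    def _labeled(self, n=120, seed=0):
        rng = np.random.default_rng(seed)
        y = np.r_[np.ones(n // 2, int), np.zeros(n // 2, int)]
        df = pd.DataFrame({
            "informative": y * 3.0 + rng.normal(size=n),
            "noise": rng.normal(size=n),
        }, index=[f"s{i}" for i in range(n)])
        return _ft(df), y

    def test_informative_beats_noise_across_seeds(self):
        hits = 0
        for seed in range(20):
            table, y = self._labeled(seed=seed)
            sel = select_features(table, dict(zip(table.sample_ids, y)),
                                  seed=seed, n_estimators=100)
            hits += sel == ["informative"]
        assert hits >= 19  # ≥95%

    def test_single_feature_returned_with_warning(self):
        df = pd.DataFrame({"only": [1.0, 2.0, 3.0, 4.0]}, index=list("abcd"))
        sel = select_features(_ft(df), {"a": 1, "b": 1, "c": 0, "d": 0}, seed=0)
        assert sel == ["only"]

    def test_identical_copies_tie_break_by_name(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=40)
        y = (base > 0).astype(int)
        df = pd.DataFrame({f"f{i}": base for i in range(5)},
                          index=[f"s{i}" for i in range(40)])
        sel = select_features(_ft(df), dict(zip(df.index, y)), seed=0)
        assert len(sel) == 3  # ceil(5/2)
        assert all(s in df.columns for s in sel)

    def test_returns_exactly_half_rounded_up(self):
        rng = np.random.default_rng(1)
        n, d = 60, 7
        y = rng.integers(0, 2, size=n)
        df = pd.DataFrame(rng.normal(size=(n, d)),
                          columns=[f"f{i}" for i in range(d)],
                          index=[f"s{i}" for i in range(n)])
        sel = select_features(_ft(df), dict(zip(df.index, y)), seed=1)
        assert len(sel) == 4 and len(set(sel)) == 4
        assert set(sel) <= set(df.columns)

    def test_missing_cells_rejected(self):
        df = pd.DataFrame({"x": [1.0, np.nan], "y": [0.0, 1.0]}, index=["a", "b"])
        with pytest.raises(ValueError, match="complete"):
            select_features(_ft(df), {"a": 1, "b": 0}, seed=0)
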