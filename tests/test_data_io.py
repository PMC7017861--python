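import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import wetstate as ws
from wetstate.data_io import MISSING, DataError
from wetstate.simulate import study_like_config, simulate_study


def _write_toy(tmp_path, codes):
    hist = pd.DataFrame(codes, columns=["site_id", "year", "survey", "code"])
    hist.to_csv(tmp_path / "h.csv", index=False)
    sites = sorted(set(hist["site_id"]))
    pd.DataFrame({"site_id": sites, "depth_class": [2] * len(sites),
                  "veg_ave": [40.0] * len(sites)}).to_csv(
        tmp_path / "s.csv", index=False)
    years = range(hist["year"].min(), hist["year"].max() + 1)
    recs = [(s, y, 50.0, 200.0, 170.0, 300.0) for s in sites for y in years]
    pd.DataFrame(recs, columns=["site_id", "year", "veg", "precip", "evap",
                                "runoff"]).to_csv(tmp_path / "sy.csv", index=False)
    return tmp_path / "h.csv", tmp_path / "s.csv", tmp_path / "sy.csv"


class TestReadStudyData:
    def test_toy_ingestion_infers_years_and_missingness(self, tmp_path):
        rows = [("a", 2006, 1, 0), ("a", 2006, 2, 0), ("a", 2008, 1, 2),
                ("b", 2006, 1, 1), ("b", 2007, 1, 1), ("b", 2008, 2, 1),
                ("c", 2007, 1, 2), ("c", 2007, 2, 1), ("c", 2008, 1, 2)]
        data = ws.read_study_data(*_write_toy(tmp_path, rows))
        assert data.n_years == 3 and data.n_sites == 3
        assert list(data.years) == [2006, 2007, 2008]
        # site a, 2007 entirely unsurveyed
        assert (data.obs[0, 1] == MISSING).all()
        assert data.obs[2, 1, 0] == 2 and data.obs[2, 1, 1] == 1
        assert data.obs[1, 2, 0] == MISSING and data.obs[1, 2, 1] == 1

    def test_unknown_code_names_line(self, tmp_path):
        rows = [("a", 2006, 1, 0), ("a", 2007, 1, 3)]
        paths = _write_toy(tmp_path, rows)
        with pytest.raises(DataError, match="line 3"):
            ws.read_study_data(*paths)

    def test_round_trip_identity(self, tmp_path):
        truth = simulate_study(study_like_config(n_sites=25, n_years=6), seed=3)
        d = truth.data
        paths = (tmp_path / "h.csv", tmp_path / "s.csv", tmp_path / "sy.csv")
        ws.write_study_data(d, *paths)
        d2 = ws.read_study_data(*paths)
        assert np.array_equal(d.obs, d2.obs)
        assert list(d.site_ids) == list(d2.site_ids)
        assert np.allclose(d.depth_class, d2.depth_class)
        assert np.allclose(d.veg_ave, d2.veg_ave)
        for name, arr in d.site_year.items():
            assert np.allclose(arr, d2.site_year[name], equal_nan=True)


class TestValidation:
    def test_clean_data_passes(self, small_truth):
        report = ws.validate_study_data(small_truth.data)
        assert report.ok and report.n_sites_dropped == 0

    def test_dry_wet_mix_is_error(self, small_truth):
        d = small_truth.data.subset(np.arange(5))
        d.obs[1, 2] = [0, 2]
        report = ws.validate_study_data(d)
        assert len(report.errors) == 1
        assert report.errors[0][0] == d.site_ids[1]

    def test_single_year_site_excluded(self, small_truth):
        d = small_truth.data.subset(np.arange(5))
        d.obs[3, :, :] = MISSING
        d.obs[3, 2] = [1, 1]
        report = ws.validate_study_data(d)
        assert d.site_ids[3] in report.excluded_sites
        assert report.n_sites_dropped == 1
        kept = ws.apply_exclusions(d, report)
        assert kept.n_sites == 4

    def test_flags_exactly_the_violating_rows(self, small_truth):
        # brute-force row scan as independent oracle
        d = small_truth.data.subset(np.arange(12))
        d.obs[2, 1] = [0, 1]
        d.obs[7, 4] = [0, 2]
        expected = set()
        for i in range(d.n_sites):
            for j in range(d.n_years):
                codes = [c for c in d.obs[i, j] if c != MISSING]
                if 0 in codes and any(c in (1, 2) for c in codes):
                    expected.add((d.site_ids[i], int(d.years[j])))
        report = ws.validate_study_data(d)
        assert {(e[0], e[1]) for e in report.errors} == expected


class TestAggregateClimate:
    def test_window_sum(self):
        monthly = pd.DataFrame({"site_id": ["a"] * 3, "year": [2006] * 3,
                                "month": [4, 5, 6], "value": [10.0, 20.0, 30.0]})
        out = ws.aggregate_climate(monthly, window={4, 5, 6})
        assert out["total"].iloc[0] == 60.0

    def test_missing_month_errors(self):
        monthly = pd.DataFrame({"site_id": ["a"] * 2, "year": [2006] * 2,
                                "month": [4, 6], "value": [10.0, 30.0]})
        with pytest.raises(DataError, match="a year 2006"):
            ws.aggregate_climate(monthly, window={4, 5, 6})

    def test_annual_sum(self):
        monthly = pd.DataFrame({"site_id": ["a"] * 12, "year": [2006] * 12,
                                "month": range(1, 13), "value": [1.0] * 12})
        out = ws.aggregate_climate(monthly, mode="annual-sum")
        assert out["total"].iloc[0] == 12.0


class TestScreenCollinearity:
    def test_perfect_correlation_flagged(self):
        df = pd.DataFrame({"x": [1.0, 2, 3], "y": [2.0, 4, 6]})
        flagged = ws.screen_collinearity(df)
        assert flagged == [("x", "y", pytest.approx(1.0))]

    def test_threshold_is_inclusive(self):
        # construct a pair with r exactly 0.60
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = 0.6 * x + 0.8 * np.array([1.0, 1.0, -1.0, -1.0])
        df = pd.DataFrame({"x": x, "y": y})
        r = float(np.corrcoef(x, y)[0, 1])
        assert r == pytest.approx(0.60, abs=1e-12)
        # flagged at a threshold equal to r itself: the comparison is inclusive
        assert len(ws.screen_collinearity(df, threshold=r)) == 1

    def test_independent_draws_not_flagged(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=1000), "y": rng.normal(size=1000)})
        # cross-check against the textbook Pearson formula
        x, y = df["x"] - df["x"].mean(), df["y"] - df["y"].mean()
        r = (x * y).sum() / np.sqrt((x ** 2).sum() * (y ** 2).sum())
        assert abs(r) < 0.1
        assert ws.screen_collinearity(df) == []

    @given(a=st.floats(0.1, 10), b=st.floats(-5, 5), flip=st.booleans())
    @settings(max_examples=25, deadline=None)
    def test_affine_invariance_and_symmetry(self, a, b, flip):
        base = np.array([0.3, -1.2, 2.4, 0.9, -0.5, 1.8])
        other = np.array([1.0, 0.2, 2.2, 1.4, -0.1, 1.1])
        df1 = pd.DataFrame({"x": base, "y": other})
        df2 = pd.DataFrame({"x": other, "y": a * base + b} if flip
                           else {"x": a * base + b, "y": other})
        f1 = ws.screen_collinearity(df1, threshold=0.0)
        f2 = ws.screen_collinearity(df2, threshold=0.0)
        assert f1[0][2] == pytest.approx(abs(f2[0][2]) * np.sign(f1[0][2]), abs=1e-9)

    def test_constant_covariate_flagged_for_review(self):
        df = pd.DataFrame({"x": [1.0, 1.0, 1.0], "y": [1.0, 2.0, 3.0]})
        flagged = ws.screen_collinearity(df)
        assert len(flagged) == 1 and np.isnan(flagged[0][2])


class TestMarkExport:
    def test_direct_mapping(self, tmp_path):
        d = simulate_study(study_like_config(n_sites=3, n_years=2), seed=0).data
        d.obs[0] = [[2, 2], [MISSING, MISSING]]
        d.obs[1] = [[MISSING] * 2] * 2
        path = tmp_path / "mark.inp"
        ws.export_mark_histories(d, path)
        lines = path.read_text().splitlines()
        assert lines[0].endswith("22.. 1;")
        assert lines[1].endswith(".... 1;")

    def test_round_trip(self, tmp_path, small_truth):
        path = tmp_path / "mark.inp"
        ws.export_mark_histories(small_truth.data, path)
        ids, obs = ws.import_mark_histories(path, small_truth.data.n_surveys)
        assert np.array_equal(obs, small_truth.data.obs)
        assert list(ids) == list(small_truth.data.site_ids)
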