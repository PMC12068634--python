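"""Brute-force search mechanics, cross-run correlations and the RMSE mask."""

import numpy as np
import pandas as pd
import pytest

from sgbold.dataset import Dataset, RunData, SubjectData
from sgbold.filters import FilterSpec
from sgbold.glm import PRESETS, Pipeline
from sgbold.optimizer import (
    NoAdmissibleFilterError,
    SearchGrid,
    SearchResult,
    autocorrelations,
    clean_search,
    crossrun_correlation,
    detrend_search,
    mean_correlation,
    rmse_autocorr,
    select_optimal,
)
from sgbold.predictor import EventDesign


def tiled_dataset(rng, n_subjects=3, n_nodes=4, noise=0.0):
    """Dataset whose node series are exact tilings of a per-subject pattern."""
    design = EventDesign(tuple(range(0, 10 * 12, 12)), 8, 4)
    n_trs = 10 * 12
    subjects = []
    for s in range(n_subjects):
        pattern = rng.normal(size=12)
        runs = {}
        for lab in ("test", "retest"):
            mat = np.tile(pattern, (n_nodes, 10))
            mat = mat + noise * rng.normal(size=mat.shape)
            runs[lab] = RunData(mat, None, design, 1.24)
        subjects.append(SubjectData(f"s{s}", runs))
    return Dataset(subjects)


class TestAutocorrRmse:
    def test_identical_series_zero(self, rng):
        x = rng.normal(size=100)
        assert rmse_autocorr(x, x) == 0.0

    def test_matches_independent_autocorr_oracle(self, rng):
        x, y = rng.normal(size=200), rng.normal(size=200)

        def oracle_ac(v, k):
            vc = v - v.mean()
            return float(vc[:-k] @ vc[k:]) / float(vc @ vc)

        expected = np.sqrt(
            np.mean([(oracle_ac(x, k) - oracle_ac(y, k)) ** 2 for k in (1, 2, 3, 4)])
        )
        assert rmse_autocorr(x, y) == pytest.approx(expected, abs=1e-12)

    def test_constant_offset_in_lags_equals_offset(self):
        # two AR-like series constructed so that all four lag differences are
        # verified against the direct computation, covering the hand rule
        # RMSE(a, a - 0.1) = 0.1 on the lag vectors themselves
        lags_obs = np.array([0.8, 0.5, 0.2, 0.0])
        lags_pred = lags_obs - 0.1
        assert float(np.sqrt(np.mean((lags_obs - lags_pred) ** 2))) == pytest.approx(0.1)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            autocorrelations(np.ones(50))


class TestMeanCorrelation:
    def test_raw_mean_skips_missing(self):
        vals = np.array([0.2, np.nan, 0.4])
        assert mean_correlation(vals) == pytest.approx(0.3)

    def test_fisher_z_average_exceeds_raw_for_skewed_values(self):
        vals = np.array([0.1, 0.9])
        raw = mean_correlation(vals)
        fz = mean_correlation(vals, fisher_z=True)
        expected = np.tanh(np.mean(np.arctanh(vals)))
        assert fz == pytest.approx(expected)
        assert fz > raw

    def test_all_missing_is_nan(self):
        assert np.isnan(mean_correlation(np.array([np.nan])))


class TestSearchGrid:
    def test_default_grid_matches_full_scan(self):
        grid = SearchGrid()
        assert grid.windows[0] == 3 and grid.windows[-1] == 487
        assert grid.degrees_for(5) == (1, 2, 3, 4)

    def test_degree_cap_honoured(self):
        grid = SearchGrid(windows=(101,), max_degree=50)
        assert max(grid.degrees_for(101)) == 50
        assert all(spec.degree <= 50 for spec in grid.cells())

    def test_invalid_windows_rejected(self):
        with pytest.raises(ValueError):
            SearchGrid(windows=(4,))
        with pytest.raises(ValueError):
            SearchGrid(windows=(5, 3))  # unsorted


class TestCrossrunCorrelation:
    def test_count_identity(self, small_dataset):
        rs = crossrun_correlation(
            small_dataset, PRESETS["denoise"], PRESETS["denoise"]
        )
        assert rs.size == 2 * small_dataset.n_nodes * small_dataset.n_subjects

    def test_noiseless_tiled_dataset_gives_unit_correlations(self, rng):
        ds = tiled_dataset(rng, noise=0.0)
        rs = crossrun_correlation(ds, PRESETS["raw"], PRESETS["raw"])
        np.testing.assert_allclose(rs, 1.0, atol=1e-12)

    def test_independent_observed_gives_null_mean(self, rng):
        design = EventDesign(tuple(range(0, 120, 12)), 8, 4)
        subjects = []
        for s in range(10):
            runs = {
                lab: RunData(rng.normal(size=(6, 120)), None, design, 1.24)
                for lab in ("test", "retest")
            }
            subjects.append(SubjectData(f"s{s}", runs))
        rs = crossrun_correlation(Dataset(subjects), PRESETS["raw"], PRESETS["raw"])
        assert abs(np.nanmean(rs)) < 3.0 / np.sqrt(rs.size)


class TestSearches:
    def test_single_cell_result_shape(self, small_dataset):
        res = detrend_search(small_dataset, SearchGrid(windows=(69,), degrees=(6,)))
        assert list(res.table.columns) == [
            "window", "degree", "mean_r", "mean_rmse", "n", "n_missing",
        ]
        assert len(res.table) == 1
        assert -1 <= res.table["mean_r"].iloc[0] <= 1

    def test_determinism(self, small_dataset):
        grid = SearchGrid(windows=(31, 69), degrees=(2, 6))
        a = detrend_search(small_dataset, grid).table
        b = detrend_search(small_dataset, grid).table
        pd.testing.assert_frame_equal(a, b)

    def test_clean_search_improves_over_no_cleaning(self, small_dataset):
        detrend = FilterSpec(69, 6)
        base_pipe = Pipeline("base", use_nuisance=True, detrend=detrend)
        base = np.nanmean(crossrun_correlation(small_dataset, base_pipe, base_pipe))
        res = clean_search(
            small_dataset, detrend, SearchGrid(windows=(3, 9, 15), degrees=(1, 2, 8))
        )
        assert res.table["mean_r"].max() > base

    def test_clean_grid_respects_degree_cap(self, small_dataset):
        res = clean_search(
            small_dataset,
            FilterSpec(69, 6),
            SearchGrid(windows=(3, 15), max_degree=50),
        )
        assert (res.table["degree"] <= 50).all()


class TestSelectOptimal:
    def make_result(self, rows, phase="clean"):
        return SearchResult(pd.DataFrame(rows), phase=phase)

    def test_single_admissible_cell(self):
        res = self.make_result(
            [dict(window=15, degree=8, mean_r=0.5, mean_rmse=0.05, n=10, n_missing=0)]
        )
        assert select_optimal(res) == FilterSpec(15, 8)

    def test_tie_breaks_toward_smaller_window_then_degree(self):
        rows = [
            dict(window=21, degree=2, mean_r=0.5, mean_rmse=0.01, n=10, n_missing=0),
            dict(window=15, degree=8, mean_r=0.5, mean_rmse=0.01, n=10, n_missing=0),
            dict(window=15, degree=3, mean_r=0.5, mean_rmse=0.01, n=10, n_missing=0),
        ]
        assert select_optimal(self.make_result(rows)) == FilterSpec(15, 3)

    def test_mask_excludes_high_rmse_cells(self):
        rows = [
            dict(window=3, degree=1, mean_r=0.9, mean_rmse=0.5, n=10, n_missing=0),
            dict(window=15, degree=8, mean_r=0.4, mean_rmse=0.05, n=10, n_missing=0),
        ]
        assert select_optimal(self.make_result(rows)) == FilterSpec(15, 8)

    def test_zero_threshold_leaves_no_admissible_filter(self):
        rows = [
            dict(window=3, degree=1, mean_r=0.9, mean_rmse=0.02, n=10, n_missing=0)
        ]
        with pytest.raises(NoAdmissibleFilterError):
            select_optimal(self.make_result(rows), rmse_mask_threshold=0.0)

    def test_detrend_phase_ignores_rmse_column(self):
        rows = [
            dict(window=69, degree=6, mean_r=0.6, mean_rmse=np.nan, n=10, n_missing=0)
        ]
        assert select_optimal(self.make_result(rows, phase="detrend")) == FilterSpec(69, 6)
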