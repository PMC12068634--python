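"""Reliability, connectivity, attenuation bound, ICC(2,1) and feasibility."""

import numpy as np
import pandas as pd
import pytest

from sgbold.dataset import Dataset, SubjectData, RunData
from sgbold.glm import PRESETS
from sgbold.metrics import (
    FeasibilitySummary,
    ReliabilityReport,
    connectivity_matrix,
    detectable_connectivity,
    feasibility,
    icc_2_1,
    summary_table,
    timecourse_reliability,
    upper_bound,
)


class TestTimecourseReliability:
    def test_identical_and_negated(self, rng):
        x = rng.normal(size=100)
        assert timecourse_reliability(x, x) == pytest.approx(1.0)
        assert timecourse_reliability(x, -x) == pytest.approx(-1.0)

    def test_independent_white_noise_is_small(self, rng):
        rs = [
            timecourse_reliability(rng.normal(size=487), rng.normal(size=487))
            for _ in range(50)
        ]
        assert np.max(np.abs(rs)) < 0.15

    def test_zero_variance_returns_missing(self):
        assert np.isnan(timecourse_reliability(np.ones(10), np.arange(10.0)))


class TestConnectivityMatrix:
    def test_duplicated_node_gives_unit_offdiagonal(self, rng):
        x = rng.normal(size=100)
        mat = np.vstack([x, x, rng.normal(size=100)])
        corr = connectivity_matrix(mat)
        assert corr[0, 1] == pytest.approx(1.0)

    def test_symmetric_unit_diagonal(self, rng):
        corr = connectivity_matrix(rng.normal(size=(10, 80)))
        np.testing.assert_allclose(corr, corr.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(corr), 1.0)

    def test_study_geometry_path_count(self):
        assert 34 * 33 // 2 == 561

    def test_zero_variance_node_flagged(self, rng):
        mat = rng.normal(size=(4, 50))
        mat[2] = 5.0
        corr = connectivity_matrix(mat)
        assert np.isnan(corr[2, 0]) and np.isnan(corr[0, 2])
        assert corr[2, 2] == 1.0


class TestUpperBound:
    @pytest.mark.parametrize(
        "ra, rb, expected",
        [(0.25, 0.25, 0.25), (0.16, 0.36, 0.24), (1.0, 1.0, 1.0)],
    )
    def test_square_root_of_product(self, ra, rb, expected):
        assert upper_bound(ra, rb) == pytest.approx(expected)

    @pytest.mark.parametrize("ra, rb", [(0.5, 0.0), (0.0, 0.5), (-0.2, 0.9)])
    def test_nonpositive_reliability_is_corrupt(self, ra, rb):
        assert np.isnan(upper_bound(ra, rb))


class TestDetectableConnectivity:
    @pytest.mark.parametrize(
        "obs, ra, rb, value, corrupt, over",
        [
            (0.4, 0.25, 0.25, 0.25, False, True),    # capped, overestimated
            (-0.5, 0.25, 0.25, -0.25, False, True),  # negative branch
            (0.2, 0.25, 0.25, 0.2, False, False),    # within bound
            (0.3, -0.1, 0.5, 0.0, True, False),      # corrupt node A
            (0.3, 0.5, 0.0, 0.0, True, False),       # corrupt node B
            (0.0, 0.5, 0.5, 0.0, False, False),      # exactly zero
        ],
    )
    def test_rule_table(self, obs, ra, rb, value, corrupt, over):
        res = detectable_connectivity(obs, ra, rb)
        assert res.value == pytest.approx(value)
        assert res.corrupt is corrupt
        assert res.overestimated is over

    def test_out_of_range_observation_rejected(self):
        with pytest.raises(ValueError):
            detectable_connectivity(1.5, 0.5, 0.5)

    def test_detectable_never_exceeds_bound(self, rng):
        for _ in range(200):
            obs = rng.uniform(-1, 1)
            ra, rb = rng.uniform(-0.3, 1, size=2)
            res = detectable_connectivity(obs, ra, rb)
            if res.corrupt:
                assert res.value == 0.0
            else:
                assert abs(res.value) <= upper_bound(ra, rb) + 1e-12


class TestIcc:
    def test_perfect_agreement(self):
        assert icc_2_1(np.array([[1, 1], [2, 2], [3, 3.0]])) == pytest.approx(1.0)

    def test_matches_pingouin_oracle(self, rng):
        import pingouin as pg

        for _ in range(5):
            n = int(rng.integers(8, 25))
            data = rng.normal(size=(n, 2)) + rng.normal(size=(n, 1))
            df = pd.DataFrame(
                {
                    "subject": np.repeat(np.arange(n), 2),
                    "session": np.tile([0, 1], n),
                    "value": data.reshape(-1),
                }
            )
            ref = pg.intraclass_corr(df, "subject", "session", "value")
            row = ref["Type"].isin(["ICC2", "ICC(A,1)"])
            ref_icc2 = float(ref.loc[row, "ICC"].iloc[0])
            assert icc_2_1(data) == pytest.approx(ref_icc2, abs=1e-9)

    def test_independent_sessions_near_zero(self, rng):
        data = rng.normal(size=(200, 2))
        assert abs(icc_2_1(data)) < 0.2

    def test_shape_contract(self):
        with pytest.raises(ValueError):
            icc_2_1(np.ones((2, 2)))


def duplicate_run_dataset(base: Dataset) -> Dataset:
    """Retest identical to test: every reliability is exactly 1."""
    subjects = []
    for subj in base.subjects:
        test = subj.test
        runs = {
            lab: RunData(test.matrix.copy(), test.nuisance, test.design, test.tr_seconds)
            for lab in ("test", "retest")
        }
        subjects.append(SubjectData(subj.subject_id, runs))
    return Dataset(subjects)


class TestSummaryTable:
    def test_noiseless_retest_gives_unit_reliability(self, small_dataset):
        ds = duplicate_run_dataset(small_dataset)
        report = summary_table(ds, PRESETS["denoise"])
        summary = report.summary()
        assert summary["grand_mean_reliability"] == pytest.approx(1.0)
        assert summary["pct_corrupt_paths"] == 0.0

    def test_count_identities(self, small_dataset):
        report = summary_table(small_dataset, PRESETS["denoise"])
        s = report.summary()
        n, p = small_dataset.n_subjects, small_dataset.n_nodes
        assert s["n_reliability_values"] == n * p
        assert s["n_path_values"] == n * p * (p - 1) // 2
        assert report.icc_per_path.size == p * (p - 1) // 2

    def test_detectable_bounded_by_upper_bound(self, small_dataset):
        report = summary_table(small_dataset, PRESETS["clean_sg15_8"])
        det = report.path_detectable.to_numpy()
        ub = report.path_upper_bound.to_numpy()
        corrupt = report.path_corrupt.to_numpy()
        assert np.all(det[corrupt] == 0.0)
        ok = ~corrupt
        assert np.all(np.abs(det[ok]) <= ub[ok] + 1e-12)

    def test_sg_cleaning_beats_denoise_only(self, small_dataset):
        rel_clean = summary_table(small_dataset, PRESETS["clean_sg15_8"]).summary()[
            "grand_mean_reliability"
        ]
        rel_denoise = summary_table(small_dataset, PRESETS["denoise"]).summary()[
            "grand_mean_reliability"
        ]
        assert rel_clean > rel_denoise


class TestAttenuationLaw:
    def test_observed_connectivity_matches_bound_for_perfect_coupling(self, rng):
        # two nodes measuring one latent signal with reliabilities rho_a, rho_b
        rho_a, rho_b, n = 0.5, 0.32, 487
        obs = []
        for _ in range(300):
            z = rng.normal(size=n)
            runs = []
            for _run in range(2):
                xa = z + rng.normal(size=n) * np.sqrt((1 - rho_a) / rho_a)
                xb = z + rng.normal(size=n) * np.sqrt((1 - rho_b) / rho_b)
                runs.append(np.corrcoef(xa, xb)[0, 1])
            obs.append(np.mean(runs))
        assert np.mean(obs) == pytest.approx(np.sqrt(rho_a * rho_b), abs=0.02)


def unit_report(n_subjects=5, n_nodes=34):
    n_paths = n_nodes * (n_nodes - 1) // 2
    ids = [f"s{i}" for i in range(n_subjects)]
    ones = lambda cols: pd.DataFrame(1.0, index=ids, columns=cols)
    paths = [f"p{i}" for i in range(n_paths)]
    falses = pd.DataFrame(False, index=ids, columns=paths)
    return ReliabilityReport(
        node_reliability=ones([f"node{i}" for i in range(n_nodes)]),
        path_connectivity=ones(paths),
        path_upper_bound=ones(paths),
        path_detectable=ones(paths),
        path_corrupt=falses,
        path_overestimated=falses.copy(),
        icc_per_path=pd.Series(1.0, index=paths),
        pipeline_name="unit",
    )


class TestFeasibility:
    def test_study_scale_pareto_thresholds(self):
        summary = feasibility(unit_report())
        assert summary.node_threshold == 7     # 20% of 34 nodes
        assert summary.path_threshold == 112   # 20% of 561 paths

    def test_all_perfect_reaches_every_cutoff(self):
        summary = feasibility(unit_report())
        assert all(v == 100.0 for v in summary.pct_subjects_nodes.values())
        assert all(v == 100.0 for v in summary.pct_subjects_paths.values())

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            feasibility(unit_report(), pareto_fraction=0.0)
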