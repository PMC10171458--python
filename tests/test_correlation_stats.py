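"""Spearman correlation, its t-approximation significance, and ICC(2,1)."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from semdwi import (
    classify_correlation, correlate_table, icc, make_specimen_cohort,
    spearman_pvalue, spearman_rho,
)
from semdwi.correlation_stats import correlation_frame, format_report
from semdwi.errors import ConfigurationError, UndefinedStatisticError
from semdwi.roi_extraction import PARAMETER_NAMES, place_roi
from semdwi.synthetic_data import LinkageParams


def local_means(truth, target):
    roi = place_roi(target, truth.voxel_size[0], 105.0, truth.ddc_map.shape)
    ii, jj, kk = roi.indices
    return truth.ddc_map[ii, jj, kk].mean(), truth.alpha_map[ii, jj, kk].mean()


class TestSpearmanRho:
    def test_monotone_increasing_is_one(self, rng):
        x = rng.normal(size=30)
        assert spearman_rho(x, np.exp(x)) == pytest.approx(1.0)

    def test_reversed_is_minus_one(self):
        x = np.arange(10.0)
        assert spearman_rho(x, x[::-1]) == pytest.approx(-1.0)

    def test_ties_match_hand_ranked_pearson(self):
        x, y = [1, 2, 3, 4], [1, 1, 2, 2]
        # midranks: x -> 1,2,3,4; y -> 1.5,1.5,3.5,3.5
        expected = np.corrcoef([1, 2, 3, 4], [1.5, 1.5, 3.5, 3.5])[0, 1]
        assert spearman_rho(x, y) == pytest.approx(expected, rel=1e-12)

    def test_matches_scipy_reference(self, rng):
        for _ in range(50):
            x = rng.integers(0, 6, 25).astype(float)  # heavy ties
            y = rng.normal(size=25)
            assert spearman_rho(x, y) == pytest.approx(
                sps.spearmanr(x, y).statistic, rel=1e-10
            )

    def test_constant_vector_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            spearman_rho([1, 1, 1, 1], [1, 2, 3, 4])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_invariant_under_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        base = spearman_rho(x, y)
        assert spearman_rho(np.exp(x), y ** 3) == pytest.approx(base, rel=1e-12)


class TestSpearmanPvalue:
    def test_null_value_gives_p_one(self):
        assert spearman_pvalue(0.0, 10) == pytest.approx(1.0)

    def test_exact_monotone_returns_zero(self):
        assert spearman_pvalue(1.0, 20) == 0.0
        assert spearman_pvalue(-1.0, 20) == 0.0

    def test_symmetry_in_sign(self):
        assert spearman_pvalue(-0.4, 30) == spearman_pvalue(0.4, 30)

    def test_small_n_rejected(self):
        with pytest.raises(ConfigurationError):
            spearman_pvalue(0.5, 3)

    @pytest.mark.parametrize("n", [6, 7])
    def test_tracks_exact_permutation_null_at_small_n(self, n):
        """Against the exhaustive permutation null, the t-approximation is
        within 0.02 wherever the exact two-tailed p is at most 0.10 (the
        decision-relevant region) and within 0.05 everywhere; the null is
        too coarse at tiny n for tighter agreement at large p."""
        x = np.arange(1.0, n + 1)
        rhos = np.array([
            spearman_rho(x, np.array(p, dtype=float))
            for p in itertools.permutations(range(n))
        ])
        for rho in np.unique(np.round(np.abs(rhos), 12)):
            p_exact = np.mean(np.abs(rhos) >= rho - 1e-9)
            p_t = spearman_pvalue(float(rho), n)
            assert abs(p_t - p_exact) <= 0.05
            if p_exact <= 0.10:
                assert abs(p_t - p_exact) <= 0.02


class TestClassifyCorrelation:
    @pytest.mark.parametrize(
        "rho,label",
        [
            (0.40, "little or fair"),       # boundary inclusive below
            (0.0, "little or fair"),
            (-0.437, "moderate to good"),
            (0.75, "moderate to good"),
            (0.80, "very good to excellent"),
            (-1.0, "very good to excellent"),
        ],
    )
    def test_bins(self, rho, label):
        assert classify_correlation(rho) == label


class TestICC:
    def test_identical_raters_exactly_one(self, rng):
        col = rng.uniform(0, 1, 12)
        res = icc(np.column_stack([col, col]))
        assert res.icc == 1.0
        assert res.agreement == "excellent"

    def test_independent_raters_near_zero(self):
        vals = []
        for seed in range(100):
            r = np.random.default_rng(seed).normal(size=(500, 2))
            vals.append(icc(r).icc)
        vals = np.array(vals)
        assert abs(vals.mean()) <= 0.1
        assert np.mean(np.abs(vals) <= 0.1) >= 0.95

    def test_hand_computed_mean_squares_table(self):
        # 6 subjects x 2 raters; oracle computed from the two-way mean
        # squares by hand:
        #   MSR=10.57, MSC=2.521, MSE=0.4542 (per the layout below)
        table = np.array([
            [7.0, 8.5], [5.0, 6.0], [8.0, 9.0],
            [4.0, 5.5], [9.0, 9.5], [3.0, 4.5],
        ])
        n, k = table.shape
        grand = table.mean()
        msr = k * ((table.mean(1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((table.mean(0) - grand) ** 2).sum() / (k - 1)
        mse = ((table - table.mean(1)[:, None] - table.mean(0)[None] + grand) ** 2).sum() / ((n - 1) * (k - 1))
        expected = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        assert icc(table).icc == pytest.approx(expected, rel=1e-12)

    def test_matches_pingouin_reference(self, rng):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        table = rng.normal(size=(20, 3)) + rng.normal(size=(20, 1))
        df = pd.DataFrame(table, columns=["r1", "r2", "r3"])
        df["subject"] = range(20)
        long = df.melt(id_vars="subject", var_name="rater", value_name="score")
        ref = pg.intraclass_corr(long, targets="subject", raters="rater",
                                 ratings="score")
        # absolute-agreement single-rater row: labelled ICC2 or ICC(A,1)
        # depending on the pingouin version
        row = ref[ref.Type.isin(["ICC2", "ICC(A,1)"])]
        icc2_1 = row["ICC"].iloc[0]
        assert icc(table).icc == pytest.approx(icc2_1, rel=1e-8)

    def test_incomplete_table_rejected(self):
        t = np.ones((6, 2))
        t[0, 0] = np.nan
        with pytest.raises(ConfigurationError):
            icc(t)


class TestCorrelateTable:
    def _params_from_truth(self, truth, targets):
        params = {}
        for t in targets:
            d, a = local_means(truth, t)
            params[(t.target_id, "ddc1500")] = d
            params[(t.target_id, "ddc5000")] = d
            params[(t.target_id, "alpha1500")] = a
            params[(t.target_id, "alpha5000")] = a
        return params

    def test_zero_link_noise_signs_all_negative(self, cohort_inputs):
        truth, _, targets = cohort_inputs
        link = LinkageParams(noise_sd_mib=0.0, noise_sd_cd34=0.0)
        cohort = make_specimen_cohort(truth, targets, link, seed=0, n_missing_mib1=0)
        results = correlate_table(cohort, self._params_from_truth(truth, targets))
        assert len(results) == 12
        driven = [
            r for r in results
            if (r.x_name.startswith("ddc") and r.y_name == "pmib1")
            or (r.x_name.startswith("alpha") and r.y_name == "cd34_mvd")
        ]
        assert len(driven) == 4
        assert all(r.rho < 0 for r in driven)

    def test_per_row_n_reflects_missing_mib1(self, cohort_inputs):
        truth, _, targets = cohort_inputs
        cohort = make_specimen_cohort(truth, targets, seed=0, n_missing_mib1=1)
        results = correlate_table(cohort, self._params_from_truth(truth, targets))
        ns = {r.y_name: r.n for r in results}
        assert ns["pmib1"] == 31
        assert ns["cd34_mvd"] == 32
        assert ns["who_grade"] == 32

    def test_unmatched_specimen_id_rejected(self, cohort_inputs):
        truth, _, targets = cohort_inputs
        cohort = make_specimen_cohort(truth, targets, seed=0)
        params = self._params_from_truth(truth, targets)
        del params[(targets[0].target_id, "ddc1500")]
        with pytest.raises(ConfigurationError):
            correlate_table(cohort, params)

    def test_permutation_null_calibration(self, rng):
        """Shuffling y makes p<0.05 fire at ~5% across permutations."""
        x = rng.normal(size=32)
        y = rng.normal(size=32)
        hits = 0
        n_perm = 1000
        for _ in range(n_perm):
            ys = rng.permutation(y)
            rho = spearman_rho(x, ys)
            hits += spearman_pvalue(rho, 32) < 0.05
        assert hits / n_perm == pytest.approx(0.05, abs=0.02)

    def test_report_layout(self, cohort_inputs):
        truth, _, targets = cohort_inputs
        cohort = make_specimen_cohort(truth, targets, seed=0)
        results = correlate_table(cohort, self._params_from_truth(truth, targets))
        text = format_report(results)
        for token in ("pMIB-1", "CD34-MVD", "WHO grades", "DDC_1500", "alpha_5000"):
            assert token in text
        df = correlation_frame(results)
        assert len(df) == 12
        assert set(df.parameter) == set(PARAMETER_NAMES)
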