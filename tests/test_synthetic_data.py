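"""Phantom generator, Rician noise model and synthetic specimen cohorts."""

import numpy as np
import pytest

from semdwi import (
    LinkageParams, NoiseModel, add_rician_noise, make_biopsy_targets,
    make_phantom, make_specimen_cohort, sem_signal, simulate_fields,
)
from semdwi.correlation_stats import spearman_rho
from semdwi.errors import ConfigurationError
from semdwi.roi_extraction import place_roi
from semdwi.synthetic_data import BACKGROUND, DEFAULT_CLASS_FRACTIONS, HGG_LIKE, LGG_LIKE, NORMAL


def local_means(truth, target):
    roi = place_roi(target, truth.voxel_size[0], 105.0, truth.ddc_map.shape)
    ii, jj, kk = roi.indices
    return truth.ddc_map[ii, jj, kk].mean(), truth.alpha_map[ii, jj, kk].mean()


class TestRicianNoise:
    def test_noiseless_limit_is_identity(self, scheme):
        nm = NoiseModel.from_scheme(scheme, sigma0=0.0)
        s = np.linspace(100, 1, len(scheme))
        np.testing.assert_array_equal(add_rician_noise(s, nm, scheme.b_values), s)

    def test_zero_signal_matches_rayleigh_mean(self):
        # sqrt(n1^2+n2^2) for s=0 is Rayleigh(sigma); mean sigma*sqrt(pi/2)
        sigma = 3.0
        nm = NoiseModel(sigma, {0.0: 1}, seed=42)
        draws = add_rician_noise(np.zeros((200_000, 1)), nm, [0.0])
        expected = sigma * np.sqrt(np.pi / 2)
        assert draws.mean() == pytest.approx(expected, rel=0.01)

    def test_nex_shrinks_noise_scale(self):
        nm = NoiseModel(2.0, {0.0: 1, 5000.0: 4})
        assert nm.sigma_at(5000.0) == pytest.approx(nm.sigma_at(0.0) / 2)

    def test_uncovered_b_is_configuration_error(self):
        nm = NoiseModel(1.0, {0.0: 1})
        with pytest.raises(ConfigurationError):
            add_rician_noise(np.ones((2, 1)), nm, [999.0])

    def test_same_seed_reproduces(self, scheme):
        nm = NoiseModel.from_scheme(scheme, sigma0=1.5, seed=9)
        s = np.full((10, len(scheme)), 50.0)
        a = add_rician_noise(s, nm, scheme.b_values)
        b = add_rician_noise(s, nm, scheme.b_values)
        np.testing.assert_array_equal(a, b)


class TestMakePhantom:
    def test_noiseless_signal_matches_forward_model(self, small_phantom, scheme):
        truth, dwi = small_phantom
        m = truth.tissue_mask
        expected = sem_signal(
            truth.s0_map[m][:, None], truth.ddc_map[m][:, None],
            truth.alpha_map[m][:, None], scheme.b_values,
        )
        np.testing.assert_allclose(dwi.data[m], expected, rtol=1e-12)

    def test_background_is_zero_signal(self, small_phantom):
        truth, dwi = small_phantom
        assert np.all(dwi.data[truth.label_map == BACKGROUND] == 0)

    def test_class_fractions_respected(self):
        truth, _ = make_phantom((32, 32, 6), seed=0)
        tissue = truth.tissue_mask
        n = tissue.sum()
        for cls, frac in DEFAULT_CLASS_FRACTIONS.items():
            got = (truth.label_map == cls).sum() / n
            assert got == pytest.approx(frac, abs=0.06)

    def test_hgg_alpha_below_lgg_alpha(self):
        truth, _ = make_phantom((32, 32, 6), seed=0)
        assert truth.alpha_map[truth.label_map == HGG_LIKE].max() < \
            truth.alpha_map[truth.label_map == LGG_LIKE].min()
        assert truth.alpha_map[truth.label_map == NORMAL].mean() > 0.85

    def test_same_seed_bit_identical(self, scheme):
        nm = NoiseModel.from_scheme(scheme, sigma0=1.0)
        _, a = make_phantom((16, 16, 4), scheme, nm, seed=77)
        _, b = make_phantom((16, 16, 4), scheme, nm, seed=77)
        np.testing.assert_array_equal(a.data, b.data)

    def test_rician_floor_at_high_b(self, scheme):
        """Zero-signal voxels at b=5000 sit at the analytic Rayleigh floor."""
        sigma0 = 2.0
        nm = NoiseModel.from_scheme(scheme, sigma0=sigma0)
        truth, dwi = make_phantom((32, 32, 6), scheme, nm, seed=13)
        bg = truth.label_map == BACKGROUND
        sigma_b = sigma0 / np.sqrt(scheme.nex[-1])
        floor = sigma_b * np.sqrt(np.pi / 2)
        assert dwi.data[bg][:, -1].mean() == pytest.approx(floor, rel=0.02)


class TestSimulateFields:
    def test_poisson_mean_within_three_standard_errors(self):
        fields = simulate_fields((8.0, 5.0), n_fields=20, field_area=0.5, seed=1)
        counts = np.array([f.cd34_count for f in fields])
        se = np.sqrt(4.0 / 20)  # Poisson mean 8*0.5=4
        assert abs(counts.mean() - 4.0) <= 3 * se

    def test_zero_proliferation_gives_all_zero_fractions(self):
        fields = simulate_fields((5.0, 0.0), n_fields=10, field_area=0.5, seed=1)
        assert all(f.mib1_positive_fraction == 0.0 for f in fields)

    def test_seed_fixed_reproduces_table(self):
        a = simulate_fields((6.0, 10.0), 12, 0.5, seed=3)
        b = simulate_fields((6.0, 10.0), 12, 0.5, seed=3)
        assert [(f.field_id, f.cd34_count, f.mib1_positive_fraction) for f in a] == \
            [(f.field_id, f.cd34_count, f.mib1_positive_fraction) for f in b]

    def test_out_of_range_field_count_warns_but_runs(self):
        with pytest.warns(UserWarning):
            fields = simulate_fields((6.0, 10.0), 2, 0.5, seed=3)
        assert len(fields) == 2


class TestSpecimenCohort:
    def test_zero_link_noise_gives_exact_monotone_links(self, cohort_inputs):
        truth, _, targets = cohort_inputs
        link = LinkageParams(noise_sd_mib=0.0, noise_sd_cd34=0.0)
        cohort = make_specimen_cohort(truth, targets, link, seed=0, n_missing_mib1=0)
        locs = np.array([local_means(truth, t) for t in targets])
        pmib = [s.pmib1_true for s in cohort]
        mvd = [s.mvd_true for s in cohort]
        assert spearman_rho(locs[:, 0], pmib) == pytest.approx(-1.0)
        assert spearman_rho(locs[:, 1], mvd) == pytest.approx(-1.0)

    def test_default_noise_association_negative_in_most_seeds(self, cohort_inputs):
        truth, _, targets = cohort_inputs
        locs = np.array([local_means(truth, t) for t in targets])
        neg = 0
        n_seeds = 200
        for s in range(n_seeds):
            cohort = make_specimen_cohort(truth, targets, seed=s, n_missing_mib1=0)
            mvd = [sp.cd34_mvd for sp in cohort]
            neg += spearman_rho(locs[:, 1], mvd) < 0
        assert neg / n_seeds >= 0.95

    def test_degenerate_thresholds_make_everything_grade_iv(self, cohort_inputs):
        truth, _, targets = cohort_inputs
        link = LinkageParams(grade_thresholds=(-1e30, -1e29))
        cohort = make_specimen_cohort(truth, targets, link, seed=0)
        assert all(s.who_grade == 4 for s in cohort)

    def test_field_aggregate_tracks_specimen_truth(self, cohort_inputs):
        truth, _, targets = cohort_inputs
        cohort = make_specimen_cohort(truth, targets, seed=4, n_missing_mib1=0)
        for s in cohort:
            # pooled count/area estimate is Poisson-consistent with the truth
            se = np.sqrt(s.mvd_true / (len(s.fields) * 0.5)) if s.mvd_true else 1.0
            assert abs(s.cd34_mvd - s.mvd_true) <= 4 * max(se, 0.5)

    def test_missing_mib1_specimen_flagged(self, cohort_inputs):
        truth, _, targets = cohort_inputs
        cohort = make_specimen_cohort(truth, targets, seed=0, n_missing_mib1=1)
        assert sum(not s.pmib1_available for s in cohort) == 1
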