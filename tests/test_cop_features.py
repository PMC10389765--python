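"""Stabilogram battery: hand geometry, entropy oracles, ellipse coverage."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sstats

from swaymetrics.cop_features import (
    COP_FEATURE_NAMES,
    confidence_ellipse,
    coarse_grain,
    cop_path_features,
    directional_extremes,
    extract_cop_features,
    multiscale_ci,
    multivariate_ci,
    multivariate_sample_entropy,
    sample_entropy,
    sway_direction_entropies,
)
from swaymetrics.session import PhaseLabel, ValidationError

from conftest import brute_sampen


class TestPathFeatures:
    def test_unit_square_path(self):
        traj = np.array([[0, 0], [1, 0], [1, 1], [0, 1], [0, 0]], dtype=float)
        f = cop_path_features(traj, rate=1.0)
        assert f["TOTEX"] == pytest.approx(4.0)
        assert f["TOTEX-ML"] == pytest.approx(2.0)
        assert f["TOTEX-AP"] == pytest.approx(2.0)
        assert f["MVELO"] == pytest.approx(1.0)

    def test_stationary_point(self):
        f = cop_path_features(np.zeros((50, 2)), rate=90.0)
        assert f["TOTEX"] == 0.0
        assert f["RDIST"] == 0.0
        assert f["SD-ML"] == 0.0 and f["SD-AP"] == 0.0

    def test_pure_ml_oscillation(self):
        t = np.linspace(0, 4 * np.pi, 200)
        traj = np.column_stack([np.sin(t), np.zeros_like(t)])
        f = cop_path_features(traj, rate=90.0)
        assert f["TOTEX"] == pytest.approx(f["TOTEX-ML"], rel=1e-12)
        assert f["TOTEX-AP"] == 0.0
        assert f["MDIST-AP"] == 0.0

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(0, 10_000))
    def test_jensen_and_velocity_identities(self, seed):
        rng = np.random.default_rng(seed)
        traj = np.cumsum(rng.standard_normal((100, 2)), axis=0)
        f = cop_path_features(traj, rate=90.0)
        assert f["MDIST-ML"] <= f["RDIST-ML"] + 1e-12
        assert f["MDIST-AP"] <= f["RDIST-AP"] + 1e-12
        assert f["RD"] <= f["RDIST"] + 1e-12
        assert f["MVELO"] * (99 / 90.0) == pytest.approx(f["TOTEX"], rel=1e-9)
        assert max(f["TOTEX-ML"], f["TOTEX-AP"]) <= f["TOTEX"] + 1e-12
        assert f["TOTEX"] <= f["TOTEX-ML"] + f["TOTEX-AP"] + 1e-12


class TestConfidenceEllipse:
    def test_isotropic_gaussian_area_and_coverage(self):
        rng = np.random.default_rng(12345)
        pts = rng.standard_normal((100_000, 2))
        ell = confidence_ellipse(pts)
        q95 = sstats.chi2.ppf(0.95, 2)
        assert ell.area == pytest.approx(math.pi * q95, rel=0.05)
        coverage = ell.contains(pts).mean()
        assert coverage == pytest.approx(0.95, abs=0.005)

    def test_area_consistency_invariant(self):
        rng = np.random.default_rng(0)
        ell = confidence_ellipse(rng.standard_normal((500, 2)) * [2.0, 0.5])
        assert ell.area == pytest.approx(
            math.pi * ell.semi_major * ell.semi_minor, rel=1e-9)
        assert ell.semi_major >= ell.semi_minor >= 0

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(7)
        pts = rng.standard_normal((2000, 2)) * [3.0, 1.0]
        th = math.radians(30)
        rot = np.array([[math.cos(th), -math.sin(th)],
                        [math.sin(th), math.cos(th)]])
        e0 = confidence_ellipse(pts)
        e1 = confidence_ellipse(pts @ rot.T)
        assert e1.area == pytest.approx(e0.area, rel=1e-9)
        shift = (e1.angle_deg - e0.angle_deg) % 180.0
        assert min(shift, 180 - shift) == pytest.approx(30.0, abs=1e-6)

    def test_collinear_degenerate(self):
        t = np.linspace(0, 1, 50)
        ell = confidence_ellipse(np.column_stack([t, 2 * t]))
        assert ell.degenerate
        assert ell.semi_minor == 0.0
        assert ell.area == 0.0

    def test_too_few_points(self):
        with pytest.raises(ValidationError):
            confidence_ellipse(np.zeros((2, 2)))


class TestSampleEntropy:
    def test_matches_brute_force_on_random_series(self):
        rng = np.random.default_rng(3)
        for _ in range(8):
            x = rng.standard_normal(rng.integers(60, 120))
            r = 0.2 * np.std(x)
            ours = sample_entropy(x, m=2, r=r)
            oracle = brute_sampen(x, 2, r)
            if math.isnan(oracle):
                assert math.isnan(ours)
            else:
                assert ours == pytest.approx(oracle, rel=1e-12)

    def test_alternating_series_equals_enumeration(self):
        x = np.array([1, 2, 1, 2, 1, 2, 1, 2, 1, 2, 1, 2, 1, 2, 1, 2, 1, 2, 1, 2],
                     dtype=float)
        assert sample_entropy(x, m=2, r=0.2) == pytest.approx(
            brute_sampen(x, 2, 0.2), rel=1e-12)

    def test_constant_series_is_zero(self):
        assert sample_entropy(np.full(100, 5.0)) == 0.0

    def test_monotone_non_increasing_in_r(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal(300)
        rs = [0.05, 0.1, 0.2, 0.4, 0.8]
        vals = [sample_entropy(x, r=r * np.std(x)) for r in rs]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_noise_exceeds_sine_of_equal_sd(self):
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            noise = rng.standard_normal(3600)
            t = np.arange(3600) / 90.0
            sine = np.sqrt(2) * np.sin(2 * np.pi * 0.3 * t + rng.uniform(0, 6))
            wins += sample_entropy(noise) > sample_entropy(sine)
        assert wins > 10

    def test_short_series_rejected(self):
        with pytest.raises(ValidationError):
            sample_entropy(np.zeros(15), m=2)


class TestMultiscale:
    def test_scale1_equals_plain_sampen(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(2000)
        prof = multiscale_ci(x)
        assert prof.sampen_per_scale[0] == pytest.approx(
            sample_entropy(x), rel=1e-12)

    def test_ci_is_sum_of_scales(self):
        rng = np.random.default_rng(2)
        prof = multiscale_ci(rng.standard_normal(2500))
        assert prof.complexity_index == pytest.approx(
            np.nansum(prof.sampen_per_scale), rel=1e-12)

    def test_white_noise_entropy_decreases_across_scales(self):
        wins = 0
        for seed in range(20):
            prof = multiscale_ci(np.random.default_rng(seed).standard_normal(3600))
            se = np.array(prof.sampen_per_scale)
            wins += se[0] > se[-1] and np.all(np.diff(se) < 0.1)
        assert wins > 10

    def test_constant_series_ci_zero(self):
        assert multiscale_ci(np.full(2500, 1.0)).complexity_index == 0.0

    def test_coarse_grain_means(self):
        np.testing.assert_allclose(coarse_grain([1, 2, 3, 4, 5], 2), [1.5, 3.5])

    def test_insufficient_length_states_minimum(self):
        with pytest.raises(ValidationError, match="200"):
            multiscale_ci(np.zeros(150), tau_max=10, m=2)


class TestMultivariate:
    def test_identical_channels_not_above_independent(self):
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.standard_normal(1200)
            same = multivariate_ci(np.column_stack([x, x]), tau_max=5)
            indep = multivariate_ci(
                np.column_stack([x, rng.standard_normal(1200)]), tau_max=5)
            wins += same <= indep
        assert wins > 10

    def test_constant_channels_zero(self):
        traj = np.full((600, 2), 2.0)
        assert multivariate_ci(traj, tau_max=5) == 0.0

    def test_channel_swap_invariance(self):
        rng = np.random.default_rng(4)
        traj = rng.standard_normal((800, 2))
        a = multivariate_sample_entropy(traj[:, 0], traj[:, 1])
        b = multivariate_sample_entropy(traj[:, 1], traj[:, 0])
        assert a == pytest.approx(b, rel=1e-12)


class TestEntropies:
    def test_uniform_directions_maximize(self):
        angles = (np.arange(36) + 0.5) / 36 * 2 * np.pi - np.pi
        d = np.column_stack([np.cos(angles), np.sin(angles)])
        traj = np.vstack([[0, 0], np.cumsum(d, axis=0)])
        _, dir_e = sway_direction_entropies(traj, n_bins=36)
        assert dir_e == pytest.approx(np.log(36), rel=1e-9)

    def test_identical_displacements_zero(self):
        traj = np.column_stack([np.arange(20.0), np.arange(20.0)])
        mag_e, dir_e = sway_direction_entropies(traj)
        assert mag_e == 0.0 and dir_e == 0.0

    def test_two_bin_hand_value(self):
        # 3 displacements up-right, 1 down-right, equal magnitudes
        d = np.array([[1, 1], [1, 1], [1, 1], [1, -1]], dtype=float)
        traj = np.vstack([[0, 0], np.cumsum(d, axis=0)])
        _, dir_e = sway_direction_entropies(traj, n_bins=2)
        expected = -(0.75 * np.log(0.75) + 0.25 * np.log(0.25))
        assert dir_e == pytest.approx(expected, rel=1e-9)


class TestDirectionalExtremes:
    def test_hand_geometry(self):
        pts = np.array([[0, 2], [0, -1], [-3, 0], [1, 0]], dtype=float)
        ext = directional_extremes(pts)
        assert ext["antero"] == (pytest.approx(2.0), pytest.approx(90.0))
        assert ext["postero"] == (pytest.approx(1.0), pytest.approx(-90.0))
        assert ext["left"] == (pytest.approx(3.0), pytest.approx(180.0))
        assert ext["right"] == (pytest.approx(1.0), pytest.approx(0.0))

    def test_empty_half_plane(self):
        pts = np.array([[0.5, 1.0], [-0.5, 2.0], [0.1, 0.5]])
        ext = directional_extremes(pts)
        assert ext["postero"][0] == 0.0
        assert math.isnan(ext["postero"][1])

    def test_rotation_180_swaps_antero_postero(self):
        rng = np.random.default_rng(5)
        pts = rng.standard_normal((50, 2))
        a = directional_extremes(pts)
        b = directional_extremes(-pts)
        assert a["antero"][0] == pytest.approx(b["postero"][0])
        assert a["left"][0] == pytest.approx(b["right"][0])


class TestFullBattery:
    def test_all_names_present_and_finite_enough(self):
        rng = np.random.default_rng(8)
        traj = np.cumsum(rng.standard_normal((600, 2)), axis=0)
        fs = extract_cop_features(traj, rate=90.0, phase=PhaseLabel.POST,
                                  tau_max=3)
        assert set(fs.values) == set(COP_FEATURE_NAMES)
        non_angle = [k for k in fs.values if not k.endswith("angle")]
        assert all(np.isfinite(fs.values[k]) for k in non_angle)
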