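"""Forward kinetic model, inputs, noise and cohort generation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from o17mri import (
    AcquisitionProtocol,
    GroupSpec,
    KineticParams,
    NoiseSpec,
    add_noise,
    arterial_input,
    body_water_input,
    excess_concentration,
    extract_roi,
    make_group_dataset,
    make_image_series,
    simulate_timecourse,
)
from o17mri.protocol import D_BRAIN


def rk_oracle(params, protocol):
    """Adaptive Runge-Kutta integration of the kinetic ODE (minutes)."""

    def rhs(t_min, y):
        t_s = t_min * 60.0
        return [
            2.0 * params.cmro2 * float(arterial_input(t_s, protocol))
            - params.k_l * y[0]
            + params.k_g * float(body_water_input(t_s, protocol))
        ]

    t = protocol.frame_times()
    sol = solve_ivp(
        rhs, [0.0, t[-1] / 60.0], [0.0], t_eval=t / 60.0,
        rtol=1e-11, atol=1e-13, max_step=0.05,
    )
    return sol.y[0]


class TestInputs:
    def test_arterial_rectangle(self, protocol_tc3):
        assert arterial_input(0.0, protocol_tc3) == 0.0
        assert arterial_input(302.0, protocol_tc3) == 0.0  # within the delay
        assert arterial_input(305.0, protocol_tc3) == pytest.approx(0.7)
        assert arterial_input(600.0, protocol_tc3) == 0.0  # after the window

    def test_body_water_ramp_and_plateau(self, protocol_tc0):
        assert body_water_input(0.0, protocol_tc0) == 0.0
        # linear ramp: 1 min into inhalation -> alpha * 1 min
        assert body_water_input(360.0, protocol_tc0) == pytest.approx(0.7)
        # constant plateau alpha * t_inhale(min) after the window
        plateau = 0.7 * 200.0 / 60.0
        assert body_water_input(600.0, protocol_tc0) == pytest.approx(plateau)
        assert body_water_input(1400.0, protocol_tc0) == pytest.approx(plateau)


class TestForwardModel:
    @pytest.mark.parametrize("k_l", [0.0, 0.05, 0.39, 2.0])
    @pytest.mark.parametrize("k_g", [0.0, 0.62])
    def test_analytic_matches_runge_kutta(self, protocol_tc3, k_l, k_g):
        params = KineticParams(cmro2=2.02, k_g=k_g, k_l=k_l)
        ana = excess_concentration(protocol_tc3.frame_times(), params, protocol_tc3)
        num = rk_oracle(params, protocol_tc3)
        scale = np.max(np.abs(num))
        assert np.max(np.abs(ana - num)) / scale < 1e-6

    def test_reduces_to_linear_slope_without_losses(self, protocol_tc0):
        # K_G = K_L = 0, Tc = 0: pure production at slope 2*CMRO2*alpha
        params = KineticParams(cmro2=1.0, k_g=0.0, k_l=0.0)
        m = excess_concentration(np.array([360.0]), params, protocol_tc0)
        assert m[0] == pytest.approx(2.0 * 1.0 * 0.7 * 1.0)  # 1.4 umol/g at 1 min

    def test_zero_before_tracer_arrival(self, protocol_tc3, ctr_params):
        curve = simulate_timecourse(ctr_params, protocol_tc3)
        pre = curve.t_s < protocol_tc3.t_baseline + protocol_tc3.tc
        assert np.all(curve.excess[pre] == 0.0)

    def test_amplitude_linearity(self, protocol_tc3):
        base = KineticParams(1.3, 0.5, 0.42)
        scaled = KineticParams(1.3 * 2.5, 0.5 * 2.5, 0.42)
        t = protocol_tc3.frame_times()
        np.testing.assert_allclose(
            excess_concentration(t, scaled, protocol_tc3),
            2.5 * excess_concentration(t, base, protocol_tc3),
            rtol=1e-14,
        )

    @settings(derandomize=True, max_examples=25)
    @given(
        cmro2=st.floats(0.1, 5.0),
        k_g=st.floats(0.0, 2.0),
        k_l=st.floats(0.0, 2.0),
        c=st.floats(0.7, 2.0),
    )
    def test_alpha_scaling_invariance(self, cmro2, k_g, k_l, c):
        # curve depends only on (alpha*CMRO2, alpha*K_G, K_L)
        p1 = AcquisitionProtocol(alpha=0.7, tc=3.0)
        p2 = AcquisitionProtocol(alpha=0.7 / c, tc=3.0)
        t = p1.frame_times()
        m1 = excess_concentration(t, KineticParams(cmro2, k_g, k_l), p1)
        m2 = excess_concentration(t, KineticParams(cmro2 * c, k_g * c, k_l), p2)
        np.testing.assert_allclose(m1, m2, rtol=1e-12, atol=1e-14)

    @pytest.mark.parametrize("k_l", [0.0, 0.39])
    def test_continuity_at_phase_boundaries(self, protocol_tc3, k_l):
        params = KineticParams(2.02, 0.62, k_l)
        eps = 1e-6  # seconds
        for boundary in (
            protocol_tc3.t_baseline + protocol_tc3.tc,
            protocol_tc3.t_baseline + protocol_tc3.tc + protocol_tc3.t_inhale,
        ):
            t = np.array([boundary - eps, boundary + eps])
            m = excess_concentration(t, params, protocol_tc3)
            assert abs(m[1] - m[0]) < 1e-6

    def test_pure_monoexponential_washout_without_recirculation(self, protocol_tc0):
        # K_G = 0: post-inhalation decay toward 0 at exactly rate K_L
        params = KineticParams(2.0, 0.0, 0.5)
        curve = simulate_timecourse(params, protocol_tc0)
        end = protocol_tc0.t_baseline + protocol_tc0.t_inhale
        mask = curve.t_s > end
        t_min = (curve.t_s[mask] - end) / 60.0
        m_end = excess_concentration(np.array([end]), params, protocol_tc0)[0]
        np.testing.assert_allclose(
            curve.excess[mask], m_end * np.exp(-0.5 * t_min), rtol=1e-12
        )

    def test_rejects_negative_parameters(self):
        with pytest.raises(ValueError):
            KineticParams(-1.0, 0.0, 0.0)


class TestNoise:
    def test_zero_sigma_is_identity(self, protocol_tc3, ctr_params):
        curve = simulate_timecourse(ctr_params, protocol_tc3)
        noisy = add_noise(curve, NoiseSpec(sigma=0.0, seed=1))
        np.testing.assert_array_equal(noisy.excess, curve.excess)

    def test_seed_determinism(self, protocol_tc3, ctr_params):
        curve = simulate_timecourse(ctr_params, protocol_tc3)
        a = add_noise(curve, NoiseSpec(sigma=0.5, seed=7))
        b = add_noise(curve, NoiseSpec(sigma=0.5, seed=7))
        np.testing.assert_array_equal(a.excess, b.excess)

    def test_sample_sd_matches_sigma(self):
        from o17mri.synthetic import VoxelTimeCourse

        n = 10_000
        curve = VoxelTimeCourse(t_s=np.arange(n, dtype=float), excess=np.zeros(n))
        noisy = add_noise(curve, NoiseSpec(sigma=0.5, seed=3))
        assert abs(noisy.excess.std(ddof=1) - 0.5) / 0.5 < 0.03

    def test_unknown_distribution_rejected(self):
        with pytest.raises(ValueError):
            NoiseSpec(sigma=0.5, distribution="poisson")


class TestImageSeries:
    def test_uniform_params_reproduce_timecourse(self, protocol_tc3, ctr_params):
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[1:3, 1:3, 1:3] = True
        series = make_image_series(mask, ctr_params, protocol_tc3, noise=None)
        expected = D_BRAIN + simulate_timecourse(ctr_params, protocol_tc3).excess
        np.testing.assert_allclose(series.data[1, 1, 1], expected)
        np.testing.assert_allclose(series.data[2, 2, 2], expected)
        assert np.all(series.data[0, 0, 0] == 0.0)

    def test_empty_mask_gives_pure_noise(self, protocol_tc3, ctr_params):
        mask = np.zeros((3, 3, 3), dtype=bool)
        series = make_image_series(
            mask, ctr_params, protocol_tc3, noise=NoiseSpec(sigma=1.0, seed=5)
        )
        assert abs(series.data.mean()) < 0.05
        assert abs(series.data.std() - 1.0) < 0.05

    def test_roi_mean_equals_direct_average(self, protocol_tc3):
        # per-voxel CMRO2 gradient: ROI mean must equal the mean of members
        shape = (4, 4, 4)
        mask = np.ones(shape, dtype=bool)
        cmro2 = np.linspace(1.0, 2.5, mask.size).reshape(shape)
        pmap = {
            "cmro2": cmro2,
            "k_g": np.full(shape, 0.5),
            "k_l": np.full(shape, 0.4),
        }
        series = make_image_series(mask, pmap, protocol_tc3, noise=None)
        roi = [(1, 1, 1), (1, 1, 2), (1, 2, 1), (1, 2, 2),
               (2, 1, 1), (2, 1, 2), (2, 2, 1), (2, 2, 2)]
        got = extract_roi(series, roi)
        brute = np.mean([series.data[i, j, k] for i, j, k in roi], axis=0)
        np.testing.assert_allclose(got, brute, rtol=1e-14)

    def test_shape_mismatch_rejected(self, protocol_tc3):
        mask = np.ones((3, 3, 3), dtype=bool)
        pmap = {
            "cmro2": np.ones((2, 2, 2)),
            "k_g": np.zeros((2, 2, 2)),
            "k_l": np.zeros((2, 2, 2)),
        }
        with pytest.raises(ValueError):
            make_image_series(mask, pmap, protocol_tc3)


class TestGroupDataset:
    def test_zero_sd_zero_noise_identical_curves(self, protocol_tc3, ctr_params):
        spec = GroupSpec("CTR", 3, ctr_params)
        cohort = make_group_dataset(
            [spec], protocol_tc3, NoiseSpec(sigma=0.0, seed=0)
        )
        ref = cohort[0].curve.excess
        for sub in cohort[1:]:
            np.testing.assert_array_equal(sub.curve.excess, ref)

    def test_reproducible_under_seed(self, protocol_tc3, ctr_params):
        spec = GroupSpec("CTR", 2, ctr_params, KineticParams(0.1, 0.05, 0.02))
        a = make_group_dataset([spec], protocol_tc3, NoiseSpec(sigma=0.5, seed=11))
        b = make_group_dataset([spec], protocol_tc3, NoiseSpec(sigma=0.5, seed=11))
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.curve.excess, sb.curve.excess)
            assert sa.true_params == sb.true_params

    def test_closed_loop_single_noiseless_subject(self, protocol_tc0):
        from o17mri import fit_linear

        truth = KineticParams(1.39, 0.0, 0.0)
        cohort = make_group_dataset(
            [GroupSpec("CTR", 1, truth)], protocol_tc0, NoiseSpec(sigma=0.0, seed=0)
        )
        res = fit_linear(cohort[0].curve, alpha=0.7)
        assert res.cmro2 == pytest.approx(1.39, abs=1e-9)

    def test_requires_a_group(self, protocol_tc3):
        with pytest.raises(ValueError):
            make_group_dataset([], protocol_tc3, NoiseSpec())
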