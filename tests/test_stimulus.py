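"""Drive construction: MS kernel shape, modulation series, drive maps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msping import stimulus as stim


class TestMSKernel:
    def test_continuity_at_onset(self):
        # both lobes vanish at t = 0, so K(0) = 1 exactly
        assert stim.ms_kernel(np.array([0.0]))[0] == pytest.approx(1.0)

    def test_peak_is_one_plus_mp(self):
        t = np.arange(0.0, 600.0, 0.1)
        k = stim.ms_kernel(t)
        assert k.max() == pytest.approx(1.5, abs=1e-6)

    def test_trough_is_one_minus_mn(self):
        t = np.arange(-200.0, 0.0, 0.1)
        k = stim.ms_kernel(t)
        assert k.min() == pytest.approx(0.8, abs=1e-6)

    def test_positive_lobe_argmax_closed_form(self):
        # argmax of exp(-t/t1) - exp(-t/t2) is ln(t1/t2) t1 t2 / (t1 - t2)
        t = np.arange(0.0, 400.0, 0.1)
        k = stim.ms_kernel(t)
        expected = np.log(100.0 / 40.0) * 100.0 * 40.0 / 60.0
        assert t[np.argmax(k)] == pytest.approx(expected, abs=0.2)
        assert expected == pytest.approx(61.1, abs=0.1)

    def test_baseline_recovery(self):
        assert stim.ms_kernel(np.array([-1500.0, 2000.0])) == pytest.approx(
            [1.0, 1.0], abs=1e-6
        )

    def test_printed_normalisation_variant_differs(self):
        p = stim.MSKernelParams(normalization="printed")
        t = np.arange(0.0, 600.0, 0.1)
        assert stim.ms_kernel(t, p).max() != pytest.approx(1.5, abs=1e-3)

    def test_invalid_taus_rejected(self):
        with pytest.raises(ValueError):
            stim.MSKernelParams(tau1_p=40.0, tau2_p=100.0)

    def test_kernel_is_deterministic(self):
        t = np.linspace(-300, 300, 1001)
        assert np.array_equal(stim.ms_kernel(t), stim.ms_kernel(t))


class TestModulationSeries:
    def test_baseline_is_one_for_long_period(self):
        p = stim.MSKernelParams(period=5000.0)
        sigma, _ = stim.ms_modulation_series(10000.0, 0.5, p)
        mid = sigma[int(2500 / 0.5) : int(3500 / 0.5)]
        assert np.allclose(mid, 1.0, atol=1e-3)

    def test_steady_state_periodicity(self):
        sigma, _ = stim.ms_modulation_series(4000.0, 0.5)
        per = 800  # samples per 400-ms interval
        a = sigma[6 * per : 7 * per]
        b = sigma[7 * per : 8 * per]
        assert np.max(np.abs(a - b)) < 1e-9

    def test_bounds_for_default_parameters(self):
        sigma, _ = stim.ms_modulation_series(4000.0, 0.5)
        assert sigma.min() >= 0.8 - 1e-6
        # the slow tail of the previous positive lobe overlaps the next
        # peak by < 0.03 at T = 400 ms
        assert sigma.max() <= 1.5 + 0.03

    def test_onsets_on_period_grid(self):
        _, onsets = stim.ms_modulation_series(2000.0, 0.5)
        assert np.array_equal(onsets, [0.0, 400.0, 800.0, 1200.0, 1600.0])

    def test_lengthened_interval_shifts_onsets_only(self):
        # the kernel lobe following each onset is identical for any period
        s1, o1 = stim.ms_modulation_series(4000.0, 0.5)
        p2 = stim.MSKernelParams(period=800.0)
        s2, o2 = stim.ms_modulation_series(4000.0, 0.5, p2)
        i1 = int(o1[2] / 0.5)
        i2 = int(o2[2] / 0.5)
        lobe = 300  # first 150 ms post-onset
        # residual tail of the previous lobe differs by < 0.03 between periods
        assert np.allclose(s1[i1 : i1 + lobe], s2[i2 : i2 + lobe], atol=0.03)


class TestDriveMaps:
    def test_smoothed_noise_reproducible_and_normalised(self):
        a = stim.smoothed_noise_pattern(40, 4.0, np.random.default_rng(3))
        b = stim.smoothed_noise_pattern(40, 4.0, np.random.default_rng(3))
        assert np.array_equal(a, b)
        assert a.min() == 0.0 and a.max() == 1.0

    def test_zero_correlation_length_is_iid(self):
        a = stim.smoothed_noise_pattern(64, 0.0, np.random.default_rng(4))
        lag1 = np.corrcoef(a[:, :-1].ravel(), a[:, 1:].ravel())[0, 1]
        assert abs(lag1) < 0.1

    def test_two_seeds_same_moments_different_fields(self):
        a = stim.smoothed_noise_pattern(40, 4.0, np.random.default_rng(5))
        b = stim.smoothed_noise_pattern(40, 4.0, np.random.default_rng(6))
        assert not np.array_equal(a, b)
        assert a.mean() == pytest.approx(b.mean(), abs=0.15)
        assert a.std() == pytest.approx(b.std(), abs=0.1)

    @pytest.mark.parametrize("orientation", ["horizontal", "vertical"])
    def test_bar_bounded_and_finite(self, orientation):
        j = stim.bar_stimulus(40, orientation)
        assert np.all(np.isfinite(j))
        assert j.min() >= 0.0 and j.max() <= 1.3

    def test_bar_orientation_transpose_symmetry(self):
        h = stim.bar_stimulus(40, "horizontal", noise_amp=0.0)
        v = stim.bar_stimulus(40, "vertical", noise_amp=0.0)
        assert np.array_equal(v, h.T)

    def test_bar_elongation_matches_label(self):
        h = stim.bar_stimulus(40, "horizontal", noise_amp=0.0)
        xs, ys = np.nonzero(h >= 1.0)
        # wrapped second moments around the bar centre
        assert np.var(xs - xs.mean()) > np.var(ys - ys.mean())

    def test_image_to_drive_scaling(self):
        patch = np.random.default_rng(0).uniform(size=(40, 40))
        j_e, j_i = stim.image_to_drive(patch)
        assert j_e.max() == pytest.approx(7.0)
        assert j_i.shape == (20, 20)
        # pointwise factor-2 ratio at registered positions
        assert np.allclose(j_e[::2, ::2] / j_i, 2.0)

    def test_constant_patch_degenerates_to_midlevel(self):
        with pytest.warns(UserWarning):
            j_e, j_i = stim.image_to_drive(np.full((40, 40), 3.3))
        assert np.allclose(j_e, 3.5)
        assert np.allclose(j_i, 1.75)


def _radial_log_slope(patch):
    n = patch.shape[0]
    f = np.fft.fftfreq(n)
    fx, fy = np.meshgrid(f, f, indexing="ij")
    r = np.sqrt(fx**2 + fy**2)
    p = np.abs(np.fft.fft2(patch - patch.mean())) ** 2
    mask = (r > 0.03) & (r < 0.4)
    return np.polyfit(np.log10(r[mask]), np.log10(p[mask] + 1e-30), 1)[0]


class TestSyntheticPatch:
    def test_values_in_unit_interval(self):
        p = stim.synthetic_natural_patch(40, rng=np.random.default_rng(1))
        assert p.min() >= 0.0 and p.max() <= 1.0

    def test_spectral_slope_near_target(self):
        slopes = [
            _radial_log_slope(
                stim.synthetic_natural_patch(40, 2.0, np.random.default_rng(k))
            )
            for k in range(10)
        ]
        assert np.mean(slopes) == pytest.approx(-2.0, abs=0.3)

    def test_zero_slope_unposterized_is_white(self):
        p = stim.synthetic_natural_patch(64, 0.0, np.random.default_rng(2), n_levels=0)
        lag1 = np.corrcoef(p[:, :-1].ravel(), p[:, 1:].ravel())[0, 1]
        assert abs(lag1) < 0.1

    def test_contains_homogeneous_regions(self):
        # posterization produces near-flat runs that a purely smooth field
        # of the same spectral slope does not have
        p = stim.synthetic_natural_patch(40, rng=np.random.default_rng(3))
        smooth = stim.synthetic_natural_patch(
            40, rng=np.random.default_rng(3), n_levels=0
        )
        flat = lambda x: np.mean(np.abs(np.diff(x, axis=0)) < 0.01)
        assert flat(p) > 2 * flat(smooth)
        assert flat(p) > 0.3


@settings(max_examples=25, deadline=None)
@given(st.floats(10.0, 200.0), st.floats(1.0, 0.99 * 200.0))
def test_kernel_bounded_for_any_valid_taus(tau1, frac):
    tau2 = min(frac, 0.9 * tau1)
    p = stim.MSKernelParams(tau1_p=tau1, tau2_p=tau2)
    t = np.linspace(-100, 500, 601)
    k = stim.ms_kernel(t, p)
    assert np.all(k <= 1.0 + p.m_p + 1e-9)
    assert np.all(k >= 1.0 - p.m_n - 1e-9)
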