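"""Spectral profiles, RGM, GP imaging, and G-factor calibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from memdyn import simgen
from memdyn import membrane_order as mo
from memdyn.core import CYTOPLASM, INTERIOR, PM, NoiseModel, RegionMask


def _uniform_mask(shape=(20, 20), label=PM):
    return RegionMask(np.full(shape, label, dtype=np.uint8))


class TestSpectralProfiles:
    def test_pure_region_reproduces_basis_peak(self, noiseless_lambda):
        spec, _, _ = noiseless_lambda
        pure = simgen.SpectralSimSpec(
            region_ordered_fraction={PM: 1.0, INTERIOR: 1.0, CYTOPLASM: 1.0},
            noise_model=NoiseModel("none"),
            seed=1,
        )
        stack, mask = simgen.simulate_lambda_stack(pure)
        prof = mo.extract_spectral_profiles(stack, mask, regions=[PM], seed=0)[0]
        ob, _ = pure.bases()
        bands = np.asarray(pure.band_centers_nm)
        assert np.allclose(prof.mean_intensity, ob)
        # Quadratic-interpolated peak is close to the basis peak (560 nm).
        assert prof.peak_wavelength_nm == pytest.approx(560.0, abs=2.0)
        assert bands.min() <= prof.peak_wavelength_nm <= bands.max()

    def test_blue_shift_with_higher_ordered_fraction(self, noiseless_lambda):
        # f = 0.8 (PM) vs f = 0.4 (endosome): more order -> shorter peak λ.
        _, stack, mask = noiseless_lambda
        profs = {
            p.region: p
            for p in mo.extract_spectral_profiles(
                stack, mask, regions=[PM, INTERIOR], seed=2
            )
        }
        assert profs[PM].peak_wavelength_nm < profs[INTERIOR].peak_wavelength_nm

    def test_monotone_blue_shift_over_fraction_grid(self):
        peaks = []
        for f in (0.0, 0.25, 0.5, 0.75, 1.0):
            spec = simgen.SpectralSimSpec(
                region_ordered_fraction={PM: f, INTERIOR: f, CYTOPLASM: f},
                noise_model=NoiseModel("none"),
                seed=0,
            )
            stack, mask = simgen.simulate_lambda_stack(spec)
            prof = mo.extract_spectral_profiles(stack, mask, regions=[PM], seed=1)[0]
            peaks.append(prof.peak_wavelength_nm)
        assert all(a > b for a, b in zip(peaks, peaks[1:]))

    def test_symmetric_mixture_peak_between_bases(self):
        # Equal-amplitude, equal-width Gaussians at 560/620 nm mixed 50/50:
        # oracle = argmax of the analytic mixture on a fine grid.
        bands = np.arange(495.0, 694.0, 9.0)
        b1 = simgen.gaussian_basis(bands, 560.0, 30.0)
        b2 = simgen.gaussian_basis(bands, 620.0, 30.0)
        spec = simgen.SpectralSimSpec(
            band_centers_nm=tuple(bands),
            ordered_basis=tuple(b1),
            disordered_basis=tuple(b2),
            region_ordered_fraction={PM: 0.5, INTERIOR: 0.5, CYTOPLASM: 0.5},
            noise_model=NoiseModel("none"),
            seed=0,
        )
        stack, mask = simgen.simulate_lambda_stack(spec)
        prof = mo.extract_spectral_profiles(stack, mask, regions=[PM], seed=0)[0]
        grid = np.linspace(bands[0], bands[-1], 20001)
        mix = 0.5 * np.exp(-((grid - 560) ** 2) / (2 * 30**2)) + 0.5 * np.exp(
            -((grid - 620) ** 2) / (2 * 30**2)
        )
        oracle = grid[np.argmax(mix)]
        assert prof.peak_wavelength_nm == pytest.approx(oracle, abs=4.5)

    def test_region_too_small_raises(self):
        labels = np.zeros((30, 30), dtype=np.uint8)
        labels[5, 5] = PM  # single pixel cannot host a 3x3 ROI
        stack, _ = simgen.simulate_lambda_stack(simgen.SpectralSimSpec(seed=0))
        small = RegionMask(np.zeros(stack.frame_shape, dtype=np.uint8))
        small.labels[5, 5] = PM
        with pytest.raises(ValueError, match="too small"):
            mo.extract_spectral_profiles(stack, small, regions=[PM], seed=0)


class TestBandIntegration:
    def test_uniform_spectrum_gives_flat_windows(self):
        bands = simgen.default_band_centers()
        data = np.full((len(bands), 8, 8), 5.0)
        from memdyn.core import ImageStack

        stack = ImageStack(data, 0.1, band_centers_nm=bands, axes="BYX")
        green = mo.band_integrate(stack, mo.GREEN_WINDOW_NM)
        red = mo.band_integrate(stack, mo.RED_WINDOW_NM)
        assert np.allclose(green, 5.0) and np.allclose(red, 5.0)

    def test_window_outside_bands_rejected(self):
        bands = simgen.default_band_centers()
        from memdyn.core import ImageStack

        stack = ImageStack(np.ones((len(bands), 4, 4)), 0.1, band_centers_nm=bands, axes="BYX")
        with pytest.raises(ValueError, match="window"):
            mo.band_integrate(stack, (900.0, 1000.0))


class TestRGM:
    def test_equal_channels_give_unity(self):
        mask = _uniform_mask()
        img = np.random.default_rng(0).uniform(50, 150, mask.shape)
        assert mo.compute_rgm(img, img, mask, PM).rgm == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "red_mean,expected",
        [(137.2, 0.686), (263.4, 1.317), (208.2, 1.041)],
    )
    def test_constructed_region_ratios(self, red_mean, expected):
        mask = _uniform_mask()
        green = np.full(mask.shape, 200.0)
        red = np.full(mask.shape, red_mean)
        r = mo.compute_rgm(green, red, mask, PM)
        assert r.rgm == pytest.approx(expected, abs=5e-4)
        assert r.rgm == r.i_660 / r.i_550

    def test_monotone_in_red_intensity(self):
        mask = _uniform_mask()
        green = np.full(mask.shape, 200.0)
        values = [
            mo.compute_rgm(green, np.full(mask.shape, v), mask, PM).rgm
            for v in (50.0, 100.0, 150.0, 250.0)
        ]
        assert all(a < b for a, b in zip(values, values[1:]))

    def test_zero_green_rejected(self):
        mask = _uniform_mask()
        with pytest.raises(ValueError, match="positive"):
            mo.compute_rgm(np.zeros(mask.shape), np.ones(mask.shape), mask, PM)


class TestGPImage:
    def test_equal_channels_give_zero(self):
        img = np.random.default_rng(1).uniform(10, 100, (16, 16))
        gp = mo.compute_gp_image(img, img, g_factor=1.0)
        assert np.allclose(gp.gp, 0.0)

    @pytest.mark.parametrize(
        "ratio,expected",
        [(3.878, 0.59), (2.7736, 0.47), (2.6364, 0.45)],
    )
    def test_known_channel_ratios(self, ratio, expected):
        gp = mo.compute_gp_image(
            np.full((4, 4), 100.0 * ratio), np.full((4, 4), 100.0)
        )
        assert float(gp.gp[0, 0]) == pytest.approx(expected, abs=0.005)

    @given(
        ordered=st.floats(0.1, 1e4),
        disordered=st.floats(0.1, 1e4),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_channel_swap_antisymmetry(self, ordered, disordered):
        a = np.full((2, 2), ordered)
        b = np.full((2, 2), disordered)
        gp_ab = mo.compute_gp_image(a, b, g_factor=1.0).gp
        gp_ba = mo.compute_gp_image(b, a, g_factor=1.0).gp
        assert np.allclose(gp_ab, -gp_ba, atol=1e-12)
        assert np.all(np.abs(gp_ab) <= 1.0)

    def test_strictly_increasing_in_channel_ratio(self):
        ratios = np.linspace(0.1, 10, 25)
        gps = [
            float(mo.compute_gp_image(np.full((1, 1), r), np.ones((1, 1))).gp[0, 0])
            for r in ratios
        ]
        assert all(a < b for a, b in zip(gps, gps[1:]))

    def test_zero_denominator_masked(self):
        gp = mo.compute_gp_image(np.zeros((3, 3)), np.zeros((3, 3)))
        assert not gp.valid.any()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            mo.compute_gp_image(np.zeros((3, 3)), np.zeros((4, 4)))


class TestGPPeaks:
    def test_constant_gp_with_noise_recovers_constant(self):
        rng = np.random.default_rng(3)
        gp_values = np.clip(rng.normal(0.52, 0.02, (120, 120)), -1, 1)
        gp = mo.GPImage(
            gp=gp_values, g_factor=1.0, ordered=np.ones((120, 120)), disordered=np.ones((120, 120))
        )
        fit = mo.fit_region_gp_peaks(gp, _uniform_mask((120, 120)))[0]
        assert fit.peak == pytest.approx(0.52, abs=0.005)

    def test_pm_ratio_with_multiplicative_noise(self):
        # Channel ratio 3.878 with 5% multiplicative noise: the fitted GP
        # peak must stay at the noiseless value 0.59.
        rng = np.random.default_rng(4)
        ordered = 387.8 * (1 + rng.normal(0, 0.05, (150, 150)))
        disordered = 100.0 * (1 + rng.normal(0, 0.05, (150, 150)))
        gp = mo.compute_gp_image(ordered, disordered)
        fit = mo.fit_region_gp_peaks(gp, _uniform_mask((150, 150)))[0]
        assert fit.peak == pytest.approx(0.59, abs=0.01)

    def test_pm_peak_exceeds_endosome_peak(self):
        rng = np.random.default_rng(5)
        labels = np.full((100, 100), PM, dtype=np.uint8)
        labels[:, 50:] = INTERIOR
        ratio = np.where(labels == PM, 3.878, 2.7736)
        ordered = ratio * 100.0 * (1 + rng.normal(0, 0.02, labels.shape))
        disordered = 100.0 * (1 + rng.normal(0, 0.02, labels.shape))
        gp = mo.compute_gp_image(ordered, disordered)
        fits = {
            f.region: f
            for f in mo.fit_region_gp_peaks(gp, RegionMask(labels))
        }
        assert fits[PM].peak > fits[INTERIOR].peak

    def test_insufficient_pixels_raise(self):
        gp = mo.compute_gp_image(np.ones((5, 5)), np.ones((5, 5)))
        with pytest.raises(ValueError, match="valid GP pixels"):
            mo.fit_region_gp_peaks(gp, _uniform_mask((5, 5)))


class TestGFactor:
    def test_reference_gp_zero_equal_channels(self):
        assert mo.calibrate_g_factor(10.0, 10.0, 0.0) == pytest.approx(1.0)

    def test_reference_gp_zero_double_ordered(self):
        assert mo.calibrate_g_factor(20.0, 10.0, 0.0) == pytest.approx(2.0)

    @given(
        i_ord=st.floats(1, 1e3),
        i_dis=st.floats(1, 1e3),
        gp_ref=st.floats(-0.95, 0.95),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_round_trip_inversion(self, i_ord, i_dis, gp_ref):
        g = mo.calibrate_g_factor(i_ord, i_dis, gp_ref)
        gp = mo.compute_gp_image(
            np.full((1, 1), i_ord), np.full((1, 1), i_dis), g_factor=g
        )
        assert float(gp.gp[0, 0]) == pytest.approx(gp_ref, abs=1e-9)

    def test_extreme_reference_rejected(self):
        with pytest.raises(ValueError):
            mo.calibrate_g_factor(1.0, 1.0, 1.0)


class TestRoundTrip:
    def test_stack_to_rgm_and_gp_consistency(self, noiseless_lambda):
        # Band-integrated channels from the synthetic stack feed RGM and GP;
        # PM (f = 0.8, more ordered) must show lower RGM and higher GP than
        # the endosome region (f = 0.4).
        _, stack, mask = noiseless_lambda
        green = mo.band_integrate(stack, mo.GREEN_WINDOW_NM)
        red = mo.band_integrate(stack, mo.RED_WINDOW_NM)
        rgm_pm = mo.compute_rgm(green, red, mask, PM).rgm
        rgm_endo = mo.compute_rgm(green, red, mask, INTERIOR).rgm
        assert rgm_pm < rgm_endo
        gp = mo.compute_gp_image(green, red)
        # Noiseless regions have constant GP; compare region means directly.
        mean_pm = np.nanmean(gp.gp[mask.region(PM)])
        mean_endo = np.nanmean(gp.gp[mask.region(INTERIOR)])
        assert mean_pm > mean_endo
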