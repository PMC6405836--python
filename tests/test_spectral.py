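"""PCA band unmixing and the SI/SP/SW/ratio feature definitions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from translume import spectral as spc
from translume.errors import ConfigurationError, DomainError

WL = np.linspace(900.0, 1700.0, 161)  # 5 nm sampling


def line(center, sigma=12.0, amp=1.0):
    return amp * np.exp(-((WL - center) ** 2) / (2 * sigma**2))


class TestPcaSpectra:
    def test_constant_cube_retains_zero_components(self, hsc_factory):
        spectra = np.tile(line(1125.0), (3, 3, 1))
        with pytest.warns(UserWarning, match="no variance"):
            res = spc.pca_spectra(hsc_factory(spectra, WL))
        assert res.n_components == 0

    def test_two_populations_with_disjoint_lines(self, hsc_factory, rng):
        spectra = np.zeros((4, 4, WL.size))
        spectra[:2] = line(1125.0, amp=100.0)
        spectra[2:] = line(1575.0, amp=100.0)
        res = spc.pca_spectra(hsc_factory(spectra, WL))
        assert res.n_components == 1
        assert res.explained_variance_fraction[0] >= 0.99
        mag = np.abs(res.loadings[0])
        top = WL[np.argsort(mag)[-10:]]
        assert np.any(np.abs(top - 1125.0) < 15) and np.any(np.abs(top - 1575.0) < 15)

    def test_four_source_mixture_loadings_cover_all_lines(self, hsc_factory, rng):
        centers = [980.0, 1125.0, 1350.0, 1600.0]
        spectra = np.zeros((8, 8, WL.size))
        for c in centers:
            amps = rng.uniform(0, 100, (8, 8, 1))
            spectra += amps * line(c)
        res = spc.pca_spectra(hsc_factory(spectra, WL))
        covered = set()
        for load in res.loadings:
            mag = np.abs(load)
            strong = WL[mag >= 0.5 * mag.max()]
            for c in centers:
                if np.any(np.abs(strong - c) < 15):
                    covered.add(c)
        assert covered == set(centers)

    def test_rank_k_noiseless_cube_retains_exactly_k(self, hsc_factory, rng):
        for k in (1, 2, 3, 4):
            centers = [1000.0, 1150.0, 1330.0, 1620.0][:k]
            spectra = np.zeros((6, 6, WL.size))
            for c in centers:
                spectra += rng.uniform(0.1, 10, (6, 6, 1)) * line(c)
            res = spc.pca_spectra(hsc_factory(spectra, WL), variance_floor=1e-6)
            assert res.n_components == k

    def test_single_grid_point_is_rejected(self, hsc_factory):
        with pytest.raises(ConfigurationError):
            spc.pca_spectra(hsc_factory(np.ones((1, 1, WL.size)), WL))


class TestIdentifyBands:
    @staticmethod
    def _pca_of(spectra):
        from translume import hypercube as hc

        cube = hc.HyperSpectralCube(
            spectra,
            np.arange(spectra.shape[0], dtype=float),
            np.arange(spectra.shape[1], dtype=float),
            WL,
        )
        return spc.pca_spectra(cube)

    def test_single_peak_gives_one_band(self, rng):
        spectra = rng.uniform(0, 1, (5, 5, 1)) * line(1125.0)
        res = self._pca_of(spectra)
        bands = spc.identify_bands(res, WL)
        assert len(bands) == 1
        assert bands[0].lambda_lo_nm < 1125.0 < bands[0].lambda_hi_nm
        assert bands[0].band_class == "beta"

    def test_er_twin_peaks_give_two_bands_sharing_the_component(self, rng):
        er = line(1125.0, amp=0.5) + line(1575.0, amp=1.0)
        spectra = rng.uniform(0, 1, (5, 5, 1)) * er
        bands = spc.identify_bands(self._pca_of(spectra), WL, loading_threshold=0.3)
        assert len(bands) == 2
        assert bands[0].pc_indices == bands[1].pc_indices
        classes = {b.band_class for b in bands}
        assert classes == {"beta", "delta"}

    def test_threshold_one_degenerates_to_single_samples(self, rng):
        spectra = rng.uniform(0, 1, (4, 4, 1)) * line(1125.0)
        bands = spc.identify_bands(self._pca_of(spectra), WL, loading_threshold=1.0)
        assert all(b.lambda_lo_nm == b.lambda_hi_nm for b in bands)

    def test_overlapping_runs_from_different_components_merge(self):
        loadings = np.zeros((2, WL.size))
        loadings[0, 40:50] = 1.0
        loadings[1, 48:58] = 1.0
        res = spc.PCAResult(loadings, np.zeros((2, 2)), np.array([0.6, 0.4]))
        bands = spc.identify_bands(res, WL)
        assert len(bands) == 1
        assert bands[0].pc_indices == (0, 1)

    def test_no_components_gives_empty_list(self):
        res = spc.PCAResult(np.zeros((0, WL.size)), np.zeros((4, 0)), np.zeros(0))
        assert spc.identify_bands(res, WL) == []


@pytest.mark.parametrize(
    "center,expected",
    [
        (980.0, "alpha"),
        (1100.0, "beta"),
        (1350.0, "gamma"),
        (1600.0, "delta"),
        (1700.0, "delta"),
        (920.0, "other"),
        (1750.0, "other"),
    ],
)
def test_classify_band(center, expected):
    assert spc.classify_band(center) == expected


BAND_BETA = spc.SpectralBand("beta", 1050.0, 1250.0, (), "beta")


class TestSpectralIntensity:
    def test_delta_line_with_zero_baseline(self, hsc_factory):
        spectra = np.zeros((2, 2, WL.size))
        k = np.argmin(np.abs(WL - 1125.0))
        spectra[:, :, k] = 42.0
        si = spc.spectral_intensity(hsc_factory(spectra, WL), BAND_BETA)
        assert np.allclose(si.values, 42.0)

    def test_uniform_spectrum_cancelled_by_baseline(self, hsc_factory):
        spectra = np.full((2, 2, WL.size), 7.0)
        si = spc.spectral_intensity(hsc_factory(spectra, WL), BAND_BETA)
        assert np.allclose(si.values, 0.0)

    def test_gaussian_line_on_sloped_background(self, hsc_factory):
        area_sigma, amp = 20.0, 50.0
        slope = 0.001
        spectra = np.tile(
            line(1150.0, area_sigma, amp) + 5.0 + slope * (WL - 1150.0),
            (2, 2, 1),
        )
        band = spc.SpectralBand("b", 1050.0, 1250.0, (), "beta")
        si = spc.spectral_intensity(hsc_factory(spectra, WL), band)
        step = WL[1] - WL[0]
        analytic = amp * area_sigma * np.sqrt(2 * np.pi) / step
        assert si.values[0, 0] == pytest.approx(analytic, rel=0.05)

    def test_band_outside_cube_is_domain_error(self, hsc_factory):
        cube = hsc_factory(np.ones((2, 2, WL.size)), WL)
        with pytest.raises(DomainError):
            spc.spectral_intensity(cube, spc.SpectralBand("x", 1800.0, 1900.0))

    def test_additive_over_disjoint_bands_at_zero_baseline(self, hsc_factory, rng):
        spectra = rng.uniform(0, 1, (3, 3, 1)) * (line(1125.0) + line(1575.0))
        cube = hsc_factory(spectra, WL)
        b1 = spc.SpectralBand("b1", 1050.0, 1250.0)
        b2 = spc.SpectralBand("b2", 1500.0, 1650.0)
        union = spc.SpectralBand("u", 1050.0, 1650.0)
        # pass all_bands covering everything nonzero so the baseline is 0
        bands = [spc.SpectralBand("all", 900.0, 1700.0)]
        si1 = spc.spectral_intensity(cube, b1, bands)
        si2 = spc.spectral_intensity(cube, b2, bands)
        si_u = spc.spectral_intensity(cube, union, bands)
        # the union also integrates the inter-band gap, which is ~0 here
        assert np.allclose(si_u.values, si1.values + si2.values, rtol=1e-3, atol=1e-6)

    def test_scales_linearly_with_amplitude(self, hsc_factory):
        spectra = np.tile(line(1125.0, amp=10.0), (2, 2, 1))
        cube1 = hsc_factory(spectra, WL)
        cube2 = hsc_factory(spectra * 37.0, WL)
        si1 = spc.spectral_intensity(cube1, BAND_BETA)
        si2 = spc.spectral_intensity(cube2, BAND_BETA)
        assert np.allclose(si2.values, 37.0 * si1.values)


class TestSpectralPosition:
    def test_symmetric_line_centroid(self, hsc_factory):
        spectra = np.tile(line(1125.0), (2, 2, 1))
        sp = spc.spectral_position(hsc_factory(spectra, WL), BAND_BETA)
        assert np.allclose(sp.values, 1125.0, atol=0.5)

    def test_two_equal_delta_lines(self, hsc_factory):
        spectra = np.zeros((1, 1, WL.size))
        spectra[:, :, np.argmin(np.abs(WL - 1100.0))] = 5.0
        spectra[:, :, np.argmin(np.abs(WL - 1150.0))] = 5.0
        sp = spc.spectral_position(hsc_factory(spectra, WL), BAND_BETA)
        assert sp.values[0, 0] == pytest.approx(1125.0)

    def test_skewed_line_matches_loop_oracle(self, hsc_factory, rng):
        spectra = np.zeros((1, 1, WL.size))
        mask = BAND_BETA.mask(WL)
        spectra[0, 0, mask] = rng.uniform(0, 3, mask.sum())
        sp = spc.spectral_position(hsc_factory(spectra, WL), BAND_BETA)
        num = den = 0.0
        for lam, w in zip(WL[mask], spectra[0, 0, mask]):
            num += lam * w
            den += w
        assert sp.values[0, 0] == pytest.approx(num / den)

    def test_within_band_interval(self, hsc_factory, rng):
        spectra = rng.uniform(0, 1, (4, 4, WL.size))
        sp = spc.spectral_position(hsc_factory(spectra, WL), BAND_BETA)
        ok = np.isfinite(sp.values)
        assert np.all(sp.values[ok] >= BAND_BETA.lambda_lo_nm)
        assert np.all(sp.values[ok] <= BAND_BETA.lambda_hi_nm)

    def test_empty_band_pixel_is_missing_not_nan_propagation(self, hsc_factory):
        spectra = np.zeros((2, 1, WL.size))
        spectra[0, 0] = line(1125.0)
        sp = spc.spectral_position(hsc_factory(spectra, WL), BAND_BETA)
        assert np.isfinite(sp.values[0, 0])
        assert np.isnan(sp.values[1, 0])


class TestSpectralWidth:
    def test_single_delta_line_has_zero_width(self, hsc_factory):
        spectra = np.zeros((1, 1, WL.size))
        spectra[:, :, np.argmin(np.abs(WL - 1125.0))] = 9.0
        sw = spc.spectral_width(hsc_factory(spectra, WL), BAND_BETA)
        assert sw.values[0, 0] == pytest.approx(0.0, abs=1e-9)

    def test_gaussian_line_gives_fwhm(self, hsc_factory):
        sw = spc.spectral_width(
            hsc_factory(np.tile(line(1125.0, 10.0), (1, 1, 1)), WL), BAND_BETA
        )
        assert sw.values[0, 0] == pytest.approx(23.548, rel=0.02)

    def test_uniform_band_matches_closed_form(self, hsc_factory):
        band = spc.SpectralBand("u", 1050.0, 1250.0)
        mask = band.mask(WL)
        spectra = np.zeros((1, 1, WL.size))
        spectra[0, 0, mask] = 3.0
        sw = spc.spectral_width(hsc_factory(spectra, WL), band)
        n = mask.sum()
        step = WL[1] - WL[0]
        width = n * step
        # discrete uniform: var = (n^2 - 1) step^2 / 12 -> W/sqrt(12) limit
        exact = 2 * np.sqrt(2 * np.log(2)) * step * np.sqrt((n**2 - 1) / 12.0)
        assert sw.values[0, 0] == pytest.approx(exact, rel=1e-9)
        assert sw.values[0, 0] == pytest.approx(
            2 * np.sqrt(2 * np.log(2)) * width / np.sqrt(12), rel=0.05
        )

    def test_invariant_under_amplitude_scaling(self, hsc_factory, rng):
        spectra = np.zeros((1, 1, WL.size))
        mask = BAND_BETA.mask(WL)
        spectra[0, 0, mask] = rng.uniform(0, 2, mask.sum())
        sw1 = spc.spectral_width(hsc_factory(spectra, WL), BAND_BETA)
        for scale in (10.0, 1000.0):
            sw2 = spc.spectral_width(hsc_factory(spectra * scale, WL), BAND_BETA)
            assert sw2.values[0, 0] == pytest.approx(sw1.values[0, 0], rel=1e-9)


class TestInterbandRatio:
    def _map(self, values):
        v = np.asarray(values, float)
        return spc.FeatureMap(v, np.arange(v.shape[0]), np.arange(v.shape[1]), "SI")

    def test_equal_maps_give_unity(self):
        m = self._map(np.full((3, 3), 50.0))
        assert np.allclose(spc.interband_ratio(m, m).values, 1.0)

    def test_zero_denominator_is_guarded(self):
        num = self._map(np.full((2, 2), 10.0))
        den = self._map(np.zeros((2, 2)))
        ratio = spc.interband_ratio(num, den, epsilon=1.0)
        assert np.allclose(ratio.values, 10.0)
        assert np.all(np.isfinite(ratio.values))

    def test_grid_mismatch_is_domain_error(self):
        with pytest.raises(DomainError):
            spc.interband_ratio(self._map(np.ones((2, 2))), self._map(np.ones((3, 3))))


class TestStokesShift:
    @pytest.mark.parametrize(
        "ex,em,shift,cls",
        [
            (980.0, 980.0, 0.0, "small"),
            (980.0, 1100.0, 1113.2, "small"),
            (980.0, 1350.0, 2796.7, "large"),
            (980.0, 1250.0, 2204.1, "intermediate"),
        ],
    )
    def test_values_and_classes(self, ex, em, shift, cls):
        got_shift, got_cls = spc.stokes_shift(ex, em)
        assert got_shift == pytest.approx(shift, abs=0.5)
        assert got_cls == cls

    def test_anti_stokes_is_domain_error(self):
        with pytest.raises(DomainError):
            spc.stokes_shift(1100.0, 980.0)

    @given(
        em1=st.floats(980.0, 1690.0),
        delta=st.floats(0.5, 200.0),
    )
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_shift_increases_with_emission_wavelength(self, em1, delta):
        s1, _ = spc.stokes_shift(980.0, em1)
        s2, _ = spc.stokes_shift(980.0, em1 + delta)
        assert s2 > s1 >= 0.0
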