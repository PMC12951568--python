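"""Spectral preprocessing and Q-band feature extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from photosar.spectra import (
    Spectrum,
    integrate_emission,
    preprocess,
    q_band_features,
    stokes_shift,
)

from conftest import make_spectrum


def gaussian_band(center, height, fwhm=18.0, lo=500.0, hi=900.0, step=0.5, **kw):
    wl = lo + step * np.arange(int((hi - lo) / step) + 1)
    sigma = fwhm / (2 * np.sqrt(2 * np.log(2)))
    vals = height * np.exp(-0.5 * ((wl - center) / sigma) ** 2)
    return Spectrum(kind="absorption", wavelengths_nm=wl, values=vals, **kw)


class TestPreprocess:
    def test_identity_baseline_gives_zero(self):
        raw = make_spectrum(values=0.5)
        assert np.allclose(preprocess(raw, raw, 0.5).values, 0.0)

    def test_constant_shift(self):
        out = preprocess(make_spectrum(values=0.5), make_spectrum(values=0.1), 0.5)
        assert np.allclose(out.values, 0.4)
        assert np.allclose(np.diff(out.wavelengths_nm), 0.5)

    def test_linear_interpolation_midpoints(self):
        # ramp sampled at 1 nm regridded to 0.5 nm: midpoints are means
        # of neighbours (closed-form linear interpolation)
        wl = np.arange(400.0, 501.0)
        raw = Spectrum(kind="absorption", wavelengths_nm=wl, values=0.01 * (wl - 400))
        zero = Spectrum(kind="absorption", wavelengths_nm=wl, values=np.zeros_like(wl))
        out = preprocess(raw, zero, 0.5)
        mids = out.values[1::2]
        expected = 0.5 * (out.values[:-1:2] + out.values[2::2])
        assert np.allclose(mids, expected)

    def test_idempotent_on_gridded_zero_baseline(self):
        raw = make_spectrum(lo=400, hi=800, n=801, values=0.3)
        zero = make_spectrum(lo=400, hi=800, n=801)
        once = preprocess(raw, zero, 0.5)
        twice = preprocess(once, zero, 0.5)
        assert np.allclose(once.wavelengths_nm, twice.wavelengths_nm)
        assert np.allclose(once.values, twice.values)

    def test_disjoint_ranges_error(self):
        with pytest.raises(ValueError, match="overlap"):
            preprocess(make_spectrum(lo=400, hi=500), make_spectrum(lo=600, hi=700), 0.5)

    def test_kind_mismatch_error(self):
        with pytest.raises(ValueError, match="kind"):
            preprocess(make_spectrum(), make_spectrum(kind="emission"), 0.5)


class TestQBandFeatures:
    def test_single_gaussian_beer_lambert(self):
        spec = gaussian_band(681.0, 0.1, concentration_M=1e-6)
        f = q_band_features(spec, window_nm=(600, 760))
        assert f.maxima_nm == (681.0,)
        assert not f.split
        assert f.epsilon_M1cm1 == pytest.approx(100_000, rel=1e-6)
        assert f.fwhm_nm == pytest.approx(18.0, rel=0.05)

    def test_split_band_two_maxima(self):
        # split Q-band pattern of a low-symmetry metal-free macrocycle
        a = gaussian_band(694.0, 0.10)
        b = gaussian_band(662.0, 0.095)
        spec = Spectrum(
            kind="absorption", wavelengths_nm=a.wavelengths_nm, values=a.values + b.values
        )
        f = q_band_features(spec, window_nm=(600, 760))
        assert f.split
        assert sorted(f.maxima_nm) == [662.0, 694.0]

    def test_alpha_vs_beta_substitution_shift(self):
        # octa-alpha vs octa-beta congeners: 757 vs 704 nm maxima
        f_alpha = q_band_features(gaussian_band(757.0, 0.13), window_nm=(620, 820))
        f_beta = q_band_features(gaussian_band(704.0, 0.28), window_nm=(620, 820))
        assert f_alpha.lambda_max_nm - f_beta.lambda_max_nm == pytest.approx(53.0)

    def test_scale_invariance_of_maxima_and_split(self):
        spec = gaussian_band(681.0, 0.1, concentration_M=1e-6)
        f1 = q_band_features(spec, window_nm=(600, 760))
        f2 = q_band_features(spec.scaled(7.5), window_nm=(600, 760))
        assert f1.maxima_nm == f2.maxima_nm
        assert f1.split == f2.split
        assert f2.epsilon_M1cm1 == pytest.approx(7.5 * f1.epsilon_M1cm1)

    def test_flat_spectrum_error(self):
        with pytest.raises(ValueError, match="no Q-band"):
            q_band_features(make_spectrum(values=0.2), window_nm=(500, 700))

    def test_missing_concentration_gives_no_epsilon(self):
        f = q_band_features(gaussian_band(681.0, 0.1), window_nm=(600, 760))
        assert f.epsilon_M1cm1 is None

    def test_aggregation_index_against_reference(self):
        mono = gaussian_band(680.0, 1.0, concentration_M=1e-6)
        half = gaussian_band(680.0, 0.4, concentration_M=1e-6)
        f = q_band_features(half, window_nm=(600, 760), monomer_reference=mono)
        assert f.aggregation_index == pytest.approx(0.6, abs=1e-9)

    def test_fwhm_proxy_flagged_without_reference(self):
        broad = gaussian_band(680.0, 0.5, fwhm=36.0)
        f = q_band_features(broad, window_nm=(600, 760))
        assert "aggregation_index_from_fwhm_proxy" in f.flags
        assert f.aggregation_index == pytest.approx(0.5, abs=0.05)


class TestIntegrateEmission:
    def test_zero_spectrum(self):
        assert integrate_emission(make_spectrum(kind="emission"), (500, 700)) == 0.0

    def test_constant_rectangle(self):
        spec = make_spectrum(kind="emission", values=1.0)
        assert integrate_emission(spec, (500, 600)) == pytest.approx(100.0)

    def test_triangle_geometric_area(self):
        wl = np.array([600.0, 640.0, 650.0, 660.0, 700.0])
        vals = np.array([0.0, 0.0, 1.0, 0.0, 0.0])
        spec = Spectrum(kind="emission", wavelengths_nm=wl, values=vals, excitation_nm=550)
        assert integrate_emission(spec, (600, 700)) == pytest.approx(10.0)

    def test_additive_over_subranges(self):
        spec = make_spectrum(kind="emission", values=None)
        rng = np.random.default_rng(0)
        spec = Spectrum(
            kind="emission",
            wavelengths_nm=spec.wavelengths_nm,
            values=rng.uniform(0, 1, spec.wavelengths_nm.size),
            excitation_nm=550,
        )
        total = integrate_emission(spec, (450, 750))
        parts = integrate_emission(spec, (450, 612.3)) + integrate_emission(spec, (612.3, 750))
        assert parts == pytest.approx(total, rel=1e-12)

    def test_grid_refinement_exact_for_piecewise_linear(self):
        wl = np.linspace(500, 700, 21)
        vals = 2.0 + 0.01 * (wl - 500)
        coarse = Spectrum(kind="emission", wavelengths_nm=wl, values=vals, excitation_nm=450)
        wl_f = np.linspace(500, 700, 401)
        fine = Spectrum(
            kind="emission",
            wavelengths_nm=wl_f,
            values=np.interp(wl_f, wl, vals),
            excitation_nm=450,
        )
        assert integrate_emission(coarse, (500, 700)) == pytest.approx(
            integrate_emission(fine, (500, 700)), rel=1e-12
        )

    def test_empty_range_error(self):
        with pytest.raises(ValueError, match="empty"):
            integrate_emission(make_spectrum(kind="emission"), (600, 600))


class TestStokesShift:
    @pytest.mark.parametrize(
        "lam_a,lam_f,expected",
        [(673.0, 682.0, 9.0), (700.0, 700.0, 0.0), (629.0, 641.0, 12.0)],
    )
    def test_values(self, lam_a, lam_f, expected):
        assert stokes_shift(lam_a, lam_f) == pytest.approx(expected)

    def test_negative_shift_warns(self):
        with pytest.warns(UserWarning, match="negative Stokes"):
            assert stokes_shift(700.0, 690.0) == -10.0

    @given(lam_a=st.floats(600, 800), shift=st.floats(1.0, 30.0))
    @settings(max_examples=50, deadline=None)
    def test_mirror_construction_positive(self, lam_a, shift):
        assert stokes_shift(lam_a, lam_a + shift) > 0


class TestSpectrumInvariants:
    def test_transmittance_bounds_enforced(self):
        with pytest.raises(ValueError, match="transmittance"):
            make_spectrum(kind="transmittance", values=1.2)

    def test_nonincreasing_wavelengths_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            Spectrum(
                kind="absorption",
                wavelengths_nm=np.array([500.0, 500.0, 501.0]),
                values=np.zeros(3),
            )

    def test_emission_requires_excitation(self):
        with pytest.raises(ValueError, match="excitation"):
            Spectrum(
                kind="emission",
                wavelengths_nm=np.array([500.0, 501.0]),
                values=np.zeros(2),
            )
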