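"""Optical model: aperture flux, dichroic absorption, PS, absorptance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.constants import c as C_LIGHT
from scipy.constants import h as PLANCK

from tieredpol import (
    CANONICAL_ABSORPTANCE,
    DichroicAbsorption,
    OpticalGeometry,
    SpectralRadiance,
    TieredPairGeometry,
    absorptance_function,
    birefringence_phase,
    broadband_absorption_rates,
    canonical_absorptance,
    exact_absorptance,
    fit_absorptance_polynomial,
    irradiance_to_radiance,
    make_delta_spectrum,
    mono_absorption_rates,
    photon_flux_at_aperture,
    pigment_template,
    polarization_sensitivity,
    read_spectrum_csv,
    split_polarization,
)

WL = np.linspace(300.0, 412.0, 113)


class TestApertureFlux:
    def test_zero_radiance_gives_zero_flux(self):
        spec = SpectralRadiance(WL, np.zeros_like(WL))
        assert photon_flux_at_aperture(spec, OpticalGeometry()) == 0.0

    def test_flat_spectrum_closed_form(self):
        l0 = 3.7e17
        spec = SpectralRadiance(WL, np.full_like(WL, l0))
        expected = (np.pi / 4) ** 2 * 0.25 * (1.55e-6) ** 2 * l0 * 112.0
        got = photon_flux_at_aperture(spec, OpticalGeometry(2.0, 1.55))
        assert got == pytest.approx(expected, rel=1e-12)

    def test_linearity_in_radiance(self):
        rng = np.random.default_rng(7)
        ra = rng.uniform(0.0, 1e18, WL.size)
        geom = OpticalGeometry()
        f1 = photon_flux_at_aperture(SpectralRadiance(WL, ra), geom)
        f2 = photon_flux_at_aperture(SpectralRadiance(WL, 2 * ra), geom)
        assert f2 == pytest.approx(2 * f1, rel=1e-12)

    def test_grid_not_covering_window_rejected(self):
        with pytest.raises(ValueError, match="cover"):
            SpectralRadiance(np.linspace(320, 412, 50), np.ones(50))


class TestIrradianceConversion:
    def test_zero_irradiance(self):
        out = irradiance_to_radiance(WL, np.zeros_like(WL))
        assert np.all(out.radiance == 0)

    def test_unit_irradiance_at_400nm(self):
        out = irradiance_to_radiance(WL, np.ones_like(WL))
        expected = 400e-9 / (np.pi * PLANCK * C_LIGHT)
        idx = np.argmin(np.abs(WL - 400.0))
        assert out.radiance[idx] == pytest.approx(expected, rel=1e-12)

    def test_proportional_to_wavelength(self):
        out = irradiance_to_radiance(WL, np.ones_like(WL))
        assert np.allclose(out.radiance / WL, out.radiance[0] / WL[0])

    def test_negative_irradiance_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            irradiance_to_radiance(WL, np.full_like(WL, -1.0))


class TestPolarizationSplit:
    @pytest.mark.parametrize(
        "flux,degree,angle,expected",
        [
            (100.0, 0.0, 17.0, (50.0, 50.0)),
            (100.0, 1.0, 0.0, (100.0, 0.0)),
            (100.0, 1.0, 30.0, (75.0, 25.0)),
        ],
    )
    def test_known_decompositions(self, flux, degree, angle, expected):
        light = split_polarization(flux, degree, angle)
        assert light.n_parallel == pytest.approx(expected[0], abs=1e-9)
        assert light.n_perpendicular == pytest.approx(expected[1], abs=1e-9)

    def test_invalid_degree_rejected(self):
        with pytest.raises(ValueError):
            split_polarization(100.0, 1.5, 0.0)

    @settings(derandomize=True, max_examples=50)
    @given(
        flux=st.floats(0.0, 1e8),
        degree=st.floats(0.0, 1.0),
        angle=st.floats(-360.0, 360.0),
    )
    def test_components_conserve_total(self, flux, degree, angle):
        light = split_polarization(flux, degree, angle)
        assert light.n_parallel >= -1e-9 * max(flux, 1.0)
        assert light.n_perpendicular >= -1e-9 * max(flux, 1.0)
        assert light.n_parallel + light.n_perpendicular == pytest.approx(flux, rel=1e-12, abs=1e-12)


class TestMonochromaticAbsorption:
    def test_zero_length_r7_absorbs_nothing(self, dichroic):
        pair = TieredPairGeometry(100.0, 1.0)
        light = split_polarization(1e5, 0.5, 20.0)
        rates = mono_absorption_rates(pair, dichroic, light)
        assert rates.a7 == 0.0

    @settings(derandomize=True, max_examples=40)
    @given(
        frac=st.floats(0.0, 1.0),
        degree=st.floats(0.0, 1.0),
        angle=st.floats(0.0, 180.0),
    )
    def test_photon_conservation_per_component(self, dichroic, frac, degree, angle):
        """Absorbed plus transmitted photons equal incident, exactly."""
        pair = TieredPairGeometry(137.0, frac)
        light = split_polarization(1e6, degree, angle)
        r = mono_absorption_rates(pair, dichroic, light)
        k_par, k_perp = dichroic.k_parallel, dichroic.k_perpendicular
        trans_par = light.n_parallel * np.exp(-k_par * pair.l7 - k_perp * pair.l8)
        trans_perp = light.n_perpendicular * np.exp(-k_perp * pair.l7 - k_par * pair.l8)
        assert r.a_par_7 + r.a_par_8 + trans_par == pytest.approx(
            light.n_parallel, rel=1e-12
        )
        assert r.a_perp_7 + r.a_perp_8 + trans_perp == pytest.approx(
            light.n_perpendicular, rel=1e-12
        )

    def test_r7_max_min_ratio_for_equal_split(self, dichroic, pair_equal):
        """Self-screening lowers R7's max/min absorption ratio to 7.5."""
        at_max = mono_absorption_rates(pair_equal, dichroic, split_polarization(1e5, 1.0, 0.0))
        at_min = mono_absorption_rates(pair_equal, dichroic, split_polarization(1e5, 1.0, 90.0))
        assert at_max.a7 / at_min.a7 == pytest.approx(7.5, abs=0.05)


class TestAbsorptance:
    def test_zero_length_absorbs_nothing(self):
        spec = SpectralRadiance(WL, np.ones_like(WL))
        assert exact_absorptance(spec, pigment_template, 0.0075, 0.0) == 0.0

    def test_saturates_to_in_band_fraction(self):
        spec = SpectralRadiance(WL, np.ones_like(WL))
        frac = exact_absorptance(spec, pigment_template, 0.0075, 1e7)
        assert 0.99 < frac <= 1.0 + 1e-12

    def test_delta_spectrum_reduces_to_single_exponential(self):
        spec = make_delta_spectrum(335.0)
        for l in (10.0, 100.0, 500.0):
            got = exact_absorptance(spec, pigment_template, 0.0075, l)
            assert got == pytest.approx(1.0 - np.exp(-0.0075 * l), rel=1e-9)

    def test_refit_from_canonical_samples_recovers_coefficients(self):
        """Fitting data generated by the model itself is self-consistent."""
        kappa = np.linspace(0.15, 7.5, 50)
        y = CANONICAL_ABSORPTANCE(kappa)
        base = 1.0 - np.exp(-kappa)
        design = np.vstack([base / y, base * kappa / y, base * kappa**2 / y]).T
        coeffs, *_ = np.linalg.lstsq(design, np.ones_like(y), rcond=None)
        assert np.allclose(coeffs, CANONICAL_ABSORPTANCE.coefficients, rtol=1e-6)

    def test_fit_quality_below_one_percent_up_to_1mm(self):
        """The cubic-in-kappa form tracks exact absorptance to <1% relative
        error for rhabdomeres up to 1 mm (unpolarized optical depth 7.5)."""
        from tieredpol import make_daylight_spectrum

        fit = fit_absorptance_polynomial(make_daylight_spectrum(), pigment_template)
        assert fit.max_rel_error is not None and fit.max_rel_error < 0.01
        assert not fit.fit_flagged

    def test_fit_vanishes_at_zero_depth(self):
        from tieredpol import make_daylight_spectrum

        fit = fit_absorptance_polynomial(make_daylight_spectrum(), pigment_template)
        assert fit(0.0) == 0.0


class TestCanonicalAbsorptance:
    def test_zero_depth(self):
        assert canonical_absorptance(0.0) == 0.0

    def test_printed_value_at_100um_parallel_depth(self):
        # kappa for k_par * 100 um with k = 0.0075, delta = 10
        assert canonical_absorptance(1.36364) == pytest.approx(0.4016, abs=2e-4)

    def test_strictly_increasing_over_validity_range(self):
        kappa = np.arange(0.0, CANONICAL_ABSORPTANCE.kappa_max + 1e-9, 0.01)
        assert np.all(np.diff(canonical_absorptance(kappa)) > 0)

    def test_bounded_in_unit_interval(self):
        kappa = np.linspace(0.0, CANONICAL_ABSORPTANCE.kappa_max, 1000)
        vals = canonical_absorptance(kappa)
        assert np.all(vals >= 0) and np.all(vals <= 1)

    def test_out_of_range_depth_rejected(self):
        with pytest.raises(ValueError, match="validity"):
            canonical_absorptance(20.0)
        with pytest.raises(ValueError, match="validity"):
            canonical_absorptance(-0.1)


class TestBroadbandAbsorption:
    def test_vanishing_r8_absorbs_nothing(self, dichroic):
        pair = TieredPairGeometry(100.0, 0.0)
        light = split_polarization(1e5, 0.3, 40.0)
        assert broadband_absorption_rates(pair, dichroic, light).a8 == 0.0

    def test_pair_total_equals_stacked_absorptance(self, dichroic):
        """R7 + R8 absorption telescopes to the whole-pair absorptance."""
        pair = TieredPairGeometry(220.0, 0.37)
        light = split_polarization(1e6, 0.8, 25.0)
        r = broadband_absorption_rates(pair, dichroic, light)
        k_par, k_perp = dichroic.k_parallel, dichroic.k_perpendicular
        total_par = CANONICAL_ABSORPTANCE(k_par * pair.l7 + k_perp * pair.l8)
        assert r.a_par_7 + r.a_par_8 == pytest.approx(
            total_par * light.n_parallel, rel=1e-12
        )

    def test_unpolarized_light_averages_components(self, dichroic, pair_equal):
        light = split_polarization(2e5, 0.0, 0.0)
        r = broadband_absorption_rates(pair_equal, dichroic, light)
        k_par, k_perp = dichroic.k_parallel, dichroic.k_perpendicular
        expected = (
            2e5
            * 0.5
            * (
                CANONICAL_ABSORPTANCE(k_par * 50.0)
                + CANONICAL_ABSORPTANCE(k_perp * 50.0)
            )
        )
        assert r.a7 == pytest.approx(expected, rel=1e-12)

    def test_matches_monochromatic_for_delta_spectrum(self, dichroic):
        """With all radiance at the peak wavelength the broadband machinery
        must reduce to the single-exponential monochromatic rates."""
        fa = absorptance_function(make_delta_spectrum(335.0), pigment_template)
        pair = TieredPairGeometry(100.0, 0.35)
        light = split_polarization(1e5, 1.0, 30.0)
        bb = broadband_absorption_rates(pair, dichroic, light, fa)
        mono = mono_absorption_rates(pair, dichroic, light)
        assert bb.a7 == pytest.approx(mono.a7, rel=1e-9)
        assert bb.a8 == pytest.approx(mono.a8, rel=1e-9)


class TestPolarizationSensitivity:
    @pytest.mark.parametrize("mode", ["monochromatic", "broadband"])
    @pytest.mark.parametrize("receptor", [7, 8])
    def test_vanishing_receptor_keeps_dichroic_ratio(self, dichroic, mode, receptor):
        pair = TieredPairGeometry(1e-3, 0.5)
        ps = polarization_sensitivity(receptor, pair, dichroic, mode)
        assert ps == pytest.approx(10.0, rel=1e-3)

    def test_peak_wavelength_values_for_equal_split(self, dichroic, pair_equal):
        assert polarization_sensitivity(7, pair_equal, dichroic, "monochromatic") == pytest.approx(7.5, abs=0.05)
        assert polarization_sensitivity(8, pair_equal, dichroic, "monochromatic") == pytest.approx(13.9, abs=0.05)

    def test_filtering_limit_exceeds_dichroic_ratio(self, dichroic):
        """A vanishing R8 behind a 100 um R7 more than triples its PS."""
        pair = TieredPairGeometry(100.0, 0.0)
        ps8 = polarization_sensitivity(8, pair, dichroic, "monochromatic")
        assert round(ps8) == 34

    @pytest.mark.parametrize("l7", [10.0, 50.0, 100.0, 200.0])
    def test_vanishing_r8_closed_form(self, dichroic, l7):
        """Numerical limit agrees with delta * exp((k_par - k_perp) l7)."""
        l8 = 1e-4  # small but above the analytic-limit switchover
        tiny = TieredPairGeometry(l7 + l8, l8 / (l7 + l8))
        numeric = polarization_sensitivity(8, tiny, dichroic, "monochromatic")
        k_par, k_perp = dichroic.k_parallel, dichroic.k_perpendicular
        closed = 10.0 * np.exp((k_par - k_perp) * l7)
        assert numeric == pytest.approx(closed, rel=1e-6)

    def test_ps_at_least_one_everywhere(self, dichroic):
        for frac in np.linspace(0.0, 1.0, 21):
            pair = TieredPairGeometry(100.0, float(frac))
            for rec in (7, 8):
                assert polarization_sensitivity(rec, pair, dichroic) >= 1.0


class TestBirefringence:
    def test_isotropic_medium_has_no_retardation(self):
        assert birefringence_phase(60.0, 0.0, 335.0) == 0.0

    def test_fly_rhabdomere_phase_below_printed_bound(self):
        phase = birefringence_phase(60.0, 1e-3, 335.0)
        assert phase == pytest.approx(1.125, abs=0.005)
        assert phase < 1.13

    def test_linear_in_length(self):
        assert birefringence_phase(120.0, 1e-3, 335.0) == pytest.approx(
            2 * birefringence_phase(60.0, 1e-3, 335.0), rel=1e-12
        )


class TestSpectrumCsv:
    def test_radiance_roundtrip(self, tmp_path):
        path = tmp_path / "sky.csv"
        ra = np.linspace(1.0, 2.0, WL.size)
        lines = ["wavelength_nm,radiance_photons"]
        lines += [f"{w},{r}" for w, r in zip(WL, ra)]
        path.write_text("\n".join(lines))
        spec = read_spectrum_csv(path)
        assert np.allclose(spec.radiance, ra)

    def test_irradiance_column_is_converted(self, tmp_path):
        path = tmp_path / "sky.csv"
        lines = ["wavelength_nm,irradiance_W_m2_nm"]
        lines += [f"{w},1.0" for w in WL]
        path.write_text("\n".join(lines))
        spec = read_spectrum_csv(path)
        expected = WL * 1e-9 / (np.pi * PLANCK * C_LIGHT)
        assert np.allclose(spec.radiance, expected)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("a,b\n1,2\n")
        with pytest.raises(ValueError):
            read_spectrum_csv(path)
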