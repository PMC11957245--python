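"""Spectral core: conversions, Gaussian broadening, spectrum algebra."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import tamraspec as ts
from tamraspec.errors import DomainError, GridError, NoPeakError


class TestEnergyWavelength:
    @pytest.mark.parametrize(
        "energy_eV, lambda_nm",
        [(2.69, 461), (2.97, 417), (2.55, 486), (2.37, 523)],
    )
    def test_printed_table_pairs(self, energy_eV, lambda_nm):
        assert round(ts.energy_to_wavelength(energy_eV)) == lambda_nm

    def test_hc_definition(self):
        assert ts.energy_to_wavelength(1.23984193) == pytest.approx(1000.0)

    @given(st.floats(0.5, 10.0), st.floats(0.5, 10.0))
    def test_strictly_decreasing(self, e1, e2):
        if e1 != e2:
            lo, hi = min(e1, e2), max(e1, e2)
            assert ts.energy_to_wavelength(lo) > ts.energy_to_wavelength(hi)

    @given(st.floats(200.0, 1200.0))
    def test_roundtrip_identity(self, wl):
        back = ts.energy_to_wavelength(ts.wavelength_to_energy(wl))
        assert back == pytest.approx(wl, rel=1e-10)

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_nonpositive_rejected(self, bad):
        with pytest.raises(DomainError):
            ts.energy_to_wavelength(bad)


class TestBroaden:
    def test_single_state_peak_position(self):
        es = ts.ExcitationSet.from_pairs("one", [(2.69, 0.8692)])
        assert ts.find_lambda_max(ts.broaden(es)) == pytest.approx(461, abs=1)

    def test_empty_set_gives_zero_spectrum(self):
        sp = ts.broaden(ts.ExcitationSet("dark", ()))
        assert np.all(sp.intensities == 0)
        assert len(sp) == 1001

    def test_two_state_band_structure(self, b3lyp_set):
        """The weak second state forms a shoulder, not a separate peak.

        Brute-force evaluation of the two-Gaussian sum on a 0.0005 eV energy
        grid shows a single local maximum near 461 nm; at 424 nm the second
        state raises the intensity well above the single-state tail.
        """
        sp = ts.broaden(b3lyp_set)
        assert ts.find_lambda_max(sp) == pytest.approx(461, abs=1)
        sigma = ts.hwhm_to_sigma(0.1)
        grid_eV = np.arange(2.0, 3.5, 0.0005)
        oracle = 0.8692 * np.exp(-((grid_eV - 2.69) ** 2) / (2 * sigma**2)) + \
            0.1259 * np.exp(-((grid_eV - 2.92) ** 2) / (2 * sigma**2))
        interior = slice(1, -1)
        local_max = (oracle[interior] > oracle[:-2]) & (oracle[interior] > oracle[2:])
        assert local_max.sum() == 1
        single = ts.broaden(ts.ExcitationSet.from_pairs("one", [(2.69, 0.8692)]))
        i424 = np.argmin(np.abs(sp.wavelengths_nm - 424.0))
        assert sp.intensities[i424] > 5 * single.intensities[i424]

    def test_matches_double_loop_oracle(self):
        """Vectorized broadening equals a naive per-point double loop."""
        rng = np.random.default_rng(42)
        pairs = [(float(e), float(f)) for e, f in
                 zip(rng.uniform(1.8, 4.0, 10), rng.uniform(0.0, 1.2, 10))]
        es = ts.ExcitationSet.from_pairs("rand", pairs)
        params = ts.BroadeningParams()
        sp = ts.broaden(es, params)
        sigma = params.sigma_eV
        for i in range(0, len(sp), 97):
            energy = ts.HC_EV_NM / sp.wavelengths_nm[i]
            expected = sum(
                f * np.exp(-((energy - e) ** 2) / (2 * sigma**2))
                for e, f in pairs
            )
            assert sp.intensities[i] == pytest.approx(expected, rel=1e-12)

    @given(
        st.lists(
            st.tuples(st.floats(1.6, 4.1), st.floats(0.0, 2.0)),
            min_size=0, max_size=6,
        )
    )
    def test_nonnegative_everywhere(self, pairs):
        sp = ts.broaden(ts.ExcitationSet.from_pairs("h", pairs))
        assert np.all(sp.intensities >= 0)

    def test_energy_integral_proportional_to_total_strength(self):
        """Closed-form Gaussian area: integral over E = sigma*sqrt(2pi)*sum(f)."""
        es = ts.ExcitationSet.from_pairs("sum", [(2.5, 0.3), (3.0, 0.7)])
        params = ts.BroadeningParams(grid_min_nm=200, grid_max_nm=1400,
                                     grid_step_nm=0.1)
        sp = ts.broaden(es, params)
        grid_eV = ts.HC_EV_NM / sp.wavelengths_nm[::-1]
        integral = np.trapezoid(sp.intensities[::-1], grid_eV)
        expected = params.sigma_eV * np.sqrt(2 * np.pi) * 1.0
        assert integral == pytest.approx(expected, rel=5e-3)


class TestAverageAndResample:
    def test_mean_of_identical_copies_is_identity(self, simple_spectrum):
        avg = ts.average_spectra([simple_spectrum] * 5)
        assert np.array_equal(avg.intensities, simple_spectrum.intensities)
        assert avg.meta["n_conformers"] == 5

    def test_pointwise_half_sum(self):
        a = ts.broaden(ts.ExcitationSet.from_pairs("a", [(2.5, 0.5)]))
        b = ts.broaden(ts.ExcitationSet.from_pairs("b", [(3.0, 0.5)]))
        avg = ts.average_spectra([a, b])
        np.testing.assert_allclose(
            avg.intensities, 0.5 * (a.intensities + b.intensities), rtol=1e-15
        )

    def test_empty_list_rejected(self):
        with pytest.raises(DomainError):
            ts.average_spectra([])

    def test_mismatched_grids_rejected(self, simple_spectrum):
        other = ts.resample_spectrum(simple_spectrum, np.arange(310.0, 790.0, 1.0))
        with pytest.raises(GridError):
            ts.average_spectra([simple_spectrum, other])

    def test_resample_same_grid_is_identity(self, simple_spectrum):
        out = ts.resample_spectrum(simple_spectrum, simple_spectrum.wavelengths_nm)
        np.testing.assert_array_equal(out.intensities, simple_spectrum.intensities)

    def test_resample_linear_ramp_exact_at_midpoints(self):
        wl = np.arange(400.0, 500.0, 1.0)
        ramp = ts.Spectrum(wl, 2.0 * wl - 700.0)
        mid = wl[:-1] + 0.5
        out = ts.resample_spectrum(ramp, mid)
        np.testing.assert_allclose(out.intensities, 2.0 * mid - 700.0, rtol=1e-14)

    def test_resample_zero_outside_support(self, simple_spectrum):
        out = ts.resample_spectrum(simple_spectrum, np.array([100.0, 500.0, 900.0]))
        assert out.intensities[0] == 0.0 and out.intensities[2] == 0.0

    def test_roundtrip_fine_coarse_fine(self, b3lyp_set):
        sp = ts.broaden(b3lyp_set)
        coarse = ts.resample_spectrum(sp, np.arange(300.0, 800.5, 2.0))
        back = ts.resample_spectrum(coarse, sp.wavelengths_nm)
        err = np.max(np.abs(back.intensities - sp.intensities)) / sp.intensities.max()
        assert err < 0.01


class TestPeaks:
    def test_symmetric_band_center(self, simple_spectrum):
        assert ts.find_lambda_max(simple_spectrum) == pytest.approx(500.0, abs=1e-6)

    def test_tie_broken_toward_longer_wavelength(self):
        wl = np.arange(400.0, 410.0, 1.0)
        inten = np.zeros_like(wl)
        inten[[2, 7]] = 1.0
        assert ts.find_lambda_max(ts.Spectrum(wl, inten)) == 407.0

    def test_all_zero_has_no_peak(self):
        sp = ts.Spectrum(np.arange(400.0, 500.0), np.zeros(100))
        with pytest.raises(NoPeakError):
            ts.find_lambda_max(sp)

    def test_window_restricts_search(self, b3lyp_set):
        sp = ts.broaden(b3lyp_set)
        lmax = ts.find_lambda_max(sp, window_nm=(400.0, 440.0))
        assert 400.0 <= lmax <= 440.0

    def test_band_shift_identical_zero(self, simple_spectrum):
        assert ts.band_shift(simple_spectrum, simple_spectrum) == 0.0

    def test_band_shift_amine_sixty_degrees(self):
        """Planar vs 60-degree amine-rotated single-state bands: ~+62 nm."""
        planar = ts.broaden(ts.ExcitationSet.from_pairs("p", [(2.69, 0.8695)]))
        rotated = ts.broaden(ts.ExcitationSet.from_pairs("r", [(2.38, 0.5290)]))
        assert ts.band_shift(planar, rotated) == pytest.approx(62, abs=2)


class TestNormalize:
    def test_max_mode_unit_peak_and_idempotent(self, simple_spectrum):
        out = ts.normalize_spectrum(simple_spectrum, "max")
        assert out.intensities.max() == pytest.approx(1.0)
        again = ts.normalize_spectrum(out, "max")
        np.testing.assert_allclose(again.intensities, out.intensities, rtol=1e-15)

    def test_area_mode_unit_integral(self, simple_spectrum):
        out = ts.normalize_spectrum(simple_spectrum, "area")
        area = np.trapezoid(out.intensities, out.wavelengths_nm)
        assert area == pytest.approx(1.0, rel=1e-12)

    @pytest.mark.parametrize("mode", ["max", "area"])
    def test_peak_position_invariant(self, simple_spectrum, mode):
        before = ts.find_lambda_max(simple_spectrum)
        after = ts.find_lambda_max(ts.normalize_spectrum(simple_spectrum, mode))
        assert before == after

    def test_all_zero_rejected(self):
        sp = ts.Spectrum(np.arange(400.0, 500.0), np.zeros(100))
        with pytest.raises(DomainError):
            ts.normalize_spectrum(sp)
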