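import math

import numpy as np
import pytest
from scipy.integrate import quad

from xascov.exceptions import ConfigError
from xascov.preedge_fit import (
    BackgroundModel,
    PseudoVoigtPeak,
    fit_preedge,
    pseudo_voigt_value,
    report_fit,
)
from xascov.spectra_io import Spectrum
from xascov.synthetic_data import SyntheticTruth, generate_spectrum


class TestPseudoVoigtShape:
    def test_pure_gaussian_height(self):
        pk = PseudoVoigtPeak(center=2470.0, fwhm=1.3, area=2.0, eta=0.0)
        expected = 2.0 * (2.0 / 1.3) * math.sqrt(math.log(2) / math.pi)
        assert pseudo_voigt_value(pk, 2470.0) == pytest.approx(expected, rel=1e-12)

    def test_pure_lorentzian_height(self):
        pk = PseudoVoigtPeak(center=2470.0, fwhm=1.3, area=2.0, eta=1.0)
        assert pseudo_voigt_value(pk, 2470.0) == pytest.approx(
            2 * 2.0 / (math.pi * 1.3), rel=1e-12
        )

    def test_fwhm_is_half_maximum_width(self):
        pk = PseudoVoigtPeak(center=0.0, fwhm=2.0, area=1.0, eta=0.5)
        top = pseudo_voigt_value(pk, 0.0)
        assert pseudo_voigt_value(pk, 1.0) == pytest.approx(top / 2, rel=1e-12)

    @pytest.mark.parametrize(
        "area,fwhm,eta",
        [(1.0, 0.8, 0.0), (2.03, 1.1, 0.5), (0.91, 1.1, 0.37), (5.0, 2.5, 1.0)],
    )
    def test_analytic_area_matches_quadrature_oracle(self, area, fwhm, eta):
        """Numerical quadrature over +-50 FWHM reproduces the area parameter."""
        pk = PseudoVoigtPeak(center=2470.0, fwhm=fwhm, area=area, eta=eta)
        integral, _ = quad(
            lambda e: float(pseudo_voigt_value(pk, e)),
            2470.0 - 50 * fwhm,
            2470.0 + 50 * fwhm,
            limit=400,
        )
        # Lorentzian tails beyond 50 FWHM hold ~area*eta/(50*pi)
        tail = area * eta * 2.0 / (math.pi * 2 * 50) + 1e-9
        assert abs(integral - area) <= max(1e-6 * area, 1.1 * tail)

    def test_invariants_enforced(self):
        with pytest.raises(ConfigError):
            PseudoVoigtPeak(center=0, fwhm=-1, area=1)
        with pytest.raises(ConfigError):
            PseudoVoigtPeak(center=0, fwhm=1, area=1, eta=1.5)
        with pytest.raises(ConfigError):
            PseudoVoigtPeak(center=0, fwhm=1, area=-0.1)


class TestFitPreedge:
    WINDOW = (2466.0, 2474.5)

    def test_noiseless_single_peak_exact_recovery(self, single_peak_spectrum):
        s, truth = single_peak_spectrum
        result = fit_preedge(s, self.WINDOW)
        pk, ref = result.peaks[0], truth.peaks[0]
        assert pk.center == pytest.approx(ref.center, abs=1e-5)
        assert pk.fwhm == pytest.approx(ref.fwhm, rel=1e-5)
        assert pk.area == pytest.approx(ref.area, rel=1e-5)
        assert pk.eta == pytest.approx(ref.eta, abs=1e-4)
        assert result.d0 == pytest.approx(ref.area, rel=1e-5)
        assert result.residual_rms < 1e-8

    def test_refit_of_own_model_is_fixed_point(self, single_peak_spectrum):
        s, _ = single_peak_spectrum
        first = fit_preedge(s, self.WINDOW)
        regenerated = s.evolve(intensities=first.model(s.energies))
        second = fit_preedge(regenerated, self.WINDOW)
        assert second.peaks[0].center == pytest.approx(first.peaks[0].center, abs=1e-8)
        assert second.peaks[0].area == pytest.approx(first.peaks[0].area, rel=1e-8)

    def test_d0_sigma_shrinks_with_noise(self, single_peak_spectrum):
        s, truth = single_peak_spectrum
        sigmas = []
        for noise in (0.02, 0.005, 0.001):
            rng = np.random.default_rng(7)
            noisy = s.evolve(
                intensities=s.intensities + rng.normal(0, noise, s.energies.size)
            )
            sigmas.append(fit_preedge(noisy, self.WINDOW, n_starts=2).d0_sigma)
        assert sigmas[0] >= sigmas[1] >= sigmas[2]

    def test_zero_intensity_window_gives_zero_d0(self):
        grid = np.round(np.arange(2460.0, 2480.0 + 1e-9, 0.1), 6)
        s = Spectrum(energies=grid, intensities=np.zeros_like(grid), normalized=True)
        result = fit_preedge(s, self.WINDOW, n_starts=2)
        assert result.d0 == pytest.approx(0.0, abs=1e-12)
        assert all(pk.area == pytest.approx(0.0, abs=1e-12) for pk in result.peaks)

    def test_window_too_small_for_parameters(self, single_peak_spectrum):
        s, _ = single_peak_spectrum
        with pytest.raises(ConfigError, match="points"):
            fit_preedge(s, (2470.0, 2470.5))

    def test_two_peak_fit_recovers_both_areas(self):
        truth = SyntheticTruth(
            peaks=[
                PseudoVoigtPeak(center=2468.8, fwhm=1.0, area=1.2, eta=0.3),
                PseudoVoigtPeak(center=2471.4, fwhm=1.2, area=0.7, eta=0.6),
            ],
            baseline_slope=0.002,
            baseline_intercept=-0.002 * 2470.0,
        )
        grid = np.round(np.arange(2460.0, 2480.0 + 1e-9, 0.1), 6)
        s, _ = generate_spectrum(truth, grid, normalized=True)
        result = fit_preedge(s, (2465.5, 2474.5), n_peaks=2)
        areas = sorted(pk.area for pk in result.peaks)
        assert areas == pytest.approx([0.7, 1.2], rel=1e-4)
        assert result.d0 == pytest.approx(1.9, rel=1e-4)

    def test_arctan_background_fit(self):
        truth = SyntheticTruth(
            peaks=[PseudoVoigtPeak(center=2470.2, fwhm=1.1, area=2.03, eta=0.5)],
            edges=[
                # arctan edge whose tail reaches into the fit window
                __import__("xascov.synthetic_data", fromlist=["EdgeStep"]).EdgeStep(
                    2475.5, 1.5, 1.0, "arctan"
                )
            ],
        )
        grid = np.round(np.arange(2460.0, 2495.0 + 1e-9, 0.1), 6)
        s, _ = generate_spectrum(truth, grid, normalized=True)
        result = fit_preedge(s, (2464.0, 2473.0), background="arctan_tail")
        assert result.d0 == pytest.approx(2.03, rel=0.02)

    def test_jackknife_reports_systematic_sensitivity(self, single_peak_spectrum):
        s, _ = single_peak_spectrum
        result = fit_preedge(s, self.WINDOW, n_starts=2, jackknife=True)
        assert result.d0_sigma_jackknife is not None
        assert result.d0_sigma_jackknife < 1e-4  # noiseless: window choice is immaterial


class TestReport:
    def test_report_structure_and_residual_definition(self, single_peak_spectrum):
        s, _ = single_peak_spectrum
        result = fit_preedge(s, (2466.0, 2474.5), n_starts=2)
        report = report_fit(result, s)
        assert len(report["peaks"]) == 1
        assert report["d0_line"] == f"D0 = {result.d0:.2f} ± {result.d0_sigma:.2f}"
        data = np.array(report["curves"]["data"])
        model = np.array(report["curves"]["model"])
        resid = np.array(report["curves"]["residual"])
        assert np.allclose(resid, data - model, atol=1e-12)

    def test_background_model_evaluate(self):
        bg = BackgroundModel(
            kind="linear_plus_arctan",
            params={
                "slope": 0.01, "intercept": -24.0,
                "step_height": 1.0, "step_center": 2475.0, "step_width": 1.0,
            },
        )
        e = np.array([2475.0])
        assert bg.evaluate(e)[0] == pytest.approx(0.01 * 2475.0 - 24.0 + 0.5)
        with pytest.raises(ConfigError):
            BackgroundModel(kind="bogus")
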