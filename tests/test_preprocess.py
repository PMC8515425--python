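import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xascov.exceptions import (
    ConfigError,
    DegeneracyError,
    GridError,
)
from xascov.preprocess import (
    DerivativeConfig,
    NormalizationConfig,
    derivative,
    estimate_impurity_fraction,
    find_edge_features,
    normalize_edge_jump,
    subtract_impurity,
)
from xascov.spectra_io import Spectrum
from xascov.synthetic_data import (
    EdgeStep,
    S_GRID,
    SyntheticTruth,
    generate_spectrum,
    mix_spectra,
    reference_fixture,
)

GRID = np.linspace(2455.0, 2495.0, 201)
NORM_CFG = NormalizationConfig(pre_range=(2455.0, 2465.0), post_range=(2485.0, 2495.0))


def _step(height=1.0, baseline=0.0, slope=0.0, center=2475.0, width=0.5):
    y = baseline + slope * GRID + height / (1 + np.exp(-(GRID - center) / width))
    return Spectrum(energies=GRID, intensities=y)


class TestNormalize:
    def test_step_of_height_two_scales_to_one(self):
        s = normalize_edge_jump(_step(height=2.0), NORM_CFG)
        assert s.normalized
        assert np.mean(s.intensities[GRID > 2490]) == pytest.approx(1.0, abs=1e-6)
        assert np.mean(s.intensities[GRID < 2460]) == pytest.approx(0.0, abs=1e-9)

    def test_sloped_baseline_removed(self):
        s = normalize_edge_jump(_step(height=1.0, baseline=-3.0, slope=0.002), NORM_CFG)
        assert np.mean(s.intensities[GRID < 2460]) == pytest.approx(0.0, abs=1e-9)
        assert np.mean(s.intensities[GRID > 2490]) == pytest.approx(1.0, abs=1e-3)

    def test_synthetic_jump_073_normalizes_to_unit(self, s_truth_factory):
        truth = s_truth_factory("two_hole", jump=0.73, noise_sigma=0.002, seed=5)
        s, _ = generate_spectrum(truth, S_GRID, edge_label="S-K")
        cfg = NormalizationConfig(
            pre_range=(2455.0, 2464.0), post_range=(2486.0, 2495.0),
            ref_energy=2490.0,
        )
        out = normalize_edge_jump(s, cfg)
        jump = float(np.mean(out.intensities[S_GRID > 2490]))
        assert jump == pytest.approx(1.0, abs=0.005)

    def test_idempotent(self):
        once = normalize_edge_jump(_step(height=2.0, baseline=0.5, slope=0.001), NORM_CFG)
        twice = normalize_edge_jump(once, NORM_CFG)
        assert np.max(np.abs(twice.intensities - once.intensities)) < 1e-9 * np.max(
            np.abs(once.intensities)
        )

    def test_window_config_errors(self):
        with pytest.raises(ConfigError):
            NormalizationConfig(pre_range=(2460.0, 2480.0), post_range=(2475.0, 2495.0))
        cfg = NormalizationConfig(pre_range=(2400.0, 2402.0), post_range=(2485.0, 2495.0))
        with pytest.raises(ConfigError, match=">= 3 points"):
            normalize_edge_jump(_step(), cfg)


class TestSubtract:
    def test_fraction_zero_is_identity(self, s_two_hole_noiseless, s_one_hole_noiseless):
        mix, _ = s_one_hole_noiseless
        imp, _ = s_two_hole_noiseless
        out = subtract_impurity(mix, imp, 0.0)
        assert np.allclose(out.intensities, mix.intensities, rtol=0, atol=0)

    def test_half_half_mixture_inverts_exactly(
        self, s_two_hole_noiseless, s_one_hole_noiseless
    ):
        a, _ = s_two_hole_noiseless
        b, _ = s_one_hole_noiseless
        mix = mix_spectra(a, b, 0.5)
        out = subtract_impurity(mix, b, 0.5)
        assert np.allclose(out.intensities, a.intensities, rtol=1e-12, atol=1e-14)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(f=st.floats(min_value=0.0, max_value=0.95))
    def test_subtraction_identity_property(self, f):
        """subtract_impurity(f*a + (1-f)*b, a, f) == b to 1e-12 relative."""
        a, _ = reference_fixture("s_two_hole", noise_sigma=0.0)
        b, _ = reference_fixture("s_one_hole", noise_sigma=0.0)
        mix = mix_spectra(a, b, f)
        out = subtract_impurity(mix, a, f)
        scale = np.max(np.abs(b.intensities))
        assert np.max(np.abs(out.intensities - b.intensities)) <= 1e-12 * scale

    def test_18_percent_contamination_inverts(
        self, s_two_hole_noiseless, s_one_hole_noiseless
    ):
        a, _ = s_two_hole_noiseless
        b, _ = s_one_hole_noiseless
        mix = mix_spectra(a, b, 0.18)
        out = subtract_impurity(mix, a, 0.18)
        assert np.allclose(out.intensities, b.intensities, rtol=1e-12, atol=1e-13)

    def test_bad_fraction_and_grid(self, s_two_hole_noiseless):
        a, _ = s_two_hole_noiseless
        with pytest.raises(ConfigError):
            subtract_impurity(a, a, 1.0)
        other = Spectrum(energies=GRID, intensities=np.zeros_like(GRID))
        with pytest.raises(GridError):
            subtract_impurity(a, other, 0.1)


class TestEstimateFraction:
    WINDOW = (2465.0, 2474.0)

    def test_noisy_mixture_recovered_within_3_sigma(
        self, s_two_hole_noiseless, s_one_hole_noiseless
    ):
        a, _ = s_two_hole_noiseless
        b, _ = s_one_hole_noiseless
        mix = mix_spectra(a, b, 0.18)
        rng = np.random.default_rng(42)
        noisy = mix.evolve(
            intensities=mix.intensities + rng.normal(0, 0.003, mix.energies.size)
        )
        f, sigma = estimate_impurity_fraction(noisy, a, b, self.WINDOW)
        assert abs(f - 0.18) <= 3 * sigma
        assert sigma < 0.01

    @pytest.mark.parametrize("f_true", [0.0, 1.0])
    def test_boundary_fractions(self, f_true, s_two_hole_noiseless, s_one_hole_noiseless):
        a, _ = s_two_hole_noiseless
        b, _ = s_one_hole_noiseless
        mix = mix_spectra(a, b, f_true)
        f, _ = estimate_impurity_fraction(mix, a, b, self.WINDOW)
        assert f == pytest.approx(f_true, abs=1e-9)

    def test_collinear_components_degenerate(self, s_two_hole_noiseless):
        a, _ = s_two_hole_noiseless
        with pytest.raises(DegeneracyError):
            estimate_impurity_fraction(a, a, a, self.WINDOW)


class TestDerivative:
    def test_linear_slope_recovered(self):
        s = Spectrum(energies=GRID, intensities=0.37 * GRID - 1.0)
        d = derivative(s, 1)
        assert np.allclose(d.intensities[5:-5], 0.37, atol=1e-9)

    def test_quadratic_second_derivative(self):
        a = 0.004
        s = Spectrum(energies=GRID, intensities=a * (GRID - 2470.0) ** 2)
        d2 = derivative(s, 2)
        assert np.allclose(d2.intensities[5:-5], 2 * a, atol=1e-9)

    def test_flat_region_is_zero_and_linearity(self):
        rng = np.random.default_rng(0)
        y1 = np.exp(-((GRID - 2475.0) ** 2) / 4.0)
        y2 = 0.01 * (GRID - 2455.0)
        s1 = Spectrum(energies=GRID, intensities=y1)
        s2 = Spectrum(energies=GRID, intensities=y2)
        combo = Spectrum(energies=GRID, intensities=2.0 * y1 + 3.0 * y2)
        d_combo = derivative(combo, 1).intensities
        d_lin = 2.0 * derivative(s1, 1).intensities + 3.0 * derivative(s2, 1).intensities
        assert np.allclose(d_combo, d_lin, atol=1e-12)
        flat = derivative(s1, 1).intensities[GRID < 2462.0]
        assert np.max(np.abs(flat)) < 1e-8
        _ = rng

    def test_arctan_step_derivative_peaks_at_center(self):
        e0 = 2474.3
        s = Spectrum(
            energies=GRID, intensities=0.5 + np.arctan((GRID - e0) / 1.5) / np.pi
        )
        d = derivative(s, 1)
        peak = GRID[int(np.argmax(d.intensities))]
        assert abs(peak - e0) <= np.diff(GRID).mean()

    def test_nonuniform_grid_rejected(self):
        e = np.concatenate([np.linspace(2455, 2470, 50), np.linspace(2470.5, 2495, 60)])
        e = np.unique(e)
        s = Spectrum(energies=e, intensities=np.zeros_like(e))
        with pytest.raises(GridError):
            derivative(s, 1)

    def test_config_validation(self):
        with pytest.raises(ConfigError):
            DerivativeConfig(smooth_window=6)
        with pytest.raises(ConfigError):
            DerivativeConfig(smooth_window=3, smooth_order=3)


class TestEdgeFeatures:
    def test_single_arctan_gives_exactly_one_inflection(self):
        truth = SyntheticTruth(edges=[EdgeStep(8984.0, 1.5, 1.0, "arctan")])
        grid = np.round(np.arange(8950.0, 9020.0 + 1e-9, 0.2), 6)
        s, _ = generate_spectrum(truth, grid)
        feats = find_edge_features(s, (8960.0, 8975.0), (8978.0, 8990.0))
        assert len(feats.inflection_energies) == 1
        assert feats.inflection_energies[0] == pytest.approx(8984.0, abs=0.2)
        # crude estimate; arctan tails bias it low
        assert feats.edge_jump == pytest.approx(1.0, abs=0.15)

    @pytest.mark.parametrize(
        "name,targets",
        [("cu_two_hole", (8982.3, 8985.9)), ("cu_one_hole", (8981.5, 8984.8))],
    )
    def test_cu_fixture_inflections_recovered(self, name, targets):
        s, _ = reference_fixture(name)
        feats = find_edge_features(
            s, (8975.0, 8981.2), (8981.0, 8990.0), DerivativeConfig(9, 3)
        )
        assert len(feats.inflection_energies) >= 2
        for target in targets:
            nearest = min(feats.inflection_energies, key=lambda x: abs(x - target))
            assert nearest == pytest.approx(target, abs=0.2)

    def test_cu_fixture_weak_shoulder_found(self):
        s, _ = reference_fixture("cu_two_hole")
        feats = find_edge_features(
            s, (8975.0, 8981.2), (8981.0, 8990.0), DerivativeConfig(9, 3)
        )
        assert feats.preedge_energy == pytest.approx(8979.8, abs=0.2)

    def test_featureless_window_warns_not_raises(self):
        truth = SyntheticTruth(edges=[EdgeStep(8984.0, 1.5, 1.0, "arctan")])
        grid = np.round(np.arange(8950.0, 9020.0 + 1e-9, 0.2), 6)
        s, _ = generate_spectrum(truth, grid)
        noisy = s.evolve(
            intensities=s.intensities
            + np.random.default_rng(1).normal(0, 1e-4, grid.size)
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            feats = find_edge_features(noisy, (8955.0, 8965.0), (8960.0, 8970.0))
        assert feats.inflection_energies == []
        assert any("no first-derivative maximum" in str(w.message) for w in caught)
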