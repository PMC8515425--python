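import numpy as np
import pytest

from xascov.preedge_fit import PseudoVoigtPeak
from xascov.synthetic_data import (
    S_GRID,
    SyntheticTruth,
    generate_spectrum,
    reference_fixture,
    s_kedge_truth,
)


@pytest.fixture
def two_col_file(tmp_path):
    """Write (energy, intensity) rows to a temp file and return its path."""

    def _write(rows, name="spec.dat", header=None):
        lines = [] if header is None else list(header)
        lines += [f"{e} {i}" for e, i in rows]
        path = tmp_path / name
        path.write_text("\n".join(lines) + "\n")
        return path

    return _write


@pytest.fixture(scope="session")
def s_two_hole_noiseless():
    return reference_fixture("s_two_hole", noise_sigma=0.0)


@pytest.fixture(scope="session")
def s_one_hole_noiseless():
    return reference_fixture("s_one_hole", noise_sigma=0.0)


@pytest.fixture(scope="session")
def single_peak_spectrum():
    """One pseudo-Voigt on a linear background, noiseless: the exact-recovery
    reference input for the pre-edge fitter."""
    truth = SyntheticTruth(
        peaks=[PseudoVoigtPeak(center=2470.2, fwhm=1.1, area=2.03, eta=0.5)],
        baseline_slope=0.004,
        baseline_intercept=0.02 - 0.004 * 2470.0,
        noise_sigma=0.0,
    )
    grid = np.round(np.arange(2460.0, 2480.0 + 1e-9, 0.1), 6)
    spectrum, truth = generate_spectrum(truth, grid, edge_label="S-K", normalized=True)
    return spectrum, truth


@pytest.fixture(scope="session")
def s_truth_factory():
    return s_kedge_truth


@pytest.fixture(scope="session")
def s_grid():
    return S_GRID
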