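"""Synthetic S and Cu K-edge spectra with exact ground truth.

Every generated spectrum is a pure function of (truth, grid, seed): an
analytic model curve — linear baseline + edge step(s) + pseudo-Voigt
features — plus i.i.d. Gaussian noise from a seeded generator.  The truth
record travels with the spectrum so parameter-recovery tests never have to
assume a value implicitly.

Templates encode the feature placement of the [4Cu:1S] cluster redox couple:

* S K-edge: a pre-edge pseudo-Voigt at 2470.2 eV (2-hole) or 2469.5 eV
  (1-hole) with the reference integrated areas 2.03 / 0.91, a 1s->4p feature
  at 2477.0 / 2475.9 eV riding the edge, and a unit edge jump.  The S edge
  step is a cumulative Gaussian placed so that its tail under the pre-edge
  fit window is negligible, keeping the background there linear by
  construction (an arctan step's Lorentzian tail would curve it).
* Cu K-edge: a weak Gaussian 1s->3d shoulder at 8979.8 eV and a rising edge
  built from two arctan components whose centers are solved (analytically,
  via the second derivative) so the first-derivative maxima fall exactly at
  the reference inflection energies: 8982.3/8985.9 eV (2-hole) or
  8981.5/8984.8 eV (1-hole).
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.optimize import fsolve

from .exceptions import ConfigError, CoverageError, GridError
from .preedge_fit import PseudoVoigtPeak, pseudo_voigt_value
from .spectra_io import Spectrum

EDGE_SHAPES = ("arctan", "cumulative_gaussian")

_FOUR_LN2 = 4.0 * math.log(2.0)
_TWO_SQRT_LN2_PI = 2.0 * math.sqrt(math.log(2.0) / math.pi)


@dataclass
class EdgeStep:
    """One absorption-edge step: arctan or cumulative-Gaussian sigmoid."""

    position: float
    width: float
    jump: float
    shape: str = "arctan"

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ConfigError("edge width must be > 0")
        if self.jump <= 0:
            raise ConfigError("edge jump must be > 0")
        if self.shape not in EDGE_SHAPES:
            raise ConfigError(f"edge shape must be one of {EDGE_SHAPES}")

    def evaluate(self, e: np.ndarray) -> np.ndarray:
        u = (np.asarray(e, float) - self.position) / self.width
        if self.shape == "arctan":
            return self.jump * (0.5 + np.arctan(u) / math.pi)
        # cumulative Gaussian, width = standard deviation
        from scipy.special import ndtr

        return self.jump * ndtr(u)


@dataclass
class SyntheticTruth:
    """Ground-truth parameter record emitted alongside every generated spectrum."""

    peaks: list[PseudoVoigtPeak] = field(default_factory=list)
    edges: list[EdgeStep] = field(default_factory=list)
    extra_features: list[PseudoVoigtPeak] = field(default_factory=list)
    baseline_slope: float = 0.0
    baseline_intercept: float = 0.0
    noise_sigma: float = 0.0
    seed: int = 0
    mixture_fraction: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def model_curve(truth: SyntheticTruth, grid: np.ndarray) -> np.ndarray:
    """Noiseless analytic model curve of a truth record on a grid."""
    e = np.asarray(grid, float)
    y = truth.baseline_slope * e + truth.baseline_intercept
    for step in truth.edges:
        y = y + step.evaluate(e)
    for pk in truth.peaks + truth.extra_features:
        y = y + pseudo_voigt_value(pk, e)
    return y


def generate_spectrum(
    truth: SyntheticTruth,
    grid: np.ndarray,
    edge_label: str = "other",
    normalized: bool = False,
) -> tuple[Spectrum, SyntheticTruth]:
    """Model curve + seeded Gaussian noise; bit-identical for identical inputs."""
    grid = np.asarray(grid, float)
    if not np.all(np.diff(grid) > 0):
        raise GridError("generation grid must be strictly increasing")
    for pk in truth.peaks + truth.extra_features:
        if pk.center - 5 * pk.fwhm < grid[0] or pk.center + 5 * pk.fwhm > grid[-1]:
            raise CoverageError(
                f"feature at {pk.center:g} eV (fwhm {pk.fwhm:g}) not covered by the "
                f"grid [{grid[0]:g}, {grid[-1]:g}] +- 5 widths"
            )
    for step in truth.edges:
        if not grid[0] <= step.position <= grid[-1]:
            raise CoverageError(f"edge at {step.position:g} eV outside grid")
    y = model_curve(truth, grid)
    if truth.noise_sigma > 0:
        rng = np.random.default_rng(truth.seed)
        y = y + rng.normal(0.0, truth.noise_sigma, size=grid.size)
    spectrum = Spectrum(
        energies=grid,
        intensities=y,
        edge_label=edge_label,
        normalized=normalized,
        meta={
            "history": [
                f"synthetic spectrum (seed {truth.seed}, noise {truth.noise_sigma:g})"
            ],
            "synthetic": True,
        },
    )
    return spectrum, truth


def mix_spectra(a: Spectrum, b: Spectrum, fraction_a: float) -> Spectrum:
    """Linear two-component mixture fraction_a*a + (1-fraction_a)*b."""
    if not (0.0 <= fraction_a <= 1.0):
        raise ConfigError(f"fraction_a must be in [0, 1], got {fraction_a}")
    if a.energies.size != b.energies.size or not np.allclose(
        a.energies, b.energies, rtol=0, atol=1e-9
    ):
        raise GridError("mix_spectra requires a common energy grid")
    mixed = fraction_a * a.intensities + (1.0 - fraction_a) * b.intensities
    return a.evolve(
        intensities=mixed,
        history_entry=f"mixture: {fraction_a:g} * a + {1 - fraction_a:g} * b",
    )


# ---------------------------------------------------------------------------
# Cu rising-edge tuning

def _arctan_d2(e, c, w, j):
    u = (e - c) / w
    return -2.0 * j * u / (math.pi * w * w * (1.0 + u * u) ** 2)


def _gaussian_second_derivative(e, center, fwhm, area):
    # d2/dE2 of area * (k/fwhm) exp(-a u^2), u = (E-center)/fwhm, a = 4 ln 2
    u = (e - center) / fwhm
    a = _FOUR_LN2
    amp = area * _TWO_SQRT_LN2_PI / fwhm
    return amp * np.exp(-a * u * u) * (4.0 * a * a * u * u - 2.0 * a) / fwhm**2


def tune_two_step_centers(
    targets: tuple[float, float],
    widths: tuple[float, float],
    jumps: tuple[float, float],
    shoulder: PseudoVoigtPeak | None = None,
) -> tuple[float, float]:
    """Solve for two arctan step centers so the summed curve's first
    derivative has local maxima exactly at ``targets``.

    The conditions are zeros of the analytic second derivative of the full
    model (including a Gaussian shoulder if given) at the target energies.
    """
    t = np.asarray(targets, float)

    def conditions(centers: np.ndarray) -> np.ndarray:
        total = np.zeros(2)
        for c, w, j in zip(centers, widths, jumps):
            total += _arctan_d2(t, c, w, j)
        if shoulder is not None:
            total += _gaussian_second_derivative(t, shoulder.center, shoulder.fwhm, shoulder.area)
        return total

    solution, info, ier, msg = fsolve(conditions, x0=t.copy(), full_output=True)
    if ier != 1:
        raise ConfigError(f"rising-edge tuning did not converge: {msg}")
    return float(solution[0]), float(solution[1])


# ---------------------------------------------------------------------------
# templates

S_GRID = np.round(np.arange(2455.0, 2495.0 + 1e-9, 0.1), 6)
CU_GRID = np.round(np.arange(8950.0, 9020.0 + 1e-9, 0.2), 6)

# (pre-edge center, pre-edge area, 1s->4p center, edge position)
_S_STATES = {
    "two_hole": (2470.2, 2.03, 2477.0, 2476.0),
    "one_hole": (2469.5, 0.91, 2475.9, 2475.3),
}

# rising-edge inflection targets per redox state
_CU_STATES = {
    "two_hole": (8982.3, 8985.9),
    "one_hole": (8981.5, 8984.8),
}

#: Weak Cu 1s->3d shoulder shared by both redox states (isoenergetic).
CU_SHOULDER = PseudoVoigtPeak(center=8979.8, fwhm=1.6, area=0.15, eta=0.0)


def s_kedge_truth(
    state: str = "two_hole",
    jump: float = 1.0,
    noise_sigma: float = 0.005,
    seed: int = 1905,
) -> SyntheticTruth:
    """S K-edge template truth for one redox state of the cluster."""
    if state not in _S_STATES:
        raise ConfigError(f"unknown S-edge state {state!r}; expected {sorted(_S_STATES)}")
    center, area, e4p, edge_pos = _S_STATES[state]
    return SyntheticTruth(
        peaks=[PseudoVoigtPeak(center=center, fwhm=1.1, area=area * jump, eta=0.5)],
        edges=[EdgeStep(position=edge_pos, width=1.0, jump=jump, shape="cumulative_gaussian")],
        extra_features=[PseudoVoigtPeak(center=e4p, fwhm=2.5, area=1.6 * jump, eta=0.0)],
        baseline_slope=0.003,
        baseline_intercept=0.01 - 0.003 * center,
        noise_sigma=noise_sigma,
        seed=seed,
    )


def cu_kedge_truth(
    state: str = "two_hole",
    noise_sigma: float = 0.002,
    seed: int = 11,
) -> SyntheticTruth:
    """Cu K-edge template truth: tuned two-arctan rising edge + weak shoulder."""
    if state not in _CU_STATES:
        raise ConfigError(f"unknown Cu-edge state {state!r}; expected {sorted(_CU_STATES)}")
    targets = _CU_STATES[state]
    widths = (1.2, 1.4)
    jumps = (0.45, 0.55)
    c1, c2 = tune_two_step_centers(targets, widths, jumps, shoulder=CU_SHOULDER)
    return SyntheticTruth(
        peaks=[copy.deepcopy(CU_SHOULDER)],
        edges=[
            EdgeStep(position=c1, width=widths[0], jump=jumps[0], shape="arctan"),
            EdgeStep(position=c2, width=widths[1], jump=jumps[1], shape="arctan"),
        ],
        baseline_slope=0.0,
        baseline_intercept=0.0,
        noise_sigma=noise_sigma,
        seed=seed,
    )


FIXTURE_NAMES = (
    "s_two_hole",
    "s_one_hole",
    "s_one_hole_contaminated",
    "cu_two_hole",
    "cu_one_hole",
)

#: Contamination level of the 1-hole S-edge spectrum in the reference study.
REFERENCE_CONTAMINATION = 0.18


def reference_fixture(
    name: str,
    noise_sigma: float | None = None,
    seed: int | None = None,
) -> tuple[Spectrum, SyntheticTruth]:
    """Seeded, versioned fixtures parameterized from the reference study values.

    ``s_two_hole`` / ``s_one_hole``: unit-jump S K-edge spectra whose truth
    carries the reference pre-edge centers (2470.2 / 2469.5 eV) and areas
    (2.03 / 0.91).  ``s_one_hole_contaminated``: 0.18 * two-hole +
    0.82 * one-hole noiseless curves plus seeded noise (default sigma 0.003,
    seed 7), truth records the mixture fraction.  ``cu_two_hole`` /
    ``cu_one_hole``: Cu K-edge spectra with the shoulder at 8979.8 eV and
    inflections at the reference energies.
    """
    if name not in FIXTURE_NAMES:
        raise ConfigError(f"unknown fixture {name!r}; expected one of {FIXTURE_NAMES}")

    if name in ("s_two_hole", "s_one_hole"):
        state = name[2:]
        truth = s_kedge_truth(
            state,
            noise_sigma=0.005 if noise_sigma is None else noise_sigma,
            seed=1905 if seed is None else seed,
        )
        spectrum, truth = generate_spectrum(truth, S_GRID, edge_label="S-K", normalized=True)
        return spectrum, truth

    if name == "s_one_hole_contaminated":
        sigma = 0.003 if noise_sigma is None else noise_sigma
        rng_seed = 7 if seed is None else seed
        truth_a = s_kedge_truth("two_hole", noise_sigma=0.0)
        truth_b = s_kedge_truth("one_hole", noise_sigma=0.0)
        f = REFERENCE_CONTAMINATION
        curve = f * model_curve(truth_a, S_GRID) + (1 - f) * model_curve(truth_b, S_GRID)
        if sigma > 0:
            curve = curve + np.random.default_rng(rng_seed).normal(0.0, sigma, S_GRID.size)
        truth = copy.deepcopy(truth_b)
        truth.mixture_fraction = f
        truth.noise_sigma = sigma
        truth.seed = rng_seed
        spectrum = Spectrum(
            energies=S_GRID.copy(),
            intensities=curve,
            edge_label="S-K",
            normalized=True,
            meta={
                "history": [
                    f"synthetic contaminated mixture (fraction {f:g}, seed {rng_seed}, "
                    f"noise {sigma:g})"
                ],
                "synthetic": True,
            },
        )
        return spectrum, truth

    state = name[3:]
    truth = cu_kedge_truth(
        state,
        noise_sigma=0.002 if noise_sigma is None else noise_sigma,
        seed=11 if seed is None else seed,
    )
    spectrum, truth = generate_spectrum(truth, CU_GRID, edge_label="Cu-K")
    return spectrum, truth
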