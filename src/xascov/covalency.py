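"""Ligand-metal covalency from pre-edge intensity.

A pre-edge peak in S K-edge XAS arises from S 1s excitation into the
antibonding acceptor MO ``psi* ~ alpha*|S 3p> - (1-alpha)|M 3d>``; the
fraction of S 3p character, alpha^2, scales the transition intensity.  With
h holes in the acceptor MO, n equivalent photoabsorbing S nuclei, and Is the
radial dipole integral <3p|r|1s> of a pure 1s->3p excitation, the integrated
pre-edge intensity obeys D0 = alpha^2 * h * Is / (3 n), inverted here as

    alpha^2 = 3 n D0 / (h Is)

Is varies with the S charge/environment and is estimated from the S 1s->4p
excitation energy via a linear calibration.  The default calibration is the
unique line through the two anchor pairs (2475.9 eV, 12.9) and
(2477.0 eV, 14.9) used in the reference analysis of the [4Cu:1S] cluster
couple; published calibration coefficients may be supplied instead and take
precedence.

Uncertainty: sigma(alpha^2) = alpha^2 * sigma(D0)/D0 by default (Is and h
treated as exact); an Is uncertainty can be folded in quadratically on
request.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .exceptions import CalibrationError, ConfigError

# Anchor pairs (S 1s->4p energy in eV, Is) defining the default calibration.
_ANCHORS = ((2475.9, 12.9), (2477.0, 14.9))


@dataclass
class DipoleIntegralCalibration:
    """Linear map from S 1s->4p excitation energy (eV) to the dipole integral Is."""

    slope: float
    intercept: float
    valid_range: tuple[float, float]

    def __post_init__(self) -> None:
        if not math.isfinite(self.slope) or not math.isfinite(self.intercept):
            raise ConfigError("calibration coefficients must be finite")
        if self.valid_range[0] >= self.valid_range[1]:
            raise ConfigError("valid_range must be a nonempty (low, high) interval")


def default_calibration() -> DipoleIntegralCalibration:
    (e0, i0), (e1, i1) = _ANCHORS
    slope = (i1 - i0) / (e1 - e0)
    return DipoleIntegralCalibration(
        slope=slope,
        intercept=i0 - slope * e0,
        valid_range=(e0 - 2.0, e1 + 2.0),
    )


def dipole_integral(e_4p: float, cal: DipoleIntegralCalibration | None = None) -> float:
    """Is from the 1s->4p excitation energy; warns slightly outside the
    calibrated range, fails if the line yields Is <= 0."""
    cal = cal or default_calibration()
    if not (cal.valid_range[0] <= e_4p <= cal.valid_range[1]):
        warnings.warn(
            f"1s->4p energy {e_4p:g} eV outside calibrated range {cal.valid_range}; "
            "extrapolating the linear calibration",
            stacklevel=2,
        )
    value = cal.slope * e_4p + cal.intercept
    if value <= 0:
        raise CalibrationError(f"calibration yields Is = {value:g} <= 0 at {e_4p:g} eV")
    return float(value)


@dataclass
class CovalencyInputs:
    """Audit record of everything entering the covalency inversion."""

    D0: float
    D0_sigma: float
    h: int
    n: int
    Is: float
    e_4p: float | None = None
    Is_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.D0 < 0:
            raise ConfigError("D0 must be >= 0")
        if self.D0_sigma < 0:
            raise ConfigError("D0_sigma must be >= 0")
        if self.h < 1:
            raise ConfigError("hole count h must be >= 1")
        if self.n < 1:
            raise ConfigError("absorber count n must be >= 1")
        if self.Is <= 0:
            raise ConfigError("Is must be > 0")


@dataclass
class CovalencyResult:
    """alpha^2 (fractional S 3p character) with 1-sigma uncertainty."""

    alpha2: float
    alpha2_sigma: float
    inputs: CovalencyInputs
    clipped: bool = False

    @property
    def percent(self) -> float:
        return 100.0 * self.alpha2

    @property
    def percent_sigma(self) -> float:
        return 100.0 * self.alpha2_sigma


def covalency_alpha2(inputs: CovalencyInputs) -> CovalencyResult:
    """Invert the pre-edge intensity relation: alpha^2 = 3 n D0 / (h Is).

    The relative uncertainty of D0 carries over directly; an Is uncertainty,
    if provided, adds in quadrature.  Values above 1 are clipped with an
    explicit flag (and a warning) rather than silently accepted.
    """
    raw = 3.0 * inputs.n * inputs.D0 / (inputs.h * inputs.Is)
    clipped = raw > 1.0
    if clipped:
        warnings.warn(
            f"alpha^2 = {raw:.3f} > 1 is unphysical; result clipped to 1 "
            "(check D0 normalization, h and Is)",
            stacklevel=2,
        )
    alpha2 = min(raw, 1.0)
    if inputs.D0 > 0:
        rel2 = (inputs.D0_sigma / inputs.D0) ** 2
        if inputs.Is_sigma:
            rel2 += (inputs.Is_sigma / inputs.Is) ** 2
        sigma = alpha2 * math.sqrt(rel2)
    else:
        sigma = 0.0
    return CovalencyResult(alpha2=alpha2, alpha2_sigma=sigma, inputs=inputs, clipped=clipped)


def predicted_d0(alpha2: float, h: int, n: int, Is: float) -> float:
    """Forward relation D0 = alpha^2 * h * Is / (3 n) (round-trip check)."""
    return alpha2 * h * Is / (3.0 * n)


_HOLES = {"two_hole": 2, "one_hole": 1, "fully_reduced": 0}


def holes_for_redox_state(state_label: str) -> int:
    """Hole count of the acceptor MO for a named redox level of the cluster.

    The neutral [4Cu:1S]0 cluster is the 2-hole state, the monoanion
    [4Cu:1S]1- the 1-hole state; the fully reduced (all-Cu(I)) state is
    closed-shell and shows no pre-edge.
    """
    try:
        h = _HOLES[state_label]
    except KeyError:
        raise ConfigError(
            f"unknown redox state {state_label!r}; expected one of {sorted(_HOLES)}"
        ) from None
    if h == 0:
        warnings.warn(
            "fully reduced state has no acceptor holes: no pre-edge intensity "
            "is expected and the covalency inversion is undefined",
            stacklevel=2,
        )
    return h
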