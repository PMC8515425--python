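"""Edge-jump normalization, impurity subtraction and derivative feature analysis.

Normalization follows standard XANES practice: a low-order polynomial fit in a
window below the edge is subtracted as baseline, and the spectrum is divided by
a post-edge polynomial evaluated at a reference energy so the edge jump equals
one.  Derivatives use Savitzky-Golay local-polynomial filtering, which
preserves peak positions to first order; rising-edge inflection points are the
local maxima of the first derivative and weak pre-edge shoulders are located
as extrema of the second derivative, both refined by a parabola through the
three points around the discrete extremum (spectra are reported to 0.1 eV,
finer than typical monochromator steps).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .exceptions import (
    ConfigError,
    DataError,
    DegeneracyError,
    GridError,
    RangeError,
)
from .spectra_io import Spectrum


@dataclass
class NormalizationConfig:
    """Windows and polynomial orders for edge-jump normalization.

    ``pre_range`` must lie entirely below ``post_range``; ``ref_energy``
    defaults to the midpoint between the two windows (a proxy for the edge
    position) and is where the post-edge polynomial is evaluated to define
    the edge jump.
    """

    pre_range: tuple[float, float]
    post_range: tuple[float, float]
    baseline_order: int = 1
    post_order: int = 1
    ref_energy: float | None = None

    def __post_init__(self) -> None:
        if self.pre_range[0] >= self.pre_range[1] or self.post_range[0] >= self.post_range[1]:
            raise ConfigError("normalization windows must be (low, high) with low < high")
        if self.pre_range[1] >= self.post_range[0]:
            raise ConfigError(
                f"pre_range {self.pre_range} must lie entirely below post_range "
                f"{self.post_range}"
            )
        if self.baseline_order not in (0, 1):
            raise ConfigError("baseline_order must be 0 or 1")
        if self.post_order not in (0, 1, 2):
            raise ConfigError("post_order must be 0, 1 or 2")

    @property
    def reference_energy(self) -> float:
        if self.ref_energy is not None:
            return self.ref_energy
        return 0.5 * (self.pre_range[1] + self.post_range[0])


@dataclass
class DerivativeConfig:
    """Savitzky-Golay settings for smoothed derivatives (window in points)."""

    smooth_window: int = 7
    smooth_order: int = 3

    def __post_init__(self) -> None:
        if self.smooth_window % 2 == 0:
            raise ConfigError("smooth_window must be odd")
        if self.smooth_window < self.smooth_order + 2:
            raise ConfigError("smooth_window must be >= smooth_order + 2")


@dataclass
class EdgeFeatures:
    """Derivative-derived edge features of one spectrum."""

    preedge_energy: float | None
    inflection_energies: list[float] = field(default_factory=list)
    edge_jump: float = 0.0


# ---------------------------------------------------------------------------
# normalization


def normalize_edge_jump(s: Spectrum, cfg: NormalizationConfig) -> Spectrum:
    """Subtract the pre-edge baseline and scale the edge jump to one.

    Idempotent: renormalizing an already-normalized spectrum with the same
    windows leaves it unchanged (baseline refits to ~0, jump refits to ~1).
    """
    pre = s.window_mask(cfg.pre_range)
    post = s.window_mask(cfg.post_range)
    if pre.sum() < 3 or post.sum() < 3:
        raise ConfigError(
            f"normalization windows must each contain >= 3 points "
            f"(pre: {int(pre.sum())}, post: {int(post.sum())})"
        )
    base_coef = np.polyfit(s.energies[pre], s.intensities[pre], cfg.baseline_order)
    baseline = np.polyval(base_coef, s.energies)
    flattened = s.intensities - baseline
    post_coef = np.polyfit(s.energies[post], flattened[post], cfg.post_order)
    jump = float(np.polyval(post_coef, cfg.reference_energy))
    if jump <= 0:
        raise DataError(f"fitted edge jump {jump:g} <= 0; check windows")
    return s.evolve(
        intensities=flattened / jump,
        normalized=True,
        history_entry=(
            f"edge-jump normalization: baseline order {cfg.baseline_order} on "
            f"{cfg.pre_range}, post order {cfg.post_order} on {cfg.post_range}, "
            f"jump {jump:.6g} at {cfg.reference_energy:g} eV"
        ),
        edge_jump=jump,
    )


def subtract_impurity(
    mixture: Spectrum, impurity: Spectrum, fraction: float
) -> Spectrum:
    """Remove a known fraction of an impurity spectrum and re-normalize.

    Returns ``(mixture - fraction*impurity) / (1 - fraction)``.  The division
    restores a unit edge jump when both inputs are unit-edge-jump spectra,
    which is the algebraically exact re-normalization for a two-component
    mixture.
    """
    if not (0.0 <= fraction < 1.0):
        raise ConfigError(f"impurity fraction must be in [0, 1), got {fraction}")
    _require_common_grid(mixture, impurity)
    corrected = (mixture.intensities - fraction * impurity.intensities) / (1.0 - fraction)
    return mixture.evolve(
        intensities=corrected,
        history_entry=f"subtracted impurity fraction {fraction:g} and re-normalized",
    )


def estimate_impurity_fraction(
    mixture: Spectrum,
    pure_a: Spectrum,
    pure_b: Spectrum,
    window: tuple[float, float],
) -> tuple[float, float]:
    """Least-squares estimate of f in mixture ~= f*pure_a + (1-f)*pure_b.

    Returns ``(f, sigma_f)`` with f constrained to [0, 1] and sigma from the
    linear-fit covariance (residual variance over the window).
    """
    _require_common_grid(mixture, pure_a)
    _require_common_grid(mixture, pure_b)
    mask = mixture.window_mask(window)
    n = int(mask.sum())
    if n < 10:
        raise ConfigError(f"estimation window must contain >= 10 points, got {n}")
    d = pure_a.intensities[mask] - pure_b.intensities[mask]
    y = mixture.intensities[mask] - pure_b.intensities[mask]
    scale = max(
        float(np.sqrt(np.mean(pure_a.intensities[mask] ** 2))),
        float(np.sqrt(np.mean(pure_b.intensities[mask] ** 2))),
        1e-30,
    )
    if np.sqrt(np.mean(d**2)) < 1e-6 * scale:
        raise DegeneracyError(
            "pure components are indistinguishable over the window; "
            "the mixture fraction is unidentifiable"
        )
    denom = float(np.dot(d, d))
    f = float(np.dot(d, y) / denom)
    f_clipped = min(max(f, 0.0), 1.0)
    resid = y - f_clipped * d
    dof = max(n - 1, 1)
    sigma = float(np.sqrt(np.dot(resid, resid) / dof / denom))
    return f_clipped, sigma


def _require_common_grid(a: Spectrum, b: Spectrum) -> None:
    if a.energies.size != b.energies.size or not np.allclose(
        a.energies, b.energies, rtol=0, atol=1e-9
    ):
        raise GridError(
            "spectra are not on a common energy grid; interpolate_to_grid first"
        )


# ---------------------------------------------------------------------------
# derivatives and feature detection


def derivative(
    s: Spectrum, order: int = 1, cfg: DerivativeConfig | None = None
) -> Spectrum:
    """Savitzky-Golay smoothed derivative of a spectrum on its own grid.

    Requires a (nearly) uniform grid: spacing variation above 1% raises
    :class:`~xascov.exceptions.GridError` and the caller should interpolate
    first.  Endpoints are handled by the filter's shrinking polynomial fit
    and flagged in the history.
    """
    cfg = cfg or DerivativeConfig()
    if order not in (1, 2):
        raise ConfigError("derivative order must be 1 or 2")
    if cfg.smooth_window > s.energies.size:
        raise ConfigError("smooth_window exceeds spectrum length")
    if cfg.smooth_order < order:
        raise ConfigError("smooth_order must be >= derivative order")
    spacings = np.diff(s.energies)
    h = float(np.mean(spacings))
    if np.max(np.abs(spacings - h)) > 0.01 * h:
        raise GridError(
            "grid spacing varies by more than 1%; interpolate onto a uniform "
            "grid before differentiating"
        )
    values = savgol_filter(
        s.intensities,
        window_length=cfg.smooth_window,
        polyorder=cfg.smooth_order,
        deriv=order,
        delta=h,
        mode="interp",
    )
    return s.evolve(
        intensities=values,
        normalized=False,
        history_entry=(
            f"Savitzky-Golay derivative order {order} "
            f"(window {cfg.smooth_window} pts, polyorder {cfg.smooth_order}; "
            "endpoints from shrinking-window polynomial fit)"
        ),
    )


def _parabolic_refine(x: np.ndarray, y: np.ndarray, i: int, halfwidth: int = 1) -> float:
    """Refine the position of a discrete extremum by a local parabola.

    A least-squares quadratic is fit to the ``2*halfwidth + 1`` points around
    index ``i`` (``halfwidth=1`` reproduces the exact three-point vertex
    formula); averaging over a few points suppresses the position jitter that
    correlated derivative noise induces.  Falls back to ``x[i]`` when the
    vertex is degenerate or falls outside the fitted span.
    """
    lo, hi = max(i - halfwidth, 0), min(i + halfwidth + 1, x.size)
    if hi - lo < 3:
        return float(x[i])
    coef = np.polyfit(x[lo:hi] - x[i], y[lo:hi], 2)
    if coef[0] == 0:
        return float(x[i])
    offset = -coef[1] / (2.0 * coef[0])
    span = x[hi - 1] - x[lo]
    if abs(offset) > span:
        return float(x[i])
    return float(x[i] + offset)


def _mad_sigma(values: np.ndarray) -> float:
    """Robust noise scale from the median absolute deviation."""
    med = np.median(values)
    return float(1.4826 * np.median(np.abs(values - med)))


def find_edge_features(
    s: Spectrum,
    preedge_window: tuple[float, float],
    edge_window: tuple[float, float],
    deriv_cfg: DerivativeConfig | None = None,
    prominence_sigma: float = 3.0,
    flat_fraction: float = 0.15,
    refine_halfwidth: int = 3,
) -> EdgeFeatures:
    """Locate pre-edge shoulder and rising-edge inflections from derivatives.

    Inflection energies are local maxima of the first derivative inside
    ``edge_window``; the pre-edge feature is the most prominent extremum
    (either sign) of the second derivative inside ``preedge_window``.  The
    prominence threshold is ``prominence_sigma`` times the MAD-estimated
    noise of the relevant derivative over the lowest-energy ``flat_fraction``
    of the spectrum, so a weak shoulder is only reported when it exceeds the
    derivative noise floor.  Both feature types are parabola-refined.
    """
    deriv_cfg = deriv_cfg or DerivativeConfig()
    for window, name in ((preedge_window, "preedge_window"), (edge_window, "edge_window")):
        if window[0] < s.energies[0] or window[1] > s.energies[-1]:
            raise RangeError(f"{name} {window} outside spectrum range")

    d1 = derivative(s, 1, deriv_cfg)
    d2 = derivative(s, 2, deriv_cfg)
    n_flat = max(int(flat_fraction * s.energies.size), 8)

    # rising-edge inflections: maxima of dI/dE
    mask_e = s.window_mask(edge_window)
    e_e, y1 = s.energies[mask_e], d1.intensities[mask_e]
    noise1 = _mad_sigma(d1.intensities[:n_flat])
    floor1 = max(prominence_sigma * noise1, 1e-12 * max(np.max(np.abs(y1)), 1e-30))
    peaks, _ = find_peaks(y1, prominence=floor1)
    inflections = sorted(
        _parabolic_refine(e_e, y1, int(i), refine_halfwidth) for i in peaks
    )
    if not inflections:
        warnings.warn(
            "no first-derivative maximum above the prominence threshold in the "
            "edge window; no inflection points reported",
            stacklevel=2,
        )

    # pre-edge shoulder: most prominent extremum of d2I/dE2 (either sign)
    mask_p = s.window_mask(preedge_window)
    e_p, y2 = s.energies[mask_p], d2.intensities[mask_p]
    noise2 = _mad_sigma(d2.intensities[:n_flat])
    floor2 = max(prominence_sigma * noise2, 1e-12 * max(np.max(np.abs(y2)), 1e-30))
    candidates: list[tuple[float, float]] = []  # (prominence, refined energy)
    for sign in (+1.0, -1.0):
        idx, props = find_peaks(sign * y2, prominence=floor2)
        for i, prom in zip(idx, props["prominences"]):
            candidates.append(
                (float(prom), _parabolic_refine(e_p, sign * y2, int(i), refine_halfwidth))
            )
    preedge_energy = max(candidates)[1] if candidates else None

    # crude step height: mean above the edge window minus mean below the pre-edge
    above = s.energies > edge_window[1]
    below = s.energies < preedge_window[0]
    if above.sum() >= 3 and below.sum() >= 3:
        jump = float(np.mean(s.intensities[above]) - np.mean(s.intensities[below]))
    else:
        jump = float(s.intensities[-1] - s.intensities[0])

    return EdgeFeatures(
        preedge_energy=preedge_energy,
        inflection_energies=inflections,
        edge_jump=jump,
    )
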