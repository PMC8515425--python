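"""Pseudo-Voigt pre-edge fitting and integrated intensity (D0) extraction.

The pre-edge lineshape is the standard eta-weighted sum of a Lorentzian and a
Gaussian sharing one center and FWHM, parameterized by *area* so the fitted
amplitude is directly the integrated pre-edge intensity D0 used in covalency
analysis.  Fits are weighted least squares (unit weights by default) via
lmfit/leastsq with seeded multi-start restarts; sigma(D0) is propagated from
the full parameter covariance, and an optional window jackknife reports the
systematic sensitivity to the window choice separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import lmfit
import numpy as np

from .exceptions import ConfigError, FitError
from .spectra_io import Spectrum

_TWO_SQRT_LN2_PI = 2.0 * math.sqrt(math.log(2.0) / math.pi)
_FOUR_LN2 = 4.0 * math.log(2.0)

BACKGROUND_KINDS = ("linear", "arctan_tail", "linear_plus_arctan")


@dataclass
class PseudoVoigtPeak:
    """One pre-edge peak: center (eV), FWHM (eV), integrated area, Lorentzian
    fraction eta in [0, 1]."""

    center: float
    fwhm: float
    area: float
    eta: float = 0.5

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ConfigError(f"fwhm must be > 0, got {self.fwhm}")
        if not 0.0 <= self.eta <= 1.0:
            raise ConfigError(f"eta must be in [0, 1], got {self.eta}")
        if self.area < 0:
            raise ConfigError(f"area must be >= 0, got {self.area}")


def pseudo_voigt_value(peak: PseudoVoigtPeak, energy: float | np.ndarray) -> np.ndarray:
    """Evaluate an area-normalized pseudo-Voigt profile.

    ``eta*L + (1-eta)*G`` where each component integrates to ``area*eta`` and
    ``area*(1-eta)`` respectively, so the total analytic area is ``area``.
    """
    return _pv(np.asarray(energy, float), peak.center, peak.fwhm, peak.area, peak.eta)


def _pv(e: np.ndarray, center: float, fwhm: float, area: float, eta: float) -> np.ndarray:
    u = (e - center) / fwhm
    gauss = _TWO_SQRT_LN2_PI / fwhm * np.exp(-_FOUR_LN2 * u * u)
    lorentz = 2.0 / (math.pi * fwhm) / (1.0 + 4.0 * u * u)
    return area * (eta * lorentz + (1.0 - eta) * gauss)


@dataclass
class BackgroundModel:
    """Background under the pre-edge window.

    ``linear``: slope, intercept.  ``arctan_tail``: step_height, step_center,
    step_width (the low-energy tail of the rising edge).
    ``linear_plus_arctan`` combines both.
    """

    kind: str = "linear"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in BACKGROUND_KINDS:
            raise ConfigError(f"background kind must be one of {BACKGROUND_KINDS}")
        if "step_width" in self.params and self.params["step_width"] <= 0:
            raise ConfigError("arctan step_width must be > 0")

    def evaluate(self, e: np.ndarray) -> np.ndarray:
        e = np.asarray(e, float)
        out = np.zeros_like(e)
        p = self.params
        if self.kind in ("linear", "linear_plus_arctan"):
            out += p.get("slope", 0.0) * e + p.get("intercept", 0.0)
        if self.kind in ("arctan_tail", "linear_plus_arctan"):
            out += p.get("step_height", 0.0) * (
                0.5 + np.arctan((e - p.get("step_center", 0.0)) / p.get("step_width", 1.0)) / math.pi
            )
        return out


@dataclass
class PreEdgeFitResult:
    """Fitted peaks + background over a window, with D0 and its uncertainty."""

    peaks: list[PseudoVoigtPeak]
    background: BackgroundModel
    d0: float
    d0_sigma: float
    covariance: np.ndarray | None
    var_names: list[str]
    residual_rms: float
    redchi: float
    window: tuple[float, float]
    escaped: list[bool]
    n_starts: int
    d0_sigma_jackknife: float | None = None

    def model(self, e: np.ndarray) -> np.ndarray:
        e = np.asarray(e, float)
        total = self.background.evaluate(e)
        for pk in self.peaks:
            total = total + pseudo_voigt_value(pk, e)
        return total


# ---------------------------------------------------------------------------
# fitting


def _background_param_names(kind: str) -> list[str]:
    names = []
    if kind in ("linear", "linear_plus_arctan"):
        names += ["bg_slope", "bg_intercept"]
    if kind in ("arctan_tail", "linear_plus_arctan"):
        names += ["bg_step_height", "bg_step_center", "bg_step_width"]
    return names


def _eval_params(params: lmfit.Parameters, e: np.ndarray, n_peaks: int, kind: str) -> np.ndarray:
    bg = BackgroundModel(
        kind=kind,
        params={
            name[3:]: params[name].value for name in _background_param_names(kind)
        },
    )
    total = bg.evaluate(e)
    for i in range(n_peaks):
        total = total + _pv(
            e,
            params[f"p{i}_center"].value,
            params[f"p{i}_fwhm"].value,
            params[f"p{i}_area"].value,
            params[f"p{i}_eta"].value,
        )
    return total


def _seed_centers(e: np.ndarray, y: np.ndarray, n_peaks: int) -> list[float]:
    """Initial peak centers from curvature minima of the windowed data."""
    if e.size >= 9:
        # local quadratic second derivative (coarse; only used for seeding)
        from scipy.signal import find_peaks, savgol_filter

        win = min(7, e.size - (1 - e.size % 2))
        if win >= 5:
            d2 = savgol_filter(y, win, 3, deriv=2, delta=float(np.mean(np.diff(e))))
            idx, props = find_peaks(-d2, prominence=0)
            if idx.size:
                ranked = idx[np.argsort(props["prominences"])[::-1]][:n_peaks]
                centers = sorted(float(e[i]) for i in ranked)
                if len(centers) == n_peaks:
                    return centers
    # fallback: evenly spaced quantile positions
    return [float(e[0] + (i + 1) / (n_peaks + 1) * (e[-1] - e[0])) for i in range(n_peaks)]


def _chord(e: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Straight line through the mean of the first and last 3 points."""
    x0, x1 = float(np.mean(e[:3])), float(np.mean(e[-3:]))
    y0, y1 = float(np.mean(y[:3])), float(np.mean(y[-3:]))
    slope = (y1 - y0) / (x1 - x0) if x1 != x0 else 0.0
    return y0 + slope * (e - x0)


def fit_preedge(
    s: Spectrum,
    window: tuple[float, float],
    n_peaks: int = 1,
    background: str = "linear",
    init: list[PseudoVoigtPeak] | None = None,
    weights: np.ndarray | None = None,
    n_starts: int = 5,
    seed: int = 1905,
    jackknife: bool = False,
) -> PreEdgeFitResult:
    """Fit ``n_peaks`` pseudo-Voigt peaks plus a background over ``window``.

    Initial guesses, when not supplied, are seeded from second-derivative
    curvature minima (centers), half the window span per peak (widths) and the
    trapezoidal area above a straight chord (areas).  ``n_starts`` seeded
    restarts jitter centers by +-0.3 eV and widths by x[0.7, 1.4]; the
    best-residual solution is kept.  D0 sums the areas of peaks whose centers
    remain inside the window (escapees are flagged and excluded) and
    sigma(D0) is propagated from the covariance including area-area
    cross terms.
    """
    if n_peaks < 1:
        raise ConfigError("n_peaks must be >= 1")
    if background not in BACKGROUND_KINDS:
        raise ConfigError(f"unknown background kind {background!r}")
    mask = s.window_mask(window)
    e = s.energies[mask]
    y = s.intensities[mask]
    n_free = 4 * n_peaks + len(_background_param_names(background))
    if e.size < math.ceil(5 * n_free / 4):
        raise ConfigError(
            f"window contains {e.size} points; need >= {math.ceil(5 * n_free / 4)} "
            f"for {n_free} free parameters"
        )
    w = np.ones_like(y) if weights is None else np.asarray(weights, float)[mask]

    span = float(e[-1] - e[0])
    chord = _chord(e, y)
    area_est = max(float(np.trapezoid(np.clip(y - chord, 0, None), e)), 0.0)

    if init is not None:
        centers = [pk.center for pk in init]
        fwhms = [pk.fwhm for pk in init]
        areas = [pk.area for pk in init]
        etas = [pk.eta for pk in init]
    else:
        centers = _seed_centers(e, y, n_peaks)
        fwhms = [0.5 * span / n_peaks] * n_peaks
        areas = [area_est / n_peaks] * n_peaks
        etas = [0.5] * n_peaks

    def make_params(jitter_rng: np.random.Generator | None) -> lmfit.Parameters:
        params = lmfit.Parameters()
        for i in range(n_peaks):
            c, fw = centers[i], fwhms[i]
            if jitter_rng is not None:
                c = c + jitter_rng.uniform(-0.3, 0.3)
                fw = fw * jitter_rng.uniform(0.7, 1.4)
            c = min(max(c, e[0]), e[-1])
            params.add(f"p{i}_center", value=c, min=e[0] - 0.1 * span, max=e[-1] + 0.1 * span)
            params.add(f"p{i}_fwhm", value=max(fw, 0.05), min=0.02, max=2.0 * span)
            params.add(f"p{i}_area", value=max(areas[i], 0.0), min=0.0)
            params.add(f"p{i}_eta", value=etas[i], min=0.0, max=1.0)
        if background in ("linear", "linear_plus_arctan"):
            x0, y0 = float(np.mean(e[:3])), float(np.mean(y[:3]))
            x1, y1 = float(np.mean(e[-3:])), float(np.mean(y[-3:]))
            slope = (y1 - y0) / (x1 - x0)
            params.add("bg_slope", value=slope)
            params.add("bg_intercept", value=y0 - slope * x0)
        if background in ("arctan_tail", "linear_plus_arctan"):
            params.add("bg_step_height", value=max(float(y[-1] - y[0]), 0.0), min=0.0)
            params.add("bg_step_center", value=float(e[-1] + 0.5), min=e[0], max=e[-1] + 0.5 * span)
            params.add("bg_step_width", value=1.0, min=0.05)
        return params

    def residual(params: lmfit.Parameters) -> np.ndarray:
        return (y - _eval_params(params, e, n_peaks, background)) * w

    rng = np.random.default_rng(seed)
    best = None
    errors: list[str] = []
    for start in range(max(n_starts, 1)):
        params = make_params(None if start == 0 else rng)
        try:
            res = lmfit.minimize(
                residual, params, method="leastsq", xtol=1e-12, ftol=1e-12, max_nfev=20000
            )
        except Exception as exc:  # noqa: BLE001 - collected into FitError
            errors.append(f"restart {start}: {exc}")
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None:
        raise FitError("all restarts failed: " + "; ".join(errors))

    peaks = [
        PseudoVoigtPeak(
            center=best.params[f"p{i}_center"].value,
            fwhm=best.params[f"p{i}_fwhm"].value,
            area=best.params[f"p{i}_area"].value,
            eta=best.params[f"p{i}_eta"].value,
        )
        for i in range(n_peaks)
    ]
    escaped = [not (window[0] <= pk.center <= window[1]) for pk in peaks]
    d0 = float(sum(pk.area for pk, esc in zip(peaks, escaped) if not esc))

    var_names = list(best.var_names)
    cov = best.covar
    d0_sigma = 0.0
    if cov is not None:
        area_idx = [
            var_names.index(f"p{i}_area")
            for i in range(n_peaks)
            if not escaped[i] and f"p{i}_area" in var_names
        ]
        var = float(sum(cov[i, j] for i in area_idx for j in area_idx))
        d0_sigma = math.sqrt(max(var, 0.0))

    bg = BackgroundModel(
        kind=background,
        params={name[3:]: best.params[name].value for name in _background_param_names(background)},
    )
    resid = y - _eval_params(best.params, e, n_peaks, background)
    result = PreEdgeFitResult(
        peaks=peaks,
        background=bg,
        d0=d0,
        d0_sigma=d0_sigma,
        covariance=cov,
        var_names=var_names,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        redchi=float(best.redchi),
        window=window,
        escaped=escaped,
        n_starts=max(n_starts, 1),
    )

    if jackknife:
        result.d0_sigma_jackknife = _window_jackknife(
            s, window, n_peaks, background, init, weights, n_starts, seed
        )
    return result


def _window_jackknife(s, window, n_peaks, background, init, weights, n_starts, seed):
    """Std of D0 under +-2-point shifts of each window edge (systematic)."""
    idx = np.searchsorted(s.energies, window)
    step = float(np.mean(np.diff(s.energies)))
    d0s = []
    for dlo in (-2, 0, 2):
        for dhi in (-2, 0, 2):
            if dlo == 0 and dhi == 0:
                continue
            shifted = (window[0] + dlo * step, window[1] + dhi * step)
            if shifted[0] >= shifted[1]:
                continue
            try:
                r = fit_preedge(
                    s, shifted, n_peaks, background, init, weights, n_starts, seed,
                    jackknife=False,
                )
            except (ConfigError, FitError):
                continue
            d0s.append(r.d0)
    _ = idx
    return float(np.std(d0s)) if len(d0s) >= 2 else None


# ---------------------------------------------------------------------------
# reporting


def report_fit(result: PreEdgeFitResult, s: Spectrum) -> dict:
    """Tabular fit summary plus overlay-ready curves on the window grid."""
    mask = s.window_mask(result.window)
    e = s.energies[mask]
    data = s.intensities[mask]
    bg = result.background.evaluate(e)
    components = [pseudo_voigt_value(pk, e) for pk in result.peaks]
    model = bg + (np.sum(components, axis=0) if components else 0.0)
    return {
        "peaks": [
            {
                "center": pk.center,
                "fwhm": pk.fwhm,
                "area": pk.area,
                "eta": pk.eta,
                "escaped_window": esc,
            }
            for pk, esc in zip(result.peaks, result.escaped)
        ],
        "background": {"kind": result.background.kind, **result.background.params},
        "d0": result.d0,
        "d0_sigma": result.d0_sigma,
        "d0_sigma_jackknife": result.d0_sigma_jackknife,
        "d0_line": f"D0 = {result.d0:.2f} ± {result.d0_sigma:.2f}",
        "residual_rms": result.residual_rms,
        "window": list(result.window),
        "curves": {
            "energy": e.tolist(),
            "data": data.tolist(),
            "model": model.tolist(),
            "background": bg.tolist(),
            "components": [c.tolist() for c in components],
            "residual": (data - model).tolist(),
        },
    }
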