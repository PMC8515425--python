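# Methods

This note documents the models, defaults and numerical choices behind
`xascov`, and what the synthetic fixtures do and do not establish about real
beamline data.

## Spectrum model and units

All energies are eV. A `Spectrum` is a strictly increasing grid (≥ 8 points)
with finite, unitless intensities; every transforming operation appends one
history entry, so any reported number can be traced to its inputs. Files
whose energy axis looks like keV (maximum < 100) are rejected instead of
converted: a silent factor of 1000 would corrupt every edge-position
comparison downstream. Duplicate energies in a file are averaged, because
repeat scans at identical monochromator points are common. Resampling is
linear by default — linear interpolation never overshoots at a sharp edge,
which matters more here than smoothness; callers wanting splines can build
them from the arrays directly.

## Edge-jump normalization

A polynomial of order 0–1 fit in a pre-edge window is subtracted as baseline;
a polynomial of order 0–2 fit in a post-edge window is evaluated at a
reference energy (default: the midpoint between the two windows, a proxy for
the edge position) and the whole spectrum is divided by that value, so the
edge jump is exactly 1 at the reference energy. The procedure is idempotent:
on an already-normalized spectrum the baseline refits to ~0 and the jump to
~1, so renormalizing is a no-op to ≲1e−9. Fitted jump ≤ 0 is a data error,
not a silent sign flip.

## Impurity subtraction and estimation

For a two-component mixture of unit-edge-jump spectra with impurity fraction
f, the algebraically exact correction is

corrected = (mixture − f·impurity) / (1 − f),

which is simultaneously the subtraction and the re-normalization (the result
has unit edge jump again). This parameter-free rule is the default; a full
re-run of `normalize_edge_jump` is available when the inputs are not unit
jump. When f is unknown, `estimate_impurity_fraction` solves the
one-parameter least-squares problem mixture ≈ f·a + (1−f)·b over a window,
constrained to [0, 1], with σ(f) from the residual variance; nearly identical
components over the window (RMS difference < 1e−6 of the component scale)
raise a degeneracy error because f is then unidentifiable.

## Derivatives and edge features

Derivatives are Savitzky–Golay local-polynomial filters (default 7 points,
order 3), which preserve extremum positions to first order and are the
standard choice for XANES derivative analysis. A uniform grid is required
(spacing variation ≤ 1 %); otherwise the caller interpolates first.

Rising-edge inflection points are local maxima of dI/dE; a weak pre-edge
shoulder is the most prominent extremum (either sign) of d²I/dE². Feature
positions are refined with a least-squares parabola over ±3 points around the
discrete extremum: reported literature energies carry 0.1 eV precision,
finer than typical grids, and averaging several points suppresses the
position jitter induced by correlated derivative noise far better than the
classic three-point vertex formula (measured on the Cu fixtures: ~0.3 eV
worst-case jitter with 3 points vs ~0.15 eV with 7 at noise σ = 0.002).
The detection threshold is 3× the MAD-estimated noise of the relevant
derivative over the lowest-energy 15 % of the spectrum — a principled floor,
since the features of interest are shoulders, not resolved peaks. For the Cu
second-derivative analysis a 9-point window is used instead of 7: the
shoulder is weak and rides two nearby sigmoids, and 9 points was the best
bias/variance compromise on the synthetic templates (wider windows start to
displace the under-resolved 1-hole inflections).

## Pseudo-Voigt pre-edge fitting

The lineshape is η·L + (1−η)·G with common center and FWHM, parameterized by
integrated area, so the fitted amplitude *is* D₀'s contribution — no
height-to-area conversion with its Jacobian enters the error propagation.
η is free per peak in [0, 1] (default init 0.5); no instrument lineshape is
assumed. The default background is linear: the pre-edge sits well below the
rising edge, and the minimal model avoids absorbing peak area into background
curvature. An `arctan_tail` (or combined) background is available when the
window must abut the edge.

Fits are unit-weight least squares (lmfit/leastsq, xtol = ftol = 1e−12) with
seeded multi-start: the first start uses data-derived guesses (centers from
curvature minima, widths from half the window span per peak, areas from the
trapezoidal excess over a straight chord), subsequent starts jitter centers
by ±0.3 eV and widths by ×[0.7, 1.4] (default 5 starts, seed 1905); the
best-residual solution wins. D₀ sums the areas of peaks whose centers remain
inside the window; escapees are flagged and excluded. σ(D₀) is propagated
from the full covariance including area–area cross terms; because weights
are unit, lmfit's residual-variance scaling makes this the usual
`s²(JᵀJ)⁻¹` estimate. An optional window jackknife (refits with each window
edge shifted ±2 points) reports the *systematic* sensitivity to the window
choice separately — it is not folded into σ(D₀).

Monte-Carlo calibration on the synthetic fixtures (100 replicates, noise
σ = 0.005): empirical area scatter 0.0134/0.0129 vs reported median σ
0.0139/0.0128 for the two fixtures — the covariance estimate is accurate,
and 3σ coverage is ≥ 95 %.

## Covalency inversion

α² = 3nD₀/(hIₛ), with σ(α²) = α²·σ(D₀)/D₀. Iₛ and h are treated as exact by
default: propagating σ(D₀) alone reproduces the reference uncertainties
(±0.1 and ±0.5 percentage points) exactly, which indicates that is how they
were derived; an Iₛ uncertainty can be added in quadrature via
`Is_sigma`. Results above 1 are clipped with an explicit flag and warning —
an unphysical covalency almost always means a normalization or hole-count
error and must not pass silently. The hole count comes from the redox state:
2 for the neutral (2Cuᴵ:2Cuᴵᴵ) cluster, 1 for the monoanion (3Cuᴵ:1Cuᴵᴵ),
0 (with a warning) for the fully reduced closed-shell state. n counts
photoabsorbing S only; n = 1 for a μ₄-S cluster. The normalization
convention of D₀ (per-absorber vs total) is moot at n = 1 but must be
revisited before applying the tool to multi-sulfur clusters.

The default dipole-integral calibration is the unique line through the two
anchor pairs (2475.9 eV, 12.9) and (2477.0 eV, 14.9) — slope 20/11 per eV —
because those are the anchor values the reference analysis prints; published
calibration coefficients, when available, can be supplied and take
precedence. Energies slightly outside the calibrated range warn and
extrapolate; Iₛ ≤ 0 is an error.

## TDDFT comparison

Calculated stick spectra are corrected by a single uniform energy shift
(config, never hard-coded — the core-potential error is functional- and
basis-specific; +40.4 eV for the reference B3LYP setup) and broadened with
area-normalized Gaussians of one FWHM (default 1.0 eV). Gaussian-only
broadening is the minimal reproducible choice given that no lineshape is
stated for the reference overlays. The broadened integral equals the summed
oscillator strengths when the grid covers all peaks; insufficient coverage
warns. The overlay metric is a pointwise RMS plus the parabola-refined shift
between pre-edge maxima.

## Synthetic data: what it emulates, and what it does not

Generation is a pure function of (truth, grid, seed): baseline + edge
sigmoid(s) + pseudo-Voigt features + i.i.d. Gaussian noise from
`numpy.random.default_rng(seed)`. Identical inputs give bit-identical
spectra. Empirical noise sd matches the requested σ within 3 % over 10⁴
points.

S K-edge templates (grid 2455–2495 eV, 0.1 eV steps; noise σ = 0.005, seed
1905): one pre-edge pseudo-Voigt (FWHM 1.1 eV — a typical S K-edge width —
η = 0.5) at 2470.2 eV with area 2.03 (2-hole) or 2469.5 eV with area 0.91
(1-hole); a Gaussian 1s→4p feature at 2477.0/2475.9 eV; a unit
cumulative-Gaussian edge step (width 1.0 eV) at 2476.0/2475.3 eV; and a
shallow linear baseline. The *cumulative-Gaussian* step (rather than arctan)
is deliberate: the pre-edge fit window must contain a genuinely linear
background for the linear-background fit to be the correct model, and an
arctan step's Lorentzian tail would curve it (measured bias: ~3 % of the
1-hole area, i.e. ~2σ — enough to break the stated 3σ recovery). With the
Gaussian step the edge contributes < 1e−3 anywhere in the fit windows
((2466.0, 2472.5) and (2465.5, 2472.0) eV). The contaminated fixture is
0.18·two-hole + 0.82·one-hole of the noiseless curves plus noise (σ = 0.003,
seed 7).

Cu K-edge templates (grid 8950–9020 eV, 0.2 eV steps; noise σ = 0.002, seed
11): a weak Gaussian 1s→3d shoulder at 8979.8 eV (FWHM 1.6 eV, area 0.15)
and a rising edge summed from two arctan sigmoids (widths 1.2/1.4 eV, jumps
0.45/0.55). The sigmoid centers are not free parameters: they are solved
(zeros of the analytic second derivative of the full model, including the
shoulder) so that the first-derivative maxima fall exactly at the template
inflection energies — 8982.3/8985.9 eV (2-hole) or 8981.5/8984.8 eV
(1-hole). The fixtures therefore make the reference feature positions true
by construction, and recovery tests measure the analysis, not the template.

Limitations: the generator does not model fluorescence self-absorption,
detector nonlinearity, monochromator glitches, energy-calibration drift, or
correlated noise; the synthetic Cu rising edge is monotone (the local
absorption maximum near 8983 eV seen in real Cu(I) edges is not emulated,
as it does not affect the derivative features being tested); and the S-edge
background under the pre-edge is linear by construction. Passing recovery
tests therefore demonstrates correctness of the estimators under their
stated model, not robustness to every artifact of real fluorescence-yield
data — on real spectra the window jackknife and the `arctan_tail` background
exist precisely to probe the assumptions the fixtures satisfy by design.

## Pipeline and determinism

`PipelineConfig` validates strictly (unknown keys rejected, windows checked)
before any computation. Reports are deterministic for fixed config and
inputs: every random draw (fit restarts, fixture noise) is seeded from the
config or fixture definitions, and timestamps go to the log, not the report.
Each report value carries the operation name that produced it and the
16-hex-digit SHA-256 prefix of the canonical config JSON.

`reproduce()` re-runs the built-in reference analysis end to end. Its
tolerances are: the reference uncertainty plus the last-digit rounding of D₀
for the covalency percentages; half the last printed digit for the
propagated σ values; 3 fitted σ for recovered areas/fractions; 0.1 eV for
fitted centers; 0.2 eV for derivative-located features. Problem sizes are
the fixture defaults above (401-point S grids, 351-point Cu grids, 66-point
fit windows); at these sizes the complete reproduction runs in a few
seconds on one core.
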