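# Methods

This note documents the models implemented in `hemepr`, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions a user relying on the results should
know about.

## Crystal-field analysis of low-spin ferric g-tensors

The one-hole (Griffith–Taylor) treatment regards the low-spin d⁵ ion as a
single t₂g hole whose Kramers ground doublet mixes |d_yz⟩, |d_xz⟩ and |d_xy⟩
with real coefficients a, b, c under spin-orbit coupling. The package
implements the forward map (coefficients → g-values), its exact algebraic
inverse through D = √(8(gz+gy−gx)), and Taylor's expressions for the rhombic
and axial splittings in units of the spin-orbit constant ξ:

    V/ξ = gx/(gz+gy) + gy/(gz−gx)
    Δ/ξ = gx/(gz+gy) + gz/(gy−gx) − (V/ξ)/2

Assumptions: purely non-bonding t₂g orbitals, e_g far enough above to be
ignored, and proper assignment of the principal axes. Inputs are therefore
re-ordered to gz ≥ gy ≥ gx on construction (with a warning), which is the
axis convention the formalism assumes. Within this convention
gz + gy − gx > 0 always holds, so the inversion is defined for every valid
tensor; the ratios additionally require gz > gx and gy > gx strictly, and a
degenerate input raises an error naming the vanishing denominator.

ξ is an optional input (default: absent, ratios only). When supplied, the
free-iron value 400 cm⁻¹ is the conventional choice; covalency in a protein
reduces the effective ξ, so absolute V and Δ should be read as upper-bound
scales rather than measurements.

The normalization m² = a² + b² + c² is reported with an advisory flag when
|m² − 1| > 0.02: below one suggests covalent delocalization of the spin onto
the ligands, above one admixture of excited states with orbital character.
This is interpretive, so it never fails validation.

Uncertainty propagation onto V/ξ, Δ/ξ, V/Δ offers three rules: worst-case
linear sum Σ|∂f/∂gᵢ|σᵢ with analytic partial derivatives (the default),
root-sum-square quadrature (always ≤ linear sum), and seeded Monte-Carlo
sampling of independent Gaussian g-values (≥1000 draws; a seed is mandatory
so that reports are reproducible). The propagation rule used for published
tables of this kind is rarely stated; the linear-sum default is conservative
and matches the printed uncertainty of the rhombic ratio of the reference
dataset at its stated g uncertainties (σ(V/ξ) ≈ 0.06 for
g = (2.440±0.005, 2.25±0.002, 1.92±0.002)).

## Powder CW-EPR simulation

The simulator evaluates the resonance condition hν = g(θ,φ)μ_B B on a
deterministic equal-area Fibonacci lattice over the hemisphere (default
2000 orientations; no random numbers, so spectra are exactly reproducible).
Each orientation contributes a field-domain Gaussian centered at the
resonance field of the effective g, with variance the sum of:

- the residual linewidth `lw_mT`, interpreted as a Gaussian **FWHM** in mT
  (the meaning of "linewidth" in common EPR usage), and
- the first-order field image of anisotropic g-strain,
  σ_B = (B/g)·√(Σᵢ (gᵢlᵢ²/g)² σᵢ²), with the strain components interpreted
  as per-axis standard deviations σᵢ of independent Gaussian distributions
  of the principal g-values. A `strain_is_fwhm` switch converts inputs given
  as FWHM; correlated strain is not supported.

Intensities carry the 1/g frequency-to-field sweep correction; the
transition-moment (g₁-type) anisotropy factor is omitted as subdominant at
X-band. Field modulation is not convolved: the first-derivative trace is
the analytic derivative of the accumulated Gaussians, a good approximation
while the modulation amplitude (1 mT in the emulated acquisitions) is small
against the ≥2 mT linewidth. The absorption integral over the sweep window
is normalized to 1 numerically, so truncating a line at the window edge
rescales rather than loses intensity; a window containing no resonance
yields a warning and a zero spectrum.

Turning-point detection (used for starting values and for validation) reads
the three canonical features of a rhombic derivative spectrum: lowest-field
maximum (gz edge), interpolated central zero crossing (gy divergence),
highest-field minimum (gx edge), after a light Savitzky–Golay smoothing so
white noise cannot masquerade as a feature.

## g-tensor fitting

`fit_gtensor` minimizes the RMS difference between a (preprocessed) spectrum
and the simulator over (gz, gy, gx, three strains, linewidth) with a bounded
Nelder–Mead simplex. Two choices matter:

- Amplitude and vertical offset are profiled analytically by linear least
  squares inside the objective, removing two nonlinear dimensions and making
  the fit exactly invariant to the scaling of the input data.
- The initial simplex is built from physical step sizes (0.01 in g, ~0.005
  in strain, 0.3 mT in linewidth). The optimizer's default 5%-of-value
  simplex takes ±0.12 steps in g — an order of magnitude beyond the width of
  the relevant minimum — and can wander to secondary minima.

The fit is deterministic given the starting point; non-convergence is
reported through a flag, never an exception. Per-parameter 1σ values come
from the diagonal quadratic approximation of the objective at the optimum
and are advisory only (they ignore parameter correlations). The orientation
grid used in the objective should be dense enough that grid ripple sits
below the noise floor; 500 orientations suffice at the 1% noise level of
the recovery tests, while fitting low-noise data warrants ≥800.

Preprocessing follows standard practice for field-swept spectra: a
polynomial baseline (default linear) anchored on the outer 10% of the sweep,
then optional Savitzky–Golay smoothing (order 2, odd window). The smoothing
window of real acquisitions is an operator choice; it is exposed rather than
fixed.

## HYSCORE analysis

Nuclear transition frequencies use the standard S = 1/2, I = 1/2 first-order
expressions with axial hyperfine coupling: A(θ) = a_iso + T(3cos²θ − 1),
B(θ) = 3T sinθcosθ, ν_{α,β} = √[(ν_I ∓ A/2)² + (B/2)²]. Correlation ridges
sweep θ over [0°, 90°] and include the mirrored branch about the diagonal.
The supported-nucleus table ships ¹H only (the quantified couplings of the
emulated study are protons); it is an ordinary dict and extensible by
assignment.

The ridge apex, `ridge_apex_shift`, is defined as the maximum elevation of
the half-sum frequency above the Larmor frequency,
max_θ[(ν_α+ν_β)/2 − ν_I], which approaches the weak-coupling closed form
9T²/(32ν_I) (≈0.63 MHz for T = 5.20 MHz at ν_I = 12.08 MHz). Note the
corresponding *sum*-frequency shift against 2ν_I is twice this number; the
half-sum convention is used here because it is the per-axis displacement of
the ridge from the antidiagonal.

Orientation selection at a field position near a principal g extremity is
modelled as a Gaussian acceptance window in θ centered on the coupling's
β angle (the polar angle of the electron-nucleus vector in the g frame);
τ-dependent blind spots sin²(πν_ατ)·sin²(πν_βτ) are an optional
multiplicative weight. Both affect intensities only — peak and ridge
*positions*, which are the validated quantities, do not depend on them.
Full density-matrix ESEEM amplitude simulation and I = 1 (¹⁴N) ridges with
quadrupole coupling are out of scope.

The point-dipole relation T = (μ₀/4πh)·g_eβ_e·g_nβ_n/r³ is evaluated from
CODATA constants (free-electron g = 2.00232, proton g_n = 5.58569); the
prefactor computes to 79.06 MHz·Å³ for ¹H and is never hard-coded. The
approximation treats the electron spin as a point at the iron; spin
delocalization onto the porphyrin biases distances below ~2 Å.

2D processing mirrors common practice for 4-pulse HYSCORE time traces:
polynomial baseline subtraction (default third order) applied sequentially
along rows then columns, separable Hamming apodization
(0.54 − 0.46cos(2πn/(N−1))), zero filling to `zerofill_factor` × the next
power of two per axis (default ×2), 2D FFT, magnitude. The (+,+) quadrant
is returned by default since weak-coupling proton ridges live there. The
pre-magnitude stage is linear and satisfies Parseval's identity, both of
which are asserted in tests.

## Bruker BES3T I/O

The reader/writer covers the subset of the BES3T format that 1D CW and 2D
pulse acquisitions produce: IKKF REAL/CPLX, IRFMT D (float64) and I (int32),
BSEQ BIG/LIT, linear X/Y axes reconstructed from MIN/WID/PTS. Values are
written as float64, so write→read is bit-exact; field axes in Gauss are
normalized to mT on read (the package-wide field unit). Nonlinear companion
axis files (.XGF/.YGF) and the legacy ESP/WinEPR format are detected and
rejected explicitly rather than mis-read, and a point-count mismatch between
descriptor and data file is always an error, never a silent truncation.

## Synthetic data

The generator emulates the statistical structure of frozen-solution X-band
data: CW spectra are simulator output plus an optional linear baseline drift
and additive white Gaussian noise scaled to the clean spectrum's maximum
(default 1% RMS, a typical signal-to-noise for a 200 µM protein sample);
HYSCORE traces are sums of exponentially decaying 2D cosines at specified
correlated frequencies (default decay 600 ns, dwell 16 ns, 128×128 points,
τ = 208 or 250 ns) with DC offset and noise. All randomness flows from one
integer seed through `numpy.random.default_rng`; array reductions are in
fixed order, so outputs are reproducible across runs and platforms.

Not emulated: 1/f drift and cavity background beyond the linear ramp, field
offsets, incomplete phase cycling artifacts, nuclear-modulation amplitudes
from the density matrix (HYSCORE component amplitudes are heuristic), and
the g ≈ 6 high-spin impurity region of real resting-state spectra. Passing
recovery tests therefore demonstrate correctness of the estimator under the
stated noise model, not robustness to every instrumental artifact.

The fixture suite (`make_fixture_suite`) writes the reference enzyme's CW
spectrum as big- and little-endian BES3T pairs plus an ASCII twin, a 2D
HYSCORE trace as BES3T plus ASCII, and the packaged g-tensor table, with a
SHA-256 manifest; identical seeds reproduce identical checksums.

## Problem sizes used in validation

Validation simulations use 1024–2048 field points with 500–4000
orientations, 10 noise seeds for the recovery study, and 128×128 HYSCORE
traces — sizes chosen so the full statistical suite completes in minutes on
a laptop while every estimate sits well inside its tolerance (the recovery
medians are ~20× below the ±0.005 acceptance band).

## Known limitations

- Tensor orientations (counter-rotation of the g frame) are outside the
  model; only principal values are analyzed.
- The crystal-field inversion assumes the proper-axis assignment produced by
  canonical ordering; chemically motivated alternative assignments (e.g.
  negative g factors) are not explored.
- The fitter is a local optimizer by design: multi-species spectra must be
  analyzed per species with user-supplied g-sets.
- Absolute V, Δ inherit the uncertainty of ξ, which is not fitted.
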