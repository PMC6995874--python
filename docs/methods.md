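# Methods

## The problem

Two-frequency spatial frequency domain imaging (SFDI) recovers wide-field
maps of the absorption coefficient μa and the reduced scattering
coefficient μs′ of a turbid medium (typically tissue) from the diffuse
reflectance of sinusoidally patterned illumination at two spatial
frequencies, f0 = 0 and fn = 0.2 mm⁻¹. The medium acts as a low-pass
filter: the attenuation of the projected fringes at fn, together with the
planar reflectance, determines (μa, μs′) through a one-to-one nonlinear
map. This package implements the full chain — a Monte-Carlo forward model,
demodulation and phantom calibration, and four inversion back-ends (dense
and low-resolution Monte-Carlo lookup tables, the diffusion approximation,
and a random-forest regressor trained on simulated data) — plus a synthetic
scene generator that stands in for a camera acquisition.

## White Monte-Carlo forward model

One scattering-only ("white") simulation of a pencil beam normally
incident on a semi-infinite homogeneous medium serves the entire property
domain:

* Exit weight is histogrammed over (exit radius ρ, total in-medium path L).
* Absorption is applied afterwards by Beer–Lambert weighting exp(−μa·L).
* A change of reduced scattering rescales all lengths by
  s = μs′_ref / μs′ (similarity).
* The spatial-frequency response is the zero-order Hankel transform
  Rd(fx) = 2π ∫ R(ρ) J0(2πfxρ) ρ dρ of the radial reflectance profile.

Choices that matter, with defaults:

* **Refractive index** n = 1.43 inside vs 1.0 outside; unpolarised Fresnel
  reflection at the planar boundary, sampled probabilistically (an internal
  reflection re-enters the walk). Reflectance is normalised to unit power
  *entering* the medium: source specular reflection is outside the model
  (crossed polarisers reject it in a real system), which also matches the
  normalisation of the diffusion closed form.
* **Phase function**: Henyey–Greenstein with g = 0.9 (tissue-like), so
  μs = μs′/(1−g). g is configurable. Note that Rd at fx = 0.2 mm⁻¹ is *not*
  phase-function-invariant at low μs′ (an isotropic walk differs by tens of
  percent at μs′ ≈ 1 because fx·l* ≈ 0.2 is already sub-diffusive), so g
  is part of the model definition; planar reflectance is g-insensitive to
  well under 1%.
* **Scattering-order hybrid**: after 100 scattering events the photon's
  direction memory is gone (g¹⁰⁰ ≈ 3·10⁻⁵) and the walk continues
  isotropically with μs = μs′. In the diffusive regime both the spatial
  spread and the path-length distribution depend on the phase function only
  through μs′, so this is exact similarity physics there, while the early
  sub-diffusive part of the walk — which carries the high-frequency content
  — keeps the full phase function. Measured bias against the pure g = 0.9
  walk is below MC noise (<1%) at both working frequencies; the speedup is
  roughly 1/(1−g) for the long diffusive tail.
* **Binning**: radii and paths use *logarithmic* bins (512 each, radii
  0.005–100 mm, paths 0.01–1000 mm, first bin from 0). Similarity scaling
  stretches lengths by up to μs′_ref/0.01 = 100, so linear bins cannot
  resolve the short-path / small-radius structure that dominates the
  low-μs′ corner of the domain: with 1-mm linear path bins the first bin
  centre (0.5 mm) turns into 50 mm after stretching and exp(−μa L)
  misestimates reflectance by many orders of magnitude. Log bins give
  constant relative resolution (~2%) across the required decades.
* **Exact bin-averaged kernels**: the absorption factor uses the exact mean
  of exp(−μa·L) over each path bin, (e^{−βL1}−e^{−βL2})/(βΔL), and the
  Hankel projection uses the exact area-average of J0 over each annulus,
  2(r2J1(kr2)−r1J1(kr1))/(k(r2²−r1²)). Both are exact for densities uniform
  within a bin, remove the bin-centre sampling artefacts at high scaled
  frequency, and make Rd(0) equal the total reflectance identically.
* **Batch evaluator**: the projection at fn is precomputed on a dense
  logarithmic grid of 512 scaled frequencies v = fn·s; a property pair then
  costs one Beer–Lambert vector over path bins, two row dot-products and a
  linear interpolation in ln v. This interpolated map *is* the package's
  canonical forward model: LUT nodes, training sets and test sets all
  evaluate exactly the same function, so inversion benchmarks measure
  method error, not forward-model disagreement. The interpolation deviates
  from the exact per-pair Hankel evaluation by ~4·10⁻⁵ relative.
* **Termination**: paths are capped at 1000 mm (≈0.9% of the weight at
  μa = 0 is booked to `absorbed_or_lost`); Russian roulette (threshold
  10⁻⁴, survival ×10) guards the weight ledger, which balances to <10⁻⁹
  relative by construction.
* **Reproducibility**: single-threaded, explicitly seeded; a fixed seed
  reproduces the histogram bit for bit.

## Diffusion model

The standard semi-infinite SFD diffusion approximation: with
μtr = μa + μs′, a′ = μs′/μtr, k = 2πfx and μeff′ = √(3μaμtr + k²),

    Rd = 3A a′ / ((μeff′/μtr + 1)(μeff′/μtr + 3A)),
    A = (1 − R_eff) / (2(1 + R_eff)),
    R_eff ≈ 0.0636 n + 0.668 + 0.710/n − 1.440/n².

The two-frequency inverse is solved semi-analytically rather than by 2-D
root finding: at fx = 0, Rd depends on the properties only through a′, so
R0 fixes a′ by a monotone 1-D bisection (machine precision in 80 steps);
Rn then gives μeff′/μtr in closed form (a quadratic), hence μtr and
(μa, μs′). This is exact, fully vectorised over pixels, and cannot
mis-converge; degenerate pixels (Rn ≥ R0, reflectance outside (0,1),
non-finite input, or a solution outside the supported domain) are flagged
per pixel rather than raising.

## Demodulation and calibration

Three-phase demodulation uses the classic formula
A = (√2/3)·√((I1−I2)² + (I2−I3)² + (I3−I1)²), exact for an ideal sinusoid
at 2π/3 spacing and invariant to the global fringe phase. The planar
amplitude is the three-phase mean of the patterned stack by default (a
separately rendered planar stack is supported). Calibration is
Rn = (An/An,ref)·Rn,ref with Rn,ref from the chosen forward model (MC by
default) at the reference-phantom properties (μa = 0.0117,
μs′ = 1.0827 mm⁻¹, the 665-nm silicone phantom values). Camera gain and
illumination cancel in the ratio. Pixels whose reference amplitude falls
below 10⁻⁶ of the reference maximum are flagged invalid; calibrated
reflectance outside [0, 1] is flagged but not clamped, leaving the
out-of-domain policy to the inversion back-end.

## Inversion back-ends

* **LUT**: a uniform P×Q grid over μa ∈ [0, 2], μs′ ∈ [0.01, 15] mm⁻¹ is
  pushed through the forward model (P = Q = 1000 dense, 100 low). A query
  (R0, Rn) is located in the forward image of a grid cell — cell-to-cell
  walk seeded by a nearest-node KD-tree in log-reflectance space, guided by
  inverse-bilinear local coordinates — and inverted bilinearly inside the
  cell (Newton, ~10⁻¹³ residual). Exact at nodes; off-grid error is bounded
  by one property-space cell. Queries outside the mapped manifold return
  the nearest boundary answer plus an out-of-domain flag; non-finite input
  is flagged invalid.
* **Random forest**: scikit-learn multi-output forest, 15 trees, min 2
  samples per leaf, trained on 10⁶ pairs sampled uniformly over the domain
  with forward reflectances as inputs. Both the sampling seed and the tree
  seed are recorded in the model archive (versioned joblib payload; the
  loader refuses unknown format versions). Training and prediction are
  single-threaded for determinism.
* **Diffusion**: the semi-analytic inverse above.

## Error metric

Mean relative error, mean(|pred − truth| / truth)·100, computed separately
for μa and μs′. The sampled μa range includes 0, where relative error is
undefined; samples with true μa < 10⁻³ mm⁻¹ (≈0.05% of a uniform draw) are
excluded from the μa metric and the excluded fraction is reported
alongside. This floor is configurable and moves the headline μa numbers:
lowering it inflates the metric with unmeasurable near-zero samples.

## Synthetic scenes

The generator renders I_k = gain·(dc·R0 + ac·Rn·cos(2πfx·x + φ_k)) per
pixel for region-wise properties (rectangles/disks on a background),
with optional additive Gaussian read noise and Poisson shot noise, at
0.15 mm/pixel and fx = 0.2 mm⁻¹. The six-patch scene spans the phantom
ranges μa 0.0135–0.0437 and μs′ 0.982–1.326 mm⁻¹. What it does *not*
emulate: lateral light transport across region edges (each pixel is
locally homogeneous, so edge pixels are idealised), projector MTF,
vignetting, specular leakage, or sample curvature. Passing closure tests
therefore demonstrate the correctness of the processing chain and the
self-consistency of the forward/inverse pair, not robustness to those
instrumental effects.

## Problem sizes and numerical tolerances

The acceptance computation uses 6·10⁶ photons for the reference histogram
and the full 10⁶/10⁶ train/test protocol; the test suite shares one
2·10⁶-photon histogram across all tests. MC noise enters the benchmark
only through the smoothness of the shared forward map, not as a
forward/inverse mismatch, so the error table is stable at these counts.
Forward-map monotonicity in μa is analytic (Beer–Lambert); monotonicity in
μs′ holds empirically at these photon counts and is asserted for the dense
table. Pipeline closure is exact to fringe-rendering precision (<10⁻⁹
camera units) in the noise-free limit.

## Known limitations

* The low-μs′ strip (μs′ ≲ 0.1 mm⁻¹, i.e. fx·l* ≳ 2) is sub-diffusive and
  thinly sampled by exiting photons; reflectance there is small and
  noise-limited, and inversion errors for *all* methods concentrate in
  this ~0.6% of the domain.
* The diffusion back-end is biased at fx = 0.2 mm⁻¹ for μs′ near 1 mm⁻¹
  (|bias| ≈ 14% in Rn against MC), which is the known failure mode of the
  standard diffusion approximation approaching sub-diffusive frequencies —
  this is why MC-based inverses are the reference.
* Layered media, fluorescence, polarisation and time-domain transport are
  out of scope; the medium is semi-infinite and homogeneous per pixel.
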