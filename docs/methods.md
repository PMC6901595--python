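# Methods

## The model

melphasor implements fit-free phasor analysis of two-photon microscopy data
for quantifying melanin composition in pigmented cells. Two modalities share
one geometric framework.

**Lifetime (FLIM) phasors.** A TCSPC detector records, per pixel, a histogram
I(t) of photon arrival times over one laser period T = 1/f (f = 80 MHz here,
so T = 12.5 ns). The phasor transform is the first Fourier coefficient of
the normalized histogram:

    g = Σ_k I(t_k) cos(h ω t_k) / Σ_k I(t_k),
    s = Σ_k I(t_k) sin(h ω t_k) / Σ_k I(t_k),     ω = 2πf,

summed over bin centers t_k. A single-exponential decay of lifetime τ maps to

    g = 1 / (1 + (hωτ)²),   s = hωτ / (1 + (hωτ)²),

which lies on the *universal circle* (g − ½)² + s² = ¼ for every τ > 0. A
complex (multi-exponential) species sits inside the circle; a pixel containing
two species sits on the chord joining the two pure-species phasors, at the
position given by its intensity (photon) fractions. That linearity is the
entire quantification machinery: no decay model is ever fitted per pixel.

**Spectral phasors.** The same transform applied to the 32-channel emission
spectrum I(λ) with angular argument 2πn(λ − λᵢ)/(λ_max − λ_min). The phase
angle tracks the emission center of mass (red shift = counter-clockwise from
(1, 0)); the modulus falls with spectral width, putting an infinitely broad
background at the origin. Phase inverts to a wavelength via
λ̂ = λᵢ + φ(λ_max − λ_min)/(2πn).

**Assumptions.** Periodic excitation (decays wrapped modulo T, which matters
at 80 MHz where multi-ns melanin decays do not finish between pulses); shot
noise only (Poisson counts; phasor scatter ∝ 1/√N); species mix linearly in
intensity; within the two-endmember decomposition, every photon comes from
one of the two melanin endmembers (violations show up as perpendicular
residual, which is reported per pixel rather than hidden).

## Pipeline steps

1. **Transform** — discrete sums over bin/channel centers. Midpoint sampling
   makes the quadrature error second-order; at 256 bins the residual bias on
   a 2 ns decay is ~4×10⁻⁵ phasor units, at 4096 bins ~10⁻⁷.
2. **Calibration** — a reference fluorophore of known single-exponential
   lifetime (ATTO 488, default 4.1 ns — a literature convention, configurable
   because instruments and solvents vary) is measured identically; the unique
   rotation+scale about the origin mapping its measured phasor to its
   analytic point corrects instrument phase delay and modulation loss
   globally. Per-pixel IRF deconvolution is out of scope.
3. **E-filter** — per-coordinate median convolution (default 3×3, 1 pass)
   that shrinks phasor variance without degrading image resolution.
   Border pixels (within the kernel radius) are returned unfiltered; masked
   neighbors are excluded; an even number of valid neighbors takes the lower
   median so the output is always an observed value and ties are
   deterministic.
4. **Segmentation** — circular cursors on the phasor plane; pixels map to the
   containing disk, overlaps to the nearest center, exact ties to the lowest
   id. Cursors are explicit inputs or placed programmatically: k cursors
   evenly spaced on the endmember chord (k = 7 reproduces the seven-cluster
   pigmentation ladder, consecutive spacing |AB|/6). No automatic cluster
   discovery: the cursor geometry *is* the analysis contract.
5. **Profiling** — the ratio fraction of a cluster is labeled pixels over
   *total* image pixels (masked pixels stay in the denominator, so fractions
   are comparable across cursors and sum to ≤ 1). Clusters are ordered along
   the eumelanin→pheomelanin direction: ascending phase for FLIM (phase grows
   monotonically with lifetime), descending phase for spectral (eumelanin is
   red-shifted).
6. **Fraction decomposition** — orthogonal projection onto the endmember
   chord; f_A = |P′ − B|/|A − B| clipped to [0, 1]; the perpendicular
   distance is reported so three-species pixels are flagged, not dropped.
7. **Statistics** — intensity-weighted average phasor points over ≥ 15
   regions per population (phasor estimators are photon-weighted by
   construction; an unweighted flag exists), sample SDs (n − 1), and a
   two-sample t test on the *s* coordinates at α = 0.05. Welch's variant is
   the default since cluster populations have visibly unequal variances
   (scatter scales with 1/√photons and clusters differ in brightness); the
   pooled test is available via a flag. Only s is tested, and no
   multiple-testing correction is applied across cluster pairs, mirroring the
   source workflow. Linearity of a cluster sequence is scored by
   total-least-squares (PCA): perpendicular RMS residual and first-component
   variance fraction.
8. **Conventional fit** — a periodic-wrapped biexponential
   a₁e^(−t/τ₁) + a₂e^(−t/τ₂) least-squares fit with a fixed multi-start grid
   (τ₁, τ₂) ∈ {(0.3, 2), (0.5, 3), (1, 4)} ns, best residual wins, ties to
   the smaller τ₁ — deterministic. It exists purely to report
   intensity-weighted average lifetimes τ_avg = Σaᵢτᵢ²/Σaᵢτᵢ next to the
   fit-free phasor results.

## The synthetic melanocyte generator

No microscope data ships with the package, so every downstream stage is
exercised on generated scenes with known per-pixel truth.

**What it emulates.** Two melanin endmembers mixed per pixel by photon
fraction f_eu:

| endmember | decay (τ ns, amplitude) | τ_avg (intensity) | emission peak | role |
|---|---|---|---|---|
| eumelanin-like | (0.5, 0.882), (2.5, 0.118) | 1.3 ns | 610 nm | dark pigment |
| pheomelanin-like | (1.0, 0.711), (3.0, 0.289) | 2.1 ns | 589 nm | light pigment |

The intensity-averaged lifetimes are the dark-cell (1.3 ns) and light-cell
(2.1 ns) melanocyte values; the hair-cortex counterparts (1.7 and 2.4 ns)
are reachable by overriding the component amplitudes. Emission profiles are
60 nm FWHM Gaussians integrated exactly (erf differences) over the 32 × 8.9
nm channels spanning 410–696 nm. Decays are wrapped over the 12.5 ns period
with exact per-bin integrals; an optional Gaussian IRF is applied as a
circular convolution (off by default so closed-form checks are exact).
Optional background species — free/bound-NADH-like, collagen/elastin-like
ECM, heme-like porphyrin — occupy non-cell pixels with illustrative but
geometrically distinct decay/spectral positions.

Scene layouts place soma disks with nucleus voids, dense perinuclear
melanosome granules plus sparse granules along thin peripheral processes.
Granule size/density statistics are not published for this system; the
defaults (≈45 granules/cell, radii 1–2 px, 4000 expected photons in a
granule vs 200 in soma) are illustrative choices exposed in configuration.
Ramp and uniform layouts exist for calibration-style tests.

**What it does not emulate.** No optical PSF or blur, no photobleaching, no
detector afterpulsing, no autofluorescence spectra beyond Gaussians, no
spatial correlation of noise. Passing tests therefore demonstrate
correctness of the *analysis geometry and statistics* under shot noise — not
robustness to optical artifacts of real tissue. The descanned-detection
penalty of spectral imaging is modeled only as a global SNR scale factor on
expected counts.

**Determinism.** All randomness flows through a counter-based Philox
generator keyed by the run seed; a (config, seed) pair regenerates stacks
bit-identically. Noiseless expectation mode is exposed for tests
(`noiseless=True` returns expected counts as floats).

## Numerical choices

- Bin/channel centers in all discrete sums (symmetric quadrature error).
- Default harmonic 1 for both modalities; λᵢ defaults to λ_min. Both are
  configuration because the conventions are not fixed by the acquisition.
- Intensity threshold 20 photons/pixel for FLIM masking: below that the
  phasor scatter (≥ 0.1 phasor units) makes cursor assignment meaningless.
  Zero-count pixels are always masked in both modalities.
- Fractions are clipped to [0, 1] after projection; residuals carry the
  off-chord information.
- Degenerate inputs are explicit: zero-modulus calibration references and
  empty decays raise; the phasor-plane origin has phase 0 with a degenerate
  flag; angle→wavelength inversions leaving the detector range are flagged
  aliased but still returned; constant identical t-test populations return
  p = 1 flagged degenerate.
- The pipeline's downstream stages (segment/profile/stats) consume the
  float32 phasor field as re-read from disk, so the umbrella command is
  byte-equivalent to composing the subcommands.

## Problem sizes and defaults used in the shipped checks

The test-suite and acceptance-script scenes are desk-scale by design:
128×128 pixels × 256 time bins for the circle-membership check (1,000
photons/pixel), 48×96 ramps at 4,000–5,000 photons/pixel for linearity and
fraction recovery, 500 replicates × 4 photon levels for the shot-noise law,
1,000 reseeded repeats for t-test calibration, and a 96×96 demo scene for
the end-to-end pipeline. These sizes keep full runs in seconds while leaving
every statistical tolerance comfortably non-marginal.

## Known limitations

- Two-component decomposition only; three or more species are handled
  geometrically by cursors, never by matrix inversion.
- Calibration is global; spatially varying instrument response is not
  corrected.
- The biexponential fitter is a per-decay tool, not an image-scale engine;
  it has no global/multi-pixel mode.
- `ratio_fraction` is sensitive to the field-of-view definition by design
  (total-pixel denominator); cropping changes fractions.
- No reader for vendor TCSPC formats (.sdt, .ptu, .lsm/.czi); data enters as
  multi-page TIFF + JSON sidecar.
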