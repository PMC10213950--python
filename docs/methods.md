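# Methods

## Sensor forward model

Every pixel of the modelled chip stacks three photodiode collection volumes
in silicon; incident photons are absorbed at a depth set by the silicon
absorption coefficient α(λ), so the three layers act as three broad spectral
channels. The default quantum-efficiency model is a three-layer
Beer–Lambert absorber: with cumulative layer boundaries d₁ < d₂ < d₃ (µm,
defaults 0.6, 2.0, 10.0 measured from the illuminated surface), the fraction
absorbed in layer *i* is `exp(−α d_{i−1}) − exp(−α d_i)`. α(λ) comes from a
built-in log-interpolated table of crystalline-silicon reference values
(400–1000 nm). Each layer fraction is multiplied by a flat carrier
collection efficiency (0.95) and by the pixel's SP or LP interference-filter
transmission, modelled as a logistic band edge (SP cut-off 662 nm, LP cut-on
668 nm, 3 nm edge width) with out-of-band transmission 10^−OD at the default
OD 4. The layer boundaries are not manufacturer data; they were chosen once
so the model reproduces the qualitative response of the physical device —
top diode blue-dominant and bottom diode red-dominant under SP, bottom ≫
middle > top in the NIR under LP, with the top-diode NIR response decaying
fastest — and digitised QE curves can be substituted via the CSV interface.

Exposure integrates photon radiance (photons s⁻¹ px⁻¹ nm⁻¹) against the QE
curve of the pixel's checkerboard parity over a 1 nm wavelength grid
(400–1000 nm, fine enough to resolve the 17 nm FWHM monochromator bands).
Noise is Poisson shot noise on the expected electrons followed by additive
Gaussian read noise (default 70 e⁻ RMS); fixed-pattern noise and dark
current are not modelled because only those two sources are quantified for
the instrument. Electrons clip at the 100 ke⁻ full well and convert to
digital numbers with a 64 DN dark offset and a gain chosen so the full well
maps onto the 12-bit ceiling (≈ 24.8 e⁻/DN); neither gain nor offset is
published for the camera, so both are explicit configuration with these
defaults. The SNR ceiling `20 log₁₀ √full_well` evaluates to 50 dB at the
defaults. All randomness flows from a single integer seed through
`numpy.random.SeedSequence`; per-frame child seeds are masked to < 2³¹.

## Scene generation

Scenes are radiance cubes with ground-truth region masks. Fluorophore
emission uses a skew-normal spectral shape (mode = emission peak, given
FWHM, red-skewed) normalised so the grid integral equals a relative
brightness factor folding quantum yield and extinction together. Peaks and
widths follow vendor spectra (IRDye 680RD conjugate 694 nm / 36 nm,
IRDye 800CW conjugate 794 nm / 40 nm, aqueous ICG 815 nm / 55 nm); the
brightness factors (1.0, 0.35, 0.28) were set once so that, at the study's
illumination (665 nm at 50 mW/cm², 785 nm at 150 mW/cm², 200 ms exposure),
the IR680 conjugate gives the highest MFI per µM, the IR800 conjugate and
ICG land at a similar level, and all three clear the detection threshold at
0.1 µM — the instrument's reported operating behaviour. Concentration →
radiance is strictly linear (no inner-filter effect, quenching or
saturation), matching the instrument's linear dilution response over
0.1–1 µM. Residual excitation laser light is a 0.8 nm Gaussian line
attenuated by the camera notch filters (OD 6.5 > the specified > 6), and
overlying tissue is a single multiplicative per-region attenuation factor,
not a transport model. The global radiometric constant (1.3 × 10⁴ photons
per µM·mW cm⁻²·s·px) calibrates 1 µM vials into the sensor's working range
(≈ 2300 DN), since absolute system throughput is unpublished.

The monochromator band sweep produces Gaussian flat fields (default
680–820 nm in 20 nm steps, 17 nm FWHM) numerically normalised to identical
integrated radiance; the default amplitude puts the recorded level at
≈ 230 DN, the matched intensity at which the bench sweep was acquired.
USAF-1951 charts render three anti-aliased vertical bars per element (bar
width 500/lpmm µm, default 2 µm/px) with per-element bar/gap positions in
the ground truth; the depth-of-focus target is a 15 lp/mm horizontal bar
field on a 45°-tilted plane whose per-column depth labels drive defocus.

Chromatic aberration is a band-dependent Gaussian PSF. Defocus σ grows as
`hypot(σ₀, s·Δd)` with σ₀ = 0.5 px and s = 1.5 px/mm of defocus Δd. The EIS
mode focuses visible and NIR on the same plane (Δd_NIR = Δd_vis); the KS
mode adds a 3.0 mm NIR focal-plane shift, a value chosen once so the
emulated conventional endoscope resolves USAF group 5 element ≈ 2 in the
NIR (the ~15 µm NIR resolution reported for that scope) while its visible
resolution is unaffected. The exact optical prescription of either scope is
not public; only this ordering, not the 60 % improvement figure, is treated
as a model output.

## Demosaicking

The raw frame is a (3, H, W) stack sharing one SP/LP checkerboard. Missing
parities are filled by averaging the four same-parity edge neighbours
(exact for affine intensity fields, no overshoot); borders use a one-pixel
mirror pad, which preserves checkerboard parity. Nearest-neighbour filling
is kept for debugging. The dark offset is subtracted, and clamped at zero,
*before* interpolation so that downstream hue–saturation arithmetic sees
signal-proportional values — hue/saturation are scale-invariant but not
offset-invariant.

## Hue–saturation statistics

The NIR triplet maps to pseudo-RGB in penetration-depth order (bottom → R,
middle → G, top → B); any fixed permutation only rotates hue, and no test
asserts absolute hue values. The hexagonal HSV transform then yields hue
(degrees) and saturation; all-zero triplets are flagged (undefined hue)
rather than raised. Wherever hue and saturation share a plane, saturation
is expressed in percent so both axes are O(10) and total-least-squares
geometry is not dominated by one unit.

Cluster statistics treat hue circularly: the centre is the circular-mean
hue, residuals are wrapped to (−180°, 180°], and the covariance is computed
in those local planar coordinates — adequate because the clusters occupy
narrow hue arcs. Tolerance ellipses scale the sample covariance by the
χ²(2 df) quantile of the requested level (population form; no small-sample
tolerance-factor correction). Rank-deficient clusters return a flagged
degenerate ellipse with a zero minor axis. Separability of two same-level
ellipses is decided by centre-containment plus a 4096-point boundary
parametrisation of each ellipse evaluated in the other's Mahalanobis metric;
tests check it against an independent dense-grid oracle.

The ratio line is the total-least-squares (first principal component) line
through the six cluster means of the 10:0 … 0:10 IR680:IR800 series,
oriented so its parameter increases with IR680 fraction. Estimation
projects a point orthogonally onto the line and interpolates the fraction
piecewise-affinely between the calibration parameters (cluster spacing
along the line is visibly non-uniform, so a single affine map would bias
mid-range ratios); if the calibration parameters are not monotone the
estimator falls back to the affine map through the pure endpoints. Results
clamp to [0, 1].

The limit of detection uses the background mean + 2 sample standard
deviations (ddof = 1) threshold and returns the smallest concentration
opening an all-above suffix of the ascending series, so a spurious
low-concentration excursion below a failing higher concentration does not
count. MFI is a plain arithmetic ROI mean of digital values; TBR divides
offset-subtracted tumour MFI by background MFI and refuses non-positive
backgrounds.

## Resolution scoring

Element contrast is Michelson `(Imax − Imin)/(Imax + Imin)` with Imax/Imin
the medians of the profile intensities at the known bar and gap centres
(peak-finding fallback without metadata); profiles take the median of three
adjacent rows to suppress pixel noise. An element is "resolved" at
Michelson contrast ≥ 0.1 — the bench criterion is visual differentiability,
so a numeric threshold is required for automation and is configurable. The
finest-resolved scan runs coarse → fine and stops at the first failure, so
aliasing-induced contrast rebounds beyond the cut-off are not credited.

## Problem sizes and determinism

Simulated studies use deliberately small frames — 12×12 px flat fields
(100 frames/band) for the band sweep, 24×24 px vials (30 frames/ratio) for
the ratio study, ~2 µm/px charts for USAF scoring — sizes at which the
ROI-level statistics are stable and every experiment reruns from scratch in
seconds. The reproduction script (`scripts/acceptance.py`) recomputes the
narrow-band separability level through the full chain at those sizes; all
stochastic tests fix seeds and every simulated frame is bit-reproducible
from the master seed.

## Limitations

The generator emulates spectra, noise and blur, not real tissue: no photon
migration, autofluorescence, specular reflection, probe pharmacokinetics or
fixed-pattern sensor artefacts. Passing tests therefore demonstrate the
correctness and intensity-invariance of the analysis chain under the stated
sensor physics, not instrument-level absolute performance: quantities that
depend on unpublished gains, optics or real specimens (absolute µM limits of
detection of the physical camera, in-vivo/clinical tumour-to-background
ratios, the 60 % NIR resolution-improvement figure) are covered only by
generator round-trip and ordering checks. Three-fluorophore linear
unmixing, white balance/colour calibration of the visible channels, and
real-time acquisition concerns are out of scope.
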