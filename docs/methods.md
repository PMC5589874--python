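# Methods

This note documents the models behind `qpraman`, the defaults it ships, what
the synthetic generator does and does not emulate, and the numerical choices
made where the underlying measurement protocol leaves the implementation
open.

## 1. Phase imaging model

The measured phase of a transparent cell in PBS, imaged in a reflection
(double-pass transmission) geometry, is

φ(x, y) = 2 ∫ (2π/λ) [n_cell(x, y, z) − n_PBS] dz ,

with λ = 0.8 µm the source centre wavelength (the ≈17 nm spectral width is
ignored; a single λ enters all conversions). The leading factor 2 is the
double pass. **We never divide this factor out**: the pipeline carries the
measured phase as-is and compensates in the dry-mass conversion, which uses
λ/4π rather than λ/2π:

m = (1/α) ∬_S (λ/4π) φ dx dy ,  α = 0.185 µm³/pg.

α is the specific refractive index increment of typical cellular material
(0.185 ± 0.002 µm³/pg); it is a parameter everywhere (`alpha=`), with the
dimensional bookkeeping µm · rad · µm² / (µm³/pg) → pg.

### Off-axis forward model and demodulation

The synthetic interferogram is `I = A + B·cos(2π k·r + φ) + noise` with
defaults A = 1, B = 0.8 (fringe visibility 0.8, typical of a well-aligned
interferometer) and carrier k = (0.25, 0) cycles/pixel. Valid carriers are
constrained to |k| ∈ [0.1, 0.4] cycles/pixel: below 0.1 the sideband window
would touch DC, above ~0.4 the carrier itself approaches Nyquist. Noise is
additive Gaussian by default (CCD read noise proxy; keeps analytic error
budgets simple); Poisson shot noise is selectable (`noise_model="shot"`).

Demodulation: FFT → recentre the +k sideband by **integer** bins → hard
circular window of radius 0.5·|k| (raised-cosine edge optional) → inverse
FFT → complex argument, wrapped to (−π, π]. Integer-bin recentring means a
sub-bin carrier residual survives as a small tilt; this is deliberate — the
background-plane stage removes any tilt, and it keeps the demodulation free
of interpolation artefacts. The default synthetic carrier is
bin-commensurate at 512², so the round trip is exact to ~10⁻⁵ rad RMSE.

### Unwrapping

Two algorithms are provided: reliability-ordered region growing (`quality`,
the default — robust on smooth cell-like phase) and an unweighted
least-squares solution via a DCT Poisson solve (`lsq`). Both return the true
surface up to one global 2πk offset; the `lsq` free constant is pinned
modulo 2π against the wrapped input so that offset is itself a 2π multiple.

### Background subtraction

A first-order plane (tilt + offset) is the background model — the dominant
instrumental terms. The "auto" region is estimated in two passes: pixels
whose residual after a provisional full-image plane fit falls below the
20th percentile seed the fit (surely background), and the region is then
widened to all pixels whose provisionally corrected phase stays below
0.1 rad (half the segmentation threshold). The second pass matters: nulling
the median over only the low-percentile tail biases the zero level upward
by about the ripple half-width, which we measured as a systematic +1–4 %
dry-mass error before introducing it. After correction the background
median is zero by construction (|median| < 0.02 rad contract).

### Segmentation and per-cell readout

Foreground is φ strictly greater than 0.2 rad; components are 4-connected;
components below 50 pixels are discarded; holes are *not* filled by default
(flag available). Each component is an independent cell observation. Area
is the projected segmented area (no convex hull). Matter density is exactly
mass/area.

Threshold segmentation truncates any part of a cell whose phase lies below
0.2 rad. Uniform-disk phantoms (entire support above threshold) therefore
recover their closed-form mass within 2 % through the full noiseless
pipeline, while tapered profiles (smoothed disk, Gaussian cap) lose their
sub-threshold rim by construction — ground-truth mass comparisons through
segmentation use the uniform profile, and the rasterisation-level checks
(no segmentation) cover the tapered ones.

## 2. Raman preprocessing model

Pipeline order is fixed: **restrict → baseline → SNV**, then band readout /
PCA.

* *Fingerprint restriction*: inclusive clip to 600–1800 cm⁻¹.
* *Baseline*: "fit and subtract a 4th-order polynomial" is ambiguous when
  peaks are present — a plain least-squares fit would subtract part of every
  band. We use the modified-polyfit scheme: fit, clip the working spectrum
  to min(data, fit), refit, until the working spectrum changes by less than
  10⁻⁶ of the intensity range or 100 iterations. The converged polynomial is
  subtracted from the *original* spectrum, so noise-level negatives survive.
  The scheme is exactly shift-equivariant under addition of any ≤4th-order
  polynomial and annihilates pure quartics to machine-level residuals.
* *SNV*: per-spectrum (x − mean)/SD with sample SD (n−1); idempotent;
  errors on constant spectra.
* *Band intensity*: mean over centre ± 5 cm⁻¹ of the SNV representation
  (the pipeline's terminal representation — the "normalized" intensity).
* Spectra arriving on different grids are linearly interpolated onto the
  first grid (single-instrument assumption). Cosmic-ray despiking is out of
  scope by default.

## 3. Chemometrics and statistics

* *PCA*: column mean-centring only (SNV already row-standardises), full SVD,
  3 components. Sign per component is fixed deterministically (largest
  |loading| element positive). Scores are the centred data projected on the
  loadings; explained-variance fractions are non-increasing.
* *Separation summary*: the published analogue is a visual 3-D scatter; a
  test needs a number, so we report the silhouette coefficient of the 3-PC
  scores (an artifact-internal choice; >0.3 ≈ visibly separated clusters).
* *Group testing*: unpaired t-test with Welch correction
  (Welch–Satterthwaite df, two-sided p). Default comparisons are each
  exposed group vs control; all pairs by flag. No multiple-testing
  correction (raw p-values are the protocol's convention).
* *Viability*: corrected absorbance = A570(sample) − mean A600(blank rows),
  grouped by exposure time.
* *Dosimetry*: fluence (J/cm²) = irradiance (W/m²) × time (s) / 10⁴. The
  `paper_precision` mode rounds to one decimal solely to compare with
  protocol-quoted doses (1.02 W/m² × 50/100/200 min → 0.306/0.612/1.224 →
  0.3/0.6/1.2 J/cm²).

## 4. The synthetic world

Defaults state one concrete, realistic experiment; they are not tuning
knobs.

**QPI arm.** 512² field at 0.1 µm/pixel (a 60×/1.0 NA scale; the protocol
does not state pixel geometry), 10 cells per group (the protocol imaged
~10 cells per group; its "20 phase images" per group are unexplained and
replicate frames of a noiseless phantom would add nothing). Phantoms are
radially symmetric so true dry mass has a closed form: uniform disk
(φ₀πR²), smoothed disk (φ₀πR²/3), truncated Gaussian cap. Base cell:
R = 15 µm, φ₀ = 1.2 rad. Group structure: mean dry mass scales by
1.00/0.85/0.70/0.60 for control/T50/T100/T200 with 5 % between-cell CV —
the dose-dependent mass loss the phase arm is designed to detect. The CV is
placed on *mass*: radius varies independently (5 %) and the peak phase
compensates quadratically (cells of fixed mass spreading to different
footprints). This matters for power: putting independent scatter on radius
would inflate mass CV to ~11 % and the smallest dose step (15 % at n = 10)
would no longer reject at p < 10⁻⁴. With the stated world, dry-mass Welch
tests control-vs-each-exposed all reject at p < 10⁻⁴. Matter-density
comparisons inherit the radius scatter (~11 % CV): T100/T200 reject
strongly but control-vs-T50 density lands near p ≈ 10⁻³ at n = 10 — an
honest power limitation of the small-n design, so the group-comparison
guarantee is stated for dry mass.

**Raman arm.** 15 spectra per group (5 cells × 3 repeats), 1 cm⁻¹ grid over
400–2000 cm⁻¹. Bands are Lorentzian by default (conventional for Raman
lines; Gaussian selectable) at the fibroblast assignment positions
(nucleic acids 720/1093/1340/1576, tyrosine 835, phenylalanine 1004, amide
III 1250, CH₂ 1440, amide I 1660). Markers: 1584 cm⁻¹ amplitude increases
strictly with dose (0.30/0.45/0.60/0.75); 1000 cm⁻¹ rises through T100 and
dips at T200 (0.30/0.50/0.70/0.45), mirroring the reported
signal-to-noise-driven dip in heavily damaged cells. A degree-4 polynomial
(decaying, amplitude ~6× band scale) plays the fluorescence background;
white noise SD 0.02 (band SNR ≈ 50) plus 5 % multiplicative per-band
jitter emulate shot noise and cell-to-cell/focus variability. At these
settings the four groups separate with 3-PC silhouette ≈ 0.5.

**Viability arm.** Corrected-absorbance group means 0.85/0.70/0.55/0.35
(monotone decline with dose), blank A600 = 0.10, replicate noise SD 0.02,
3 replicates per group.

**What the generator does not emulate** — and hence what a green test does
*not* establish: speckle decorrelation, partial coherence, diffraction and
optical aberrations (only a demodulatable fringe image is modelled);
non-symmetric or internally structured cells; correlated (non-white)
spectral noise, wavenumber miscalibration and cosmic rays; any biology —
group effect sizes are stated inputs, so recovering them validates the
*computation*, not the radiobiological claim.

## 5. Numerical conventions

* RMSE metrics on phase exclude a 5-pixel border (window edge effects).
* Wrapped phase lives in (−π, π] (`np.angle` convention).
* Fitting the baseline uses the wavenumber axis rescaled to [0, 1] for
  conditioning; generator baseline coefficients are defined on that same
  axis, making them grid-independent.
* All randomness flows from explicit seeds through `numpy` Generators;
  sub-seeds for per-image/per-group streams derive from
  `SeedSequence([seed, tag, index])`, keeping every generated artefact
  bit-reproducible. CSV outputs of `run_all` are byte-identical across
  re-runs of the same config.
* Group summaries use the sample SD (n−1). Singleton groups report SD 0
  with a warning (spectra) or NaN (cell tables, n ≥ 2 expected).

## 6. Known limitations

* Integer-bin recentring leaves a sub-bin carrier tilt to the background
  stage; carriers chosen pathologically close to half-bin offsets on tiny
  images could leave a residual ramp of a few mrad across the field.
* The hard sideband window rings on phase discontinuities (uniform-disk
  edges): phase RMSE near the rim is ~0.04 rad even noiselessly, though the
  *integral* (mass) stays within budget. The raised-cosine edge reduces
  ringing at a slight resolution cost.
* The auto background region assumes cells occupy well under half the
  field; confluent fields need an explicit mask.
* The iterative-clip baseline slightly undercuts very broad bands
  (width ≳ 1/6 of the fitted range); band areas are preserved to ~5 % for
  typical fingerprint line widths.
* Absolute per-group dry-mass/density values of the emulated study are not
  reproducible from published material (figure-only); only the group
  *structure* is modelled.
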