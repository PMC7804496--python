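# Methods

## Model

The package computes one quantity — radially generalized contrast energy —
and maps it to predicted identification accuracy.

**Filtering.**  Each stimulus is convolved with a single
difference-of-Gaussians kernel ς = M_σF − M_σB.  Both Gaussians use the
2-D normalisation `(2πσ²)⁻¹`, are sampled at integer pixel offsets on the
common support of radius `ceil(4·σ_B)`, and the difference is
mean-subtracted after truncation so the kernel sums to exactly zero:
uniform images produce an identically zero response regardless of
truncation error.  The surround is a fixed multiple of the centre,
σ_B = K·σ_F with K = 5 by default.  Convolution pads the image with its
declared background level (the display beyond the canvas is assumed
blank), and switches from direct to FFT evaluation when the kernel side
exceeds 64 px; the two paths agree to ~1e−10 and the threshold is purely
a speed choice.

**The semi-norm.**  Contrast energy is the root mean square of the
filtered image, `C = sqrt(mean(response²))`.  The per-pixel (mean-square)
normalisation is chosen so that the degenerate mask — impulse foreground,
uniform background over the image — reduces C exactly to textbook RMS
contrast; a sum-square convention is selectable per call for users who
prefer unnormalised energy.  Which normalisation the original analyses
used is not stated explicitly; nothing downstream depends on the choice
because the behavioural mapping is applied in ratio space (below).

**Receptive-field scale.**  Two modes supply σ_F.  Reproduction mode uses
the tabulated sigma (in pixels) shipped with each experiment condition.
Model mode derives sigma from the dendritic-field power law
`8.64·x^1.04` µm at `x` retinal mm, via a retinal magnification constant
(0.29 mm/deg) and a diameter-to-sigma factor (one half).  The tabulated
sigmas cannot be recovered from the power law with any single pair of
such constants across conditions (e.g. the 5° condition of the
distant-viewing experiment has a smaller angular sigma than the 3.88°
vernier condition), so the two model-mode constants are exposed,
documented as unvalidated against the tables, and bypassed entirely in
reproduction mode.  One kernel is used per image, evaluated at the target
centre's eccentricity; the tabulated dendritic data were collected over a
17.2°-wide window (recorded in the config), but sigma is not varied
across the image.

**Behavioural mapping.**  Identification accuracy is
`p = ceiling · (G_τ(C) + 1 − G_ϕ(C))` with both Gaussians centred on the
target-alone contrast μ_τ.  σ_τ is fixed by the assumption that a 10 %
contrast change produces a 1 % identification rate
(σ_τ = 0.1 μ_τ/√(−h), h = 2 ln 0.01 < 0); σ_ϕ = k_ϕ σ_τ follows from the
single behavioural parameter E_α through
k_ϕ = |E_α − μ_τ|/(0.1 μ_τ).  The squared forms make the sign of
E_α − μ_τ irrelevant; ratios below 1 are rejected rather than clipped
because they would push p above the ceiling.  The 0.85 ceiling reflects
the empirical maximum of the modelled experiments and multiplies the
whole expression.  Between roughly |C − μ_τ| ≈ 2σ_τ and ≈ k_ϕσ_τ the
prediction dips — that dip is the predicted crowding regime.

**Ratio-space calibration.**  Absolute contrast energy depends on free
rendering choices (canvas size, exact stimulus dimensions), so
experiment runs self-calibrate: μ_τ is measured from this package's own
target-alone render, and E_α is placed at `μ_τ·(1 + 0.1·k_ϕ)` using the
published dimensionless k_ϕ, which is invariant under any rescaling of
the contrast axis.  Predictions therefore depend only on how far the
flankers move contrast energy *relative to* the isolated target.  The
published μ_τ and E_α values are still consumed verbatim by the
summary-table reproduction and the acceptance script.

## Condition table and the PL/PS inconsistency

The shipped YAML config carries the eight published condition rows
(eccentricity, viewing distance, 0.282 mm pixel pitch, sigma in pixels,
μ_τ, σ_τ, E_α, k_ϕ).  The two letter-array rows are mutually
inconsistent as printed: their k_ϕ columns (10.8333, 9.9999) match
|E_α − μ_τ|/(0.1 μ_τ) only if the two E_α entries (0.010, 0.025) are
exchanged.  Both readings are retained in the config; the reproduction
report shows both and no code guesses which was intended.  Experiment
runs use the printed k_ϕ column directly, which is well defined under
either reading.

## Synthetic stimuli

All stimuli are generated in code; there are no image assets.  Shapes are
drawn as analytic boolean masks (annuli with rectangular gap slots at
standard 5:1 Landolt proportions, rectangles for bars and vernier
segments) on a grid optionally supersampled by an integer factor and then
block-averaged; supersampling provides grayscale anti-aliasing and
sub-pixel placement, while the default binary rendering keeps pixel-count
oracles exact.  Letters are fixed embedded 6×5 bitmaps scaled by
nearest-neighbour — deterministic across platforms, deliberately not a
typographic match to any publication font.  Rendering is a pure function
of the spec.

The generators emulate stimulus *geometry and intensity layout* only:
uniform background, two ink levels, no noise, no luminance calibration,
no temporal structure.  Passing tests therefore show that the metric and
mapping behave as claimed on idealised displays; they do not certify
predictions for photographs, textured or colour stimuli.

Free dimensions not restated in the source tables were fixed once, as
follows, and recorded here as the package's defaults:

* **Letter arrays** (5–20° eccentricity, 34.58 px/deg): target "r",
  four "a" flankers at 0.15° letter height, gray-on-white (ink 0.5 on
  background 1.0).  Flank distance is edge-to-edge between glyph boxes:
  with the published 0.05–0.4° sweep, centre-to-centre placement would
  physically overlap the letters over most of the range.  Supersampling 8
  keeps sub-pixel placement ripple below ~0.5 %.
* **Landolt C with bars** (5° eccentricity, 1423.48 px/deg): C diameter
  4′ (stroke and gap 0.8′), black on gray (0 on 0.5), four tangential
  bars of width 0.8′, flank distance edge-to-edge in arcminutes as in the
  original acuity study.  Bar length (2′) was set so the rendered
  contrast-energy curve reproduces the anchor values stated for the
  original analysis — near-contact contrast a few percent above the
  interior minimum and well below the large-distance asymptote; the
  stated near-contact value is read as 0.0220 (its printed form appears
  to carry a one-digit typo).
* **Vernier with line flankers** (3.88°, 46.42 px/deg): two 20′ segments,
  4′ vertical gap, 2′ horizontal offset, 1′ stroke, white on black;
  flankers at 10′ spacing, heights 0.5/1/2 × the vernier.
* **Concentric Cs** (10°, 35.90 px/deg): target C of 1.25° diameter,
  flanking rings at mid-radius steps of 0.375° with the target's 0.25°
  stroke, gap orientations cycling a fixed sequence, optionally ungapped.
  The ring-step sweep (0.375–0.5625°) keeps ring separations above the
  surround scale σ_B ≈ 0.12°: at touching separations the ungapped rings
  merge into a solid band and lose their edges, inverting the
  gapped/ungapped ordering — a regime the original, well-separated
  stimuli do not enter.

Canvas sizes are fixed per condition across a sweep (the mean-square norm
divides by pixel count, so sweeps must share a pixel count) and sized to
hold the largest sweep configuration.

## Numerical choices

* Kernel truncation at 4σ_B captures >99.9 % of both Gaussians; exact
  constant-annihilation is restored by mean subtraction.  Comparisons of
  the discrete spectrum against the closed-form Gaussian transforms use a
  wider support (factor 8), because 4σ_B truncation alone leaves a
  ~3×10⁻⁴ spectral residual; the support factor is an exposed parameter.
* Images are row-major, origin top-left, intensities in [0, 1]; 8-bit I/O
  rescales by 1/255.  Response maps export as 32-bit float TIFF.
* Degenerate inputs: non-positive sigmas, K < 1, intensities outside
  [0, 1], stimuli exceeding their canvas, odd vernier flanker counts and
  overlapping vernier flankers all raise `ValueError` rather than being
  silently repaired.
* Problem sizes: experiment sweeps run at the native pixels-per-degree of
  each condition (images from ~52 px to ~380 px square; the largest
  kernel, for the distant-viewing condition, is 437 px and uses the FFT
  path).  A full five-condition reproduction takes well under a minute on
  one core.

## Known limitations

* Only Gaussian centre-surround profiles are implemented.
* Crowding effects that the contrast account does not claim to explain —
  notably jittered-flanker configurations — are out of scope, as are
  colour, temporal dynamics, and comparisons against raw human trial
  data (none is shipped; the behavioural side of each condition enters
  only through E_α).
* Model-mode sigma derivation is approximate (single magnification
  constant, no nasal/temporal asymmetry) and is not used by the shipped
  reproductions.
* The absolute contrast-energy scale of a render is meaningful only
  relative to its own canvas and calibration; cross-condition comparisons
  should use contrast ratios, as the runner does.
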