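# Methods

`fibrediff` implements the time-resolved small-angle X-ray fibre-diffraction
analysis used to quantify thick-filament activation and actin-attached
myosin motors in intact, electrically stimulated muscle, together with a
forward simulator that renders synthetic detector frames so every stage of
the analysis can be validated against known ground truth.

## Coordinate conventions

Reciprocal spacings are q = 1/d in nm⁻¹ (not 2π/d), so the third-order
myosin meridional reflection (M3, d ≈ 14.44 nm) sits near 0.069 nm⁻¹.  The
pixel→q mapping is linear (`q = offset × reciprocal_scale`), adequate at the
camera lengths (3–31 m) this analysis emulates; Ewald-sphere curvature is
ignored.  Detector arrays are indexed `[axial, radial]` with axis 0 parallel
to the fibre (meridian).  Pixel coordinates are 0-based with pixel centres
at integer coordinates; the beam centre is fractional.

## The analysis chain

1. **Centring and tilt** (`reduction.find_centre_and_tilt`).  The ±1,0
   equatorial reflections are located with sub-pixel Gaussian fits to the
   marginal sums of background-subtracted windows; the beam centre is their
   midpoint and the tilt the angle of the line through them.  Two
   locate→rotate passes are run; rotation is bilinear, about the beam
   centre, with masked pixels propagated.  If one 1,0 spot is masked by a
   tile gap, the ±1,1 pair is used instead.
2. **Mirroring** (`reduction.mirror`).  Before mirroring, the frame is
   translated by a sub-pixel shift so the beam centre lies on an integer
   pixel; quadrant reflection is then an exact index involution, which makes
   `mirror(mirror(f))` identical to `mirror(f)`.  Masked pixels are excluded
   with weights renormalized; `quadrant-select` averages an explicit subset
   of reflections to step around tile gaps.
3. **Integration** (`reduction.integrate`).  Named bands reproduce the
   standard limits (meridional half-width 0.0038 nm⁻¹, equatorial
   0.0036 nm⁻¹, layer-line radial band 0.037–0.064 nm⁻¹, and so on; see
   `profiles.DEFAULT_ROIS`).  Masked pixels are excluded with the per-bin
   weight renormalized to the full band width, and Poisson variance is
   propagated.
4. **Baseline** (`reduction.arc_hull_baseline`).  The diffuse background
   under a 1D profile is removed with a lower-convex-hull ("arc hull")
   baseline of the boxcar-smoothed profile (smoothing 2 ≡ a 5-point boxcar;
   depth pushes the hull below the data by a multiple of the local noise
   scale).  The hull guarantees baseline ≤ smoothed profile; negative
   residuals are kept so band integrals stay unbiased.  The exact behaviour
   of the proprietary tool this emulates is unpublished; the hull definition
   was chosen because it is deterministic and has the documented properties.
5. **Peak fitting** (`peakfit`).  Intensities are Gaussian **areas**
   (amplitude × σ × √2π), not heights, so the sum rule
   total = Σ areas × radial width is exact.
   * Equator: three Gaussians with centres constrained to 1/d10, √3/d10,
     2/d10 (one free spacing), free widths and amplitudes, fitted over
     0.02–0.065 nm⁻¹.  The weak ~0.04 nm⁻¹ Z-disc reflection of fast muscle
     is not modelled (it is very weak in slow muscle).
   * M3/M6 clusters: LA/MA/HA interference sub-peaks share one width; the
     M3L (~15.52 nm) and M6L (~7.62 nm) satellites are separate; four extra
     equal-width peaks at 0.062–0.067 nm⁻¹ are fitted but excluded from the
     M3 total and spacing.  Centres are seeded at the nominal spacings,
     shifted as a comb to the observed cluster maximum, and bounded with a
     0.0004 nm⁻¹ minimum separation.  LA/MA/HA labels are assigned by
     descending spacing after the fit.  The reported spacing is the
     area-weighted mean of the sub-peak spacings; the total intensity is the
     sub-peak area sum times the cross-meridional width.
   * Cross-meridional width: a concentric double Gaussian plus offset on the
     signed radial profile of the reflection's axial band; the narrower σ is
     returned.  The SSR landscape of this decomposition is multi-modal, so
     the fit scans a width grid (the model is linear in the amplitudes and
     offset for fixed widths) before polishing — see "numerical choices".
   * AL6: a two-stage global deconvolution.  Three Gaussians (M7, AL6, M8)
     are fitted to the series-mean profile with bounded centres; spacings
     and widths are then frozen and per-frame amplitudes solved by
     non-negative linear least squares.  A narrow-window mode integrates
     0.166–0.170 nm⁻¹ only, for geometries where part of the region is off
     the detector.
6. **Calibration** (`calibration`).  The nm⁻¹-per-pixel scale comes from a
   linear regression of grating peak positions (etched 100 nm grating,
   orders up to 11) against order index; the intercept is a centring
   diagnostic.  Sarcomere length uses the Bragg relation SL = n/qₙ with a
   single-Gaussian fit to the 14th-order reflection (5–7 µm⁻¹) or the first
   order (0.25–0.57 µm⁻¹), and flags low confidence when residual structure
   near the fitted peak suggests multiple sarcomere populations.
7. **Time courses** (`timecourse`).  Intensity series are divided frame-wise
   by the relative diffuse background under the first layer line (the
   mass-in-beam correction; skipped, with provenance, when the maximum
   change is below 1%), then normalized to the mean of all pre-stimulus
   frames.  Spacings and d10 stay absolute, as do intensity *ratios* such as
   I₁,₁/I₁,₀ (a ratio is dimensionless; the correction cancels).  Amplitude
   series are A = √I, an interpretation of the square-of-diffractors rule
   that reproduces the published intensity/amplitude pairs (0.52 → 0.72).
   Period summaries average 3–4 frames per period (rest, peak force,
   isometric relaxation, mechanically relaxed; "mechanically relaxed" is
   defined here as the first frames with force below 5% of peak, a threshold
   the source does not state numerically).
8. **Kinetics** (`kinetics`).  "Sigmoidal" fits are logistics with a
   baseline offset, y = y₀ + a/(1 + exp(−(t − t½)/τ)); the functional form
   is not specified by the source and the logistic was chosen as the
   simplest symmetric two-parameter shape (no alternative forms are
   implemented).  Biphasic signals (I_M3, A_M3, S_M3 tetanus activation) use
   a sum of two logistics with opposite-sign amplitudes, initialised with
   the fast branch at the extremum opposite to the net change and ≥20 ms
   branch separation; if one amplitude collapses the fit falls back to a
   single logistic with a notice.  Conventions: activation t½ relative to
   the first stimulus (fit window −26 to 234 ms tetanus, −17.75 to 52.25 ms
   twitch); tetanus relaxation t½ relative to the last stimulus (fit 234–604
   ms); twitch relaxation relative to 52.25 ms.  Slow K_REL is the 244–324
   ms linear slope normalized by the 244 ms-minus-rest amplitude; fast K_REL
   is an exponential fit over 344–604 ms.
9. **Mechanics** (`mechanics`).  Lattice volume V = (2/√3)·d10²·SL and area
   per thick filament (2/√3)·d10²; 1 kPa × 1 nm² = 10⁻³ pN.  The per-motor
   chain divides muscle stress by the myofibrillar fraction (0.8), the
   filament area (1667 nm², which back-computes to d10 ≈ 38.0 nm — the
   operation takes d10 or the area explicitly because no single printed d10
   reproduces it), and the attached motor count (attached fraction × 294
   motors per half filament), then derives stiffness (strain 4.5 nm), work
   (stroke 6 nm) and efficiency (ATP free energy 100 pN·nm; all
   configurable).  `released_fraction(I) = 1 − √I` converts retained
   OFF-state intensity to the fraction of motors released, because
   diffracted intensity scales with the square of the number of coherently
   ordered diffractors.

## The synthetic world

`simulate.tetanus_config()` encodes a fixed-end tetanus of slow muscle:
64 frames of 8 ms integration + 2 ms latency (frame times are window
centres, −26 + 10·i ms, which reproduces every kinetics window boundary),
stimuli at 80 Hz for ~237 ms, peak force 110 kPa with t½ 72.3 ms, sarcomere
shortening 2.43 → 2.15 µm (t½ 29.1 ms), d10 39.10 → 39.70 nm, S_M3
14.442 nm at rest rising ~0.8% with a fast early dip, S_M6 7.230 → 7.292 nm
(t½ 44.2 ms), I₁,₁/I₁,₀ 0.58 → ~1.3, and intensity changes of the
meridional, layer-line and off-axis reflections matching the reported
rest→peak ratios.  Relaxation is a linear decline (1.7 s⁻¹ for force) from
244 to 344 ms followed by an exponential (23 s⁻¹).  A twitch configuration
(70 × 5 ms frames, peak ~19 kPa) is also provided.  The mass-in-beam factor
ramps to 1.10 at the peak and multiplies *all* counts, reflections and
diffuse scatter alike, so the correction the analysis applies has the effect
it is designed to have.

Rendering places each reflection as a separable 2D Gaussian at
(±q_r, ±q_z) — four-quadrant symmetric before the detector tilt — on a
diffuse background modelled as a double exponential in |q| with a single
axial anisotropy factor (the real diffuse scatter is unspecified; this is a
simulator choice, smooth and peak-free so the hull baseline can remove it).
Tile gaps are zeroed and counts are Poisson-drawn from per-frame substreams
of one master seed, making frames bit-reproducible.  Sampled layer-line
amplitudes are set empirically so that at rest I₁,₁,₁ > I₁,₀,₁,
I₁,₁,₂ > I₁,₀,₂ and I₁,₀,₃ > I₁,₁,₃; no helical-transform physics is
attempted, and sarcomere reflections are rendered as even orders 14–24
(8.26 m geometry) or orders 1–9 (31 m geometry).

Choices made where the emulated experiment left the value open, fixed once:

* S_M3 early-dip depth 0.10% of rest (~0.014 nm).  A first draft used
  0.05%, which makes the fast branch of the double-sigmoid unidentifiable
  even on noise-free data — inconsistent with the reported success of that
  fit — so the dip was set to the smallest depth compatible with the
  reported fast-branch uncertainty.
* Detector scale 2×10⁻⁴ nm⁻¹/px for the small-angle camera, count levels
  giving ~10³–10⁴ counts at the main peaks (SNR comparable to published
  profiles), beam-centre offset (1.7, −2.3) px and tilt 0.4° as the default
  mis-alignment exercise.
* Cross-meridional widths 0.004 nm⁻¹ (narrow) and 0.02 nm⁻¹ (broad
  misalignment component), constant in time.

**What a green test does and does not establish.**  The generator shares
the analysis' model family (Gaussian peaks, smooth background, Poisson
noise), so end-to-end recovery demonstrates the pipeline's correctness and
numerical stability, not robustness to real-detector pathologies (point
spread, zingers, polarization, non-Gaussian tails) or to helical-transform
fine structure, none of which are simulated.  Two measured series are
*biased* relative to their naive ground truth by construction: the first
myosin layer-line band intensity (I_ML1) and the combined 1,1,1+2,0,1 band
include contributions from the overlapping actin layer line that grow
during contraction, exactly the contamination the radial/axial window
choices of the original analysis are designed to minimise.  The recovery
acceptance therefore asserts the clean observables (d10, SL, S_M3, S_M6,
I_M3, I_M6, I_AL6, I₁,₁/I₁,₀) at their stated tolerances and treats the
mixed-layer-line bands as qualitative.

## Numerical choices

* All fits are bounded least squares (`scipy.optimize.least_squares` /
  `curve_fit` with bounds); no fitting framework dependency.
* The cross-meridional double Gaussian is ill-posed when the broad
  component is shallow inside the fitted window: a spurious ultra-narrow
  minimum exists.  The fit therefore (a) floors both widths at ~2.5 pixels
  (instrument resolution), (b) scans a geometric width grid solving the
  linear amplitude/offset subproblem exactly, and (c) polishes the best
  basin.  The pipeline additionally excises the radial bands holding the
  sampled layer-line spots of the same axial window before fitting.
* Interference-cluster centres are bounded within ±0.0009 nm⁻¹ of the
  comb-shifted seeds with a 0.0004 nm⁻¹ minimum separation penalty; if the
  LA amplitude pins at zero the cluster is refitted without it.
* Degenerate double-Gaussian widths (within 5%) return the mean with a
  warning; a vanishing second amplitude returns the dominant width with a
  warning.
* Hull baselines are computed with an O(n) monotone-chain lower hull.
* The 1:2:1 smoothing uses renormalized truncated kernels at the ends.

## Known limitations

* No flat-field, polarization, dezingering or detector point-spread
  corrections (out of scope); camera background subtraction is a plain
  frame difference.
* The equatorial fit assumes a resolved 1,0; severely disordered lattices
  (very broad, merged equatorials) will fail centring rather than degrade
  silently.
* Sarcomere-length determination refuses (rather than guesses) when
  multiple sarcomere populations appear, as during exponential relaxation.
* Absolute wavelength calibration and multi-position camera-length
  extrapolation are represented only as metadata.
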