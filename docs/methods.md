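# Methods

`memdyn` quantifies three aspects of plasma-membrane (PM) dynamics from
fluorescence microscopy: lateral mobility of membrane proteins by
single-particle tracking (SPT), endocytic uptake from dye-labeled puncta,
and lipid order from the spectral behavior of an environment-sensitive
membrane dye.  Because raw micrographs of this kind are rarely shareable,
the package ships a synthetic-data generator with exact ground truth, and
every analysis stage is validated against that truth.

## Motion model and diffusion estimation

Particles follow free 2D Brownian motion: per frame, each coordinate takes
an independent Gaussian step of standard deviation σ, so the diffusion
coefficient is D = σ²/(2Δt) per axis, and the 2D mean squared displacement
is MSD(τ) = 4Dτ.  No confinement, drift, or anomalous exponent is modeled;
the analysis treats D and motion range purely empirically.

The estimation chain is standard SPT practice:

1. **Detection.** Scale-normalized Laplacian-of-Gaussian filtering at the
   PSF scale; local maxima above `snr_threshold` (default 5) times the
   robust (MAD-based) response noise; sub-pixel refinement by least-squares
   2D Gaussian fit in a 7×7 window; candidates within one PSF σ merged,
   keeping the brighter.  Detection can be restricted to a labeled region,
   in which case the noise estimate comes from that region only.
2. **Linking.** Per-frame-pair Hungarian assignment minimizing total
   squared displacement, gated at `max_step_um × elapsed frames`
   (default 0.3 μm), with gaps up to `max_gap` frames (default 1) closed and
   tracks shorter than `min_length` frames (default 5) discarded.  Ties
   resolve toward the lower track id; tracking uses no randomness.
3. **MSD and D.** Time-averaged MSD over all ordered pairs at each lag; an
   unweighted least-squares line through the first 4 lags with a free
   intercept gives D = slope/4.  The free intercept absorbs static
   localization noise, which offsets the whole MSD curve by 4σ_loc²;
   with 20 nm localization noise this offset (1.6×10⁻³ μm²) exceeds the
   per-lag Brownian increment for the slow populations studied here, so an
   intercept-free fit would be badly biased.  Negative slopes are clipped
   to D = 0, flagged, counted, and excluded from population histograms.
4. **Motion range.** The trajectory diameter — the maximum pairwise
   distance between positions.  Net displacement and radius of gyration are
   plausible alternatives for this (field-ambiguous) quantity; the diameter
   is scale-free, matches the magnitudes reported for membrane-bound
   clathrin (~0.18–0.47 μm), and equals an exhaustive pairwise-max oracle
   on every trajectory (property-tested).  For long tracks the search runs
   on the convex hull; degenerate geometries fall back to the full scan.

## Histogram peaks (Ĝ) and bimodality

Population distributions of per-track D (or motion range, or per-pixel GP)
are summarized by the peak Ĝ of a Gaussian fitted to their histogram.
Binning is Freedman–Diaconis by default; diffusion coefficients are binned
on log₁₀ D, because two populations whose D differ ~6-fold are inseparable
on a linear grid, and fitted peaks are reported back on the linear scale.
One- and two-component Gaussian curves are fit to the binned density by
multi-start nonlinear least squares (5 deterministic starts).  The
two-component model is selected only when

* it improves the BIC (computed from the residual sum of squares over the
  histogram bins) by more than 10, **and**
* the two components are genuinely resolvable: Ashman's
  D = |μ₁ − μ₂| / √((σ₁² + σ₂²)/2) exceeds 2 and the minor component
  carries ≥ 10% of the mixture weight.

The resolvability requirement exists because ΔBIC alone lets the
two-component model "win" by splitting a single skewed or noisy peak into
two overlapping (or extremely unbalanced) Gaussians; Ashman's D rejects
such splits while a true 70/30 mixture with 6-fold separated D (log₁₀
separation ≈ 0.8, D ≈ 4.6) passes comfortably.  With the gate, the
false-bimodality rate on unimodal data is below 5% over 100 seeds.

## Endocytosis quantification

Given a labeled mask (PM band / interior / background), internalized
puncta are detected with the same LoG+Gaussian detector restricted to the
interior label (outside pixels are replaced by the interior median first so
the bright PM ridge cannot leak responses inward).  Per cell we report:

* `n_puncta` — the count;
* `mean_internal_intensity` — mean of the original image over disk
  footprints of radius 2·PSF σ around each punctum center;
* `relative_internal_intensity` — that mean divided by the mean over all
  PM ∪ interior pixels.  This normalization is one reasonable reading of
  "relative intracellular intensity"; it is dimensionless, invariant to
  global intensity rescaling, and typically in (0, 1) when the PM is the
  brightest structure — but it is *not* hard-bounded above by 1 (bright
  puncta over a dim PM exceed it), so it is reported unclipped;
* `pm_mean_intensity` — mean over the PM label; group-level PM intensity is
  expressed as percent of a control group by pooling PM pixels per group.

Group comparisons use the two-sample equal-variance Student's t-test with
the conventional flags (* p < 0.05, ** p < 0.01) and sample SD (ddof = 1).
Percent change is computed on group means and is invariant to common
rescaling.  A heuristic PM segmentation (smoothed-intensity ridge) is
provided for raw micrographs; synthetic data always carry exact masks.

## Membrane order: spectra, RGM, GP

A λ-stack samples each pixel's emission spectrum on 23 bands at 495 + 9k nm
(k = 0…22).  The nominal acquisition range "495–691 nm at 9 nm steps" is
not an integer number of steps; the grid above (ending at 693 nm, last band
conventionally labeled 691) is used throughout.

* **Spectral profiles.**  Per region, 20 rectangular ROIs (3×3 px by
  default, seeded RNG) lying entirely inside the region label are averaged
  per band; the profile is normalized to its maximum and the peak
  wavelength interpolated by a parabola through the three bands around the
  discrete maximum.  A blue-shift of the peak with increasing ordered
  fraction is a monotonicity invariant (property-tested on a grid of
  mixing fractions).
* **RGM.**  The red-to-green ratio RGM = I₆₆₀/I₅₅₀, implemented as the
  ratio of region means of the window-integrated images: green 500–580 nm,
  red 620–750 nm, with bands overlapping a window boundary contributing
  pro-rata by overlap fraction.  (The conventional subscripts 660/550 name
  the windows, not single bands.)  Lower RGM = more ordered membrane.
* **GP.**  Per pixel, GP = (I_ord − G·I_dis)/(I_ord + G·I_dis); pixels with
  denominator at or below a configurable floor (default 0) are masked.
  The instrument G-factor defaults to 1; `calibrate_g_factor` solves
  G = (I_ord/I_dis)·(1 − GP_ref)/(1 + GP_ref) from a reference sample of
  known GP when calibration data exist.  Region-wise characteristic GP
  values come from a single-Gaussian fit to the pixel-GP histogram
  (data-driven binning for the fit; a fixed 64-bin histogram over [−1, 1]
  is exported for display).  GP is antisymmetric under channel swap at
  G = 1 and strictly increasing in the channel ratio — both are property
  invariants.

## Synthetic data: what it emulates, and what it does not

* **TIRF movies** place diffraction-limited spots (isotropic Gaussian PSF,
  σ = 0.125 μm ≈ the diffraction limit for GFP at NA 1.45) at Brownian
  ground-truth positions on a constant background, with Poisson shot noise
  and optional Gaussian read noise.  Acquisition defaults (0.1 μm pixels,
  50 ms frames) are typical variable-angle TIRF settings and are config,
  not constants.  Initial positions keep a minimum separation (default
  1 μm) so the single-particle analysis is well posed, and an optional
  Gaussian `localization_jitter_um` on rendered spot positions emulates a
  stated localization-noise level directly.  Trajectories are truncated at
  field exit.  Not modeled: photobleaching, blinking, 3D PSFs,
  evanescent-depth effects, motion blur within a frame.
* **Cell images** are disk cells with an annular PM band, flat interior
  and background levels, and planted puncta (strictly inside the interior,
  ≥ 2 punctum σ from the PM, ≥ 6 PSF σ apart by default, rejection-sampled
  with a 10⁴-attempt budget).  Real cells are neither circular nor flat;
  these images test the measurement chain, not segmentation.
* **λ-stacks** give each region a spectrum that is a convex mixture
  f·ordered + (1−f)·disordered of two unimodal basis spectra (defaults:
  Gaussians peaking at 560 and 630 nm), the ordered fraction set per
  region (defaults PM 0.8, endosomes 0.4, cytoplasm 0.3).  Real dye spectra
  are asymmetric and concentration-dependent; the two-basis model captures
  only the order-dependent peak shift the ratiometric analysis relies on.

Passing tests therefore demonstrate the correctness of the estimators and
formulas under the stated noise models — not robustness to segmentation
errors, optical aberrations, or dye photophysics in real tissue.

## Numerical choices and degenerate inputs

* Detection on a constant or blank image returns an empty spot list (not an
  error); a constant histogram (all values identical) is an error.
* Spot refinement uses unbounded Levenberg–Marquardt with post-hoc
  rejection of fits that leave the window or whose width departs the PSF
  scale by more than 5× (or below 0.2×).
* Population fractions must sum to 1 within 1e-9; per-axis step σ may be 0
  (stationary particles) but the RMS 2D step must not exceed half the
  field.
* Quadratic spectral-peak interpolation falls back to the discrete band
  center when the maximum sits on an edge band or the parabola degenerates,
  and the result is clamped to the band range.
* Per-stage RNG streams are derived from the master seed and the stage
  name, so identical config + seed reproduces every output bit for bit and
  adding a stage never perturbs the others.

## Problem sizes used in the shipped checks

The self-checks simulate 300 single-population tracks (50 frames each,
detection over a 300×300 px field) and 600 two-population tracks
(420×420 px) for the diffusion analyses, 10 cells per condition for the
puncta analyses, and 200×200 px regions for the GP histograms.  These sizes
give stochastic errors comfortably inside each check's tolerance while
keeping a full run on a single CPU in the low minutes.

## Known limitations

* Motion-range and relative-intensity definitions are explicit
  interpretations of ambiguous field usage (diameter; internal/whole-cell
  ratio); both are configurable at the call sites that consume them.
* The D estimator's accuracy degrades when 4σ_loc² ≫ 4DΔt; at 20 nm
  localization noise, populations below ~5×10⁻⁴ μm²/s are not reliably
  recoverable from 50-frame tracks (this is a physics limit of MSD-line
  fitting, not an implementation artifact).
* The heuristic PM segmentation is a convenience, not a validated
  segmenter; quantitative results assume trusted masks.
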