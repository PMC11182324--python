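# Methods

This note records the models, conventions, and numerical choices behind
`iorg`, and what the synthetic validation does and does not establish.

## Signal model and extraction pipeline

An acquisition is a registered T×H×W stack (default 6 s at 29.4 Hz,
T = 176) with per-frame validity flags and a stimulus frame — the first
frame whose timestamp k/29.4 s reaches the nominal 2.0 s delivery time
(frame 59). Extraction proceeds:

1. **Acquisition gating.** Registered acquisitions retaining fewer than
   half their original frames are dropped (exactly half is retained).
2. **Standardization.** Image-containing pixels of each frame are
   z-scored and rescaled to mean 70 / SD 35, suppressing image-wide
   intensity fluctuations while staying in image units. "Image-
   containing" defaults to pixels > 0 (registration fills empty canvas
   with zeros); an explicit mask can be supplied. Zero-variance frames
   are flagged invalid rather than divided by zero.
3. **Distortion mitigation.** Per horizontal strip of a reference
   frame, the median (over frames) of the strip's best translation is
   estimated by phase correlation and its inverse applied to that strip
   in all frames; the median makes the estimate robust to a minority of
   badly aligned frames.
4. **Full-frame affine registration.** Each frame is mapped by the
   affine transform maximizing its correlation with the reference over
   the *valid overlap* (canvas filled by the warp is excluded from the
   metric — with it included, border zeros dominate the covariance and
   the optimum is badly biased). The search is a Nelder–Mead direct
   search over six parameters with the linear part acting about the
   image center (decoupling rotation from translation, which otherwise
   conditions the problem poorly), initialized by phase-correlation
   translation. Frames whose registered correlation stays below 0.2 are
   flagged invalid with a warning.
5. **Coordinate refinement.** Greedy 8-connected hill climbing on the
   acquisition average image, ties broken in row-major order, at most
   10 steps and a configurable displacement cap — deterministic by
   construction. Coordinates on plateaus stay put.
6. **Column extraction.** The column radius is half of
   (median nearest-neighbor spacing × fwhm_fraction), fwhm_fraction
   default 0.6, floored at 1 px. A cone's signal at frame t is the mean
   intensity over pixels whose centers lie within the radius of the
   (possibly fractional) cone center — the same disc every frame, i.e.
   a cylinder; partial pixels are excluded.
7. **Exclusion rules.** A cone is excluded if >50% of frames within
   0.2 s of stimulus delivery are missing, if ≥50% of the acquisition's
   frames are missing, or if it is present in <50% of the location's
   acquisitions. The boundary semantics are deliberately asymmetric
   (>, ≥, <) and the three predicates are independent, so application
   order cannot matter. The 0.2-s window is one-sided
   ([stim, stim + ⌈0.2·rate⌉] inclusive); a centered window is a
   plausible alternative and is worth a sensitivity check on real data.
8. **Mean subtraction.** Each cone's mean over non-missing frames
   strictly before the stimulus frame is subtracted from its whole
   signal. Cones with no valid pre-stimulus frame are dropped and
   logged. (Amplitude extraction separately uses a 1-s pre-stimulus
   window; the subtraction uses all pre-stimulus frames.)

## RMS summaries and amplitudes

Population-RMS and individual-RMS are the frame-wise root mean squares
over cones and over acquisitions respectively, skipping missing terms
and recording the count that contributed at each frame. The amplitude
of a trace is the 99th percentile of the RMS in the 1-s window after
delivery ((t_stim, t_stim+1]) minus the mean in the 1-s window before
([t_stim−1, t_stim)); percentiles interpolate linearly between order
statistics, and missing frames are dropped from both windows rather
than imputed. Individual amplitudes are log-transformed base 10 (their
SD is proportional to their mean); non-positive amplitudes cannot be
log-transformed and are flagged and excluded from CDFs. The healthy
fraction of a sample is the proportion of log amplitudes at or above
the 5th percentile of a normative control distribution — the threshold
percentile reflecting the ~5% S-cone share that the 554 nm stimulus
barely excites, so a fully healthy mosaic scores ≈0.95 against its own
normative sample by construction.

Noise floors behave as expected of an RMS statistic: noise-only signals
yield strictly positive amplitudes whose mean decreases as acquisitions
accumulate, so amplitudes must be compared at matched acquisition
counts.

## Synthetic acquisitions

The generator emulates the study geometry: a 1×1° field (291 px at the
default 291 µm/° magnification, 1 px/µm), hexagonal cone packing with
per-axis Gaussian jitter, 6-s acquisitions at 29.4 Hz, stimulus 2 s in,
trials of 10 acquisitions, one no-stimulus control trial plus three
stimulus trials per location, ~5% non-responding cells, frame dropout,
and optional small per-frame translations recorded in the manifest.
Tests and the acceptance script run reduced fields (0.08–0.3°, ~60–370
cones) and sometimes fewer acquisitions; these sizes are stated per
experiment and keep full runs to minutes on one core.

Choices worth noting:

- **Cone profile.** Isotropic Gaussian, FWHM = 0.6 × lattice spacing —
  cones image as near-Gaussian waveguide profiles, and this width keeps
  neighboring columns separable. The extraction default fwhm_fraction
  matches it.
- **Response process.** A responding cone's column-mean reflectance
  deviates from baseline by exactly ± its true amplitude (independent
  random signs per frame/acquisition) during the 1-s response window.
  Any zero-mean process with controlled RMS would serve the analysis;
  the fixed-magnitude form makes extracted amplitude equal programmed
  amplitude deterministically, so recovery can be validated to 1%
  rather than statistically. A Gaussian-amplitude process would make
  the frame RMS chi-distributed and the p99-based amplitude a biased,
  noisy functional of the programmed SD.
- **Crosstalk calibration.** Neighboring Gaussians overlap each other's
  extraction discs. Rendered peak amplitudes are obtained by solving
  M·peaks = programmed column means, where M[c, n] is the mean of cone
  n's (truncated) stamp over cone c's in-frame disc. This removes the
  few-percent p99 bias that uncorrected crosstalk injects, and makes a
  zero-amplitude cone's extracted signal exactly zero at zero noise.
- **Amplitude distribution.** log₁₀ amplitudes ~ N(1.25, 0.35); the
  mean puts the simulated control population-RMS amplitude near the
  mid-30s AU of control data at parafoveal eccentricities, and the SD
  gives individual-cone amplitudes the roughly decade-wide spread seen
  in control CDFs. Pixel noise SD 15 AU against a 100 AU baseline puts
  the individual-RMS noise floor near log₁₀ ≈ 0.4, well below the
  responder distribution. Cohort generation scales amplitudes and
  mosaic spacing with eccentricity following the bundled normative
  profiles.
- **Validation extraction path.** Recovery experiments extract with
  ground-truth coordinates and without per-frame standardization:
  synthetic stacks are already on one intensity scale, and both
  refinement (snap-to-pixel maxima) and standardization (per-frame
  gain) would inject percent-level distortions unrelated to the
  arithmetic under test. Both stages stay on by default in the
  end-to-end pipeline.
- **Stimulus duration.** 68 ms in the acquisition timeline, 66 ms in
  the photometry default — both appear in the source protocol and both
  are configurable; they are kept as separate fields.

What passing synthetic tests shows: the signal path (projection,
exclusion, mean subtraction, RMS, percentile amplitude, log/CDF,
healthy fraction) is arithmetically correct, deterministic under seeds,
and recovers programmed effects of realistic size. What it does not
show: robustness to real AOSLO phenomena absent from the generator —
intra-frame sinusoidal scan distortion, torsion, reflectance
multistability ("twinkling"), rods, vasculature shadows, registration
residuals beyond small translations, or spatially correlated noise.

## Mosaic metrics

Per-cone NND is the Euclidean distance to the nearest other cone after
scaling pixels to µm with a single isotropic factor. "Bound" cones are
those whose Voronoi cell is finite and lies entirely inside the ROI
(default: the coordinate bounding box); only bound cones enter the
mean, removing edge bias. On an unjittered hexagonal lattice the mean
bound NND equals the spacing to ~1e-9 (floating-point row geometry).
Z-scores are (value − normative mean)/SD with both signed and absolute
forms — summary tables conventionally print magnitudes, so both are
emitted.

## Outer-segment length

The two most prominent local maxima of the (optionally Gaussian-
smoothed, SD 1 sample) reflectance profile inside the search window are
taken as the EZ and IZ peaks; prominence must exceed 10% of the
profile's range, which rejects noise ripples at SNR ≥ ~5. Each peak is
refined by a three-point parabola, giving sub-sample precision; the
detection is invariant to reflectance gain and offset, and profiles may
arrive in either depth orientation. Recovered lengths outside
12.8–38.4 µm (the plausible control span across 1–8°) raise a QC flag,
not an error. At 0.5 µm sampling and 10% peak-height noise, recovery
RMSE is ≈0.7 µm over 100 seeds.

## Photometry

Photons/µm² per flash = P·λ/(hc) · T_lens · T_macula · duration /
(RMF² · (AL/24)²), with P the corneal power density per deg² (17.6
µW/deg² default), λ = 554 nm, duration 66 ms, RMF = 291 µm/°. Two
ambiguities are resolved explicitly:

- The per-deg² power is *not* divided again by the 1.13 deg² stimulus
  area; that division applies only when total corneal power is supplied
  (`power_is_total=True`). The default convention reproduces both the
  hand-derived unit-transmission value (3.823×10⁷ photons/µm²) and,
  with typical adult lens/macular transmissions (~0.78/0.80), values
  inside the observed cohort span (1.86–2.77×10⁷).
- Axial length enters by dividing by (AL/24)²: a longer eye spreads
  the stimulus over a larger retinal area, lowering density — this
  ordering matches the cohort (longest eye, lowest density). The
  literal linear multiply is available as `axial_convention="linear"`.

Age-dependent transmission tables are pluggable inputs; the package
ships no spectral integration (the source spectrum is treated as
monochromatic at 554 nm).

## Cohort statistics

Sample SDs use the n−1 denominator throughout (this reproduces the
printed demographic SDs). Structure-function bands are *prediction*
intervals for a new observation, not confidence bands for the mean —
individual locations are judged against them; confidence bands are
also available. Spearman p-values adapt to sample size: full
permutation enumeration for n ≤ 8, seeded Monte-Carlo permutation
(9999 resamples) for n ≤ 20, and the t-approximation beyond — exact
enumeration at n = 20 would need ~2.4×10¹⁸ permutations, so the
Monte-Carlo tier replaces it. Sensitivity pairing is nearest-
eccentricity with ties resolved toward the fovea; regressions pool
locations rather than averaging within subject first.

## Known limitations

- The full-frame affine registration is a simplified stand-in for
  strip-based normalized-cross-correlation registration; it corrects
  drift and torsion-scale rotation, not intra-frame shear.
- Jitter shrinks the generated mosaic's mean NND below the nominal
  spacing (the nearest of ~6 displaced neighbors is biased short;
  ≈4.13 µm at spacing 5 µm, per-axis jitter 0.5 µm), so jittered
  spacing should be validated through `bound_nnd`, not assumed.
- The healthy-fraction threshold is an empirical quantile; with
  exactly 5% programmed non-responders its position between the
  non-responder cluster and the responder tail fluctuates seed to
  seed, which is why arm comparisons in validation are run paired
  (same cohort, amplitudes scaled).
- `correct_intraframe_distortion` estimates strip translations by
  phase correlation at 0.1 px resolution; sub-strip distortion is out
  of scope.
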