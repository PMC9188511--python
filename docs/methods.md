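# Methods

`starstack` is a desk-scale simulation and reconstruction toolbox for 3D
real-time stack-of-stars MRI of swallowing.  It covers the full chain:
trajectory design, point-spread-function (PSF) incoherence analysis, a
dynamic digital phantom with exhaustive ground truth, multi-coil k-space
simulation with hardware imperfections, compressed-sensing (CS)
reconstruction with a sliding window, and quantitative swallowing metrics.
This note documents the models, the defaults and why, the numerical
choices, and the limits of what the synthetic experiments demonstrate.

## Sampling geometry and conventions

Image arrays are ordered `(t, z, y, x)`, with the in-plane centre voxel at
index `n // 2` (0-based).  k-space coordinates are in cycles/FOV, so the
Cartesian grid of an `n`-voxel image maps to integer coordinates in
`[-n/2, n/2)`.  The forward model is the unnormalised DFT
`s(k) = Σ_u f(u) exp(-2πi k·(u-u0)/n)`.  Spokes are full diameters with a
2x-oversampled readout (`n_readout = 2 × matrix` by default), spacing
`matrix/n_readout` cycles/FOV, and exactly one sample at in-plane k = 0.
kz partitions are Cartesian integers spanning the (slice-oversampled)
slab; azimuths are stored modulo 360° so opposed spokes remain distinct
events (gradient-delay estimation needs them).  Default sequence timing
follows the swallowing protocol: TR 3.0 ms, TE 1.26 ms (metadata only),
flip angle 10° (metadata only), matrix 128, voxels 2 x 2 x 6 mm, slice
oversampling 1.28 (7 slices → 9 kz encodings, 21 → 27).  No relaxation or
contrast physics is simulated: the object is a proton-density-like complex
image.

### Angle sequences

The tiny golden angles are `ψ_N = 180° / (φ + N - 1)` with φ the golden
ratio; `ψ_1 ≈ 111.25°` is the classical golden angle and `ψ_9 ≈ 18.71°`.
Patterns:

* **ASOS** — aligned stack-of-stars: all kz encodings of star *s* share
  azimuth `s·ψ_1`; kz is the inner loop, linear ascending (the convention
  is configurable in principle; linear is the simplest and is what the
  tests pin down).
* **RSOS-ψ1 / RSOS-ψ9** — continuously rotated: the azimuth advances by ψ
  on *every* event, so the kz loop's increment is continued by the in-plane
  loop and any contiguous event window is a valid reconstruction window
  (sliding-window capable).  For RSOS-ψ9 the tiny-angle order defaults to
  the kz count (9 for 7 slices x 1.28).  For 21-slice comparisons the
  order is kept at 9: that is the pattern the protocol names, and order 27
  would cluster the six spokes of a frame into a ~15° fan per partition,
  destroying exactly the per-frame uniformity the tiny golden angle is
  chosen to provide.
* **RSOS-GR** — a simulation-only comparator for golden-ratio-rotated
  stacks: uniform azimuth spacing `180°/n_spokes` within each partition,
  partitions offset by `kz_index · ψ_1 / n_kz`.  The published scheme it
  stands in for depends on the spoke count and is incompatible with a
  sliding window; this convention is approximate and labelled as such.

The frame budget is 6 spokes per slice per frame, giving 6.2 fps at 7
slices and 2.1 fps at 21 (TR 3 ms), doubled to 12 fps by the sliding
window.  Full sampling is `round(π·n_readout/2)` spokes per slice (402 at
256 readout samples; 1.2 s per slice).

## NUFFT engine

The stack-of-stars transform factorises into a Cartesian FFT along kz and
a 2D NUFFT in-plane.  The 2D NUFFT is Kaiser-Bessel gridding on a
2x-oversampled grid with kernel width 8 and the Beatty shape parameter;
apodization is corrected with the kernel's analytic Fourier transform.
The interpolation is precomputed as a sparse matrix per kz partition, so
iterative reconstruction reuses it and `adjoint` is the exact conjugate
transpose of `forward` by construction.  Against a direct O(N·M) DFT
summation the transform is accurate to ~1e-7 relative (width 8); the test
suite pins 1e-6 on 32x32x3 instances.  Width and oversampling are
arguments, not magic numbers.

## PSF incoherence

The PSF of a trajectory (or of one frame of it) is the adjoint NUFFT of
unit samples with ramp density compensation (|k| with a DC weight of a
quarter sample spacing; compensation can be disabled).  Incoherence is the
central-peak magnitude divided by the standard deviation of side-lobe
*magnitudes*, side lobes being all voxels outside a 1-voxel-radius ball at
the centre; the scalar is computed on the full 3D volume.  A perfectly
clean PSF (side-lobe SD numerically zero relative to the peak) reports
infinite incoherence.

Two caveats the numbers made explicit.  First, incoherence magnitudes
depend on grid size and weighting, so only *orderings* across patterns are
meaningful, and the published figure's values are not reproduced — the
sweep at 6 spokes per slice robustly ranks all three rotated patterns
above the aligned one.  Second, "fully sampled ⇒ delta-like PSF" holds
only up to the diffraction rings of the disc-shaped k-space aperture
(first rings at a few percent of the peak regardless of spoke count); the
aliasing-free property is therefore tested as agreement with a densely
sampled reference PSF rather than as a raw peak-to-side-lobe ratio.

## Digital phantoms

**Static phantom** ("pineapple"): an ellipsoidal body with radial wedges,
rings and smoothed speckle (seeded), background exactly zero, and edges
softened by a 0.9-voxel Gaussian.  The softening matters: radial sampling
covers only the inscribed k-space disc, so a sharp-edged object has
unrecoverable corner-frequency energy and no reconstruction could meet a
2% closed-loop error target.  Texture contrast (SD/mean ≈ 0.37 inside the
body) makes SSIM degradation under blur measurable.

**Dynamic swallowing phantom**: a midsagittal-oriented slab (sagittal
slices, central slice midsagittal; y runs superior→inferior, x
anterior→posterior).  Tissue classes at fixed intensities — soft tissue
0.45, spine 0.30, hyoid marker 0.70, larynx 0.80, mandible marker 0.90,
bolus 1.0 (the "pineapple juice" is the brightest class).  One swallow is
driven by a raised-cosine envelope `g(t)` spanning the middle half of the
series, normalised so the sampled maximum is exactly 1 and exactly zero at
rest, hence:

* the larynx ellipsoid translates superiorly by exactly
  `laryngeal_elevation_mm · g(t)` (default 20 mm, the scale of published
  normal values);
* the mandible→hyoid distance scales by `1 + contraction/100 · g(t)`
  (default −25%);
* the bolus (default 20 mL) is the set of exactly
  `round(volume/voxel_volume)` voxels nearest (in mm) to a point moving
  along an oral → pharyngeal → oesophageal path, its progress the
  integral of `g`; rigid structures exclude their voxels from the bolus
  and are painted on top (cartilage displaces fluid).

All programmed amplitudes are recorded exactly in the ground truth
(tracks in mm, per-frame masks, stationarity flags), which is what makes
the metrics module testable by round trip.  Structure positions are FOV
fractions chosen so that at the 64-matrix desk scale (128 mm FOV) the
20 mL bolus ball never enters another structure's tracking window.

**Coil sensitivities**: broad Gaussian lobes on a ring around the FOV
with low-order random phase and a 0.15 floor (rSOS bounded away from
zero); `smoothness=inf` gives flat unit maps (identity-coil limit).  The
noise covariance is `A A^H/n + 0.5 I` with complex Gaussian `A` —
Hermitian positive definite with off-diagonal coupling.

## Forward simulation and hardware imperfections

Per event the object state is the nearest phantom frame in time (no
intra-spoke motion).  Noise is complex Gaussian with the coil covariance,
scaled by `noise_sd`.  A global gradient delay shifts every spoke's
samples along its own readout by a fractional sample count (FFT phase
ramp).

The eddy-current model is heuristic (the underlying physics is only
qualitatively known here) and off by default.  It has two first-order
terms, both growing with the azimuthal jump from the previous event:

1. a constant phase per event, `eddy_coupling · Δaz` — the literal
   "phase error proportional to the jump".  For the continuously rotated
   patterns the jump is constant, so this term is a *global* phase and
   provably cannot change any magnitude image; it is kept for complete-
   ness and for the mean-|phase| scaling test (ratio ψ1/ψ9 = 111.25/18.71);
2. a k-space trajectory offset along the *gradient-change* direction,
   `Δk_n = c · (ê_n − ê_{n−1})` (`c` in cycles/FOV per unit direction
   change, so `|Δk| = 2c·sin(Δaz/2)`), simulated by sampling the object at
   the offset coordinates while the reconstruction assumes the nominal
   ones.  A same-per-spoke shift along the readout was rejected for the
   same reason as the phase term: for constant increments it is a global
   gradient delay, self-consistent across the whole acquisition.  The
   perpendicular component of the gradient-change offset is mutually
   inconsistent between opposed spokes — the classic eddy artifact — and
   this is what degrades large-jump patterns.

A coupling sweep (0.3–1.0) shows the image-quality reversal (aligned
beating golden-angle-rotated at 7 slices, as reported in vivo) appears
once the golden jump's trajectory error reaches roughly one Nyquist cell;
the demonstrations use `c = 0.6`, comfortably inside that regime and
robust across seeds.  Without eddy terms the ordering follows incoherence:
at 21 slices the tiny-golden-angle pattern beats the aligned one.

## Reconstruction

Pipeline order: noise prewhitening (Cholesky; maps transformed
consistently), gradient-delay estimation from approximately opposed spoke
pairs (cross-spectrum phase slope between a spoke and its reversed
opposed partner measures twice the delay; adjacent-bin phase increments
avoid unwrapping; accurate to ±0.05 samples in closed loop), sensitivity
estimation (low-resolution gridded coil images over root-sum-of-squares,
Gaussian k-space taper at 15% of kmax, support-masked — a deliberately
simple, pluggable stand-in for autocalibrated estimators), then:

* **Reference**: conjugate-gradient SENSE on the ramp-density-weighted
  normal equations, tolerance 1e-6 relative residual, up to 60 iterations
  (the closed-loop tests run 100).  Weighted CG converges fast because the
  weighted normal operator is well conditioned near full sampling.
* **Real-time CS**: minimise
  `½ Σ_t ‖√w (A_t x_t − y_t)‖² + λ_LLR Σ ‖Casorati patch‖_* + λ_TV ‖∇_t x‖_1`
  with λ_LLR = 0.001 (locally-low-rank in plane) and λ_TV = 0.005
  (temporal total variation).  The λ values refer to unit-normalised data:
  the Lipschitz-preconditioned gridded image `A^H W y / L` is scaled to
  maximum 1 before iterating (absolute k-space scale is arbitrary in
  simulation, so the weights are tied to image units).  Solver: proximal
  gradient with FISTA momentum (restart on objective increase), step
  `1/(1.1 L)` with `L` from power iteration, and alternating proximal
  operators — singular-value soft-thresholding of 8x8 in-plane space-time
  Casorati matrices (random cycle shift per outer iteration, seeded) and
  an exact temporal-TV prox by warm-started projected dual (Chambolle)
  iterations, 12 inner steps.  Default 30 outer iterations, objective
  tolerance 1e-4; the objective is logged and non-monotonicity beyond the
  restart tolerance warns.  FISTA matters: plain proximal gradient needs
  several times more iterations at these undersampling factors (R ≈ 30
  in-plane per frame).
* **Sliding window**: two *independent* CS runs, the second with frame
  bins offset by half a frame of events; frames interleaved by
  acquisition midpoint time (2T−1 frames, no blending), doubling the
  displayed rate.
* **Flat field**: divide the magnitude volume by its Gaussian-blurred
  self plus `ε = 1e-3 ·` max blurred intensity; default width 32 mm,
  proportioned to the 256 mm in-vivo FOV ("wide" is otherwise
  unspecified), ~1 in homogeneous regions, no NaN/Inf on zero background.

## Evaluation

SSIM uses the scikit-image implementation (Gaussian 1.5σ window, K1 =
0.01, K2 = 0.03, sample covariance), computed on the central slice of
magnitude volumes with the reference maximum as data range; an explicit
sliding-window formula implementation in the test suite pins the numeric
path to 1e-9 with a uniform window.  The protocol mirrors the phantom
experiment: one fully sampled acquisition per pattern, CG-SENSE reference
from all spokes, CS from the same spokes binned at six per slice per
frame, SSIM of the central CS frame against the reference.  The published
SSIM magnitudes come from scanner data and are not desk-reproducible;
only orderings are asserted, under the conditions stated above.

## Swallowing metrics

Metrics operate on landmark tracks and bolus masks, not on images — in
the study they were produced by a human rater, and automating clinical
segmentation would be unvalidatable here.  Definitions: duration = moving
frames between the last pre-swallow stationary frame and the first return
to stationary, divided by the frame rate, first swallow only; bolus area
(cm²) on the middle prescribed slice and volume (cm³) over all slices at
the rest frame; laryngeal elevation = maximum displacement of the most
inferior thyroid point from its rest position; submental contraction =
percent change of the mandible–hyoid distance at its extremum (negative =
shortening).  Rest references use the median over pre-swallow stationary
frames, identical to the single-frame definition when the rest pose is
exactly static (as in the phantom) and robust to annotation jitter
otherwise.

For phantom *reconstructions* a template-matching annotator stands in for
the rater: normalised cross-correlation of saturated,
baseline-subtracted structure templates (the geometry a rater also
knows), searched sequentially within a per-frame continuity window, with
parabolic sub-voxel refinement and a 3-frame median filter; the bolus is
the largest connected component above the midpoint of the measured tissue
and bolus levels; motion states come from tracked-structure displacement
against the initial rest configuration plus bolus-centroid speed
(threshold 2.5 mm), despeckled morphologically.  Closed loop at matrix 64,
7 slices, 5 s, 6 coils, 1% noise: elevation recovered within ~0.7 mm,
contraction within ~2.5 points, bolus volume within ~9%.  Duration is
systematically short by 2–4 frames because the raised-cosine envelope's
onset and offset move structures by less than a voxel — genuinely
invisible motion, not an annotator defect.

## Problem sizes

The test and acceptance runs use scaled-down grids chosen to preserve the
regime, not the cost, of the full protocol: oracle equivalence at 32x32x3;
closed-loop static reconstruction at matrix 48 (96 readout, 5 slices);
incoherence at matrix 64 with the protocol's 256 readout points and 9 kz;
pattern SSIM comparisons at matrix 32 (7 and 21 slices); dynamic recovery
at matrix 64, 7 slices, 5 s.  Undersampling factors, spoke budgets per
frame, λ values, oversampling and slice counts match the protocol
throughout.

## Known limitations

* No Bloch/contrast simulation, no B0/off-resonance, no slab excitation
  profile; intensities are class constants.
* The eddy model is first-order and heuristic; the real distortion
  spectrum of a scanner is richer, so only the direction of pattern
  rankings, not their magnitudes, is meaningful.
* The sensitivity estimator is a low-resolution ratio method; a full
  autocalibrated estimator (e.g. ESPIRiT) can be plugged in through the
  same `SensitivityMaps` interface.
* The RSOS-GR comparator uses a documented stand-in convention, not the
  published implementation.
* Phantom anatomy is schematic: it contains exactly the structures the
  four metrics need.  Passing closed-loop tests shows the pipeline and
  metrics are self-consistent at realistic noise and undersampling — it
  does not certify rater-level accuracy on real anatomy.
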