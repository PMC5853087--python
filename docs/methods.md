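# Methods

`cbppg` implements fully automated, anatomy-free region-of-interest (ROI)
selection and tracking for camera-based photoplethysmography, plus the
downstream signal analysis that turns ROI traces into heart-rate (HR) and
signal-to-noise (SNR) estimates.  This note records the model, the
numerical choices, and what the synthetic test bed does and does not show.

## Pipeline model

A recording is a pair of synchronized streams: RGB frames `I_R, I_G, I_B`
and monochrome near-infrared frames `I_N`, both on a 12-bit intensity
scale (0–4095).

**Skin classification.**  A histogram Bayes classifier over RGB color:
a pixel with color `c` is skin when `p(c|skin) / p(c|¬skin) ≥ θ` with
θ = 5.  The class densities are 3-D histograms (32 bins per channel over
the 8-bit domain; 12-bit values are right-shifted by 4 before binning)
normalized by total counts.  Colors unseen in the non-skin corpus but seen
in the skin corpus are skin; colors unseen in both are non-skin — the
conservative choice, since the segmentation can recover under-detection
but wastes effort on false positives.  Classification runs on an
intensity-adjusted image: a per-channel linear stretch mapping the
1st/99th percentiles to the full scale.  The adjustment is pluggable
(`skin.adjust_intensity`); percentile stretching is the package's default.

**Two-phase level-set segmentation.**  The ROI `Ω₁` is the positive phase
of a signed-distance field `Φ` evolved by gradient descent on a regional
homogeneity energy:

    ∂Φ/∂t = H'(Φ) [ Σ_j log( p_1j(F_j) / p_2j(F_j) ) + ν · div(∇Φ/|∇Φ|) ]

`F` is the feature stack — `(I_R, I_G, I_B, J_RGB)` for RGB,
`(I_N, J_N)` for NIR, where `J` is the local 5×5 standard deviation
(texture) and `J_RGB` the mean of the three per-channel textures.
`p_ij` is a Gaussian with the mean and standard deviation of feature `j`
inside region `Ω_i`, recomputed from the hard masks {Φ>0}/{Φ≤0} every
iteration, with the standard deviation floored at 1.0 intensity unit.
The curvature weight is ν = 0.001·|Ω|^0.7 of the grid size.  Segmentation
is initialized with the classified skin mask (RGB, ≤300 iterations) or the
registered RGB ROI (NIR, ≤100 iterations); tracking re-segments each frame
from the previous frame's ROI (≤50 iterations, early stop when the inside
area changes by <50 px between iterations).  Early stopping is enabled for
tracking only: with a distant initialization the per-iteration area change
can be small while the contour is far from its optimum, so detection runs
its fixed budget.

**Registration.**  The RGB ROI is transferred to the NIR grid by matching
every overlapping 5×5 green-channel block fully inside the ROI against NIR
blocks displaced by `(d_x, d_y)` in the inclusive window d_x ∈ [−60, 0],
d_y ∈ [0, 10] (camera-rig prior).  The criterion is the mean-adjusted MSE
`Σ[(I_G−μ_G) − (I_N−μ_N)]²`, invariant to constant inter-camera intensity
offsets.  Ties break toward the smallest |d_x|+|d_y|, then row-major
order; blocks leaving the image at a candidate displacement skip that
candidate; blocks are independent (no displacement-field smoothness — the
subsequent NIR segmentation cleans up incoherence).

**Tracking and artifact monitoring.**  Both streams are tracked
independently.  Two failure paths re-run the full detector chain:
(i) the tracked region disappears — operationally, its area drops below
100 px or exceeds 80% of the grid (a two-phase segmentation with a
near-empty outside region has meaningless statistics; this is the
"filled the grid" degeneracy); (ii) the standard deviation of the mean ROI
intensity over the trailing 10 s exceeds 50 units.  The monitored channel
is the stream's primary channel (green for RGB, NIR itself).  After every
successful (re)detection, monitoring pauses for 10 s and the intensity
buffer is cleared — a fresh ROI sets a fresh photometric baseline; the
initial detection is treated the same way for uniformity.  The event log
records one event per episode start (`redetect_no_skin`,
`redetect_unstable`) and a `pause_start` on the frame where reselection
succeeds, so episodes are directly countable.  After 100 consecutive
detector failures the retry cadence backs off to every 10th frame.

**Signal analysis.**  Per frame and channel, the cbPPG sample is the
spatial mean over the ROI (missing where no ROI exists).  Traces are cut
into consecutive 10-s segments from the recording start; any segment
containing a missing sample is invalid and excluded from spectral
analysis, but still counts as a false detection in the HDR.  Valid
segments are linearly detrended, highpass filtered (order-250
Hamming-windowed-sinc FIR, 0.5 Hz cutoff, applied forward–backward for
zero phase), zero-padded to 2¹³ points and Fourier transformed.  The HR is
the amplitude-spectrum maximum in 30–200 bpm (ties toward the lower
frequency); the SNR is `10·log₁₀` of the power within ±5 bpm of the
reference HR and its first harmonic against the remaining 30–200 bpm
power, capped at ±80 dB to keep noise-free fixtures finite.  The harmonic
band contributes only its part inside 30–200 bpm.

**Evaluation.**  The HR detection rate (HDR) of a channel is the
percentage of segments with |HR − reference| < 5 bpm (strict), missing
segments counted false.  Channel combinations take the per-segment OR of
correctness (an oracle picks whichever channel is right).  Median SNR is
computed over valid segments only.  Per-subject paired improvements are
tested with a one-tailed Wilcoxon signed-rank test: for n ≤ 25 the exact
conditional null distribution is computed by dynamic programming over
midranks (zeros dropped; doubled ranks keep the DP integral), because the
standard exact routines refuse tied ranks; larger n uses the normal
approximation with Pratt zero handling.  All-zero differences return
p = 0.5.

## Numerical scheme

* **Time stepping.**  Because `Φ` is reinitialized to an exact signed
  Euclidean distance after every iteration, contour-adjacent pixels always
  sit at Φ = ±0.5 and only sign flips carry information between
  iterations.  The update is therefore bounded per pixel:
  `ΔΦ = 0.9 · (H'(Φ)/H'(0)) · f/(|f| + 1)` with `f` the total force.
  A contour pixel flips exactly when its force exceeds ≈1.6
  log-likelihood units; the front advances at most one pixel ring per
  iteration (unconditionally stable).  A global step normalized by the
  force maximum is not usable here: the Gaussian log-ratio is heavy-tailed
  (a tight region's small σ makes wrong-side penalties orders of magnitude
  larger than right-side gains), which would leave must-flip pixels with
  sub-threshold updates that the reinitialization then wipes.
* **Smooth delta.**  `H'` is the derivative of the arctan Heaviside
  `H_ε(Φ) = ½(1 + (2/π)·arctan(Φ/ε))` with ε = 1.5 px.
* **Reinitialization.**  Exact signed EDT from the current sign pattern,
  with a half-pixel offset (`distance − 0.5` on both sides) so that
  |∇Φ| ≈ 1 across the zero crossing; {Φ>0} reproduces the mask exactly.
* **Verifying the distance property.**  |∇Φ| is estimated with central
  differences; pixels where one-sided differences along any axis or
  diagonal disagree in sign (local extrema: medial axes, single-pixel
  protrusions) or differ by more than 0.35 (nearest-boundary generator
  switches) are genuine discontinuities of ∇(distance) and are excluded.
  On the remainder of a 3-px contour band the estimate stays within
  [0.9, 1.1] throughout evolution.
* **Curvature.**  `div(∇Φ/|∇Φ|)` with central differences and an 1e-8
  regularizer; pointwise values on a pixelized contour are staircase-noisy
  but their average over the contour ring matches −1/r on discs within a
  few percent.
* **Degeneracies.**  Regions with <2 px abort statistics; a vanished or
  grid-filling phase is reported as a status (never raised) so callers can
  redetect.

## Synthetic test bed

The `synthetic` module defines the study conditions: 64×96 px frames at
30 fps (scaled down from a clinical 320×420 @ 100 fps geometry so the full
suite runs at desk scale; 30 fps keeps a 10-s segment, 300 samples, longer
than the order-250 FIR), elliptical skin patches (base RGB
(2600, 1900, 1600), NIR 2500) with a shared static texture field
(sd 25 units) on a flat background, additive Gaussian sensor noise
(sd 5), and a raised-cosine pulse with one harmonic
(`a·[cos(2πft) + 0.3·cos(4πft)]`, per-channel amplitudes
(R, G, B, NIR) = (4, 10, 3, 8) units, peak ≤ 13 ≤ the 15-unit bound at
12-bit depth, default 72 bpm).  The NIR camera sees the same scene
displaced by an integer viewpoint offset ((d_x, d_y) = (−8, 3), inside the
registration window) with independent illumination and an optional radial
LED-falloff gain.  Two one-pixel calibration columns (values 40/3950)
emulate fixed bright/dark set pieces rigidly attached to the recording
rig; they anchor the percentile adjustment so that global illumination
changes do not destabilize classification.  The skin-pixel corpus is a
trivariate Gaussian skin-tone cluster versus a mixture of a uniform
background distribution and a dark cluster (50 000 draws per class by
default).

Scripted events: full-frame flat occlusions (default color
(900, 1900, 900) / NIR 2500 — green and NIR matched to the skin region's
means so an occlusion exercises the ROI-loss path rather than the
intensity monitor), global illumination steps (RGB-only by default: the
NIR stream has dedicated illumination), and rigid scene translations.
Everything is a pure function of (script, seed); identical inputs give
bit-identical frames.

What the generator does **not** emulate: physically based skin rendering
and wavelength-dependent pulse shapes, ballistocardiographic motion,
camera sensor noise models (read noise, fixed-pattern), rolling shutter,
non-rigid motion, or sub-pixel camera disparity.  Passing tests therefore
demonstrate the correctness of the algorithmic chain under its stated
assumptions, not clinical performance.

## Design choices and limitations

* **Features from raw frames.**  Only the classifier sees the adjusted
  image; segmentation, monitoring and signals use raw 12-bit values, since
  the 50-unit monitor threshold and the ±15-unit pulse bound live on the
  raw scale.
* **Holes and disconnection.**  The delta-restricted update is
  contour-local: interior pixels cannot flip, so holes and disconnected
  components originate from the initialization (the pixel-level classifier
  naturally produces them) and are then preserved and refined — they do not
  nucleate spontaneously.
* **Smooth gradients are absorbed.**  Region competition with adaptive
  Gaussian statistics swallows a smooth illumination gradient ring by ring
  (σ creeps upward); it reliably rejects *step-wise* darker subregions.
  Homogeneity selection should be read as rejecting distinctly darker or
  textured areas, not as flattening arbitrary gradients.
* **Decision band.**  A pixel whose total force is below ≈1.6
  log-likelihood units (likelihood ratio < e^1.6 ≈ 5) never flips; the
  converged contour can differ from the exact pixelwise argmax inside this
  indifference band.  On well-separated fixtures the band is empty and the
  fixed point is exactly the maximum-likelihood labeling.
* **Maximum ROI fraction.**  0.8 of the grid; larger "ROIs" are failure
  modes (e.g. a flat occluder absorbed wholesale) and trigger redetection.
* **Problem sizes.**  The shipped tests use 10–15 fps for tracking-logic
  fixtures, 30 fps for spectral fixtures, recordings of 1–190 s, and
  64×96 px frames; `scripts/acceptance.py` re-runs the study at 90 s
  (clean) plus 60 s (artifact script).  These sizes are the package's
  reference conditions; all thresholds above are resolution- and
  fps-independent except ν, which scales with the grid as stated.
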