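# Methods

## Model

A line-scan acquisition samples luminance I(x, t) along a fixed line
through a vessel at spatial resolution Δx (µm/pixel) and line period Δt
(ms/line); rows of the space-time image are successive lines (time),
columns are positions (space). An RBC moving at constant velocity v
traces a straight streak whose angle from the time axis is
θ = arctan(v·Δt/Δx); inverting, v = (Δx/Δt)·tan θ in mm/s (µm/ms).
θ = 0 is stagnant flow (vertical streaks); |θ| → 90° is unmeasurably
fast (horizontal streaks). Positive θ means displacement toward
increasing column index per line; the anatomical direction is the
user's to interpret. All modules share this convention, angles are
always reduced modulo 180° into [−90°, 90°), and windows are half-open
0-based row ranges.

## Pre-processing filters

The recommended filter is the 3×3 vertical Sobel operator
S = [[1,2,1],[0,0,0],[−1,−2,−1]], applied as a true 2-D convolution
(kernel flipped; the alternative correlation orientation only flips the
output sign, which the variance detector cannot see). It is a
smoothed temporal derivative: any structure constant along time
(vertical bands) is annihilated exactly, slowly time-varying structure
(heartbeat/respiration luminance drifts spanning many lines) is
attenuated in proportion to its temporal slope, and the sharp RBC
streak edges — one or two pixels in two-photon data — pass at full
gain. Output is cropped to the valid interior (one row/column lost per
side): zero-padded borders would bias the projection variance, and two
lines out of a ≥100-line window are negligible. Kernel size is fixed at
3×3; larger kernels add nothing for edges this sharp.

Two baselines are provided for comparison. Temporal ("vertical")
demeaning subtracts each column's time-mean and removes only
time-invariant artifacts; whole-image demeaning subtracts the scalar
mean. Both preserve shape. Per-column demeaning has a subtler defect:
when wide streaks cross a short window, band coverage — and hence the
column mean — varies periodically with column position, and subtracting
it superimposes a spurious vertical-stripe pattern that biases the
detected angle. The Sobel filter is immune (column-constant offsets are
in its null space); the accuracy ordering is asserted by the test suite
on wide-streak images, where the effect is strongest. At exactly 45°
the two filters are statistically indistinguishable on the clean
generator; Sobel wins at the other mid-range angles and in aggregate.

## Radon projection and variance profile

The projection at angle θ integrates the image along parallel rays at
θ. Discretization is pixel-driven (the adjoint of rotate-and-sum): each
pixel center is rotated about the image center and its value split
linearly between the two nearest unit-spaced offset bins,
u = (x − cx)·cos θ − (t − cy)·sin θ with integer centers cx = w//2,
cy = h//2. This conserves total mass exactly at every angle and makes
the θ = 0 projection exactly the column sums. The pull form
(rotate-resample-sum) was tried first and rejected: bilinear
resampling loses up to 3% of the mass of streak images and 30% of a
point mass, and it is slower. A MATLAB-style 2×2-subpixel nearest-bin
dispatch was also prototyped and rejected — it sharpens, rather than
smooths, the bin-alignment resonance ripple described below.

The streak angle is the θ maximizing the variance of the projection
over offsets. Two geometric corrections stabilize the profile:

* bins whose ray length through the image is below half the maximum
  (short corner rays at oblique angles) are excluded;
* the variance is taken on the residual after removing the
  ray-length-proportional component (mean image intensity × ray
  length). Raw sums over rays of unequal length carry purely geometric
  variance — nonzero even for a constant image — which would mask
  degenerate windows. For zero-mean (filtered) images the correction
  vanishes. Per-bin division by ray length was tried instead and
  rejected: the discrete ray lengths are jagged, and dividing by them
  biased the peak by ~0.3° at 45°.

Ties in the argmax are broken toward the smallest |θ|, then the
earlier list position, so degenerate inputs behave deterministically.

The discrete variance profile of a *periodic* streak pattern carries
~1% resonance ripple across the flat top of the peak (micro-spikes
where the projection bins align with the pattern), so the fine-grid
argmax is well-defined only to ~±0.15° on a 100×100 image. The test
oracle therefore locates the peak as the centroid of the contiguous
2%-plateau; aperiodic real streaks do not share this artifact.

## Iterative angle search

Iteration 1 evaluates {−67.5°, −22.5°, +22.5°, +67.5°} — a 45° step
spanning the full 180° range, phased to avoid both 0° (structurally
zero variance after the vertical Sobel filter) and the ±90° wrap.
Iteration i ≥ 2 evaluates {c ± 0.5·s, c ± 1.5·s} around the running
best c, with s = 45° for i = 2 and halving thereafter; any candidate
landing exactly on 0° is replaced by the sign-preserving s/100. The
*global* best (angle, variance) pair is carried forward — if no
candidate beats it, the center stays put — so the running best variance
is non-decreasing. After i iterations the resolution is
δ = 45/2^(i−1); the number of iterations for a target δ is
⌈log₂(45/δ)⌉ + 1, and the transform count 4·i grows logarithmically in
1/δ versus ⌈180/δ⌉ for a grid search. Candidates are never cached
across iterations, so the count identity is exact. A structureless
window (all variances ≈ 0 relative to the image energy, e.g. a
constant image or vertical streaks after Sobel filtering) yields a
result flagged invalid instead of an exception, so long recordings with
unusable stretches process end to end.

## Precision planning

For a measured angle θ₀ on a w × h window, one streak spans
ws = min(w, ⌈h·tan|θ₀|⌉) by hs = min(h, ⌈w·cot|θ₀|⌉) pixels (the
degenerate 0°/90° cases return (1, h) and (w, 1) by convention).
Offsetting the streak endpoint one pixel in its longer dimension gives
the single-streak angle resolution δ_s1 (two branches by ws ≶ hs, which
mirror exactly under transposition); with n_s streaks the theoretical
limit is δ_n = δ_s1/n_s. The streak count packs the minimum
inter-streak distance d_s (µm, default 4 — a typical capillary RBC
spacing) along the space axis when streaks span the full height
(n_s = ⌊w·Δx/d_s⌋), or the minimum inter-streak time along the time
axis when they span the full width; when both extents are full, the
spatial branch is used. The count is floored at 1 (with a warning) so
δ_n stays defined. An angle step δ maps to a detectable fractional
velocity change via Δv/v = tan(θ₀ ± δ)/tan θ₀ − 1 and back via
δ = |arctan((Δv/v + 1)·tan θ₀) − θ₀|; the affordable δ for a given
Δv/v peaks at θ₀ = 45° in the small-change limit (the exact optimum is
arctan(1/√(1+Δv/v)), ≈37° at Δv/v = 0.8), which is why acquisition
re-scaling targets 45°: speeding acquisition by k = tan θ moves any θ
to 45°, with k = (Δx_new/Δx)·(Δt/Δt_new) realizable through resolution
or dwell-time changes.

## Windowed pipeline

Long sequences are cut into windows of `window` lines every `step`
lines (defaults 100 and 25, overlapping), each filtered and searched
independently — the method uses no angle prior, so velocity steps
between windows are tracked immediately. When a fractional-sensitivity
target Δv/v is given instead of a fixed δ, each window runs a fixed
7-iteration pre-pass, converts the provisional angle to the required δ
(the mapping depends on θ₀), and deepens the same search as needed.
Sample timestamps are window-center line index × Δt; a trailing partial
window is dropped. Samples whose angle falls within a margin of ±90°
are flagged invalid — residual time-varying artifacts masquerade as
near-horizontal streaks and cluster at the boundary — and a
moving-average smoother over a time span (for spanning multiple cardiac
cycles) excludes flagged samples and leaves them flagged.

## Synthetic data

The generator renders dark diagonal bands (RBCs against labeled
plasma; invertible) on a constant background: band centers are spaced
`streak_spacing` pixels apart along the streak normal, with a
trapezoidal cross-section anti-aliased over one pixel, matching the
one-to-two-pixel edges of two-photon streaks. Defaults (3 px wide
bands every 12 px, contrast 50 on background 100 at 0.5 µm/px and
1 ms/line) emulate a capillary record with ~8 streaks per 100-px
window. Additive Gaussian noise is seeded and bit-reproducible.
Artifact injectors cover the observed taxonomy: a time-invariant
vertical band (scan path outside the vessel) and smooth raised-cosine
horizontal darkening pulses with ~10% jittered period and depth
(heartbeat-driven brain motion; a few hundred lines per period at
typical line rates corresponds to the 3–8 Hz cardiac band). Epoch
concatenation continues streak phase across an angle step, producing
kinked but unbroken streaks.

What the generator does not emulate — and what passing tests therefore
do not establish about real data: shot noise and depth-dependent
contrast loss; RBC-to-RBC variability in size, spacing and speed
(bands here are strictly periodic, which creates the resonance ripple
noted above and makes variance peaks narrower than in vivo); scanner
flyback and nonuniform line timing; and streak curvature within a
window when flow accelerates.

## Limitations

* **Near-vertical streaks at low SNR.** The Sobel response scales with
  sin θ, so slow flow (|θ| ≲ 10°) at image SNR ~5 leaves the variance
  peak tails below the noise floor of the coarse first iteration. The
  noise floor itself is tilted: projection variance of Sobel-filtered
  white noise rises from ~0 at 0° (the kernel telescopes along
  near-vertical sums) to a maximum at ±90° (temporal difference of row
  sums), so a stranded search drifts to the boundary. The exhaustive
  grid recovers the same windows — this is the cost of 28-vs-180
  transforms at low SNR — and the failures land exactly in the ±90°
  zone the outlier flag removes; they never produce silently wrong
  interior angles in our tests. At moderate angles (|θ| ≥ 15°) recovery
  is complete at SNR 5.
* **Quantization.** The final angle is a stencil point, so even on
  clean images the estimate is within, not at, δ of the peak; δ should
  be chosen from the Δv/v calculus, not minimized blindly past δ_n.
* **±90° is unmeasurable.** Horizontal streaks (tangent singularity)
  cannot be converted to velocity; such samples are flagged, and
  sustained flags suggest re-planning the acquisition speed (k factor)
  rather than deeper searches.
* **Throughput claims are transform counts,** not wall-clock times;
  per-transform cost depends on window size.
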