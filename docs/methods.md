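# Methods

This note documents the models, parameter choices, and numerical decisions
behind `vnc2p`, and what its synthetic benchmarks do and do not establish
about real recordings.

## Synthetic data model

The generator emulates a tethered-fly VNC imaging session on a
photon-count-like intensity scale (background ≈ 300, cell bodies up to
≈ 4000, as in 12-bit acquisition):

- **Structural template.** Sparse Gaussian blobs (cell bodies/neurites) on a
  dim, weakly textured background, so that even blob-free regions carry
  enough gradient for matching.
- **Deformation.** Independent Gaussian displacement noise per component,
  spatially low-pass filtered at the `deformation_smoothness` scale
  (default 8 px), temporally smoothed by a 5-frame moving average, anchored
  so frame 0 (the reference) carries zero motion. Fields are rescaled so the
  95th-percentile magnitude equals `deformation_amplitude` and the rare
  excess is hard-clipped, keeping max |**w**| ≤ amplitude exactly while
  typical displacements genuinely stress registration. Defaults (3 px on a
  64 px image) stay under 10% of the image width — large tissue motion
  without breaking invertibility. Stored fields map reference coordinates
  onto frame coordinates (the registration convention); frames are rendered
  by warping the template with the numerical (fixed-point) inverse of each
  field, so the stored field is exactly what a perfect registration should
  return.
- **Activity.** The activity channel is the template multiplied by
  (1 + gain · Σ mask·a(t)) before warping, where a(t) is the planted event
  train convolved with a peak-normalized causal exponential
  (t½ = 1.1448 s). Multiplicative coupling keeps the structural channel
  activity-independent, mirroring the role of a second fluorophore. Noise is
  additive Gaussian on both channels (Poisson available behind
  `poisson_noise`); the downstream math does not depend on the noise family.
- **Optic flow.** Piecewise-constant state rates (forward +0.5 rot/s,
  backward −0.3, turns ±0.5 yaw with a small forward component, a biphasic
  ±0.6 anterior-posterior pulse for push-down) plus Gaussian noise at
  800 Hz. Signs: positive anterior-posterior flow = forward walking,
  negative yaw = left turn.
- **Behavior video.** 30 fps grayscale frames in which a rear-leg region is
  re-textured every frame during walking states and a front region during
  grooming; both regions are large enough that the blurred difference image
  clears the walking pixel-count threshold with margin.
- **Ratio traces** (event-detection benchmarks). Transients rise with a
  0.15 s time constant (indicator binding; the rise spans one-to-two samples
  at 8 Hz) and decay with t½ = 1.1448 s; amplitude defaults to 50 %ΔR/R
  against white Gaussian noise of sd 4 (peak SNR 12.5). Displayed traces of
  these sparse neuron classes show transients of 100–300 %ΔR/R against
  roughly 10% noise, so this is the realistic regime. Events are planted at
  gaps of 3 s + Exp(2 s), about one per five seconds.

Everything is deterministic given `rng_seed`; each generator derives an
independent stream from it, so adding one generator never shifts another.

## Motion correction

The energy combines an L1 intensity-conservation term (bilinear sampling,
edge clamping), an L1 feature-matching term on sparse correspondences, and a
quadratic forward-difference gradient penalty (boundary rows/columns
contribute no forward term — this is the exact discrete energy used
everywhere, including tests).

**Matching.** Keypoints on an 8 px grid, gated at 5% of the image's maximum
gradient magnitude; normalized cross-correlation of 9×9 patches within ±8 px;
matches below NCC 0.5 dropped. A featureless image yields an empty match
set, and the feature term vanishes.

**Solver.** Warp-and-linearize outer iterations; inside each, ADMM with two
splitting variables — one absorbing the linearized data term (per-pixel
shrinkage, the classic threshold step of L1 flow), one the feature term
(soft-threshold toward the match at keypoints). The coupled smoothness step
solves (2λL + 2μI)w = μ(a+b) per component with a cached sparse
factorization. Outer iterates are accepted only when the true nonlinear
energy decreases, with up to three backtracking halvings toward the previous
iterate; the recorded energy sequence is therefore monotone by
construction. Three pyramid levels (×0.5, stopping below 12 px) extend the
linearization range to multi-pixel motion. Defaults: λ = 100, γ = 1,
penalty μ = 10, 50 outer × 8 inner iterations, relative tolerance 1e-4.
None of these is data-derived; λ and γ are per-experiment grid-search
quantities in practice.

**Post-processing.** A 5×5 weighted median filter (weights Gaussian in
structural-intensity difference, σ = 10% of dynamic range) smooths the
field; the filtered field, its integer rounding, and the raw field compete
on the true energy. A final greedy multi-scale block-coordinate integer
refinement (whole image → halves → quarters, unit offsets, run from both the
best candidate and a zero field) only ever accepts energy decreases; it
rescues the discrete optima that linearized continuous updates cannot reach
on tiny or strongly quantized instances and is a no-op otherwise.

**Artifacts and parameter selection.** Divergence by central differences
(one-sided at borders), threshold −1.2, 4-connected components, flagged
above 20 pixels. The grid search registers every 5th frame per (λ, γ),
discards flagged pairs, and maximizes the mean gradient magnitude of the
temporal mean image ("mean" resolves an ambiguity: sum and norm rank
identically up to monotone transforms on fixed image size). All ties break
toward larger λ.

## Behavior quantification

Running averages are centered and truncated at the edges. Interpolation to a
common timebase targets the highest-rate signal's grid on the common
overlap. Bout thresholds are strict inequalities (a sample exactly at
±0.31 mm s⁻¹ is "still"); pixel-count thresholds are ≥. "Non-zero" after
blurring means > 0 for integer video and > 1e-9 for float frames. The
hysteresis filter is minimum-run-length suppression, shortest runs first,
absorbed into the surrounding state; it is idempotent. It is applied to
walking first; grooming is then recomputed under subservience (hard-masked
where walking) and filtered with its own length. Sideways-walking
segmentation reuses the ±0.31 mm s⁻¹ thresholds on v_side via `use_side`.

## Regression maps

The CIR is a peak-normalized causal exponential truncated at five
half-lives (kernel has decayed to ~3%; normalization and truncation only
scale the weights, so map rankings are unaffected). ΔF/F uses the mean of
ten sequential quiescent frames as F; `suggest_quiescent_window` proposes
the 10-frame window of minimal total temporal variance as a programmatic
stand-in for choosing frames with visibly minimal, unchanging fluorescence.
Pixels with baseline below 1% of the movie's dynamic range are masked
(weight 0) to avoid division blow-ups. The regression is univariate with no
intercept, exactly w = (XᵀX)⁻¹Xᵀy per pixel, computed with the time axis
contiguous so an exact fit returns 1.0 bit-exactly; raw (unsmoothed) ΔF/F
is used.

## ROI signals

Otsu detection uses Gaussian σ = 2 px and erosion radius 1 px (defaults;
both caller-tunable), minimum area 3 px. Tracking correlates the structural
channel (activity-independent) within ±10 px and flags frames scoring below
NCC 0.5 for review — the programmatic analog of manual verification.
Elliptical ROIs are rasterized analytically (boundary pixels included). The
%ΔR/R baseline is read as: average the ratio trace in non-overlapping 2.5 s
bins and take the minimum bin mean as a single global baseline — events
occupy a minority of time, so this yields one stationary baseline matching
flat displayed baselines; a rolling or per-bin reading is the main
alternative and was rejected for producing a nonstationary baseline.

## Event detection

The derivative is the first difference divided by the sample interval;
percentiles interpolate linearly between order statistics; pooled
derivatives are signed. Onsets are walked back from each upward threshold
crossing to the last non-positive derivative sample; crossings sharing a
rise collapse onto the first onset; onsets within 10 s of either end are
dropped (the presentation window is ±10 s). Copied events (covarying rule)
keep the partner's timestamp; greedy time-ordered nearest matching defines
the pairing; copies that would land inside the partner's edge-exclusion
zone are dropped when the trace range is supplied. Bootstrap CIs are
percentile-method over events, 1000 replicates by default, seeded.

The derivative-percentile detector has a structural operating requirement:
the pooled percentile pins the number of supra-threshold samples, so false
alarms vanish only when event-rise derivative samples fill that quota and
stand above the noise-derivative tail. At the benchmark's event density
(~0.2 events/s at 8 Hz) this needs peak SNR on the order of 10; at peak SNR
5 the same detector recovers only ~70% of planted events. The synthetic
benchmarks therefore run at SNR 12.5, and detection performance quoted here
should not be extrapolated to substantially dimmer or sparser real signals.

## What the synthetic benchmarks do not show

The generator omits scanning artifacts (line shear, bidirectional offset),
photobleaching, z-drift out of the imaging plane, and anatomical realism;
its deformations are spatially smooth by construction, so the registration
accuracy quoted on it does not bound performance under tissue tearing or
occlusion. Behavior video contains no limb structure, so annotation results
validate the differencing/threshold/hysteresis logic, not pose-level
robustness. Ratio-trace noise is white; slow shared artifacts are handled
by the ratiometric baseline in the movie pathway but are not separately
stressed in the event benchmarks.

## Problem sizes

The test suite exercises registration at 64×64×100 frames (the acceptance
property), other stages at 160–240 frame or 240 s scales; the acceptance
script uses 40 frames for registration and three 240 s traces for events.
These sizes give stable statistics for the stated tolerances on a single
CPU.
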