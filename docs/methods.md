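# Methods

This note documents the models implemented in `navmoco`, their
assumptions, the parameters that matter, and the design decisions taken
where several reasonable options existed. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Coordinate model

All 3D quantities live in patient coordinates (LR, AP, HF) in
millimetres, with +LR = patient-left, +AP = posterior and +HF = head.
This triple is numerically identical to DICOM LPS; NIfTI affines (RAS+)
are converted at the I/O boundary by negating the first two axes. The
sign conventions are a choice — motion directions are physically
meaningful only up to the axis labelling — and are isolated behind
`named_plane` and the conversion helpers in `io_cli`.

A navigator slice is an oriented plane: orthonormal in-plane unit
vectors `e1` (image x/column) and `e2` (image y/row), the patient
position of pixel (0, 0), pixel sizes and matrix size. The named planes
follow standard radiological display: coronal (e1 = LR+, e2 = HF−),
sagittal (e1 = AP+, e2 = HF−), transversal (e1 = LR+, e2 = AP+); image y
pointing foot-ward on coronal/sagittal slices. Any oblique plane can be
supplied explicitly. Image coordinates are 0-based with pixel centres
at integers.

The image→patient map is `x = R P d (+ q)` with `R = (e1, e2)`,
`P = diag(p_x, p_y)`. The origin shift `q` is applied only in position
mode: displacement fusion consumes differences in which `q` cancels.
The reverse map is the orthogonal projection onto the plane basis; it
discards through-plane information by construction, which is exactly
the degeneracy the multi-slice fusion exists to resolve.

## Edge features and SVD fusion

Each tracked bounding box contributes four scalar observations, one per
edge: left/right edges move along `e1`, top/bottom along `e2`, with
signed lengths in mm. For a rigid box the two features per direction
are redundant and deliberately kept (m = 4 per slice): the
representation also accommodates boxes that change size, where the four
edges genuinely differ. All weights default to 1.

Stacking m features gives `W A x = W b` with unit rows `aᵢᵀ` in A. The
solution uses the SVD of the weighted matrix with Tikhonov-filtered
inverse singular values, `x = Σᵢ (uᵢᵀ b̃) vᵢ σᵢ/(σᵢ² + τ²)`, τ = 0.05
(dimensionless). Numerical choices:

- Singular values below 1e-12·σ_max are treated as exact rank
  deficiency and dropped before filtering, so null-space components of
  x are exactly zero (a single coronal slice says nothing about AP and
  leaves it at 0) rather than "small".
- The filter is applied to the weighted right-hand side b̃ = W b; with
  W = I the two formulations coincide.
- With τ = 0 and a full-rank system the result is the ordinary weighted
  least-squares solution (verified against a brute-force solve in the
  tests at 1e-9 relative error).

τ = 0.05 trades a relative shrinkage of ~σ²/(σ²+τ²) per singular
direction (about 1.25e-3 for the σ = √2 of two redundant unit rows)
against stability when slices fail and the system nears rank
deficiency. Failed slices are dropped from the pool; only a frame with
no valid slice at all skips the update (configurable behaviour was
considered and rejected as needless surface: the hold-last-position
policy is what a scanner implementation can actually do).

## Trackers

Navigators are single-channel, low-resolution and low-contrast, so both
native trackers use raw grayscale features only — no HOG or colour
channels. All patches are min-max normalized before filtering, making
tracker output exactly invariant under positive intensity rescaling
(MR magnitude images carry no absolute scale). Initialization on a
constant (flat) patch raises an explicit error rather than silently
building a zero filter.

**MOSSE** trains a frequency-domain filter `H* = Σ Ĝ⊙F̂* / Σ F̂⊙F̂*` on
the initial search window plus 8 random small-angle (±5°) / sub-pixel
perturbations, against a Gaussian target response. Preprocessing is
log(1+I), zero-mean/unit-variance, Hann window. Confidence is the
peak-to-sidelobe ratio with an 11×11 exclusion window; PSR below 8
declares failure and leaves the state untouched. Learning rate 0.125.

**KCF** solves `α̂ = ŷ/(k̂ˣˣ + λ)` with a Gaussian kernel correlation
computed via circulant/FFT identities on the Hann-windowed window;
detection re-centres at the response argmax (wrapped shifts), and both
template and dual coefficients are updated by linear interpolation
(rate 0.02). Failure is declared when the detection peak falls below a
fraction (0.25) of the exponentially-smoothed running mean of past
peaks — the first update cannot fail by this criterion, which is the
price of a reference-free relative threshold.

Defaults (padding 2.0, λ = 1e-4, kernel σ = 0.5, output σ factor 0.1)
are the canonical values of the original correlation-filter methods;
all are exposed in `TrackerParams` because no single set is optimal for
every navigator geometry. Sub-pixel refinement is a parabolic fit
around the response peak, clamped to ±0.5 px, enabled by default and
switchable off for integer-pixel oracle comparisons.

**NCC baseline**: exhaustive normalized cross-correlation of the fixed
initialization patch over a clipped search window (radius 12 px),
computed with `skimage.feature.match_template`. It adapts to nothing
and is therefore the transparent oracle against which the adaptive
trackers are tested. External tracker libraries plug in through
`register_tracker` without becoming dependencies.

Displacements are bounding-box-centre shifts relative to the
initialization frame; failed frames carry NaN displacements and are
excluded from precision data downstream.

## Synthetic navigator generator

The generator emulates the *appearance* of fast 2D navigators, not
their contrast physics: a bright compact target (disc, 1.4:1 ellipse,
or ring with inner radius at 60%) on a darker background, anti-aliased
over one pixel; optional exponential intensity falloff from the y = 0
image edge (scale in mm) standing in for surface-coil B1 — deliberately
a one-parameter caricature, not a coil model; Rician noise as the
magnitude of a complex Gaussian, the correct statistics for magnitude
MR images, with σ expressed as a fraction of target intensity so
SNR = 1/σ directly. Defaults: 64×64 px at 2.7 mm isotropic (typical
navigator geometry), 20 mm target radius, background 0.15 of target
intensity, SNR 10.

Through-plane motion shrinks the apparent target radius by chord
geometry (the visible disc of a displaced sphere) and removes it
entirely beyond one radius — enough to exercise failure handling, but
no partial-volume or slice-profile modelling.

Motion traces: a breathing-like sinusoid `A_c sin(2πt/T)` along a
configurable unit direction with per-cycle lognormal amplitude jitter
and linear drift (defaults: 4 s period, direction mostly head-foot),
and the step-wise staircase of a motion phantom (4 mm per TR up to
40 mm and back, by default). Multi-slice series sample each slice at
its acquisition mid-time (70 ms per slice by default), so slices of one
repetition see slightly different positions — real intra-navigator
motion. Noise streams derive from (seed, frame, slice); identical seeds
give bit-identical series.

What passing tests on this generator do **not** show: robustness to
organ deformation, pulsatile intensity changes, saturation bands,
receive-profile drift or genuinely low-contrast anatomy. The generator
bounds what the geometric and timing machinery can do with a
well-behaved target; in-vivo tracker performance is a separate,
data-dependent question.

## Prospective loop and signal models

One repetition per TR: acquire k navigator slices sequentially, track,
fuse, apply the update at `t_trigger + k·t_nav + t_proc` (defaults
70 ms and 40 ms). The true position is evaluated at the midpoint of
the target acquisition window starting at that instant — midpoint
because any other choice biases the error by half the window. The
applied position at any time is the most recent update whose apply time
has passed; repetitions where all slices fail hold the last position
and are flagged. Consequence of this timing model: the residual equals
the motion between navigator sampling and target acquisition, so error
is non-decreasing in processing latency on monotone trace segments, a
property the tests assert.

Residual-displacement cost models, both for pure translation: the
rectangular-voxel overlap `Π max(0, L−|Δ|)/L`, and the fraction of a
spherical target's volume remaining inside the voxel box, computed on a
cell-centred 96³ voxelization of the sphere (deterministic, ~1e-3
accuracy, verified against the spherical-cap closed form). NoCo
amplitudes use the full displacement as residual; MoCo amplitudes use
the tracking residual.

## CSI point-spread-function simulation

Phase-encoded CSI acquires one Cartesian k-space sample per TR; a point
source at r contributes `S(k) = exp(−2πi k·r(t_k))`, k in cycles/mm.
Sampling order is line-by-line with the first phase-encode axis cycling
fastest (centre-out and swapped orders available). Averages repeat the
full pass and sum coherently. Reconstruction is a plain inverse DFT
(1/N normalization): the static PSF is the 2D Dirichlet kernel with
peak exactly 1 at the centre voxel, and Parseval reads
`Σ|image|² = Σ|k|²/N`, checked to 1e-9.

The MoCo latency model: the residual of each TR is
`latency_fraction × (r(t_k) − r(t_k − TR))`, the per-TR displacement
increment scaled by the uncorrected fraction, defaulting to processing
latency / TR (40 ms / 2 s = 0.02). This is the simplest mechanism that
leaves exactly the just-before-update motion uncorrected; it is a
declared model, not an inferred one, and is fully configurable. With
latency fraction 0, MoCo is identical to the static scan to machine
precision.

PSF metrics: peak and centre-voxel magnitudes, FWHM per axis from
16× band-limited upsampling (zero-padded spectrum — linear
interpolation of the coarse grid would be meaningless for a kernel
whose off-peak samples are zero), and the sidelobe energy fraction
(energy outside the 3×3 block around the peak).

## Evaluation methodology

Tracking error is the per-frame Euclidean distance between tracked and
reference 2D motion in mm; frames with reported tracker failure are
removed (a reported failure permits re-acquisition and should not count
as a missed measurement — unreported wrong updates do count). Precision
curves resample the empirical CDF to 100 points using inverted-CDF
(order-statistic) quantiles, so reading the curve at a threshold
reproduces the exact counting fraction to within 1/n; curves pool
across datasets by pointwise quantile averaging. The threshold
"≤ 5 mm" is inclusive, keeping the all-zero-error case at precision 1.
For anisotropic pixels the 2 px threshold converts to mm via the
geometric-mean pixel size (configurable).

Spatial robustness: 5 shifts per image axis × 5 symmetric scale changes
of width and height about the box centre, in 2 px steps — 125 boxes
including the original, clipped to the image with duplicates kept and
counted. Scale changes are centre-anchored because the perturbation
should test box *placement*, not introduce a systematic drift.
Reported statistics are mean and sample standard deviation (ddof 1).

Trace statistics: per-axis amplitude as the 10th-to-90th percentile
range; principal motion directions from the SVD of the mean-centred
displacement matrix, each direction's largest-magnitude component made
positive (principal axes are defined up to sign).

## Problem sizes

Test and acceptance runs use 64×64 navigators, series of 40–60 frames,
10 seeded datasets for the end-to-end precision property, 200 random
systems for the fusion oracle, a 96³ grid for sphere voxelization and
the 32×16 / 320×160 mm CSI matrix — sizes chosen so every property is
exercised at full fidelity while the whole suite remains a desk-scale
computation.

## Known limitations

- Rigid translations only: no rotations, scaling or deformation
  fields, and no robust (outlier-rejecting) fusion.
- The navigator simulator models appearance, not MR contrast or
  k-space of the navigator acquisition itself.
- Failure thresholds (PSR 8, KCF peak fraction 0.25) govern the
  failure *mechanism*; absolute failure rates on real data depend on
  anatomy and protocol and are not claimed.
- The CSI simulation has no spectral dimension, relaxation, field
  inhomogeneity or acquisition weighting.
- The prospective loop models timing, not sequence physics: no trigger
  jitter, gradient timing or RF behaviour.
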