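# Methods

This note documents the models, numerical choices and limitations of the
`funci` package: what each stage computes, which parameters matter, what the
synthetic phantoms do and do not emulate, and where the design was genuinely
open.

## Phase-based conductivity model

The reconstruction assumes the phase-only MREPT approximation

σ ≈ ∇²φ± / (2 μ₀ ω),

where φ± is the **full transceive phase** in radians (the factor 2 encodes
the transceive assumption that the transmit phase is half the image phase —
inputs must not be pre-halved), μ₀ = 4π×10⁻⁷ H/m, and ω = 2πf with
f = 127.76 MHz for the default 3 T profile.  ω is always derived from the
Larmor frequency, never stored separately.  The approximation neglects B₁
magnitude gradients and is only meaningful within reasonably homogeneous
tissue; boundary handling is therefore pushed into the kernel rules below.

## Laplacian estimation (average parabolic fitting)

Per axis, the one-sided rows through the target voxel are restricted to the
symmetric kernel reach (⌊extent/2⌋ per side; the default 9×9×6 box gives
reaches 4, 4, 3, the short axis conventionally the slice/partition
direction), to voxels sharing the target's tissue label, and to voxels whose
magnitude differs relatively by at most `amplitude_tol` (default 10% — the
underlying criterion is qualitative, "close image amplitudes", so an
explicit, testable default was chosen).  Rows are truncated at the first
excluded voxel, so fits never jump across a gap.  A least-squares parabola
is fitted to {target + side}; a side needs ≥ 2 usable voxels (3 points
determine a parabola); the axis second derivative is the mean of the
available one-sided curvatures.

Acceptance: each used side must have Pearson correlation > `min_corr`
(default 0.7) between fitted and measured phase.  This is evaluated per
side — the strictest reading.  A zero-variance (constant) sample is an exact
fit, where Pearson correlation is undefined; it is defined as 1 and
accepted.  A voxel's Laplacian is valid iff **all three axes** are accepted
and the total number of surrounding voxels used is ≥ `min_neighbors`
(default 6); the per-voxel neighbour count is retained and a histogram
diagnostic is emitted.  Second derivatives are computed per voxel² and
converted with the axis spacing to rad/m² before summation, so σ comes out
in S/m.  Conductivities outside a plausibility window (default [−1, 5] S/m,
configurable) are flagged invalid rather than reported.

Consequences worth knowing: with ≤ 5 points and 3 parameters, a pure-noise
side passes the 0.7 correlation gate only ~25–50% of the time, so
unsmoothed noisy phase yields very few valid voxels — denoising before
reconstruction is not optional at realistic noise levels, which mirrors the
intended processing chain.

## Phase unwrapping

The unwrapper implements the region-growing scheme: the wrapped [0, 2π)
interval is split into six sub-intervals; 6-connected regions of constant
sub-interval are internally wrap-free; the merged set grows from the largest
region, absorbing at each step the neighbour sharing the largest border
(ties broken toward the larger region index) with the 2π multiple chosen by
the **median** wrapped difference across the shared faces (robust to
isolated noisy voxels).  Each connected mask component finally receives the
global 2π multiple minimising its mean absolute phase.  On smooth fields the
result is exact to rounding (< 1e-9 rad).  This is the published sketch,
not the full production algorithm (no interval-splitting refinements, no
speed guarantees); a `bypass` flag accepts externally unwrapped phase.

## Denoising

Perona–Malik-type anisotropic diffusion with sigmoid conductance
g(|∇φ|) = 1/(1 + exp((|∇φ| − κ)/s)), explicit time stepping in divergence
form with zero-flux (reflecting) boundaries at the mask edge — the in-mask
mean is conserved exactly.  Defaults: 400 iterations, integration constant
dt = 0.18, interpreted as the explicit time step (the source material does
not define the constant precisely; users who know otherwise can rescale).
κ is data-driven: 2× the median absolute in-mask forward difference; the
sigmoid slope defaults to **κ/2**.  The slope choice is a stability
constraint, not a tuning knob: with slope κ/4 the flat-region conductance is
g(0) = 1/(1+e⁻⁴) = 0.982 and dt·6·g(0) = 1.06 > 1, so the 3D explicit
scheme loses the maximum principle at the stated dt and checkerboard noise
is amplified; κ/2 gives g(0) = 0.881, dt·6·g(0) = 0.95 < 1 and
dt·λmax ≈ 1.9 < 2, making the in-mask variance strictly decreasing.
dt is capped at 0.25 (2D bound) and validated.

`denoise_tissues` applies the filter per tissue compartment (no flux across
tissue boundaries), mirroring the tissue-restricted kernel: unrestricted
diffusion would smear phase curvature across exactly the boundaries the
reconstruction is designed to respect.

## Jitter pooling and response fitting

Timing conventions:

- a frame's conductivity is assigned to its mid-acquisition time
  (`(i + 0.5)·dynamic_duration`);
- the event table provides nominal cycle onsets and per-event jitters; the
  actual stimulus time is onset + jitter, and t = frame mid-time − actual
  onset;
- cycle *i* owns the frames in [onset_i − pre_window, onset_{i+1} −
  pre_window); `pre_window` (default 1.8 s) reserves pre-onset baseline
  frames and must exceed the largest jitter.  Boundaries are nudged by 1 µs
  so frames landing exactly on a cycle edge are assigned deterministically;
- samples are binned to the 0.1 s grid by nearest centre, ties to the
  earlier bin.  Bin counts record (cycle, frame) samples; Σ counts equals
  the number of assigned frames.

Response voxels are those whose σ in the first post-onset frame of cycle 1
exceeds that voxel's mean over the pre-onset frames of cycle 1 (voxels must
be valid in all compared frames).  Voxel averaging happens per frame over
the currently valid voxels, before binning.

The CRF is fitted to the baseline-subtracted pooled values at t ≥ 0
(baseline = count-weighted mean of pre-onset bins) by count-weighted least
squares in an orthonormal discrete-Laguerre basis.  "10th order" is read as
10 basis functions (indices 0–9), configurable.  The basis is generated by
the standard all-pass recurrence with decay α ∈ (0, 1) and re-orthonormalised
on the finite grid by QR (positive diagonal), which preserves the span while
making the Gram matrix the identity to machine precision; as α→0 the first
function tends to a unit impulse.  α defaults to automatic selection by
golden-section search of the weighted residual over (0.05, 0.95) — the
decay parameter has no published value, so a deterministic data-driven rule
was chosen.

Sparse jitter designs leave empty bins where the basis expansion is
unconstrained and can swing arbitrarily; the stored fitted curve is
therefore the LS fit at populated bins, linearly interpolated across gaps
(zero before the first populated bin, matching a causal response), and peak
metrics are read only at populated bins.  With full 16-jitter coverage this
equals the basis expansion everywhere.  The peak amplitude is the maximum of
the fitted curve above baseline (a curvature-based peak definition is
ambiguous; the maximum is well defined and its first-derivative zero
crossing coincides for unimodal fits); the return-to-baseline time is the
first post-peak grid time at which the fit falls to ≤ 5% of the peak.
Repeatability uses the one-way single-score ICC(1,1) from the standard
one-way ANOVA decomposition, and stimulus duration/contrast series are
summarised by ordinary simple linear regression of peak amplitude on the
predictor.

## GLM activation mapping

The task regressor is the unit-height event boxcar on the 0.1 s grid,
discretely convolved with the fitted CRF and sampled at frame mid-times;
columns other than the intercept are mean-centred, with an optional linear
drift column (off by default — no nuisance regressors are assumed).  Per
voxel, ordinary least squares gives β and t = β/SE(β); voxels valid in
< 90% of frames are excluded, voxels with occasional invalid frames are
fitted on their valid frames.  dof = frames − rank(design).  The default
display threshold is an uncorrected T > 2.2; an optional Benjamini–Hochberg
FDR mask is provided but off by default.  No spatial smoothing is applied
to conductivity maps.  With i.i.d. Gaussian frame noise the null t
statistics are exactly t-distributed, which the calibration tests exploit.

## The synthetic phantoms

`make_static_phantom` paints non-overlapping compartments (boxes/slabs,
spheres, ellipsoids) with tissue labels and conductivities, and builds the
clean phase per compartment as φ(r) = (μ₀ωσ/3)·‖r − r₀‖² about a shared
centre, so the analytic Laplacian is exactly 2μ₀ωσ — the ground truth lies
*inside the reconstruction's exactness class*, separating
algorithm-correctness tests from model-error tests.  A Gaussian-bump phase
helper exercises the non-exact regime.  Magnitude is piecewise constant per
tissue with a 2% deterministic ripple (well inside the 10% amplitude
tolerance); noise is i.i.d. Gaussian on phase from a single seeded stream
(bitwise reproducible); optional wrapping differs from the clean phase by
exact 2π multiples.  The default static phantom is 64³ at 3 mm with WM
0.42 / GM 0.64 S/m slabs; the shared phase centre sits on the interface, so
the inter-compartment phase jump stays ≪ π and the field is unwrappable.

`make_dynamic_phantom` emulates the response-function estimation
acquisitions: 3.75 mm voxels, 1.2 s dynamic scans, 220 dynamics, 16 cycles
of 0.5 s stimuli at contrast 0.45 whose onsets are jittered over −0.3…1.2 s
in 0.1 s steps in seeded semi-random order (cycle period 16.8 s, first
onset 3.6 s — chosen so 16 cycles fit the 220-frame series with pre-onset
baseline frames in every cycle).  The activation adds
amplitude·h(t − onset) to σ throughout the grey-matter compartment, with
h a unit-peak gamma-like curve h(t) = (t/tp)ᵃ·exp(a(1 − t/tp)), defaults
tp = 0.7 s and a = 2 — rising immediately at stimulus onset, peaking
shortly after a 0.5 s stimulus ends and decaying back within ~3 s of the
peak.  The default injected amplitude is 0.1 S/m and the default phase
noise 0.05 rad.  The phase term of the activation carries the same
quadratic profile, so the framewise analytic Laplacian matches
2μ₀ω·(σ + A·h) exactly.

What the phantoms deliberately do **not** emulate: B₁ field physics (the
phase is constructed from the conductivity equation, not from
electromagnetic simulation), magnitude-coupled (SNR-dependent) phase noise,
scanner drift and physiological confounds, partial-volume mixing at
boundaries, and anatomically realistic geometry.  Passing the phantom
suites therefore demonstrates correctness of the numerics and of parameter
recovery under the stated noise model — not in-vivo validity.

## Phantom analysis profile

Two pipeline constants adapt the in-vivo defaults to compartments a few
tens of voxels across:

- `PHANTOM_DIFFUSION` = 8 iterations at dt 0.18.  Explicit diffusion for
  total time T = iterations·dt must stay well below the compartment's
  zero-flux relaxation time (L/π)² voxel², or the quadratic phase curvature
  — which *is* the signal — decays along with the noise.  Eight iterations
  cut 0.05 rad white noise by roughly an order of magnitude (smoothing
  scale √(2T) ≈ 1.7 voxels) while the measured grey-matter interior
  baseline changes by only ~1% (0.632 vs 0.640 S/m).  The 400-iteration
  default remains appropriate for whole-brain volumes where L is hundreds
  of voxels.
- `PHANTOM_ROI_EROSION` = 6.  The zero-flux boundary layer contaminates the
  curvature of any voxel whose fit row touches a boundary-adjacent voxel,
  so the contamination depth is the kernel reach (4) plus the smoothing
  scale; phantom ROIs are eroded 6 voxels from tissue boundaries (falling
  back to shallower erosion on very small phantoms).

With this profile the full chain recovers an injected 0.1 S/m response at
0.098–0.100 S/m (mean over 10 noise seeds) with the peak time correct to
one 0.1 s bin.

## Problem sizes and other numerics

The test and acceptance simulations use the study-scale static phantom
(64³) and dynamic phantoms of 32×32×24 voxels with 220 frames (10 seeds)
for response recovery, 110 frames (6 cycles, 10 seeds) for activation
mapping, and 24×24×16 / 64 frames (20 seeds) for null calibration — sizes
chosen so each compartment is large relative to kernel reach and boundary
layers while whole suites run on a single CPU in minutes.  Remaining
numerical conventions: all phase in radians, float64 throughout; kernel fits
use precomputed pseudo-inverse operators per side length; the
zero-variance threshold for the correlation rule is 1e-28; series dummy
scans are dropped at read time so timing has one source of truth.

## Known limitations

- The unwrapper targets smooth fields; severely aliased or disconnected
  noisy phase may need an external tool (use the bypass flag).
- The denoiser's edge preservation depends on the data-driven κ; very low
  SNR pushes κ toward the noise scale and edges below κ will blur.
- Near tissue boundaries the combination of denoising and kernel reach
  biases σ within ~6 voxels; quantitative ROI statistics should use eroded
  masks, as the pipeline does for phantoms.
- The GLM assumes temporally white noise; physiological autocorrelation in
  real data would inflate the nominal t tail.
- `fit_glm` loops voxelwise over partially valid voxels; volumes with many
  such voxels reconstruct slowly.
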