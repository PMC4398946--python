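# Methods

This note documents the models, parameter choices and numerical decisions
behind periomap, and what the synthetic validation does and does not show.

## The estimation pipeline

**Sparse-design GLM.** Sparse temporal sampling acquires one 1 s volume
every 10 s, with stimuli presented in the silent gap and every other
acquisition silent. Each volume is therefore a single sample of the evoked
response, and the GLM needs no hemodynamic convolution: one indicator
column per condition, the silent baseline as the implicit intercept.
Consequences of that parameterisation: each condition coefficient *is* the
stimulus-vs-baseline effect, and its t-test is the contrast the maps are
built from. High-pass filtering is implemented as discrete-cosine drift
regressors inside the design (periods above the 300 s cutoff; a session of
N volumes at TR seconds gets `floor(2·N·TR/300)` of them) rather than
pre-filtering, which keeps residual degrees of freedom exact. Global
scaling normalises every volume to an in-brain mean of 100 — in-brain
voxels are those whose temporal mean exceeds 1/8 of the grand mean — so
betas read as percent signal change and the whole analysis is invariant to
rescaling the raw data. The omnibus F tests all condition coefficients
jointly; voxels with numerically zero residual variance are treated as
infinitely significant if any condition effect is present and as untestable
(excluded from every mask) otherwise.

A documented limitation of the truncated cosine basis: a pure cosine drift
at a 600 s period is removed essentially exactly, but its quadrature (sine)
component at the same period is only approximated by the truncated basis
and can leak up to ~2 % of a 5-unit drift into condition betas. Drifts
well above the cutoff period are unaffected.

**Maps.** Contrast maps subtract mean betas, high set minus low set; the
subtraction direction is fixed (high − low) and recorded in the map's
provenance so a renderer can flip sign without ambiguity. Best maps take
the voxelwise argmax of t-values, with ties resolved toward the lower
stimulus value. The two statistics differ deliberately (effect size for
contrasts, evidence for winners) and both are kept. Because per-condition
standard errors differ slightly through condition/drift correlations in
the design, the t-argmax can disagree with the raw tuning order for
voxels tuned within the SE ratio of a condition midpoint; the tests bound
this from the design matrix itself.

**Surface projection.** A vertex receives the mean (scalar maps) or the
majority vote (label maps) of the in-mask voxels whose centres lie within
1.6 mm. Membership is by voxel-centre distance, not partial-volume
weighting — exactly testable against brute-force enumeration. Projection
happens after masking so baseline-only voxels never dilute vertex values;
vertices with no qualifying voxel are missing, not zero.

**Gradient statistics.** Field vertices are projected onto the field's
best-fit (principal-axes) plane; axes are rotated so +u is the in-plane
anterior direction and +v the in-plane lateral direction, with
right-hemisphere v negated so the two hemispheres report in the same
frame. The regression `value = b0 + bu·u + bv·v` yields a full direction
`atan2(bv, bu)` in [0°, 360°) — the sign of increase matters, because
relative angles above 90° (toward anti-parallel) must be distinguishable
from their complements — plus R² and the F-test of (bu, bv) with
(2, n−3) df. The relative angle folds the direction difference into
[0°, 180°]. Table aggregation uses plain arithmetic means and sample
standard deviations (ddof = 1), not circular statistics, because the
published summary rows this mirrors are plain means of the printed
values; a single-row field reports its value with a missing SD, and
p-values below 1e-16 are printed interval-censored as `<1E-16`. Best-map
gradients reuse the same regression on ordinal condition ranks and are
flagged ordinal; a field with a single best condition has no specifiable
gradient and raises.

**Phase-encoded analysis.** Both run directions are band-passed
(zero-phase Butterworth, order 3, 0.02–0.1 Hz; the 1/30 Hz stimulus cycle
sits in the passband with gain ≈ 1) and scaled to percent signal change
with the pre-filter voxel mean. The default lag estimator folds each run
onto a 0.2 s cycle-phase grid (the 1.4 s TR is incommensurate with the
30 s cycle, so successive cycles tile the grid) and circularly
cross-correlates the folded cycles; a parabolic refinement around the
peak gives sub-sample lags. A voxel preferring ladder step k responds at
2k s into the low-to-high progression and 2(8−k) s into the high-to-low
progression, so lag = 4k − 16 s and the shared hemodynamic delay cancels.
Inverting, `k = round((lag + 16)/4)`, with one subtlety: the ladder spans
lags ±16 s but a 30 s cycle folds lags into ±15 s, so the two extreme
steps alias across the wrap; the inversion therefore evaluates the three
cycle-unwrappings and keeps the one closest to an integer step. Swapping
the runs negates the lag and maps k to 8−k exactly.

Assigning a voxel requires its peak correlation to exceed a threshold
(default 0.2 — a configurable screening value, not an empirically
calibrated one). The cycle-averaged correlation is unsuitable for null
screening: after band-passing, a folded 30 s noise cycle retains only the
three cycle harmonics inside the band (~6 effective degrees of freedom),
so even pure-noise voxels show large peak circular correlations. The
full-series mode (`mode="full"`) keeps far more degrees of freedom and is
the mode of choice when rejection of untuned voxels matters; at the 0.2
default it leaves most null voxels unassigned, and a 0.9 threshold
removes essentially all of them. The tests exercise this separation
rather than a fixed null rejection rate.

## The synthetic cortex

The generator stands in for undeposited macaque data; its defaults are
the study conditions the pipeline is meant for.

**Geometry.** A flat 30 × 20 mm sheet (the superior temporal plane is
nearly planar at this scale; curvature is out of scope, which keeps
flattening exact and the gradient oracle analytic), triangulated at 1 mm,
embedded mid-plane in a 34 × 24 × 8 voxel grid of 1 mm voxels. The
parcellation is an idealised geometric layout — A1 central, R and RT
anterior, CL/ML/AL as a lateral belt strip, CM caudo-medial — not a
data-driven reversal detection; reversal detection remains testable
because the truth plants the reversals. Right-hemisphere sheets are exact
mirrors of left ones.

**Planted topographies.** Preferred AM rate is concentric:
`r(d) = 128·2^(−d/λ)` Hz clipped to [0.5, 128], d the distance from the
postero-medial corner, λ = 4 mm (chosen so the 8-octave rate range spans
the sheet). 512 Hz is deliberately outside the planted range — the
highest tested rate is barely represented. Preferred frequency is a
continuous piecewise-affine map: log2 f runs along a per-band axis within
each core band (A1: 345°, R: 165°, RT: 345°; slope 0.4 oct/mm around a
2.8 kHz mid frequency, clipped to 0.5–16 kHz), is continuous along the
anterior axis across band borders (where the gradient sign reverses,
producing the low- and high-frequency reversal borders), and extends
medio-laterally across the belt so iso-frequency contours cross field
borders without jumps. Continuity matters: an earlier per-field-anchored
construction placed value steps at field borders, and smoothing plus
sphere projection turned those steps into several degrees of systematic
direction bias inside A1.

With these defaults the fitted truth gradients in A1 are 345.0°
(frequency, exact — the map is affine there) and 233.6° (rate, the
field-centre bearing of the concentric centre), i.e. axes 165°/53.6°
(mod 180°) and a truth relative angle of 111.4°. The directions are
planted antipodally to the 165°/53° axis convention because, with the
high-rate centre postero-medial and contrast defined high − low, the A1
rate gradient necessarily points into the postero-medial quadrant; the
relative angle is invariant under the joint 180° flip.

**Signal model.** Neural tuning is Gaussian in log2(stimulus) with a
1.5-octave width (the study constrains no tuning model; 1.5 octaves puts
adjacent half-octave conditions well inside a tuning curve while keeping
the 6-rate conditions distinguishable). A stimulus volume takes the value
`baseline · (1 + a·G(condition)/100)` with baseline 100 and amplitude
a = 1 % — so the GLM's percent-unit betas equal `a·G` directly. Voxels
inherit tuning from the nearest vertex within 2 mm (guaranteeing the
1.6 mm projection sphere finds signal); farther voxels are pure baseline.
Noise is i.i.d. Gaussian, SD 6.7, optionally AR(1); SD 6.7 makes the
per-condition beta SE ≈ 1 for a single 45-volume-per-condition session,
i.e. per-condition SNR ≈ 1 — a calibration choice, not a measured fact.
The default dataset simulates the full pooled acquisition (7 rate
sessions = 315 volumes per stimulus, 3 frequency sessions = 360), which
is what the combined-session GLM sees.

Phase-encoded runs drive a per-voxel boxcar during the voxel's preferred
2 s block of each cycle (cycle 1 at t = 0; the trailing ~30 s of the
343-volume acquisition is silence; no lead-in discard by default),
convolve with a gamma kernel `(t/τ)^3·e^(3−t/τ)` peaking at the
hemodynamic delay (default 4 s; delay 0 degenerates to an identity for
timing tests), and sample at the 1.4 s TR.

**What the synthetic validation does not show.** The sheet is flat and
the parcellation exact, so flattening and field assignment contribute no
error here, while on real anatomy surface reconstruction and
reversal-based field delineation are major error sources. The noise is
white (no physiological 1/f, vascular structure, or motion), borders are
straight, and tuning is homogeneous; passing recovery tests therefore
demonstrates correctness of the estimation chain under the stated
generative model, not robustness to real-data artefacts.

## Problem sizes and tolerances

Parameter recovery runs the complete chain (simulate → smooth → scale →
GLM → mask → contrast → project → 2D regression) on the default dataset
for ten seeds; the recovered A1 relative angle is required to land within
10° of the planted 112° on average, with every fit's R² above 0.3. The
per-seed angle scatter (~10° SD) is dominated by contrast-map noise made
spatially coherent by smoothing and sphere projection — the effective
number of independent vertices in an 8 × 9 mm field is small. Phase
recovery is exercised noiselessly across hemodynamic delays {0, 2, 4, 6} s
and must be exact for all nine ladder steps. Estimators are checked
against independent oracles (explicit normal equations and F
distributions, statsmodels OLS) at 1e-8 relative tolerance; geometric
identities (isometry, rotation equivariance, angle folding) at 1e-9. The
omnibus F's type-I error is verified on 1000 pure-noise voxels at
0.05 ± 0.02. Degenerate inputs are defined, not accidental: constant maps
report a missing direction with R² 0, collinear fields and rank-deficient
designs raise with the offending columns named, zero-variance voxels are
untestable, and ties break deterministically toward the lower stimulus
value everywhere a vote or argmax occurs.
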