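# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `cereflow`. It is written for a reader who wants to know
exactly what the package computes and why, not just how to call it.

## Signal model

The time-resolved non-contrast MRA acquisition labels inflowing arterial
spins and images them over `n_frames = 12` frames at 60 ms per frame
(`AcquisitionSpec`). The frame axis is 1-based: frame 1 is the first
acquired frame, and all TTP values are reported on the 1..12 frame axis
(consistent with the cohort's printed per-patient TTPs of 3.73–10.18).
A vessel voxel's time course is modeled as a gamma-variate bolus curve

    s(t) = A · ((t − t0)/τ)^α · exp(−(t − t0)/τ),   t > t0,

the standard parametric shape for spin-labeled bolus passage, with analytic
mode (peak position) `t0 + α·τ`. The package never *fits* this parametric
form to data — it is the generating model of the synthetic phantoms and the
analytic oracle for tests; the analysis itself is nonparametric (spline
based), since real inflow curves need not be gamma-variates.

## Reference-curve estimation

### Why a reference curve

With 12 samples per voxel and realistic noise, a per-voxel argmax is
quantized to whole frames and noise-dominated. The method instead pools 250
randomly sampled vessel curves into one smooth, densely supported
*reference* inflow curve, and reads the global TTP off that. Per-voxel TTPs
are then obtained by registering the smooth reference to each voxel curve,
which transfers the sub-frame precision of the reference to single voxels.

### The alignment model

Curves are aligned with four-parameter linear transforms: time shift `b`
(frames), time scale `a` (dimensionless, positive), magnitude shift `m`
(intensity) and magnitude scale `s` (dimensionless, positive). Applying a
transform yields `c'(t) = s·c(a·t + b) + m`; a feature at time `p` of `c`
appears at `(p − b)/a` in `c'`. Composition and inversion follow from this
definition and are exercised by algebraic identity tests.

The least-squares fit of a moving curve onto a target proceeds as follows:

* The moving curve is evaluated off-grid by cubic B-spline interpolation of
  its 12 samples.
* Only target sample points whose warped coordinate `a·t + b` falls inside
  the moving curve's support [1, 12] enter the residual. A measured curve
  carries no information beyond its first and last frame; letting
  constant-extension values participate measurably distorts the fit. A warp
  that keeps fewer than half of the points (or fewer than 4) in support is
  inadmissible.
* For each candidate time warp `(a, b)`, the magnitude parameters have the
  closed-form ordinary-least-squares solution; a candidate whose best-fit
  magnitude scale is nonpositive (anti-correlated overlap) is inadmissible.
  This matters: clamping such scales to a small positive number instead
  produces enormous inverted transforms (`1/s`) that poison the averaging
  step.
* The time warp is found by a deterministic coarse-to-fine grid search over
  the bounded box (shift within ±n/2 frames, scale within [0.5, 2]): a full
  coarse grid (shift step 0.4 frames, 9 log-spaced scales, identity always
  included) followed by three zoom stages to a resolution of ~0.002 frames
  and ~0.2% in scale. One-off fits optionally finish with a bounded Powell
  polish; the batched inner loops rely on the grid alone, which keeps the
  O(n²) pairwise pass vectorizable (all 250 targets are fitted against one
  moving curve in a handful of array operations per stage).

The fit residual is the RMS over the in-support points. The search is
derivative-free and fully deterministic, so identical inputs give identical
transforms — a property the byte-identical report test relies on.

### The unbiased averaging step

One pairwise pass works as follows. Every curve `j` is fitted onto every
other curve `i`, giving `T(j→i)`. For each curve `c`, the fits of all other
curves *onto* `c` are inverted and averaged:

    M_c = mean{ invert(T(j→c)) : j ≠ c }

with arithmetic means for the two shifts and geometric means for the two
scales. Applying `M_c` to `c` moves it into the ensemble-mean frame: for a
shift-only ensemble with peaks `p_j`, the peak of the transformed `c` lands
exactly at the ensemble mean `p̄`, for every `c`. Geometric averaging of
scales is what makes a warp and its inverse cancel; arithmetic averaging
would bias the pooled peak. (The direction of this construction matters:
averaging `invert(T(c→j))` — the fits *of* `c`, inverted — reflects each
curve away from the mean frame instead of toward it. The implemented
direction is the one under which the average frame is a fixed point, which
is the meaning of "unbiased" here; under exact fit symmetry it equals the
mean of the forward fits of `c` onto the others.)

All transformed discrete samples are pooled into one point cloud, restricted
to the frame support [1, 12] (warped positions outside it describe no frame
the reference is defined on), and a least-squares cubic B-spline with 8
uniform interior knots is fitted. Subsequent iterations fit every curve to
the current reference (no pairwise pass) and refit the spline, stopping when
the reference TTP changes by < 1e-3 frames or after 10 iterations;
`max_iterations = 1` reproduces the plain single pass. In practice the TTP
is stable after the second iteration.

Degenerate inputs: flat (zero-variance) curves are dropped before
alignment; an all-flat ensemble raises a degenerate-input error; a single
curve yields its own interpolating-spline fit.

### What "unbiased" does and does not mean

The averaging construction is unbiased with respect to the *ensemble*: its
fixed point is the ensemble-mean frame. If the curves are generated by
warping one master curve with random transforms whose population mean is
the identity (mean shift 0, geometric-mean scale 1), the reference TTP is
an unbiased estimate of the master TTP, and the replicate-ensemble test
verifies this to within ±0.05 frames. If the scale distribution's geometric
mean differs from 1 the ensemble's own mean frame moves, and the reference
correctly follows it: scales drawn *uniformly* from [0.8, 1.25] have
geometric mean 1.0167, which displaces the target by ≈ −0.08 frames
relative to the master. This is a property of the ensemble, not an
estimator defect — the unbiasedness test therefore draws scales
log-uniformly (geometric mean exactly 1), while the 250-curve recovery
check uses plain uniform draws and the correspondingly wider 0.15-frame
band.

### Global and per-voxel TTP

The global TTP is the argmax of the smooth reference over its support,
located by a dense grid (2048 points) plus bounded scalar minimization;
maxima attained at a support endpoint are flagged (`at_boundary`), since a
boundary argmax usually means the bolus peak was not captured within the
acquisition window. Per-voxel TTP fits the *reference* (moving) to each
voxel curve (target) and maps the reference TTP through the recovered time
warp, clamped to [1, 12]. A voxel whose fit residual RMS exceeds
`0.5 × std(voxel curve)` is left undefined (NaN in the exported map): for a
noise-only voxel the best achievable residual is about the curve's own
standard deviation, so the threshold separates noise-dominated voxels
without per-dataset tuning.

### Numerical safeguards

`make_lsq_spline` does not verify the Schoenberg–Whitney conditions and can
return a silently exploding fit when a knot interval is data-sparse; the
cloud-spline fitter evaluates each candidate on a probe grid and rejects
fits whose magnitude exceeds 10× the data range, falling back to fewer
interior knots (and ultimately to an interpolating spline through the
averaged unique abscissae). The TTP argmax compares the refined interior
optimum against both support endpoints explicitly, so monotone references
report the correct boundary frame.

## Segmentation and sampling

The 4D series is reduced to a temporal maximum-intensity projection
(per-voxel max over frames), which is independent of arrival time. The
cerebrovascular segmentation on it is deliberately simple: threshold at the
99th percentile of the strictly-positive voxels (strictly greater;
zero-padded background excluded from the percentile), remove 26-connected
components smaller than 20 voxels, optionally apply a binary closing
(radius 0 = off by default). This replaces the multi-step segmentation
framework used in the original clinical pipeline: downstream, the
segmentation serves only as the voxel support for curve sampling and TTP
mapping, and on high-contrast MRA a percentile threshold recovers a bright
tube phantom completely (the noiseless-phantom test demands ≥ 95% recovery
with ≤ 5% false positives; the measured values are 100% and 0%). It is not
a clinical-grade segmenter; see Limitations.

Curve sampling draws exactly `min(250, mask size)` distinct voxels
uniformly without replacement from the mask, driven by a user-supplied seed
that is echoed in the analysis report — the study's random selection is
otherwise unreproducible. Uniform sampling over the mask is an assumption
(caliber-weighted sampling would be an alternative); the two-seed overlap
test checks the uniform hypergeometric behavior.

## SWI venous contrast

SWI is BOLD-sensitive: deoxygenated venous blood is dark, so vein
conspicuity on minimum-intensity projections tracks venous deoxyhemoglobin.
The minIP tiles the chosen axis into slabs (default 8 slices, axial — the
configurable default mirrors common reading practice) and takes the
per-pixel minimum in each slab; the last slab may be short. The ordinal
score is the four-row mapping (deep, cortical) →
{(no,no):1, (no,medium):2, (medium,good):3, (good,good):4}; combinations
off the table (e.g. visible deep veins without cortical veins) are rejected
with the legal pairs listed. The visual rating itself remains a radiologist
judgment: the package deliberately does **not** invent a quantitative
vein-contrast index, because no such computation exists in the study design
it implements — it encodes, validates and stores the manual scores.

## Cohort statistics

Conventions follow the study: two-tailed tests, significance threshold
P < 0.05, no multiple-testing correction, Pearson correlation applied
directly to the ordinal 1–4 score (no polyserial alternative), and pairwise
deletion of missing values — every statistic uses all records with the
required fields present, which is why per-variable n varies (13 etCO2
values, 36 TTP values, …). Missing values are explicit (`None`/NaN), never
zero-filled.

* **Pearson**: sample r; two-tailed p from the t distribution with n−2
  degrees of freedom (the standard approach; the tests cross-check r and p
  against a from-scratch formula/numeric-integration oracle).
* **Mann–Whitney U**: U from midranks; exact-distribution p when
  `n1·n2 ≤ 400` and the pooled data are tie-free, otherwise a normal
  approximation with tie correction and a *sign-aware* continuity
  correction (|U − μ| reduced by 0.5, floored at 0), so that identical
  groups give z = 0 and p = 1 rather than a spurious p < 1.
* **Summaries** use the sample SD (n−1); printed-style values are produced
  by decimal round-half-up at report time only, never inside computations.

`replicate_published_statistics` runs the full battery (all correlations, both
group splits, summaries, counts) and flags, at printed precision, which
published values the supplied table reproduces. Chemistry columns
(hemoglobin, hematocrit, creatinine, urea) live in the study's
supplementary table, which is not redistributable here; without a clinical
CSV those statistics are skipped with explicit messages rather than
silently dropped.

### Known discrepancies in the bundled table

The bundled fixture transcribes the study's demographics table verbatim.
Two printed prose values disagree with the table rows:

1. *MRI-normal count*: the prose says 19 of 36 normal; the table rows code
   20 patients as signal-change 0. With the verbatim 16/20 split the SWI
   score comparison gives group means 1.44 / 2.00 and a two-tailed
   Mann–Whitney p of 0.067 (0.064–0.095 across standard p-variants) — above
   the printed P = 0.04. A 17/19 split (one score-1 patient counted
   abnormal) reproduces the printed group means 1.41 / 2.05 exactly and
   gives p ≈ 0.034, so the printed significance almost certainly reflects
   the 19-normal grouping that the transcribed table cannot express. The
   package reports what the verbatim table yields and documents the gap
   rather than editing the data.
2. *Sex counts*: prose 26 female / 10 male; table rows 23 / 13. The fixture
   keeps the rows; tests assert the transcribed counts.

All other checked values (r(SWI, TTP) = 0.35 with P = 0.036, TTP
7.9 ± 1.4 frames range 3.7–10.2, etCO2 mean 30.9 over 13 values, 19
complete-loss / 33 low-contrast / 2 high-etCO2 patients) reproduce exactly
from the verbatim table.

## Synthetic data

`generate_phantom` emulates what the TTP pipeline needs from real data: a
bright tubular vessel (straight tube or Y-branch, radius 1.5 voxels in a
32³ grid) of gamma-variate curves (A = 100, t0 = 2, α = 3, τ = 1 → mode
offset 3 frames) with an affine arrival-time field along the vessel
(default 0 → 3 frames, so true voxel TTPs span 5–8), constant background
(level 1), and Gaussian noise of `0.05·A` (SNR 20; Rician optional — at
this SNR the difference is immaterial to TTP, and the Gaussian default
keeps the noise zero-mean). The tube occupies < 1% of the volume so the
99th-percentile segmentation threshold falls in the background tail.
Ground truth (mask, per-voxel TTP `t0 + δ(x) + α·τ`, and its vessel mean as
the global TTP) is returned exactly. What the phantom does *not* emulate:
partial-volume edges, vessel-caliber variation, pulsation/motion, spatially
correlated noise, and background tissue structure — so passing phantom
tests demonstrates the estimator's correctness under the stated model, not
clinical robustness.

`generate_cohort` draws hemoglobin as the driver (N(8.2, 1.4²) g/dL — the
anemic cohort's observed moments), links hematocrit (slope 2.89 %/(g/dL),
residual SD 1.5 → marginal SD ≈ 4.3, matching the observed 4.2) and TTP
(slope 0.35 frames/(g/dL), residual SD 1.31 → marginal ≈ 7.9 ± 1.4 and
r(Hb, TTP) ≈ 0.35) linearly, and thresholds a latent contrast variable
(0.5·z_Hb + 0.25·z_TTP + noise, unit variance) at cutpoints chosen so the
score marginal reproduces the observed 19/10/4/3 distribution over 36.
`link_for_correlation` converts a target correlation into slope and
residual SD. The returned truth dict carries the implied population
correlations for recovery tests. The generator does not model selection
effects, measurement error in chemistry, or the discreteness of clinical
timing.

## Problem sizes and runtimes

The O(n²) pairwise pass dominates: a 250-curve build is ~20 s on one core,
and the full 32³×12 phantom pipeline (segmentation + 250-curve reference +
288-voxel TTP map) runs in ~25 s. The test suite exercises the unbiasedness
property at 20 replicates × 40 curves and the end-to-end recovery at
10 seeds × 250 curves; the heavier single-ensemble checks (250 curves, the
spec sample size of the protocol) run once each. Null-calibration
simulations use 1000 replicates at the cohort's sample sizes (n = 36;
groups 16/20).

## Limitations

* The segmentation is a deliberate simplification; on clinical data with
  skull signal or inhomogeneous background it would need replacing (the
  module boundary accepts any `VesselMask`).
* TTP is reported in frames relative to the acquisition start; absolute
  bolus-arrival physiology (and CBF in mL/100g/min) is out of scope, as are
  OEF/CMRO2 — the study linked those only qualitatively.
* The 4-parameter transform assumes inflow curves differ by affine
  time/magnitude changes; dispersion (shape change along the vascular tree)
  is absorbed into the residual, which is why noise-dominated or strongly
  dispersed voxels are flagged undefined rather than forced into the map.
* The ordinal score is analyzed with Pearson correlation for fidelity to
  the study's statistics, not because it is the optimal choice for ordinal
  data.
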