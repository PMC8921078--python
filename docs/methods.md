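# Methods

This note documents the models, conventions, and design choices behind
`fractalperf`, in the order the pipeline applies them.

## Intensity calibration and the unit problem

The grayscale blanket fractal dimension is **not** invariant to amplitude
rescaling: the blanket grows by one height unit per lattice step, so the
ratio between texture relief and the height unit sets the estimator's
operating point. Raw scanner intensities carry an arbitrary affine scale,
so every series is first mapped to canonical units anchored on the internal
obturator muscle: its pre-contrast mean maps to 0 and its contrast-enhanced
mean (default: frames in the final quarter of the series, i.e. the plateau)
to 100 calibrated units. One calibrated unit is one blanket height step.

Consequences worth stating plainly:

* FD values, and therefore the grade cutoffs 2.20 / 2.31 / 2.40, are tied
  to this convention. Transferring the cutoffs to pipelines with different
  calibration targets (or no calibration) is not guaranteed to work.
* Downstream FD is exactly invariant to any affine transform of the raw
  series (tested to machine precision), because calibration removes it.

Noise is estimated as the sample standard deviation (ddof = 1) of muscle
voxels pooled over pre-contrast frames. Each analyzed frame is denoised
with an edge-preserving bilateral filter (scikit-image), range sd = 2σ and
spatial sd = 1.5 mm ≈ the in-plane resolution; σ = 0 bypasses the filter.
Both factors are exposed in `RunConfig`.

## Blanket fractal dimension

For image u₀ = b₀ = image, the surfaces evolve per scale ε as

    u_ε(p) = max( u_{ε−1}(p) + 1,  max_{q ∈ N(p)} u_{ε−1}(q) )
    b_ε(p) = min( b_{ε−1}(p) − 1,  min_{q ∈ N(p)} b_{ε−1}(q) )

with 4-connectivity by default (8-connectivity via config). The blanket
volume is v_ε = Σ_p (u_ε − b_ε) and the surface area A(ε) = (v_ε −
v_{ε−1}) / 2. FD = 2 − slope of the OLS fit of log A(ε) on log ε over the
scale set, default ε ∈ {1, 2, 3, 4} — small scales matched to the 3×3
local kernel and ~1.5 mm resolution. Estimates are clipped to the
embedding bounds [2, 3]; the raw slope and fit r² are kept as diagnostics.
Border pixels use truncated neighborhoods and truncated kernel windows (no
padding: padding would invent texture at the margins). Since each gap
increment is ≥ 2 per pixel, A(ε) > 0 always and the regression is well
defined; a defensive degenerate-texture error guards the log anyway.

The local FD map grows the blankets once on the full frame and aggregates
volume increments over a sliding kernel (default 3×3, truncated at
borders) with a vectorized per-pixel regression. It agrees exactly with a
naive per-pixel reimplementation (tested on ≤ 32² images).

### Canonical texture presentation

Because of the amplitude dependence, the estimator's reference behavior is
defined at two canonical presentations, both in calibrated units:

* **Self-affine textures** are presented at relief sd
  `CANONICAL_TEXTURE_SD = 30` (≈ 30% of the muscle-enhancement anchor).
  There, fractional Brownian surfaces read within ±0.15 of the theoretical
  3 − H for H ∈ {0.2, 0.5, 0.8}, strictly decreasing in H.
* **Uncorrelated noise** is presented at a lag-1 increment RMS of
  `CANONICAL_NOISE_INCREMENT_RMS = 2` height units — relief matching the
  blanket's two-sided growth per step — where it reads ≈ 2.5, the midpoint
  of the embedding range. At much larger relief any local surface-area
  estimator drives white noise toward 3; at much smaller relief toward 2.
  The half-response point is the principled place to pin the reference.

These two constants are estimator calibration, not free parameters; the
test suite asserts the reference values at exactly these presentations.

## Margin band

The hyperperfused core is segmented on a reference frame chosen as the one
where the lesion is most uniformly enhanced relative to background
(median of a 4 mm disk at the seed minus median of a 15–21 mm annulus,
minus the disk's median absolute deviation — the MAD term rejects frames
where the region is speckled rather than enhancing). Segmentation keeps
the connected component above `rel_threshold` (default 0.6) × the 99th
percentile of the seed neighborhood, holes filled. Slice selection mimics
the "paramedian slice with a large core depiction": the core is segmented
on every slice and the largest-area slice *excluding* the single largest
(central) one is used; a config override exists.

The band is the set of pixels within 1.5 mm of the core interface
(straddling: 1.5 mm inside + 1.5 mm outside; an outside-only variant is
selectable), intersected with the prostate, minus pixels whose nearest
boundary arc touches the capsule or leaves the prostate. Distances are
physical (mm, anisotropic spacing honored) and are measured to the
*interface* on an 8× upsampled grid: per-pixel EDT distances are quantized
to lattice gaps (1, √2, 2, …) and systematically overshoot the inter-pixel
interface, which biases a fixed-width band; the upsampled distance
reproduces the analytic annulus area within a few percent.

## FD time curve and FDmax

Every frame of the calibrated series is denoised, mapped to local FD, and
averaged over the band; FDmax is the maximum over frames (ties → earliest
frame, consistent with the first-pass physiology of peak margin chaos).
Frames failing FD computation are flagged and excluded. Motion adjustment,
when enabled, searches integer shifts within ±3 px maximizing the NCC of
the core neighborhood against the reference frame; a shift is accepted only
if its NCC reaches 0.7 and beats the unshifted NCC by 0.05 — frames without
trackable shared structure (pure noise, fully decorrelated texture) keep
the nominal band position rather than wandering.

## Grading and statistics

FDmax → pooled grade group via strictly-greater cutoffs (a value exactly at
a cutoff falls in the lower pool; the convention is config-exposed since
the boundary side is not fixed by the cutoffs themselves). ISUP groups 4
and 5 are merged (not separable by FD). ADC_25 is the 25th percentile
(linear interpolation between order statistics, numpy default) of the
hotspot ROI; values strictly below 905 ×10⁻⁶ mm²/s call groups 2–5.
Significance rules: `pirads_only` (≥ 4), `fd_only` (> 2.20), `adc_only`
(< 905), and the combinations `pirads_and_fd` (default; the AND raises
specificity while keeping sensitivity) and `pirads_or_fd`.

Statistics layer conventions, declared because the methods are not
otherwise pinned down: exact two-sided Clopper–Pearson binomial CIs
(statsmodels `proportion_confint(method="beta")`), report percentages
rounded half-up to integers with full precision retained; quadratic-
weighted κ by direct formula with a seeded nonparametric bootstrap CI
(2000 resamples); AUC by the rank (Mann–Whitney) estimator with midrank
ties, CI and paired comparison by DeLong's method; Youden-J cutoff with
ties resolved to the lower cutoff; Mann–Whitney tests exact where sample
sizes permit (scipy `method="auto"`), Bonferroni = multiply by the number
of pairwise comparisons, capped at 1; Bland–Altman limits = bias ±
1.96 × sd(differences, ddof = 1). Undefined statistics (zero denominators,
single-class cohorts) are reported as undefined, never as 0.

## Phantom generator

The phantom emulates exactly the features the pipeline consumes, on the
reference acquisition grid (1.5 × 1.5 mm in-plane, 4 mm slices, 46 frames
every 3.5 s ≈ 2:40 min):

* a spherical tumor core whose structural enhancement follows a first-pass
  gamma-variate (onset 10 s, peak 35 s) — the core is brightest and
  texture-free at its peak, where segmentation happens;
* a small sharp enhancement step at the core boundary (~3 calibrated
  units, adjacent tissue at 20% of core amplitude) plus a gentle logistic
  falloff far outside. Sharp makes the segmented border insensitive to the
  exact threshold; small keeps the FD footprint of the edge negligible. A
  tall edge would saturate any local surface-area estimator — this is a
  physical property of the method, and the reason the generator controls
  structural relief so tightly;
* margin texture: a fractional Brownian field with the spec's Hurst
  exponent, applied under a Gaussian envelope centered on the boundary and
  modulated by a *delayed* first-pass curve (onset 40 s, peak 90 s), so the
  margin FD peaks during the enhancement window and the segmentation frame
  stays texture-free. The field's local mean (Gaussian, σ = 4 px) is
  removed so that large-scale fBm drift does not masquerade as enhancement
  structure; the surviving fine-scale relief is deliberately not
  renormalized — smooth (high-H) margins keep their naturally small relief
  at analysis scales, which is what makes the pipeline's FDmax respond
  monotonically to H (measured: FDmax ≈ 2.77 → 2.26 for H 0.2 → 0.8,
  strictly decreasing per seed);
* a muscle reference box with slow mild enhancement (calibration gain 2
  by construction), Gaussian acquisition noise (sd 0.4 raw units), and an
  ADC map (background 1100 ± 50, hotspot 700 ± 50 ×10⁻⁶ mm²/s).

Identical specs regenerate bit-identical phantoms; all randomness flows
from the spec seed. The pseudo-grade labels derived from H bands
(H ≥ 0.70 → 1, ≥ 0.55 → 2, ≥ 0.40 → 3, else 4) are a testing construct
for end-to-end ordering checks, not a clinical claim.

**What the phantom does not emulate:** anatomy (shapes are spheres and
boxes), pharmacokinetics (no tracer-kinetic model), partial-volume and
motion artifacts (motion is injected synthetically in tests), coil
inhomogeneity, and — importantly — the amplitude relations of real tissue:
the structural enhancement is kept deliberately small relative to the
margin texture so that the margin FD isolates the texture signal. Passing
tests therefore demonstrate that the pipeline measures controlled texture
roughness correctly through all of its stages; they do not demonstrate
clinical accuracy, which requires the clinical cohort.

## Problem sizes and determinism

Default test/validation sizes: 96 × 96 × 3 voxel grids, 46 frames,
128² texture patches for estimator references, 5 seeds per condition,
two-arm cohorts of 10 + 10 lesions (~0.5 s per lesion end to end). The
full pipeline is deterministic given config and seeds; bootstrap and
phantom seeds are always explicit.

## Known limitations

* FD cutoff transfer across calibration conventions is untested by design
  (see the unit problem above).
* The original semi-automatic reader interactions (ROI fitting, motion
  editing, slice choice) are replaced by the declared deterministic
  surrogates; equivalence with any particular reader is not claimed.
* The blanket estimator is biased toward 2 at low relief and toward 3 near
  tall edges; comparisons are only meaningful within the canonical unit
  convention.
* 3D (volumetric) blanket dimension and alternative FD estimators
  (box-count, variogram) are out of scope except as test oracles.
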