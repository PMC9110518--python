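# Methods

This note documents the models implemented in `bonequant`, the
parameter choices that matter, what the synthetic phantoms do and do
not emulate, and the package's known limitations.

## SUV model

Voxel activity concentration `A` (Bq/mL) is mapped to a standardized
uptake value as `SUV = A / (administered activity / body weight) × 100`,
expressed in percent. Two assumptions are inherited deliberately and
not corrected:

* **no decay correction** — voxel values are used as reconstructed;
* **unit tissue density** — Bq/mL is divided by Bq/g as if 1 mL ≡ 1 g.

`compute_suv_map(..., percent=False)` drops the ×100 for a conventional
dimensionless SUV. Because the normalisation is a single voxelwise
scale factor, every control-normalised ratio (rSUVmax, rSUVmean, rTBU)
is identical whether computed on the activity volume or the SUV map;
this cancellation is asserted in the tests to 1e-10 relative.

## Histogram threshold rule

Given the voxels of a user-drawn target range:

1. histogram with `n_bins = 128` uniform bins over `[min, max]`
   (explicit `bin_edges` may be supplied instead, mainly for tests);
2. **mode** = center of the most frequent bin, ties broken toward the
   lower-value bin;
3. **base value**: `freq95` (default) scans from the modal bin toward
   higher values and takes the center of the first bin whose count has
   fallen to ≤ 95% of the modal count; `value95` instead takes
   0.95 × the modal bin center. Both are exposed because the wording
   of the workstation rule ("the pixel value reduced from the most
   frequent value to 95%") admits either reading;
4. **threshold** = base + `sd_multiplier` (default 0.5) × sample SD
   (ddof = 1) of the target-range voxels (`sd_scope="supra_base"`
   restricts the SD to voxels at/above the base value).

The supra-threshold test is closed (`≥`), which makes the
constant-valued target range well defined (threshold = that value).
The lesion VOI is the 26-connected supra-threshold component containing
the maximum-valued voxel of the target range (deterministic anchor;
`numpy.argmax` order breaks exact ties). No hole filling is applied, so
a cold necrotic core below threshold is excluded from the VOI. A target
range whose maximum is ≤ 0 raises an error rather than segmenting the
whole background at threshold 0.

Degenerate inputs: empty target range → error; single voxel → SD 0 and
threshold equal to that value; raising `sd_multiplier` can only shrink
the VOI (asserted as a monotonicity property).

## Metrics

`MBV = voxel count × voxel volume` counts whole voxels at/above
threshold — no partial-volume weighting, matching the "total volume
above the threshold" definition. `TBU = MBV × SUVmean` is therefore
additive over disjoint VOI splits. Ratios require a strictly positive
control SUVmean/SUVmax; a zero control is reported as an invalid
control VOI rather than an infinite ratio.

## Stage statistics

* **Kruskal–Wallis**: `H = 12/(N(N+1)) Σ nᵢ(R̄ᵢ − (N+1)/2)²` on
  midranks; tie correction `C = 1 − Σ(t³−t)/(N³−N)`; p from the χ²
  upper tail of `H/C` on k−1 df. All-identical data returns H = 0,
  p = 1. The implementation is cross-checked against
  `scipy.stats.kruskal` and against exact permutation enumeration.
* **Steel–Dwass** (Critchlow–Fligner form): for each pair, the
  rank-sum of the pair-only pooled sample is standardised by its
  tie-corrected null mean and variance, and `√2·|t|` is referred to
  the studentized-range distribution with k groups and infinite df
  (`scipy.stats.studentized_range`, which supports df = ∞). With k = 2
  this reduces exactly to the two-sided normal rank-sum approximation.
* **Permutation post hoc**: each draw independently re-randomises every
  pair's pooled sample between its two groups; the reference
  distribution is the max over pairs of |t*|. This keeps each pair's
  marginal null exactly the finite two-sample split distribution (so
  for 3-vs-3 no adjusted p can drop below the enumerable minimum 0.1)
  and is deliberately conservative relative to the asymptotic referral
  at moderate p. The seed is a required argument; ≥ 10,000 draws are
  enforced.
* **Summaries**: median and IQR use linear interpolation between order
  statistics (`numpy.percentile` default), so printed IQRs are
  comparable to other software only up to that convention.
* Two-sided tests, α = 0.05; no multiplicity adjustment across
  metrics. Groups of size < 2 produce a warning and an
  `unreliable` flag instead of an error, mirroring the tiny stage
  sizes (3 and 4) such clinical series contain.

### Small-sample calibration

At total N ≈ 9–10 the χ² tail tracks the exact permutation law well in
the rejection tail (|Δp| ≈ 0.02 at the separated three-triplet fixture)
but deviates by up to ~0.09 for tied or mid-p data (median |Δp| ≈ 0.04
over random fixtures). The unit tests assert this envelope (0.05 in the
tail, 0.12 at mid-p); a simulated type-I error at group sizes
(3, 16, 4) stays ≤ 7% at α = 0.05 over 2,000 null replicates.

## Digital phantoms

Phantoms emulate *reconstructed, SUV-scaled* volumes, not raw
projections: no attenuation, scatter, collimator or reconstruction
modelling. Components and defaults:

| parameter | default | meaning |
| --- | --- | --- |
| grid / spacing | 128×128×64 at 3.90 mm isotropic | scanner matrix and voxel size |
| background SUV | 1.0 | unaffected jaw-bone uptake level (arbitrary scale; only ratios matter) |
| lesion | ellipsoid, uniform uptake | optional inner cold core (fraction of semi-axes) at background level |
| blur | 8 mm FWHM Gaussian, world units | stands in for total system + reconstruction smoothing |
| noise | none / Poisson(value×scale)/scale | scale 100 ≈ moderate count density |

Blur uses `scipy.ndimage.gaussian_filter` with normalised kernels and
nearest-edge handling, so total intensity is conserved to < 0.5% for
interior lesions (asserted). All randomness flows from one top-level
seed through per-lesion `SeedSequence` substreams, making every
replicate individually reproducible.

**Cohort generator** (study conditions): stage lesion counts (3, 16, 4);
per-stage MBV log-normal medians 8.28 / 15.28 / 34.61 cm³ with
log-sigma 0.4 (chosen so simulated IQRs bracket the magnitude of the
clinical IQRs); lesion-to-background uptake ratios log-normal with
stage-independent medians 4.93 / 5.03 / 4.89 and log-sigma 0.3 (set
from the stage-1 ratio IQR, log(5.90/3.90)/(2×0.674) ≈ 0.31). Each MBV
draw becomes a sphere-equivalent lesion in a compact 48³ single-lesion
grid with a 10-mm control sphere placed 65 mm away, outside the blur
tail — a problem size chosen so whole-cohort replicates run in under a
second without changing any physics at the lesion scale. The recovery
harness draws the target-range box at 1.25 × the lesion semi-axes, a
snug clinician-style box fixed once during oracle calibration: a tight
(1.0×) box lets the histogram mode flip to the lesion plateau, pushing
the freq95 base above the maximum and emptying the VOI.

### What passing tests do and do not show

The phantoms share the clinical data's sampling structure and
first-order imaging physics (resolution blur, counting noise) but not
mandible anatomy, heterogeneous bone background, patient motion or
reconstruction artefacts. Passing recovery and power tests therefore
demonstrate the *pipeline's* correctness and the statistical
detectability of volume effects of the stated size under idealised
imaging — not clinical accuracy of the threshold rule on real jaws.

## Partial-volume behaviour of the threshold rule (known limitation)

With the default rule the threshold lands at
`≈ background + 0.5 × SD(target range)`, i.e. at most ~25% of the
lesion-to-background contrast (the SD of a bounded two-level mix cannot
exceed half the contrast). Volume-preserving segmentation of an object
smoothed with an 8-mm-FWHM Gaussian requires a threshold near the
*half-maximum* of the edge profile; a threshold at the 15–25% level
crosses the blurred edge ~2–3 mm outside the true surface regardless
of contrast. For spheres this inflates recovered MBV by roughly +90% at
8 cm³, +50% at 15 cm³ and +45% at 35 cm³ (blur-free recovery is exact,
and recovery degrades smoothly with noise). The bias is monotone in
lesion size, so rank-based stage comparisons survive it: Spearman
correlation between true and recovered MBV is ≈ 0.98, and the
Kruskal–Wallis test on recovered MBV detects the stage-separated
medians in ~97% of 200 replicate cohorts at the study's sample sizes,
while recovered rSUVmean (stage-independent truth) rejects at ~7.5%,
near the nominal 5% — slightly elevated because partial-volume dilution
of SUVmean couples weakly to the stage-dependent lesion sizes.
Absolute MBV from this rule should be treated as a consistently scaled
surrogate, not a physical volume.

## Other design choices

* World-coordinate (mm, voxel-center) geometry everywhere; regions are
  resolution-independent; boxes are world-axis aligned.
* On-disk volumes are NIfTI-2 (nibabel), whose float64 affine
  round-trips geometry exactly; NIfTI-1 is read transparently. DICOM
  import is out of scope.
* Negative voxels are clamped to zero at ingestion with the clamp
  count logged and stored on the volume.
* Geometry comparisons use a 1e-4 mm absolute tolerance on spacing and
  origin.
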