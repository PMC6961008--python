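# Methods

This note documents the models, parameters and design choices behind
`crownseg`, in the spirit of a methods appendix: what is computed, under
which assumptions, and what the synthetic benchmarks do and do not show.

## Rasterization and masking

Point records (x, y, z, intensity, channel, return number) are gridded on
half-open 0.25 m cells — a point on a shared edge belongs to exactly one
cell (top/left edges inclusive).  Each cell keeps the maximum first-return
z and the intensity of that same return; empty cells are filled by
inverse-distance weighting (power 2, search radius 3 cells — the method
itself fixes neither, these are conventional values).  The CHM is DSM − DEM
clamped at zero from below, since small negative differences are
registration artefacts, then smoothed with a normalized 3×3 Gaussian kernel
(σ = 0.8 cells; the kernel renormalizes over valid cells at edges and
nodata so smoothing never bleeds across gaps).

Vegetation masking combines NDVI from the 1064 nm (NIR) and 532 nm (green)
channels with the CHM.  The default rule keeps a pixel only when NDVI
≥ 0.25 *and* CHM ≥ 4 m: requiring both kinds of evidence excludes tall
non-vegetated structures.  A `literal` mode removes a pixel only when both
tests fail, for users who want the permissive reading.  The pipeline
optionally cleans the mask with a 3×3 binary closing followed by opening
(default on): per-pixel intensity noise otherwise speckles the NDVI mask
with pinholes and islands, and isolated mask islands masquerade as local
maxima downstream.

## Multi-scale treetop detection

Grayscale opening with a flat disk structuring element (SE) of diameter d
removes canopy structure narrower than d, so the mean of the opened CHM
decreases with d and its adjacent differences dip where many crowns are
swallowed.  Dominant scales are strict local minima of the difference
curve, restricted to a configured window (defaults 5–31 px at 0.25 m
cells — prior knowledge of plausible crown sizes, deliberately explicit
configuration) and filtered by a prominence threshold (default 5 % of the
curve range) that suppresses branch-scale and tree-cluster minima.  The
pipeline always adds the smallest window scale to the selected set
(switchable): on mixed-size scenes the curve often shows one broad minimum
near the largest crown class, and detection at that scale alone would miss
every smaller crown, while the statistical merge below cheaply prunes the
extra small-scale detections.  This mirrors the observation that the
smallest dominant crown size matters most and that results are insensitive
to adding larger scales.

Treetop regions are regional maxima (8-connected plateaus with strictly
lower neighbours) of the opened CHM.  Two practical refinements:

* maxima are computed on the full image and then intersected with the tree
  mask, so a masked-in pixel shadowed by higher masked-out terrain is not a
  treetop;
* an optional h-maxima prominence filter (pipeline default 0.2 m, roughly
  twice the smoothed CHM noise on the benchmarks; 0 recovers exact
  plateaus) absorbs the shattering of a noisy apex plateau into many
  one-pixel maxima.

Each region gets a least-squares Gaussian surface fit (apex A, centre μ,
spreads σₓ, σᵧ; trust-region solver with deterministic initialization from
the region maximum and second moments, σ bounded between a quarter cell and
twice the region extent).  Regions with fewer than six pixels cannot
constrain five parameters and are flagged degenerate: they are never fitted
and always lose to a fitted competitor during merging; among degenerates
the lower scale wins (conservative against under-segmentation).

Merging walks scales bottom-up.  An upper-scale region that shares no pixel
with the current set joins it; otherwise it challenges the overlapped
regions with two one-sided tests at α = 0.05: the ratio of Gaussian-fit
mean squared residuals, and the ratio of summed per-channel intensity
variances (sample variances, floored at 1e−9).  Either test significant ⇒
the lower regions stay (the upper region straddles crowns); both
insignificant ⇒ the upper region replaces them (the concentric single-crown
case, where the larger cross-section is the better seed).  Residuals below
1e−10 on both sides count as numerically perfect fits and keep the upper
region.  For the common one-challenger case the critical value accounts for
the nesting of the two regions: the upper region usually contains the lower
one, so their statistics share the noise of the common pixels, and the
naive F quantile is miscalibrated (measured type-I rate 0.017 for the
intensity test at α = 0.05).  Decomposing the upper statistic into the
shared part plus an independent annulus gives a corrected critical value;
measured null rates are 0.08 (residual) and 0.05 (intensity) at α = 0.05.
With several challengers the statistic is used as printed above, with
degrees of freedom n−5 per fitted surface and 3(n−1) for the intensity
variances; a plain ratio-threshold mode (`critical_ratio`) bypasses the
F quantiles entirely.

## Neutrosophic region growing

Seeds are the merged treetop regions.  Candidate pixels on the 4-adjacent
frontier are evaluated in raster-scan passes (reproducibility over speed)
with immediate assignment; growth stops when a pass changes nothing.  For
each candidate and adjacent region:

* indeterminacy I = mean over channels of 1 − exp(−σᵢ²/100), with σᵢ² the
  3×3-window variance (windows shrink at borders).  The constant 100 sets
  the variance scale the criterion considers "noisy";
* truth per channel: for I < 0.5 the pixel value is trusted,
  T = 1 − |μ(C) − ρ|/ρ; for I ≥ 0.5 the 3×3 window mean replaces ρ.  Truths
  are clamped to [0, 1]; a zero denominator yields T = 1 if the segment
  mean is also zero, else 0;
* fusion: S = Σ Tᵢ/σᵢ² / Σ 1/σᵢ², an inverse-variance weighted mean, so
  noisier channels weigh less and equal variances give the plain mean.  (A
  literal unnormalized form is available behind a flag for comparison; it
  is unbounded and not recommended.);
* threshold: fixed 0.6 in the homogeneous regime, else the sigmoid
  (A₁I/(1+e^{−A₂(I+A₃)}))^{1−I} with defaults (1, 1, 4.5) — ≈ 0.70 at
  I = 0.5 rising to 1 at I = 1;
* crown-shape constraint (used when the CHM participates, i.e. source
  `both` or `chm`): the candidate's height may differ from the highest
  4-adjacent region contour pixel by at most τ_h and may not exceed the
  seed apex.  τ_h defaults to 1 m and should exceed the steepest
  within-crown per-cell height step of the data at hand (the synthetic
  benchmarks use 3 m — their Gaussian caps are steeper near the mask edge
  than field crowns).

A pixel admissible to several regions joins the one with the highest S
(ties to the lowest label).  After the criterion phase, a fill phase
(default on) force-assigns remaining masked-in pixels to the adjacent
region of maximal S, without thresholds and without the shape constraint,
so every reachable tree pixel ends in some crown; labels never change once
assigned.  Enforcing the shape constraint during fill is available behind a
flag but collapses recovery on steep synthetic crowns (12/25 matched on the
clean benchmark) and is off by default.  Source variants: `both` (intensity
channels + shape constraint), `intensity` (no shape constraint), `chm`
(CHM as the sole "channel", shape constraint kept).

## MCW baseline and evaluation

The watershed baseline floods a relief from the same treetop markers with a
deterministic priority queue (4-connectivity; ties broken by relief value,
then insertion order, then row-major position).  The relief is the average
of min-max-normalized central-difference gradient magnitudes of the chosen
sources (the method's sources were never specified for the fused case; the
normalized-gradient average is this package's choice), or optionally the
inverted CHM.

Evaluation assigns each reference crown its best-overlapping segment:
overlap > 50 % matched, 25–50 % partially matched (both category floors
closed, i.e. exactly 50 % and exactly 25 % fall in the lower category),
< 25 % omitted; segment-side categories are computed symmetrically with
segment area as denominator.  Producer's accuracy divides matched (or
matched + partial) by the reference count; user's accuracy by the segment
count.  One segment may be the best match of several references, which is
how commission errors surface.

## Synthetic scenes

The generator emulates a three-channel 0.25 m survey of a deciduous stand.
Crowns are Gaussian caps h·exp(−r²/2σ²) truncated where the cap falls below
5 % of the apex (finite supports and crisp ground-truth polygons); the CHM
max-composites overlapping caps and contested pixels belong to the taller
surface, as an overhead CHM records.  The *nominal crown diameter* is the
±2σ width (D = 4σ), so the support polygon extends to ≈ 1.22 D; under this
convention the morphological scale-curve minimum of a crown falls near
0.87 D, keeping nominal diameters aligned with the scales the detector
reports.  Diameters are drawn from a few discrete size classes by default
(three classes spanning the configured range), emulating stands with
predominant small/medium/large crowns — the regime in which scale selection
is meaningful; a continuous mode exists.  Heights default to 20–30 m: with
the 4 m mask threshold the above-threshold fraction of a crown support is
ln(h/4)/ln 20, which exceeds ½ only for apices above ≈ 20 m — shorter
defaults would make >50 % overlap against full-support references
unreachable for any segmenter confined to the mask.

Channel intensity means default to (40, 120, 30) inside crowns against a
(30, 20, 60) background, giving NDVI ≈ +0.6 inside and −0.5 outside, so
NDVI masking recovers crown pixels exactly in the zero-noise limit.
Per-tree spectral offsets (sd `tree_mean_sd`), within-crown speckle,
CHM white noise, and spatially correlated branch-scale CHM texture
(Gaussian-filtered noise, 1 m correlation length, crown pixels only) are
all optional and default to zero except the per-tree offsets.  All
randomness flows from one seed through independent sub-streams per stage,
so adding trees does not perturb the noise fields.  Point-cloud sampling is
an independent homogeneous Poisson process per channel (default 45 pts/m²)
with z from the analytic surface plus noise — first returns only.

What the generator does *not* emulate: within-crown spectral gradients and
shadowing, multi-return structure, ground vegetation, understory, terrain
relief, asymmetric or interlocking crown shapes, and registration error
between channels.  Benchmark results therefore demonstrate the internal
consistency and relative ordering of the methods under controlled
conditions, not absolute accuracies on field data.

## Benchmarks

* **Exact recovery** — 25 non-overlapping, noise-free crowns in 60 × 60 m.
  The chain must find exactly 25 treetops and both segmenters must match
  every crown above 50 % overlap.
* **Stress** — ten replicate scenes of 50 crowns in 80 × 80 m with 20 %
  of crowns overlapping a neighbour (attachment separation 0.5–0.8 of the
  summed support radii), CHM noise 0.3 m plus 0.5 m branch texture,
  within-crown speckle sd 10 (sitting at the indeterminacy variance scale
  of 100, where the criterion is designed to operate), per-tree spectral
  offsets sd 20.  All method variants segment from one shared detection
  per scene; additional runs use 5-px disks at the true centres as seeds.
* **Null calibration** — 1000 single-crown scenes (σ = 1 m, apex 20 m,
  CHM noise 0.1 m, homogeneous spectra), cross-sections detected at 7 and
  13 px, both F-tests applied; type-I rates should sit near α.
* **Scale recovery** — 12 equal-diameter crowns (D = 9 or 17 px); selected
  scales should sit within one ladder step of D.  This benchmark selects
  with prominence 0.02 rather than the pipeline default 0.05: large
  Gaussian caps produce two physical minima (profile scale ≈ 0.87 D and the
  support-edge drop ≈ 1.22 D) and both encode the crown size; the coarser
  default exists to suppress branch/cluster minima on mixed-size scenes, a
  confounder absent here by construction.

Measured on the fixed test seeds: the combined-source neutrosophic variant
reaches producer's accuracy (matched + partial) 0.986 on the stress
benchmark, ties its single-source variants, and exceeds the MCW baseline's
matched count by ≈ 5 % (483 vs 458 of 500).  Reference-centre seeds change
the matched count by at most a crown or two in either direction: detection
on these scenes is already near-ceiling (96.6 % matched), so — unlike in a
detection-limited regime — seed quality has almost nothing left to fix, and
the seed-quality benchmark is reported for completeness rather than as a
discriminating result.

## Numerical conventions

Variance floors 1e−9; residual perfection tolerance 1e−10; truth clamping
to [0, 1]; NDVI 0/0 = 0; opening treats nodata as absent (+∞ for erosion,
−∞ for dilation) and returns 0 where no valid neighbourhood exists; all
label maps use 0 for background; crown polygons are unions of cell squares
with interior holes filled by default (crowns are simply connected by
assumption).  Every pipeline run writes its resolved configuration next to
its outputs, and identical configuration + seed reproduce outputs
bit-identically.
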