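# crownseg

Individual tree crown (ITC) delineation from multispectral airborne LiDAR
rasters.

Accurate crown outlines are the starting point of individual-tree analysis —
species classification, growth monitoring, biomass estimation.  On a canopy
height model (CHM) alone, neighbouring deciduous crowns blur together; on
intensity imagery alone, treetops are hard to localize.  `crownseg`
implements a delineation chain that uses both: the CHM drives treetop
detection and a crown-shape constraint, while per-channel LiDAR intensities
(three wavelengths, emulating a 1550/1064/532 nm sensor) drive the region
merging that draws boundaries between adjacent crowns.  It is aimed at
remote-sensing researchers who want a complete, reproducible reference
implementation they can run end-to-end on synthetic scenes or on their own
rasters.

## Method

1. **Preprocessing** — first returns are rasterized at 0.25 m cells (cell
   maximum of z, with that return's intensity), empty cells filled by
   inverse-distance weighting, CHM = DSM − DEM smoothed with a 3×3 Gaussian.
   Non-tree pixels are masked using NDVI = (I₁₀₆₄ − I₅₃₂)/(I₁₀₆₄ + I₅₃₂)
   < 0.25 and CHM < 4 m.
2. **Multi-scale treetop detection** — grayscale opening with disk
   structuring elements of odd diameters d = 3, 5, …; the mean opened-CHM
   differences over d locate the dominant crown scales.  Regional maxima of
   the opened CHM at each scale are crown cross-sections.  For each region a
   Gaussian crown surface

   G(x, y) = A·exp(−((x−μₓ)²/2σₓ² + (y−μᵧ)²/2σᵧ²))

   is fitted by least squares.  Regions detected at adjacent scales are
   reconciled by two one-sided F-tests at α = 0.05 — on the fitted mean
   squared residuals ε² = (1/n)Σⱼ(CHM(xⱼ,yⱼ) − G(xⱼ,yⱼ))², and on summed
   per-channel intensity variances.  A significant test means the upper
   (larger-scale) region straddles several crowns and the lower-scale
   regions are kept; otherwise the upper region replaces them.
3. **Neutrosophic seeded region growing** — crowns grow from the treetop
   regions.  For a candidate pixel, the indeterminacy
   I = (1/n)Σᵢ(1 − exp(−σᵢ²/100)) over a 3×3 window gates the evidence: for
   I < 0.5 the pixel truth Tᵢ = 1 − |μ(C)ᵢ − ρᵢ|/ρᵢ is compared to 0.6; for
   I ≥ 0.5 the window-mean truth is compared to a sigmoid threshold
   (A₁·I/(1+e^{−A₂(I+A₃)}))^{1−I} with (A₁, A₂, A₃) = (1, 1, 4.5).  Truths
   are fused across channels by an inverse-variance weighted mean.  A
   crown-shape constraint on the CHM additionally rejects pixels whose
   height jumps more than τ_h relative to the region contour or exceeds the
   seed apex.
4. **Baseline & evaluation** — a marker-controlled watershed (MCW) flooded
   from the same treetops over a fused gradient relief serves as the
   comparison method.  Delineations are scored against reference crowns by
   Overlap = 100·|segment ∩ reference|/|reference|: matched (> 50 %),
   partially matched (25–50 %), omitted (< 25 %), summarized as producer's
   and user's accuracies.

A synthetic-scene generator (truncated Gaussian-cap crowns, vegetation-like
channel spectra, optional noise, branch-scale canopy texture, and exported
ground truth) provides reproducible study conditions; see
`docs/methods.md`.

## Worked example

Simulate a clean 25-crown scene and run the full chain:

```bash
crownseg simulate --seed 7 --out demo/scene
crownseg run-all --scene demo/scene --seed 7 --out demo/run
```

which prints (abridged):

```
neutrosophic: {"reference_matched": 25, "reference_partial": 0,
               "reference_omitted": 0, "producer_acc_matched": 1.0, ...}
mcw:          {"reference_matched": 25, "reference_partial": 0,
               "reference_omitted": 0, "producer_acc_matched": 1.0, ...}
```

and `demo/run/scales.json` contains `{"scales": [5, 25]}`.  Reading: the
scale analysis found the dominant crown scale at 25 px (≈ 6 m crowns; the
smallest configured scale is always kept so small crowns cannot be missed),
all 25 planted crowns were recovered as treetops, and on this noise-free
scene both the neutrosophic growing and the watershed baseline delineate
every crown at more than 50 % overlap with the ground truth
(`reference_matched: 25`, producer's accuracy 1.0).  The run directory also
holds the resolved configuration, the smoothed CHM and tree mask, the scale
curve CSV, fitted treetop centres (GeoJSON), crown label maps (TIFF) and
crown polygons (GeoJSON).

The same pipeline is available as a library:

```python
from crownseg import PipelineConfig, run_pipeline, generate_scene, SyntheticSceneSpec

scene, truth = generate_scene(SyntheticSceneSpec(n_trees=25, rng_seed=7))
result = run_pipeline(PipelineConfig(), scene, truth)
print(result.reports["neutrosophic"].to_dict())
```

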