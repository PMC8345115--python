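# Methods

This note records the models behind each analysis, the parameters that
matter, what the synthetic-data generators do and do not emulate, and the
numerical choices made where the design was genuinely open. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Coordinates, ROIs and boundary conventions

Localisation tables use continuous nm coordinates, origin at the image
top-left, x rightward, y downward (the convention of common localisation
software). ROI polygons are simple polygons in nm, implicitly closed.
Points exactly on a polygon edge or vertex count as **inside**: dropping
boundary localisations silently would bias counts, and the inclusive
convention makes `filter_by_roi` idempotent. CSV column matching is exact
after whitespace trimming; other dialects are handled by a user-supplied
header map rather than guessing.

## Density binning

Events are assigned to half-open square bins `[k·b, (k+1)·b)` (default
`b = 50 nm`) on a grid anchored at the fixed origin `(0, 0)` — anchoring at
the data bounding box would make per-bin indices depend on outliers, and
the summary statistics of interest are origin-insensitive. A point on a bin
edge belongs to the higher-index bin.

The count distribution is taken **over occupied bins only** (count ≥ 1).
Two reasons: a log-scaled count axis cannot represent empty bins, and the
diagnostic statement "most bins hold a single event" is only meaningful
relative to occupied bins. Quantiles use linear interpolation between order
statistics (the common box-plot convention); whiskers sit at the most
extreme data points within `q1 − 1.5·IQR` and `q3 + 1.5·IQR`; everything
outside is an outlier. Replicates are pooled by concatenating their
occupied-bin count multisets before summarising.

## Equal-area radial rings

The ring construction scales the ROI contour about its **area centroid**
with factors `s_k = sqrt(k/n)` (default `n = 6`). Because a scaled copy has
area `s²·A`, consecutive contours enclose exactly `A/n` — *provided the
scaled copies nest*, which holds exactly when the polygon is star-shaped
about its centroid. Star-shapedness is tested exactly (the centroid must
lie in the kernel, i.e. on the inner side of every edge); non-star-shaped
polygons are processed with a `RingWarning` since real nuclear contours are
near-convex, but their ring areas are then only approximate. A
distance-transform erosion construction was considered and rejected: it
does not produce equal areas without an iterative search per nucleus.

Ring membership uses the **containment scale**: for point `p`, the ray from
the centroid through `p` meets the boundary at parameter `t` (`p` sits at
`t = 1`), so the smallest containing contour has `s* = 1/t`. A point exactly
on the `s_k` contour belongs to ring `k`; a point on the ROI boundary
belongs to ring `n`. Densities are counts divided by the ring area
`A/n` converted to µm² (1 µm² = 10⁶ nm²); the per-pixel alternative is a
constant factor away and not reported.

## Confocal chromatin compaction

Per nucleus crop (one nucleus per crop; the largest thresholded component
wins):

1. **Nucleus mask** — Gaussian smoothing (`smoothing_sigma_px`, default 1),
   global Otsu threshold, largest connected component, holes filled. A
   two-class Otsu fails on nuclei whose internal domain contrast exceeds
   the nucleus-background contrast (it segments the domains); this is
   detected by comparing against the lowest threshold of a 3-class split —
   if the Otsu mask covers less than 80% of the 3-class mask, the image is
   treated as trimodal and the lower threshold is used. On genuinely
   bimodal images the plain Otsu cut is kept because it crosses the blurred
   edge at its midpoint and therefore recovers object area accurately.
2. **Domain maxima** — h-maxima (topographic prominence ≥
   `prominence_fraction` × in-mask intensity range, default 10%) of the
   smoothed image, with peaks closer than `min_separation_px` (default 3)
   merged keeping the brighter. The range and the peaks are evaluated on
   the mask eroded by the smoothing support (3σ): smoothing creates an
   intensity ramp along the nuclear rim that would otherwise register as
   structure. Residual in-mask variation below 1% of the in-mask level is
   treated as flat (zero domains). The defaults recover planted blobs
   exactly at SNR ≥ 5 and are config-exposed.
3. **Domain growth** — marker-based watershed of the inverted smoothed
   image seeded at the maxima, each region clipped to pixels with raw
   intensity ≥ `b + level_fraction·(I_peak − b)` (default `level_fraction
   = 0.5`). The background level `b` is a robust minimum: the 1st
   percentile (`background_quantile`) of in-nucleus intensity. The median
   was considered and rejected — in a nucleus that is more than half
   compact the median *is* the domain level, which collapses the growth
   threshold onto the peak and makes high compaction fractions
   unrecoverable. With the robust minimum, the rule reduces to the
   half-maximum contour for an isolated peak on a flat background and
   remains correct across the whole 5–96% compaction range seen in
   practice.
4. **Summary** — `compact_percent = 100 · domain_area / nucleus_area`;
   `dark_area = nucleus_area − domain_area` (exact in pixel units). All
   thresholds are relative, so the whole analysis is invariant to a global
   intensity rescaling.

Cohort distributions are summarised as **mode ± SD**: the mode is the
centre of the tallest Freedman–Diaconis histogram bin (ties break toward
the lowest bin; a KDE mode was rejected to avoid bandwidth tuning), the SD
is the sample standard deviation (n−1). The summary also reports the
number of prominent histogram peaks (prominence ≥ ¼ of the tallest bin);
two or more peaks flag a multimodal cohort for which a single central
value should not be quoted. Note the tallest-bin mode estimator of a
finite sample is only pinned to within about two bin widths.

## miRNA-FISH quantification

Nuclei are Otsu-thresholded on the smoothed nuclear-dye channel, split by a
distance-transform watershed, and size-filtered (`min_nucleus_area_um2`).
Each cell's cytoplasm is its nucleus dilated by `cytoplasm_width_px`
(default 5; the width is a modelling choice, config-exposed) minus **all**
nuclei, with contested pixels assigned to the nearest nucleus — cytoplasm
regions are therefore pairwise disjoint and disjoint from every nucleus.

The per-cell readout is the **mean** miR-channel intensity over the
cytoplasm on the 0–255 (8-bit) scale, the statistic high-content screening
software reports for regions; the maximum is selectable. A cell is miR⁺
when this value is **≥ 5** — the threshold is inclusive, chosen because
scrambled-probe controls stay below 5, and of the two phrasings in
circulation ("above or higher" vs "equal to or higher") the inclusive one
is the operational definition. Optional background subtraction (scalar or
image, clipped at 0) is applied before classification.

Group comparisons use a one-sided unpaired Wilcoxon rank-sum (Mann–Whitney
U from midranks). With no ties and a combined sample ≤ 12 the p-value is
exact by enumeration of all C(n+m, n) labellings; otherwise a normal
approximation with tie correction and a 0.5 continuity correction is used.
Significance is declared at p ≤ 0.05. `scipy.stats.mannwhitneyu` is used
in the test suite as an independent cross-check, never as the
implementation.

## Rendering and line profiles

The reconstruction stand-in is a plain 2-D count histogram (default 20 nm
pixels, half-open footprints): parameter-free and count-conserving
(`Σ pixels = rendered events`); a Gaussian-blurred variant is available for
visual parity with typical SMLM viewers. The widefield comparator renders
the same events at 100 nm camera pixels and blurs with a Gaussian PSF of
σ = 110 nm (≈ diffraction-limited; the pixel size is the camera's, the PSF
width is this package's stated choice). Line profiles sample by bilinear
interpolation at uniform steps with both endpoints included, so swapping
endpoints exactly reverses the series. The contrast statistic is the ratio
of `(max − min)/mean` between reconstruction and widefield profiles after
unit-mean normalisation; values > 1 mean the reconstruction resolves
density excursions the widefield image smooths away.

## Synthetic data: what is emulated, and what is not

**Localisation tables.** Chromatin is modelled as `n_clusters` Gaussian
nanoclusters (σ default 25 nm, i.e. FWHM ≈ 59 nm, inside the 50–60 nm
cluster-diameter range reported for dense chromatin domains) over a uniform
background fraction inside a star-shaped contour. Cluster points falling
outside the contour are redrawn (rejection), keeping the total count exact;
cluster occupancies are equal up to a randomly placed remainder, so the
planted per-cluster count is sharp. Cluster centres follow a radial law
with weight ∝ s^γ in the containment scale s; because the angular part of
a uniform draw in the polygon is independent of its containment scale, a
uniform point can be rescaled radially to the target law without shape
bias, giving the exact closed-form ring probabilities

&nbsp;&nbsp;&nbsp;&nbsp;`p_k = (k/n)^(1+γ/2) − ((k−1)/n)^(1+γ/2)`

exposed by `expected_ring_probabilities` and used as the independent check
of the ring analysis. γ = 0 recovers a uniform process.

**Regime presets.** `normal-like` (background 0.2, 400 clusters × 40
points), `muscle-like` (0.5, 200 clusters), `carcinoma-like` (0.9, 50
clusters), all at 20,000 events so comparisons are count-matched. Preset
contour radii are set so that the **per-area localisation density** matches
the regime each preset emulates (≈ 21,000 /µm² for normal epithelium,
≈ 1,400 /µm² for carcinoma, 9,000 /µm² intermediate for muscle): at
desk-scale event counts this means geometrically scaled-down nuclei at
constant density. Per-bin occupancy statistics depend on density, not on
absolute nucleus size, so this choice preserves exactly the statistic the
binning analysis summarises; what it does **not** preserve is the absolute
nucleus geometry (clusters overlap in the shrunken normal-like contour),
which the ring and compaction analyses therefore test on their own,
full-size inputs instead.

**Nucleus images.** A disk nucleus (radius 48 px at 0.1 µm/px, baseline 40,
domains 160, render blur σ 0.6 px, additive noise σ 2) carries `n_domains`
bright patches built as the nucleus's Voronoi cells about random seeds,
each shrunk by √f about its centroid. Shrinking a convex cell about an
interior point stays inside the cell, so the union covers exactly the
planted fraction f of the nucleus for **any** f ∈ (0, 1) (±1% pixelation);
non-overlapping disk packings, by contrast, cannot exceed ≈ 70% coverage.

**Tissue fields.** Disk nuclei on a jittered grid (no overlaps by
construction, `PlacementError` if an explicit field shape is too small);
each cytoplasm annulus is painted at the positive (30) or negative (1)
mean on the 0–255 scale, straddling the threshold of 5, with exactly
`round(p·n_cells)` positive cells; channels are quantised to 8 bit.

**Not emulated:** blinking kinetics, camera noise models, drift,
localisation-precision heterogeneity, tissue autofluorescence beyond
additive noise, irregular nuclear shapes in the image generators, and
cell-to-cell intensity variability beyond the two planted classes. Passing
the recovery tests therefore demonstrates correctness of the measurement
code under the stated statistical structure, not robustness to every
artefact of real tissue data.

## Problem sizes and determinism

All generators are bit-reproducible from their seed; every planted truth
is returned alongside the data. The validation runs use desk-scale sizes:
10,000 points for the binning oracle, 4 × 10⁶ Monte-Carlo samples per shape
for ring areas (oracle SE ≈ 0.1%, well under the 0.5% margin on an exact
construction), 60,000 points per seed for the radial law, 100 seeds for
the monotonicity / regime-ordering / significance rates, 20 seeds for the
profile-contrast rate, and fields of 20–100 cells. Exemplar per-nucleus
event totals in real data are two orders of magnitude larger; the
analyses are linear or near-linear in event count, so the scale-down
changes runtimes, not code paths.

## Known limitations

* Equal ring areas are exact only for contours star-shaped about the
  centroid; strongly concave ROIs get approximate rings and a warning.
* The compaction pipeline assumes one nucleus per crop and a bright
  object on a darker background; touching nuclei must be cropped apart
  first.
* The trimodality guard in `segment_nucleus` switches thresholds
  discontinuously at its 80% coverage criterion; images sitting exactly at
  the boundary may segment differently under small perturbations.
* The exact rank-sum enumeration is limited to combined samples of 12; for
  larger samples the corrected normal approximation is used even when ties
  are absent.
* miR⁺ classification uses a single global threshold; per-field adaptive
  background estimation beyond scalar/image subtraction is out of scope.
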