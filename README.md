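# chromatex

Quantitative analysis of **chromatin nanotexture** and **miRNA-FISH signal**
in tissue sections, for microscopists and computational pathologists working
with single-molecule localisation microscopy (SMLM) and confocal imaging of
carcinoma versus normal tissue.

Carcinoma nuclei differ from normal epithelial nuclei in size, in the
fraction of compacted chromatin, and in the nanoscale spatial statistics of
DNA density. `chromatex` implements the corresponding measurements as a
tested, reusable pipeline:

* **Localisation I/O** — ThunderSTORM-style localisation CSVs, polygonal
  nuclear ROIs (JSON), boundary-inclusive ROI filtering.
* **Density binning** — per-bin counts of blinking events on a 50 × 50 nm²
  grid; box-plot summary (median, quartiles, 1.5·IQR whiskers, outliers) of
  the occupied-bin count distribution, pooled over replicates. Densely
  clustered chromatin gives high per-bin medians; diffuse sparse signal
  gives a median near 1.
* **Radial ring profiles** — the nuclear ROI is split into *n* concentric
  rings of exactly equal area by scaling the contour about its centroid with
  factors s<sub>k</sub> = √(k/n); per-ring localisation densities
  (localisations/µm²) quantify the centre-to-periphery density gradient.
* **Chromatin compaction (confocal)** — nucleus segmentation, chromatin
  domains as prominent local maxima grown by a watershed with a half-rise
  intensity cut, percent compact chromatin and dark (low-density) area;
  mode ± SD cohort summaries with a multimodality flag.
* **miRNA-FISH quantification** — per-cell cytoplasmic miR intensity from a
  nuclear-dye + probe channel pair; a cell is miR⁺ when its mean cytoplasm
  intensity ≥ 5 (0–255 scale); per-field percentages compared across groups
  with a one-sided unpaired Wilcoxon rank-sum test (exact for small
  tie-free samples, tie/continuity-corrected normal approximation
  otherwise).
* **Rendering & profiles** — count-conserving histogram reconstruction,
  emulated widefield comparator (100 nm pixels + Gaussian PSF), bilinear
  line profiles, and the excursion-contrast ratio between them.
* **Synthetic data** — planted-truth generators for localisation tables
  (Gaussian nanocluster + background mixture with a closed-form radial
  density law), nucleus images with an exact planted compact fraction, and
  tissue fields with a planted miR⁺ fraction.

## Worked example

```python
import chromatex as cx

# 1. Occupied-bin count distributions, clustered vs diffuse regimes
normal = [cx.bin_localisations(cx.simulate_localisations(
    cx.smlm_preset("normal-like", seed=s))[0]) for s in (0, 1)]
carcinoma = [cx.bin_localisations(cx.simulate_localisations(
    cx.smlm_preset("carcinoma-like", seed=s))[0]) for s in (2, 3, 4, 5)]
print(cx.merge_distributions(normal).median,
      cx.merge_distributions(carcinoma).median)
# -> 47.0 3.0

# 2. Radial ring profile of a periphery-weighted nucleus (gamma = 2)
roi = cx.circle_polygon(5000.0, (6000.0, 6000.0))   # 5 um radius, nm units
spec = cx.SmlmSimulationSpec(contour=roi, total_count=60_000,
                             n_clusters=60_000, cluster_sigma_nm=0.0,
                             radial_gradient_gamma=2.0, seed=1)
table, truth = cx.simulate_localisations(spec)
profile = cx.ring_profile(table, cx.build_rings(roi))
print(profile.counts.tolist())
# -> [1626, 5066, 8550, 11597, 14898, 18263]   (expected fractions 1/36..11/36)

# 3. Chromatin compaction of a synthetic nucleus (30% planted)
img, _ = cx.simulate_nucleus_image(
    cx.NucleusImageSpec(compact_fraction=0.3, seed=1))
seg = cx.analyse_nucleus(img)
print(f"{seg.nucleus_area_um2:.1f} um2, {seg.n_domains} domains, "
      f"{seg.compact_percent:.1f}% compact")
# -> 71.5 um2, 12 domains, 30.5% compact

# 4. miR+ cell fraction and a tumour-vs-normal comparison
field, _ = cx.simulate_tissue_field(
    cx.TissueFieldSpec(n_cells=100, positive_fraction=0.3, seed=1))
cells = cx.detect_cells(field, min_nucleus_area_um2=2.0, cytoplasm_width_px=4)
print(cx.field_summary(cells).percent_positive)
# -> 30.0
res = cx.rank_sum_one_sided([52, 60, 45, 55, 48], [5, 4, 6, 3, 7], "greater")
print(res.u_statistic, round(res.p_value, 5), res.method)
# -> 25.0 0.00397 exact
```

Line 1 reproduces the qualitative density-regime signature: pooling the
occupied-bin counts of clustered "normal-epithelium-like" nuclei gives a
median of 47 events per 50-nm bin, while the sparse diffuse
"carcinoma-like" regime pools to a median of 3 — low-density chromatin
dominates the carcinoma signal. Line 2 shows ring counts rising
monotonically from nuclear centre (ring 1) to periphery (ring 6), matching
the planted radial law. Lines 3–4 recover the planted compaction and miR⁺
fractions and show a fully separated two-group comparison with an exact
one-sided p below 0.05.

## Command line

```bash
chromatex simulate --kind smlm --preset carcinoma-like --seed 5 --out-dir sim/
chromatex density --pair sim/localisations.csv=sim/roi.json --out-dir out/density
chromatex rings   --pair sim/localisations.csv=sim/roi.json --out-dir out/rings
chromatex compaction nucleus_*.tif --pixel-size-um 0.1 --out-dir out/compaction
chromatex mir --field nuc.tif=mir.tif=tumour ... --compare tumour normal --out-dir out/mir
chromatex profiles sim/localisations.csv --out-dir out/profiles
```

Every run writes a `manifest.json` (config hash, seed, input digests) so
deterministic stages reproduce bit-identically.

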