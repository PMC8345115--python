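"""Synthetic data with planted ground truth for every analysis stage.

No public repository of patient-tissue localisation data exists for this
kind of study, so each analysis is validated against simulations that
emulate the statistical structure the methods assume:

* **SMLM tables** -- nanoscale chromatin modelled as small compacted
  clusters (Gaussian spread, default sigma 25 nm, i.e. FWHM ~ 59 nm,
  matching the reported 50-60 nm cluster diameters) interspersed in a
  uniform low-density background, with an optional radial density gradient
  toward the nuclear periphery.
* **Nucleus images** -- disk nuclei with a planted compact-chromatin
  fraction: bright chromatin patches constructed as Voronoi cells shrunk
  about their centroids, which covers *exactly* the requested area fraction
  for any fraction in (0, 1) (non-overlapping disk packings cannot exceed
  ~70% coverage).
* **Tissue fields** -- disk nuclei with painted cytoplasm annuli in the
  miR channel at a positive or negative mean intensity on the 0-255 scale,
  straddling the positivity threshold of 5.

All generators are bit-reproducible from their seed, and every planted
truth is returned (and can be written) alongside the data.

Radial gradient
---------------
Cluster centres are placed with weight proportional to ``s**gamma`` where
``s`` is the containment scale of the equal-area ring construction.  The
resulting ring probabilities have the closed form

``p_k = (k/n)**(1 + gamma/2) - ((k-1)/n)**(1 + gamma/2)``

exposed by :func:`expected_ring_probabilities` -- the independent check used
for the radial-profile analysis.  ``gamma = 0`` recovers a uniform point
process.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import shapely

from .chromatin_compaction import NucleusImage
from .exceptions import GeometryError, ParameterError, PlacementError
from .loc_io import LocalisationTable, RoiPolygon
from .mir_fish_quant import TissueField
from .radial_rings import build_rings, containment_scales, is_star_shaped
from scipy import ndimage as ndi


# ---------------------------------------------------------------------------
# geometry helpers

def circle_polygon(radius_nm: float, center_nm=(0.0, 0.0), n_vertices: int = 64) -> RoiPolygon:
    """Regular ``n_vertices``-gon approximating a circle (nm units)."""
    theta = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    cx, cy = center_nm
    return RoiPolygon(np.column_stack([cx + radius_nm * np.cos(theta),
                                       cy + radius_nm * np.sin(theta)]))


def blob_polygon(radius_nm: float, center_nm=(0.0, 0.0), n_vertices: int = 64,
                 roughness: float = 0.12, n_modes: int = 5,
                 rng: np.random.Generator | None = None) -> RoiPolygon:
    """Smooth star-shaped blob: a circle with low-order Fourier perturbation.

    Mimics a hand-drawn nuclear contour.  With the default roughness the
    result is star-shaped about its centroid.
    """
    rng = rng or np.random.default_rng(0)
    theta = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    r = np.ones_like(theta)
    for m in range(2, 2 + n_modes):
        amp = roughness * rng.uniform(0.2, 1.0) / m
        r += amp * np.cos(m * theta + rng.uniform(0, 2 * np.pi))
    r *= radius_nm
    cx, cy = center_nm
    return RoiPolygon(np.column_stack([cx + r * np.cos(theta),
                                       cy + r * np.sin(theta)]))


def uniform_points_in_polygon(roi: RoiPolygon, n: int,
                              rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample ``n`` uniform points inside the polygon."""
    minx, miny, maxx, maxy = roi.polygon.bounds
    out = np.empty((0, 2))
    while out.shape[0] < n:
        need = n - out.shape[0]
        batch = max(2 * need, 64)
        cand = np.column_stack([rng.uniform(minx, maxx, batch),
                                rng.uniform(miny, maxy, batch)])
        keep = shapely.contains_xy(roi.polygon, cand[:, 0], cand[:, 1])
        out = np.vstack([out, cand[keep]])
    return out[:n]


def expected_ring_probabilities(gamma: float, n_rings: int = 6) -> np.ndarray:
    """Closed-form equal-area ring probabilities of the planted radial law."""
    if gamma < 0:
        raise ParameterError("gamma must be >= 0")
    k = np.arange(0, n_rings + 1)
    cdf = (k / n_rings) ** (1.0 + gamma / 2.0)
    return np.diff(cdf)


# ---------------------------------------------------------------------------
# SMLM localisation tables

@dataclass(frozen=True)
class SmlmSimulationSpec:
    """Planted-structure SMLM simulation parameters.

    ``background_fraction`` of ``total_count`` events is uniform in the
    contour; the rest is split over ``n_clusters`` Gaussian clusters whose
    centres follow the ``s**gamma`` radial law.
    """

    contour: RoiPolygon
    total_count: int
    n_clusters: int
    cluster_sigma_nm: float = 25.0
    background_fraction: float = 0.0
    radial_gradient_gamma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.total_count < 0 or self.n_clusters < 0:
            raise ParameterError("counts must be non-negative")
        if not 0 <= self.background_fraction <= 1:
            raise ParameterError("background_fraction must be in [0, 1]")
        if self.cluster_sigma_nm < 0:
            raise ParameterError("cluster_sigma_nm must be >= 0")
        if self.radial_gradient_gamma < 0:
            raise ParameterError("radial_gradient_gamma must be >= 0")
        if self.background_fraction < 1 and self.total_count > 0 and self.n_clusters == 0:
            raise ParameterError("cluster points requested but n_clusters is 0")


def _sample_radial(roi: RoiPolygon, n: int, gamma: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Points whose containment scale follows CDF ``s**(gamma+2)``.

    The angular part of a uniform draw in the polygon is independent of its
    containment scale, so a uniform point can be rescaled radially about
    the centroid to any target scale law without biasing the shape.
    """
    if n == 0:
        return np.empty((0, 2))
    rings = build_rings(roi, 2)  # carrier for centroid + contour geometry
    q = uniform_points_in_polygon(roi, n, rng)
    t = containment_scales(q, rings)
    t = np.maximum(t, 1e-12)
    s = rng.random(n) ** (1.0 / (gamma + 2.0))
    c = rings.centroid_nm
    return c + (q - c) * (s / t)[:, None]


def simulate_localisations(spec: SmlmSimulationSpec):
    """Generate a localisation table with planted cluster/background truth.

    Returns ``(table, truth)``; ``truth["labels"]`` holds the cluster index
    per event (-1 for background), ``truth["centres"]`` the cluster centres.
    The table has exactly ``total_count`` rows, all inside the contour.
    """
    if not is_star_shaped(spec.contour):
        raise GeometryError("simulation contour must be star-shaped about its centroid")
    rng = np.random.default_rng(spec.seed)
    n_bg = int(round(spec.background_fraction * spec.total_count))
    n_cl = spec.total_count - n_bg

    centres = _sample_radial(spec.contour, spec.n_clusters,
                             spec.radial_gradient_gamma, rng)
    if n_cl and spec.n_clusters:
        # clusters get equal occupancy (remainder spread at random): the
        # planted per-cluster point count is sharp, not multinomial
        alloc = np.full(spec.n_clusters, n_cl // spec.n_clusters)
        rem = n_cl - int(alloc.sum())
        if rem:
            alloc[rng.choice(spec.n_clusters, rem, replace=False)] += 1
        labels_cl = np.repeat(np.arange(spec.n_clusters), alloc)
        pts = centres[labels_cl].copy()
        if spec.cluster_sigma_nm > 0:
            pts += rng.normal(0, spec.cluster_sigma_nm, pts.shape)
            # rejection-resample points scattered outside the contour so the
            # total count stays exact
            for _ in range(10_000):
                bad = ~shapely.contains_xy(spec.contour.polygon, pts[:, 0], pts[:, 1])
                if not bad.any():
                    break
                pts[bad] = centres[labels_cl[bad]] + rng.normal(
                    0, spec.cluster_sigma_nm, (int(bad.sum()), 2))
            else:
                raise PlacementError("could not keep cluster points inside the contour")
    else:
        pts = np.empty((0, 2))
        labels_cl = np.empty(0, dtype=int)

    bg = uniform_points_in_polygon(spec.contour, n_bg, rng)
    xy = np.vstack([pts, bg])
    labels = np.concatenate([labels_cl, np.full(n_bg, -1, dtype=int)])
    order = rng.permutation(len(xy))
    xy, labels = xy[order], labels[order]

    table = LocalisationTable(
        frame=np.arange(1, len(xy) + 1),
        x_nm=xy[:, 0], y_nm=xy[:, 1],
        intensity=rng.gamma(2.0, 500.0, len(xy)),
    )
    truth = {
        "labels": labels,
        "centres": centres,
        "gamma": spec.radial_gradient_gamma,
        "background_fraction": spec.background_fraction,
        "expected_ring_p": expected_ring_probabilities(
            spec.radial_gradient_gamma, 6),
        "seed": spec.seed,
    }
    return table, truth


# regime presets: cluster structure and per-area localisation density chosen
# to reproduce the bin-occupancy regimes of the tissue types (dense clustered
# chromatin in normal epithelium, sparse mostly-diffuse signal in carcinoma).
# Contour radii follow from total_count / density.
_SMLM_PRESETS = {
    "normal-like": dict(total_count=20_000, background_fraction=0.2,
                        n_clusters=400, density_per_um2=21_000.0),
    "muscle-like": dict(total_count=20_000, background_fraction=0.5,
                        n_clusters=200, density_per_um2=9_000.0),
    "carcinoma-like": dict(total_count=20_000, background_fraction=0.9,
                           n_clusters=50, density_per_um2=1_400.0),
}


def smlm_preset(name: str, seed: int = 0,
                radial_gradient_gamma: float = 1.0) -> SmlmSimulationSpec:
    """Named simulation preset (``normal-like``, ``muscle-like``, ``carcinoma-like``)."""
    if name not in _SMLM_PRESETS:
        raise ParameterError(
            f"unknown preset {name!r}; choose from {sorted(_SMLM_PRESETS)}")
    p = _SMLM_PRESETS[name]
    area_um2 = p["total_count"] / p["density_per_um2"]
    radius_nm = 1000.0 * np.sqrt(area_um2 / np.pi)
    centre = (2 * radius_nm, 2 * radius_nm)  # keep coordinates non-negative
    return SmlmSimulationSpec(
        contour=circle_polygon(radius_nm, centre),
        total_count=p["total_count"],
        n_clusters=p["n_clusters"],
        background_fraction=p["background_fraction"],
        radial_gradient_gamma=radial_gradient_gamma,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# nucleus images

@dataclass(frozen=True)
class NucleusImageSpec:
    """Disk nucleus with a planted compact-chromatin fraction."""

    compact_fraction: float
    nucleus_radius_px: int = 48
    n_domains: int = 12
    noise_sigma: float = 2.0
    seed: int = 0
    pixel_size_um: float = 0.1
    baseline_intensity: float = 40.0
    domain_intensity: float = 160.0
    blur_sigma_px: float = 0.6

    def __post_init__(self):
        if not 0 < self.compact_fraction < 1:
            raise ParameterError("compact_fraction must be in (0, 1)")
        if self.n_domains < 1:
            raise ParameterError("n_domains must be >= 1")
        if self.nucleus_radius_px < 8:
            raise ParameterError("nucleus_radius_px must be >= 8")
        if self.noise_sigma < 0:
            raise ParameterError("noise_sigma must be >= 0")


def _place_seeds(n: int, radius: float, center: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Dart-throwing seed placement with a relaxing minimum separation."""
    min_sep = 1.4 * radius / np.sqrt(n)
    while min_sep > 0.5:
        seeds: list[np.ndarray] = []
        for _ in range(2000):
            r = 0.85 * radius * np.sqrt(rng.random())
            th = rng.uniform(0, 2 * np.pi)
            cand = np.array([center + r * np.sin(th), center + r * np.cos(th)])
            if all(np.hypot(*(cand - s)) >= min_sep for s in seeds):
                seeds.append(cand)
                if len(seeds) == n:
                    return np.array(seeds)
        min_sep *= 0.7
    raise PlacementError("could not place domain seeds inside the nucleus")


def simulate_nucleus_image(spec: NucleusImageSpec):
    """Render a nucleus image; returns ``(NucleusImage, truth)``.

    The planted domain mask is the union of the nucleus's Voronoi cells
    (about random seeds) shrunk by ``sqrt(compact_fraction)`` about their
    centroids.  Shrinking a convex cell about an interior point keeps it
    inside the cell, so the union covers ``compact_fraction`` of the
    nucleus area exactly up to pixelation (within +/-1%).
    """
    rng = np.random.default_rng(spec.seed)
    R = spec.nucleus_radius_px
    size = 2 * (R + 8)
    center = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    nucleus = (yy - center) ** 2 + (xx - center) ** 2 <= R ** 2

    seeds = _place_seeds(spec.n_domains, R, center, rng)
    coords = np.column_stack(np.nonzero(nucleus)).astype(float)  # (P, 2) row, col
    d2 = ((coords[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
    cell = d2.argmin(axis=1)

    cell_area = np.bincount(cell, minlength=spec.n_domains)
    if (spec.compact_fraction * cell_area < 4).any():
        raise ParameterError(
            "compact_fraction unreachable: a domain would shrink below 4 pixels")

    shrink = np.sqrt(spec.compact_fraction)
    centroids = np.stack([coords[cell == i].mean(axis=0)
                          for i in range(spec.n_domains)])
    mapped = centroids[cell] + (coords - centroids[cell]) / shrink
    md2 = ((mapped[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
    in_cell = md2.argmin(axis=1) == cell
    in_disk = ((mapped[:, 0] - center) ** 2 + (mapped[:, 1] - center) ** 2) <= R ** 2
    keep = in_cell & in_disk

    domain_mask = np.zeros_like(nucleus)
    domain_mask[coords[keep, 0].astype(int), coords[keep, 1].astype(int)] = True

    img = np.full((size, size), 10.0)
    img[nucleus] = spec.baseline_intensity
    img[domain_mask] = spec.domain_intensity
    img = ndi.gaussian_filter(img, spec.blur_sigma_px)
    if spec.noise_sigma > 0:
        img = img + rng.normal(0, spec.noise_sigma, img.shape)
    img = np.clip(img, 0, None)

    truth = {
        "domain_mask": domain_mask,
        "nucleus_mask": nucleus,
        "compact_fraction_planted": spec.compact_fraction,
        "compact_fraction_actual": float(domain_mask.sum() / nucleus.sum()),
        "seeds": seeds,
        "seed": spec.seed,
    }
    return NucleusImage(img, spec.pixel_size_um), truth


# ---------------------------------------------------------------------------
# tissue fields

@dataclass(frozen=True)
class TissueFieldSpec:
    """Field of disk cells with a planted fraction of miR+ cells."""

    n_cells: int
    positive_fraction: float
    positive_mean: float = 30.0
    negative_mean: float = 1.0
    noise_sigma: float = 1.0
    seed: int = 0
    nucleus_radius_px: int = 6
    cytoplasm_width_px: int = 4
    pixel_size_um: float = 0.5
    shape: tuple[int, int] | None = None

    def __post_init__(self):
        if self.n_cells < 1:
            raise ParameterError("n_cells must be >= 1")
        if not 0 <= self.positive_fraction <= 1:
            raise ParameterError("positive_fraction must be in [0, 1]")
        for v in (self.positive_mean, self.negative_mean):
            if not 0 <= v <= 255:
                raise ParameterError("channel means must lie within [0, 255]")


def simulate_tissue_field(spec: TissueFieldSpec):
    """Render a two-channel tissue field; returns ``(TissueField, truth)``.

    Cells sit on a jittered grid so nuclei and their cytoplasm annuli never
    overlap.  Exactly ``round(positive_fraction * n_cells)`` cells carry the
    positive miR intensity.  Channels are quantised to the 0-255 (8-bit)
    scale.  With an explicit ``shape`` too small for the requested cell
    count, a :class:`PlacementError` is raised.
    """
    rng = np.random.default_rng(spec.seed)
    r, w = spec.nucleus_radius_px, spec.cytoplasm_width_px
    jitter = 2
    pitch = 2 * (r + w) + 2 * jitter + 2
    margin = r + w + jitter + 2

    if spec.shape is None:
        cols = int(np.ceil(np.sqrt(spec.n_cells)))
        rows = int(np.ceil(spec.n_cells / cols))
        shape = (rows * pitch + 2 * margin - pitch + 1,
                 cols * pitch + 2 * margin - pitch + 1)
    else:
        shape = tuple(spec.shape)
        cols = max((shape[1] - 2 * margin) // pitch + 1, 0)
        rows = max((shape[0] - 2 * margin) // pitch + 1, 0)
        if rows * cols < spec.n_cells:
            raise PlacementError(
                f"field of shape {shape} holds at most {rows * cols} cells, "
                f"{spec.n_cells} requested")

    grid = [(margin + i * pitch, margin + j * pitch)
            for i in range(rows) for j in range(cols)]
    order = rng.permutation(len(grid))[:spec.n_cells]
    centers = np.array([grid[i] for i in order], dtype=float)
    centers += rng.uniform(-jitter, jitter, centers.shape)

    n_pos = int(round(spec.positive_fraction * spec.n_cells))
    labels = np.zeros(spec.n_cells, dtype=bool)
    labels[:n_pos] = True
    labels = labels[rng.permutation(spec.n_cells)]

    yy, xx = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
    nuclear = np.full(shape, 5.0)
    mir = np.zeros(shape)
    for (cy, cx), pos in zip(centers, labels):
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        nucleus = d2 <= r ** 2
        annulus = (d2 <= (r + w) ** 2) & ~nucleus
        nuclear[nucleus] = 200.0
        mir[annulus] = spec.positive_mean if pos else spec.negative_mean
    nuclear += rng.normal(0, 2.0, shape)
    if spec.noise_sigma > 0:
        mir = mir + rng.normal(0, spec.noise_sigma, shape)
    nuclear = np.clip(np.round(nuclear), 0, 255)
    mir = np.clip(np.round(mir), 0, 255)

    truth = {
        "centers": centers,
        "is_positive": labels,
        "n_positive": int(labels.sum()),
        "positive_fraction_planted": spec.positive_fraction,
        "seed": spec.seed,
    }
    return TissueField(nuclear, mir, spec.pixel_size_um), truth


# ---------------------------------------------------------------------------
# truth sidecars

def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    return obj


def write_truth(truth: dict, path: str | Path) -> None:
    """Write a planted-truth record as a JSON sidecar."""
    with open(path, "w") as fh:
        json.dump({k: _jsonable(v) for k, v in truth.items()}, fh)
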