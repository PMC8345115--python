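"""Equal-area concentric-ring radial density profiles of a nucleus.

The nuclear ROI polygon is subdivided into ``n`` concentric rings of exactly
equal area by scaling the contour about its area centroid with factors
``s_k = sqrt(k / n)``: a scaled copy has area ``s^2 * A``, so consecutive
scaled contours enclose ``A/n`` each, provided the scaled copies nest.  They
nest exactly when the polygon is star-shaped about its centroid (true for
the near-convex contours of real nuclei); other polygons are processed with
a warning, since the set differences then only approximate equal areas.

Ring 1 is the centre, ring ``n`` touches the nuclear periphery.  A point
exactly on the ``s_k`` contour belongs to ring ``k`` (smallest containing
scale), and a point on the ROI boundary belongs to the outermost ring.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import GeometryError, RingWarning
from .loc_io import LocalisationTable, RoiPolygon, filter_by_roi, roi_area


def _ccw_vertices(vertices: np.ndarray) -> np.ndarray:
    x, y = vertices[:, 0], vertices[:, 1]
    signed = 0.5 * (np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    return vertices if signed > 0 else vertices[::-1]


def is_star_shaped(roi: RoiPolygon, about: np.ndarray | None = None) -> bool:
    """True if ``about`` (default: centroid) lies in the polygon's kernel.

    The kernel is the intersection of the inner half-planes of all edges, so
    the test is exact: for a CCW polygon the point must be on or left of
    every edge.
    """
    c = roi.centroid if about is None else np.asarray(about, dtype=float)
    v = _ccw_vertices(roi.vertices)
    a, b = v, np.roll(v, -1, axis=0)
    e = b - a
    cross = e[:, 0] * (c[1] - a[:, 1]) - e[:, 1] * (c[0] - a[:, 0])
    scale = np.linalg.norm(e, axis=1) * max(np.abs(v).max(), 1.0)
    return bool(np.all(cross >= -1e-9 * scale))


@dataclass(frozen=True)
class RingSet:
    """Concentric equal-area ring construction for one nuclear ROI."""

    roi: RoiPolygon
    n_rings: int
    scales: np.ndarray          # s_1 < ... < s_n = 1
    ring_area_um2: float
    centroid_nm: np.ndarray
    star_shaped: bool


@dataclass(frozen=True)
class RingProfile:
    """Localisation counts and densities per ring (index 0 = centre)."""

    counts: np.ndarray
    densities_per_um2: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def build_rings(roi: RoiPolygon, n_rings: int = 6) -> RingSet:
    """Construct ``n_rings`` equal-area rings by centroid-similarity scaling."""
    if n_rings < 2:
        raise GeometryError("n_rings must be >= 2")
    star = is_star_shaped(roi)
    if not star:
        warnings.warn(
            "ROI polygon is not star-shaped about its centroid; scaled contours "
            "do not nest and ring areas are only approximately equal",
            RingWarning, stacklevel=2)
    scales = np.sqrt(np.arange(1, n_rings + 1) / n_rings)
    return RingSet(roi, int(n_rings), scales, roi_area(roi) / n_rings,
                   roi.centroid, star)


def scaled_contour(rings: RingSet, s: float) -> np.ndarray:
    """Vertices of the ROI contour scaled by ``s`` about the centroid."""
    c = rings.centroid_nm
    return c + s * (rings.roi.vertices - c)


def containment_scales(xy: np.ndarray, rings: RingSet) -> np.ndarray:
    """Smallest contour scale containing each point.

    For a point ``p`` the ray from the centroid through ``p`` meets the
    polygon boundary at parameter ``t`` (``p`` itself sits at ``t = 1``);
    the smallest scaled contour containing ``p`` has ``s = 1/t``.  Values
    > 1 mean the point is outside the ROI.  For non-star-shaped polygons
    the farthest boundary intersection is used.
    """
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    c = rings.centroid_nm
    v = rings.roi.vertices
    a = v
    e = np.roll(v, -1, axis=0) - v       # (E, 2) edge vectors
    d = xy - c                            # (N, 2) ray directions
    r = np.linalg.norm(d, axis=1)

    ac = a - c                            # (E, 2)
    # solve c + t d = a + u e per point/edge pair
    denom = d[:, 0:1] * e[:, 1] - d[:, 1:2] * e[:, 0]          # (N, E)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ac[:, 0] * e[:, 1] - ac[:, 1] * e[:, 0]) / denom  # (N, E)
        u = (ac[:, 0] * d[:, 1:2] - ac[:, 1] * d[:, 0:1]) / denom
    valid = np.isfinite(t) & (t > 0) & (u >= -1e-12) & (u <= 1 + 1e-12)
    t = np.where(valid, t, -np.inf)
    t_boundary = t.max(axis=1)
    s = np.full(xy.shape[0], np.inf)
    ok = t_boundary > 0
    s[ok] = 1.0 / t_boundary[ok]
    s[r == 0] = 0.0                       # the centroid itself
    return s


def assign_ring(point, rings: RingSet):
    """Ring index in ``1..n_rings`` for one point, or ``"outside"``."""
    x, y = float(point[0]), float(point[1])
    if not rings.roi.contains(x, y)[0]:
        return "outside"
    s = containment_scales(np.array([[x, y]]), rings)[0]
    k = int(np.searchsorted(rings.scales, min(s, 1.0), side="left"))
    return min(k, rings.n_rings - 1) + 1


def ring_profile(table: LocalisationTable, rings: RingSet) -> RingProfile:
    """Count in-ROI localisations per ring and convert to areal densities.

    Every in-ROI event lands in exactly one ring (conservation); events
    outside the ROI are ignored.  Densities are localisations per um^2 of
    ring area (``roi_area / n_rings``).
    """
    inside = filter_by_roi(table, rings.roi)
    counts = np.zeros(rings.n_rings, dtype=np.int64)
    if len(inside):
        s = containment_scales(inside.xy, rings)
        k = np.searchsorted(rings.scales, np.minimum(s, 1.0), side="left")
        k = np.minimum(k, rings.n_rings - 1)
        counts = np.bincount(k, minlength=rings.n_rings).astype(np.int64)
    return RingProfile(counts, counts / rings.ring_area_um2)
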