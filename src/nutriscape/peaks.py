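"""Peak-region estimation on reconstructed landscapes.

The peak region is the set of grid points at or above a high quantile of
the landscape values (default 0.95).  Its centroid gives the peak P:C
ratio; its shape is summarized by an ellipse aligned with the principal
components of the region coordinates, with area pi*a*b optionally clipped
at the space boundary.

Estimation can be restricted to the part of the landscape supported by the
anchor points (their convex hull): surface values beyond the sampled
region are extrapolations, and peak estimates are truncated at the
boundary of what the anchors can support.  Sparse designs such as
fixed-ratio rails therefore yield truncated peak regions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay, cKDTree
from shapely import affinity
from shapely.geometry import Point, box

from nutriscape.designs import NutrientSpace
from nutriscape.landscape import Landscape

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Ellipse:
    center: tuple[float, float]
    a: float  # semi-major axis (g/L)
    b: float  # semi-minor axis (g/L)
    angle: float  # orientation of the major axis, radians from the P axis

    @property
    def raw_area(self) -> float:
        return math.pi * self.a * self.b

    def to_polygon(self, quad_segs: int = 64):
        circ = Point(self.center).buffer(1.0, quad_segs=quad_segs)
        ell = affinity.scale(circ, self.a, self.b, origin=self.center)
        return affinity.rotate(ell, math.degrees(self.angle), origin=self.center)


@dataclass
class PeakEstimate:
    region: np.ndarray  # (m, 2) grid coordinates at/above threshold
    centroid: tuple[float, float]
    pc_ratio: float
    boundary_flag: bool
    ellipse: Ellipse
    area: float
    quantile: float
    threshold: float


def hull_mask(coords: np.ndarray, anchors: np.ndarray) -> np.ndarray:
    """Boolean mask of grid coords supported by the anchor set.

    A location is supported when it lies inside the anchors' convex hull or
    within one typical anchor spacing (the median nearest-neighbor distance
    among anchors) of some anchor.  The buffer keeps the thin margin between
    a lattice design's outermost anchors and the space edge estimable, while
    locations far outside a sparse design's hull remain extrapolation and
    are excluded.
    """
    coords = np.asarray(coords, dtype=float)
    anchors = np.asarray(anchors, dtype=float)
    tri = Delaunay(anchors)
    inside = tri.find_simplex(coords) >= 0
    tree = cKDTree(anchors)
    nn_anchor = tree.query(anchors, k=2)[0][:, 1]
    buffer = float(np.median(nn_anchor))
    near = tree.query(coords)[0] <= buffer
    return inside | near


def peak_region(
    landscape: Landscape,
    quantile: float = 0.95,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Grid points with value >= the given quantile of landscape values.

    ``mask`` optionally restricts both the quantile computation and the
    region to a subset of grid points (e.g. the anchor hull).  Ties at
    exactly the threshold are included, so the maximum of the considered
    values is always in the region and the result is never empty.
    """
    if not 0 < quantile < 1:
        raise ValueError("quantile must lie strictly between 0 and 1")
    values = landscape.values
    coords = landscape.coords_array()
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != values.shape:
            raise ValueError("mask shape does not match landscape")
        if not mask.any():
            raise ValueError("mask excludes every grid point")
        values = values[mask]
        coords = coords[mask]
    threshold = float(np.quantile(values, quantile))
    keep = values >= threshold
    if keep.all():
        logger.warning("degenerate landscape: all values tie, region = whole grid")
    return coords[keep]


def region_threshold(
    landscape: Landscape, quantile: float, mask: np.ndarray | None = None
) -> float:
    values = landscape.values if mask is None else landscape.values[np.asarray(mask, bool)]
    return float(np.quantile(values, quantile))


def peak_centroid_ratio(
    region: np.ndarray,
    spacing: float,
    space: NutrientSpace | None = None,
) -> tuple[tuple[float, float], float, bool]:
    """Unweighted centroid of the region, its P/C ratio, and a boundary flag.

    The flag is raised when the centroid lies within one grid spacing of the
    space edge (if the space is given) or when centroid carbohydrate falls
    below one spacing, where the ratio blows up.
    """
    region = np.asarray(region, dtype=float).reshape(-1, 2)
    if len(region) == 0:
        raise ValueError("peak region is empty")
    cen_p = float(region[:, 0].mean())
    cen_c = float(region[:, 1].mean())
    boundary = cen_c < spacing
    if space is not None and space.edge_distance(cen_p, cen_c) < spacing:
        boundary = True
    ratio = cen_p / cen_c if cen_c > 1e-12 else math.inf
    return (cen_p, cen_c), ratio, boundary


def region_touches_boundary(
    region: np.ndarray,
    estimable_coords: np.ndarray,
    spacing: float,
) -> bool:
    """True if any region point sits on the rim of the estimable grid set.

    A point is on the rim when one of its four lattice neighbors (one
    spacing away) is not itself estimable — i.e. the peak region is
    truncated by the space edge or by the anchor hull.
    """
    region = np.asarray(region, dtype=float).reshape(-1, 2)
    est = np.asarray(estimable_coords, dtype=float).reshape(-1, 2)
    origin = est.min(axis=0)
    keys = {tuple(k) for k in np.round((est - origin) / spacing).astype(int)}
    rkeys = np.round((region - origin) / spacing).astype(int)
    for i, j in rkeys:
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            if (i + di, j + dj) not in keys:
                return True
    return False


def fit_peak_ellipse(
    region: np.ndarray,
    k: float = 2.0,
    space: NutrientSpace | None = None,
) -> tuple[Ellipse, float]:
    """Principal-component ellipse of the region and its area.

    Semi-axes are k * sqrt(eigenvalues) of the coordinate covariance
    (k = 2 covers ~95% of a Gaussian-shaped region).  When a space is
    given, the reported area is that of the ellipse clipped to the space
    rectangle.  Degenerate regions (single point, collinear) give area 0.
    """
    region = np.asarray(region, dtype=float).reshape(-1, 2)
    if len(region) == 0:
        raise ValueError("peak region is empty")
    center = (float(region[:, 0].mean()), float(region[:, 1].mean()))
    if len(region) == 1:
        return Ellipse(center, 0.0, 0.0, 0.0), 0.0
    cov = np.cov(region.T, ddof=0)
    evals, evecs = np.linalg.eigh(cov)
    evals = np.clip(evals, 0.0, None)
    # eigh returns ascending order; major axis last
    a = k * math.sqrt(evals[1])
    b = k * math.sqrt(evals[0])
    angle = math.atan2(evecs[1, 1], evecs[0, 1])
    ell = Ellipse(center, a, b, angle)
    if b == 0.0:
        logger.warning("degenerate peak region (collinear points): area 0")
        return ell, 0.0
    area = ell.raw_area
    if space is not None:
        rect = box(space.p_min, space.c_min, space.p_max, space.c_max)
        area = float(ell.to_polygon().intersection(rect).area)
    return ell, area


def estimate_peak(
    landscape: Landscape,
    space: NutrientSpace | None = None,
    quantile: float = 0.95,
    k: float = 2.0,
    clip_to: np.ndarray | None = None,
) -> PeakEstimate:
    """Full peak summary: region, centroid P:C ratio, and ellipse area.

    ``clip_to`` takes anchor coordinates; estimation is then restricted to
    grid points inside their convex hull.  The boundary flag is raised when
    the centroid hugs the space edge or the region is truncated by the rim
    of the estimable area.
    """
    coords = landscape.coords_array()
    mask = None
    if clip_to is not None:
        mask = hull_mask(coords, clip_to)
        if not mask.any():
            logger.warning("anchor hull excludes the whole grid; clipping skipped")
            mask = None
    region = peak_region(landscape, quantile, mask=mask)
    centroid, ratio, flag = peak_centroid_ratio(region, landscape.grid_spacing, space)
    estimable = coords if mask is None else coords[mask]
    if not flag:
        flag = region_touches_boundary(region, estimable, landscape.grid_spacing)
    ellipse, area = fit_peak_ellipse(region, k=k, space=space)
    return PeakEstimate(
        region=region,
        centroid=centroid,
        pc_ratio=ratio,
        boundary_flag=flag,
        ellipse=ellipse,
        area=area,
        quantile=quantile,
        threshold=region_threshold(landscape, quantile, mask=mask),
    )
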