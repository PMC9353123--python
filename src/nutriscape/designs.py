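"""Two-nutrient space representation and anchor-point design generators.

Four sampling strategies are provided: fixed-ratio rails ("gf"), hexagonal
lattice, square lattice, and uniform random points.  Lattice strategies
return exactly the requested number of points: the lattice is generated at
the largest cell size yielding at least ``resolution`` in-space centers and
the excess points farthest from the space centroid are dropped.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import ConvexHull, cKDTree

logger = logging.getLogger(__name__)

_SQRT3 = math.sqrt(3.0)


@dataclass(frozen=True)
class NutrientSpace:
    """Rectangular protein x carbohydrate domain, bounds in g/L."""

    p_min: float = 0.0
    p_max: float = 60.0
    c_min: float = 0.0
    c_max: float = 120.0

    def __post_init__(self) -> None:
        if not (self.p_min < self.p_max and self.c_min < self.c_max):
            raise ValueError("nutrient space bounds must satisfy min < max on both axes")
        if self.p_min < 0 or self.c_min < 0:
            raise ValueError("nutrient concentrations cannot be negative")

    @property
    def width(self) -> float:
        return self.p_max - self.p_min

    @property
    def height(self) -> float:
        return self.c_max - self.c_min

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def centroid(self) -> tuple[float, float]:
        return (0.5 * (self.p_min + self.p_max), 0.5 * (self.c_min + self.c_max))

    def contains(self, p: float, c: float, tol: float = 1e-9) -> bool:
        return (
            self.p_min - tol <= p <= self.p_max + tol
            and self.c_min - tol <= c <= self.c_max + tol
        )

    def edge_distance(self, p: float, c: float) -> float:
        """Distance from (p, c) to the nearest boundary edge."""
        return min(p - self.p_min, self.p_max - p, c - self.c_min, self.c_max - c)


@dataclass(frozen=True)
class AnchorPoint:
    """A diet treatment: fixed protein and carbohydrate coordinates.

    ``rail_ratio``/``concentration`` tags are set only by the fixed-ratio
    generator.  A rail ratio of 0 is the pure-carbohydrate rail (p = 0);
    ``math.inf`` is reserved for the pure-protein rail (c = 0).
    """

    p: float
    c: float
    rail_ratio: float | None = None
    concentration: float | None = None

    def __post_init__(self) -> None:
        if self.rail_ratio is not None and self.c > 0 and math.isfinite(self.rail_ratio):
            if abs(self.p / self.c - self.rail_ratio) > 1e-9:
                raise ValueError(
                    f"anchor ({self.p}, {self.c}) does not lie on rail {self.rail_ratio}"
                )

    @property
    def coords(self) -> tuple[float, float]:
        return (self.p, self.c)


@dataclass
class Design:
    """An ordered set of anchor points with strategy metadata."""

    strategy: str
    resolution: int
    points: list[AnchorPoint]
    cell_apothem: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        seen: set[tuple[float, float]] = set()
        deduped = []
        for pt in self.points:
            if pt.coords in seen:
                logger.warning("dropping duplicate anchor point %s", pt.coords)
                continue
            seen.add(pt.coords)
            deduped.append(pt)
        self.points = deduped

    def __len__(self) -> int:
        return len(self.points)

    def coords_array(self) -> np.ndarray:
        """(n, 2) array of anchor coordinates in design order."""
        return np.array([[pt.p, pt.c] for pt in self.points], dtype=float)


@dataclass(frozen=True)
class CertaintyKernel:
    """Gaussian certainty density around an anchor point.

    density(x, y) = amplitude * exp(-[(x-x0)^2/(2*sigma_x2) + (y-y0)^2/(2*sigma_y2)])
    """

    amplitude: float
    x0: float
    y0: float
    sigma_x2: float
    sigma_y2: float

    def __post_init__(self) -> None:
        if self.sigma_x2 <= 0 or self.sigma_y2 <= 0:
            raise ValueError("kernel variances must be strictly positive")


def certainty_density(kernel: CertaintyKernel, x, y):
    """Evaluate the Gaussian certainty density at (x, y); vectorized."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    expo = (x - kernel.x0) ** 2 / (2.0 * kernel.sigma_x2) + (y - kernel.y0) ** 2 / (
        2.0 * kernel.sigma_y2
    )
    return kernel.amplitude * np.exp(-expo)


# ---------------------------------------------------------------------------
# fixed-ratio ("gf") designs


def gf_point(ratio: float, concentration: float) -> tuple[float, float]:
    """Project a (P:C ratio, total concentration) pair to (p, c) coordinates."""
    if concentration <= 0:
        raise ValueError(f"concentration must be positive, got {concentration}")
    if ratio < 0:
        raise ValueError(f"rail ratio must be >= 0, got {ratio}")
    if math.isinf(ratio):  # pure-protein rail
        return (concentration, 0.0)
    if ratio == 0:  # pure-carbohydrate rail
        return (0.0, concentration)
    p = concentration * ratio / (1.0 + ratio)
    return (p, concentration - p)


def make_gf_design(
    space: NutrientSpace,
    ratios: Sequence[float],
    concentrations: Sequence[float],
) -> Design:
    """One anchor per (rail ratio, total concentration) pair.

    Each rail is a ray p/c = ratio from the origin; diets on a rail differ
    only in total nutrient concentration p + c.
    """
    if not ratios or not concentrations:
        raise ValueError("ratios and concentrations must be non-empty")
    points = []
    for ratio in ratios:
        for conc in concentrations:
            p, c = gf_point(ratio, conc)
            if not space.contains(p, c):
                raise ValueError(
                    f"rail ratio {ratio} at concentration {conc} projects to "
                    f"({p:.4g}, {c:.4g}), outside the nutrient space"
                )
            points.append(AnchorPoint(p, c, rail_ratio=ratio, concentration=conc))
    return Design(strategy="gf", resolution=len(points), points=points)


# ---------------------------------------------------------------------------
# lattice designs (hexagonal and square)


def _hex_lattice(space: NutrientSpace, r: float) -> np.ndarray:
    """Centers of a flat-top hexagonal tiling with apothem r, clipped to space.

    Rows are spaced sqrt(3)*r apart and alternately offset by r so every
    point is exactly 2r from its six lattice neighbors.
    """
    rows = []
    j = 0
    y = space.c_min + r
    tol = 1e-9
    while y <= space.c_max + tol:
        x0 = space.p_min + r + (j % 2) * r
        n = int(math.floor((space.p_max - x0) / (2.0 * r) + tol))
        if n >= 0:
            xs = x0 + 2.0 * r * np.arange(n + 1)
            rows.append(np.column_stack([xs, np.full(xs.shape, y)]))
        j += 1
        y = space.c_min + r + j * _SQRT3 * r
    if not rows:
        return np.empty((0, 2))
    return np.vstack(rows)


def _square_lattice(space: NutrientSpace, r: float) -> np.ndarray:
    """Centers of adjacent squares with apothem r (side 2r), clipped to space."""
    tol = 1e-9
    nx = int(math.floor((space.width - 2.0 * r) / (2.0 * r) + tol))
    ny = int(math.floor((space.height - 2.0 * r) / (2.0 * r) + tol))
    if nx < 0 or ny < 0:
        return np.empty((0, 2))
    xs = space.p_min + r + 2.0 * r * np.arange(nx + 1)
    ys = space.c_min + r + 2.0 * r * np.arange(ny + 1)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    return np.column_stack([gx.ravel(), gy.ravel()])


def _exact_count_lattice(
    space: NutrientSpace, resolution: int, lattice_fn, strategy: str
) -> Design:
    if resolution < 1:
        raise ValueError(f"resolution must be >= 1, got {resolution}")
    if resolution == 1:
        cp, cc = space.centroid
        return Design(
            strategy=strategy,
            resolution=1,
            points=[AnchorPoint(cp, cc)],
            cell_apothem=min(space.width, space.height) / 2.0,
        )

    # largest apothem whose clipped lattice holds >= resolution centers;
    # counts grow as r shrinks, so bisect then nudge down for safety
    r_hi = max(space.width, space.height)
    r_lo = 0.5 * math.sqrt(space.area / (4.0 * resolution)) / 4.0
    while len(lattice_fn(space, r_lo)) < resolution:
        r_lo /= 2.0
    for _ in range(200):
        mid = 0.5 * (r_lo + r_hi)
        if len(lattice_fn(space, mid)) >= resolution:
            r_lo = mid
        else:
            r_hi = mid
    r = r_lo
    pts = lattice_fn(space, r)
    while len(pts) < resolution:  # paranoia against boundary-tolerance slips
        r *= 0.999
        pts = lattice_fn(space, r)

    # keep the `resolution` centers closest to the space centroid (stable order)
    cp, cc = space.centroid
    d2 = (pts[:, 0] - cp) ** 2 + (pts[:, 1] - cc) ** 2
    keep = np.argsort(d2, kind="stable")[:resolution]
    keep.sort()  # preserve lattice (row-major) ordering
    chosen = pts[keep]
    return Design(
        strategy=strategy,
        resolution=resolution,
        points=[AnchorPoint(p, c) for p, c in chosen],
        cell_apothem=r,
    )


def make_hex_design(space: NutrientSpace, resolution: int) -> Design:
    """Hexagonal-packing design: anchor spacing 2r for apothem r."""
    return _exact_count_lattice(space, resolution, _hex_lattice, "hexagonal")


def make_square_design(space: NutrientSpace, resolution: int) -> Design:
    """Square-grid design: anchors at square centers, row/column spacing 2r."""
    return _exact_count_lattice(space, resolution, _square_lattice, "square")


def make_random_design(space: NutrientSpace, resolution: int, seed: int) -> Design:
    """Uniform random anchors over the space rectangle; reproducible by seed."""
    if resolution < 1:
        raise ValueError(f"resolution must be >= 1, got {resolution}")
    rng = np.random.default_rng(seed)
    ps = rng.uniform(space.p_min, space.p_max, size=resolution)
    cs = rng.uniform(space.c_min, space.c_max, size=resolution)
    return Design(
        strategy="random",
        resolution=resolution,
        points=[AnchorPoint(p, c) for p, c in zip(ps, cs)],
        seed=seed,
    )


# ---------------------------------------------------------------------------
# diagnostics


@dataclass
class DesignDiagnostics:
    """Nearest-neighbor spacing distribution and convex-hull coverage."""

    nn_distances: np.ndarray
    coverage_fraction: float
    hull_defined: bool
    notes: list[str] = field(default_factory=list)


def design_diagnostics(design: Design, space: NutrientSpace) -> DesignDiagnostics:
    coords = design.coords_array()
    n = len(coords)
    if n >= 2:
        tree = cKDTree(coords)
        dists, _ = tree.query(coords, k=2)
        nn = dists[:, 1]
    else:
        nn = np.empty(0)
    notes = []
    if n >= 3:
        try:
            hull = ConvexHull(coords)
            coverage = float(hull.volume / space.area)
        except Exception:  # collinear point sets
            coverage = float("nan")
            notes.append("convex hull degenerate (collinear points)")
    else:
        coverage = float("nan")
        notes.append("fewer than 3 points: hull undefined")
    return DesignDiagnostics(
        nn_distances=nn,
        coverage_fraction=coverage,
        hull_defined=not math.isnan(coverage),
        notes=notes,
    )
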