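"""Dense trait landscapes on regular grids and quadratic response surfaces."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from nutriscape.designs import AnchorPoint, Design, NutrientSpace

logger = logging.getLogger(__name__)


@dataclass
class Landscape:
    """Trait values on a regular (p, c) grid.

    ``p``, ``c`` and ``values`` are parallel 1-D arrays; the grid covers a
    rectangular space with constant ``grid_spacing`` on both axes.
    """

    trait_name: str
    grid_spacing: float
    p: np.ndarray
    c: np.ndarray
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        self.c = np.asarray(self.c, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if not (self.p.shape == self.c.shape == self.values.shape):
            raise ValueError("p, c, values must have identical shapes")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("landscape values must be finite")

    def __len__(self) -> int:
        return len(self.values)

    def coords_array(self) -> np.ndarray:
        return np.column_stack([self.p, self.c])

    def sort_index(self) -> np.ndarray:
        """Indices ordering grid points lexicographically by (p, c)."""
        return np.lexsort((self.c, self.p))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trait": self.trait_name,
                "protein_gL": self.p,
                "carbohydrate_gL": self.c,
                "value": self.values,
            }
        )


def make_grid(space: NutrientSpace, spacing: float) -> np.ndarray:
    """Regular lattice over the space, closed at both ends when divisible.

    Returns an (n, 2) array of (p, c) coordinates in row-major order.
    """
    if spacing <= 0:
        raise ValueError("grid spacing must be positive")
    if spacing >= min(space.width, space.height):
        raise ValueError("grid spacing must be smaller than the space sides")
    tol = 1e-9
    np_steps = int(math.floor(space.width / spacing + tol))
    nc_steps = int(math.floor(space.height / spacing + tol))
    ps = space.p_min + spacing * np.arange(np_steps + 1)
    cs = space.c_min + spacing * np.arange(nc_steps + 1)
    gp, gc = np.meshgrid(ps, cs, indexing="ij")
    return np.column_stack([gp.ravel(), gc.ravel()])


@dataclass(frozen=True)
class QuadraticSurface:
    """value = b0 + b1*P + b2*C + b3*P^2 + b4*C^2 + b5*P*C."""

    beta: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "beta", np.asarray(self.beta, dtype=float))
        if self.beta.shape != (6,):
            raise ValueError("quadratic surface needs exactly 6 coefficients")

    def predict(self, p, c):
        p = np.asarray(p, dtype=float)
        c = np.asarray(c, dtype=float)
        b = self.beta
        return b[0] + b[1] * p + b[2] * c + b[3] * p * p + b[4] * c * c + b[5] * p * c


def quadratic_design_matrix(p: np.ndarray, c: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(p), p, c, p * p, c * c, p * c])


def fit_quadratic_surface(landscape: Landscape) -> QuadraticSurface:
    """OLS fit of the six-term quadratic over all grid points."""
    if len(landscape) < 6:
        raise ValueError("need at least 6 grid points to fit a quadratic surface")
    X = quadratic_design_matrix(landscape.p, landscape.c)
    if np.linalg.matrix_rank(X) < 6:
        raise ValueError("quadratic design matrix is rank-deficient")
    beta, *_ = np.linalg.lstsq(X, landscape.values, rcond=None)
    return QuadraticSurface(beta=beta)


def sample_design_values(
    surface: QuadraticSurface,
    design: Design,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> list[tuple[AnchorPoint, float]]:
    """Simulated experiment: surface value at each anchor plus Gaussian noise.

    With ``noise_sd == 0`` the surface is reproduced exactly.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    coords = design.coords_array()
    values = surface.predict(coords[:, 0], coords[:, 1])
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd, size=len(values))
    return list(zip(design.points, (float(v) for v in values)))


def baseline_from_observations(
    table: pd.DataFrame,
    space: NutrientSpace,
    spacing: float,
    trait: str | None = None,
    smoothing: float = 0.001,
) -> Landscape:
    """Dense baseline landscape predicted from scattered diet observations.

    A lightly smoothed thin-plate spline (``smoothing`` = 0.001 by default)
    is fitted to the observed (protein, carbohydrate, trait) records and
    evaluated at every node of the regular grid, extending over the full
    space even beyond the observed extent.
    """
    from nutriscape.tps import tps_fit, tps_predict  # deferred: avoids cycle

    required = {"protein_gL", "carbohydrate_gL"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"diet table missing columns: {sorted(missing)}")
    if trait is None:
        candidates = [col for col in table.columns if col not in required]
        if not candidates:
            raise ValueError("diet table has no trait column")
        trait = candidates[0]
    if trait not in table.columns:
        raise ValueError(f"trait column {trait!r} not in diet table")

    sub = table[["protein_gL", "carbohydrate_gL", trait]].dropna()
    pts = sub[["protein_gL", "carbohydrate_gL"]].to_numpy(dtype=float)
    vals = sub[trait].to_numpy(dtype=float)
    if len(np.unique(pts, axis=0)) < 6:
        raise ValueError("need >= 6 distinct diet locations for a baseline")

    model = tps_fit(pts, vals, lam=smoothing)
    grid = make_grid(space, spacing)
    pred = tps_predict(model, grid)
    if np.any(pred < 0):
        logger.warning(
            "baseline extrapolation produced %d negative values (not clamped)",
            int(np.sum(pred < 0)),
        )
    return Landscape(
        trait_name=trait,
        grid_spacing=spacing,
        p=grid[:, 0],
        c=grid[:, 1],
        values=pred,
        meta={"predictor": "tps", "smoothing": smoothing, "n_obs": int(len(sub))},
    )
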