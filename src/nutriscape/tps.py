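"""Smoothed thin-plate splines for 2-D scattered-data surface reconstruction.

The model is value(x) = a0 + a1*p + a2*c + sum_i w_i * phi(||x - x_i||) with
kernel phi(d) = d^2 * log(d) (phi(0) = 0), fitted by solving the bordered
linear system

    [K + n*lam*I   P] [w]   [v]
    [P^T           0] [a] = [0]

where P = [1, p, c].  The zero block enforces the side conditions
sum(w) = sum(w*p) = sum(w*c) = 0, so affine data are reproduced exactly for
every lam >= 0.

Convention: coordinates are standardized to the unit square before kernel
evaluation, so the meaning of ``lam`` does not depend on the g/L scale of
the axes, and the penalty ``lam`` is added directly to the kernel diagonal
(the same convention as scipy's RBFInterpolator ``smoothing``).  Exact
numerical equivalence with other TPS implementations, which rescale the
smoothing parameter internally, is not promised.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from nutriscape.designs import AnchorPoint, Design, NutrientSpace
from nutriscape.landscape import Landscape, make_grid

logger = logging.getLogger(__name__)


def tps_kernel(d: np.ndarray) -> np.ndarray:
    """phi(d) = d^2 log d, with phi(0) = 0 (natural log)."""
    d = np.asarray(d, dtype=float)
    out = np.zeros_like(d)
    nz = d > 0
    out[nz] = d[nz] * d[nz] * np.log(d[nz])
    return out


@dataclass
class TPSModel:
    anchor_coords: np.ndarray  # (n, 2), original g/L scale
    rbf_weights: np.ndarray  # (n,), for the standardized kernel
    affine: np.ndarray  # (a0, a1, a2) on the original scale
    lam: float
    offset: np.ndarray  # standardization: u = (x - offset) / scale
    scale: np.ndarray

    def std_coords(self) -> np.ndarray:
        return (self.anchor_coords - self.offset) / self.scale

    def side_condition_residuals(self) -> np.ndarray:
        """[sum(w), sum(w*p), sum(w*c)] — all ~0 for a valid model."""
        w = self.rbf_weights
        u = self.std_coords()
        return np.array([w.sum(), (w * u[:, 0]).sum(), (w * u[:, 1]).sum()])


def _merge_near_duplicates(
    points: np.ndarray, values: np.ndarray, tol: float = 1e-9
) -> tuple[np.ndarray, np.ndarray]:
    if len(points) < 2:
        return points, values
    d = cdist(points, points)
    np.fill_diagonal(d, np.inf)
    if d.min() >= tol:
        return points, values
    keep_pts, keep_vals, used = [], [], np.zeros(len(points), dtype=bool)
    for i in range(len(points)):
        if used[i]:
            continue
        group = np.where(d[i] < tol)[0]
        group = np.concatenate([[i], group[~used[group]]])
        used[group] = True
        keep_pts.append(points[i])
        keep_vals.append(values[group].mean())
        if len(group) > 1:
            logger.info("merged %d near-duplicate anchors at %s", len(group), points[i])
    return np.array(keep_pts), np.array(keep_vals)


def tps_fit(points, values, lam: float = 0.05) -> TPSModel:
    """Fit a smoothed thin-plate spline to scattered (p, c, value) data."""
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    values = np.asarray(values, dtype=float).ravel()
    if len(points) != len(values):
        raise ValueError("points and values length mismatch")
    if lam < 0:
        raise ValueError("smoothing parameter must be >= 0")
    points, values = _merge_near_duplicates(points, values)
    n = len(points)
    if n < 4:
        raise ValueError("need at least 4 distinct points to fit a TPS")

    P_orig = np.column_stack([np.ones(n), points])
    if np.linalg.matrix_rank(P_orig) < 3:
        raise ValueError("anchor points are collinear; TPS system is singular")

    offset = points.min(axis=0)
    scale = np.ptp(points, axis=0)
    u = (points - offset) / scale

    K = tps_kernel(cdist(u, u))
    P = np.column_stack([np.ones(n), u])
    A = np.zeros((n + 3, n + 3))
    A[:n, :n] = K + lam * np.eye(n)
    A[:n, n:] = P
    A[n:, :n] = P.T
    b = np.concatenate([values, np.zeros(3)])
    try:
        sol = np.linalg.solve(A, b)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"TPS system is singular: {exc}") from exc
    w = sol[:n]
    a_std = sol[n:]

    # re-express the affine part on the original g/L scale
    a1 = a_std[1] / scale[0]
    a2 = a_std[2] / scale[1]
    a0 = a_std[0] - a1 * offset[0] - a2 * offset[1]
    return TPSModel(
        anchor_coords=points,
        rbf_weights=w,
        affine=np.array([a0, a1, a2]),
        lam=lam,
        offset=offset,
        scale=scale,
    )


def tps_predict(model: TPSModel, coords) -> np.ndarray:
    """Evaluate the fitted spline at (p, c) coordinates."""
    coords = np.asarray(coords, dtype=float).reshape(-1, 2)
    u = (coords - model.offset) / model.scale
    K = tps_kernel(cdist(u, model.std_coords()))
    a = model.affine
    return a[0] + a[1] * coords[:, 0] + a[2] * coords[:, 1] + K @ model.rbf_weights


def tps_rss(model: TPSModel, values) -> float:
    """Residual sum of squares at the model's own anchors."""
    pred = tps_predict(model, model.anchor_coords)
    return float(np.sum((np.asarray(values, dtype=float) - pred) ** 2))


def tps_bending_energy(model: TPSModel) -> float:
    """w^T K w on the standardized scale (non-negative up to round-off)."""
    u = model.std_coords()
    K = tps_kernel(cdist(u, u))
    return float(model.rbf_weights @ K @ model.rbf_weights)


def reconstruct_landscape(
    anchor_values: list[tuple[AnchorPoint, float]],
    space: NutrientSpace,
    spacing: float,
    lam: float = 0.05,
    trait_name: str = "trait",
    design: Design | None = None,
) -> Landscape:
    """Fit a TPS to anchor values and evaluate it on the dense regular grid."""
    pts = np.array([[a.p, a.c] for a, _ in anchor_values], dtype=float)
    vals = np.array([v for _, v in anchor_values], dtype=float)
    model = tps_fit(pts, vals, lam=lam)
    grid = make_grid(space, spacing)
    pred = tps_predict(model, grid)
    meta = {"lambda": lam, "n_anchors": int(len(pts))}
    if design is not None:
        meta["strategy"] = design.strategy
        meta["resolution"] = design.resolution
    return Landscape(
        trait_name=trait_name,
        grid_spacing=spacing,
        p=grid[:, 0],
        c=grid[:, 1],
        values=pred,
        meta=meta,
    )
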