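"""Reconstruction accuracy metrics and the strategy-comparison experiment.

The accuracy metric is a binned "topological profile": grid points of the
baseline and reconstructed landscapes are paired by identical coordinates,
the per-point distance is the absolute value difference, and points are
binned along x = protein * carbohydrate (the paired points share x, so the
Euclidean distance between profile points reduces to |delta value|).

``run_comparison`` orchestrates the full simulated experiment per
(baseline, strategy, resolution): sample a design, fit a quadratic surface
to the baseline, assign anchor values from it, reconstruct with a smoothed
TPS, estimate the peak, and profile the reconstruction against the
baseline.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from nutriscape.designs import (
    Design,
    NutrientSpace,
    gf_point,
    make_gf_design,
    make_hex_design,
    make_random_design,
    make_square_design,
)
from nutriscape.landscape import Landscape, fit_quadratic_surface, sample_design_values
from nutriscape.peaks import PeakEstimate, estimate_peak
from nutriscape.tps import reconstruct_landscape
from nutriscape.io_csv import RunConfig

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProfileBin:
    bin_index: int
    x_lo: float  # bounds on the P*C product, (g/L)^2
    x_hi: float
    mean_dist: float  # nan for empty bins
    sd_dist: float
    n_points: int


def _check_same_grid(a: Landscape, b: Landscape) -> tuple[np.ndarray, np.ndarray]:
    ia, ib = a.sort_index(), b.sort_index()
    ca = a.coords_array()[ia]
    cb = b.coords_array()[ib]
    if ca.shape != cb.shape or not np.allclose(ca, cb, atol=1e-9):
        if ca.shape != cb.shape:
            raise ValueError(
                f"landscapes have different grid sizes: {len(ca)} vs {len(cb)}"
            )
        bad = np.where(~np.all(np.isclose(ca, cb, atol=1e-9), axis=1))[0][0]
        raise ValueError(
            f"landscape grids differ at sorted position {bad}: "
            f"{tuple(ca[bad])} vs {tuple(cb[bad])}"
        )
    return ia, ib


def topological_profile(
    baseline: Landscape, reconstructed: Landscape, n_bins: int = 100
) -> list[ProfileBin]:
    """Mean/SD of |value difference| in equal-width bins of P*C."""
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    ia, ib = _check_same_grid(baseline, reconstructed)
    coords = baseline.coords_array()[ia]
    dist = np.abs(baseline.values[ia] - reconstructed.values[ib])
    x = coords[:, 0] * coords[:, 1]
    x_lo, x_hi = float(x.min()), float(x.max())
    if x_hi == x_lo:  # degenerate: single product value
        edges = np.array([x_lo, x_lo + 1.0])
        idx = np.zeros(len(x), dtype=int)
        n_bins = 1
    else:
        edges = np.linspace(x_lo, x_hi, n_bins + 1)
        # right-open bins, last bin closed
        idx = np.digitize(x, edges[1:-1], right=False)
    bins = []
    for i in range(n_bins):
        mask = idx == i
        n = int(mask.sum())
        bins.append(
            ProfileBin(
                bin_index=i,
                x_lo=float(edges[i]),
                x_hi=float(edges[i + 1]),
                mean_dist=float(dist[mask].mean()) if n else float("nan"),
                sd_dist=float(dist[mask].std(ddof=0)) if n else float("nan"),
                n_points=n,
            )
        )
    return bins


def overall_mean_distance(baseline: Landscape, reconstructed: Landscape) -> float:
    ia, ib = _check_same_grid(baseline, reconstructed)
    return float(np.abs(baseline.values[ia] - reconstructed.values[ib]).mean())


def top_decile_mean_distance(profile: Sequence[ProfileBin]) -> float:
    """Mean distance over the non-empty bins in the top 10% of the P*C axis."""
    n = len(profile)
    top = [b for b in profile[int(math.ceil(0.9 * n)):] if b.n_points > 0]
    if not top:
        return float("nan")
    return float(np.mean([b.mean_dist for b in top]))


# ---------------------------------------------------------------------------
# design construction for the comparison loop


def gf_concentrations(
    space: NutrientSpace, ratios: Sequence[float], n_levels: int
) -> list[float]:
    """Evenly spaced total-concentration levels that keep all rails in-space."""
    conc_max = math.inf
    for ratio in ratios:
        lo = 0.0
        hi = (space.p_max + space.c_max) * 2
        for _ in range(80):  # bisect the largest in-space concentration
            mid = 0.5 * (lo + hi)
            p, c = gf_point(ratio, mid)
            if space.contains(p, c):
                lo = mid
            else:
                hi = mid
        conc_max = min(conc_max, lo)
    return [conc_max * (i + 1) / n_levels for i in range(n_levels)]


def build_design(
    strategy: str,
    resolution: int,
    space: NutrientSpace,
    seed: int = 0,
    gf_ratios: Sequence[float] = (1 / 16, 1 / 8, 1 / 4, 1 / 2, 1.0, 2.0),
) -> Design:
    """Dispatch to the four generators.

    For the fixed-ratio strategy the requested resolution sets the number
    of concentration levels per rail (round(resolution / n_rails)), so the
    anchor count approximates — but need not equal — the other strategies'.
    """
    if strategy in ("hexagonal", "hex"):
        return make_hex_design(space, resolution)
    if strategy in ("square", "sq"):
        return make_square_design(space, resolution)
    if strategy in ("random", "rand"):
        return make_random_design(space, resolution, seed)
    if strategy == "gf":
        n_levels = max(1, round(resolution / len(gf_ratios)))
        concs = gf_concentrations(space, gf_ratios, n_levels)
        return make_gf_design(space, list(gf_ratios), concs)
    raise ValueError(f"unknown strategy {strategy!r}")


# ---------------------------------------------------------------------------
# full comparison


@dataclass
class ComparisonRecord:
    trait: str
    strategy: str
    resolution: int
    n_anchors: int
    seed: int
    peak: PeakEstimate
    profile: list[ProfileBin]
    overall_mean_dist: float
    reconstructed: Landscape | None = None


@dataclass
class ComparisonResult:
    records: list[ComparisonRecord] = field(default_factory=list)
    config: RunConfig | None = None

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "trait": r.trait,
                    "strategy": r.strategy,
                    "resolution": r.resolution,
                    "n_anchors": r.n_anchors,
                    "pc_ratio": r.peak.pc_ratio,
                    "boundary_flag": r.peak.boundary_flag,
                    "centroid_p": r.peak.centroid[0],
                    "centroid_c": r.peak.centroid[1],
                    "peak_area": r.peak.area,
                    "overall_mean_dist": r.overall_mean_dist,
                }
            )
        return pd.DataFrame(rows)

    def metrics_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            for b in r.profile:
                rows.append(
                    {
                        "trait": r.trait,
                        "strategy": r.strategy,
                        "resolution": r.resolution,
                        "bin_index": b.bin_index,
                        "x_lo": b.x_lo,
                        "x_hi": b.x_hi,
                        "n_points": b.n_points,
                        "mean_dist": b.mean_dist,
                        "sd_dist": b.sd_dist,
                    }
                )
        return pd.DataFrame(rows)

    def peaks_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            e = r.peak.ellipse
            rows.append(
                {
                    "trait": r.trait,
                    "strategy": r.strategy,
                    "resolution": r.resolution,
                    "quantile": r.peak.quantile,
                    "centroid_p": r.peak.centroid[0],
                    "centroid_c": r.peak.centroid[1],
                    "pc_ratio": r.peak.pc_ratio,
                    "boundary_flag": r.peak.boundary_flag,
                    "ellipse_a": e.a,
                    "ellipse_b": e.b,
                    "ellipse_angle": e.angle,
                    "area": r.peak.area,
                }
            )
        return pd.DataFrame(rows)

    def get(self, trait: str, strategy: str, resolution: int) -> ComparisonRecord:
        for r in self.records:
            if (r.trait, r.strategy, r.resolution) == (trait, strategy, resolution):
                return r
        raise KeyError((trait, strategy, resolution))


def simulate_reconstruction(
    baseline: Landscape,
    design: Design,
    space: NutrientSpace,
    config: RunConfig,
    seed: int = 0,
) -> Landscape:
    """Steps ii-iii of the simulated experiment for one design."""
    surface = fit_quadratic_surface(baseline)
    anchor_values = sample_design_values(
        surface, design, noise_sd=config.noise_sd, seed=seed
    )
    return reconstruct_landscape(
        anchor_values,
        space,
        config.spacing,
        lam=config.lam,
        trait_name=baseline.trait_name,
        design=design,
    )


def run_comparison(
    baselines: Mapping[str, Landscape] | Sequence[Landscape],
    strategies: Sequence[str] | None = None,
    resolutions: Sequence[int] | None = None,
    config: RunConfig | None = None,
    keep_landscapes: bool = False,
) -> ComparisonResult:
    """The full strategy-comparison experiment over all combinations."""
    config = config or RunConfig()
    strategies = list(strategies or config.strategies)
    resolutions = list(resolutions or config.resolutions)
    if isinstance(baselines, Mapping):
        items = list(baselines.items())
    else:
        items = [(ls.trait_name, ls) for ls in baselines]

    space = config.space
    result = ComparisonResult(config=config)
    for t_idx, (trait, baseline) in enumerate(items):
        for s_idx, strategy in enumerate(strategies):
            for resolution in resolutions:
                # stable per-combination seed derived from the config seed
                seed = config.seed * 1_000_003 + t_idx * 10_007 + s_idx * 101 + resolution
                try:
                    design = build_design(
                        strategy, resolution, space, seed=seed, gf_ratios=config.gf_ratios
                    )
                    recon = simulate_reconstruction(
                        baseline, design, space, config, seed=seed
                    )
                    peak = estimate_peak(
                        recon,
                        space,
                        quantile=config.quantile,
                        k=config.ellipse_k,
                        clip_to=design.coords_array() if config.clip_to_hull else None,
                    )
                    profile = topological_profile(baseline, recon, config.n_bins)
                    overall = overall_mean_distance(baseline, recon)
                except Exception as exc:
                    raise RuntimeError(
                        f"comparison failed for trait={trait!r} "
                        f"strategy={strategy!r} resolution={resolution}: {exc}"
                    ) from exc
                logger.info(
                    "compared trait=%s strategy=%s resolution=%d seed=%d",
                    trait,
                    strategy,
                    resolution,
                    seed,
                )
                result.records.append(
                    ComparisonRecord(
                        trait=trait,
                        strategy=strategy,
                        resolution=resolution,
                        n_anchors=len(design),
                        seed=seed,
                        peak=peak,
                        profile=profile,
                        overall_mean_dist=overall,
                        reconstructed=recon if keep_landscapes else None,
                    )
                )
    return result
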