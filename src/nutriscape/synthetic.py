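"""Synthetic baseline landscapes and diet-trait tables.

Three built-in archetypes mimic the qualitative structure of classic
fly diet-response traits:

* ``lifespan_like`` — peak on the carbohydrate axis (P:C ~ 0:1), realized
  as a half-Gaussian truncated at p = 0 so the maximum sits exactly on the
  boundary;
* ``lifetime_eggs_like`` — interior peak at P:C = 1:3;
* ``daily_eggs_like`` — interior peak at P:C = 1:2.

Shapes are (optionally correlated) bivariate Gaussians.  Default peak
locations were chosen central enough in the default space that the
quadratic-surface step of the simulated experiment preserves each
archetype's peak ratio (kernels hugging a domain edge provably do not
survive a global quadratic fit).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from nutriscape.designs import Design, NutrientSpace
from nutriscape.landscape import Landscape, make_grid


@dataclass(frozen=True)
class Scenario:
    name: str
    peak_p: float
    peak_c: float
    amplitude: float = 100.0
    sigma_p: float = 20.0
    sigma_c: float = 20.0
    rho: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")
        if not abs(self.rho) < 1:
            raise ValueError("|rho| must be < 1")
        if self.sigma_p <= 0 or self.sigma_c <= 0:
            raise ValueError("sigma_p and sigma_c must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def peak_ratio(self) -> float:
        return self.peak_p / self.peak_c


#: Archetype defaults on the standard [0, 60] x [0, 120] g/L space.
SCENARIO_DEFAULTS: dict[str, dict] = {
    "lifespan_like": dict(peak_p=0.0, peak_c=75.0, sigma_p=10.0, sigma_c=30.0, rho=0.0),
    "lifetime_eggs_like": dict(peak_p=20.0, peak_c=60.0, sigma_p=20.0, sigma_c=20.0, rho=0.0),
    "daily_eggs_like": dict(peak_p=30.0, peak_c=60.0, sigma_p=20.0, sigma_c=20.0, rho=0.0),
}


def make_scenario(name: str, space: NutrientSpace | None = None, **overrides) -> Scenario:
    """Build a named archetype (or ``custom`` with explicit parameters)."""
    if name == "custom":
        params = dict(overrides)
    elif name in SCENARIO_DEFAULTS:
        params = dict(SCENARIO_DEFAULTS[name])
        params.update(overrides)
    else:
        raise ValueError(
            f"unknown scenario {name!r}; choose from "
            f"{sorted(SCENARIO_DEFAULTS)} or 'custom'"
        )
    scenario = Scenario(name=name, **params)
    if space is not None:
        if not space.contains(scenario.peak_p, scenario.peak_c):
            raise ValueError(
                f"scenario peak ({scenario.peak_p}, {scenario.peak_c}) lies "
                "outside the nutrient space"
            )
    return scenario


def scenario_surface(scenario: Scenario, p, c) -> np.ndarray:
    """Noiseless trait surface value at (p, c); vectorized.

    Correlated bivariate Gaussian bump with maximum ``amplitude`` at the
    scenario peak.  Boundary-peak scenarios are simply evaluated on the
    half-plane p >= 0, so their maximum lies on the axis.
    """
    p = np.asarray(p, dtype=float)
    c = np.asarray(c, dtype=float)
    dp = (p - scenario.peak_p) / scenario.sigma_p
    dc = (c - scenario.peak_c) / scenario.sigma_c
    rho = scenario.rho
    z = (dp * dp - 2.0 * rho * dp * dc + dc * dc) / (2.0 * (1.0 - rho * rho))
    return scenario.amplitude * np.exp(-z)


def scenario_landscape(
    scenario: Scenario, space: NutrientSpace, spacing: float
) -> Landscape:
    """Noiseless baseline landscape for the scenario on a regular grid."""
    grid = make_grid(space, spacing)
    values = scenario_surface(scenario, grid[:, 0], grid[:, 1])
    return Landscape(
        trait_name=scenario.name,
        grid_spacing=spacing,
        p=grid[:, 0],
        c=grid[:, 1],
        values=values,
        meta={
            "scenario": scenario.name,
            "peak_p": scenario.peak_p,
            "peak_c": scenario.peak_c,
            "seed": scenario.seed,
        },
    )


def scenario_diet_table(scenario: Scenario, design: Design) -> pd.DataFrame:
    """One observation row per anchor: surface value plus Gaussian noise.

    Reproducible under the scenario seed; ``noise_sd == 0`` gives exact
    surface values.
    """
    coords = design.coords_array()
    values = scenario_surface(scenario, coords[:, 0], coords[:, 1])
    if scenario.noise_sd > 0:
        rng = np.random.default_rng(scenario.seed)
        values = values + rng.normal(0.0, scenario.noise_sd, size=len(values))
    return pd.DataFrame(
        {
            "protein_gL": coords[:, 0],
            "carbohydrate_gL": coords[:, 1],
            scenario.name: values,
        }
    )


def with_noise(scenario: Scenario, noise_sd: float, seed: int | None = None) -> Scenario:
    """Copy of the scenario with a different noise level (and optional seed)."""
    kwargs = {"noise_sd": noise_sd}
    if seed is not None:
        kwargs["seed"] = seed
    return replace(scenario, **kwargs)
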