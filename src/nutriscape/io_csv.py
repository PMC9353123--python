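"""CSV I/O, run configuration, and metadata headers.

All artifacts are plain CSV (UTF-8, "." decimal, comma separator, mandatory
header row).  Files open with "#"-prefixed comment lines carrying tool
version, a config hash, and seeds, so every output is self-describing.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass, field, fields

import numpy as np
import pandas as pd
import yaml

from nutriscape.designs import AnchorPoint, Design, NutrientSpace
from nutriscape.landscape import Landscape

logger = logging.getLogger(__name__)

DEFAULT_GF_RATIOS = (1 / 16, 1 / 8, 1 / 4, 1 / 2, 1.0, 2.0)


@dataclass
class RunConfig:
    """All tunables of the simulated strategy comparison, with defaults."""

    p_min: float = 0.0
    p_max: float = 60.0
    c_min: float = 0.0
    c_max: float = 120.0
    spacing: float = 4.0  # baseline grid spacing (g/L)
    lam: float = 0.05  # TPS smoothing
    baseline_smoothing: float = 0.001
    n_bins: int = 100  # topological-profile bins
    quantile: float = 0.95  # peak-region threshold
    ellipse_k: float = 2.0
    noise_sd: float = 0.0  # simulated experiments are noiseless by default
    clip_to_hull: bool = True  # truncate peak estimation at the anchor hull
    strategies: tuple = ("gf", "hexagonal", "square", "random")
    resolutions: tuple = (30, 50, 250)
    seed: int = 0
    gf_ratios: tuple = DEFAULT_GF_RATIOS

    @property
    def space(self) -> NutrientSpace:
        return NutrientSpace(self.p_min, self.p_max, self.c_min, self.c_max)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["strategies"] = list(d["strategies"])
        d["resolutions"] = list(d["resolutions"])
        d["gf_ratios"] = list(d["gf_ratios"])
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("strategies", "resolutions", "gf_ratios"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


# ---------------------------------------------------------------------------
# metadata headers


def _version() -> str:
    from nutriscape import __version__

    return __version__


def write_csv_with_header(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    meta = dict(meta or {})
    meta.setdefault("tool", f"nutriscape {_version()}")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=False)


def read_csv_meta(path) -> dict:
    meta = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if ":" in line:
                key, _, value = line[1:].partition(":")
                meta[key.strip()] = value.strip()
    return meta


def read_csv_body(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# ---------------------------------------------------------------------------
# designs


def write_design_csv(design: Design, path, meta: dict | None = None) -> None:
    rows = []
    for i, pt in enumerate(design.points):
        rows.append(
            {
                "strategy": design.strategy,
                "point_id": i,
                "protein_gL": pt.p,
                "carbohydrate_gL": pt.c,
                "rail_ratio": pt.rail_ratio if pt.rail_ratio is not None else "",
                "concentration": pt.concentration if pt.concentration is not None else "",
            }
        )
    header = dict(meta or {})
    header["strategy"] = design.strategy
    header["resolution"] = design.resolution
    if design.cell_apothem is not None:
        header["cell_apothem"] = repr(design.cell_apothem)
    if design.seed is not None:
        header["seed"] = design.seed
    write_csv_with_header(pd.DataFrame(rows), path, header)


def read_design_csv(path) -> Design:
    meta = read_csv_meta(path)
    df = read_csv_body(path)
    points = []
    for _, row in df.iterrows():
        rail = row.get("rail_ratio")
        conc = row.get("concentration")
        rail = None if rail is None or (isinstance(rail, float) and math.isnan(rail)) else float(rail)
        conc = None if conc is None or (isinstance(conc, float) and math.isnan(conc)) else float(conc)
        points.append(
            AnchorPoint(
                float(row["protein_gL"]),
                float(row["carbohydrate_gL"]),
                rail_ratio=rail,
                concentration=conc,
            )
        )
    strategy = str(df["strategy"].iloc[0]) if len(df) else meta.get("strategy", "unknown")
    return Design(
        strategy=strategy,
        resolution=int(meta.get("resolution", len(points))),
        points=points,
        cell_apothem=float(meta["cell_apothem"]) if "cell_apothem" in meta else None,
        seed=int(meta["seed"]) if "seed" in meta else None,
    )


# ---------------------------------------------------------------------------
# landscapes


def write_landscape_csv(landscape: Landscape, path, meta: dict | None = None) -> None:
    header = dict(meta or {})
    header["grid_spacing"] = repr(landscape.grid_spacing)
    for key, value in landscape.meta.items():
        header.setdefault(str(key), value)
    write_csv_with_header(landscape.to_dataframe(), path, header)


def read_landscape_csv(path) -> Landscape:
    meta = read_csv_meta(path)
    df = read_csv_body(path)
    if "grid_spacing" not in meta:
        raise ValueError(f"{path}: missing grid_spacing metadata header")
    return Landscape(
        trait_name=str(df["trait"].iloc[0]),
        grid_spacing=float(meta["grid_spacing"]),
        p=df["protein_gL"].to_numpy(dtype=float),
        c=df["carbohydrate_gL"].to_numpy(dtype=float),
        values=df["value"].to_numpy(dtype=float),
        meta={k: v for k, v in meta.items() if k not in {"grid_spacing", "tool"}},
    )


# ---------------------------------------------------------------------------
# diet tables


def read_diet_table(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read a diet-trait table, applying an optional column renaming.

    ``column_map`` maps source column names to canonical ones, so external
    tables can be ingested without code changes.  Rows missing any trait
    value are dropped with a logged count.
    """
    df = read_csv_body(path)
    if column_map:
        df = df.rename(columns=column_map)
    required = ["protein_gL", "carbohydrate_gL"]
    missing = [col for col in required if col not in df.columns]
    if missing:
        raise ValueError(f"diet table {path} missing mandatory columns: {missing}")
    n_before = len(df)
    df = df.dropna()
    dropped = n_before - len(df)
    if dropped:
        logger.warning("dropped %d rows with missing values from %s", dropped, path)
    return df.reset_index(drop=True)


def write_diet_table(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    write_csv_with_header(df, path, meta)
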