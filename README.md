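# nutriscape

Simulation toolkit for comparing experimental sampling designs in
two-nutrient (protein x carbohydrate) performance-landscape studies.

Diet-response experiments traditionally place diets along "nutritional
rails" — rays of fixed protein:carbohydrate (P:C) ratio, subdivided by
total concentration — which leaves large parts of the nutrient space
unsampled. `nutriscape` quantifies what that costs. It:

1. generates anchor-point designs under four strategies — fixed-ratio
   rails (`gf`), hexagonal lattice, square lattice, and uniform random —
   with exact anchor counts (resolutions 30 / 50 / 250 by default);
2. builds dense baseline landscapes, either from an observed diet–trait
   table or from built-in synthetic archetypes (boundary peak at
   P:C ~ 0:1, interior peaks at 1:3 and 1:2);
3. simulates the experiment: a quadratic response surface fitted to the
   baseline assigns trait values to the anchors, and a smoothed
   thin-plate spline (TPS) reconstructs the landscape on a regular grid
   (4 g/L spacing, smoothing lambda = 0.05);
4. estimates the peak region (95th-percentile threshold, truncated at
   the area supported by the anchors), its centroid P:C ratio, and its
   area via a principal-component ellipse; and
5. scores reconstructions against the baseline with a binned topological
   profile (|value difference| binned along x = P*C, 100 bins).

## CLI

```sh
nutriscape design --strategy hex --resolution 50 --out design.csv
nutriscape synth --scenario daily_eggs_like --design hex --resolution 50 \
    --seed 1 --out-table diet_table.csv --out-landscape baseline.csv
nutriscape baseline --table diet_table.csv --out baseline.csv
nutriscape reconstruct --table diet_table.csv --lambda 0.05 --spacing 4 \
    --out recon.csv
nutriscape peaks --landscape recon.csv --out peaks.csv
nutriscape compare --traits lifespan_like,daily_eggs_like \
    --strategies gf,hexagonal,square,random --resolutions 30,50,250 \
    --seed 1 --outdir results/
```

All outputs are plain CSV with `#`-prefixed metadata headers (tool
version, config hash, seeds). `compare` writes `summary.csv` (peak ratio
and area per trait/strategy/resolution), `metrics.csv` (profile bins),
and `peaks.csv` (ellipse parameters). Defaults can be overridden with a
YAML config (`--config`); see `nutriscape.io_csv.RunConfig` for the keys.

The default nutrient space is [0, 60] x [0, 120] g/L; all commands accept
`--space pmin,pmax,cmin,cmax`.

## Conventions worth knowing

- **TPS smoothing.** The spline solves the standard bordered system with
  kernel d^2 log d on coordinates standardized to the unit square, with
  `lambda` added directly to the kernel diagonal (the same convention as
  scipy's `RBFInterpolator` smoothing). Other implementations rescale
  lambda internally; numeric equivalence with them is not promised.
- **Peak truncation.** Peak estimation only considers grid points
  supported by the design: inside the anchors' convex hull or within one
  median anchor spacing of an anchor. Sparse rail designs therefore
  yield truncated peak regions — one of the effects the simulation is
  designed to expose.
- **Boundary flag.** A peak is flagged as a boundary peak when its
  centroid lies within one grid spacing of the space edge or its region
  is truncated by the rim of the estimable area.
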