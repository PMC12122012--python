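# spheropack

Analysis of cell packing on spherical epithelial surfaces.

Growing hollow spheroids — such as lung alveolospheres, whose shell is a
single monolayer of alveolar epithelial cells — tile their curved
surface with cells whose neighbor statistics are surprisingly lawful:
the mean neighbor number is pinned by topology at `z_av = 6 − 12/N`, and
the *composition* of neighbor orders (fractions of cells with fewer
than, exactly, and more than six neighbors) is controlled by a single
dimensionless number, the ratio of the nuclear short axis to the average
cell size. `spheropack` implements that analysis end to end:

- **Spherical geometry** — geodesic distances, sphere fitting and radial
  projection of 3D nuclear centroids, the average occupied length
  `L_av = sqrt((4πR²/N)·(2/√3))`, and the effective hard-disk area
  fraction `φ = (π/(2√3)) x_min²`.
- **Tessellation** — spherical Voronoi neighbor topology via convex-hull
  duality, with the exact topological identities `Σ(6 − z_i) = 12` and
  `z_av = 6 − 12/N` verified on every configuration.
- **Packing simulation** — random sequential adsorption of N particles
  with pairwise geodesic distances ≥ `x_min·L_av`, plus an optional
  constraint-guarded Lloyd relaxation stage.
- **Order metrics** — neighbor-distance distributions and the
  `mean − 3 s.d.` estimator of the exclusion scale, bond-orientational
  order `|ψ6|`, and the geodesic radial distribution function `g(s)`
  normalized so uniform points give 1.
- **Phase analysis** — the structural gas-to-liquid transition: critical
  `x_c(N)` from the first peak of `g(s)`, a coordination-number
  alternative, ternary composition diagrams, phase classification, and
  trajectory-span motility statistics.
- **Synthetic alveolospheres** — a generator emulating nuclear-position
  data from growing spheroids (minimum-distance positions, per-cell
  nuclear sizes, saturating growth of the nucleus-to-cell ratio, osmotic
  compression/swelling, surface random-walk trajectories), so every
  stage of the pipeline runs with no external data.

## Worked example

```python
from spheropack import (
    sample_uniform_sphere, spherical_voronoi, neighbor_order_summary,
    PackingConfig, pack_ensemble,
)
import numpy as np

# topology pins the mean neighbor count
pts = sample_uniform_sphere(100, seed=1)
tess = spherical_voronoi(pts)
print(np.sum(6 - tess.z), tess.z_av)        # -> 12  5.88  (= 6 - 12/100)

# exclusion drives hexagonal order at fixed N
for x_min in (0.0, 0.3, 0.5, 0.7):
    packs = pack_ensemble(PackingConfig(N=800, x_min=x_min, seed=1), 5)
    f6 = [neighbor_order_summary(spherical_voronoi(p)).f_6 for p in packs]
    print(x_min, round(float(np.mean(f6)), 3))
```

prints

```
12 5.88
0.0 0.288
0.3 0.318
0.5 0.367
0.7 0.483
```

Twelve neighbor "defects" are forced by the sphere's topology no matter
how the 100 points are placed, and the hexagon fraction at N = 800 rises
from 0.29 (random, gas-like) to 0.48 as the minimum-distance constraint
tightens toward `x_min = 0.7` — the emergence of packing order from a
hard-disk exclusion alone. The `examples/` directory walks through each
capability: topology, packings, order metrics, a synthetic growth
series with matched simulations, osmotic perturbations, and the
gas-liquid phase diagram; each script prints the numbers it computes
with a note on what they mean.

A thin command-line interface wraps the same library:

```sh
spheropack synth --n 50,200,800 --seed 7 --out data/
spheropack analyze --points data/sample_N800.csv --out results/
spheropack phase --n-grid 100,400,800 --xmin-grid 0:0.7:0.1 --replicates 10 --seed 1 --out phase.json
```

Every run writes a JSON manifest (parameters, seed, package version)
sufficient to reproduce its outputs bitwise.

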