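# Methods

## Model overview

`spheropack` treats a spherical epithelial monolayer (an alveolosphere:
a hollow spheroid whose shell is a single layer of iPSC-derived alveolar
type II cells) as a set of N points — nuclear centroids — on a sphere of
radius R, and asks how ordered their packing is and what controls that
order. The working physical picture is that each cell's nucleus acts as
an effective hard disk of diameter d_n lying in the epithelial surface:
cell centers cannot approach each other closer than a minimum geodesic
distance set by the nuclear scale, and this single exclusion length,
together with the topology of the sphere, determines the observed
neighbor statistics.

All lengths are nondimensionalized by the average occupied length

    L_av = sqrt( (4 pi R^2 / N) * (2 / sqrt 3) ),

the diameter of the disk inscribed in the regular hexagon whose area is
the per-cell share of the surface. (The hexagon-equivalent form is the
unique choice for which the area fraction of exclusion disks of diameter
x_min L_av reduces exactly to the planar hexagonal-packing expression
phi = (pi / (2 sqrt 3)) x_min^2, so x_min = 1 corresponds to
phi = 0.9069, the hexagonal close-packing bound.) Neighbor distances
D_c become x = D_c / L_av, and the minimum distance becomes the
dimensionless exclusion scale x_min.

## Tessellation and topology

Neighbor relations are defined by the spherical Voronoi tessellation.
We exploit the duality between the Voronoi diagram of points on a sphere
and their convex hull (the spherical Delaunay triangulation): two
generators are neighbors iff they share a hull edge, and the Voronoi
vertices are the outward unit normals of the hull facets. Per-cell
polygon areas are accumulated from fan triangles by l'Huilier's formula
and sum to 4 pi R^2 to machine precision.

On a closed surface of Euler characteristic 2 with trivalent vertices,
the identities V - E + F = 2 and 3V = 2E force

    sum_i (6 - z_i) = 12,     z_av = 6 - 12/N,

independent of the configuration. This "topological charge" of 12 is
asserted for every tessellation the package builds. Degenerate
configurations in which four or more cells meet at a vertex (e.g. the
eight cube vertices as generators) are resolved by qhull's deterministic
facet triangulation, which splits each k-valent dual vertex into k - 2
coincident trivalent vertices — equivalent to a symbolic infinitesimal
perturbation of the generators. `verify_topology` checks the three
identities and reports how many degenerate vertices were resolved.

## Packing simulation

The baseline point process is random sequential adsorption (RSA):
candidates are drawn area-uniformly (normalized Gaussians) and rejected
when any placed particle lies within D_p_min = x_min L_av. With
x_min = 0 this is exactly i.i.d. uniform sampling. Failed insertions
trigger a full restart with a fresh stream (default 10 restarts, 10^4
attempts per particle) so no bias from jammed partial configurations
enters; RSA on a surface saturates near area fraction 0.547, and
configurations near that bound warn at construction. Everything is
reproducible from a single integer seed; ensembles derive replicate k's
seed as seed + k.

An optional relaxation stage (`relax_sweeps` in `PackingConfig`,
default 0) applies constraint-guarded Lloyd sweeps after insertion: each
point moves toward the area-weighted centroid of its Voronoi cell,
re-projected to the sphere, and any move that would violate the
minimum-distance constraint is rejected, so the exclusion postcondition
survives exactly. The stage is deterministic (no randomness) and is off
for all baseline simulations; it exists for the tissue generator (below).

## Order metrics

- Neighbor distances. One geodesic distance per Voronoi-adjacent pair.
  The exclusion scale of a sample is estimated as mean(x) - 3 sd(x) with
  the sample (n-1) standard deviation: for a distribution whose lower
  edge sits 3 standard deviations below the mean, this recovers the
  minimum. The estimator is exact for measured tissue-like
  distributions; on a broad RSA gas it underestimates severely (see
  "Generator" below).
- Bond-orientational order. psi6_i = (1/z_i) sum_j exp(6 i theta_ij)
  with theta_ij the angle of Voronoi neighbor j's direction projected
  into the tangent plane at i, measured against a deterministic tangent
  frame. Only |psi6_i| is frame- and rotation-invariant on a sphere
  (phases are gauge-dependent), so only magnitudes are reported or
  compared.
- Radial distribution function. g per geodesic-distance bin is the
  observed pair count divided by the uniform expectation
  (N(N-1)/2) * [cos(a/R) - cos(b/R)]/2 for bin (a, b], so area-uniform
  points give g = 1 everywhere and bins cover (0, pi R]. Default bin
  width is 0.1 L_av, which resolves the contact peak at every tested N.
  Ensembles average per-replicate g curves (not pooled counts).

A caveat found while validating: mean |psi6| is *not* monotone in x_min
at weak exclusion. At N = 800 the uniform gas gives <|psi6|> = 0.360
while x_min = 0.3 gives 0.355 (30 replicates, s.e.m. ~0.001); the dip
persists, slightly deeper, after Metropolis equilibration of the
constrained configurations, so it is a property of weakly-excluded
hard-disk fluids with Voronoi neighborhoods rather than an insertion
artifact. Order as measured by psi6 only rises clearly for
x_min >~ 0.5.

## Gas-liquid structural transition

A configuration ensemble is "liquid-like" when its averaged g develops a
first peak: the smallest-s local maximum exceeding 1 whose prominence
over the flanking minima is at least 0.1. Because g is a ratio of
Poisson counts, every bin fluctuates with standard error
~ 1/sqrt(expected pairs); a candidate peak must additionally exceed 1 by
at least 4.5 times its counting standard error. The 4.5 guard is a
Bonferroni-style control: a phase-diagram scan inspects a few thousand
bins, so holding the family-wise false-peak rate near 5% requires ~4.2
standard errors, while genuine contact peaks sit at >~15 standard errors
at every tested size — the guard costs no sensitivity.

x_c(N) is the smallest grid x_min whose ensemble g has a first peak; the
(N, x_c) curve is the gas-liquid boundary. `classify_phase` interpolates
x_c linearly in N and counts the boundary as liquid (inclusive) — an
arbitrary but fixed convention. An alternative boundary from the mean
coordination number (neighbors within the first minimum of g after the
first peak, threshold >= 1) is provided as a flagged best-effort
surrogate; it is validated only by agreeing with the g-peak boundary
within two grid steps, since no authoritative rule is available for it.

Compositions (f_{z<6}, f_{z=6}, f_{z>6}) are mapped to a ternary simplex
with corners z<6 at (0,0), z=6 at (1,0), z>6 at (1/2, sqrt3/2), for
overlaying growth trajectories on the boundary.

## Synthetic alveolosphere generator

The generator emulates the measured features of alveolosphere
nuclear-position data so the whole pipeline runs with no external data:

- Positions: a minimum-distance packing at x_min = dn_ratio (nuclei as
  hard disks) followed by 6 constraint-guarded Lloyd sweeps. The
  relaxation models the space-filling tendency of a confluent
  epithelium: measured tissue has neighbor-distance spread
  sd(x) ~ 0.13, whereas a plain RSA gas has ~0.30, far too broad for the
  mean - 3 s.d. estimator to be meaningful. The sweep count is
  calibrated once so that the estimator recovers the generation scale
  without bias at the study conditions (N = 800, ratio 0.57: estimate
  0.578 +- 0.006); the resulting spread, sd(x) ~ 0.15, remains somewhat
  wider than the measured 0.13 — a known limitation of using a single
  global relaxation stage.
- Nuclear sizes: per-cell d_n from a normal with mean
  dn_ratio * L_av and coefficient of variation `dn_ratio_cv`
  (default 0.1), truncated at zero by resampling. The distribution
  family is the least-structured positive choice; measurements show
  violin-shaped but unparameterized distributions.
- Growth series: one sample per N along the saturating curve
  r(N) = r_max N / (N_half + N), default plateau r_max = 0.575 (the
  measured modal nucleus-to-cell ratio of the BU3 donor line) and
  N_half = 50 as a realistic half-saturation for a ratio that rises
  during growth and plateaus at large N; no curve parameters are
  available to fit. A second preset, "SPC2-like" with plateau 0.50,
  illustrates a smaller-nucleus donor line qualitatively.
- Osmotic perturbations: compression multiplies dn_ratio by 1 + f,
  swelling by 1/(1 + f); positions are re-packed at the new x_min with N
  and R preserved, nuclear sizes redrawn at the scaled mean with the
  original CV.
- Trajectories: per-cell isotropic tangent-plane random walks with
  half-normal step lengths, re-projected to the sphere; defaults of 10
  frames at 15-minute intervals span the 150-minute observation window
  (first frame at t = 0, 135 minutes elapsed). Step-scale defaults are
  illustrative — no measured motility magnitudes are available — so
  trajectory statistics should be read comparatively (gas vs liquid
  side), not absolutely.

What the generator does *not* emulate: per-cell polydisperse exclusion
(a single scalar x_min constrains positions), elliptical nuclear
orientation, cell division during a growth series, active or correlated
motion, and any deviation of the shell from a perfect sphere. Passing
tests on synthetic data therefore demonstrate the correctness and
self-consistency of the analysis pipeline and the hard-disk model's
internal logic — not that real tissue obeys the model.

## Numerical choices

- Dot products are clamped to [-1, 1] before arccos everywhere.
- Sphere fitting is algebraic (linearized) least squares: closed-form
  and deterministic, adequate for near-spherical shells; the projection
  radius for explicit centers is the mean point-center distance.
- Coincident generators are rejected at 1e-9; SpherePoints renormalizes
  unit vectors to machine precision at construction.
- The tangent frame at p is built from the coordinate axis least aligned
  with p — deterministic, and immaterial to any reported quantity since
  only |psi6| is used.
- Sample standard deviations use ddof = 1 throughout (small-N samples).
- Default grids for phase scans: N in {20, 50, 100, 200, 400, 800,
  1000}, x_min from 0 to 0.7 in steps of 0.05, 30 replicates. Tests and
  examples use coarser grids (step 0.1) and 5-10 replicates; those are
  the package's default desk scales and leave boundary estimates stable
  to one grid step.

## Known limitations

- The RSA + optional-Lloyd pair brackets, but does not reproduce, the
  unknown generative process of real epithelial packing; in particular
  the relaxed process slightly under-orders large systems at fixed sweep
  count (mean f_6 at N = 800 sits ~0.01 below N = 400 at equal x_min).
  Combined with the saturating growth curve this makes the hexagon
  fraction plateau — not strictly rise — beyond N ~ 200, matching the
  qualitative observation that hexagon fractions saturate in large
  spheroids.
- The coordination-number boundary is a surrogate (see above).
- mean - 3 s.d. is a heuristic lower-edge estimator; its bias depends on
  the distribution shape and is only calibrated at the study conditions.
- The generator's bond-orientational order is flat in N (the relaxation
  stage saturates |psi6| near 0.5 at every size), so the slow rise of
  <|psi6|> with spheroid size seen in measurements is not emulated; only
  the uniform-baseline comparison (flat in N) is meaningful against it.
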