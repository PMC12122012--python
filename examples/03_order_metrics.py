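"""Order metrics of one configuration.

Analyzes a synthetic spheroid sample: the neighbor-distance distribution
and its mean - 3 s.d. estimate of the exclusion scale, the
bond-orientational order |psi6|, and (for a matched particle ensemble)
the geodesic radial distribution function g(s) with its first-peak test.
"""

from spheropack import (
    PackingConfig,
    detect_first_peak,
    ensemble_radial_distribution,
    estimate_xmin,
    generate_alveolosphere,
    neighbor_distances,
    pack_ensemble,
    psi6,
    spherical_voronoi,
)

sample = generate_alveolosphere(N=800, dn_ratio_mean=0.57, dn_ratio_cv=0.1, seed=2)
tess = spherical_voronoi(sample.points)

est = estimate_xmin(neighbor_distances(sample.points, tess))
print(f"neighbor distances: mean x = {est.mean:.3f}, sd = {est.sd:.3f} (x = D_c / L_av)")
print(f"mean - 3 s.d. estimate of x_min = {est.x_min:.3f}  (generation value 0.57)")
print(f"<|psi6|> = {psi6(sample.points, tess).mean:.3f}")

g = ensemble_radial_distribution(pack_ensemble(PackingConfig(N=800, x_min=0.57, seed=2), 10))
peak = detect_first_peak(g)
print(f"matched-ensemble g(s) first peak at s = {peak:.3f}" if peak else "g(s): no peak (gas-like)")
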