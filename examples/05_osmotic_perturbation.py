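"""Osmotic perturbation of a spheroid.

Compression shrinks cells relative to their (stiff) nuclei, raising the
nucleus-to-cell ratio d_n/L_av and with it the hexagon fraction;
swelling does the opposite.  The per-spheroid shift is small relative to
replicate scatter, so the mean over 20 spheroids is reported.
"""

import numpy as np

from spheropack import generate_alveolosphere, neighbor_order_summary, osmotic_perturbation, spherical_voronoi

f6 = {"control": [], "compressed": [], "swollen": []}
for seed in range(20):
    s = generate_alveolosphere(N=400, dn_ratio_mean=0.5, dn_ratio_cv=0.1, seed=seed)
    c = osmotic_perturbation(s, "compress", 0.15, seed=100 + seed)
    w = osmotic_perturbation(s, "swell", 0.15, seed=200 + seed)
    for sample in (s, c, w):
        f6[sample.condition].append(neighbor_order_summary(spherical_voronoi(sample.points)).f_6)

for cond in ("swollen", "control", "compressed"):
    vals = f6[cond]
    ratio = {"swollen": 0.5 / 1.15, "control": 0.5, "compressed": 0.5 * 1.15}[cond]
    print(f"{cond:>10s}: d_n/L_av = {ratio:.3f}  hexagon fraction = {np.mean(vals):.3f} +- {np.std(vals, ddof=1):.3f}")
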