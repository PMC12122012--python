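"""Neighbor topology of points on a sphere.

Builds spherical Voronoi tessellations for platonic solids and a random
cloud and prints the per-cell neighbor counts, the mean neighbor number
z_av, and the topological charge sum(6 - z_i).  On any sphere the charge
is exactly 12 and z_av = 6 - 12/N: twelve "missing" neighbors are forced
by the surface topology no matter how the points are arranged.
"""

import numpy as np

from spheropack import SpherePoints, neighbor_order_summary, sample_uniform_sphere, spherical_voronoi

tetra = SpherePoints(np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]]) / np.sqrt(3))
cloud = sample_uniform_sphere(100, seed=1)

for name, pts in [("tetrahedron (N=4)", tetra), ("uniform random (N=100)", cloud)]:
    tess = spherical_voronoi(pts)
    s = neighbor_order_summary(tess)
    print(f"{name}:")
    print(f"  z_av = {s.z_av:.4f}  (theory 6 - 12/N = {6 - 12 / pts.N:.4f})")
    print(f"  topological charge sum(6 - z_i) = {int(np.sum(6 - tess.z))}")
    print(f"  fractions  z<6: {s.f_lt6:.2f}  z=6: {s.f_6:.2f}  z>6: {s.f_gt6:.2f}")
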