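"""The structural gas-to-liquid transition.

Scans a small (N, x_min) grid, finds the critical exclusion scale x_c(N)
where the radial distribution function first develops a peak, classifies
the synthetic growth trajectory against that boundary, and compares cell
motility (trajectory spans) on the two sides.  Growing spheroids cross
from the gas side to the liquid side as their nucleus-to-cell ratio
rises.
"""

import numpy as np

from spheropack import (
    classify_phase,
    compute_phase_diagram,
    generate_alveolosphere,
    generate_trajectories,
    saturating_dn_ratio,
    ternary_map,
    trajectory_span,
)

Ns = [50, 200, 800]
diagram = compute_phase_diagram(Ns, np.round(np.arange(0, 0.71, 0.1), 2), replicates=5, seed=3)
print("gas-liquid boundary x_c(N):", dict(zip(Ns, diagram.x_c)))

for n in Ns:
    r = float(saturating_dn_ratio(np.array([n]))[0])
    phase = classify_phase(n, r, diagram)
    xy = ternary_map(diagram.fractions[Ns.index(n), -1])
    print(f"N={n:4d}: growth-path x_min={r:.3f} -> {phase}; ternary coords of x_min=0.7 cell: ({xy[0]:.3f}, {xy[1]:.3f})")

# motility: gas-phase cells roam further than liquid-phase cells
small = generate_alveolosphere(N=50, R=30.0, dn_ratio_mean=0.3, seed=1)
large = generate_alveolosphere(N=800, R=160.0, dn_ratio_mean=0.55, seed=1)
fast = trajectory_span(generate_trajectories(small, step_scale=2.0, frames=10, seed=2))
slow = trajectory_span(generate_trajectories(large, step_scale=1.0, frames=10, seed=2))
print(f"mean trajectory span over 10 frames: small/gas {fast.mean:.2f} um, large/liquid {slow.mean:.2f} um")
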