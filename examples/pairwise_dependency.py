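"""Classifying pairwise interactions: competition vs conditional mutualism.

Pin one organism's abundance on a grid and track the allowed abundance
range of a second.  Two organisms competing for one substrate show a
strictly falling ceiling (max X_B = X0 - a).  Adjacent members of a
cross-feeding ring show a rising region — more of the partner means
more of its amino acid — before total-biomass accounting pushes the
ceiling back down.
"""

import numpy as np

from steadycom import fixtures, pairwise_fva, solve_steadycom
from steadycom.fixtures import ToySpec, build_toy

competitive = build_toy(
    ToySpec(2, {"org1": 1.0, "org2": 1.0}, community_uptake={"s": 2.0})
)
mu_max = solve_steadycom(competitive).mu_max
scan = pairwise_fva(competitive, "org1", "org2", mu_frac=0.9, mu_max=mu_max,
                    grid=np.linspace(0.1, 0.9, 9))
print(f"shared substrate: {scan.classification}")
print(scan.to_frame().to_string(index=False, float_format=lambda v: f"{v:.3f}"))

ring = fixtures.make_auxotroph_ring(4)
mu_max = solve_steadycom(ring).mu_max
scan = pairwise_fva(ring, "org1", "org2", mu_frac=0.9, mu_max=mu_max)
print(f"\ncross-feeding ring: {scan.classification}")
# dep_max first rises with the fixed abundance (mutualistic region),
# then falls; grid points outside the feasible band are marked absent.
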