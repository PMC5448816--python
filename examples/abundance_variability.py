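"""How much can member abundances vary at a given community growth rate?

Four obligate cross-feeders form a ring: each needs an amino acid made
only by its predecessor.  Flux variability analysis at fractions of the
maximal growth rate shows every member is essential (its minimum
abundance is positive) and bands at higher growth nest inside those at
lower growth.  For this ring the bands are set by the amino-acid
production/consumption ratios, which scale with growth, so they are
identical at every positive fraction — communities with maintenance
demands or multiple substrates show genuine narrowing.
"""

from steadycom import abundance_fva, fixtures, solve_steadycom

cm = fixtures.make_auxotroph_ring(n=4, export_yield=1.5, uptake=1.0)
res = solve_steadycom(cm)
print(f"mu_max = {res.mu_max:.6f} h^-1")

table = abundance_fva(cm, mu_fracs=[0.5, 0.9, 0.99], mu_max=res.mu_max)
print(table.to_string(index=False, float_format=lambda v: f"{v:.4f}"))

# Each row is one organism at one growth fraction: [min, max] is the
# range of biomass fractions compatible with that growth rate.  No
# minimum is 0: every member is obligate at any positive growth.
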