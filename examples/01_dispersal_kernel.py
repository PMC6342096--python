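"""Build the annual dispersal kernel and summarize how far deer move.

The short-term movement matrix is a softmax over each cell's queen
neighbourhood with distance decay β0; sixteen repeated short-term moves
(Δt = 1/16 year, 22.8 days each) give the annual kernel.  On a homogeneous
landscape the reference β0 = −1.852 yields a root-mean-square annual
displacement of about 6.5 km.
"""

import gridpop as gp

land = gp.build_lattice(35, 35, cell_side=2.0)
params = gp.default_psi().movement()
kernel = gp.build_kernel(land, params)

origin = 17 * 35 + 17                       # central cell
stats = gp.displacement_stats(kernel, land, origin)
stay = kernel.annual[origin, origin]

print(f"short-term step length : {params.days_per_step:.1f} days")
print(f"P(stay in natal cell)  : {stay:.3f}")
print(f"mean displacement      : {stats['mean_km']:.2f} km/year")
print(f"RMS displacement       : {stats['rms_km']:.2f} km/year")
print()
print("The RMS displacement is the 'annual dispersal distance' of the")
print("homogeneous-landscape kernel; covariates (forest, rivers) make it")
print("directional and spatially variable on real landscapes.")
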