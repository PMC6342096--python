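"""Simulate a decade of range expansion and the surveys observing it.

A synthetic landscape (smooth forest covariates, rivers, management units,
a contiguous initial range) is populated at the reference parameters and
pushed through the annual cycle: Poisson growth, unit-level hunting removal,
multinomial dispersal.  The survey generator then produces the three data
streams the inference machinery consumes: sparse pellet counts, block
counts in a few units, and unit hunting totals.
"""

import numpy as np

import gridpop as gp

land = gp.make_landscape(12, 12, seed=7)
psi = gp.default_psi()
states, data = gp.simulate_dataset(land, psi, years=8, seed=3)

print("year  total  occupied-cells")
for s in states:
    print(f"{s.year:4d} {s.N_r.sum():6d} {int((s.N_r > 0).sum()):10d}")

print()
print(f"pellet records : {len(data.pellet):4d} "
      f"({100 * len(data.pellet) / (land.n * len(states)):.1f}% of cell-years)")
print(f"block records  : {len(data.block):4d}")
print(f"hunted total   : {int(data.hunting['total'].sum()):4d} deer over "
      f"{data.hunting['year'].nunique()} years")
print()
print("Totals grow at roughly r(1-h) ~ 1.25/year while the occupied area")
print("expands by dispersal; the surveys cover only a sparse fraction of")
print("cell-years, which is what makes the estimation problem hard.")
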