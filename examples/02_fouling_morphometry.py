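"""Apply synthetic protein fouling and quantify the structural change.

Fouling converts pore-wall voxels to solid with a bias toward small
pores and exit-proximal depths, emulating protein deposition in the
size-selective layer.  The morphometric signature to look for: porosity
drops everywhere (most near the exit), and the count of small pores
falls much more than the count of large pores.
"""

import numpy as np

from poreflow import (
    FoulingSpec,
    MembraneProfile,
    apply_fouling,
    generate_membrane,
    pore_size_distribution,
    porosity_profile,
)

membrane = generate_membrane(MembraneProfile.default(thickness_um=64 * 7e-3), (64, 64, 64), seed=1)
fouled = apply_fouling(membrane, FoulingSpec(deposit_fraction=0.4), seed=2)

p0, p1 = porosity_profile(membrane), porosity_profile(fouled)
print("porosity per 250 nm slab (clean -> fouled):")
for mid, a, b in zip(p0.midpoints_um, p0.porosity, p1.porosity):
    print(f"  z = {mid:5.2f} µm   {a:.3f} -> {b:.3f}")

d0 = pore_size_distribution(membrane).diameters_nm
d1 = pore_size_distribution(fouled).diameters_nm
small0, small1 = (d0 <= 21).sum(), (d1 <= 21).sum()
large0, large1 = (d0 >= 42).sum(), (d1 >= 42).sum()
print(f"\nsmall-pore voxels (<= 21 nm): {small0} -> {small1}  ({small1 / small0:.2f}x)")
print(f"large-pore voxels (>= 42 nm): {large0} -> {large1}  ({large1 / max(large0, 1):.2f}x)")
print("The small-pore count shrinks by the larger factor: deposition preferentially")
print("blocks the smallest pores, the mechanism behind flux decline in fouled filters.")
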