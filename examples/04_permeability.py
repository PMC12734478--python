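"""Stokes permeability of clean and fouled membranes.

Solves creeping flow through the voxel pore space at a 210 kPa
transmembrane pressure (no-slip walls, lateral symmetry, open
inlet/outlet) and reports the permeability in the membrane-practice
units L m⁻² h⁻¹ kPa⁻¹ together with the flux-decline ratio J/J0.
"""

from poreflow import (
    FoulingSpec,
    MembraneProfile,
    apply_fouling,
    flux_ratio,
    generate_membrane,
    permeability,
    solve_stokes,
    verify_pressure_match,
)

membrane = generate_membrane(MembraneProfile.default(thickness_um=48 * 7e-3), (48, 48, 48), seed=1)
fouled = apply_fouling(membrane, FoulingSpec(deposit_fraction=0.35), seed=2)

field_clean = solve_stokes(membrane, delta_p_kpa=210.0)
k_clean = permeability(field_clean, membrane)
ok, achieved = verify_pressure_match(field_clean, 210.0, rel_tol=1e-3)
print(f"clean:  kappa = {k_clean.kappa:6.2f} L/m2/h/kPa  "
      f"(dP = {achieved:.2f} kPa, match within 0.21 kPa: {ok}, "
      f"divergence {field_clean.max_divergence:.1e})")

field_fouled = solve_stokes(fouled, delta_p_kpa=210.0, warm_start=field_clean)
k_fouled = permeability(field_fouled, fouled)
print(f"fouled: kappa = {k_fouled.kappa:6.2f} L/m2/h/kPa")

jj0 = flux_ratio(k_fouled.kappa, k_clean.kappa)
print(f"\nflux ratio J/J0 = {jj0:.2f} — the fraction of clean-membrane flux that")
print("survives fouling; 1 - J/J0 is the flux decline a constant-pressure")
print("filtration experiment would measure.")
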