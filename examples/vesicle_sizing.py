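"""Vesicle size from the encapsulated-water diffusion coefficient.

Encapsulated water diffuses with the vesicle carrying it, so the slow
diffusion coefficient sizes the vesicle through the Stokes-Einstein
relation; subtracting two bilayer wall thicknesses gives the aqueous core.
"""

import ufdexsy as u

d_slow = 6.0e-11  # m^2/s, the slow (vesicle-bound) diffusion coefficient
geo = u.GeometryParams(temperature=298.0, viscosity=1.13e-3,
                       monomer_length=1.2e-9)

d_outer = u.hydrodynamic_diameter(d_slow, geo)
d_core = u.core_diameter(d_outer, geo.monomer_length)
print(f"D = {d_slow:.1e} m^2/s at {geo.temperature:.0f} K, "
      f"eta = {1e3 * geo.viscosity:.2f} mPa s")
print(f"vesicle hydrodynamic diameter: {1e9 * d_outer:.2f} nm")
print(f"aqueous core diameter:         {1e9 * d_core:.2f} nm "
      f"(bilayer wall = 2 x {1e9 * geo.monomer_length:.1f} nm per side)")
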