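"""Immersion-test bookkeeping: hydrogen volume → mass loss → corrosion rate.

Magnesium dissolving in simulated body fluid releases one mole of H2 per mole
of Mg, so the collected gas volume converts to corroded mass, and mass (or
µCT volume loss) converts to a mm/year corrosion rate via
CR = 8.76e4 · W / (A · t · ρ).
"""

import pitscan as ps

# a 2-week immersion: 28 mL of hydrogen collected from a specimen with
# 2.0 cm² exposed surface
v_h2_ml, area_cm2, time_h, rho = 28.0, 2.0, 336.0, 1.84

w = ps.mass_from_hydrogen(v_h2_ml)
cr_h2 = ps.corrosion_rate(w, area_cm2, time_h, rho)
print(f"H2 collected           : {v_h2_ml:.0f} mL")
print(f"corroded Mg mass       : {w:.4f} g")
print(f"corrosion rate (H2)    : {cr_h2:.2f} mm/year")

# the same specimen's µCT scan shows 49 mm³ of core volume lost
dv_mm3 = 49.0
w_ct = ps.mass_from_volume_loss(dv_mm3, rho)
cr_ct = ps.corrosion_rate(w_ct, area_cm2, time_h, rho)
print(f"µCT volume loss        : {dv_mm3:.0f} mm³  →  {w_ct:.4f} g")
print(f"corrosion rate (µCT)   : {cr_ct:.2f} mm/year")
print(f"µCT / H2 rate ratio    : {ps.rate_ratio(cr_ct, cr_h2):.2f}")
print()
print(f"gauge cross-section    : {ps.nominal_area(1.5):.2f} mm² (r = 1.5 mm)")
print(f"V/S sufficiency        : {ps.volume_to_surface_sufficiency(3.36):.1f}×"
      " the 0.20 mL/mm² immersion-standard minimum")
print()
print("Hydrogen capture systematically underestimates the loss (gas escapes,")
print("hydrogen binds into the degradation layer), so the µCT rate is the")
print("more reliable of the two; the ratio quantifies the gap.")
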