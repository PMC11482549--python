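"""Laminar shear stress and flow-rate design for the perfusion channel.

Uses the study channel (1 mm x 50 um, cell culture medium at 37 C,
40 uL/min) to compute the mean inlet velocity, the parallel-plates and
series-solution wall shear, the Reynolds number, and the flow rate needed
to hit a physiological 12 dyn/cm^2 target.
"""

from barrierkit.hemodynamics import (
    ChannelGeometry,
    FlowConditions,
    design_flow_rate,
    duct_wall_shear_profile,
    mean_inlet_velocity,
    plates_wall_shear,
    reynolds_number,
)

geom = ChannelGeometry(width_m=1e-3, height_m=50e-6, length_m=15e-3)
flow = FlowConditions.from_ul_min(40.0)  # rho=1012 kg/m^3, mu=0.964 mPa s

u = mean_inlet_velocity(geom, flow)
print(f"mean inlet velocity: {u:.4f} m/s (prints as 0.013)")

tau_plates = plates_wall_shear(geom, flow)
profile = duct_wall_shear_profile(geom, flow)
mid = len(profile.bottom_dyn_cm2) // 2
print(f"wall shear, plates formula 6 mu Q/(w h^2): {tau_plates:.1f} dyn/cm^2")
print(f"wall-centre shear, duct series solution:  "
      f"{profile.bottom_dyn_cm2[mid]:.1f} dyn/cm^2")
print("(brain capillaries in vivo: ~11-13 dyn/cm^2)")

re_dh = reynolds_number(geom, flow, "hydraulic_diameter")
re_h = reynolds_number(geom, flow, "height")
print(f"Reynolds number: {re_dh:.2f} (hydraulic diameter) / "
      f"{re_h:.2f} (height) -> deeply laminar")

q12 = design_flow_rate(geom, flow.mu_pa_s, target_shear_dyn_cm2=12.0)
print(f"flow rate for a 12 dyn/cm^2 target: {q12:.1f} uL/min")
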