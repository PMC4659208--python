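"""Derive the pressure boundary conditions from vital signs.

Walks the chain MAP -> CPP -> territorial CVRs at the default resting
parameterization (DP 80, SP 120, HR 80; ICP 3 mmHg; CBF 12.5 ml/s split
22/45/33 % over ACA/MCA/PCA) and prints each station.
"""
from cowflow import (PerfusionConstants, VitalSigns, build_boundary_set,
                     cerebral_perfusion_pressure, mean_arterial_pressure)

vitals = VitalSigns()
constants = PerfusionConstants()

map_full = mean_arterial_pressure(vitals)
cpp = cerebral_perfusion_pressure(map_full, constants.intracranial_pressure)
boundary = build_boundary_set(vitals, constants)

print(f"mean arterial pressure : {map_full:7.3f} mmHg  (reported: {round(map_full)})")
print(f"perfusion pressure     : {cpp:7.3f} mmHg  (reported: {round(cpp)})")
print(f"CVR ACA territory      : {boundary.cvr_aca:7.4f} mmHg/ml/min "
      f"(reported: {boundary.cvr_aca:.2f})")
print(f"CVR MCA territory      : {boundary.cvr_mca:7.4f} mmHg/ml/min "
      f"(reported: {boundary.cvr_mca:.2f})")
print(f"CVR PCA territory      : {boundary.cvr_pca:7.4f} mmHg/ml/min "
      f"(reported: {boundary.cvr_pca:.2f})")
print(f"outlet pressures       : ACA {boundary.outlet_pressure_aca}, "
      f"MCA {boundary.outlet_pressure_mca}, PCA {boundary.outlet_pressure_pca} mmHg")
# The inlet (CPP) and the three outlet pressures are everything the
# network solver needs; the CVRs document the distal beds they stand for.
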