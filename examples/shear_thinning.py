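"""Carreau shear-thinning viscosity across the physiological range.

Prints the apparent viscosity at a few shear rates and the effective
viscosity a 4 mm carotid sees at increasing flow.  Blood thins by an
order of magnitude between stasis and arterial shear rates, which is
why segment resistances must be re-evaluated as flows change.
"""
from cowflow import (CarreauParameters, carreau_viscosity,
                     effective_viscosity, wall_shear_rate)

params = CarreauParameters()
print("shear rate (1/s)   viscosity (mPa.s)")
for gamma in (0.0, 1.0, 10.0, 100.0, 1000.0, 1e5):
    print(f"{gamma:12.1f}       {1e3 * carreau_viscosity(gamma, params):8.3f}")

print("\nflow in a 4 mm vessel  wall shear (1/s)  effective viscosity (mPa.s)")
for q in (0.0, 0.5, 2.5, 6.0):
    gamma = wall_shear_rate(q, 4.0)
    mu = effective_viscosity(q, 4.0, params)
    print(f"{q:10.1f} ml/s       {gamma:10.1f}        {1e3 * mu:8.3f}")
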