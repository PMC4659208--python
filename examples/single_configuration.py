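"""Build, calibrate and solve the complete circle of Willis.

The nominal synthetic geometry is calibrated so the healthy circle
carries 12.5 ml/s split 22/45/33 % over the ACA/MCA/PCA territories,
then solved once without stenosis.  The printout shows the efferent
flows (symmetric left/right), the near-zero ACoA cross-flow and the
small anterior-to-posterior PCoA flows expected of a balanced circle.
"""
from cowflow import (build_boundary_set, build_complete_cow, calibrate,
                     nominal_geometry, reynolds_check, solve_flows)

boundary = build_boundary_set()
topology = calibrate(build_complete_cow(nominal_geometry()), boundary)
solution = solve_flows(topology, boundary)

print(f"converged in {solution.iterations} Picard iterations; "
      f"mass residual {solution.max_mass_residual:.2e} ml/s")
print(f"total cerebral flow: {solution.total_inflow(topology):.3f} ml/s\n")

print("efferent flows (ml/s):")
for sid, q in sorted(solution.efferent_outflows(topology).items()):
    print(f"  {sid:5s} {q:6.3f}")

print("\ncommunicating arteries (signed, ml/s):")
print(f"  ACoA  {solution.segment_flows['ACoA']:+.3e}  (positive = toward right)")
print(f"  RPCoA {solution.segment_flows['RPCoA']:+.3f}  (positive = toward anterior)")
print(f"  LPCoA {solution.segment_flows['LPCoA']:+.3f}")

numbers, warnings = reynolds_check(solution, topology)
print(f"\nlargest Reynolds number: {max(numbers.values()):.0f} "
      f"({'laminar everywhere' if not warnings else warnings})")
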