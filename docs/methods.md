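# Methods

## Model

The circle of Willis is reduced to a steady, rigid-wall, zero-dimensional
resistive network. Each arterial segment is a straight cylinder carrying
fully developed laminar flow, so its pressure–flow relation is
Hagen–Poiseuille, `ΔP = R(Q)·Q` with `R(Q) = 128 μ L / (π d⁴)`. Blood is
shear-thinning: the viscosity entering `R` is the Carreau law evaluated
at a single representative shear rate per segment, the Poiseuille wall
shear rate `γ̇ = 32|Q|/(π d³)`. A scalar representative shear rate is the
standard reduced-order closure — the 3D shear field of a full CFD model
has no 0D counterpart — and the wall value is the natural choice because
it dominates the viscous loss. At `Q = 0` the wall shear rate is exactly
zero and the viscosity is exactly the zero-shear plateau; no quantity is
ever divided by a flow.

Assumptions inherited from this reduction: steady flow (pulsatility
averaged away; the literature on circle-of-Willis flow distribution
supports steady boundary conditions when only mean flows are of
interest), rigid walls, no junction or curvature minor losses, no
cerebral autoregulation (distal resistances are fixed, not
flow-regulated). Consequences are discussed under *Limitations*.

## Boundary conditions

The inlet pressure at all three afferent roots is the cerebral perfusion
pressure, `CPP = MAP − ICP`, with the mean arterial pressure estimated
from cuff vitals and heart rate:
`MAP ≅ DP + 0.01·exp(4.14 − 40.74/HR)·(SP − DP)`.
At the defaults (DP 80 mmHg, SP 120 mmHg, HR 80 min⁻¹, ICP 3 mmHg) this
gives MAP 95.10 (reported rounded to 95) and CPP 92.10 (reported 92)
mmHg. Internally full precision is kept; rounding is applied only in
reporting.

Each efferent territory (ACA, MCA, PCA — both sides per territory) ends
at a constant outlet pressure of 46, 56 and 43.5 mmHg respectively.
These are configured constants, *not* recomputed from the territorial
cerebrovascular resistances: the CVRs that follow from `CBF = CPP/CVR`
at the default split (0.558, 0.273, 0.372 mmHg/ml/min) are not mutually
consistent with those outlet pressures under any single steady-flow
derivation, so the pressures are taken as the operative boundary
condition and the CVRs are carried as documentation. For the PCA
territory the quotient CPP/(0.33·12.5·60) evaluates to ≈0.372
mmHg/ml/min; the package always reports this computed value (0.37 at two
decimals) rather than echoing any externally printed figure.

## Nonlinear solver

Unknowns are the internal node pressures. For fixed viscosities the
network is linear: assembling per-segment conductances `g = 1/R` into
the nodal balance matrix, imposing the fixed inlet/outlet pressures, and
solving the (small, dense) system yields pressures and then flows
`Q = g·ΔP`. Because `R` depends on `Q` through the viscosity, the solver
iterates this linear solve (Picard / successive substitution),
evaluating viscosities at under-relaxed flows
(`Q̃ ← ω Q_new + (1−ω) Q̃`, ω = 0.5) until the maximum flow change,
relative to the largest flow, falls below 1e-8 (defaults: ≤200
iterations). Under-relaxed Picard is robust for monotone shear-thinning
laws; the circle converges in ~20–40 iterations. At the fixed point
every segment satisfies `Q·R(Q) = ΔP` and every internal node conserves
mass (residuals ~1e-13 ml/s in practice); non-convergence is returned
explicitly (`converged=False` plus a flag), never silently. Network
components with no path to any fixed-pressure node (possible after
variant plus occlusion edits) are excluded from the linear system,
given zero flow and flagged; efferents cut off from every inlet are
flagged and naturally receive zero flow at their boundary pressure.

Correctness of the fixed point is checked two ways that share only the
equations: against the Poiseuille closed form in the Newtonian
single-tube limit (1e-10 relative), and against a generic brute-force
root-find on the full residual system (independently re-derived physics,
`scipy.optimize.root`) on randomized small networks (1e-6 relative).

## Stenosis and variants

Stenosis severity follows the NASCET diameter definition
`S = (1 − d_s/d_n)·100 %`. A degree strictly between 0 and 100 splits
the target segment (default: right ICA) in series into a narrowed
throat of configurable axial length (default 10 mm — the source study
never states the extent; the value is configurable and enters only the
throat's resistance linearly) and a healthy remainder. Occlusion
(S = 100 %) removes the segment outright: a zero-diameter tube has
infinite resistance, and edge removal avoids the ill-conditioning of a
huge-but-finite resistance element. Anatomical variants remove exactly
one named ring segment (ACoA, either A1, either PCoA) and never touch
dimensions. Both edits are pure functions returning new topologies.

## Calibration

The distal vasculature is lumped into one constant (Newtonian)
resistance per territory class, appended in series to each efferent
segment. The three resistances are fitted by cyclic coordinate
bisection: for each class in turn, bisect its resistance (bracket
[0, 10⁴] mmHg/(ml/s)) until the class flow equals its target share of
total CBF; cycle until the resistances are stationary (relative change
< 1e-7) and the totals meet tolerance. Class flow is strictly
decreasing in its own distal resistance, which guarantees the bisection
bracket; if each class meets its absolute target the total (12.5 ml/s)
follows automatically. Unattainable targets (the bare network cannot
supply the requested flow even with zero distal resistance) raise an
error naming the offending territory. The fitted resistances at the
nominal geometry are ≈27 (ACA), ≈9.6 (MCA) and ≈15 (PCA) mmHg/(ml/s) —
an order of magnitude above the segment resistances, as expected:
most of the pressure drop belongs to the distal beds.

## Synthetic geometry

The original study's patient CT geometry is unpublished, so the
geometry module generates a synthetic stand-in (so labelled in the data
file): a left-right symmetric table of literature-plausible dimensions.
Afferent and efferent vessels use the standard 1D-network values
(ICA 177×4.0 mm, VA 148×2.72 mm, BA 29×3.24 mm, MCA 119×2.86 mm,
A1 12×2.34 mm, A2 103×2.40 mm, P1 5×2.14 mm, P2 86×2.10 mm). The
communicating arteries use the classical lumped-model values — PCoA
15×1.0 mm, ACoA 3×1.2 mm — from the small end of their anatomical
class: with top-of-class communicating diameters (≈1.5 mm) the 0D
circle is over-collateralized, carrying ≈0.6 ml/s through each PCoA of
the healthy symmetric circle, whereas a balanced circle should show
near-zero ACoA cross-flow and only a small (≲0.3 ml/s)
anterior-to-posterior PCoA flow; the small-end values restore that
baseline pattern. Seeded multiplicative jitter (each length and
diameter scaled by an independent uniform factor in [1−j, 1+j],
j < 0.3, `numpy` Generator seeded explicitly) emulates anatomical
variability; jitter 0 returns the exact nominal table and identical
seeds give identical tables.

What the generator does *not* emulate: real vessel curvature, taper,
siphons, junction geometry, or any correlation structure between
segment sizes. Passing tests on this geometry therefore validate the
network mechanics and the qualitative collateral logic, not
patient-specific flow magnitudes.

## Experiment grid and reporting conventions

The sweep crosses the six configurations (complete, absent ACoA, absent
right/left A1, absent right/left PCoA) with stenosis degrees
0/25/50/75/90/100 % on the calibrated circle. Reported quantities follow
the source conventions: totals as the sum of efferent outflows;
percentage change as `100·(Q − Q_ref)/Q_ref` against the (complete,
0 %) cell, rounded to two decimals; ACoA flow signed positive toward the
right hemisphere and PCoA flows positive toward the anterior
circulation (both conventions are wired into the graph orientation, so
the signed segment flow is the reported number). The reversal "turning
point" of a communicating artery is located by linear interpolation
between the last sample of the initial sign and the first of the
opposite sign — the simplest defensible rule given only gridded
samples; an exactly zero sample is itself the turning point.

The percentage-change reproduction uses the published total-flow table
as a packaged fixture rather than solver output: the solver cannot
replicate an unpublished 3D patient geometry, but the derived-table
arithmetic is exactly checkable (all 36 entries reproduce at
two-decimal rounding).

## Numerical constants and conventions

Working units are mmHg, ml/s and mm throughout, converted to SI only
inside the resistance formula (1 mmHg = 133.322387415 Pa, centralized
in `units.py`). Blood density, used only by the Reynolds diagnostic, is
1050 kg/m³; the diagnostic uses the infinite-shear viscosity (the most
pessimistic choice) and warns at Re ≥ 2100. At the calibrated nominal
geometry the largest Reynolds number is ≈440, comfortably laminar.

## Problem sizes

The default grid is 36 cells; each solve is a dense linear system of at
most ~10 internal nodes iterated a few dozen times, so the full sweep
runs in well under a second and the fine-grained (1 % step, 101-cell)
reversal sweeps used in the examples and tests in a few seconds.
Randomized solver-oracle comparisons use 20–25 networks of at most six
segments.

## Limitations

* Straight-tube Poiseuille resistances underestimate the losses of real
  (curved, tapering, branching) cerebral arteries, so collateral
  pathways compensate more effectively here than in 3D patient models:
  total-flow reductions under occlusion are milder (≈11 % for the
  complete circle vs ≈35 % in the 3D study this emulates) and
  communicating-artery reversal points sit lower. Signs, orderings and
  monotonicities — the claims the package asserts — are preserved.
* No cerebral autoregulation: distal resistances are constant, so
  perfusion deficits are upper bounds on what a regulating bed would
  show.
* Steady flow only; no wall shear stress, no wave propagation, no
  elastic walls.
* Fetal-type and fused-vessel variants are not modelled.
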