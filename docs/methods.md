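# Methods

This note records the model, its assumptions, the parameters that
matter, and the choices made where the design was genuinely open. It is
the companion to the package docstrings; nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Scope and assumptions

The simulator treats the cerebral arterial system from the main-artery
trunks to the penetrating arterioles as a steady, zero-dimensional
(lumped) resistor network:

- **Poiseuille flow** in every segment: conductance
  k = π d⁴ / (128 µ L) with constant Newtonian viscosity
  µ = 3.5×10⁻³ Pa·s. No pulsatility, wall compliance, non-Newtonian
  rheology, or autoregulation — the network is passive and linear.
- **Geometry as graph**: vessels are straight segments with a single
  diameter; curvature enters only through edge lengths (tree edges are
  subdivided and projected onto the cortical surface, so their paths
  follow the cortex).
- **Boundary conditions**: Dirichlet 100 mmHg at the four inlets
  (L/R internal carotid, L/R vertebral). Every penetrating terminal
  carries a Robin outlet p = p₀ + R·q representing the downstream
  microvascular bed, with per-terminal R = Δp_cortex / q_nominal, a
  65 mmHg nominal cortical drop, and q_nominal the terminal's areal
  share of 715 mL/min total cerebral flow. Interior nodes have zero
  source terms; all inflow/outflow happens at these boundaries.

Internally all hydraulics are SI (Pa, m, m³/s); interfaces use mmHg,
µm/mm and mL/min with conversions centralized in `units.py`
(1 mmHg = 133.322 Pa, 1 mL/min = 1/60 × 10⁻⁶ m³/s), which avoids the
classic mixed-unit conductance error.

## Network construction

**Cortex.** The synthetic cortex is a closed, consistently oriented
genus-0 triangulation of an ellipsoid (icosphere-based; UV sphere where
the target triangle count is far from 20·4ⁿ), optionally wrinkled by a
smooth radial field with seeded random phases. A closed surface was
chosen so the pial dual graph needs no boundary handling. Real meshes
can be loaded from PLY/STL/OFF and are validated (watertight, consistent
winding) on load.

**Seeds and inlets.** Six territory seeds sit at the surface points
nearest canonical sextant directions (left/right × anterior/middle/
posterior); carotid inlets feed the anterior and middle territories,
vertebral inlets the posterior ones, one stub per territory. The
R-ICA→RMCA stub is the designated occlusion target. Root diameters
default to a Murray-consistent sizing: the six roots share the total d³
of a reference set (MCA 2.5 mm, ACA/PCA 2.0 mm) in proportion to their
territory area (= flow) shares. On a symmetric synthetic cortex with
equal territory areas this yields six equal ~2.2 mm roots. The rationale
is hydraulic: the real circle of Willis and main trunks follow the same
minimum-energy law as their distal trees, which balances terminal
pressures across territory boundaries; fixed unequal roots on an
equal-area cortex would create an artificial cross-boundary pressure
bias and push spurious flow through anastomoses already in the normal
state. A `fixed` mode uses the reference diameters verbatim.

**Partitioning.** The paper-level construction needs near-equal-area,
contiguous subregions; the algorithm here is area-weighted k-means on
triangle centroids followed by connectivity repair (triangles stranded
outside their region's main component are reassigned to the neighbor
with the largest shared boundary). Deterministic for a fixed seed.

**Tree growth.** A deliberately simplified CCO: terminals are inserted
in seeded random order; each new terminal connects to the best of the
k = 5 nearest existing segments, with the bifurcation point at the
clamped projection onto the segment (15–85% of its span) and the
connection cost Σ length × flow — a proxy for the minimum-energy
objective. There is no global re-optimization or staged re-balancing;
the growth-quality test asserts that a grown tree's total length is
within 10% of the best of 20 re-seeded runs. Terminal target flows
q_i = Q·|Ω_i|/|Ω| weight growth and diameter splitting only; they are
*not* boundary conditions of the flow solve.

**Diameters.** Top-down Murray assignment: at each bifurcation
d_child = d_parent (q_child/q_parent)^(1/γ), which satisfies
d_parent^γ = Σ d_child^γ exactly; γ = 3 by default (configurable in
[2, 4]); diameters are floor-clamped at 30 µm and are therefore monotone
non-increasing root→terminal.

**Pial layer.** The dual graph of the triangulation: one node per
triangle centroid, one 40 µm edge per interior mesh edge (length =
centroid distance; the primal mean-edge length is used for the
penetrating arteriole hanging off each node, per the construction the
layer idealizes). On a closed mesh every pial node has degree 3 and dual
faces around degree-6 vertices are hexagons. Fine-tree terminals attach
to their nearest pial node with a connector of the terminal's diameter
(1 µm length floor).

**Density-compensated lumping.** The physiological penetrating-artery
density is 8.7/mm². Scaled-down runs use far coarser pial meshes
(the test fixture: ~0.45/mm²), where each modeled vessel stands in for
s = 8.7/actual-density real ones and mesh edges are √s longer. Keeping
40 µm diameters would then overstate the bed's resistance by orders of
magnitude, so by default diameters are widened to keep the lumped layer
hydraulically equivalent to the fully resolved one: penetrating
diameter × s^(3/8) (preserves the parallel bed's total conductance) and
pial diameter × s^(1/8) (preserves the sheet conductance per square).
At or above target density the factors are exactly 1 and every vessel
is 40 µm. What the lumping cannot preserve is the injection pattern:
with N₁·N₂ fine terminals instead of the paper-scale ~7×10⁴, each
terminal must spread its flow over a ~30× larger pial catchment, which
adds genuine spreading resistance (see *Operating point* below).

**Intermediate anastomoses.** Candidates are coarse terminals of the
occludable territory whose region shares a mesh edge with the adjacent
territory, each paired with its nearest (3D Euclidean; the geodesic
alternative was not implemented since terminals lie on a convex-ish
surface where the ordering coincides) terminal across the boundary;
symmetric duplicates removed; diameter = arithmetic mean of the two
terminal branches; length = straight separation. Exactly which
terminals pair up — and hence the candidate count N — is geometry- and
partition-dependent.

## Flow solve

Inlet nodes are eliminated as Dirichlet rows; Robin terminals are folded
in as a series conductance 1/R to a ghost node at p₀, keeping the
reduced matrix symmetric positive definite (this also yields the
discrete maximum principle p₀ ≤ p ≤ p_inlet, asserted on every solve in
the tests). Direct sparse LU is used up to 50,000 unknowns, and
ILU-preconditioned conjugate gradients (relative residual 1e-10)
beyond; on small networks the two are tested to agree with a dense
solve to 1e-8. Flows are signed along the stored edge orientation.

Repeated solves that differ from a factorized base system by a few
conductance edits — the trunk occlusion is a rank-1 diagonal + RHS
update, each trial anastomosis a rank-1 Laplacian update — go through
the Woodbury identity against the cached factorization. This is exact
(verified in tests against full reassembly to 1e-9) and makes the
greedy procedure's N(N+1)/2 occluded solves cost one factorization plus
cheap triangular solves per round.

**Operating point.** The vascular-bed pressure p₀ is not a measured
quantity; it is calibrated so that the normal-condition total inflow
equals the 715 mL/min total cerebral flow. Total inflow is exactly
affine and strictly decreasing in p₀ (network linearity), so two solves
identify the root, and a third verifies it to ±1 mL/min;
`calibrate_bed_pressure` raises with the achievable range when the
target is outside [0, min inlet pressure). On strongly scaled-down
fixtures the target can be genuinely unreachable even at p₀ = 0 —
the sparse fine-terminal injection adds pial spreading resistance that
the full-scale network does not have — in which case the pipeline
operates at p₀ = 0 (the closest achievable point) and records the
achieved inflow in the run manifest. All reported occlusion metrics are
flow *ratios* and remain well-defined at that operating point.

## Experiments

Occlusion scales the RMCA trunk diameter by 0.01 (conductance ×10⁻⁸);
scale 1 reproduces the normal solution bit-for-bit. Recovery is
quantified per fine subregion by summing the penetrating-terminal
outflows assigned to it and taking q_occlusion/q_normal; subregions with
q_normal below 10⁻¹² mL/min are reported as undefined and excluded from
area-weighted histograms rather than clamped (no fabricated infinite
recoveries). Default histogram bins: 0–5–10–15–20–30–50–100%–∞.

Greedy selection: round r evaluates each remaining candidate by adding
it to the adopted set, solving the occluded network, and computing the
occluded territory's total recovery; the argmax is adopted (ties to the
lowest candidate id, for determinism) and the procedure repeats until no
candidates remain — N(N+1)/2 evaluations. The normal-state reference
flow is recomputed for each evaluated set (the anastomoses perturb
normal flows by well under 1%, but the ratio definition pairs matched
networks). The n = 0 baseline (pial-only) is computed once and not
counted as a selection solve.

## Parameters

| parameter | default | units | note |
|---|---|---|---|
| inlet pressure | 100 | mmHg | all four inlets |
| total cerebral flow Q | 715 | mL/min | areal distribution target |
| cortical drop | 65 | mmHg | sets per-terminal R |
| viscosity µ | 3.5×10⁻³ | Pa·s | Newtonian |
| N₁ / N₂ | 2000 / 37 | – | coarse/fine subregions |
| Murray exponent γ | 3 | – | configurable 2–4 |
| terminal diameter floor | 30 | µm | distal clamp |
| pial & penetrating diameter | 40 | µm | before density lumping |
| penetrating density | 8.7 | /mm² | lumping reference |
| occlusion diameter scale | 0.01 | – | 99% stenosis |
| root reference diameters | MCA 2.5, ACA/PCA 2.0 | mm | total d³ redistributed by area share |

## Problem sizes used in tests

The full-scale configuration (N₁ = 2000, N₂ = 37, 8.7/mm² pial density,
~10⁶ pial nodes) is supported by the code but not exercised in the test
suite; tests and the acceptance script run a scaled fixture — a 60 mm
sphere cortex with 20,480 triangles (~20k pial nodes, ~83k total nodes,
~95k edges), N₁ = 200, N₂ = 10, seed 1 — plus a minimal smoke
configuration (1,280 triangles, N₁ = 12, N₂ = 3). These sizes keep the
whole suite and the acceptance run within minutes on one CPU while
retaining every structural tier.

## What the synthetic cortex does and does not show

The generator produces a smooth (optionally wrinkled) ellipsoid with
canonical seed placement — a geometry stand-in, not an anatomical model:
no sulci/gyri, no subject-specific circle of Willis, equal-area
territories, and anastomosis counts N of order tens rather than the
geometry-bound counts of an imaged brain. Passing tests therefore
demonstrate the *mechanisms* (mass-conserving flow, Murray trees, dual
pial topology, occlusion starvation, tier-2 dominance of collateral
recovery, greedy bookkeeping) and not patient-specific magnitudes.
Quantities tied to real geometry — exact candidate counts, exact
recovery percentages, territory flow asymmetries — are asserted only as
trends or bounds.

## Known limitations

- Steady linear flow: no autoregulation, no pulsatility, no
  non-Newtonian effects; collateral supply is likely underestimated
  relative to a vasodilating real bed.
- The hexagonal pial idealization has a single loop scale; real pial
  networks are hierarchical.
- The simplified CCO makes no claim of matching staged-optimization CCO
  implementations; it is documented as its own variant.
- Tier-1 (circle of Willis) variation studies and extracranial
  collaterals are out of scope.
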