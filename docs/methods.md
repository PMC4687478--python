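# Methods

## Model

The package treats one hydrogen (or deuterium) nucleus moving in a fixed
external potential E(q), where q is the displacement along the
donor→acceptor direction of a hydrogen bond and every other nucleus is
frozen (an *unrelaxed* scan). The nuclear Schrödinger equation

    [ −(ħ²/2m) d²/dq² + E(q) ] ψ_i(q) = ε_i ψ_i(q)

is solved on the tabulated interval with the Born–Oppenheimer potential
entering as given. Assumptions this buys and their costs:

- **One dimension.** Coupling of the proton motion to heavy-atom modes
  (above all the donor–acceptor O…O stretch) is neglected. Observables are
  conditional on one frozen environment geometry.
- **Bare nuclear mass.** Because the scan moves a lone nucleus against a
  frozen environment there is no vibrating partner; m is the bare proton
  (1.007276 amu) or deuteron (2.013553 amu) mass, not an O–H reduced mass.
  A custom mass can be supplied.
- **Collinear bond-length mapping.** R(q) = R₀ + q with slope exactly 1.
  The small non-collinearity of a real O–H⋯O geometry is not representable
  in 1D and is ignored consistently in both the potential and the
  observable.

Unit system: Å / amu / kcal·mol⁻¹ / K. The two derived constants are
computed from CODATA values at import time: ħ²/(2·1 amu) =
0.0481984 kcal·mol⁻¹·Å² and k_B = 0.00198720 kcal·mol⁻¹·K⁻¹.

## Eigensolver

**Discretization.** The kinetic operator is the Colbert–Miller sine-DVR
for a finite interval: the grid's two end nodes act as hard (Dirichlet)
walls and the interior nodes are the DVR points. This variant was chosen
over the infinite-interval sinc-DVR for two reasons: (i) the box is pinned
to the tabulated span, so refining the grid does not move the walls and
eigenvalues converge monotonically to a fixed problem; (ii) for a constant
potential the operator reproduces the particle-in-a-box spectrum to
machine precision, which gives a closed-form oracle with no discretization
error. For smooth potentials convergence is spectral: at the default
production grid (1001 nodes) doubling the grid moves the fixture
eigenvalues by < 10⁻¹⁰ kcal/mol, far inside the 10⁻⁵ convergence gate the
test suite enforces.

**Potential.** Tabulated curves are interpolated to the solver grid with a
cubic spline (not-a-knot ends); tabulated nodes are reproduced exactly.

**Boundary handling.** Hard walls suit unrelaxed scans, which rise steeply
at both ends. If the ground state still reaches a wall with dimensionless
amplitude > 10⁻⁶ at the adjacent node, a `BoundaryLeakageWarning` is
issued: results remain usable but energies are confined upward. The
PYP-like fixtures trigger this at the ~10⁻⁵–10⁻⁴ level on their default
span — a deliberate reminder that the tabulated range, not the solver, is
the accuracy limit there.

**Cross-check.** An independent three-point finite-difference Hamiltonian
with the same wall convention must agree with the DVR to 10⁻⁴ kcal/mol on
all fixtures (it converges as O(Δq²), verified by a Richardson ratio
test).

**Determinism and conventions.** Dense symmetric eigensolve
(`scipy.linalg.eigh`, lowest-index subset); energies ascend and are
referenced to the curve's energy zero (the global minimum), not the ground
state; each wavefunction's sign is fixed so its first non-negligible
amplitude is positive; normalization is Σψ²Δq = 1.

## Observables

- ⟨R⟩_i = R₀ + Σ q ψ_i²(q) Δq (rectangle rule; exact to the DVR's own
  quadrature, and checked against spline quadrature to 10⁻⁶ Å).
- Boltzmann weights are computed with energies shifted by the lowest
  level — mathematically identical to the unshifted form, numerically safe
  at low T. Default temperature 300 K. The thermal average uses all solved
  states (default 3); with ≥ 4 states a truncation check warns if the
  3-state R_T differs by > 0.005 Å.
- Stationary points are the exact roots of the spline's piecewise-cubic
  derivative (no iterative refinement needed), classified by the second
  derivative; numerically flat candidates (|E″| < 10⁻¹⁰ of the curve's
  curvature scale) are discarded, and endpoint extrema are never counted
  as wells. "Double-well" requires an interior maximum flanked by two
  interior minima; barrier height is E(top) − E(global minimum).
- LBHB classification: "ZPE-dominated (LBHB-like)" when the proton ε₀
  reaches within 0.5 kcal/mol (configurable) of the barrier, else
  "barrier-localized"; single wells report "no-barrier (single-well)".
  The 0.5 kcal/mol default is ~k_BT at room temperature: a barrier the
  zero-point level approaches that closely no longer confines the proton.

## Synthetic curves

The generators stand in for quantum-chemical proton-migration scans of the
PYP Glu46–chromophore site, which were published only as figures with a
few printed scalar features. The fixtures are calibrated to exactly those
printed features and nothing else:

- **Equilibrium-like fixture** (`pyp_equilibrium`): Morse well
  E = D_e(1 − e^(−a q))², D_e = 20 kcal/mol, a = 2.2 Å⁻¹, minimum at
  q = 0 (R₀ = 1.08 Å). Reproduces the published qualitative shape — a
  barrier-free single well, stiff on the compression side and soft toward
  the acceptor — with a proton zero-point level (≈ 2.1 kcal/mol) and first
  gap (≈ 3.9 kcal/mol) in the published range. D_e and a are otherwise
  free choices of a typical O–H anharmonicity scale.
- **Crystal-like fixture** (`pyp_crystal`): the constrained double-well
  polynomial with global minimum E = 0 at q = −0.15 Å (R = 1.06 Å),
  barrier E = 2.36 kcal/mol at q = +0.10 Å (R = 1.31 Å), R₀ = 1.21 Å.
  The acceptor-side well is unpublished; the default places it at
  q = +0.35 Å (R = 1.56 Å, ~1 Å from the acceptor oxygen at O…O 2.56 Å)
  with a +1.0 kcal/mol offset, both overridable.
- **Double-well family**: the unique quintic Hermite interpolant through
  the three prescribed stationary points (values 0, barrier, asymmetry;
  zero slope at each), plus — when the bare quintic's tail would dip below
  zero or admit extra stationary points on the grid — the smallest
  confining sextic correction c₆·[(q−q₁)(q−q_b)(q−q₂)]², which vanishes to
  second order at all three nodes and therefore preserves every
  constraint. c₆ is selected deterministically from a geometric ladder
  (factor 1.4 from barrier/(q₂−q₁)⁶), preferring candidates whose walls
  exceed the barrier at the grid ends; too large a c₆ turns the barrier
  point into a minimum of the correction term, so an empty ladder is
  reported as a construction error naming the stationary-point layout. In
  the symmetric zero-asymmetry case the construction degenerates to the
  classic quartic a(q² − b²)².
- **Default fixture sampling**: q ∈ [−0.45, +0.75] Å at 0.01 Å spacing
  (121 samples), emulating the span of a scan. The 0.01 Å step puts every
  calibrated stationary point on a sample node, so the tabulated minimum
  is exactly 0; the solver densifies by spline to 1001 nodes.
- Generators place the global minimum at 0 kcal/mol, matching
  minimum-referenced barrier and level reporting.

**What the fixtures are not.** They are smooth, noise-free, and calibrated
only to printed scalars; they do not reproduce the published eigenvalues or
averaged bond lengths, which depend on the full (unpublished) curve shape.
Tests that pass on them validate the solver and the observable pipeline,
not the electronic structure of PYP. The quantities that *are* recomputable
from print — the 300 K thermal averages of the published per-state values
(1.17 Å for H, 1.15 Å for D at the equilibrium geometry), the excited-state
populations (< 3 %), the ground-state H−D difference (0.06 Å), the proton
quantum elongation (0.17 Å), the deuteron gap (0.96 kcal/mol), and the
crystal barrier calibration (2.36 kcal/mol) — are asserted in the test
suite and recomputed by `scripts/acceptance.py`.

A note on the crystal-geometry published table: Boltzmann-averaging its
*rounded* per-state values gives R_T = 1.24 Å (H) and 1.21 Å (D), one
printed digit above the published 1.23/1.20 Å — consistent with the
original averages having been formed from unrounded inputs. Those two R_T
values are therefore not treated as recomputable, while the
equilibrium-geometry pair recomputes cleanly.

## Numerical choices and edge cases

- Curve files are plain text (`# R0_angstrom=`, `# label=` headers, two
  numeric columns) written with repr-exact floats: a write→read round trip
  is bit-identical. Unsorted files are sorted on read with a logged
  warning; duplicate or non-numeric rows and a missing R₀ header raise
  format errors with line numbers.
- Degenerate inputs: curves with no interior minimum raise
  `DegenerateCurveError` from the stationary-point analysis; requesting
  more states than interior grid nodes, grids outside the tabulated span,
  non-positive temperatures or masses raise `ParameterError`.
- Ties: eigenvalues are returned in ascending solver order (1D bound
  states are non-degenerate, so ties do not occur for valid input).
- The pipeline is fully deterministic; report JSON/TSV bytes are identical
  across runs. A `--seed` is accepted (and logged) only for optional
  Gaussian noise on synthetic curves.
- Problem sizes: the test suite solves 201–2001-point grids; production
  defaults (1001 nodes, 3 states) solve in well under a second per
  isotope.

## Limitations

- One-dimensional and unrelaxed: no O…O stretch coupling, no
  multi-mode or nuclear–electronic coupling, no free-energy sampling.
- The bond-length observable assumes the collinear mapping; 3D averaged
  geometries are out of reach of a 1D model.
- Published eigenvalues for the PYP site are not reproducible without the
  original potential scans; the fixtures are calibrated stand-ins, clearly
  labelled as such.
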