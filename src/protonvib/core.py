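"""One-dimensional nuclear quantum vibrational analysis of hydrogen bonds.

This module implements a complete pipeline for studying a hydrogen (or
deuterium) nucleus migrating along the donor--acceptor axis of a short,
strong hydrogen bond, such as the Glu46--chromophore contact in photoactive
yellow protein (PYP):

1.  **Potential curves** -- generate, read, write and interpolate tabulated
    one-dimensional potential energy curves E(q), where q (in angstrom) is
    the displacement of the migrating nucleus along the donor->acceptor
    direction and the O--H bond length is R(q) = R0 + q.  Analytic harmonic
    and Morse wells serve as exactly solvable references; a polynomial
    double-well family and two PYP-like fixtures emulate proton-transfer
    scans from unrelaxed quantum-chemical calculations.

2.  **Eigensolver** -- solve the 1D nuclear Schroedinger equation on a
    uniform grid with a sine (particle-in-a-box) discrete variable
    representation of the kinetic operator (Colbert--Miller finite-interval
    DVR) and hard walls at the tabulated ends; a three-point
    finite-difference solver provides an independent cross-check.

3.  **Observables** -- vibrationally averaged bond lengths <R>_i, Boltzmann
    thermal averages R_T at temperature T, zero-point energies, excitation
    gaps, stationary-point (barrier) analysis of the potential, H/D isotope
    comparisons, and a low-barrier-hydrogen-bond (LBHB) classification that
    compares the proton zero-point energy with the proton-transfer barrier.

4.  **Pipeline** -- an end-to-end driver that turns a curve (fixture or
    file) into a per-isotope vibrational report, plus bundled
    printed-table fixtures of published vibrational levels so the thermal
    averaging stage can be exercised independently of the solver.

Units throughout: angstrom (length), amu (mass), kcal/mol (energy),
kelvin (temperature).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import scipy.constants as _codata
import scipy.linalg as _sla
from numpy.polynomial import polynomial as _poly
from scipy.interpolate import CubicSpline

__all__ = [
    # constants & config
    "HBAR_SQ_OVER_TWO_AMU", "KB_KCAL_PER_MOL_K", "MASS_PROTON_AMU",
    "MASS_DEUTERON_AMU", "ROOM_TEMPERATURE_K", "DEFAULT_FIXTURE_GRID",
    "PRODUCTION_GRID_POINTS",
    # errors & warnings
    "ProtonvibError", "ParameterError", "CurveFormatError",
    "ConstructionError", "DegenerateCurveError", "NumericalError",
    "BoundaryLeakageWarning",
    # types
    "GridSpec", "ParticleMass", "PotentialCurve", "VibrationalSpectrum",
    "StationaryPoint", "BarrierReport", "LbhbClassification",
    "ThermalState", "ThermalReport", "IsotopeComparison",
    "PrintedVibrationalTable", "RunConfig",
    # potential models
    "make_harmonic", "make_morse", "make_double_well",
    "make_pyp_equilibrium_fixture", "make_pyp_crystal_fixture",
    "read_curve", "write_curve", "curve_to_csv", "interpolate_curve",
    "add_noise",
    # solver
    "solve_states", "solve_states_fd", "zero_point_energy",
    "write_spectrum",
    # observables
    "expectation_bond_length", "boltzmann_weights", "thermal_average",
    "excitation_gaps", "barrier_analysis", "lbhb_classify",
    "build_thermal_report", "isotope_report",
    # pipeline
    "PRINTED_TABLES", "FIXTURE_BUILDERS", "build_fixture",
    "run_pipeline", "printed_table_report", "render_report_tsv",
    "render_report_json",
]

logger = logging.getLogger("protonvib")

# --------------------------------------------------------------------------
# Physical constants in the angstrom / amu / kcal-per-mol unit system
# --------------------------------------------------------------------------

#: 1 kcal/mol expressed in joule per molecule.
_KCALMOL_IN_J = 4184.0 / _codata.Avogadro

#: Kinetic-energy prefactor hbar^2 / (2 * 1 amu) in kcal/mol * A^2.
#: Divide by the nuclear mass in amu to obtain hbar^2/(2m).
HBAR_SQ_OVER_TWO_AMU = _codata.hbar**2 / (
    2.0 * _codata.atomic_mass * 1e-20 * _KCALMOL_IN_J
)

#: Boltzmann constant in kcal/(mol K).
KB_KCAL_PER_MOL_K = _codata.Boltzmann / _KCALMOL_IN_J

#: Bare nuclear masses, amu (not reduced masses: the scans move only the
#: hydrogen nucleus with every other atom frozen).
MASS_PROTON_AMU = 1.007276
MASS_DEUTERON_AMU = 2.013553

ROOM_TEMPERATURE_K = 300.0

#: Default dense-solver grid size (points spanning the tabulated range).
PRODUCTION_GRID_POINTS = 1001

#: Dimensionless ground-state amplitude at the node adjacent to a wall
#: above which a boundary-leakage warning is raised.
BOUNDARY_LEAKAGE_THRESHOLD = 1e-6


# --------------------------------------------------------------------------
# Errors and warnings
# --------------------------------------------------------------------------

class ProtonvibError(Exception):
    """Base class for all errors raised by this package."""


class ParameterError(ProtonvibError, ValueError):
    """An argument violates a documented precondition."""


class CurveFormatError(ProtonvibError, ValueError):
    """A curve file is malformed; the message carries a line number."""


class ConstructionError(ProtonvibError, RuntimeError):
    """A requested analytic potential cannot be constructed."""


class DegenerateCurveError(ProtonvibError, ValueError):
    """A curve has no interior minimum and cannot be analysed."""


class NumericalError(ProtonvibError, RuntimeError):
    """The eigensolver failed to converge."""


class BoundaryLeakageWarning(UserWarning):
    """Ground-state amplitude is non-negligible at a Dirichlet wall.

    The hard-wall box spanned by the tabulated curve is too small for the
    state; energies may be biased upward.
    """


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    """Uniform solver grid over ``[q_start, q_end]`` with both endpoints
    included as nodes.

    The eigensolver imposes hard (Dirichlet) walls exactly at ``q_start``
    and ``q_end``, so the wavefunction is identically zero at the two end
    nodes and the box does not move when the grid is refined.
    """

    q_start: float
    q_end: float
    n_points: int

    def __post_init__(self) -> None:
        if not self.q_start < self.q_end:
            raise ParameterError(
                f"grid requires q_start < q_end, got [{self.q_start}, {self.q_end}]"
            )
        if self.n_points < 5:
            raise ParameterError(f"grid needs at least 5 points, got {self.n_points}")

    @property
    def spacing(self) -> float:
        return (self.q_end - self.q_start) / (self.n_points - 1)

    def points(self) -> np.ndarray:
        return np.linspace(self.q_start, self.q_end, self.n_points)


@dataclass(frozen=True)
class ParticleMass:
    """Nuclear mass of the migrating particle.

    Presets use bare nuclear masses because the scan moves a lone nucleus
    with all other atoms frozen (no reduced-mass partner).
    """

    mass_amu: float
    isotope_label: str = "custom"

    def __post_init__(self) -> None:
        if not self.mass_amu > 0:
            raise ParameterError(f"mass must be positive, got {self.mass_amu}")

    @classmethod
    def proton(cls) -> "ParticleMass":
        return cls(MASS_PROTON_AMU, "H")

    @classmethod
    def deuteron(cls) -> "ParticleMass":
        return cls(MASS_DEUTERON_AMU, "D")

    @classmethod
    def from_label(cls, label: str, mass_amu: float | None = None) -> "ParticleMass":
        if label == "H":
            return cls.proton()
        if label == "D":
            return cls.deuteron()
        if mass_amu is None:
            raise ParameterError(f"custom isotope {label!r} needs an explicit mass")
        return cls(mass_amu, label)


@dataclass(frozen=True)
class PotentialCurve:
    """Tabulated 1D potential E(q) along the proton-migration coordinate.

    ``q_values`` are strictly increasing displacements (angstrom) and
    ``energies`` the potential samples (kcal/mol).  The O--H bond length is
    the affine map ``R(q) = R0 + q`` (collinear-migration convention: the
    nucleus moves along the donor->acceptor axis, so displacement and bond
    elongation coincide).
    """

    q_values: np.ndarray
    energies: np.ndarray
    R0: float
    label: str = ""

    def __post_init__(self) -> None:
        q = np.asarray(self.q_values, dtype=float)
        e = np.asarray(self.energies, dtype=float)
        object.__setattr__(self, "q_values", q)
        object.__setattr__(self, "energies", e)
        if q.ndim != 1 or e.ndim != 1 or q.size != e.size:
            raise ParameterError("q_values and energies must be 1D and equal length")
        if q.size < 5:
            raise ParameterError(f"a curve needs at least 5 samples, got {q.size}")
        if not np.all(np.diff(q) > 0):
            raise ParameterError("q_values must be strictly increasing")
        if not np.all(np.isfinite(q)) or not np.all(np.isfinite(e)):
            raise ParameterError("curve contains non-finite values")

    def __len__(self) -> int:
        return int(self.q_values.size)

    @property
    def bond_lengths(self) -> np.ndarray:
        """O--H bond length at every sample, R = R0 + q."""
        return self.R0 + self.q_values

    def bond_length(self, q: float | np.ndarray) -> float | np.ndarray:
        return self.R0 + q

    def spline(self) -> CubicSpline:
        """Cubic-spline interpolant of the tabulated samples."""
        return CubicSpline(self.q_values, self.energies)


@dataclass(frozen=True)
class VibrationalSpectrum:
    """Bound vibrational states of one nuclear mass on one curve.

    ``energies`` are minimum-referenced eigenvalues in ascending order
    (kcal/mol, measured from the curve's energy zero, not from the ground
    state).  ``wavefunctions`` has shape ``(n_grid, n_states)``; column i is
    the i-th eigenfunction sampled on ``grid.points()`` and normalized so
    that ``sum(psi**2) * dq == 1`` (units of 1/sqrt(angstrom)).
    """

    energies: np.ndarray
    wavefunctions: np.ndarray
    grid: GridSpec
    mass: ParticleMass
    curve_label: str = ""

    @property
    def n_states(self) -> int:
        return int(self.energies.size)


@dataclass(frozen=True)
class StationaryPoint:
    q: float
    bond_length: float
    energy: float
    kind: str  # "minimum" | "maximum"


@dataclass(frozen=True)
class BarrierReport:
    """Stationary-point analysis of a potential curve.

    ``classification`` is "single-well" when the spline interpolant has no
    interior maximum flanked by two minima, else "double-well".  Barrier
    fields are ``None`` for single wells.  Endpoint extrema are never
    counted as wells.
    """

    stationary_points: tuple[StationaryPoint, ...]
    classification: str
    global_min_q: float
    global_min_energy: float
    global_min_bond_length: float
    barrier_height: float | None = None
    barrier_q: float | None = None
    barrier_bond_length: float | None = None


@dataclass(frozen=True)
class LbhbClassification:
    """Barrier-versus-zero-point-energy verdict for the proton.

    category is one of:

    * ``"no-barrier (single-well)"`` -- the curve has a single minimum;
    * ``"ZPE-dominated (LBHB-like)"`` -- the proton zero-point level reaches
      within ``tolerance`` of the barrier top, so the proton delocalizes
      across both wells;
    * ``"barrier-localized"`` -- the barrier exceeds the zero-point energy
      by more than the tolerance and the proton stays in one well.

    ``barrier_minus_zpe`` is reported when positive (the gap that keeps a
    heavier isotope localized below the barrier).
    """

    category: str
    zero_point_energy: float
    barrier_height: float | None = None
    barrier_minus_zpe: float | None = None
    tolerance: float = 0.5


@dataclass(frozen=True)
class ThermalState:
    index: int
    energy: float
    mean_bond_length: float
    weight: float


@dataclass(frozen=True)
class ThermalReport:
    """Per-state averages and the Boltzmann thermal mean at temperature T."""

    temperature: float
    states: tuple[ThermalState, ...]
    thermal_mean_bond_length: float


@dataclass(frozen=True)
class IsotopeComparison:
    """Paired H/D observables on the same curve.

    * ``delta_mean_r_ground`` -- ground-state <R>(H) - <R>(D), angstrom;
    * ``quantum_elongation`` -- <R>_0 minus the bond length at the potential
      minimum, per isotope (pure nuclear-quantum effect);
    * ``thermal_elongation`` -- R_T - <R>_0 per isotope (thermal effect);
    * ``first_gap`` -- first excitation energy per isotope, kcal/mol.
    """

    delta_mean_r_ground: float
    quantum_elongation: Mapping[str, float]
    thermal_elongation: Mapping[str, float]
    first_gap: Mapping[str, float]
    temperature: float


# --------------------------------------------------------------------------
# Potential models: analytic generators
# --------------------------------------------------------------------------

#: Default sampling for the PYP-like fixtures: q in [-0.45, +0.75] A at
#: 0.01 A spacing, emulating the span of an unrelaxed proton-migration scan.
#: The 0.01 A step places every calibrated stationary point (q = -0.15, 0,
#: +0.10, +0.35) exactly on a sample node, so the tabulated minimum is 0.
DEFAULT_FIXTURE_GRID = GridSpec(-0.45, 0.75, 121)


def make_harmonic(
    force_constant: float, q_min: float, R0: float, grid: GridSpec
) -> PotentialCurve:
    """Harmonic well ``E = 0.5 * k * (q - q_min)**2`` sampled on ``grid``.

    For mass m (amu) the analytic level spacing is
    ``hbar*omega = sqrt(2 * k * HBAR_SQ_OVER_TWO_AMU / m)`` kcal/mol.
    """
    if not force_constant > 0:
        raise ParameterError(f"force constant must be positive, got {force_constant}")
    if not (grid.q_start <= q_min <= grid.q_end):
        raise ParameterError(f"q_min={q_min} lies outside the grid range")
    q = grid.points()
    e = 0.5 * force_constant * (q - q_min) ** 2
    return PotentialCurve(q, e, R0, label=f"harmonic k={force_constant:g} q_min={q_min:g}")


def harmonic_force_constant(hbar_omega: float, mass_amu: float = 1.0) -> float:
    """Force constant (kcal/mol/A^2) giving level spacing ``hbar_omega``
    (kcal/mol) for a particle of ``mass_amu``."""
    return hbar_omega**2 * mass_amu / (2.0 * HBAR_SQ_OVER_TWO_AMU)


def make_morse(
    D_e: float, a: float, q_min: float, R0: float, grid: GridSpec
) -> PotentialCurve:
    """Morse well ``E = D_e * (1 - exp(-a*(q - q_min)))**2``.

    Exact bound levels for mass m:
    ``E_n = hw*(n+1/2) - (hw*(n+1/2))**2 / (4*D_e)`` with
    ``hw = a * sqrt(4 * D_e * HBAR_SQ_OVER_TWO_AMU / m)``.
    """
    if not D_e > 0:
        raise ParameterError(f"dissociation energy must be positive, got {D_e}")
    if not a > 0:
        raise ParameterError(f"Morse width parameter must be positive, got {a}")
    q = grid.points()
    e = D_e * (1.0 - np.exp(-a * (q - q_min))) ** 2
    return PotentialCurve(q, e, R0, label=f"morse D_e={D_e:g} a={a:g} q_min={q_min:g}")


def morse_levels(D_e: float, a: float, mass_amu: float, n_states: int) -> np.ndarray:
    """Closed-form Morse eigenvalues for the bound states requested."""
    hw = a * np.sqrt(4.0 * D_e * HBAR_SQ_OVER_TWO_AMU / mass_amu)
    n = np.arange(n_states)
    return hw * (n + 0.5) - (hw * (n + 0.5)) ** 2 / (4.0 * D_e)


def _hermite_quintic(
    min1_q: float, barrier_q: float, min2_q: float,
    barrier_height: float, asymmetry: float,
) -> np.ndarray:
    """Unique degree-<=5 polynomial with prescribed values (0, barrier,
    asymmetry) and zero slope at the three stationary abscissae.
    Coefficients in ascending-power order."""
    nodes = (min1_q, barrier_q, min2_q)
    targets = (0.0, barrier_height, asymmetry)
    A = np.zeros((6, 6))
    rhs = np.zeros(6)
    for r, (x, v) in enumerate(zip(nodes, targets)):
        A[r] = [x**c for c in range(6)]
        rhs[r] = v
        A[r + 3] = [0.0] + [c * x ** (c - 1) for c in range(1, 6)]
    try:
        return np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as exc:  # coincident nodes are pre-checked
        raise ConstructionError(f"degenerate stationary-point layout: {exc}") from exc


def _valid_double_well(coef: np.ndarray, grid: GridSpec,
                       stationary: Sequence[float], barrier_height: float,
                       require_walls: bool) -> bool:
    """True when the analytic polynomial has exactly the three prescribed
    stationary points inside the grid span and is bounded below by ~0
    there; with ``require_walls`` it must also rise above the barrier at
    both ends (confining box)."""
    der = _poly.polyder(coef)
    roots = np.roots(der[::-1])
    real = sorted(
        r.real for r in roots
        if abs(r.imag) < 1e-9 and grid.q_start < r.real < grid.q_end
    )
    if len(real) != 3:
        return False
    if max(abs(r - s) for r, s in zip(real, sorted(stationary))) > 1e-6:
        return False
    qs = np.linspace(grid.q_start, grid.q_end, 4 * grid.n_points)
    vals = _poly.polyval(qs, coef)
    if vals.min() < -1e-9:
        return False
    if require_walls:
        return vals[0] >= barrier_height and vals[-1] >= barrier_height
    return True


def make_double_well(
    min1_q: float, barrier_q: float, min2_q: float,
    barrier_height: float, asymmetry: float, R0: float, grid: GridSpec,
) -> PotentialCurve:
    """Polynomial double well with prescribed stationary structure.

    Constructs the lowest-degree polynomial satisfying E(min1_q) = 0,
    E(barrier_q) = barrier_height, E(min2_q) = asymmetry, all with zero
    slope: the unique quintic Hermite interpolant, plus -- when the quintic
    tail would leak states or admit spurious stationary points inside the
    grid span -- the smallest confining sextic correction
    ``c6 * ((q-min1_q)(q-barrier_q)(q-min2_q))**2``, which preserves all six
    constraints exactly.  ``c6`` is found by doubling from
    ``barrier_height / (min2_q - min1_q)**6``.

    In the symmetric, zero-asymmetry case the construction degenerates to
    the quartic ``a*(q**2 - b**2)**2`` (for minima at -b, +b).
    """
    if not (min1_q < barrier_q < min2_q):
        raise ParameterError(
            f"need min1_q < barrier_q < min2_q, got {min1_q}, {barrier_q}, {min2_q}"
        )
    if not barrier_height > 0:
        raise ParameterError(f"barrier height must be positive, got {barrier_height}")
    if not (0 <= asymmetry < barrier_height):
        raise ParameterError(
            f"need 0 <= asymmetry < barrier_height, got asymmetry={asymmetry}"
        )
    quintic = _hermite_quintic(min1_q, barrier_q, min2_q, barrier_height, asymmetry)
    stationary = (min1_q, barrier_q, min2_q)

    w = _poly.polymul(
        _poly.polymul([-min1_q, 1.0], [-barrier_q, 1.0]), [-min2_q, 1.0]
    )
    w2 = _poly.polymul(w, w)

    # candidate sextic strengths: the bare quintic first, then a geometric
    # ladder; c6 too large flips the barrier point into a minimum of the
    # confinement term, so the ladder is fine-stepped and bounded
    base_c6 = barrier_height / (min2_q - min1_q) ** 6
    candidates = [0.0] + [base_c6 * 1.4**k for k in range(90)]
    coef = None
    for require_walls in (True, False):
        for c6 in candidates:
            trial = _poly.polyadd(quintic, c6 * w2) if c6 else quintic
            if _valid_double_well(trial, grid, stationary, barrier_height,
                                  require_walls):
                coef = trial
                break
        if coef is not None:
            break
    if coef is None:
        raise ConstructionError(
            "no polynomial of this family reproduces the requested stationary "
            f"points ({min1_q}, {barrier_q}, {min2_q}) as the only extrema on "
            "this grid; the violated constraint is the stationary-point layout "
            "(wells too close or too asymmetric for the grid span)"
        )

    # post-hoc constraint audit on the analytic polynomial
    checks = {
        f"E({min1_q}) = 0": abs(_poly.polyval(min1_q, coef)),
        f"E({barrier_q}) = {barrier_height}": abs(
            _poly.polyval(barrier_q, coef) - barrier_height
        ),
        f"E({min2_q}) = {asymmetry}": abs(_poly.polyval(min2_q, coef) - asymmetry),
    }
    for constraint, residual in checks.items():
        if residual > 1e-8:
            raise ConstructionError(
                f"constraint {constraint} violated by {residual:.2e} kcal/mol"
            )

    q = grid.points()
    return PotentialCurve(
        q, _poly.polyval(q, coef), R0,
        label=(
            f"double-well min1={min1_q:g} top={barrier_q:g} min2={min2_q:g} "
            f"barrier={barrier_height:g} asym={asymmetry:g}"
        ),
    )


def make_pyp_equilibrium_fixture(grid: GridSpec | None = None) -> PotentialCurve:
    """PYP-like single-well curve for the energy-minimized geometry.

    An anharmonic Morse well (D_e = 20 kcal/mol, a = 2.2 1/A) with its
    minimum at q = 0, i.e. R = 1.08 A: stiff repulsive wall on the
    compression side (q < 0), softer rise toward the acceptor (q > 0), and
    no barrier.  Emulates the short-donor-acceptor geometry (O...O 2.47 A)
    in which proton transfer has no metastable product well.
    """
    grid = grid or DEFAULT_FIXTURE_GRID
    curve = make_morse(D_e=20.0, a=2.2, q_min=0.0, R0=1.08, grid=grid)
    return dataclasses.replace(curve, label="equilibrium-like, O...O 2.47 A")


def make_pyp_crystal_fixture(
    grid: GridSpec | None = None,
    second_min_q: float = 0.35,
    asymmetry: float = 1.0,
) -> PotentialCurve:
    """PYP-like asymmetric double well for the crystal geometry.

    Calibrated to the published crystal-structure scan features: reference
    bond length R0 = 1.21 A (the neutron-diffraction O--H distance), global
    minimum at q = -0.15 A (R = 1.06 A) with E = 0, and a proton-transfer
    barrier of 2.36 kcal/mol at q = +0.10 A (R = 1.31 A).  The acceptor-side
    well (position ``second_min_q``, depth offset ``asymmetry``) is not
    constrained by published numbers; the defaults put it ~1 A from the
    acceptor oxygen at O...O 2.56 A.
    """
    grid = grid or DEFAULT_FIXTURE_GRID
    curve = make_double_well(
        min1_q=-0.15, barrier_q=0.10, min2_q=second_min_q,
        barrier_height=2.36, asymmetry=asymmetry, R0=1.21, grid=grid,
    )
    return dataclasses.replace(curve, label="crystal-like, O...O 2.56 A")


def add_noise(curve: PotentialCurve, sigma: float, seed: int | None = None) -> PotentialCurve:
    """Gaussian energy noise (std ``sigma`` kcal/mol), shifted so the noisy
    minimum stays at zero.  Intended for robustness experiments only."""
    if sigma < 0:
        raise ParameterError("noise sigma must be non-negative")
    rng = np.random.default_rng(seed)
    e = curve.energies + rng.normal(0.0, sigma, size=len(curve))
    e = e - e.min()
    return dataclasses.replace(curve, energies=e, label=f"{curve.label} +noise({sigma:g})")


# --------------------------------------------------------------------------
# Potential models: file I/O and resampling
# --------------------------------------------------------------------------
#
# Curve file format: UTF-8 text, "#"-prefixed header lines
#   # R0_angstrom=<float>
#   # label=<free text>
# followed by two whitespace-separated numeric columns
#   q_angstrom  energy_kcal_per_mol

def write_curve(curve: PotentialCurve, path: str | Path) -> Path:
    """Write a curve file; floats use repr-exact precision so a write->read
    round trip reproduces the curve bit for bit."""
    path = Path(path)
    lines = [
        f"# R0_angstrom={float(curve.R0)!r}",
        f"# label={curve.label}",
        "# columns: q_angstrom energy_kcal_per_mol",
    ]
    for q, e in zip(curve.q_values, curve.energies):
        lines.append(f"{float(q)!r}\t{float(e)!r}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def read_curve(path: str | Path) -> PotentialCurve:
    """Read a curve file, canonicalizing unsorted rows with a warning.

    Raises :class:`CurveFormatError` (with the offending line number) for
    non-numeric rows, duplicate q samples, or a missing ``R0_angstrom``
    header.
    """
    path = Path(path)
    r0: float | None = None
    label = ""
    qs: list[float] = []
    es: list[float] = []
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if body.startswith("R0_angstrom="):
                try:
                    r0 = float(body.split("=", 1)[1])
                except ValueError as exc:
                    raise CurveFormatError(
                        f"{path}:{lineno}: bad R0_angstrom header: {body!r}"
                    ) from exc
            elif body.startswith("label="):
                label = body.split("=", 1)[1]
            continue
        parts = line.split()
        if len(parts) != 2:
            raise CurveFormatError(
                f"{path}:{lineno}: expected two numeric columns, got {raw!r}"
            )
        try:
            q, e = float(parts[0]), float(parts[1])
        except ValueError as exc:
            raise CurveFormatError(
                f"{path}:{lineno}: non-numeric row {raw!r}"
            ) from exc
        if q in qs:
            raise CurveFormatError(f"{path}:{lineno}: duplicate q sample {q!r}")
        qs.append(q)
        es.append(e)
    if r0 is None:
        raise CurveFormatError(f"{path}: missing required '# R0_angstrom=' header")
    q_arr = np.asarray(qs)
    e_arr = np.asarray(es)
    order = np.argsort(q_arr)
    if not np.array_equal(order, np.arange(len(qs))):
        logger.warning("curve file %s had unsorted q samples; sorting on read", path)
        q_arr, e_arr = q_arr[order], e_arr[order]
    try:
        return PotentialCurve(q_arr, e_arr, r0, label)
    except ParameterError as exc:
        raise CurveFormatError(f"{path}: {exc}") from exc


def curve_to_csv(curve: PotentialCurve, path: str | Path) -> Path:
    """Export a curve as a plain CSV (for plotting in external tools)."""
    path = Path(path)
    rows = ["q_angstrom,R_angstrom,energy_kcal_per_mol"]
    for q, r, e in zip(curve.q_values, curve.bond_lengths, curve.energies):
        rows.append(f"{float(q)!r},{float(r)!r},{float(e)!r}")
    path.write_text("\n".join(rows) + "\n", encoding="utf-8")
    return path


def interpolate_curve(curve: PotentialCurve, n_points: int) -> PotentialCurve:
    """Cubic-spline resample onto a uniform ``n_points`` grid spanning the
    tabulated range.  Original nodes are reproduced exactly; a not-a-knot
    spline also reproduces any cubic polynomial to machine precision."""
    if n_points < 5:
        raise ParameterError(f"need at least 5 points, got {n_points}")
    if n_points < len(curve):
        raise ParameterError(
            f"refusing to decimate: n_points={n_points} < tabulated {len(curve)}"
        )
    q = np.linspace(curve.q_values[0], curve.q_values[-1], n_points)
    return dataclasses.replace(curve, q_values=q, energies=curve.spline()(q))


# --------------------------------------------------------------------------
# Schroedinger solver
# --------------------------------------------------------------------------

def _sine_dvr_kinetic(n_interior: int, dq: float, mass_amu: float) -> np.ndarray:
    """Colbert--Miller sine-DVR kinetic matrix for a particle in a box.

    The box is ``[x_0 - dq, x_0 + n_interior*dq]`` with the ``n_interior``
    DVR nodes strictly inside; here the two tabulated end nodes of the
    solver grid serve as the walls, so the box spans exactly the grid range.
    For a constant potential this operator has the exact particle-in-a-box
    spectrum (it is a unitary image of the sine basis), and for smooth
    potentials it converges spectrally fast.
    """
    np1 = n_interior + 1
    i = np.arange(1, n_interior + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    pref = (HBAR_SQ_OVER_TWO_AMU / mass_amu) * (np.pi / (np1 * dq)) ** 2 / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (-1.0) ** (ii - jj) * (
            1.0 / np.sin(np.pi * (ii - jj) / (2 * np1)) ** 2
            - 1.0 / np.sin(np.pi * (ii + jj) / (2 * np1)) ** 2
        )
    t[np.diag_indices(n_interior)] = (
        (2 * np1**2 + 1) / 3.0 - 1.0 / np.sin(np.pi * i / np1) ** 2
    )
    return pref * t


def _potential_on_grid(curve: PotentialCurve, grid: GridSpec) -> np.ndarray:
    eps = 1e-9 * max(1.0, abs(curve.q_values[0]), abs(curve.q_values[-1]))
    if grid.q_start < curve.q_values[0] - eps or grid.q_end > curve.q_values[-1] + eps:
        raise ParameterError(
            f"grid [{grid.q_start}, {grid.q_end}] exceeds the tabulated span "
            f"[{curve.q_values[0]}, {curve.q_values[-1]}]"
        )
    return curve.spline()(grid.points())


def _canonicalize(psi: np.ndarray) -> np.ndarray:
    """Fix each column's sign so its first non-negligible amplitude is
    positive."""
    out = psi.copy()
    for j in range(out.shape[1]):
        col = out[:, j]
        idx = np.nonzero(np.abs(col) > 1e-8 * np.abs(col).max())[0]
        if idx.size and col[idx[0]] < 0:
            out[:, j] = -col
    return out


def _finalize_spectrum(
    vals: np.ndarray, interior: np.ndarray, curve: PotentialCurve,
    mass: ParticleMass, grid: GridSpec,
) -> VibrationalSpectrum:
    dq = grid.spacing
    # DVR/FD coefficients are unit vectors; ground-state amplitude at the
    # nodes adjacent to the walls signals the Dirichlet box is too small
    edge = max(abs(interior[0, 0]), abs(interior[-1, 0]))
    if edge > BOUNDARY_LEAKAGE_THRESHOLD:
        warnings.warn(
            f"ground-state amplitude {edge:.2e} at the box wall "
            f"(grid [{grid.q_start}, {grid.q_end}], isotope "
            f"{mass.isotope_label}); energies may be confined upward",
            BoundaryLeakageWarning,
            stacklevel=3,
        )
    psi = np.zeros((grid.n_points, interior.shape[1]))
    psi[1:-1, :] = interior / np.sqrt(dq)
    return VibrationalSpectrum(
        energies=vals,
        wavefunctions=_canonicalize(psi),
        grid=grid,
        mass=mass,
        curve_label=curve.label,
    )


def solve_states(
    curve: PotentialCurve,
    mass: ParticleMass,
    grid: GridSpec | None = None,
    n_states: int = 3,
) -> VibrationalSpectrum:
    """Solve the 1D nuclear Schroedinger equation on ``curve``.

    Hamiltonian: sine-DVR kinetic operator (prefactor hbar^2/2m in
    kcal/mol * A^2 / amu) plus the spline-interpolated potential on the
    diagonal; hard walls at the grid ends.  Returns the ``n_states`` lowest
    states with minimum-referenced energies.

    By default the solver densifies to ``PRODUCTION_GRID_POINTS`` nodes over
    the tabulated span.
    """
    if n_states < 1:
        raise ParameterError(f"n_states must be >= 1, got {n_states}")
    if grid is None:
        grid = GridSpec(curve.q_values[0], curve.q_values[-1], PRODUCTION_GRID_POINTS)
    n_interior = grid.n_points - 2
    if n_states > n_interior:
        raise ParameterError(
            f"n_states={n_states} exceeds the {n_interior} interior grid nodes"
        )
    v = _potential_on_grid(curve, grid)
    h = _sine_dvr_kinetic(n_interior, grid.spacing, mass.mass_amu)
    h[np.diag_indices(n_interior)] += v[1:-1]
    logger.debug(
        "solve_states: %d interior nodes, mass=%.6f amu (%s), "
        "kinetic prefactor=%.6f kcal/mol*A^2",
        n_interior, mass.mass_amu, mass.isotope_label,
        HBAR_SQ_OVER_TWO_AMU / mass.mass_amu,
    )
    try:
        vals, vecs = _sla.eigh(h, subset_by_index=[0, n_states - 1])
    except _sla.LinAlgError as exc:
        raise NumericalError(f"dense eigensolve failed: {exc}") from exc
    return _finalize_spectrum(vals, vecs, curve, mass, grid)


def solve_states_fd(
    curve: PotentialCurve,
    mass: ParticleMass,
    grid: GridSpec | None = None,
    n_states: int = 3,
) -> VibrationalSpectrum:
    """Independent cross-check solver: 3-point finite-difference Laplacian
    with the same hard-wall convention as :func:`solve_states`.  Converges
    as O(dq^2); use for validation, not production."""
    if n_states < 1:
        raise ParameterError(f"n_states must be >= 1, got {n_states}")
    if grid is None:
        grid = GridSpec(curve.q_values[0], curve.q_values[-1], PRODUCTION_GRID_POINTS)
    n_interior = grid.n_points - 2
    if n_states > n_interior:
        raise ParameterError(
            f"n_states={n_states} exceeds the {n_interior} interior grid nodes"
        )
    v = _potential_on_grid(curve, grid)
    c = HBAR_SQ_OVER_TWO_AMU / mass.mass_amu / grid.spacing**2
    try:
        vals, vecs = _sla.eigh_tridiagonal(
            2.0 * c + v[1:-1],
            np.full(n_interior - 1, -c),
            select="i",
            select_range=(0, n_states - 1),
        )
    except _sla.LinAlgError as exc:
        raise NumericalError(f"tridiagonal eigensolve failed: {exc}") from exc
    return _finalize_spectrum(vals, vecs, curve, mass, grid)


def zero_point_energy(spectrum: VibrationalSpectrum) -> float:
    """Ground-state energy above the potential minimum, kcal/mol."""
    if spectrum.n_states < 1:
        raise ParameterError("spectrum has no states")
    return float(spectrum.energies[0])


def write_spectrum(
    spectrum: VibrationalSpectrum,
    path: str | Path,
    wavefunction_path: str | Path | None = None,
) -> Path:
    """Write eigenvalues as TSV; optionally write gridded wavefunctions as a
    sidecar TSV (columns q, psi_0, psi_1, ...)."""
    path = Path(path)
    lines = [f"# isotope={spectrum.mass.isotope_label} mass_amu={spectrum.mass.mass_amu!r}",
             f"# curve={spectrum.curve_label}",
             "state\tenergy_kcal_per_mol"]
    for i, e in enumerate(spectrum.energies):
        lines.append(f"{i}\t{float(e)!r}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    if wavefunction_path is not None:
        wp = Path(wavefunction_path)
        header = "q_angstrom\t" + "\t".join(
            f"psi_{i}" for i in range(spectrum.n_states)
        )
        rows = [header]
        for q, amps in zip(spectrum.grid.points(), spectrum.wavefunctions):
            rows.append(
                "\t".join([f"{float(q)!r}"] + [f"{float(a)!r}" for a in amps])
            )
        wp.write_text("\n".join(rows) + "\n", encoding="utf-8")
    return path


# --------------------------------------------------------------------------
# Observables
# --------------------------------------------------------------------------

def expectation_bond_length(
    spectrum: VibrationalSpectrum, curve: PotentialCurve, state_index: int
) -> float:
    """Vibrationally averaged bond length <R>_i = R0 + <psi_i| q |psi_i>."""
    if not 0 <= state_index < spectrum.n_states:
        raise ParameterError(
            f"state_index {state_index} out of range for {spectrum.n_states} states"
        )
    q = spectrum.grid.points()
    psi = spectrum.wavefunctions[:, state_index]
    return float(curve.R0 + np.sum(q * psi**2) * spectrum.grid.spacing)


def boltzmann_weights(energies: Sequence[float], temperature: float) -> np.ndarray:
    """Normalized Boltzmann populations of the supplied levels at T.

    Energies are shifted by the lowest supplied level before
    exponentiation; the populations are invariant under any constant energy
    shift, so this only improves numerical stability.
    """
    if temperature <= 0:
        raise ParameterError(f"temperature must be positive, got {temperature}")
    e = np.asarray(energies, dtype=float)
    if e.size < 1:
        raise ParameterError("need at least one energy level")
    w = np.exp(-(e - e.min()) / (KB_KCAL_PER_MOL_K * temperature))
    return w / w.sum()


def thermal_average(
    values: Sequence[float], energies: Sequence[float], temperature: float
) -> float:
    """Boltzmann-weighted mean of state-resolved values at temperature T:
    ``R_T = sum_i R_i exp(-eps_i/kT) / sum_i exp(-eps_i/kT)``."""
    v = np.asarray(values, dtype=float)
    e = np.asarray(energies, dtype=float)
    if v.size != e.size:
        raise ParameterError(
            f"values ({v.size}) and energies ({e.size}) differ in length"
        )
    return float(np.sum(boltzmann_weights(e, temperature) * v))


def excitation_gaps(spectrum: VibrationalSpectrum) -> np.ndarray:
    """Excitation energies eps_i - eps_0 for i >= 1, kcal/mol."""
    if spectrum.n_states < 2:
        raise ParameterError("need at least two states for excitation gaps")
    return np.asarray(spectrum.energies[1:] - spectrum.energies[0])


def barrier_analysis(curve: PotentialCurve) -> BarrierReport:
    """Locate interior stationary points of the spline interpolant.

    Stationary points are the exact roots of the piecewise-cubic
    derivative, classified by the sign of the second derivative.  A curve
    with an interior maximum flanked by two interior minima is classified
    "double-well" and its barrier height is E(top) - E(global minimum);
    otherwise "single-well".  Endpoint extrema are never counted as wells.
    """
    spline = curve.spline()
    dspline = spline.derivative()
    roots = np.asarray(dspline.roots(extrapolate=False), dtype=float)
    span = curve.q_values[-1] - curve.q_values[0]
    interior = [
        r for r in np.unique(np.round(roots, 12))
        if curve.q_values[0] + 1e-9 * span < r < curve.q_values[-1] - 1e-9 * span
    ]
    points: list[StationaryPoint] = []
    curv_scale = max(1.0, float(np.abs(spline(curve.q_values, 2)).max()))
    for r in interior:
        dd = float(spline(r, 2))
        if abs(dd) < 1e-10 * curv_scale:
            continue  # inflection / numerically flat: not an extremum
        points.append(
            StationaryPoint(
                q=float(r),
                bond_length=float(curve.R0 + r),
                energy=float(spline(r)),
                kind="minimum" if dd > 0 else "maximum",
            )
        )
    points.sort(key=lambda p: p.q)
    minima = [p for p in points if p.kind == "minimum"]
    if not minima:
        raise DegenerateCurveError(
            "curve has no interior minimum; cannot analyse stationary points"
        )
    global_min = min(minima, key=lambda p: p.energy)
    tops = [
        p for p in points
        if p.kind == "maximum" and minima[0].q < p.q < minima[-1].q
    ]
    if len(minima) >= 2 and tops:
        top = max(tops, key=lambda p: p.energy)
        return BarrierReport(
            stationary_points=tuple(points),
            classification="double-well",
            global_min_q=global_min.q,
            global_min_energy=global_min.energy,
            global_min_bond_length=global_min.bond_length,
            barrier_height=top.energy - global_min.energy,
            barrier_q=top.q,
            barrier_bond_length=top.bond_length,
        )
    return BarrierReport(
        stationary_points=tuple(points),
        classification="single-well",
        global_min_q=global_min.q,
        global_min_energy=global_min.energy,
        global_min_bond_length=global_min.bond_length,
    )


def lbhb_classify(
    curve: PotentialCurve,
    spectrum_h: VibrationalSpectrum,
    tolerance: float = 0.5,
) -> LbhbClassification:
    """Classify the hydrogen bond by comparing the proton zero-point energy
    with the proton-transfer barrier.

    A barrier reached (within ``tolerance`` kcal/mol) or overtopped by the
    zero-point level lets the proton delocalize across both wells -- the
    low-barrier-hydrogen-bond regime.  Single-well curves are labelled
    "no-barrier (single-well)" rather than raising.
    """
    zpe = zero_point_energy(spectrum_h)
    report = barrier_analysis(curve)
    if report.classification == "single-well":
        return LbhbClassification(
            category="no-barrier (single-well)",
            zero_point_energy=zpe,
            tolerance=tolerance,
        )
    barrier = float(report.barrier_height)
    gap = barrier - zpe
    category = (
        "ZPE-dominated (LBHB-like)" if zpe >= barrier - tolerance
        else "barrier-localized"
    )
    return LbhbClassification(
        category=category,
        zero_point_energy=zpe,
        barrier_height=barrier,
        barrier_minus_zpe=gap if gap > 0 else None,
        tolerance=tolerance,
    )


def build_thermal_report(
    spectrum: VibrationalSpectrum,
    curve: PotentialCurve,
    temperature: float = ROOM_TEMPERATURE_K,
) -> ThermalReport:
    """Per-state <R>_i with Boltzmann weights and the thermal mean R_T.

    Uses every solved state.  When four or more states are available the
    report checks truncation: if dropping to three states moves R_T by more
    than 0.005 A a convergence warning is logged.
    """
    mean_r = np.array([
        expectation_bond_length(spectrum, curve, i) for i in range(spectrum.n_states)
    ])
    w = boltzmann_weights(spectrum.energies, temperature)
    r_t = float(np.sum(w * mean_r))
    if spectrum.n_states >= 4:
        r_t3 = thermal_average(mean_r[:3], spectrum.energies[:3], temperature)
        if abs(r_t - r_t3) > 0.005:
            logger.warning(
                "thermal average not converged with 3 states: "
                "R_T(3)=%.4f A vs R_T(%d)=%.4f A", r_t3, spectrum.n_states, r_t,
            )
    states = tuple(
        ThermalState(i, float(spectrum.energies[i]), float(mean_r[i]), float(w[i]))
        for i in range(spectrum.n_states)
    )
    return ThermalReport(
        temperature=temperature, states=states, thermal_mean_bond_length=r_t
    )


def isotope_report(
    spec_h: VibrationalSpectrum,
    spec_d: VibrationalSpectrum,
    curve: PotentialCurve,
    temperature: float = ROOM_TEMPERATURE_K,
) -> IsotopeComparison:
    """Assemble the H/D comparison: ground-state bond-length difference,
    quantum and thermal elongations, and first excitation gaps."""
    if spec_h.grid != spec_d.grid:
        raise ParameterError("isotope spectra were solved on different grids")
    r_min = barrier_analysis(curve).global_min_bond_length
    out_q: dict[str, float] = {}
    out_t: dict[str, float] = {}
    out_g: dict[str, float] = {}
    ground: dict[str, float] = {}
    for spec in (spec_h, spec_d):
        label = spec.mass.isotope_label
        rep = build_thermal_report(spec, curve, temperature)
        r0_mean = rep.states[0].mean_bond_length
        ground[label] = r0_mean
        out_q[label] = r0_mean - r_min
        out_t[label] = rep.thermal_mean_bond_length - r0_mean
        out_g[label] = float(excitation_gaps(spec)[0])
    labels = list(ground)
    return IsotopeComparison(
        delta_mean_r_ground=ground[labels[0]] - ground[labels[1]],
        quantum_elongation=out_q,
        thermal_elongation=out_t,
        first_gap=out_g,
        temperature=temperature,
    )


# --------------------------------------------------------------------------
# Pipeline: printed-table fixtures, config, end-to-end driver
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PrintedVibrationalTable:
    """Published per-state vibrational levels and averaged bond lengths.

    Bundling the printed numbers lets the Boltzmann-averaging stage be run
    and tested independently of the eigensolver (whose input potential
    scans were never published numerically).  ``energies`` and
    ``mean_bond_lengths`` map isotope label -> values for states 0, 1, 2
    (ascending); ``minimum_bond_length`` is the bond length at the
    potential minimum.
    """

    name: str
    minimum_bond_length: float
    energies: Mapping[str, tuple[float, ...]]
    mean_bond_lengths: Mapping[str, tuple[float, ...]]


#: Published levels for the energy-minimized PYP geometry (single well,
#: minimum at R = 1.08 A).
PRINTED_EQUILIBRIUM_TABLE = PrintedVibrationalTable(
    name="pyp_equilibrium",
    minimum_bond_length=1.08,
    energies={"H": (2.02, 5.46, 10.14), "D": (1.47, 3.73, 6.52)},
    mean_bond_lengths={"H": (1.17, 1.23, 1.21), "D": (1.15, 1.24, 1.22)},
)

#: Published levels for the neutron crystal PYP geometry (double well,
#: minimum at R = 1.06 A, barrier 2.36 kcal/mol).
PRINTED_CRYSTAL_TABLE = PrintedVibrationalTable(
    name="pyp_crystal",
    minimum_bond_length=1.06,
    energies={"H": (2.08, 3.76, 7.36), "D": (1.67, 2.63, 4.77)},
    mean_bond_lengths={"H": (1.23, 1.34, 1.29), "D": (1.17, 1.39, 1.28)},
)

PRINTED_TABLES: dict[str, PrintedVibrationalTable] = {
    t.name: t for t in (PRINTED_EQUILIBRIUM_TABLE, PRINTED_CRYSTAL_TABLE)
}

FIXTURE_BUILDERS: dict[str, Callable[..., PotentialCurve]] = {
    "pyp_equilibrium": make_pyp_equilibrium_fixture,
    "pyp_crystal": make_pyp_crystal_fixture,
}


def build_fixture(name: str, grid: GridSpec | None = None, **params) -> PotentialCurve:
    """Build a named synthetic curve (``pyp_equilibrium``, ``pyp_crystal``,
    ``harmonic``, ``morse``, ``double_well``)."""
    grid = grid or DEFAULT_FIXTURE_GRID
    if name in FIXTURE_BUILDERS:
        return FIXTURE_BUILDERS[name](grid=grid, **params)
    if name == "harmonic":
        defaults = dict(force_constant=10.0, q_min=0.0, R0=1.0)
        defaults.update(params)
        return make_harmonic(grid=grid, **defaults)
    if name == "morse":
        defaults = dict(D_e=20.0, a=2.2, q_min=0.0, R0=1.0)
        defaults.update(params)
        return make_morse(grid=grid, **defaults)
    if name == "double_well":
        defaults = dict(
            min1_q=-0.15, barrier_q=0.10, min2_q=0.35,
            barrier_height=2.36, asymmetry=1.0, R0=1.21,
        )
        defaults.update(params)
        return make_double_well(grid=grid, **defaults)
    raise ParameterError(f"unknown fixture {name!r}")


@dataclass(frozen=True)
class RunConfig:
    """Configuration for the end-to-end pipeline.

    ``curve_source`` is either a curve-file path or ``"fixture:<name>"``.
    ``seed`` feeds optional synthetic-curve noise only; the pipeline itself
    is deterministic.
    """

    curve_source: str
    isotopes: tuple[str, ...] = ("H", "D")
    n_states: int = 3
    temperature: float = ROOM_TEMPERATURE_K
    grid_points: int = PRODUCTION_GRID_POINTS
    out_dir: str = "protonvib_out"
    formats: tuple[str, ...] = ("json", "tsv")
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_states < 1:
            raise ParameterError("n_states must be >= 1")
        if self.temperature <= 0:
            raise ParameterError("temperature must be positive")
        for iso in self.isotopes:
            if iso not in ("H", "D"):
                raise ParameterError(f"unknown isotope {iso!r} (use H or D)")

    @classmethod
    def from_mapping(cls, data: Mapping) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        clean = dict(data)
        for key in ("isotopes", "formats"):
            if key in clean:
                clean[key] = tuple(clean[key])
        return cls(**clean)


def _resolve_curve(config: RunConfig) -> PotentialCurve:
    if config.curve_source.startswith("fixture:"):
        name = config.curve_source.split(":", 1)[1]
        curve = build_fixture(name)
        if config.seed is not None:
            logger.info("seed=%d accepted (no noise requested; unused)", config.seed)
        return curve
    return read_curve(config.curve_source)


def run_pipeline(config: RunConfig) -> dict:
    """Run curve -> spectra -> observables and return the report dict.

    Writes ``report.json`` / ``report.tsv`` (per ``config.formats``) plus
    per-isotope spectrum TSVs and wavefunction sidecars into
    ``config.out_dir``.  Identical configs produce byte-identical outputs.
    """
    curve = _resolve_curve(config)
    grid = GridSpec(curve.q_values[0], curve.q_values[-1], config.grid_points)
    logger.info(
        "pipeline: curve=%s R0=%.4f A, grid=[%g, %g] x %d, T=%.1f K, "
        "k_B=%.10g kcal/mol/K, hbar^2/2amu=%.10g kcal/mol*A^2, "
        "m_H=%.6f amu, m_D=%.6f amu",
        curve.label, curve.R0, grid.q_start, grid.q_end, grid.n_points,
        config.temperature, KB_KCAL_PER_MOL_K, HBAR_SQ_OVER_TWO_AMU,
        MASS_PROTON_AMU, MASS_DEUTERON_AMU,
    )
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    barrier = barrier_analysis(curve)
    report: dict = {
        "curve": {
            "label": curve.label,
            "R0_angstrom": curve.R0,
            "n_samples": len(curve),
            "source": config.curve_source,
        },
        "temperature_K": config.temperature,
        "constants": {
            "k_B_kcal_per_mol_K": KB_KCAL_PER_MOL_K,
            "hbar_sq_over_2amu_kcal_per_mol_A2": HBAR_SQ_OVER_TWO_AMU,
            "mass_H_amu": MASS_PROTON_AMU,
            "mass_D_amu": MASS_DEUTERON_AMU,
        },
        "barrier": {
            "classification": barrier.classification,
            "global_min_q_angstrom": barrier.global_min_q,
            "global_min_R_angstrom": barrier.global_min_bond_length,
            "barrier_height_kcal_per_mol": barrier.barrier_height,
            "barrier_q_angstrom": barrier.barrier_q,
            "barrier_R_angstrom": barrier.barrier_bond_length,
        },
        "isotopes": {},
    }

    spectra: dict[str, VibrationalSpectrum] = {}
    for iso in config.isotopes:
        mass = ParticleMass.from_label(iso)
        spec = solve_states(curve, mass, grid, config.n_states)
        spectra[iso] = spec
        thermal = build_thermal_report(spec, curve, config.temperature)
        report["isotopes"][iso] = {
            "zero_point_energy_kcal_per_mol": zero_point_energy(spec),
            "R_T_angstrom": thermal.thermal_mean_bond_length,
            "states": [
                {
                    "state": s.index,
                    "epsilon_kcal_per_mol": s.energy,
                    "mean_R_angstrom": s.mean_bond_length,
                    "weight": s.weight,
                }
                for s in thermal.states
            ],
        }
        write_spectrum(
            spec,
            out_dir / f"spectrum_{iso}.tsv",
            out_dir / f"wavefunctions_{iso}.tsv",
        )

    if "H" in spectra:
        cls = lbhb_classify(curve, spectra["H"])
        report["classification"] = {
            "category": cls.category,
            "zero_point_energy_kcal_per_mol": cls.zero_point_energy,
            "barrier_height_kcal_per_mol": cls.barrier_height,
            "barrier_minus_zpe_kcal_per_mol": cls.barrier_minus_zpe,
            "tolerance_kcal_per_mol": cls.tolerance,
        }
    if "H" in spectra and "D" in spectra:
        iso_cmp = isotope_report(spectra["H"], spectra["D"], curve, config.temperature)
        report["isotope_comparison"] = {
            "delta_mean_R_ground_angstrom": iso_cmp.delta_mean_r_ground,
            "quantum_elongation_angstrom": dict(iso_cmp.quantum_elongation),
            "thermal_elongation_angstrom": dict(iso_cmp.thermal_elongation),
            "first_gap_kcal_per_mol": dict(iso_cmp.first_gap),
        }

    if "json" in config.formats:
        (out_dir / "report.json").write_text(render_report_json(report), encoding="utf-8")
    if "tsv" in config.formats:
        (out_dir / "report.tsv").write_text(render_report_tsv(report), encoding="utf-8")
    return report


def printed_table_report(
    table: str | PrintedVibrationalTable,
    temperature: float = ROOM_TEMPERATURE_K,
) -> dict:
    """Thermal-averaging report built directly from a bundled printed
    table, bypassing the eigensolver.  Row layout matches the published
    tables (per-state epsilon and <R>, then R_T)."""
    if isinstance(table, str):
        if table not in PRINTED_TABLES:
            raise ParameterError(
                f"unknown printed table {table!r}; choose from {sorted(PRINTED_TABLES)}"
            )
        table = PRINTED_TABLES[table]
    report: dict = {
        "curve": {
            "label": f"printed table {table.name}",
            "R0_angstrom": None,
            "n_samples": 0,
            "source": f"table:{table.name}",
        },
        "temperature_K": temperature,
        "isotopes": {},
    }
    for iso in table.energies:
        eps = table.energies[iso]
        mean_r = table.mean_bond_lengths[iso]
        w = boltzmann_weights(eps, temperature)
        report["isotopes"][iso] = {
            "zero_point_energy_kcal_per_mol": eps[0],
            "R_T_angstrom": thermal_average(mean_r, eps, temperature),
            "states": [
                {
                    "state": i,
                    "epsilon_kcal_per_mol": eps[i],
                    "mean_R_angstrom": mean_r[i],
                    "weight": float(w[i]),
                }
                for i in range(len(eps))
            ],
        }
    return report


def render_report_json(report: Mapping) -> str:
    """Machine-readable report at full precision; key-sorted and therefore
    byte-stable for identical inputs."""
    return json.dumps(report, indent=2, sort_keys=True) + "\n"


def render_report_tsv(report: Mapping) -> str:
    """Human-readable table mirroring the published layout: one row per
    state with isotope, state index, epsilon, <R>, and a final R_T row per
    isotope.  Values rounded to 2 decimals like the published tables."""
    lines = ["isotope\tstate\tepsilon_kcal_per_mol\tmean_R_angstrom\tR_T_angstrom"]
    for iso, block in report["isotopes"].items():
        for s in block["states"]:
            lines.append(
                f"{iso}\t{s['state']}\t{s['epsilon_kcal_per_mol']:.2f}"
                f"\t{s['mean_R_angstrom']:.2f}\t"
            )
        lines.append(f"{iso}\tR_T\t\t\t{block['R_T_angstrom']:.2f}")
    barrier = report.get("barrier")
    if barrier:
        lines.append(f"# classification\t{barrier['classification']}")
        if barrier["barrier_height_kcal_per_mol"] is not None:
            lines.append(
                f"# barrier_kcal_per_mol\t{barrier['barrier_height_kcal_per_mol']:.2f}"
                f"\tat q={barrier['barrier_q_angstrom']:.2f}"
                f"\tR={barrier['barrier_R_angstrom']:.2f}"
            )
    cls = report.get("classification")
    if cls:
        lines.append(f"# H-bond class\t{cls['category']}")
    return "\n".join(lines) + "\n"
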