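"""Single-point calculator contract and the built-in toy backends.

Real explorations delegate energies, gradients, Hessians, bond orders and
partial charges to an electronic-structure engine behind a generic
calculator interface.  This package keeps the interface and swaps the
physics for two analytic backends that are cheap enough to drive every
downstream algorithm:

* :class:`MorseCalculator` — a pairwise Morse potential with a Pauling-style
  exponential bond order, optionally augmented with a Gaussian barrier on
  selected element pairs so that association/dissociation paths possess a
  first-order saddle.  This is the simplest 3D potential that supports bond
  formation, cleavage, reaction barriers and the bond-order stop criteria of
  the scan algorithms.
* :class:`MuellerBrownCalculator` — the classic two-dimensional
  multi-Gaussian surface, treated as a single pseudo-atom with a frozen
  ``z = 0`` plane; used to exercise optimizers and scans against an exactly
  known landscape.

Units: energies in a Hartree-like arbitrary unit, lengths in Å.  A plug-in
docking a real quantum-chemistry program only needs to implement
:meth:`Calculator.compute` with the same contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .data_model import Structure
from .elements import DEFAULT_RADII, CovalentRadiiTable, UnknownElementError


class CalculationFailure(RuntimeError):
    """A single-point evaluation failed (non-finite result, bad input…).

    Feeds stop criterion (iii) of the scan algorithms.
    """


class CapabilityError(RuntimeError):
    """The calculator cannot treat the requested system or property."""


@dataclass
class CalcResult:
    energy: float
    gradient: Optional[np.ndarray] = None  # (N, 3)
    hessian: Optional[np.ndarray] = None  # (3N, 3N)
    bond_orders: Optional[np.ndarray] = None  # (N, N), symmetric, zero diag
    partial_charges: Optional[np.ndarray] = None  # (N,)


@dataclass(frozen=True)
class PairParams:
    """Morse + bond-order parameters of one element pair.

    ``equilibrium`` is the sum of the two covalent radii; ``barrier_height``
    of zero means a plain Morse well.  The optional Gaussian barrier is
    centred at ``equilibrium + barrier_offset``.
    """

    well_depth: float  # D_e, energy
    equilibrium: float  # r0 = r_cov(A) + r_cov(B), Å
    morse_width: float  # a, 1/Å
    bo_decay: float  # b in BO = exp((r0 - r)/b), Å
    barrier_height: float = 0.0  # energy
    barrier_offset: float = 0.33  # Å past r0
    barrier_width: float = 0.07  # Å
    repulsive_only: bool = False  # keep only the exponential wall (inert pair)

    def __post_init__(self) -> None:
        if min(self.well_depth, 0.0) < 0 or self.equilibrium <= 0:
            raise ValueError("well depth must be >= 0 and equilibrium > 0")
        if self.morse_width <= 0 or self.bo_decay <= 0:
            raise ValueError("morse width and bond-order decay must be positive")


@dataclass
class PairPotentialParams:
    """Parameter set of the pairwise toy backend.

    Per-pair overrides are keyed by a frozenset of the two element symbols;
    unknown pairs fall back to the defaults with the equilibrium length taken
    from the radii table.
    """

    radii: CovalentRadiiTable = field(default_factory=lambda: DEFAULT_RADII)
    default_well_depth: float = 0.17
    default_morse_width: float = 1.9
    default_bo_decay: float = 0.25
    default_barrier_height: float = 0.0
    default_barrier_offset: float = 0.33
    default_barrier_width: float = 0.07
    overrides: dict[frozenset, PairParams] = field(default_factory=dict)

    def pair(self, symbol_a: str, symbol_b: str) -> PairParams:
        key = frozenset((symbol_a, symbol_b))
        if key in self.overrides:
            return self.overrides[key]
        return PairParams(
            well_depth=self.default_well_depth,
            equilibrium=self.radii.radii_sum(symbol_a, symbol_b),
            morse_width=self.default_morse_width,
            bo_decay=self.default_bo_decay,
            barrier_height=self.default_barrier_height,
            barrier_offset=self.default_barrier_offset,
            barrier_width=self.default_barrier_width,
        )

    def set_pair(self, symbol_a: str, symbol_b: str, params: PairParams) -> None:
        self.overrides[frozenset((symbol_a, symbol_b))] = params


def barrier_params(
    radii: CovalentRadiiTable = DEFAULT_RADII,
    well_depth: float = 0.17,
    barrier_height: float = 0.04,
    barrier_offset: float = 0.33,
    barrier_width: float = 0.07,
) -> PairPotentialParams:
    """Pair-potential defaults with a dissociation barrier on every pair.

    The barrier crest sits past the bond-perception distance but before the
    bond-order "broken" stop distance of a scan, so a dissociation scan
    records an interior energy maximum from which a transition-state guess
    can be extracted.
    """
    return PairPotentialParams(
        radii=radii,
        default_well_depth=well_depth,
        default_barrier_height=barrier_height,
        default_barrier_offset=barrier_offset,
        default_barrier_width=barrier_width,
    )


def toy_bond_order(
    r: float, element_a: str, element_b: str, params: PairPotentialParams
) -> float:
    """Pauling-style bond order BO = exp((r0 − r)/b), capped at 3.

    BO(r0) = 1 by construction and BO decreases monotonically with distance.
    """
    if r <= 0:
        raise ValueError("distance must be positive")
    pp = params.pair(element_a, element_b)
    return float(min(np.exp((pp.equilibrium - r) / pp.bo_decay), 3.0))


class Calculator:
    """Single-point calculator contract.

    ``compute(structure, required)`` populates exactly the requested
    properties; results are deterministic for a fixed input.  Backends set
    ``has_rigid_modes`` to declare whether rigid translations/rotations are
    zero modes of their Hessian (true for molecular pair potentials, false
    for the pinned 2D surface).
    """

    has_rigid_modes: bool = True

    def compute(self, structure: Structure, required: set[str]) -> CalcResult:
        raise NotImplementedError

    # convenience shorthands -------------------------------------------
    def energy(self, structure: Structure) -> float:
        return self.compute(structure, {"energy"}).energy

    def gradient(self, structure: Structure) -> np.ndarray:
        return self.compute(structure, {"energy", "gradient"}).gradient


class MorseCalculator(Calculator):
    """Pairwise Morse potential with exponential bond orders.

    V(r) = D_e (x² − 2x) + h·exp(−((r − r_c)/w)²),  x = exp(−a (r − r0)),

    summed over all atom pairs.  V(r0) = −D_e (+ a negligible barrier tail)
    and V(∞) = 0, so the well depth is the separated dissociation energy.
    Partial charges split the total charge over connected fragments weighted
    by electronegativity (only consumers: product separation).
    """

    has_rigid_modes = True

    def __init__(self, params: Optional[PairPotentialParams] = None) -> None:
        self.params = params or PairPotentialParams()

    # -- internals ------------------------------------------------------
    def _pair_energy_derivative(self, r: float, pp: PairParams) -> tuple[float, float]:
        x = np.exp(-pp.morse_width * (r - pp.equilibrium))
        if pp.repulsive_only:
            energy = pp.well_depth * x * x
            deriv = -2.0 * pp.morse_width * pp.well_depth * x * x
        else:
            energy = pp.well_depth * (x * x - 2.0 * x)
            deriv = 2.0 * pp.morse_width * pp.well_depth * x * (1.0 - x)
        if pp.barrier_height:
            center = pp.equilibrium + pp.barrier_offset
            u = (r - center) / pp.barrier_width
            bump = pp.barrier_height * np.exp(-u * u)
            energy += bump
            deriv += -2.0 * u / pp.barrier_width * bump
        return energy, deriv

    def compute(self, structure: Structure, required: set[str]) -> CalcResult:
        for symbol in structure.elements:
            if symbol not in self.params.radii:
                raise CapabilityError(f"element not parameterized: {symbol}")
        pos = structure.positions
        n = structure.n_atoms
        energy = 0.0
        gradient = np.zeros((n, 3))
        need_bo = "bond_orders" in required or "partial_charges" in required
        bond_orders = np.zeros((n, n)) if need_bo else None
        for i in range(n):
            for j in range(i + 1, n):
                vec = pos[j] - pos[i]
                r = float(np.linalg.norm(vec))
                if r < 1e-12:
                    raise CalculationFailure(f"coincident atoms {i}, {j}")
                pp = self.params.pair(structure.elements[i], structure.elements[j])
                e_ij, de_ij = self._pair_energy_derivative(r, pp)
                energy += e_ij
                unit = vec / r
                gradient[i] -= de_ij * unit
                gradient[j] += de_ij * unit
                if need_bo:
                    bo = min(np.exp((pp.equilibrium - r) / pp.bo_decay), 3.0)
                    bond_orders[i, j] = bond_orders[j, i] = bo
        if not np.isfinite(energy):
            raise CalculationFailure("non-finite energy")
        result = CalcResult(energy=float(energy))
        if "gradient" in required:
            result.gradient = gradient
        if "bond_orders" in required:
            result.bond_orders = bond_orders
        if "partial_charges" in required:
            result.partial_charges = self._partial_charges(structure, bond_orders)
        if "hessian" in required:
            result.hessian = finite_difference_hessian(structure, self)
        return result

    def _partial_charges(
        self, structure: Structure, bond_orders: np.ndarray
    ) -> np.ndarray:
        """Electronegativity-weighted split of the total charge over atoms.

        The toy charges only serve product separation (deciding which
        fragment keeps a formal charge); they are not physical.
        """
        del bond_orders  # weighting is geometry-independent
        if structure.charge == 0:
            return np.zeros(structure.n_atoms)
        weights = np.array(
            [
                self.params.radii.electronegativity(symbol) or 1.0
                for symbol in structure.elements
            ]
        )
        return weights / weights.sum() * structure.charge


# standard Müller–Brown parameter set
_MB_A = np.array([-200.0, -100.0, -170.0, 15.0])
_MB_a = np.array([-1.0, -1.0, -6.5, 0.7])
_MB_b = np.array([0.0, 0.0, 11.0, 0.6])
_MB_c = np.array([-10.0, -10.0, -6.5, 0.7])
_MB_x0 = np.array([1.0, 0.0, -0.5, -1.0])
_MB_y0 = np.array([0.0, 0.5, 1.5, 1.0])


def mueller_brown_energy(x: float, y: float) -> float:
    dx = x - _MB_x0
    dy = y - _MB_y0
    # exponent clipped: keeps far-out probe points finite instead of overflowing
    exponent = np.minimum(_MB_a * dx**2 + _MB_b * dx * dy + _MB_c * dy**2, 60.0)
    return float(np.sum(_MB_A * np.exp(exponent)))


def mueller_brown_gradient(x: float, y: float) -> np.ndarray:
    dx = x - _MB_x0
    dy = y - _MB_y0
    exponent = np.minimum(_MB_a * dx**2 + _MB_b * dx * dy + _MB_c * dy**2, 60.0)
    terms = _MB_A * np.exp(exponent)
    gx = np.sum(terms * (2.0 * _MB_a * dx + _MB_b * dy))
    gy = np.sum(terms * (_MB_b * dx + 2.0 * _MB_c * dy))
    return np.array([gx, gy])


class MuellerBrownCalculator(Calculator):
    """The 2D Müller–Brown surface as a one-pseudo-atom backend.

    The single atom moves in the ``z = 0`` plane; gradient and Hessian
    entries involving z are zero.  Rigid-body modes are *not* zero modes of
    this pinned surface, so ``has_rigid_modes`` is false.
    """

    has_rigid_modes = False

    def compute(self, structure: Structure, required: set[str]) -> CalcResult:
        if structure.n_atoms != 1:
            raise CapabilityError("the 2D analytic surface hosts exactly one atom")
        x, y = float(structure.positions[0, 0]), float(structure.positions[0, 1])
        energy = mueller_brown_energy(x, y)
        if not np.isfinite(energy):
            raise CalculationFailure("non-finite energy")
        result = CalcResult(energy=energy)
        if "gradient" in required:
            g2 = mueller_brown_gradient(x, y)
            result.gradient = np.array([[g2[0], g2[1], 0.0]])
        if "hessian" in required:
            result.hessian = finite_difference_hessian(structure, self)
        if "bond_orders" in required:
            result.bond_orders = np.zeros((1, 1))
        if "partial_charges" in required:
            result.partial_charges = np.array([float(structure.charge)])
        return result


def finite_difference_hessian(
    structure: Structure, calculator: Calculator, step: float = 1e-4
) -> np.ndarray:
    """Symmetrized central-difference Hessian from analytic gradients."""
    if step <= 0:
        raise ValueError("finite-difference step must be positive")
    n = structure.n_atoms
    hessian = np.zeros((3 * n, 3 * n))
    base = structure.positions.copy()
    probe = structure.copy()
    for k in range(3 * n):
        atom, axis = divmod(k, 3)
        probe.positions = base.copy()
        probe.positions[atom, axis] += step
        g_plus = calculator.gradient(probe).ravel()
        probe.positions = base.copy()
        probe.positions[atom, axis] -= step
        g_minus = calculator.gradient(probe).ravel()
        hessian[k] = (g_plus - g_minus) / (2.0 * step)
    return 0.5 * (hessian + hessian.T)
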