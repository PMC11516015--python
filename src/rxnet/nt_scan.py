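"""Newton-trajectory scans: forced uphill walks toward saddle regions.

Both scan variants replace the component of the natural gradient along the
trial reactive coordinate with an artificial force inside a steepest-descent
position update

    R ← R − α_SD · g̃,

so that the constrained atoms are driven together (or apart) while every
other degree of freedom relaxes downhill.

* **NT1** forces two atom *sets* {L} and {R} onto one another along the
  vector between their geometric centres.  Single-atom sites have the
  reactive-coordinate component of their natural gradient discarded;
  multi-atom sites have each member's gradient orthogonalized to the
  reactive coordinate.  All site atoms then receive the same artificial
  force of magnitude α_NT1/2, so the constrained-pair distance closes by
  α_SD·α_NT1 per macro cycle — which makes |R_C|/(α_SD·α_NT1) the expected
  number of cycles until collision, a convenient runtime estimate.
* **NT2** forces declared atom *pairs* to bond or to cleave.  Each
  constrained atom's gradient is orthogonalized against the span of every
  pair vector it belongs to; each pair then contributes ±α_NT2·F, where the
  formation direction carries a (r_cov sum)/distance weighting (so pairs
  starting farther out move faster, favouring concerted arrivals) and the
  cleavage direction is the plain unit vector.

Between macro steps, optional micro-cycles relax all unconstrained atoms
with BFGS while the constrained atoms stay frozen.  Scans terminate on a
gradient-call budget, on collision/conversion of the constrained
coordinates, or on calculator failure — failures are encoded in the
trajectory's stop reason, never raised.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize

from .calculator import Calculator, CalculationFailure
from .data_model import Structure, ValidationError
from .elements import CovalentRadiiTable
from .reactive_complex import TrialCoordinate


@dataclass
class MicrocycleSettings:
    enabled: bool = True
    max_steps: int = 50
    gradient_threshold: float = 1e-4  # max component, energy/Å


@dataclass
class NTSettings:
    """Tunable knobs of both scan algorithms.

    ``alpha_sd`` (Å²/energy) scales the steepest-descent update; the
    artificial-force scales are chosen so a macro cycle moves the reactive
    coordinate by about 0.05 Å with the defaults (α_SD·α_NT1 for NT1,
    2·α_SD·α_NT2·weight per symmetric NT2 pair).
    """

    alpha_sd: float = 0.5
    alpha_nt1: float = 0.1
    alpha_nt2: float = 0.05
    attract: bool = True  # NT1: push sites together (False: pull apart)
    max_gradient_calls: int = 400
    collision_factor: float = 0.9  # NT1: stop below this × radii sum
    nt2_collision_factor: float = 1.0  # NT2 "crashing into one another"
    bo_formed: float = 0.75
    bo_broken: float = 0.15
    microcycle: MicrocycleSettings = field(default_factory=MicrocycleSettings)

    def __post_init__(self) -> None:
        if min(self.alpha_sd, self.alpha_nt1, self.alpha_nt2) <= 0:
            raise ValidationError("all scan scale factors must be positive")
        if not (0.0 < self.bo_broken < self.bo_formed):
            raise ValidationError("need 0 < bo_broken < bo_formed")


@dataclass
class Frame:
    positions: np.ndarray
    energy: float
    gradient_calls: int


@dataclass
class Trajectory:
    """Ordered macro-step frames of a scan (or IRC branch) plus stop reason.

    ``structure_template`` carries the element/charge metadata shared by all
    frames, so single frames can be materialized as full structures.
    """

    frames: list[Frame]
    stop_reason: str  # max_calls | collision_or_converted | calc_failure | converged
    structure_template: Optional[Structure] = None

    def frame_structure(self, index: int) -> Structure:
        if self.structure_template is None:
            raise ValidationError("trajectory lacks a structure template")
        return self.structure_template.copy(
            positions=self.frames[index].positions.copy(), label="unoptimized"
        )

    @property
    def energies(self) -> np.ndarray:
        return np.array([frame.energy for frame in self.frames])

    @property
    def n_frames(self) -> int:
        return len(self.frames)


# ---------------------------------------------------------------------------
# gradient modification


def _orthogonalize_sequential(
    vector: np.ndarray, directions: Sequence[np.ndarray]
) -> np.ndarray:
    """Remove the components of a 3-vector along the span of directions.

    The directions are first orthonormalized sequentially (in the given
    sorted-pair order, dropping near-dependent ones), then projected out, so
    the result is orthogonal to *every* input direction.  Three linearly
    independent constraints on one atom therefore null its gradient.
    """
    basis: list[np.ndarray] = []
    for direction in directions:
        reduced = direction.copy()
        for b in basis:
            reduced -= np.dot(reduced, b) * b
        norm = np.linalg.norm(reduced)
        if norm > 1e-10:
            basis.append(reduced / norm)
    out = vector.copy()
    for b in basis:
        out -= np.dot(out, b) * b
    return out


def nt1_modified_gradient(
    positions: np.ndarray,
    natural_gradient: np.ndarray,
    sites_lhs: Sequence[int],
    sites_rhs: Sequence[int],
    settings: NTSettings,
) -> np.ndarray:
    """Modified gradient of the fragment-based scan.

    With attraction, the left site is driven toward the right one; the
    natural gradient along the reactive coordinate is discarded (zeroed for
    the strict single-atom/single-atom case, orthogonalized for multi-atom
    sites) on all constrained atoms; unconstrained atoms are untouched.
    """
    lhs = sorted(sites_lhs)
    rhs = sorted(sites_rhs)
    if not lhs or not rhs:
        raise ValidationError("both reactive sites must be non-empty")
    if set(lhs) & set(rhs):
        raise ValidationError("reactive sites overlap")
    center_l = positions[lhs].mean(axis=0)
    center_r = positions[rhs].mean(axis=0)
    coord = center_r - center_l
    norm = np.linalg.norm(coord)
    if norm < 1e-12:
        raise ValidationError("coincident reactive-site centres")
    unit = coord / norm
    sign = 1.0 if settings.attract else -1.0
    # per-atom artificial gradient; step = -alpha_sd * g moves left atoms
    # along +unit (toward the right site) when attracting
    force_l = -sign * 0.5 * settings.alpha_nt1 * unit
    force_r = +sign * 0.5 * settings.alpha_nt1 * unit
    modified = natural_gradient.copy()
    single_pair = len(lhs) == 1 and len(rhs) == 1
    for indices, artificial in ((lhs, force_l), (rhs, force_r)):
        for index in indices:
            if single_pair:
                surviving = modified[index] - np.dot(modified[index], unit) * unit
            else:
                surviving = _orthogonalize_sequential(modified[index], [unit])
            modified[index] = surviving + artificial
    return modified


def nt2_modified_gradient(
    positions: np.ndarray,
    natural_gradient: np.ndarray,
    form_pairs: Sequence[tuple[int, int]],
    break_pairs: Sequence[tuple[int, int]],
    radii: CovalentRadiiTable,
    elements: Sequence[str],
    settings: NTSettings,
) -> np.ndarray:
    """Modified gradient of the pair-based scan.

    Each constrained atom's natural gradient is orthogonalized against the
    span of every pair vector it belongs to (basis built in sorted pair
    order); then every formation pair adds an attracting force weighted by
    (radii sum)/distance and every cleavage pair adds a unit-direction
    separating force.
    """
    form_pairs = sorted(tuple(sorted(p)) for p in form_pairs)
    break_pairs = sorted(tuple(sorted(p)) for p in break_pairs)
    pair_vectors: dict[int, list[np.ndarray]] = {}
    units: dict[tuple[int, int], np.ndarray] = {}
    distances: dict[tuple[int, int], float] = {}
    for a, b in form_pairs + break_pairs:
        vec = positions[b] - positions[a]
        dist = float(np.linalg.norm(vec))
        if dist < 1e-12:
            raise ValidationError(f"zero-length constrained pair vector ({a}, {b})")
        unit = vec / dist
        units[(a, b)] = unit
        distances[(a, b)] = dist
        pair_vectors.setdefault(a, []).append(unit)
        pair_vectors.setdefault(b, []).append(unit)
    modified = natural_gradient.copy()
    for index, directions in pair_vectors.items():
        modified[index] = _orthogonalize_sequential(modified[index], directions)
    for a, b in form_pairs:
        weight = radii.radii_sum(elements[a], elements[b]) / distances[(a, b)]
        force = settings.alpha_nt2 * weight * units[(a, b)]
        # step = -alpha_sd * g: pull a toward b and b toward a
        modified[a] -= force
        modified[b] += force
    for a, b in break_pairs:
        force = settings.alpha_nt2 * units[(a, b)]
        modified[a] += force
        modified[b] -= force
    return modified


# ---------------------------------------------------------------------------
# scan driver


def _constrained_atoms(coordinate: TrialCoordinate) -> list[int]:
    if coordinate.mode == "NT1":
        return sorted(set(coordinate.sites_lhs) | set(coordinate.sites_rhs))
    atoms: set[int] = set()
    for a, b in list(coordinate.form_pairs) + list(coordinate.break_pairs):
        atoms.update((a, b))
    return sorted(atoms)


def _microcycle_relax(
    structure: Structure,
    calculator: Calculator,
    frozen: Sequence[int],
    settings: MicrocycleSettings,
) -> None:
    """Constrained BFGS relaxation of all unconstrained atoms, in place."""
    free = [i for i in range(structure.n_atoms) if i not in set(frozen)]
    if not free:
        return
    base = structure.positions.copy()
    probe = structure.copy()

    def objective(x: np.ndarray):
        probe.positions = base.copy()
        probe.positions[free] = x.reshape(-1, 3)
        result = calculator.compute(probe, {"energy", "gradient"})
        return result.energy, result.gradient[free].ravel()

    solution = minimize(
        objective,
        base[free].ravel(),
        jac=True,
        method="BFGS",
        options={"gtol": settings.gradient_threshold, "maxiter": settings.max_steps},
    )
    structure.positions = base
    structure.positions[free] = solution.x.reshape(-1, 3)


def _nt1_collided(
    structure: Structure,
    coordinate: TrialCoordinate,
    radii: CovalentRadiiTable,
    settings: NTSettings,
) -> bool:
    """Any constrained left/right interatomic distance below the collision cut."""
    for i in coordinate.sites_lhs:
        for j in coordinate.sites_rhs:
            cut = settings.collision_factor * radii.radii_sum(
                structure.elements[i], structure.elements[j]
            )
            if np.linalg.norm(structure.positions[i] - structure.positions[j]) < cut:
                return True
    return False


def _nt2_converted(
    structure: Structure,
    bond_orders: np.ndarray,
    coordinate: TrialCoordinate,
    radii: CovalentRadiiTable,
    settings: NTSettings,
) -> bool:
    """All formations formed (or collided) and all cleavages broken."""
    for a, b in coordinate.form_pairs:
        distance = np.linalg.norm(structure.positions[a] - structure.positions[b])
        collided = distance < settings.nt2_collision_factor * radii.radii_sum(
            structure.elements[a], structure.elements[b]
        )
        if bond_orders[a, b] < settings.bo_formed and not collided:
            return False
    for a, b in coordinate.break_pairs:
        if bond_orders[a, b] > settings.bo_broken:
            return False
    return True


def run_nt_scan(
    complex_structure: Structure,
    coordinate: TrialCoordinate,
    calculator: Calculator,
    settings: Optional[NTSettings] = None,
    radii: Optional[CovalentRadiiTable] = None,
) -> Trajectory:
    """Run one scan: alternate modified steepest-descent macro steps with
    optional constrained micro-cycle relaxations until a stop criterion hits.

    Stop criteria: (i) the macro gradient-call budget is exhausted, (ii) the
    constrained coordinate collided (NT1) or all declared bond modifications
    completed (NT2), (iii) a single-point evaluation failed.  The returned
    trajectory holds one frame per macro gradient evaluation.
    """
    settings = settings or NTSettings()
    if radii is None:
        from .elements import DEFAULT_RADII

        radii = DEFAULT_RADII
    need = {"energy", "gradient"}
    if coordinate.mode == "NT2":
        need.add("bond_orders")
    current = complex_structure.copy(label="complex")
    frozen = _constrained_atoms(coordinate)
    frames: list[Frame] = []
    stop_reason = "max_calls"
    calls = 0
    while calls < settings.max_gradient_calls:
        try:
            result = calculator.compute(current, need)
        except CalculationFailure:
            stop_reason = "calc_failure"
            break
        calls += 1
        frames.append(Frame(current.positions.copy(), result.energy, calls))
        if coordinate.mode == "NT1":
            converted = _nt1_collided(current, coordinate, radii, settings)
        else:
            converted = _nt2_converted(
                current, result.bond_orders, coordinate, radii, settings
            )
        if converted:
            stop_reason = "collision_or_converted"
            break
        if coordinate.mode == "NT1":
            modified = nt1_modified_gradient(
                current.positions,
                result.gradient,
                coordinate.sites_lhs,
                coordinate.sites_rhs,
                settings,
            )
        else:
            modified = nt2_modified_gradient(
                current.positions,
                result.gradient,
                coordinate.form_pairs,
                coordinate.break_pairs,
                radii,
                current.elements,
                settings,
            )
        current.positions = current.positions - settings.alpha_sd * modified
        if settings.microcycle.enabled:
            try:
                _microcycle_relax(current, calculator, frozen, settings.microcycle)
            except CalculationFailure:
                stop_reason = "calc_failure"
                break
    return Trajectory(
        frames=frames,
        stop_reason=stop_reason,
        structure_template=complex_structure.copy(),
    )
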