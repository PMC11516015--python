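"""Reactive-complex construction and trial-coordinate enumeration.

A *trial reactive coordinate* declares which atom pairs a scan should force
to bond (formations) or to cleave (dissociations), or — for the
fragment-based first scan algorithm — which two atom sets are pushed onto
one another.  Enumeration is purely combinatorial over the molecular graph:
formation pairs are drawn from currently non-bonded atom pairs, dissociation
pairs from existing bonds, within the configured limits.  The order is
deterministic (lexicographic over sorted index pairs) so that exploration
runs are reproducible without seeds.

Reactive complexes place two reactants rigidly along their chosen attack
directions; intramolecular trials use the starting structure unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .data_model import Structure, ValidationError
from .elements import DEFAULT_RADII, CovalentRadiiTable
from .molgraph import MolecularGraph


@dataclass(frozen=True)
class TrialCoordinate:
    """The declared bond modifications (NT2) or fragments (NT1) of a trial."""

    form_pairs: frozenset = frozenset()
    break_pairs: frozenset = frozenset()
    sites_lhs: tuple = ()
    sites_rhs: tuple = ()
    mode: str = "NT2"
    molecularity: int = 1

    def __post_init__(self) -> None:
        if self.mode not in {"NT1", "NT2"}:
            raise ValidationError(f"unknown scan mode: {self.mode}")
        if self.mode == "NT1" and set(self.sites_lhs) & set(self.sites_rhs):
            raise ValidationError("NT1 reactive sites must be disjoint")
        if self.molecularity not in (1, 2):
            raise ValidationError("molecularity must be 1 or 2")

    @property
    def n_modifications(self) -> int:
        return len(self.form_pairs) + len(self.break_pairs)

    def sort_key(self) -> tuple:
        return (sorted(self.form_pairs), sorted(self.break_pairs))


@dataclass(frozen=True)
class ReactiveSite:
    atom_index: int
    attack_directions: tuple  # tuple of unit 3-vectors (as tuples)


@dataclass
class ExplorationOptions:
    """Key settings controlling how many elementary-step trials are set up.

    Defaults follow the standard minimal protocol: up to two intermolecular
    bond formations for bimolecular trials; up to two formations, one
    dissociation and three total bond modifications for unimolecular trials;
    one attack direction, no extra rotamers, no conformer ensembles, and
    intermolecular self-reactions disabled.
    """

    max_intermol_formations: int = 2
    max_intramol_formations: int = 2
    max_intramol_dissociations: int = 1
    max_bond_modifications: int = 3
    n_attack_directions: int = 1
    n_rotamers: int = 1
    multiple_conformers: bool = False
    allow_self_reactions: bool = False
    complex_offset: float = 1.0  # Å added to the covalent-radii sum on placement
    clash_threshold: float = 0.4  # Å; reject complexes with closer contacts

    def __post_init__(self) -> None:
        for name in (
            "max_intermol_formations",
            "max_intramol_formations",
            "max_intramol_dissociations",
            "max_bond_modifications",
            "n_attack_directions",
            "n_rotamers",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")


# ---------------------------------------------------------------------------
# reactive sites


def reactive_sites(
    structure: Structure,
    graph: MolecularGraph,
    n_directions: int = 1,
    buried_tolerance: float = 0.1,
    cone_half_angle: float = math.pi / 6,
    rng: Optional[np.random.Generator] = None,
) -> list[ReactiveSite]:
    """Attack directions per atom from steric considerations.

    The primary direction is the negated, normalized sum of unit vectors to
    bonded neighbours (the least hindered exit direction).  Isolated atoms
    get an arbitrary axis; atoms whose neighbour-vector sum nearly cancels
    are either *buried* (excluded, e.g. a tetrahedral centre) or — when the
    cancellation stems from a symmetric linear environment — assigned a
    perpendicular direction.  Additional directions are sampled on a cone
    around the primary one.
    """
    if graph.n_atoms != structure.n_atoms:
        raise ValidationError("graph does not match structure")
    sites: list[ReactiveSite] = []
    for index in range(structure.n_atoms):
        neighbors = graph.neighbors(index)
        if not neighbors:
            primary = np.array([1.0, 0.0, 0.0])
        else:
            units = []
            for j in neighbors:
                vec = structure.positions[j] - structure.positions[index]
                norm = np.linalg.norm(vec)
                if norm < 1e-10:
                    raise ValidationError(f"coincident bonded atoms {index}, {j}")
                units.append(vec / norm)
            total = -np.sum(units, axis=0)
            norm = np.linalg.norm(total)
            if norm < buried_tolerance:
                if len(neighbors) >= 3:
                    # surrounded on all sides: buried, not a reactive site
                    continue
                # linear symmetric environment: any perpendicular works
                primary = _any_perpendicular(units[0])
            else:
                primary = total / norm
        directions = [primary]
        if n_directions > 1:
            directions.extend(
                _cone_directions(primary, n_directions - 1, cone_half_angle, rng)
            )
        sites.append(
            ReactiveSite(index, tuple(tuple(d) for d in directions))
        )
    return sites


def _any_perpendicular(vec: np.ndarray) -> np.ndarray:
    trial = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(trial, vec)) > 0.9:
        trial = np.array([0.0, 1.0, 0.0])
    perp = trial - np.dot(trial, vec) * vec
    return perp / np.linalg.norm(perp)


def _cone_directions(
    primary: np.ndarray,
    count: int,
    half_angle: float,
    rng: Optional[np.random.Generator],
) -> list[np.ndarray]:
    """Evenly spaced directions on a cone around the primary direction."""
    perp = _any_perpendicular(primary)
    phase = 0.0 if rng is None else float(rng.uniform(0.0, 2.0 * math.pi))
    out = []
    for k in range(count):
        angle = phase + 2.0 * math.pi * k / max(count, 1)
        rot_about_primary = Rotation.from_rotvec(angle * primary)
        tilted = math.cos(half_angle) * primary + math.sin(half_angle) * perp
        out.append(rot_about_primary.apply(tilted))
    return out


# ---------------------------------------------------------------------------
# enumeration


def _nonbonded_pairs(graph: MolecularGraph) -> list[tuple[int, int]]:
    bonded = graph.edges
    return [
        (i, j)
        for i in range(graph.n_atoms)
        for j in range(i + 1, graph.n_atoms)
        if (i, j) not in bonded
    ]


CoordinateFilter = Callable[[TrialCoordinate], bool]


def enumerate_trial_coordinates(
    graphs: Sequence[MolecularGraph],
    options: ExplorationOptions,
    coordinate_filter: Optional[CoordinateFilter] = None,
) -> list[TrialCoordinate]:
    """Enumerate all trial reactive coordinates for one or two molecules.

    Unimolecular (one graph): every combination of ``f`` formation pairs
    drawn from non-bonded atom pairs (f ≤ max intramolecular formations) and
    ``b`` dissociation pairs drawn from existing bonds (b ≤ max
    intramolecular dissociations) with 1 ≤ f+b ≤ max bond modifications.

    Bimolecular (two graphs): formation pairs across the two molecules only
    (second molecule's atoms re-indexed after the first), 1 ≤ f ≤ max
    intermolecular formations.

    Deterministic lexicographic order; an optional filter drops coordinates.
    """
    if len(graphs) not in (1, 2):
        raise ValidationError("enumeration takes one or two molecular graphs")
    out: list[TrialCoordinate] = []
    if len(graphs) == 1:
        graph = graphs[0]
        if graph.n_atoms == 0:
            return []
        nonbonded = sorted(_nonbonded_pairs(graph))
        bonds = sorted(graph.edges)
        for n_form in range(options.max_intramol_formations + 1):
            for n_break in range(options.max_intramol_dissociations + 1):
                total = n_form + n_break
                if total < 1 or total > options.max_bond_modifications:
                    continue
                for form in combinations(nonbonded, n_form):
                    for broken in combinations(bonds, n_break):
                        out.append(
                            TrialCoordinate(
                                form_pairs=frozenset(form),
                                break_pairs=frozenset(broken),
                                mode="NT2",
                                molecularity=1,
                            )
                        )
    else:
        g1, g2 = graphs
        if g1.n_atoms == 0 or g2.n_atoms == 0:
            return []
        cross = [
            (i, g1.n_atoms + j) for i in range(g1.n_atoms) for j in range(g2.n_atoms)
        ]
        for n_form in range(1, options.max_intermol_formations + 1):
            for form in combinations(cross, n_form):
                out.append(
                    TrialCoordinate(
                        form_pairs=frozenset(form),
                        mode="NT2",
                        molecularity=2,
                    )
                )
    out.sort(key=TrialCoordinate.sort_key)
    if coordinate_filter is not None:
        out = [coord for coord in out if coordinate_filter(coord)]
    return out


def count_by_class(
    coordinates: Iterable[TrialCoordinate],
) -> dict[tuple[int, int], int]:
    """Count coordinates per (formations, dissociations) class."""
    counts: dict[tuple[int, int], int] = {}
    for coord in coordinates:
        key = (len(coord.form_pairs), len(coord.break_pairs))
        counts[key] = counts.get(key, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# complex building


class ClashError(RuntimeError):
    """Fragment placement produced overlapping atoms."""


def build_reactive_complex(
    s1: Structure,
    s2: Optional[Structure],
    coordinate: TrialCoordinate,
    options: ExplorationOptions,
    radii: CovalentRadiiTable = DEFAULT_RADII,
    attack_direction_1: Optional[np.ndarray] = None,
    attack_direction_2: Optional[np.ndarray] = None,
    rng_seed: Optional[int] = None,
) -> list[Structure]:
    """Build starting structures for a scan from one or two reactants.

    Unimolecular trials return the input coordinates unchanged (one
    complex).  Bimolecular trials rigidly rotate the second fragment so the
    two attack directions are antiparallel and place it so the first
    reactive pair sits at (covalent-radii sum + configured offset); one
    complex per requested rotamer, rotated about the reactive axis.
    Fragments whose placement produces interatomic contacts below the clash
    threshold are rejected.
    """
    del rng_seed  # randomized cone sampling is seeded in reactive_sites
    if coordinate.molecularity == 1:
        if s2 is not None:
            raise ValidationError("unimolecular coordinate with two structures")
        complex_structure = s1.copy(label="complex")
        return [complex_structure]
    if s2 is None:
        raise ValidationError("bimolecular coordinate needs two structures")
    if not coordinate.form_pairs:
        raise ValidationError("bimolecular trial needs at least one formation pair")
    a, b_global = sorted(coordinate.form_pairs)[0]
    b = b_global - s1.n_atoms
    if not (0 <= a < s1.n_atoms and 0 <= b < s2.n_atoms):
        raise ValidationError("first formation pair does not span the two fragments")
    d1 = (
        np.asarray(attack_direction_1, dtype=float)
        if attack_direction_1 is not None
        else np.array([1.0, 0.0, 0.0])
    )
    d2 = (
        np.asarray(attack_direction_2, dtype=float)
        if attack_direction_2 is not None
        else np.array([1.0, 0.0, 0.0])
    )
    d1 /= np.linalg.norm(d1)
    d2 /= np.linalg.norm(d2)
    # rotate fragment 2 so its attack direction opposes fragment 1's
    rotation, _ = Rotation.align_vectors([-d1], [d2])
    pos2 = rotation.apply(s2.positions - s2.positions[b])
    distance = radii.radii_sum(s1.elements[a], s2.elements[b]) + options.complex_offset
    anchor = s1.positions[a] + d1 * distance
    complexes: list[Structure] = []
    n_rot = max(options.n_rotamers, 1)
    for k in range(n_rot):
        angle = 2.0 * math.pi * k / n_rot
        spin = Rotation.from_rotvec(angle * d1)
        placed = spin.apply(pos2) + anchor
        merged = Structure(
            elements=list(s1.elements) + list(s2.elements),
            positions=np.vstack([s1.positions, placed]),
            charge=s1.charge + s2.charge,
            multiplicity=_combined_multiplicity(s1, s2, radii),
            label="complex",
            model_tag=s1.model_tag,
        )
        _check_clashes(merged, s1.n_atoms, options.clash_threshold)
        complexes.append(merged)
    return complexes


def _combined_multiplicity(
    s1: Structure, s2: Structure, radii: CovalentRadiiTable
) -> int:
    """Minimal total spin consistent with the combined electron parity."""
    n1 = s1.electron_count(radii)
    n2 = s2.electron_count(radii)
    if n1 is None or n2 is None:
        return 1
    return 1 if (n1 + n2) % 2 == 0 else 2


def _check_clashes(structure: Structure, n_first: int, threshold: float) -> None:
    pos1 = structure.positions[:n_first]
    pos2 = structure.positions[n_first:]
    diffs = pos1[:, None, :] - pos2[None, :, :]
    distances = np.linalg.norm(diffs, axis=-1)
    if distances.min() < threshold:
        raise ClashError(
            f"fragment placement clash: min distance {distances.min():.3f} Å"
        )


# ---------------------------------------------------------------------------
# filters


@dataclass
class Filter:
    """Composable predicate over trial coordinates and their reactants.

    ``accept(coordinate, structures)`` returns whether the trial should be
    run.  The default filter accepts everything; filters combine through the
    logical operators ``and`` / ``or`` with short-circuit evaluation.
    """

    predicate: Callable[[TrialCoordinate, Sequence[Structure]], bool] = field(
        default=lambda coordinate, structures: True
    )
    name: str = "accept_all"

    def accept(self, coordinate: TrialCoordinate, structures: Sequence[Structure]) -> bool:
        return bool(self.predicate(coordinate, structures))


def compose_filters(filters: Sequence[Filter], operator: str) -> Filter:
    """Combine filters with a short-circuit logical operator."""
    if operator not in {"and", "or"}:
        raise ValidationError(f"unknown filter operator: {operator!r}")
    filters = list(filters)
    if not filters:
        return Filter()

    if operator == "and":
        def predicate(coordinate, structures):
            return all(f.accept(coordinate, structures) for f in filters)
    else:
        def predicate(coordinate, structures):
            return any(f.accept(coordinate, structures) for f in filters)

    name = f" {operator} ".join(f.name for f in filters)
    return Filter(predicate=predicate, name=f"({name})")


def max_molecular_weight_filter(
    limit: float, radii: CovalentRadiiTable = DEFAULT_RADII
) -> Filter:
    """Reject trials whose combined reactant mass exceeds the limit (u)."""

    def predicate(coordinate, structures):
        del coordinate
        total = sum(
            radii.record(symbol).mass for s in structures for symbol in s.elements
        )
        return total <= limit

    return Filter(predicate=predicate, name=f"max_weight<={limit}")


def element_pair_filter(forbidden: set[frozenset]) -> Filter:
    """Reject coordinates that would form a bond between forbidden element pairs."""

    def predicate(coordinate, structures):
        elements: list[str] = []
        for s in structures:
            elements.extend(s.elements)
        for i, j in coordinate.form_pairs:
            if frozenset((elements[i], elements[j])) in forbidden:
                return False
        return True

    return Filter(predicate=predicate, name="element_pair")
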