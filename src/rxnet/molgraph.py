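"""Connectivity perception, canonical graph keys, component splitting.

Structures are deduplicated throughout the network via a serialized,
permutation-invariant string representation of their molecular graph plus
charge and multiplicity.  Canonicalization uses iterative neighbourhood
colour refinement (1-WL) seeded by element labels, with individualization
branching on ties and a lexicographically minimal certificate — sound on the
small molecular graphs this package handles (exponential only on highly
regular pathological graphs).  Stereochemistry is deliberately out of scope:
the toy potentials cannot resolve it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from .data_model import Structure, ValidationError
from .elements import DEFAULT_RADII, CovalentRadiiTable

#: bond-order threshold for perceiving an edge (distinct from the 0.75/0.15
#: formation/cleavage stop thresholds of the scan algorithms)
DEFAULT_EDGE_THRESHOLD = 0.5


@dataclass
class MolecularGraph:
    """Simple undirected bonded graph with element-labelled nodes."""

    elements: list[str]
    edges: set[tuple[int, int]]
    charge: int = 0
    multiplicity: int = 1

    def __post_init__(self) -> None:
        normalized = set()
        n = len(self.elements)
        for i, j in self.edges:
            if i == j:
                raise ValidationError("self-loops are not molecular bonds")
            if not (0 <= i < n and 0 <= j < n):
                raise ValidationError(f"edge ({i}, {j}) out of range for {n} atoms")
            normalized.add((min(i, j), max(i, j)))
        self.edges = normalized

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def to_networkx(self) -> nx.Graph:
        graph = nx.Graph()
        for index, symbol in enumerate(self.elements):
            graph.add_node(index, element=symbol)
        graph.add_edges_from(self.edges)
        return graph

    def neighbors(self, index: int) -> list[int]:
        out = [j for i, j in self.edges if i == index]
        out += [i for i, j in self.edges if j == index]
        return sorted(out)

    def edge_list_dump(self) -> str:
        """Human-readable edge list, one bond per line."""
        lines = [f"{i}({self.elements[i]})-{j}({self.elements[j]})" for i, j in sorted(self.edges)]
        return "\n".join(lines)


def perceive_graph(
    structure: Structure,
    bond_orders: np.ndarray,
    threshold: float = DEFAULT_EDGE_THRESHOLD,
) -> MolecularGraph:
    """Perceive connectivity: edge iff bond order >= threshold."""
    bond_orders = np.asarray(bond_orders)
    n = structure.n_atoms
    if bond_orders.shape != (n, n):
        raise ValidationError(
            f"bond-order matrix shape {bond_orders.shape} does not match {n} atoms"
        )
    edges = {
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if bond_orders[i, j] >= threshold
    }
    return MolecularGraph(
        elements=list(structure.elements),
        edges=edges,
        charge=structure.charge,
        multiplicity=structure.multiplicity,
    )


# ---------------------------------------------------------------------------
# canonicalization


def _refine(colors: list[int], adjacency: list[list[int]]) -> list[int]:
    """Iterative neighbourhood colour refinement to a fixpoint."""
    n = len(colors)
    while True:
        signatures = [
            (colors[i], tuple(sorted(colors[j] for j in adjacency[i]))) for i in range(n)
        ]
        palette = {sig: rank for rank, sig in enumerate(sorted(set(signatures)))}
        new_colors = [palette[sig] for sig in signatures]
        if new_colors == colors:
            return colors
        colors = new_colors


def _serialize(order: Sequence[int], graph: MolecularGraph) -> str:
    position = {node: rank for rank, node in enumerate(order)}
    elements = ",".join(graph.elements[node] for node in order)
    edges = sorted(
        (min(position[i], position[j]), max(position[i], position[j]))
        for i, j in graph.edges
    )
    edge_str = ";".join(f"{i}-{j}" for i, j in edges)
    return f"{elements}|{edge_str}|c{graph.charge}|m{graph.multiplicity}"


def _canonical_serialization(
    colors: list[int], adjacency: list[list[int]], graph: MolecularGraph
) -> str:
    colors = _refine(list(colors), adjacency)
    n = len(colors)
    classes: dict[int, list[int]] = {}
    for node, color in enumerate(colors):
        classes.setdefault(color, []).append(node)
    ambiguous = [c for c, members in classes.items() if len(members) > 1]
    if not ambiguous:
        order = sorted(range(n), key=lambda node: colors[node])
        return _serialize(order, graph)
    # branch on the smallest ambiguous colour class: individualize each
    # member in turn and keep the lexicographically minimal certificate
    target = min(ambiguous)
    best: Optional[str] = None
    fresh = max(colors) + 1
    for node in classes[target]:
        branched = list(colors)
        branched[node] = fresh
        candidate = _canonical_serialization(branched, adjacency, graph)
        if best is None or candidate < best:
            best = candidate
    return best  # type: ignore[return-value]


@dataclass(frozen=True)
class GraphKey:
    value: str

    def __str__(self) -> str:
        return self.value


def canonical_key(graph: MolecularGraph) -> GraphKey:
    """Permutation-invariant canonical string for a molecular graph.

    Identical for any atom permutation of the same graph; differs whenever
    element multiset, edge structure, charge, or multiplicity differ.
    """
    n = graph.n_atoms
    adjacency: list[list[int]] = [[] for _ in range(n)]
    for i, j in graph.edges:
        adjacency[i].append(j)
        adjacency[j].append(i)
    palette = {symbol: rank for rank, symbol in enumerate(sorted(set(graph.elements)))}
    seed = [palette[symbol] for symbol in graph.elements]
    return GraphKey(_canonical_serialization(seed, adjacency, graph))


# ---------------------------------------------------------------------------
# component splitting


def minimal_multiplicity(electron_count: int) -> int:
    """Minimal-spin rule: singlet for even electron count, doublet for odd."""
    return 1 if electron_count % 2 == 0 else 2


def split_components(
    structure: Structure,
    graph: MolecularGraph,
    partial_charges: np.ndarray,
    total_charge: Optional[int] = None,
    total_multiplicity: Optional[int] = None,
    radii: CovalentRadiiTable = DEFAULT_RADII,
    tolerance: float = 0.05,
) -> list[Structure]:
    """Split a structure into one structure per connected component.

    Component charges are the integer-rounded sums of atomic partial
    charges, adjusted by ±1 on the components with the largest rounding
    residual so the total charge is conserved exactly.  Multiplicities
    follow the minimal-spin rule from each component's electron parity.
    """
    del total_multiplicity  # minimal-spin rule decides component spins
    if total_charge is None:
        total_charge = structure.charge
    partial_charges = np.asarray(partial_charges, dtype=float)
    if partial_charges.shape != (structure.n_atoms,):
        raise ValidationError("one partial charge per atom required")
    if abs(partial_charges.sum() - total_charge) > tolerance:
        raise ValidationError(
            f"partial charges sum to {partial_charges.sum():.4f}, "
            f"expected total charge {total_charge}"
        )
    components = sorted(
        (sorted(c) for c in nx.connected_components(graph.to_networkx())),
        key=lambda members: members[0],
    )
    if len(components) == 1:
        return [structure.copy()]
    sums = np.array([partial_charges[members].sum() for members in components])
    charges = np.rint(sums).astype(int)
    deficit = int(total_charge - charges.sum())
    residuals = sums - charges
    # push ±1 onto the components whose rounding residual points the right way
    while deficit != 0:
        step = 1 if deficit > 0 else -1
        index = int(np.argmax(step * residuals))
        charges[index] += step
        residuals[index] -= step
        deficit -= step
    out: list[Structure] = []
    for members, charge in zip(components, charges):
        elements = [structure.elements[i] for i in members]
        electron_count = sum(radii.atomic_number(s) for s in elements) - int(charge)
        out.append(
            Structure(
                elements=elements,
                positions=structure.positions[members].copy(),
                charge=int(charge),
                multiplicity=minimal_multiplicity(electron_count),
                label="unoptimized",
                model_tag=structure.model_tag,
            )
        )
    return out
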