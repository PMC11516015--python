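"""Network data model and embedded document-store persistence.

The schema mirrors the standard reaction-network bookkeeping hierarchy:

* a **Structure** is a single point on a potential-energy surface (elements,
  Cartesian coordinates, charge, spin multiplicity);
* a **Compound** is the equivalence class of structures sharing the same
  molecular-graph key, charge and multiplicity;
* an **ElementaryStep** connects a reactant valley with a product valley
  through a single transition state;
* a **Reaction** is the equivalence class of elementary steps connecting the
  same (unordered pair of) compound multisets;
* **Properties** exist only in reference to a structure, and
  **CalculationRecords** track the jobs that produced data.

Persistence is a deliberately small embedded document store serialized to one
JSON file — desk-scale explorations do not need a database server.  Document
ids are content-independent unique tokens (``st-000001`` …), so re-adding
bit-identical content yields a fresh id; deduplication is the compound /
reaction gears' job, not the store's.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from typing import Any, Iterable, Optional

import numpy as np

from .elements import DEFAULT_RADII, CovalentRadiiTable

STRUCTURE_LABELS = {"user_guess", "minimum", "transition_state", "complex", "unoptimized"}


class ValidationError(ValueError):
    """A domain invariant was violated."""


@dataclass(frozen=True)
class Model:
    """High-level tag identifying how data was generated.

    Equality on these fields defines data comparability; job-level knobs
    (convergence thresholds etc.) live in ``CalculationRecord.settings``.
    """

    method_family: str = "toy"
    method: str = "morse"
    program: str = "rxnet"
    solvation: Optional[str] = None


@dataclass
class Structure:
    """One point on a potential energy surface."""

    elements: list[str]
    positions: np.ndarray  # (N, 3), Å
    charge: int = 0
    multiplicity: int = 1
    label: str = "user_guess"
    model_tag: Model = field(default_factory=Model)
    graph_key: Optional[str] = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValidationError("positions must have shape (N, 3)")
        if len(self.elements) != self.positions.shape[0]:
            raise ValidationError("element count does not match position count")
        if self.multiplicity < 1:
            raise ValidationError("multiplicity must be a positive integer (2S+1)")
        if self.label not in STRUCTURE_LABELS:
            raise ValidationError(f"unknown structure label: {self.label!r}")
        n_el = self.electron_count()
        if n_el is not None:
            if n_el < 0:
                raise ValidationError("negative electron count")
            # n_unpaired = multiplicity - 1 must share parity with the
            # electron count (you cannot have a singlet with an odd number
            # of electrons).
            if (n_el - (self.multiplicity - 1)) % 2 != 0:
                raise ValidationError(
                    f"multiplicity {self.multiplicity} inconsistent with "
                    f"{n_el} electrons"
                )

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def electron_count(self, radii: CovalentRadiiTable = DEFAULT_RADII) -> Optional[int]:
        """Σ atomic numbers − charge; ``None`` if any element is unknown."""
        total = 0
        for symbol in self.elements:
            if symbol not in radii:
                return None
            total += radii.atomic_number(symbol)
        return total - self.charge

    def copy(self, **updates: Any) -> "Structure":
        data = dict(
            elements=list(self.elements),
            positions=self.positions.copy(),
            charge=self.charge,
            multiplicity=self.multiplicity,
            label=self.label,
            model_tag=self.model_tag,
            graph_key=self.graph_key,
        )
        data.update(updates)
        return Structure(**data)

    def to_doc(self) -> dict[str, Any]:
        return {
            "elements": list(self.elements),
            "positions": self.positions.tolist(),
            "charge": self.charge,
            "multiplicity": self.multiplicity,
            "label": self.label,
            "model_tag": vars(self.model_tag).copy(),
            "graph_key": self.graph_key,
        }

    @classmethod
    def from_doc(cls, doc: dict[str, Any]) -> "Structure":
        return cls(
            elements=list(doc["elements"]),
            positions=np.asarray(doc["positions"], dtype=float),
            charge=int(doc["charge"]),
            multiplicity=int(doc["multiplicity"]),
            label=doc["label"],
            model_tag=Model(**doc["model_tag"]),
            graph_key=doc.get("graph_key"),
        )


_COLLECTIONS = (
    "structures",
    "compounds",
    "elementary_steps",
    "reactions",
    "properties",
    "calculations",
)

_ID_PREFIX = {
    "structures": "st",
    "compounds": "cp",
    "elementary_steps": "es",
    "reactions": "rx",
    "properties": "pr",
    "calculations": "ca",
}


class Database:
    """Single-file JSON document store for the exploration network."""

    def __init__(self) -> None:
        self._data: dict[str, dict[str, dict[str, Any]]] = {c: {} for c in _COLLECTIONS}
        self._counters: dict[str, int] = {c: 0 for c in _COLLECTIONS}

    # -- generic document interface ------------------------------------
    def insert(self, collection: str, doc: dict[str, Any]) -> str:
        if collection not in self._data:
            raise KeyError(f"unknown collection: {collection}")
        self._counters[collection] += 1
        doc_id = f"{_ID_PREFIX[collection]}-{self._counters[collection]:06d}"
        self._data[collection][doc_id] = doc
        return doc_id

    def get(self, collection: str, doc_id: str) -> dict[str, Any]:
        return self._data[collection][doc_id]

    def update(self, collection: str, doc_id: str, **fields: Any) -> None:
        self._data[collection][doc_id].update(fields)

    def all(self, collection: str) -> dict[str, dict[str, Any]]:
        return self._data[collection]

    def __len__(self) -> int:
        return sum(len(c) for c in self._data.values())

    # -- persistence ----------------------------------------------------
    def save(self, path: str) -> None:
        payload = {"collections": self._data, "counters": self._counters}
        with open(path, "w", encoding="utf-8") as handle:
            json.dump(payload, handle, indent=1, sort_keys=True)

    @classmethod
    def load(cls, path: str) -> "Database":
        with open(path, "r", encoding="utf-8") as handle:
            payload = json.load(handle)
        db = cls()
        db._data = {c: dict(payload["collections"].get(c, {})) for c in _COLLECTIONS}
        db._counters = {c: int(payload["counters"].get(c, 0)) for c in _COLLECTIONS}
        return db

    # -- structure helpers ----------------------------------------------
    def get_structure(self, structure_id: str) -> Structure:
        return Structure.from_doc(self.get("structures", structure_id))


# ---------------------------------------------------------------------------
# operations


def add_structure(structure: Structure, db: Database) -> str:
    """Persist a structure; each call yields a fresh unique id."""
    if not isinstance(structure, Structure):
        raise ValidationError("expected a Structure")
    return db.insert("structures", structure.to_doc())


def add_property(
    db: Database,
    name: str,
    value: Any,
    structure_id: str,
    model_tag: Model = Model(),
) -> str:
    if structure_id not in db.all("structures"):
        raise ValidationError(f"property requires an existing structure: {structure_id}")
    if isinstance(value, np.ndarray):
        value = value.tolist()
    return db.insert(
        "properties",
        {
            "name": name,
            "value": value,
            "structure_id": structure_id,
            "model_tag": vars(model_tag).copy(),
        },
    )


def add_calculation(
    db: Database,
    job_type: str,
    settings: Optional[dict[str, Any]] = None,
    input_structure_ids: Optional[list[str]] = None,
) -> str:
    return db.insert(
        "calculations",
        {
            "job_type": job_type,
            "settings": settings or {},
            "input_structure_ids": input_structure_ids or [],
            "status": "pending",
            "produced_ids": [],
            "empty_result": False,
        },
    )


def finish_calculation(
    db: Database, calc_id: str, produced_ids: Iterable[str], failed: bool = False
) -> None:
    produced = list(produced_ids)
    status = "failed" if failed else "done"
    db.update(
        "calculations",
        calc_id,
        status=status,
        produced_ids=produced,
        empty_result=(not produced and not failed),
    )


def aggregate_into_compound(structure_id: str, db: Database) -> str:
    """Attach a structure to the compound matching (graph_key, charge,
    multiplicity), creating the compound if none matches."""
    doc = db.get("structures", structure_id)
    key = doc.get("graph_key")
    if not key:
        raise ValidationError("structure has no graph_key; perceive its graph first")
    charge, multiplicity = doc["charge"], doc["multiplicity"]
    for compound_id, compound in db.all("compounds").items():
        if (
            compound["graph_key"] == key
            and compound["charge"] == charge
            and compound["multiplicity"] == multiplicity
        ):
            if structure_id not in compound["structure_ids"]:
                compound["structure_ids"].append(structure_id)
            return compound_id
    return db.insert(
        "compounds",
        {
            "structure_ids": [structure_id],
            "graph_key": key,
            "charge": charge,
            "multiplicity": multiplicity,
        },
    )


def _element_multiset(db: Database, structure_ids: Iterable[str]) -> Counter:
    counter: Counter = Counter()
    for sid in structure_ids:
        counter.update(db.get("structures", sid)["elements"])
    return counter


def _total_charge(db: Database, structure_ids: Iterable[str]) -> int:
    return sum(db.get("structures", sid)["charge"] for sid in structure_ids)


def add_elementary_step(
    db: Database,
    reactant_structure_ids: list[str],
    product_structure_ids: list[str],
    ts_id: str,
    barriers: Optional[dict[str, Any]] = None,
    path_spline: Optional[dict[str, Any]] = None,
) -> str:
    """Store a validated elementary step, enforcing conservation laws."""
    if _element_multiset(db, reactant_structure_ids) != _element_multiset(
        db, product_structure_ids
    ):
        raise ValidationError("element multiset not conserved across the step")
    if _total_charge(db, reactant_structure_ids) != _total_charge(
        db, product_structure_ids
    ):
        raise ValidationError("total charge not conserved across the step")
    return db.insert(
        "elementary_steps",
        {
            "reactant_structure_ids": list(reactant_structure_ids),
            "product_structure_ids": list(product_structure_ids),
            "ts_id": ts_id,
            "barriers": barriers or {},
            "path_spline": path_spline,
        },
    )


def _compound_of(db: Database, structure_id: str) -> Optional[str]:
    for compound_id, compound in db.all("compounds").items():
        if structure_id in compound["structure_ids"]:
            return compound_id
    return None


def aggregate_into_reaction(step_id: str, db: Database) -> str:
    """Attach a step to the reaction with the same unordered pair of compound
    multisets (direction-agnostic: A→B joins the reaction of B→A)."""
    step = db.get("elementary_steps", step_id)
    sides = []
    for side_key in ("reactant_structure_ids", "product_structure_ids"):
        compounds = []
        for sid in step[side_key]:
            compound_id = _compound_of(db, sid)
            if compound_id is None:
                raise ValidationError(
                    f"structure {sid} is not assigned to a compound yet"
                )
            compounds.append(compound_id)
        sides.append(sorted(compounds))
    pair = sorted([tuple(sides[0]), tuple(sides[1])])
    for reaction_id, reaction in db.all("reactions").items():
        existing = sorted(
            [tuple(reaction["reactant_compound_ids"]), tuple(reaction["product_compound_ids"])]
        )
        if existing == pair:
            if step_id not in reaction["step_ids"]:
                reaction["step_ids"].append(step_id)
            return reaction_id
    return db.insert(
        "reactions",
        {
            "step_ids": [step_id],
            "reactant_compound_ids": list(sides[0]),
            "product_compound_ids": list(sides[1]),
        },
    )


# ---------------------------------------------------------------------------
# export


def export_json(db: Database, path: str) -> None:
    """Dump the whole network as one JSON document."""
    db.save(path)


def export_graphml(db: Database, path: str) -> None:
    """Write the compound/reaction network as GraphML.

    Nodes are compounds (attributes: graph key, charge, multiplicity, member
    count); edges are reactions with the lowest member-step complexed forward
    barrier as an attribute.  Multi-compound sides are connected pairwise.
    """
    import networkx as nx

    graph = nx.Graph()
    for compound_id, compound in db.all("compounds").items():
        graph.add_node(
            compound_id,
            graph_key=compound["graph_key"],
            charge=compound["charge"],
            multiplicity=compound["multiplicity"],
            n_structures=len(compound["structure_ids"]),
        )
    for reaction_id, reaction in db.all("reactions").items():
        barriers = []
        for step_id in reaction["step_ids"]:
            step = db.get("elementary_steps", step_id)
            barrier = step.get("barriers", {}).get("barrier_complexed")
            if barrier is not None:
                barriers.append(barrier)
        lowest = min(barriers) if barriers else float("nan")
        for lhs in reaction["reactant_compound_ids"]:
            for rhs in reaction["product_compound_ids"]:
                graph.add_edge(lhs, rhs, reaction=reaction_id, lowest_barrier=lowest)
    nx.write_graphml(graph, path)
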