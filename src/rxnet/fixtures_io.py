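"""XYZ input/output and the built-in fixture registry.

XYZ is the sole structure exchange format: count line, comment line (with
``charge=<int> multiplicity=<int>`` for round-tripping), then one
``element x y z`` row per atom in Å.  Multi-frame files hold trajectories,
with per-frame energies in the comment line.

Fixtures provide deterministic toy molecules so every algorithm is testable
without downloads: diatomics, bent/linear triatomics, a peroxide, the full-H
bonded graph of 3-hydroperoxypropanal (for enumeration; no 3D geometry is
implied by the toy potentials), and the single pseudo-atom bound to the 2D
analytic surface.
"""

from __future__ import annotations

import math
import re
from typing import Union

import numpy as np

from .data_model import Structure, ValidationError
from .elements import DEFAULT_RADII
from .molgraph import MolecularGraph
from .nt_scan import Trajectory


class XYZParseError(ValueError):
    """Malformed XYZ content; the message names the offending line."""


_COMMENT_RE = re.compile(r"charge=(-?\d+)\s+multiplicity=(\d+)")


def _parse_frame(lines: list[str], start: int) -> tuple[Structure, int]:
    try:
        count = int(lines[start].strip())
    except (ValueError, IndexError):
        raise XYZParseError(f"line {start + 1}: expected an atom count") from None
    comment = lines[start + 1] if start + 1 < len(lines) else ""
    charge, multiplicity = 0, 1
    match = _COMMENT_RE.search(comment)
    if match:
        charge, multiplicity = int(match.group(1)), int(match.group(2))
    elements: list[str] = []
    rows: list[list[float]] = []
    for offset in range(count):
        line_no = start + 2 + offset
        if line_no >= len(lines) or not lines[line_no].strip():
            raise XYZParseError(
                f"line {line_no + 1}: count line says {count} atoms but the "
                f"frame ends after {offset} rows"
            )
        parts = lines[line_no].split()
        if len(parts) < 4:
            raise XYZParseError(f"line {line_no + 1}: need element + 3 coordinates")
        symbol = parts[0]
        if not symbol[0].isalpha():
            raise XYZParseError(f"line {line_no + 1}: unknown element {symbol!r}")
        try:
            rows.append([float(p) for p in parts[1:4]])
        except ValueError:
            raise XYZParseError(
                f"line {line_no + 1}: malformed coordinate triple"
            ) from None
        elements.append(symbol)
    structure = Structure(
        elements=elements,
        positions=np.array(rows),
        charge=charge,
        multiplicity=multiplicity,
    )
    return structure, start + 2 + count


def read_xyz(path: str) -> Union[Structure, list[Structure]]:
    """Read an XYZ file; multi-frame files return a list of structures."""
    with open(path, "r", encoding="utf-8") as handle:
        lines = handle.read().splitlines()
    frames: list[Structure] = []
    cursor = 0
    while cursor < len(lines):
        if not lines[cursor].strip():
            cursor += 1
            continue
        structure, cursor = _parse_frame(lines, cursor)
        frames.append(structure)
    if not frames:
        raise XYZParseError("line 1: empty XYZ file")
    return frames[0] if len(frames) == 1 else frames


def _format_frame(structure: Structure, comment: str) -> str:
    lines = [str(structure.n_atoms), comment]
    for symbol, (x, y, z) in zip(structure.elements, structure.positions):
        lines.append(f"{symbol} {x:.12g} {y:.12g} {z:.12g}")
    return "\n".join(lines)


def write_xyz(item: Union[Structure, Trajectory], path: str) -> None:
    """Write a structure, or a trajectory as a multi-frame XYZ with
    per-frame energy comment lines."""
    if isinstance(item, Structure):
        comment = f"charge={item.charge} multiplicity={item.multiplicity}"
        blocks = [_format_frame(item, comment)]
    elif isinstance(item, Trajectory):
        template = item.structure_template
        if template is None:
            raise ValidationError("trajectory lacks a structure template")
        blocks = []
        for index, frame in enumerate(item.frames):
            structure = template.copy(positions=frame.positions)
            comment = (
                f"charge={structure.charge} multiplicity={structure.multiplicity} "
                f"frame={index} energy={frame.energy:.12g}"
            )
            blocks.append(_format_frame(structure, comment))
    else:
        raise ValidationError(f"cannot write {type(item).__name__} as XYZ")
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("\n".join(blocks) + "\n")


# ---------------------------------------------------------------------------
# fixtures


def _bond(radii_sum_of: tuple[str, str]) -> float:
    return DEFAULT_RADII.radii_sum(*radii_sum_of)


def _h2() -> Structure:
    r = _bond(("H", "H"))
    return Structure(["H", "H"], [[0.0, 0.0, 0.0], [r, 0.0, 0.0]])


def _two_h_atoms() -> Structure:
    return Structure(["H", "H"], [[0.0, 0.0, 0.0], [3.0, 0.0, 0.0]])


def _h2o_like() -> Structure:
    r = _bond(("O", "H"))
    half = math.radians(104.5 / 2.0)
    return Structure(
        ["O", "H", "H"],
        [
            [0.0, 0.0, 0.0],
            [r * math.sin(half), r * math.cos(half), 0.0],
            [-r * math.sin(half), r * math.cos(half), 0.0],
        ],
    )


def _hcn_like() -> Structure:
    r_hc = _bond(("H", "C"))
    r_cn = _bond(("C", "N"))
    return Structure(
        ["H", "C", "N"],
        [[0.0, 0.0, 0.0], [r_hc, 0.0, 0.0], [r_hc + r_cn, 0.0, 0.0]],
    )


def _h2o2_like() -> Structure:
    r_oo = _bond(("O", "O"))
    r_oh = _bond(("O", "H"))
    angle = math.radians(100.0)
    dihedral = math.radians(115.0)
    o1 = np.array([0.0, 0.0, 0.0])
    o2 = np.array([r_oo, 0.0, 0.0])
    h1 = o1 + r_oh * np.array([math.cos(angle), math.sin(angle), 0.0])
    h2 = o2 + r_oh * np.array(
        [
            -math.cos(angle),
            math.sin(angle) * math.cos(dihedral),
            math.sin(angle) * math.sin(dihedral),
        ]
    )
    return Structure(["O", "O", "H", "H"], np.array([o1, o2, h1, h2]))


def _mueller_brown_particle() -> Structure:
    # near the deepest basin of the 2D analytic surface; z frozen at 0
    return Structure(["X"], [[-0.55, 1.44, 0.0]])


def hydroperoxypropanal_graph() -> MolecularGraph:
    """Full-hydrogen bonded graph of 3-hydroperoxypropanal, HOO–CH2–CH2–CHO.

    Atom order: C0 (aldehyde C), C1, C2, O3 (carbonyl), O4, O5 (peroxide),
    H6 (aldehyde H), H7–H10 (methylene H), H11 (hydroxyl H).  12 atoms,
    11 bonds (the C=O double bond is a single graph edge).
    """
    elements = ["C", "C", "C", "O", "O", "O", "H", "H", "H", "H", "H", "H"]
    edges = {
        (0, 1),  # C0-C1
        (1, 2),  # C1-C2
        (2, 4),  # C2-O4
        (4, 5),  # O4-O5 peroxide
        (0, 3),  # C0=O3 carbonyl
        (0, 6),  # aldehyde H
        (1, 7),
        (1, 8),
        (2, 9),
        (2, 10),
        (5, 11),  # O5-H hydroxyl
    }
    return MolecularGraph(elements=elements, edges=edges)


_STRUCTURE_FIXTURES = {
    "h2": _h2,
    "two_h_atoms": _two_h_atoms,
    "h2o_like": _h2o_like,
    "hcn_like": _hcn_like,
    "h2o2_like": _h2o2_like,
    "mueller_brown_particle": _mueller_brown_particle,
}


def make_fixture(name: str) -> Union[Structure, MolecularGraph]:
    """Deterministic built-in toy systems by name.

    ``hydroperoxypropanal_graph`` returns a bonded graph (the toy potentials
    imply no reliable 3D geometry for it); every other name returns a
    structure at its toy-potential bond lengths.
    """
    if name == "hydroperoxypropanal_graph":
        return hydroperoxypropanal_graph()
    try:
        return _STRUCTURE_FIXTURES[name]()
    except KeyError:
        known = sorted(_STRUCTURE_FIXTURES) + ["hydroperoxypropanal_graph"]
        raise ValidationError(f"unknown fixture {name!r}; known: {known}") from None
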