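"""Element data: covalent radii, electronegativities, atomic numbers.

The covalent radii are the single-bond radii commonly tabulated for the
main-group and first-row transition elements (Å).  The table is shipped as a
CSV asset so the numbers are auditable and replaceable: pass a custom
:class:`CovalentRadiiTable` wherever radii are consumed (pair potentials,
collision criteria, complex building) to override or extend it.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources


class UnknownElementError(KeyError):
    """Raised when an element symbol is not parameterized."""


@dataclass(frozen=True)
class ElementRecord:
    symbol: str
    atomic_number: int
    covalent_radius: float  # Å
    electronegativity: float  # Pauling scale; 0.0 for noble gases
    mass: float  # u


def _load_default_records() -> dict[str, ElementRecord]:
    records: dict[str, ElementRecord] = {}
    path = resources.files("rxnet.data").joinpath("covalent_radii.csv")
    with path.open("r", encoding="utf-8") as handle:
        for row in csv.DictReader(handle):
            rec = ElementRecord(
                symbol=row["symbol"],
                atomic_number=int(row["atomic_number"]),
                covalent_radius=float(row["covalent_radius"]),
                electronegativity=float(row["electronegativity"]),
                mass=float(row["mass"]),
            )
            records[rec.symbol] = rec
    return records


@dataclass
class CovalentRadiiTable:
    """Element symbol → covalent radius (Å), with auxiliary element data.

    ``overrides`` lets callers register additional (or replacement) entries,
    e.g. pseudo-atoms used by analytic test surfaces.
    """

    overrides: dict[str, ElementRecord] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._records = dict(_DEFAULT_RECORDS)
        for symbol, rec in self.overrides.items():
            if rec.covalent_radius <= 0:
                raise ValueError(f"covalent radius must be positive: {symbol}")
            self._records[symbol] = rec

    def record(self, symbol: str) -> ElementRecord:
        try:
            return self._records[symbol]
        except KeyError:
            raise UnknownElementError(symbol) from None

    def radius(self, symbol: str) -> float:
        return self.record(symbol).covalent_radius

    def radii_sum(self, symbol_a: str, symbol_b: str) -> float:
        return self.radius(symbol_a) + self.radius(symbol_b)

    def atomic_number(self, symbol: str) -> int:
        return self.record(symbol).atomic_number

    def electronegativity(self, symbol: str) -> float:
        return self.record(symbol).electronegativity

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._records

    def register(
        self,
        symbol: str,
        covalent_radius: float,
        atomic_number: int = 0,
        electronegativity: float = 0.0,
        mass: float = 0.0,
    ) -> None:
        """Register a custom element (e.g. a pseudo-atom) in this table."""
        if covalent_radius <= 0:
            raise ValueError("covalent radius must be positive")
        self._records[symbol] = ElementRecord(
            symbol, atomic_number, covalent_radius, electronegativity, mass
        )


_DEFAULT_RECORDS = _load_default_records()

#: Shared default table; treat as read-only, copy to customize.
DEFAULT_RADII = CovalentRadiiTable()


def atomic_number(symbol: str) -> int:
    return DEFAULT_RADII.atomic_number(symbol)
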