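"""Elemental masses, molecular formulas, ion m/z and double-bond equivalence.

This module is the numeric foundation of the package: a bundled table of
monoisotopic element masses (CODATA/AME values, isotope variants included),
a :class:`MolecularFormula` container with Hill-style parsing/formatting,
exact monoisotopic mass and single-charge ion m/z (electron mass applied),
signed ppm mass error, and the ring-plus-double-bond index

    DBE = N_C - N_H/2 - N_X/2 + N_N/2 + N_P/2 + 1

where N_C, N_H, N_X, N_N, N_P count carbon, hydrogen, halogen (F, Cl, Br,
I), nitrogen and phosphorus atoms. Isotope variants of C, Cl and Br count
toward their parent element's term, so e.g. ``[13C]`` contributes to N_C.
Computed directly on an [M±H] ion composition the index is half-integer;
``dbe(..., convention="neutral")`` reports the neutral-molecule value
instead (one H transferred according to polarity).

Formula string dialect
----------------------
Hill-style ``ElementCount`` tokens, count omitted when 1: ``C15H22N4O3Na``.
Isotope variants are written as a bracketed nucleon-number prefix token:
``[13C]2C14H20O3`` means two heavy carbons plus fourteen light ones.
Formatting emits Hill order (C, then H, then all other symbols
alphabetically; an isotope variant sorts directly after its parent).
"""

from __future__ import annotations

import csv
import re
from collections.abc import Iterator, Mapping
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

__all__ = [
    "ELECTRON_MASS",
    "ElementSpec",
    "ElementTable",
    "DEFAULT_ELEMENTS",
    "MolecularFormula",
    "IonSpecies",
    "parse_formula",
    "format_formula",
    "monoisotopic_mass",
    "ion_mz",
    "dbe",
    "ppm_error",
]

#: Electron rest mass in Da (CODATA 2018).
ELECTRON_MASS = 0.000548579909

_DBE_CLASSES = {
    "carbon",
    "hydrogen",
    "halogen",
    "nitrogen_group",
    "phosphorus_group",
    "neutral",
}

# DBE contribution per atom of each class; the +1 constant is added once.
_DBE_WEIGHT = {
    "carbon": 1.0,
    "hydrogen": -0.5,
    "halogen": -0.5,
    "nitrogen_group": 0.5,
    "phosphorus_group": 0.5,
    "neutral": 0.0,
}


@dataclass(frozen=True)
class ElementSpec:
    """A chemical element or isotope variant known to the mass table."""

    symbol: str
    monoisotopic_mass: float
    dbe_class: str

    def __post_init__(self) -> None:
        if self.monoisotopic_mass <= 0:
            raise ValueError(f"mass of {self.symbol!r} must be positive")
        if self.dbe_class not in _DBE_CLASSES:
            raise ValueError(
                f"unknown dbe_class {self.dbe_class!r} for {self.symbol!r}"
            )


class ElementTable(Mapping):
    """Immutable symbol -> :class:`ElementSpec` lookup.

    The default table covers the elements used in SIMS depth-profile
    searches (C, H, N, O, S, P, Na, Ca, Cl, Al, K, halogens) plus the
    heavy-isotope variants of C, Cl and Br. Extend via :meth:`from_csv`
    or :meth:`with_elements`.
    """

    def __init__(self, specs: list[ElementSpec]):
        self._specs: dict[str, ElementSpec] = {}
        for spec in specs:
            if spec.symbol in self._specs:
                raise ValueError(f"duplicate element symbol {spec.symbol!r}")
            self._specs[spec.symbol] = spec

    def __getitem__(self, symbol: str) -> ElementSpec:
        try:
            return self._specs[symbol]
        except KeyError:
            raise KeyError(f"unknown element symbol {symbol!r}") from None

    def __iter__(self) -> Iterator[str]:
        return iter(self._specs)

    def __len__(self) -> int:
        return len(self._specs)

    def mass(self, symbol: str) -> float:
        return self[symbol].monoisotopic_mass

    def with_elements(self, specs: list[ElementSpec]) -> "ElementTable":
        merged = {**self._specs, **{s.symbol: s for s in specs}}
        return ElementTable(list(merged.values()))

    @classmethod
    def from_csv(cls, path: str | Path) -> "ElementTable":
        """Load a table from CSV with columns symbol, monoisotopic_mass, dbe_class."""
        specs = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                specs.append(
                    ElementSpec(
                        symbol=row["symbol"].strip(),
                        monoisotopic_mass=float(row["monoisotopic_mass"]),
                        dbe_class=row["dbe_class"].strip(),
                    )
                )
        return cls(specs)


def _load_default_table() -> ElementTable:
    ref = resources.files("simsfilter.data") / "elements.csv"
    with resources.as_file(ref) as path:
        return ElementTable.from_csv(path)


DEFAULT_ELEMENTS = _load_default_table()

# "[13C]2" or "C15"; an isotope token is a bracketed nucleon-number prefix.
_TOKEN_RE = re.compile(r"(\[\d+[A-Z][a-z]?\]|[A-Z][a-z]?)(\d*)")


class MolecularFormula(Mapping):
    """An element -> count map for a neutral or ion composition.

    Counts are non-negative integers; zero-count entries are dropped, so
    two formulas compare equal iff their maps are equal. Supports ``+``
    and ``-`` (the latter rejects negative results), integer ``*``, and
    hashing, so formulas can key dictionaries and sets.
    """

    __slots__ = ("_counts", "_hash")

    def __init__(self, counts: Mapping[str, int] | None = None):
        clean: dict[str, int] = {}
        for sym, n in (counts or {}).items():
            n = int(n)
            if n < 0:
                raise ValueError(f"negative count for {sym!r}")
            if n > 0:
                clean[sym] = n
        self._counts = clean
        self._hash = hash(frozenset(clean.items()))

    # -- Mapping protocol -------------------------------------------------
    def __getitem__(self, symbol: str) -> int:
        return self._counts[symbol]

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def get(self, symbol: str, default: int = 0) -> int:
        return self._counts.get(symbol, default)

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        counts = dict(self._counts)
        for sym, n in other.items():
            counts[sym] = counts.get(sym, 0) + n
        return MolecularFormula(counts)

    def __sub__(self, other: "MolecularFormula") -> "MolecularFormula":
        counts = dict(self._counts)
        for sym, n in other.items():
            counts[sym] = counts.get(sym, 0) - n
        return MolecularFormula(counts)  # raises on negative counts

    def __mul__(self, k: int) -> "MolecularFormula":
        return MolecularFormula({s: n * k for s, n in self._counts.items()})

    __rmul__ = __mul__

    def __eq__(self, other: object) -> bool:
        if isinstance(other, MolecularFormula):
            return self._counts == other._counts
        return NotImplemented

    def __hash__(self) -> int:
        return self._hash

    def __repr__(self) -> str:
        return f"MolecularFormula({format_formula(self)!r})"

    @classmethod
    def parse(cls, text: str) -> "MolecularFormula":
        return parse_formula(text)

    def __str__(self) -> str:
        return format_formula(self)


@dataclass(frozen=True)
class IonSpecies:
    """A detected single-charge ion: its full composition (adduct atoms
    included) plus signed charge."""

    composition: MolecularFormula
    charge: int

    def __post_init__(self) -> None:
        if self.charge not in (-1, 1):
            raise ValueError("only singly charged ions are supported")

    @property
    def polarity(self) -> str:
        return "positive" if self.charge > 0 else "negative"


def parse_formula(text: str) -> MolecularFormula:
    """Parse a Hill-style formula string (dialect in the module docstring).

    Raises ``ValueError`` naming the character position of the first
    malformed token.
    """
    if not isinstance(text, str):
        raise TypeError("formula must be a string")
    counts: dict[str, int] = {}
    pos = 0
    stripped = text.strip()
    while pos < len(stripped):
        m = _TOKEN_RE.match(stripped, pos)
        if m is None:
            raise ValueError(
                f"malformed formula {text!r}: unexpected character at position {pos}"
            )
        sym, digits = m.group(1), m.group(2)
        counts[sym] = counts.get(sym, 0) + (int(digits) if digits else 1)
        pos = m.end()
    return MolecularFormula(counts)


def _parent_symbol(symbol: str) -> str:
    """'[13C]' -> 'C'; plain symbols pass through."""
    if symbol.startswith("["):
        return re.sub(r"[\[\]\d]", "", symbol)
    return symbol


def _hill_key(symbol: str) -> tuple:
    parent = _parent_symbol(symbol)
    group = 0 if parent == "C" else 1 if parent == "H" else 2
    # isotope variants sort directly after the parent element
    return (group, parent, symbol.startswith("["), symbol)


def format_formula(formula: MolecularFormula) -> str:
    """Format in Hill order; ``parse_formula(format_formula(f)) == f``."""
    parts = []
    for sym in sorted(formula, key=_hill_key):
        n = formula[sym]
        parts.append(sym if n == 1 else f"{sym}{n}")
    return "".join(parts)


def monoisotopic_mass(
    formula: MolecularFormula, table: ElementTable = DEFAULT_ELEMENTS
) -> float:
    """Exact mass in Da: sum of count x monoisotopic element mass."""
    return sum(n * table[sym].monoisotopic_mass for sym, n in formula.items())


def ion_mz(
    ion: IonSpecies | MolecularFormula,
    charge: int | None = None,
    table: ElementTable = DEFAULT_ELEMENTS,
) -> float:
    """m/z of a singly charged ion, electron mass included.

    A cation is one electron light (m/z = M - m_e); an anion is one
    electron heavy (m/z = M + m_e). At m/z below ~600 the electron mass
    is a >1 ppm effect and cannot be neglected against the sub-ppm
    accuracy of Orbitrap-based SIMS.
    """
    if isinstance(ion, IonSpecies):
        composition, z = ion.composition, ion.charge
    else:
        if charge is None:
            raise ValueError("charge required when passing a bare formula")
        composition, z = ion, int(charge)
    if z == 0:
        raise ValueError("charge must be ±1; use monoisotopic_mass for neutrals")
    if z not in (-1, 1):
        raise ValueError("only singly charged ions are supported")
    return monoisotopic_mass(composition, table) - z * ELECTRON_MASS


def dbe(
    formula: MolecularFormula,
    table: ElementTable = DEFAULT_ELEMENTS,
    convention: str = "ion",
    polarity: str | None = None,
) -> float:
    """Double-bond equivalence (rings plus double bonds) of a composition.

    With ``convention="ion"`` (default) the formula is taken as-is, so
    [M±H] ion compositions give half-integer values — e.g. deprotonated
    palmitate C16H31O2 gives 1.5. With ``convention="neutral"`` the value
    for the neutral parent is reported instead, assuming one proton was
    transferred according to ``polarity``: +0.5 for a protonated positive
    ion, -0.5 for a deprotonated negative ion.
    """
    if len(formula) == 0:
        raise ValueError("DBE of the empty formula is undefined")
    value = 1.0
    for sym, n in formula.items():
        value += n * _DBE_WEIGHT[table[sym].dbe_class]
    if convention == "ion":
        return value
    if convention == "neutral":
        if polarity not in ("positive", "negative"):
            raise ValueError("neutral convention requires polarity")
        return value + (0.5 if polarity == "positive" else -0.5)
    raise ValueError(f"unknown DBE convention {convention!r}")


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical mass must be positive")
    return (observed - theoretical) / theoretical * 1e6
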