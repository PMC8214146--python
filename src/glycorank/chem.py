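"""Elemental-formula arithmetic and monoisotopic masses.

Formulas are immutable element->count mappings supporting addition,
subtraction and integer scaling; the monoisotopic mass is the dot product
with an embedded IUPAC atomic-mass table, so all mass arithmetic is exact
and reproducible without network access.
"""
from __future__ import annotations

import re
from collections.abc import Iterator, Mapping

__all__ = [
    "ElementalFormula",
    "MONOISOTOPIC_MASS",
    "PROTON_MASS",
    "WATER",
    "SULFATE",
    "ACETYL",
]

# Monoisotopic masses of the most abundant isotope (Da), IUPAC/CODATA values.
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "S": 31.97207069,
    "P": 30.97376151,
    "Na": 22.98976928,
    "K": 38.96370649,
    "Ca": 39.96259086,
    "F": 18.99840316,
    "Cl": 34.96885268,
    "Br": 78.9183376,
    "I": 126.9044719,
    "Li": 7.0160034,
}

#: Mass of a proton (charge carrier for deprotonated ions), Da.
PROTON_MASS = 1.007276466879

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class ElementalFormula(Mapping):
    """An immutable, nonnegative elemental composition.

    Supports ``+``, ``-`` (raising on negative counts), ``*`` by a
    nonnegative integer, equality, hashing and string round-tripping via
    :meth:`parse` / ``str()``.
    """

    __slots__ = ("_counts", "_hash")

    def __init__(self, counts: Mapping[str, int] | None = None, **kwargs: int):
        merged: dict[str, int] = {}
        for source in (counts or {}), kwargs:
            for element, count in source.items():
                if element not in MONOISOTOPIC_MASS:
                    raise ValueError(f"unknown element symbol: {element!r}")
                if not isinstance(count, int) or count < 0:
                    raise ValueError(
                        f"element count must be a nonnegative integer, "
                        f"got {element}={count!r}"
                    )
                if count:
                    merged[element] = merged.get(element, 0) + count
        self._counts = merged
        self._hash: int | None = None

    @classmethod
    def parse(cls, text: str) -> "ElementalFormula":
        """Parse a concatenated ``Element[count]`` string, e.g. ``"C6H3NO2"``.

        An omitted count means 1; the empty string is the empty formula.
        """
        text = text.strip()
        counts: dict[str, int] = {}
        pos = 0
        while pos < len(text):
            m = _TOKEN.match(text, pos)
            if m is None or m.start() != pos or not m.group(1):
                raise ValueError(f"malformed formula token at {text[pos:]!r}")
            element, digits = m.group(1), m.group(2)
            if element not in MONOISOTOPIC_MASS:
                raise ValueError(f"unknown element symbol: {element!r}")
            counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
            pos = m.end()
        return cls(counts)

    # -- Mapping interface -------------------------------------------------
    def __getitem__(self, element: str) -> int:
        return self._counts[element]

    def get(self, element: str, default: int = 0) -> int:  # type: ignore[override]
        return self._counts.get(element, default)

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        if not isinstance(other, ElementalFormula):
            return NotImplemented
        counts = dict(self._counts)
        for element, count in other._counts.items():
            counts[element] = counts.get(element, 0) + count
        return ElementalFormula(counts)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        if not isinstance(other, ElementalFormula):
            return NotImplemented
        counts = dict(self._counts)
        for element, count in other._counts.items():
            new = counts.get(element, 0) - count
            if new < 0:
                raise ValueError(
                    f"subtraction yields negative count for {element} "
                    f"({self} - {other})"
                )
            counts[element] = new
        return ElementalFormula({e: c for e, c in counts.items() if c})

    def __mul__(self, n: int) -> "ElementalFormula":
        if not isinstance(n, int):
            return NotImplemented
        if n < 0:
            raise ValueError("cannot scale a formula by a negative integer")
        return ElementalFormula({e: c * n for e, c in self._counts.items()})

    __rmul__ = __mul__

    def __eq__(self, other: object) -> bool:
        if isinstance(other, ElementalFormula):
            return self._counts == other._counts
        return NotImplemented

    def __hash__(self) -> int:
        if self._hash is None:
            self._hash = hash(frozenset(self._counts.items()))
        return self._hash

    @property
    def mass(self) -> float:
        """Monoisotopic mass in Da; 0.0 for the empty formula."""
        return sum(MONOISOTOPIC_MASS[e] * c for e, c in self._counts.items())

    def __str__(self) -> str:
        # CHNOS first (the glycan-relevant block), remaining elements sorted.
        order = ["C", "H", "N", "O", "S"]
        parts = []
        for e in order + sorted(set(self._counts) - set(order)):
            c = self._counts.get(e, 0)
            if c:
                parts.append(e if c == 1 else f"{e}{c}")
        return "".join(parts)

    def __repr__(self) -> str:
        return f"ElementalFormula({str(self)!r})"


def parse_elemental_formula(text: str) -> ElementalFormula:
    """Module-level alias for :meth:`ElementalFormula.parse`."""
    return ElementalFormula.parse(text)


def monoisotopic_mass(formula: ElementalFormula) -> float:
    """Monoisotopic mass of *formula* in Da."""
    return formula.mass


WATER = ElementalFormula(H=2, O=1)
SULFATE = ElementalFormula(S=1, O=3)  # SO3, the neutral sulfation increment
ACETYL = ElementalFormula(C=2, H=2, O=1)  # net N-acetylation increment
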