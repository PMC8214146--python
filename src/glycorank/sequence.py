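"""Sequences, compositions and the canonical sequence-string grammar.

A :class:`Sequence` is an ordered backbone of residues with a concrete
modification placement; residues are numbered 1..dp from the nonreducing
end.  The canonical string joins residue names with ``-`` and brackets the
modifications, e.g. ``dHexA[2S]-HexN[NS,6S]-HexA-HexN[NAc]``.  An HS HexN
with no bracketed amine token carries a free amine.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import cached_property

from .chem import ACETYL, ElementalFormula, SULFATE, WATER
from .residues import GAGClass, KIND_INFO, KindInfo, ResidueKind, class_kinds

__all__ = ["Residue", "Sequence", "Composition", "MassTolerances", "sequence_formula"]

_MOD_ORDER = {"NAc": 0, "NS": 0, "2S": 2, "3S": 3, "4S": 4, "6S": 6}


@dataclass(frozen=True)
class Residue:
    """One monosaccharide with its modification state.

    ``amine`` is ``'NAc'``, ``'NS'`` or ``'free'`` for HS HexN and ``None``
    for every other kind (CS/KS amino sugars carry a fixed acetyl that is
    part of their base formula).
    """

    kind: ResidueKind
    osulf: frozenset[str] = frozenset()
    amine: str | None = None

    def __post_init__(self) -> None:
        info = self.info
        bad = set(self.osulf) - set(info.o_positions)
        if bad:
            raise ValueError(f"illegal sulfation {sorted(bad)} on {self.kind.value}")
        if info.variable_amine:
            if self.amine not in ("NAc", "NS", "free"):
                raise ValueError(f"HexN amine state must be NAc/NS/free, got {self.amine!r}")
        elif self.amine is not None:
            raise ValueError(f"{self.kind.value} has no variable amine state")

    @property
    def info(self) -> KindInfo:
        return KIND_INFO[self.kind]

    @property
    def n_sulfates(self) -> int:
        return len(self.osulf) + (1 if self.amine == "NS" else 0)

    @property
    def n_acetyls(self) -> int:
        """Variable acetyls only (HS N-acetylation)."""
        return 1 if self.amine == "NAc" else 0

    @property
    def formula(self) -> ElementalFormula:
        f = self.info.formula + SULFATE * self.n_sulfates
        if self.amine == "NAc":
            f = f + ACETYL
        return f

    @property
    def mods(self) -> tuple[str, ...]:
        """All modification tokens in canonical order."""
        toks = list(self.osulf)
        if self.amine in ("NAc", "NS"):
            toks.append(self.amine)
        return tuple(sorted(toks, key=lambda t: (_MOD_ORDER[t], t)))

    def __str__(self) -> str:
        mods = self.mods
        return self.kind.value + (f"[{','.join(mods)}]" if mods else "")


_RESIDUE_RE = re.compile(
    r"^(dHexA|HexA|HexN|GalNAc|GlcNAc|Gal)(?:\[([^\]]*)\])?$"
)
_NAME_TO_KIND = {k.value: k for k in ResidueKind}


@dataclass(frozen=True)
class Sequence:
    """An ordered, fully modified GAG chain with an optional reducing-end tag."""

    residues: tuple[Residue, ...]
    tag: ElementalFormula = field(default_factory=ElementalFormula)

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("a sequence needs at least one residue")
        for a, b in zip(self.residues, self.residues[1:]):
            if a.info.is_amino == b.info.is_amino:
                raise ValueError(
                    "residues must strictly alternate between amino and "
                    f"non-amino sugars ({a.kind.value} then {b.kind.value})"
                )

    @property
    def dp(self) -> int:
        return len(self.residues)

    @property
    def n_sulfates(self) -> int:
        return sum(r.n_sulfates for r in self.residues)

    @property
    def n_acetyls(self) -> int:
        return sum(r.n_acetyls for r in self.residues)

    @cached_property
    def formula(self) -> ElementalFormula:
        f = ElementalFormula()
        for r in self.residues:
            f = f + r.formula
        return f + WATER + self.tag

    @property
    def mass(self) -> float:
        return self.formula.mass

    def __str__(self) -> str:
        return "-".join(str(r) for r in self.residues)

    @classmethod
    def parse(cls, text: str, tag: ElementalFormula | None = None) -> "Sequence":
        """Parse the canonical sequence grammar back into a Sequence."""
        residues = []
        for token in text.strip().split("-"):
            m = _RESIDUE_RE.match(token)
            if m is None:
                raise ValueError(f"malformed residue token {token!r}")
            kind = _NAME_TO_KIND[m.group(1)]
            mods = [t for t in (m.group(2) or "").split(",") if t]
            amine: str | None = None
            osulf = set()
            for mod in mods:
                if mod in ("NAc", "NS"):
                    if not KIND_INFO[kind].variable_amine:
                        raise ValueError(f"{kind.value} cannot carry {mod}")
                    amine = mod
                elif mod in _MOD_ORDER:
                    osulf.add(mod)
                else:
                    raise ValueError(f"unknown modification token {mod!r}")
            if KIND_INFO[kind].variable_amine and amine is None:
                amine = "free"
            residues.append(Residue(kind, frozenset(osulf), amine))
        return cls(tuple(residues), tag or ElementalFormula())


def sequence_formula(seq: Sequence) -> ElementalFormula:
    """Neutral elemental formula of an intact chain (residues + H2O + tag)."""
    return seq.formula


@dataclass(frozen=True)
class Composition:
    """A precursor composition: residue counts plus total modifications.

    ``n_acetyls`` counts variable acetyls and is therefore only nonzero for
    HS; CS/KS amino sugars are acetylated by construction.
    """

    gag_class: GAGClass
    n_non_amino: int          # HexA (HS/CS) or Gal (KS) residues
    n_amino: int
    n_sulfates: int = 0
    n_acetyls: int = 0
    unsaturated: bool = False  # nonreducing terminus is dHexA
    tag: ElementalFormula = field(default_factory=ElementalFormula)

    def __post_init__(self) -> None:
        if self.n_non_amino < 0 or self.n_amino < 0 or self.dp < 1:
            raise ValueError("residue counts must be nonnegative and dp >= 1")
        if abs(self.n_non_amino - self.n_amino) > 1:
            raise ValueError("residue counts must support strict alternation")
        if self.gag_class is not GAGClass.HS and self.n_acetyls:
            raise ValueError("variable acetyls exist only for HS")
        if self.n_acetyls > self.n_amino:
            raise ValueError("more acetyls than amino sugars")
        if self.unsaturated:
            if self.gag_class is GAGClass.KS:
                raise ValueError("KS has no uronic acid; no unsaturated terminus")
            if self.n_non_amino == 0 or self.n_amino > self.n_non_amino:
                raise ValueError(
                    "unsaturated nonreducing terminus requires a uronic acid "
                    "in position 1"
                )
        if self.n_sulfates > self.max_sulfation_positions:
            raise ValueError(
                f"{self.n_sulfates} sulfates exceed the "
                f"{self.max_sulfation_positions} legal positions"
            )

    @property
    def dp(self) -> int:
        return self.n_non_amino + self.n_amino

    @property
    def max_sulfation_positions(self) -> int:
        """Open sulfation positions given the acetylation count."""
        u, a = self.n_non_amino, self.n_amino
        if self.gag_class is GAGClass.HS:
            return u + 3 * a - self.n_acetyls   # 2-O per HexA; N/3-O/6-O per GlcN
        if self.gag_class is GAGClass.CS:
            return u + 2 * a                    # 2-O per HexA; 4-O/6-O per GalNAc
        return self.dp                          # KS: 6-O per residue

    @cached_property
    def formula(self) -> ElementalFormula:
        non_amino_kind, amino_kind = class_kinds(self.gag_class)
        f = (
            KIND_INFO[non_amino_kind].formula * self.n_non_amino
            + KIND_INFO[amino_kind].formula * self.n_amino
            + SULFATE * self.n_sulfates
            + ACETYL * self.n_acetyls
            + WATER
            + self.tag
        )
        if self.unsaturated:
            f = f - WATER  # dHexA replaces one HexA
        return f

    @property
    def mass(self) -> float:
        return self.formula.mass

    def __str__(self) -> str:
        non_amino_kind, amino_kind = class_kinds(self.gag_class)
        parts = [
            f"{non_amino_kind.value}{self.n_non_amino}",
            f"{amino_kind.value}{self.n_amino}",
            f"{self.n_sulfates}S",
        ]
        if self.gag_class is GAGClass.HS:
            parts.append(f"{self.n_acetyls}Ac")
        if self.unsaturated:
            parts.append("dHexA-NRE")
        return f"{self.gag_class.value}[{' '.join(parts)}]"


@dataclass(frozen=True)
class MassTolerances:
    """Fragment-matching and score-tie tolerances."""

    ppm: float = 5.0            # relative mass tolerance for fragment matching
    score_tie: float = 1e-12    # relative tolerance for BiRank score ties

    def __post_init__(self) -> None:
        if self.ppm <= 0:
            raise ValueError("ppm tolerance must be positive")
        if self.score_tie < 0:
            raise ValueError("score-tie tolerance must be nonnegative")
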