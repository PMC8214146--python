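"""GAG classes, monosaccharide residue kinds and their modification chemistry.

Sulfated GAGs are linear chains of strictly alternating amino sugars and
non-amino sugars.  Per class the repeating disaccharide is:

* HS  — HexA(1->4)GlcN, GlcN N-position free, N-acetylated or N-sulfated;
  sulfation at HexA 2-O and GlcN 3-O / 6-O.
* CS  — HexA(1->3)GalNAc (DS is handled as CS, its epimer being isobaric);
  sulfation at HexA 2-O and GalNAc 4-O / 6-O.
* KS  — Gal(1->4)GlcNAc; sulfation at Gal 6-O and GlcNAc 6-O.

Residue formulas are dehydrated ("residue") forms; one water is added per
intact chain.  Uronic-acid epimers (GlcA/IdoA) are isobaric and are not
enumerated.  A 4,5-unsaturated uronic acid (dHexA, the lyase digestion
product) may replace the nonreducing-terminal HexA.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass

from .chem import ElementalFormula

__all__ = ["GAGClass", "ResidueKind", "KIND_INFO", "MOD_CARBON"]


class GAGClass(enum.Enum):
    HS = "HS"
    CS = "CS"
    KS = "KS"

    @classmethod
    def parse(cls, text: str) -> "GAGClass":
        t = text.strip().upper()
        if t == "DS":
            raise ValueError(
                "DS is a class of CS; use the initials CS for dermatan sulfate"
            )
        try:
            return cls(t)
        except ValueError:
            raise ValueError(f"unknown GAG class {text!r}; expected HS, CS or KS")


class ResidueKind(enum.Enum):
    HEXA = "HexA"      # hexuronic acid (GlcA/IdoA, undistinguished)
    DHEXA = "dHexA"    # 4,5-unsaturated hexuronic acid (lyase product)
    HEXN = "HexN"      # HS glucosamine, variable amine state
    GALNAC = "GalNAc"  # CS amino sugar, acetyl fixed
    GAL = "Gal"        # KS galactose
    GLCNAC = "GlcNAc"  # KS amino sugar, acetyl fixed


def _f(text: str) -> ElementalFormula:
    return ElementalFormula.parse(text)


@dataclass(frozen=True)
class KindInfo:
    """Static chemistry of one residue kind."""

    formula: ElementalFormula          # dehydrated residue formula
    is_amino: bool
    o_positions: tuple[str, ...]       # legal O-sulfation positions
    variable_amine: bool               # HS GlcN only
    linkage_in: str                    # ring carbon accepting the chain-in bond
    # Elemental groups for ring atoms C2..C6 and the ring oxygen O5; the C1
    # remainder (formula minus these) always works out to CHO.  Used to build
    # cross-ring (A/X) fragment arcs; groups sum exactly to `formula`.
    arc_groups: dict[str, ElementalFormula]


KIND_INFO: dict[ResidueKind, KindInfo] = {
    ResidueKind.HEXA: KindInfo(
        formula=_f("C6H8O6"),
        is_amino=False,
        o_positions=("2S",),
        variable_amine=False,
        linkage_in="C4",
        arc_groups={
            "C2": _f("CH2O"), "C3": _f("CH2O"), "C4": _f("CH"),
            "C5": _f("CH"), "C6": _f("CHO2"), "O5": _f("O"),
        },
    ),
    ResidueKind.DHEXA: KindInfo(
        formula=_f("C6H6O5"),
        is_amino=False,
        o_positions=("2S",),
        variable_amine=False,
        linkage_in="C4",
        # Bookkeeping partition of C6H6O5 for the 4,5-ene ring; not atom-exact.
        arc_groups={
            "C2": _f("CH2O"), "C3": _f("CH2O"), "C4": _f("C"),
            "C5": _f("C"), "C6": _f("CHO2"), "O5": _f("O"),
        },
    ),
    ResidueKind.HEXN: KindInfo(
        formula=_f("C6H11NO4"),
        is_amino=True,
        o_positions=("3S", "6S"),
        variable_amine=True,
        linkage_in="C4",
        arc_groups={
            "C2": _f("CH3N"), "C3": _f("CH2O"), "C4": _f("CH"),
            "C5": _f("CH"), "C6": _f("CH3O"), "O5": _f("O"),
        },
    ),
    ResidueKind.GALNAC: KindInfo(
        formula=_f("C8H13NO5"),  # HexN + fixed acetyl
        is_amino=True,
        o_positions=("4S", "6S"),
        variable_amine=False,
        linkage_in="C3",
        arc_groups={
            "C2": _f("C3H5NO"), "C3": _f("CH"), "C4": _f("CH2O"),
            "C5": _f("CH"), "C6": _f("CH3O"), "O5": _f("O"),
        },
    ),
    ResidueKind.GAL: KindInfo(
        formula=_f("C6H10O5"),
        is_amino=False,
        o_positions=("6S",),
        variable_amine=False,
        linkage_in="C3",
        arc_groups={
            "C2": _f("CH2O"), "C3": _f("CH"), "C4": _f("CH2O"),
            "C5": _f("CH"), "C6": _f("CH3O"), "O5": _f("O"),
        },
    ),
    ResidueKind.GLCNAC: KindInfo(
        formula=_f("C8H13NO5"),  # HexN + fixed acetyl
        is_amino=True,
        o_positions=("6S",),
        variable_amine=False,
        linkage_in="C4",
        arc_groups={
            "C2": _f("C3H5NO"), "C3": _f("CH2O"), "C4": _f("CH"),
            "C5": _f("CH"), "C6": _f("CH3O"), "O5": _f("O"),
        },
    ),
}

#: Ring carbon carrying each modification position.
MOD_CARBON: dict[str, str] = {
    "2S": "C2", "3S": "C3", "4S": "C4", "6S": "C6", "NS": "C2", "NAc": "C2",
}


def class_kinds(cls: GAGClass) -> tuple[ResidueKind, ResidueKind]:
    """(non-amino kind, amino kind) for a GAG class."""
    return {
        GAGClass.HS: (ResidueKind.HEXA, ResidueKind.HEXN),
        GAGClass.CS: (ResidueKind.HEXA, ResidueKind.GALNAC),
        GAGClass.KS: (ResidueKind.GAL, ResidueKind.GLCNAC),
    }[cls]
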