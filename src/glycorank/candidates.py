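"""Precursor composition inference, backbone construction and isomer
enumeration.

Given the neutral precursor mass, the composition is the arithmetically
closest member of a bounded search space (degree of polymerization 2-12 by
default, every legal sulfate/acetyl count, both saturation states).  When
the two residue counts are equal and the nonreducing end is saturated, the
terminal residues cannot be inferred and two backbones are considered: one
with amino sugars in the odd positions and one with amino sugars in the
even positions.  Sequences are then generated combinatorially by choosing
acetylated amino sugars (HS) and distributing sulfates over the remaining
open positions, at most one sulfate per position.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb

from .chem import ElementalFormula, PROTON_MASS
from .residues import GAGClass, KIND_INFO, ResidueKind, class_kinds
from .sequence import Composition, Residue, Sequence

__all__ = [
    "Backbone",
    "CompositionSearchBounds",
    "neutral_mass_from_precursor",
    "precursor_mz",
    "infer_composition",
    "determine_backbones",
    "enumerate_sequences",
    "count_sequences",
]


def neutral_mass_from_precursor(mz: float, z: int) -> float:
    """Neutral monoisotopic mass of an [M - nH]^n- ion.

    ``z`` is the (negative) charge; each charge restores one proton.
    """
    if mz <= 0:
        raise ValueError("m/z must be positive")
    if z >= 0:
        raise ValueError("charge must be a negative integer (deprotonated ions)")
    n = -z
    return n * mz + n * PROTON_MASS


def precursor_mz(neutral_mass: float, z: int) -> float:
    """m/z of the [M - nH]^n- ion of a neutral mass (inverse of the above)."""
    if z >= 0:
        raise ValueError("charge must be a negative integer")
    n = -z
    return (neutral_mass - n * PROTON_MASS) / n


@dataclass(frozen=True)
class Backbone:
    """An ordered residue-kind chain without modifications."""

    kinds: tuple[ResidueKind, ...]
    provenance: str  # 'determined' | 'ambiguous-variant-A' | 'ambiguous-variant-B'

    @property
    def dp(self) -> int:
        return len(self.kinds)


@dataclass(frozen=True)
class CompositionSearchBounds:
    """Bounds for the composition search space."""

    dp_min: int = 2
    dp_max: int = 12
    max_sulfates: int | None = None     # None = every legal position
    max_acetyls: int | None = None      # None = every amino sugar (HS)
    include_unsaturated: bool = True

    def __post_init__(self) -> None:
        if not 1 <= self.dp_min <= self.dp_max:
            raise ValueError("need 1 <= dp_min <= dp_max")


def iter_compositions(
    gag_class: GAGClass,
    tag: ElementalFormula | None = None,
    bounds: CompositionSearchBounds = CompositionSearchBounds(),
):
    """Yield every Composition inside the search bounds."""
    tag = tag or ElementalFormula()
    for dp in range(bounds.dp_min, bounds.dp_max + 1):
        if dp % 2 == 0:
            splits = [(dp // 2, dp // 2)]
        else:
            splits = [((dp + 1) // 2, dp // 2), (dp // 2, (dp + 1) // 2)]
        for n_non_amino, n_amino in splits:
            ac_max = n_amino if gag_class is GAGClass.HS else 0
            if bounds.max_acetyls is not None:
                ac_max = min(ac_max, bounds.max_acetyls)
            for n_ac in range(ac_max + 1):
                saturations = [False]
                if (
                    bounds.include_unsaturated
                    and gag_class is not GAGClass.KS
                    and n_non_amino >= 1
                    and n_amino <= n_non_amino
                ):
                    saturations.append(True)
                for unsat in saturations:
                    probe = Composition(
                        gag_class, n_non_amino, n_amino,
                        n_sulfates=0, n_acetyls=n_ac,
                        unsaturated=unsat, tag=tag,
                    )
                    s_max = probe.max_sulfation_positions
                    if bounds.max_sulfates is not None:
                        s_max = min(s_max, bounds.max_sulfates)
                    for n_s in range(s_max + 1):
                        yield Composition(
                            gag_class, n_non_amino, n_amino,
                            n_sulfates=n_s, n_acetyls=n_ac,
                            unsaturated=unsat, tag=tag,
                        )


def infer_composition(
    neutral_mass: float,
    gag_class: GAGClass,
    tag: ElementalFormula | None = None,
    bounds: CompositionSearchBounds = CompositionSearchBounds(),
) -> tuple[Composition, float]:
    """Pick the composition whose neutral mass is arithmetically closest.

    Returns ``(composition, ppm_error)``.  Exact mass ties are broken
    deterministically: fewest total modifications, then lowest dp, then
    saturated before unsaturated.
    """
    if neutral_mass <= 0:
        raise ValueError("neutral mass must be positive")
    best: Composition | None = None
    best_key: tuple | None = None
    for comp in iter_compositions(gag_class, tag, bounds):
        delta = abs(neutral_mass - comp.mass)
        key = (delta, comp.n_sulfates + comp.n_acetyls, comp.dp, comp.unsaturated)
        if best_key is None or key < best_key:
            best, best_key = comp, key
    if best is None:
        raise ValueError("empty composition search space")
    ppm = (neutral_mass - best.mass) / best.mass * 1e6
    return best, ppm


def determine_backbones(comp: Composition) -> list[Backbone]:
    """Backbone(s) consistent with the residue counts and saturation flag."""
    non_amino_kind, amino_kind = class_kinds(comp.gag_class)
    u, a = comp.n_non_amino, comp.n_amino

    def chain(first_amino: bool) -> tuple[ResidueKind, ...]:
        kinds = []
        for i in range(comp.dp):
            amino = first_amino if i % 2 == 0 else not first_amino
            kinds.append(amino_kind if amino else non_amino_kind)
        return tuple(kinds)

    if u != a:
        # Odd dp: the majority kind occupies both termini.
        kinds = chain(first_amino=a > u)
    elif comp.unsaturated:
        kinds = chain(first_amino=False)
    else:
        return [
            Backbone(chain(first_amino=True), "ambiguous-variant-A"),
            Backbone(chain(first_amino=False), "ambiguous-variant-B"),
        ]
    if comp.unsaturated:
        if kinds[0] is not non_amino_kind:
            raise ValueError("unsaturated terminus requires a uronic acid first")
        kinds = (ResidueKind.DHEXA,) + kinds[1:]
    return [Backbone(kinds, "determined")]


def _open_positions(
    backbone: Backbone, acetylated: frozenset[int]
) -> list[tuple[int, str]]:
    """Canonical list of open sulfation positions: (residue index, position)."""
    positions: list[tuple[int, str]] = []
    for i, kind in enumerate(backbone.kinds):
        info = KIND_INFO[kind]
        if info.variable_amine and i not in acetylated:
            positions.append((i, "NS"))
        for pos in info.o_positions:
            positions.append((i, pos))
    return positions


def _build_sequence(
    backbone: Backbone,
    acetylated: frozenset[int],
    sulfated: tuple[tuple[int, str], ...],
    tag: ElementalFormula,
) -> Sequence:
    osulf: dict[int, set[str]] = {}
    nsulf: set[int] = set()
    for i, pos in sulfated:
        if pos == "NS":
            nsulf.add(i)
        else:
            osulf.setdefault(i, set()).add(pos)
    residues = []
    for i, kind in enumerate(backbone.kinds):
        info = KIND_INFO[kind]
        amine: str | None = None
        if info.variable_amine:
            amine = "NAc" if i in acetylated else ("NS" if i in nsulf else "free")
        residues.append(Residue(kind, frozenset(osulf.get(i, set())), amine))
    return Sequence(tuple(residues), tag)


def enumerate_sequences(
    backbones: list[Backbone] | Backbone, comp: Composition
) -> list[Sequence]:
    """Every modification placement for the composition, in canonical order."""
    if isinstance(backbones, Backbone):
        backbones = [backbones]
    out: list[Sequence] = []
    for backbone in backbones:
        amino_idx = [
            i for i, k in enumerate(backbone.kinds) if KIND_INFO[k].variable_amine
        ]
        if comp.gag_class is GAGClass.HS:
            if comp.n_acetyls > len(amino_idx):
                raise ValueError("more acetyls than amino sugars in backbone")
            ac_choices = itertools.combinations(amino_idx, comp.n_acetyls)
        else:
            ac_choices = [()]
        for ac in ac_choices:
            acetylated = frozenset(ac)
            open_pos = _open_positions(backbone, acetylated)
            if comp.n_sulfates > len(open_pos):
                raise ValueError("more sulfates than open positions in backbone")
            for sulfated in itertools.combinations(open_pos, comp.n_sulfates):
                out.append(_build_sequence(backbone, acetylated, sulfated, comp.tag))
    return out


def count_sequences(
    backbones: list[Backbone] | Backbone, comp: Composition
) -> int:
    """Closed-form twin of :func:`enumerate_sequences`."""
    if isinstance(backbones, Backbone):
        backbones = [backbones]
    total = 0
    for backbone in backbones:
        a = sum(1 for k in backbone.kinds if KIND_INFO[k].variable_amine)
        n_open_base = len(_open_positions(backbone, frozenset()))
        if comp.gag_class is GAGClass.HS:
            n_ac = comp.n_acetyls
            n_open = n_open_base - n_ac  # each acetyl closes one N position
            total += comb(a, n_ac) * comb(n_open, comp.n_sulfates)
        else:
            total += comb(n_open_base, comp.n_sulfates)
    return total
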