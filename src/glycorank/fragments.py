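"""Theoretical fragment generation and observed-peak matching.

Fragment families follow Domon–Costello nomenclature:

* terminal glycosidic — B/C retain the nonreducing end (C = B + H2O); Y/Z
  retain the reducing end and tag (Z = Y - H2O);
* terminal cross-ring — A/X ions from two ring cleavages, built from a
  configurable arc table; X is the exact mass complement of its A ion so
  that A + X equals the neutral precursor mass;
* internal double-glycosidic — a contiguous residue span touching neither
  terminus, with mass = span residues + H2O.

Internal glycosidic–cross-ring and cross-ring–cross-ring ions are not
generated.  Each fragment may additionally shed 0..k SO3 neutral losses,
bounded by its retained sulfate count.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import accumulate

import numpy as np

from .chem import ElementalFormula, PROTON_MASS, SULFATE, WATER
from .residues import MOD_CARBON
from .sequence import MassTolerances, Sequence

__all__ = [
    "CROSS_RING_ARCS",
    "Fragment",
    "ObservedPeak",
    "MergedPeak",
    "theoretical_fragments",
    "merge_peaks",
    "match",
]

TERMINAL = "terminal"
INTERNAL = "internal"

#: Default cross-ring cleavage table: label -> ring atoms retained on the
#: nonreducing (A) side.  C1 always leaves with the reducing side.
CROSS_RING_ARCS: dict[str, frozenset[str]] = {
    "0,2": frozenset({"C3", "C4", "C5", "C6", "O5"}),
    "1,5": frozenset({"C2", "C3", "C4", "C5", "C6"}),
    "2,4": frozenset({"C3", "C4"}),
    "3,5": frozenset({"C4", "C5", "C6"}),
}


@dataclass(frozen=True)
class Fragment:
    """An annotated theoretical product ion (neutral species)."""

    annotation: str
    family: str                      # TERMINAL or INTERNAL
    formula: ElementalFormula
    n_sulfates: int                  # retained sulfates before losses
    n_losses: int = 0                # SO3 neutral losses already applied

    @property
    def mass(self) -> float:
        return self.formula.mass


@dataclass(frozen=True)
class ObservedPeak:
    """One row of a GAGfinder-style peak/fragment list."""

    annotation: str
    mz: float
    charge: int
    intensity: float
    gscore: float

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("m/z must be positive")
        if self.charge >= 0:
            raise ValueError("charge must be a negative integer")
        if self.intensity < 0:
            raise ValueError("intensity must be nonnegative")
        if self.gscore < 0:
            raise ValueError("G-score must be nonnegative")

    @property
    def neutral_mass(self) -> float:
        n = -self.charge
        return n * self.mz + n * PROTON_MASS


@dataclass(frozen=True)
class MergedPeak:
    """Observed peaks collapsed to one fragment node (charge states merged).

    Intensities are summed and the best (smallest) G-score kept.
    """

    mass: float
    intensity: float
    gscore: float
    annotations: tuple[str, ...] = ()
    rows: tuple[int, ...] = ()       # source row indices in the peak list


def _with_losses(
    base: Fragment, max_losses: int, out: list[Fragment]
) -> None:
    out.append(base)
    for k in range(1, min(max_losses, base.n_sulfates) + 1):
        out.append(
            Fragment(
                annotation=f"{base.annotation}-{k}SO3",
                family=base.family,
                formula=base.formula - SULFATE * k,
                n_sulfates=base.n_sulfates,
                n_losses=k,
            )
        )


def _arc_formula(res, retained: frozenset[str]) -> tuple[ElementalFormula, int]:
    """Retained-arc formula and sulfate count for a cross-ring cut."""
    info = res.info
    f = ElementalFormula()
    for atom in retained:
        f = f + info.arc_groups[atom]
    n_s = 0
    for pos in res.osulf:
        if MOD_CARBON[pos] in retained:
            f = f + SULFATE
            n_s += 1
    if "C2" in retained and res.amine == "NS":
        f = f + SULFATE
        n_s += 1
    if "C2" in retained and res.amine == "NAc":
        f = f + ElementalFormula(C=2, H=2, O=1)
    return f, n_s


def theoretical_fragments(
    seq: Sequence,
    max_losses: int = 0,
    cross_ring_arcs: dict[str, frozenset[str]] | None = None,
) -> list[Fragment]:
    """All theoretical fragments of a sequence, with SO3-loss variants."""
    if max_losses < 0:
        raise ValueError("max_losses must be nonnegative")
    arcs = CROSS_RING_ARCS if cross_ring_arcs is None else cross_ring_arcs
    dp = seq.dp
    res = seq.residues
    formulas = [r.formula for r in res]
    sulfates = [r.n_sulfates for r in res]
    prefix = list(accumulate(formulas))           # prefix[i] = residues 1..i+1
    prefix_s = list(accumulate(sulfates))
    total = seq.formula
    total_s = prefix_s[-1]

    out: list[Fragment] = []

    # Terminal glycosidic: one B/C/Y/Z quartet per glycosidic bond.
    for i in range(1, dp):
        b = prefix[i - 1]
        sb = prefix_s[i - 1]
        y = total - b                              # suffix + H2O + tag
        sy = total_s - sb
        _with_losses(Fragment(f"B{i}", TERMINAL, b, sb), max_losses, out)
        _with_losses(Fragment(f"C{i}", TERMINAL, b + WATER, sb), max_losses, out)
        _with_losses(Fragment(f"Y{dp - i}", TERMINAL, y, sy), max_losses, out)
        _with_losses(Fragment(f"Z{dp - i}", TERMINAL, y - WATER, sy), max_losses, out)

    # Terminal cross-ring: A/X complement pairs at each residue.
    for i in range(1, dp + 1):
        r = res[i - 1]
        linkage = r.info.linkage_in
        for label, retained in arcs.items():
            if i > 1 and linkage not in retained:
                continue  # arc disconnected from the nonreducing prefix
            arc_f, arc_s = _arc_formula(r, retained)
            a_f = (prefix[i - 2] + arc_f) if i > 1 else arc_f
            a_s = (prefix_s[i - 2] + arc_s) if i > 1 else arc_s
            x_f = total - a_f
            x_s = total_s - a_s
            _with_losses(
                Fragment(f"{label}A{i}", TERMINAL, a_f, a_s), max_losses, out
            )
            _with_losses(
                Fragment(f"{label}X{dp - i}", TERMINAL, x_f, x_s), max_losses, out
            )

    # Internal double-glycosidic: spans touching neither terminus.
    for start in range(2, dp):                     # 1-based residue positions
        for end in range(start, dp):
            span_f = prefix[end - 1] - prefix[start - 2] + WATER
            span_s = prefix_s[end - 1] - prefix_s[start - 2]
            _with_losses(
                Fragment(f"I{start}-{end}", INTERNAL, span_f, span_s),
                max_losses,
                out,
            )
    return out


def merge_peaks(
    peaks: list[ObservedPeak], tol: MassTolerances = MassTolerances()
) -> list[MergedPeak]:
    """Collapse peaks whose neutral masses agree within the ppm tolerance.

    Greedy merge over mass-sorted peaks; intensities are summed and the
    minimum G-score kept, so multiple charge states of one fragment form a
    single fragment node.
    """
    if not peaks:
        return []
    order = sorted(range(len(peaks)), key=lambda i: peaks[i].neutral_mass)
    groups: list[list[int]] = [[order[0]]]
    for idx in order[1:]:
        ref = peaks[groups[-1][0]].neutral_mass
        m = peaks[idx].neutral_mass
        if abs(m - ref) <= ref * tol.ppm * 1e-6:
            groups[-1].append(idx)
        else:
            groups.append([idx])
    merged = []
    for group in groups:
        members = [peaks[i] for i in group]
        weight = sum(p.intensity for p in members)
        mass = (
            sum(p.neutral_mass * p.intensity for p in members) / weight
            if weight > 0
            else float(np.mean([p.neutral_mass for p in members]))
        )
        merged.append(
            MergedPeak(
                mass=mass,
                intensity=weight,
                gscore=min(p.gscore for p in members),
                annotations=tuple(p.annotation for p in members),
                rows=tuple(sorted(group)),
            )
        )
    return merged


def match(
    theoretical: list[Fragment],
    peaks: list[MergedPeak],
    tol: MassTolerances = MassTolerances(),
) -> list[tuple[int, str]]:
    """Match one sequence's fragments against merged peaks.

    Returns ``(peak index, family)`` pairs, one per matched peak; when a
    peak is isobaric with both a terminal and an internal fragment the
    terminal family wins.
    """
    edges: dict[int, str] = {}
    for frag in theoretical:
        fmass = frag.mass
        window = fmass * tol.ppm * 1e-6
        for j, peak in enumerate(peaks):
            if abs(peak.mass - fmass) <= window:
                if frag.family == TERMINAL or j not in edges:
                    edges[j] = frag.family
    return sorted(edges.items())
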