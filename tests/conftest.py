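"""Shared builders for randomized compositions, sequences and spectra."""
from __future__ import annotations

import random

import pytest

from glycorank import (
    Composition,
    GAGClass,
    Sequence,
    determine_backbones,
    enumerate_sequences,
)
from glycorank.chem import ElementalFormula


def random_composition(
    rng: random.Random,
    gag_class: GAGClass | None = None,
    dp_range: tuple[int, int] = (2, 8),
    max_sulfates: int = 4,
    tag: ElementalFormula | None = None,
) -> Composition:
    """A random legal composition; sulfate count bounded to keep isomer
    counts tractable."""
    cls = gag_class or rng.choice(list(GAGClass))
    dp = rng.randint(*dp_range)
    if dp % 2 == 0:
        u = a = dp // 2
    else:
        u = rng.choice([(dp + 1) // 2, dp // 2])
        a = dp - u
    n_ac = rng.randint(0, a) if cls is GAGClass.HS else 0
    unsat = False
    if cls is not GAGClass.KS and u >= 1 and a <= u:
        unsat = rng.random() < 0.3
    probe = Composition(cls, u, a, 0, n_ac, unsat, tag or ElementalFormula())
    n_s = rng.randint(0, min(max_sulfates, probe.max_sulfation_positions))
    return Composition(cls, u, a, n_s, n_ac, unsat, tag or ElementalFormula())


def random_sequence(
    rng: random.Random,
    gag_class: GAGClass | None = None,
    dp_range: tuple[int, int] = (2, 6),
    tag: ElementalFormula | None = None,
) -> Sequence:
    comp = random_composition(rng, gag_class, dp_range, tag=tag)
    seqs = enumerate_sequences(determine_backbones(comp), comp)
    return rng.choice(seqs)


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20240901)
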