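"""Synthetic peak-list generation for known ground-truth sequences.

The simulator emulates the upstream peak-picking output for a spectrum of
one sequence or an isomeric mixture at stated abundance ratios: each
theoretical fragment of each truth is detected with a per-family
probability, true peaks get log-normal intensities (terminal ions brighter
than internal ones) scaled by the mixture ratio and small G-scores
(uniform 0.1-2), and optional decoy peaks are drawn away from every
theoretical fragment mass of every candidate isomer (rejection within 3x
the matching tolerance) with worse G-scores (uniform 1-5).  Output rows
are sorted by ascending G-score, so the model's top-N selection keeps the
best-fit peaks.  Everything is deterministic under the seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .candidates import determine_backbones, enumerate_sequences, precursor_mz
from .fragments import INTERNAL, ObservedPeak, TERMINAL, theoretical_fragments
from .model import SequenceRanker
from .ranking import BiRankParams
from .residues import GAGClass, ResidueKind
from .sequence import Composition, MassTolerances, Sequence

__all__ = [
    "SimulationSpec",
    "composition_of",
    "simulate_peaks",
    "recovery_experiment",
    "RecoveryReport",
]


def composition_of(seq: Sequence) -> Composition:
    """Recover the precursor composition a sequence instantiates."""
    kinds = [r.kind for r in seq.residues]
    if ResidueKind.HEXN in kinds:
        cls = GAGClass.HS
    elif ResidueKind.GALNAC in kinds:
        cls = GAGClass.CS
    elif ResidueKind.GAL in kinds or ResidueKind.GLCNAC in kinds:
        cls = GAGClass.KS
    else:
        raise ValueError("cannot infer GAG class from residue kinds")
    n_amino = sum(1 for r in seq.residues if r.info.is_amino)
    return Composition(
        gag_class=cls,
        n_non_amino=seq.dp - n_amino,
        n_amino=n_amino,
        n_sulfates=seq.n_sulfates,
        n_acetyls=seq.n_acetyls,
        unsaturated=kinds[0] is ResidueKind.DHEXA,
        tag=seq.tag,
    )


@dataclass
class SimulationSpec:
    """Ground truths, abundance ratios and peak statistics for one spectrum."""

    sequences: list[Sequence]
    ratios: list[float] | None = None        # normalized; None = equal parts
    terminal_detection: float = 0.9
    internal_detection: float = 0.5
    # Peak picking misses a weak component's fragments more often: detection
    # is scaled by ratio**abundance_exponent, so a pure sample (ratio 1) is
    # unaffected and a minority isomer loses part of its fragment complement.
    abundance_exponent: float = 0.5
    max_losses: int = 0
    n_decoys: int = 0
    decoy_mass_range: tuple[float, float] = (200.0, 1500.0)
    intensity_log_mean: dict[str, float] = field(
        default_factory=lambda: {TERMINAL: np.log(1000.0), INTERNAL: np.log(100.0)}
    )
    intensity_log_sigma: float = 0.5
    tolerances: MassTolerances = field(default_factory=MassTolerances)
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("need at least one ground-truth sequence")
        comps = {str(composition_of(s)) for s in self.sequences}
        if len(comps) > 1:
            raise ValueError("mixture components must be isomers (one composition)")
        if self.ratios is None:
            self.ratios = [1.0 / len(self.sequences)] * len(self.sequences)
        if len(self.ratios) != len(self.sequences):
            raise ValueError("one ratio per sequence required")
        total = sum(self.ratios)
        if total <= 0:
            raise ValueError("ratios must sum to a positive value")
        self.ratios = [r / total for r in self.ratios]
        for p in (self.terminal_detection, self.internal_detection):
            if not 0 <= p <= 1:
                raise ValueError("detection probabilities must be in [0, 1]")


def _candidate_masses(spec: SimulationSpec) -> np.ndarray:
    """Sorted theoretical masses over every candidate isomer (for decoys)."""
    comp = composition_of(spec.sequences[0])
    candidates = enumerate_sequences(determine_backbones(comp), comp)
    masses = [
        frag.mass
        for seq in candidates
        for frag in theoretical_fragments(seq, spec.max_losses)
    ]
    return np.sort(np.array(masses))


def simulate_peaks(spec: SimulationSpec) -> list[ObservedPeak]:
    """Sample one synthetic peak/fragment list from the spec."""
    rng = np.random.default_rng(spec.seed)
    peaks: list[ObservedPeak] = []
    for seq, ratio in zip(spec.sequences, spec.ratios):
        if ratio <= 0:
            continue
        for frag in theoretical_fragments(seq, spec.max_losses):
            p_detect = (
                spec.terminal_detection
                if frag.family == TERMINAL
                else spec.internal_detection
            ) * ratio ** spec.abundance_exponent
            if rng.uniform() >= p_detect:
                continue
            intensity = ratio * float(
                rng.lognormal(
                    spec.intensity_log_mean[frag.family], spec.intensity_log_sigma
                )
            )
            charge = -int(rng.integers(1, 3))
            peaks.append(
                ObservedPeak(
                    annotation=frag.annotation,
                    mz=precursor_mz(frag.mass, charge),
                    charge=charge,
                    intensity=intensity,
                    gscore=float(rng.uniform(0.1, 2.0)),
                )
            )
    if spec.n_decoys:
        forbidden = _candidate_masses(spec)
        guard = 3 * spec.tolerances.ppm * 1e-6
        lo, hi = spec.decoy_mass_range
        made = 0
        while made < spec.n_decoys:
            mass = float(rng.uniform(lo, hi))
            idx = np.searchsorted(forbidden, mass)
            near = forbidden[max(0, idx - 1): idx + 1]
            if near.size and np.any(np.abs(near - mass) <= near * guard):
                continue
            peaks.append(
                ObservedPeak(
                    annotation=f"decoy{made + 1}",
                    mz=precursor_mz(mass, -1),
                    charge=-1,
                    intensity=float(rng.lognormal(np.log(100.0), 0.5)),
                    gscore=float(rng.uniform(1.0, 5.0)),
                )
            )
            made += 1
    peaks.sort(key=lambda p: (p.gscore, p.mz))
    return peaks


@dataclass(frozen=True)
class RecoveryReport:
    """Outcome of ranking a simulated spectrum against its ground truths."""

    truths: tuple[str, ...]
    rank_spans: tuple[tuple[int, int], ...]
    percent_outscored: tuple[float, ...]
    n_sequences: int


def recovery_experiment(
    spec: SimulationSpec,
    params: BiRankParams | None = None,
    precursor_charge: int = -2,
) -> RecoveryReport:
    """Simulate, rank with the full pipeline and report each truth's rank."""
    peaks = simulate_peaks(spec)
    comp = composition_of(spec.sequences[0])
    ranker = SequenceRanker(
        peaks,
        comp.gag_class,
        precursor_mz(comp.mass, precursor_charge),
        precursor_charge,
        tag=comp.tag,
        max_losses=spec.max_losses,
        tolerances=spec.tolerances,
    )
    results = ranker.fit(params)
    spans = []
    pcts = []
    for truth in spec.sequences:
        spans.append(results.rank_of(truth))
        pcts.append(results.percent_outscored(truth))
    return RecoveryReport(
        truths=tuple(str(s) for s in spec.sequences),
        rank_spans=tuple(spans),
        percent_outscored=tuple(pcts),
        n_sequences=results.n_sequences,
    )
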