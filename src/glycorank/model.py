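"""High-level modelling interface: SequenceRanker -> RankingResults.

``SequenceRanker`` is built once from a peak list and the precursor
description; construction runs the deterministic pipeline stages (neutral
mass, composition inference, backbone setup, isomer enumeration and
theoretical fragment generation).  ``fit`` then assembles the bipartite
graph for a parameter setting and iterates BiRank, returning a
``RankingResults`` object carrying scores, tie-aware ranks, convergence
diagnostics and a ``summary()`` table.  Refitting with different
parameters reuses all cached candidate chemistry, which is what makes the
simulated-annealing parameter search affordable.
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from io import StringIO

import numpy as np

from .candidates import (
    Backbone,
    CompositionSearchBounds,
    determine_backbones,
    enumerate_sequences,
    infer_composition,
    neutral_mass_from_precursor,
)
from .chem import ElementalFormula
from .fragments import (
    MergedPeak,
    ObservedPeak,
    TERMINAL,
    merge_peaks,
    theoretical_fragments,
)
from .ranking import (
    BiRankParams,
    BipartiteModel,
    DEFAULT_PARAMS,
    RankResult,
    birank,
    fragment_query,
    rank,
    sequence_prior,
)
from .residues import GAGClass
from .sequence import Composition, MassTolerances, Sequence

__all__ = ["SequenceRanker", "RankingResults"]


class SequenceRanker:
    """Rank every modification isomer of a precursor against its spectrum.

    Parameters
    ----------
    peaks
        Observed peak/fragment rows, in file order (order matters for the
        top-N fragment selection).
    gag_class
        HS, CS or KS (DS samples are encoded as CS).
    precursor_mz, precursor_charge
        The deprotonated precursor ion; charge is negative.
    tag
        Net elemental addition of a reducing-end derivatization.
    max_losses
        SO3 neutral losses to generate per fragment.
    """

    def __init__(
        self,
        peaks: list[ObservedPeak],
        gag_class: GAGClass,
        precursor_mz: float,
        precursor_charge: int,
        *,
        tag: ElementalFormula | None = None,
        max_losses: int = 0,
        tolerances: MassTolerances = MassTolerances(),
        search_bounds: CompositionSearchBounds = CompositionSearchBounds(),
    ):
        if not peaks:
            raise ValueError("empty peak list")
        self.peaks = list(peaks)
        self.gag_class = GAGClass(gag_class)
        self.tag = tag or ElementalFormula()
        self.max_losses = int(max_losses)
        self.tolerances = tolerances
        self.precursor_mz = float(precursor_mz)
        self.precursor_charge = int(precursor_charge)
        self.neutral_mass = neutral_mass_from_precursor(
            self.precursor_mz, self.precursor_charge
        )
        self.composition, self.ppm_error = infer_composition(
            self.neutral_mass, self.gag_class, self.tag, search_bounds
        )
        self.backbones: list[Backbone] = determine_backbones(self.composition)
        self.sequences: list[Sequence] = enumerate_sequences(
            self.backbones, self.composition
        )

    # -- cached candidate chemistry ---------------------------------------
    @cached_property
    def _theoretical_index(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """All candidates' fragment masses, flattened and mass-sorted.

        Returns (mass, sequence index, family code) arrays; family code 0
        is terminal, 1 internal.
        """
        masses: list[float] = []
        seq_idx: list[int] = []
        fam: list[int] = []
        for i, seq in enumerate(self.sequences):
            for frag in theoretical_fragments(seq, self.max_losses):
                masses.append(frag.mass)
                seq_idx.append(i)
                fam.append(0 if frag.family == TERMINAL else 1)
        mass_arr = np.array(masses)
        order = np.argsort(mass_arr, kind="stable")
        return (
            mass_arr[order],
            np.array(seq_idx, dtype=np.intp)[order],
            np.array(fam, dtype=np.int8)[order],
        )

    @cached_property
    def _priors(self) -> np.ndarray:
        return np.array([sequence_prior(s) for s in self.sequences])

    # -- graph assembly ----------------------------------------------------
    def select_peaks(self, n_fragments: int | None) -> list[ObservedPeak]:
        """First-N row selection of the peak list, as provided."""
        if n_fragments is None:
            return self.peaks
        return self.peaks[: n_fragments]

    def build_graph(
        self, params: BiRankParams
    ) -> tuple[BipartiteModel, list[MergedPeak]]:
        """Merge peaks, match against every candidate and weight the edges."""
        merged = merge_peaks(
            self.select_peaks(params.n_fragments), self.tolerances
        )
        theo_mass, theo_seq, theo_fam = self._theoretical_index
        n_seq = len(self.sequences)
        W = np.zeros((n_seq, len(merged)))
        w_internal = 0.2 ** params.r1
        rel = self.tolerances.ppm * 1e-6
        for j, peak in enumerate(merged):
            # |obs - theo| <= theo * ppm  =>  theo in [obs/(1+ppm), obs/(1-ppm)]
            lo = np.searchsorted(theo_mass, peak.mass / (1 + rel), side="left")
            hi = np.searchsorted(theo_mass, peak.mass / (1 - rel), side="right")
            if lo == hi:
                continue
            fam = theo_fam[lo:hi]
            seqs = theo_seq[lo:hi]
            W[seqs[fam == 1], j] = w_internal   # internal first ...
            W[seqs[fam == 0], j] = 1.0          # ... terminal precedence wins
        p0 = fragment_query(merged, params.r2)
        u0_raw = self._priors ** params.r3
        u0 = u0_raw / u0_raw.sum()
        return BipartiteModel(W=W, p0=p0, u0=u0, params=params), merged

    # -- fitting -----------------------------------------------------------
    def fit(
        self,
        params: BiRankParams | None = None,
        *,
        tol: float = 1e-9,
        max_iter: int = 1000,
    ) -> "RankingResults":
        params = params or DEFAULT_PARAMS
        model, merged = self.build_graph(params)
        if model.W.sum() == 0:
            raise ValueError(
                "empty graph: no observed peak matches any candidate fragment"
            )
        p, u, n_iter, converged = birank(model, tol=tol, max_iter=max_iter)
        return RankingResults(
            ranker=self,
            params=params,
            graph=model,
            merged_peaks=merged,
            fragment_scores=p,
            sequence_scores=u,
            n_iter=n_iter,
            converged=converged,
        )


@dataclass
class RankingResults:
    """Converged BiRank scores for every candidate sequence."""

    ranker: SequenceRanker
    params: BiRankParams
    graph: BipartiteModel
    merged_peaks: list[MergedPeak]
    fragment_scores: np.ndarray
    sequence_scores: np.ndarray
    n_iter: int
    converged: bool

    @cached_property
    def ranking(self) -> list[RankResult]:
        return rank(
            self.ranker.sequences,
            self.sequence_scores,
            tie_tol=self.ranker.tolerances.score_tie,
        )

    @property
    def n_sequences(self) -> int:
        return len(self.ranker.sequences)

    def _find(self, truth: Sequence | str) -> RankResult:
        key = str(truth) if isinstance(truth, Sequence) else truth
        for r in self.ranking:
            if str(r.sequence) == key:
                return r
        raise ValueError(f"sequence {key!r} is not among the candidates")

    def rank_of(self, truth: Sequence | str) -> tuple[int, int]:
        """Tie-aware rank span (lo, hi) of a known sequence."""
        r = self._find(truth)
        return r.rank_lo, r.rank_hi

    def percent_outscored(self, truth: Sequence | str) -> float:
        """Percent of the other candidates strictly outscored by *truth*."""
        return self._find(truth).percent_outscored

    def summary(self, top: int = 10) -> str:
        """Human-readable report in the spirit of a model-results summary."""
        rk = self.ranker
        buf = StringIO()
        n = self.n_sequences
        buf.write("GAG sequence ranking (BiRank)\n")
        buf.write("=" * 64 + "\n")
        buf.write(f"GAG class:        {rk.gag_class.value}\n")
        buf.write(
            f"Precursor:        m/z {rk.precursor_mz:.4f}, "
            f"z {rk.precursor_charge:+d}, M {rk.neutral_mass:.4f} Da\n"
        )
        buf.write(
            f"Composition:      {rk.composition} "
            f"({rk.ppm_error:+.2f} ppm)\n"
        )
        buf.write(f"Backbones:        {len(rk.backbones)}\n")
        buf.write(f"Candidates:       {n}\n")
        buf.write(f"Fragment nodes:   {len(self.merged_peaks)}\n")
        n_edges = int(np.count_nonzero(self.graph.W))
        buf.write(f"Edges:            {n_edges}\n")
        buf.write(
            f"Parameters:       r1={self.params.r1} r2={self.params.r2} "
            f"r3={self.params.r3} alpha={self.params.alpha} "
            f"beta={self.params.beta} "
            f"N={'all' if self.params.n_fragments is None else self.params.n_fragments}\n"
        )
        buf.write(
            f"Iterations:       {self.n_iter} "
            f"({'converged' if self.converged else 'NOT converged'})\n"
        )
        buf.write("-" * 64 + "\n")
        buf.write(f"{'rank':>10}  {'score':>12}  sequence\n")
        for r in self.ranking[:top]:
            buf.write(f"{r.rank_span:>10}  {r.score:>12.6e}  {r.sequence}\n")
        if n > top:
            buf.write(f"... {n - top} more sequences\n")
        return buf.getvalue()

    def to_tsv(self, path) -> None:
        from .io import write_ranking

        write_ranking(self.ranking, path)
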