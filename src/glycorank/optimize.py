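"""Simulated-annealing search over the six ranking parameters.

The fitness of a parameter setting is the average, over training
compounds, of the fraction of incorrect sequences whose BiRank score is
strictly worse than the correct sequence's (1.0 when the truth ranks
first, 0.0 when it ranks last).  The annealer starts at temperature 1,
multiplies it by 0.9 after dwelling 100 iterations at each level, and
accepts a worsening move with probability exp((f_new - f_current) / T);
improving moves are always accepted.  A neighbor redraws exactly one
randomly chosen parameter uniformly from its bounds: alpha, beta in [0, 1]
rounded to 0.01; r1, r2, r3 in [0, 10] rounded to 0.1; the fragment count
N an integer in 5..100 or 'all'.  The best solution ever visited is stored
and returned.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import RankingResults, SequenceRanker
from .ranking import BiRankParams, RankResult
from .sequence import Sequence

__all__ = [
    "SAConfig",
    "TrainingCase",
    "SAResult",
    "TraceRecord",
    "fitness",
    "compound_fitness",
    "acceptance_probability",
    "neighbor",
    "random_params",
    "anneal",
]

_PARAM_NAMES = ("r1", "r2", "r3", "alpha", "beta", "n_fragments")
_N_CHOICES: tuple[int | None, ...] = tuple(range(5, 101)) + (None,)  # None = all


@dataclass(frozen=True)
class SAConfig:
    """Cooling schedule and parameter-move configuration."""

    t_initial: float = 1.0
    cooling: float = 0.9
    iters_per_temp: int = 100
    t_stop: float = 1e-3
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.cooling < 1:
            raise ValueError("cooling factor must be in (0, 1)")
        if self.t_initial <= 0 or self.t_stop <= 0:
            raise ValueError("temperatures must be positive")
        if self.iters_per_temp < 1:
            raise ValueError("iters_per_temp must be >= 1")


@dataclass
class TrainingCase:
    """One training compound: a prepared ranker plus its known sequence."""

    ranker: SequenceRanker
    truth: Sequence | str

    def __post_init__(self) -> None:
        key = str(self.truth)
        if key not in {str(s) for s in self.ranker.sequences}:
            raise ValueError(f"truth {key!r} is not among the candidates")


def compound_fitness(ranking: list[RankResult], truth: Sequence | str) -> float:
    """Fraction of incorrect sequences strictly outscored by the truth.

    A single-candidate compound contributes 1.0 (vacuous denominator).
    """
    n = len(ranking)
    if n == 1:
        return 1.0
    key = str(truth)
    for r in ranking:
        if str(r.sequence) == key:
            return r.percent_outscored / 100.0
    raise ValueError(f"truth {key!r} is not among the ranked sequences")


def fitness(cases: list[tuple[list[RankResult], Sequence | str]]) -> float:
    """Mean compound fitness over a training set."""
    if not cases:
        raise ValueError("no training cases")
    return sum(compound_fitness(rk, t) for rk, t in cases) / len(cases)


def acceptance_probability(f_new: float, f_current: float, t: float) -> float:
    """min(1, exp((f_new - f_current) / T)); improvements always accepted."""
    if t <= 0:
        raise ValueError("temperature must be positive")
    if f_new >= f_current:
        return 1.0
    return math.exp((f_new - f_current) / t)


def _draw(name: str, rng: np.random.Generator):
    if name in ("alpha", "beta"):
        return round(float(rng.uniform(0, 1)), 2)
    if name in ("r1", "r2", "r3"):
        return round(float(rng.uniform(0, 10)), 1)
    return _N_CHOICES[int(rng.integers(len(_N_CHOICES)))]


def random_params(rng: np.random.Generator) -> BiRankParams:
    """Uniform draw of all six parameters (the annealer's starting state)."""
    return BiRankParams(**{name: _draw(name, rng) for name in _PARAM_NAMES})


def neighbor(params: BiRankParams, rng: np.random.Generator) -> BiRankParams:
    """Redraw one uniformly chosen parameter; the others are unchanged."""
    name = _PARAM_NAMES[int(rng.integers(len(_PARAM_NAMES)))]
    return params.replace(**{name: _draw(name, rng)})


@dataclass(frozen=True)
class TraceRecord:
    iteration: int
    temperature: float
    params: BiRankParams
    f_current: float
    f_best: float


@dataclass
class SAResult:
    best_params: BiRankParams
    best_fitness: float
    trace: list[TraceRecord] = field(default_factory=list)


def _evaluate(params: BiRankParams, cases: list[TrainingCase]) -> float:
    total = 0.0
    for case in cases:
        try:
            results: RankingResults = case.ranker.fit(params)
        except ValueError:
            # No matched edges for this peak subset: worst possible fitness.
            total += 0.0
            continue
        total += compound_fitness(results.ranking, case.truth)
    return total / len(cases)


def anneal(cases: list[TrainingCase], cfg: SAConfig = SAConfig()) -> SAResult:
    """Run the cooling schedule; reproducible under ``cfg.seed``."""
    if not cases:
        raise ValueError("training set is empty")
    rng = np.random.default_rng(cfg.seed)
    current = random_params(rng)
    f_current = _evaluate(current, cases)
    best, f_best = current, f_current
    trace: list[TraceRecord] = [
        TraceRecord(0, cfg.t_initial, current, f_current, f_best)
    ]

    t = cfg.t_initial
    iteration = 0
    while t >= cfg.t_stop:
        for _ in range(cfg.iters_per_temp):
            iteration += 1
            proposal = neighbor(current, rng)
            f_new = _evaluate(proposal, cases)
            if rng.uniform() < acceptance_probability(f_new, f_current, t):
                current, f_current = proposal, f_new
            if f_current > f_best:
                best, f_best = current, f_current
            trace.append(TraceRecord(iteration, t, current, f_current, f_best))
        t *= cfg.cooling
    return SAResult(best_params=best, best_fitness=f_best, trace=trace)
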