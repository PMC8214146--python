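"""Bipartite graph assembly, BiRank iteration and tie-aware rank reporting.

The graph links candidate sequences (partition *u*) to observed fragment
nodes (partition *p*).  Edge weights are

    w_xy = 1.0      if fragment x is a terminal fragment of sequence y
    w_xy = 0.2**r1  if fragment x is an internal double-glycosidic fragment

Query vectors encode prior belief: fragments get p0_x = I_x / G_x**r2
(intensity over GAGfinder goodness-of-fit), sequences get u0_y =
(prod_m score_m)**r3 with the residue likelihood

    score_m = 1.0 - 0.6*N_m - 0.3*S_m

penalizing free amines (N_m) and 3-O-sulfation without 6-O-sulfation on an
HS glucosamine (S_m), both rare in nature.  BiRank then iterates

    p <- alpha * S^T u + (1 - alpha) * p0
    u <- beta  * S  p + (1 - beta)  * u0

with the symmetrically degree-normalized weight matrix
S = Du^{-1/2} W Dp^{-1/2} until the L1 change falls below tolerance.
A larger converged u_y means a higher-ranked sequence.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .fragments import INTERNAL, MergedPeak, TERMINAL
from .sequence import Residue, Sequence

__all__ = [
    "BiRankParams",
    "DEFAULT_PARAMS",
    "BipartiteModel",
    "RankResult",
    "edge_weight",
    "fragment_query",
    "residue_score",
    "sequence_query",
    "birank",
    "rank",
]

#: Floor applied to G-scores before exponentiation, so a perfect isotopic
#: fit (G = 0) does not divide by zero.
GSCORE_FLOOR = 1e-6


@dataclass(frozen=True)
class BiRankParams:
    """Tunable parameters of the ranking model.

    Defaults are the medians of the optimal combinations found by the
    simulated-annealing search on the training standards.  ``n_fragments``
    limits how many peak-list rows are used (``None`` = all).
    """

    r1: float = 5.4
    r2: float = 5.1
    r3: float = 0.4
    alpha: float = 0.98
    beta: float = 0.94
    n_fragments: int | None = 68

    def __post_init__(self) -> None:
        for name in ("r1", "r2", "r3"):
            v = getattr(self, name)
            if not 0 <= v <= 10:
                raise ValueError(f"{name} must be in [0, 10], got {v}")
        for name in ("alpha", "beta"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_fragments is not None and self.n_fragments < 1:
            raise ValueError("n_fragments must be positive or None")

    def replace(self, **changes) -> "BiRankParams":
        return replace(self, **changes)


DEFAULT_PARAMS = BiRankParams()


def edge_weight(family: str, r1: float) -> float:
    """Edge weight for a fragment family."""
    if family == TERMINAL:
        return 1.0
    if family == INTERNAL:
        return 0.2 ** r1
    raise ValueError(f"unknown fragment family {family!r}")


def fragment_query(peaks: list[MergedPeak], r2: float) -> np.ndarray:
    """Fragment query vector p0: intensity over G-score**r2, sum-normalized."""
    raw = np.array(
        [p.intensity / max(p.gscore, GSCORE_FLOOR) ** r2 for p in peaks],
        dtype=float,
    )
    total = raw.sum()
    if total <= 0:
        raise ValueError("fragment query vector is all zero (no intensity)")
    return raw / total


def residue_score(residue: Residue) -> float:
    """Residue likelihood in [0.1, 1.0] (Eq. 4 of the ranking model)."""
    n_m = 1 if residue.amine == "free" else 0
    s_m = 1 if ("3S" in residue.osulf and "6S" not in residue.osulf) else 0
    return 1.0 - 0.6 * n_m - 0.3 * s_m


def sequence_prior(seq: Sequence) -> float:
    """Product of residue likelihoods (before the r3 exponent)."""
    prior = 1.0
    for r in seq.residues:
        prior *= residue_score(r)
    return prior


def sequence_query(sequences: list[Sequence], r3: float) -> np.ndarray:
    """Sequence query vector u0: residue-likelihood product**r3, normalized."""
    if not sequences:
        raise ValueError("no sequences")
    raw = np.array([sequence_prior(s) ** r3 for s in sequences], dtype=float)
    return raw / raw.sum()


@dataclass
class BipartiteModel:
    """Weight matrix plus query vectors, ready for BiRank.

    ``W`` has one row per sequence and one column per fragment node.
    """

    W: np.ndarray
    p0: np.ndarray
    u0: np.ndarray
    params: BiRankParams = DEFAULT_PARAMS

    def __post_init__(self) -> None:
        n_u, n_p = self.W.shape
        if self.p0.shape != (n_p,) or self.u0.shape != (n_u,):
            raise ValueError("query vector shapes do not match W")
        if (self.W < 0).any() or (self.p0 < 0).any() or (self.u0 < 0).any():
            raise ValueError("W, p0 and u0 must be nonnegative")


def birank(
    model: BipartiteModel,
    tol: float = 1e-9,
    max_iter: int = 1000,
    p_init: np.ndarray | None = None,
    u_init: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, int, bool]:
    """Iterate BiRank to convergence.

    Returns ``(p, u, n_iter, converged)``.  Zero-degree rows/columns get a
    zero normalization factor, so their scores relax to the query-vector
    component; a convergence failure warns and returns the last iterate.
    """
    W = np.asarray(model.W, dtype=float)
    if W.sum() == 0:
        raise ValueError("weight matrix has no edges")
    p0 = model.p0 / model.p0.sum()
    u0 = model.u0 / model.u0.sum()
    alpha, beta = model.params.alpha, model.params.beta

    du = W.sum(axis=1)  # weighted sequence degrees
    dp = W.sum(axis=0)  # weighted fragment degrees
    with np.errstate(divide="ignore"):
        du_inv = np.where(du > 0, 1.0 / np.sqrt(du), 0.0)
        dp_inv = np.where(dp > 0, 1.0 / np.sqrt(dp), 0.0)
    S = du_inv[:, None] * W * dp_inv[None, :]

    p = p0.copy() if p_init is None else np.asarray(p_init, dtype=float).copy()
    u = u0.copy() if u_init is None else np.asarray(u_init, dtype=float).copy()
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        p_new = alpha * (S.T @ u) + (1 - alpha) * p0
        u_new = beta * (S @ p_new) + (1 - beta) * u0
        change = np.abs(p_new - p).sum() + np.abs(u_new - u).sum()
        p, u = p_new, u_new
        if change < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"BiRank did not converge within {max_iter} iterations",
            RuntimeWarning,
            stacklevel=2,
        )
    return p, u, n_iter, converged


@dataclass(frozen=True)
class RankResult:
    """Per-sequence score with a tie-aware rank span.

    Ranks are 1-based; a tie group shares the contiguous span
    ``rank_lo..rank_hi`` (reported as e.g. ``#2-#4``).
    ``percent_outscored`` is the percent of the *other* sequences with a
    strictly worse score, the headline accuracy measure.
    """

    sequence: Sequence
    score: float
    rank_lo: int
    rank_hi: int
    percent_outscored: float

    @property
    def rank_span(self) -> str:
        if self.rank_lo == self.rank_hi:
            return f"#{self.rank_lo}"
        return f"#{self.rank_lo}-#{self.rank_hi}"


def rank(
    sequences: list[Sequence],
    scores: np.ndarray,
    tie_tol: float = 1e-12,
) -> list[RankResult]:
    """Sort descending and assign tie-aware rank spans.

    Scores within ``tie_tol`` (relative) of each other are one tie group.
    """
    scores = np.asarray(scores, dtype=float)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    if len(sequences) != len(scores):
        raise ValueError("sequences and scores differ in length")
    order = np.argsort(-scores, kind="stable")
    n = len(order)
    results: list[RankResult | None] = [None] * n

    # Walk the sorted scores, cutting a new tie group when the gap exceeds
    # the relative tolerance of the group's leading score.
    groups: list[list[int]] = []
    for pos, idx in enumerate(order):
        if groups:
            lead = scores[order[groups[-1][0]]]
            if abs(lead - scores[idx]) <= tie_tol * max(abs(lead), 1e-300):
                groups[-1].append(pos)
                continue
        groups.append([pos])

    for group in groups:
        lo, hi = group[0] + 1, group[-1] + 1
        for pos in group:
            idx = order[pos]
            n_below = n - hi  # sequences strictly below this tie group
            pct = 100.0 * n_below / (n - 1) if n > 1 else 100.0
            results[pos] = RankResult(
                sequence=sequences[idx],
                score=float(scores[idx]),
                rank_lo=lo,
                rank_hi=hi,
                percent_outscored=pct,
            )
    return [r for r in results if r is not None]
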