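"""Edge weights, query vectors, BiRank iteration and tie-aware ranking."""
from __future__ import annotations

import numpy as np
import pytest

from glycorank import (
    BiRankParams,
    BipartiteModel,
    Residue,
    ResidueKind,
    Sequence,
    birank,
    edge_weight,
    fragment_query,
    rank,
    residue_score,
    sequence_query,
)
from glycorank.fragments import INTERNAL, MergedPeak, TERMINAL


def _peak(intensity=100.0, gscore=2.0, mass=500.0):
    return MergedPeak(mass=mass, intensity=intensity, gscore=gscore)


class TestEdgeWeight:
    @pytest.mark.parametrize(
        "family, r1, expected",
        [
            (TERMINAL, 5.4, 1.0),
            (INTERNAL, 1.0, 0.2),
            (INTERNAL, 2.0, 0.04),
            (INTERNAL, 0.0, 1.0),
        ],
    )
    def test_values(self, family, r1, expected):
        assert edge_weight(family, r1) == pytest.approx(expected)

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            edge_weight("cross", 1.0)


class TestResidueScore:
    @pytest.mark.parametrize(
        "canonical, expected",
        [
            ("HexN[NAc,6S]", 1.0),          # no penalized features
            ("HexN", 0.4),                  # free amine
            ("HexN[3S]", 0.1),              # free amine + 3-O without 6-O
            ("HexN[NS,3S]", 0.7),           # 3-O without 6-O only
            ("HexN[NS,3S,6S]", 1.0),        # 6-O rescues the 3-O penalty
            ("HexA[2S]", 1.0),
            ("GalNAc[4S]", 1.0),
        ],
    )
    def test_likelihoods(self, canonical, expected):
        residue = Sequence.parse(f"HexA-{canonical}" if canonical.startswith(("HexN", "GalNAc")) else f"{canonical}-HexN[NAc]").residues[
            1 if canonical.startswith(("HexN", "GalNAc")) else 0
        ]
        assert residue_score(residue) == pytest.approx(expected)


class TestQueryVectors:
    def test_fragment_query_is_intensity_over_gscore_power(self):
        peaks = [_peak(100.0, 2.0), _peak(100.0, 1.0)]
        p0 = fragment_query(peaks, r2=1.0)
        # raw values 50 and 100 -> normalized 1/3, 2/3
        assert p0 == pytest.approx([1 / 3, 2 / 3])

    def test_r2_zero_ignores_gscore(self):
        peaks = [_peak(30.0, 2.0), _peak(70.0, 0.1)]
        assert fragment_query(peaks, r2=0.0) == pytest.approx([0.3, 0.7])

    def test_equal_raw_values_normalize_to_half(self):
        peaks = [_peak(100.0, 2.0), _peak(50.0, 1.0)]
        assert fragment_query(peaks, r2=1.0) == pytest.approx([0.5, 0.5])

    def test_zero_intensity_everywhere_is_an_error(self):
        with pytest.raises(ValueError):
            fragment_query([_peak(0.0, 1.0)], r2=1.0)

    def test_perfect_gscore_does_not_divide_by_zero(self):
        p0 = fragment_query([_peak(10.0, 0.0), _peak(10.0, 1.0)], r2=2.0)
        assert np.isfinite(p0).all()

    def test_sequence_query_prior_products(self):
        clean = Sequence.parse("HexA-HexN[NAc]")
        rare = Sequence.parse("HexA-HexN")          # free amine, prior 0.4
        u0 = sequence_query([clean, rare], r3=1.0)
        assert u0 == pytest.approx([1.0 / 1.4, 0.4 / 1.4])

    def test_r3_zero_gives_uniform_prior(self):
        seqs = [Sequence.parse("HexA-HexN[NAc]"), Sequence.parse("HexA-HexN")]
        assert sequence_query(seqs, r3=0.0) == pytest.approx([0.5, 0.5])


def _model(W, p0=None, u0=None, **kw):
    W = np.asarray(W, dtype=float)
    n_u, n_p = W.shape
    return BipartiteModel(
        W=W,
        p0=np.full(n_p, 1.0 / n_p) if p0 is None else np.asarray(p0, float),
        u0=np.full(n_u, 1.0 / n_u) if u0 is None else np.asarray(u0, float),
        params=BiRankParams(**kw),
    )


class TestBiRank:
    def test_query_only_limit_at_alpha_beta_zero(self):
        model = _model([[1.0, 0.0], [0.0, 1.0]], alpha=0.0, beta=0.0)
        p, u, n_iter, converged = birank(model)
        assert converged
        assert p == pytest.approx(model.p0)
        assert u == pytest.approx(model.u0)

    def test_single_edge_fixed_point_matches_closed_form(self):
        # For one sequence and one fragment with w=1 the normalized S is 1
        # and the fixed point solves p = a*u + (1-a), u = b*p + (1-b).
        alpha, beta = 0.85, 0.6
        model = _model([[1.0]], alpha=alpha, beta=beta)
        p, u, _, converged = birank(model, tol=1e-14)
        assert converged
        p_star = (alpha * (1 - beta) + (1 - alpha)) / (1 - alpha * beta)
        u_star = (beta * (1 - alpha) + (1 - beta)) / (1 - alpha * beta)
        assert p[0] == pytest.approx(p_star, abs=1e-10)
        assert u[0] == pytest.approx(u_star, abs=1e-10)

    def test_two_initializations_converge_to_the_same_point(self):
        rng = np.random.default_rng(11)
        W = rng.uniform(size=(6, 9)) * (rng.uniform(size=(6, 9)) < 0.5)
        W[0, 0] = 1.0
        model = _model(W, alpha=0.9, beta=0.8)
        p1, u1, _, c1 = birank(model, tol=1e-12)
        p_init = rng.dirichlet(np.ones(9))
        u_init = rng.dirichlet(np.ones(6))
        p2, u2, _, c2 = birank(model, tol=1e-12, p_init=p_init, u_init=u_init)
        assert c1 and c2
        assert p1 == pytest.approx(p2, abs=1e-8)
        assert u1 == pytest.approx(u2, abs=1e-8)

    def test_permuting_sequences_permutes_scores(self):
        rng = np.random.default_rng(5)
        W = (rng.uniform(size=(5, 7)) < 0.4).astype(float)
        W[2, 3] = 1.0
        u0 = rng.dirichlet(np.ones(5))
        model = _model(W, u0=u0, alpha=0.95, beta=0.9)
        _, u, _, _ = birank(model, tol=1e-12)
        perm = np.array([3, 0, 4, 1, 2])
        model_p = _model(W[perm], u0=u0[perm], alpha=0.95, beta=0.9)
        _, u_perm, _, _ = birank(model_p, tol=1e-12)
        assert u_perm == pytest.approx(u[perm], abs=1e-10)

    def test_zero_degree_nodes_relax_to_query_component(self):
        W = np.array([[1.0, 0.0], [0.0, 0.0]])  # fragment 2 & sequence 2 isolated
        model = _model(W, alpha=0.9, beta=0.9)
        p, u, _, converged = birank(model)
        assert converged
        assert np.isfinite(p).all() and np.isfinite(u).all()
        assert u[1] == pytest.approx((1 - 0.9) * 0.5, abs=1e-9)

    def test_scores_stay_nonnegative(self):
        rng = np.random.default_rng(2)
        W = (rng.uniform(size=(8, 10)) < 0.3).astype(float)
        W[0, 0] = 1.0
        model = _model(W, alpha=0.98, beta=0.94)
        p, u, _, _ = birank(model)
        assert (p >= 0).all() and (u >= 0).all()

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            birank(_model([[0.0]]))


def _seqs(n):
    a = Sequence.parse("HexA-HexN[NAc]")
    b = Sequence.parse("HexA-HexN[NS]")
    c = Sequence.parse("HexA-HexN")
    d = Sequence.parse("HexA[2S]-HexN")
    pool = [a, b, c, d]
    # distinct Sequence objects are not required to be unique for ranking
    return (pool * ((n + 3) // 4))[:n]


class TestRank:
    def test_tie_groups_share_contiguous_rank_spans(self):
        results = rank(_seqs(4), np.array([0.5, 0.3, 0.3, 0.1]))
        spans = [r.rank_span for r in results]
        assert spans == ["#1", "#2-#3", "#2-#3", "#4"]

    def test_top_ranked_sequence_outscored_everyone(self):
        results = rank(_seqs(10), np.linspace(1.0, 0.1, 10))
        assert results[0].percent_outscored == pytest.approx(100.0)
        assert results[-1].percent_outscored == pytest.approx(0.0)

    def test_tied_group_percent_matches_table_style_report(self):
        # A three-way tie at ranks 2-4 among 1848 sequences outscores
        # 1844 of 1847 incorrect sequences: 99.8%.
        scores = np.concatenate([[1.0], np.full(3, 0.5), np.linspace(0.4, 0.01, 1844)])
        results = rank(_seqs(1848), scores)
        tied = results[1]
        assert (tied.rank_lo, tied.rank_hi) == (2, 4)
        assert tied.percent_outscored == pytest.approx(100 * 1844 / 1847, abs=1e-9)
        assert round(tied.percent_outscored, 1) == 99.8

    def test_nonfinite_scores_rejected(self):
        with pytest.raises(ValueError):
            rank(_seqs(2), np.array([np.nan, 1.0]))
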