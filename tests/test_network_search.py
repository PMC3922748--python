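"""IC algorithm: partial correlations, HPD decisions, skeleton and orientation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import CovarianceDraws, conjugate_covariance_posterior, simulate_dag_residuals
from milknet.network_search import (
    PDAG,
    OrientationConflictError,
    SeparationRecord,
    count_ic_tests,
    hpd_interval,
    ic_skeleton,
    orient_colliders,
    partial_correlation,
    posterior_partial_correlations,
    propagate_orientations,
)


def _recursion_oracle(corr: np.ndarray, i: int, j: int, S: tuple) -> float:
    """First-order recursion for partial correlations (independent oracle)."""
    if not S:
        return corr[i, j] / np.sqrt(corr[i, i] * corr[j, j])
    k, rest = S[0], tuple(S[1:])
    rij = _recursion_oracle(corr, i, j, rest)
    rik = _recursion_oracle(corr, i, k, rest)
    rjk = _recursion_oracle(corr, j, k, rest)
    return (rij - rik * rjk) / np.sqrt((1 - rik**2) * (1 - rjk**2))


class TestPartialCorrelation:
    def test_identity_matrix_gives_zero(self):
        assert partial_correlation(np.eye(5), 0, 3, (1, 4)) == 0.0

    def test_equicorrelated_first_order_value(self):
        sigma = np.full((3, 3), 0.5)
        np.fill_diagonal(sigma, 1.0)
        assert partial_correlation(sigma, 0, 1, (2,)) == pytest.approx(1 / 3)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_inversion_equals_recursion_oracle(self, seed):
        rng = np.random.default_rng(seed)
        t = int(rng.integers(3, 7))
        w = rng.normal(size=(t, t + 3))
        sigma = w @ w.T + 0.5 * np.eye(t)
        others = [v for v in range(2, t)]
        S = tuple(others[: int(rng.integers(0, len(others) + 1))])
        assert partial_correlation(sigma, 0, 1, S) == pytest.approx(
            _recursion_oracle(sigma, 0, 1, S), abs=1e-10
        )

    def test_singular_submatrix_reports_condition_number(self):
        sigma = np.ones((3, 3))
        with pytest.raises(ValueError, match="condition number"):
            partial_correlation(sigma, 0, 1, (2,))

    def test_overlapping_indices_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            partial_correlation(np.eye(3), 0, 1, (1,))


class TestPosteriorPartialCorrelations:
    def test_point_mass_posterior_gives_point_masses(self):
        sigma = np.array([[1.0, 0.6, 0.3], [0.6, 1.0, 0.5], [0.3, 0.5, 1.0]])
        draws = CovarianceDraws(("x", "y", "z"), np.repeat(sigma[None], 40, axis=0))
        pcp = posterior_partial_correlations(draws)
        for (i, j, S), vals in pcp.draws.items():
            expect = partial_correlation(sigma, i, j, S)
            assert np.allclose(vals, expect)

    def test_five_trait_plan_has_eighty_series(self):
        rng = np.random.default_rng(0)
        w = rng.normal(size=(5, 8))
        sig = np.repeat((w @ w.T + np.eye(5))[None], 35, axis=0)
        pcp = posterior_partial_correlations(CovarianceDraws(tuple("abcde"), sig))
        assert pcp.n_series == count_ic_tests(5)[2] == 80
        assert len(pcp.subsets_for(0, 1)) == 8

    def test_singular_draws_flagged_and_excluded(self):
        good = np.array([[1.0, 0.2], [0.2, 1.0]])
        bad = np.ones((2, 2))
        stack = np.concatenate([np.repeat(good[None], 30, 0), bad[None]])
        pcp = posterior_partial_correlations(CovarianceDraws(("a", "b"), stack))
        assert pcp.total_excluded() == 1
        assert pcp.get(0, 1).size == 30

    def test_max_cond_size_caps_subsets(self):
        sig = np.repeat(np.eye(4)[None], 31, axis=0) + 0.1
        pcp = posterior_partial_correlations(
            CovarianceDraws(tuple("abcd"), sig), max_cond_size=1
        )
        assert all(len(S) <= 1 for _, _, S in pcp.draws)


class TestHPDInterval:
    def test_point_mass(self):
        lo, hi = hpd_interval(np.full(50, 3.0), 0.95)
        assert (lo, hi) == (3.0, 3.0)

    def test_full_content_gives_range(self):
        x = np.arange(100.0)
        assert hpd_interval(x, 1.0) == (0.0, 99.0)

    def test_exponential_matches_analytic_interval(self):
        x = np.random.default_rng(0).exponential(size=100_000)
        lo, hi = hpd_interval(x, 0.95)
        assert lo == pytest.approx(0.0, abs=0.02)
        assert hi == pytest.approx(-np.log(0.05), abs=0.05)

    def test_agrees_with_arviz_hdi(self):
        az = pytest.importorskip("arviz")
        x = np.random.default_rng(1).normal(2.0, 0.5, size=20_000)
        lo, hi = hpd_interval(x, 0.9)
        ref_lo, ref_hi = az.hdi(x, hdi_prob=0.9)
        # estimators differ by at most one order statistic at the ends
        assert lo == pytest.approx(ref_lo, abs=0.01)
        assert hi == pytest.approx(ref_hi, abs=0.01)

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            hpd_interval(np.ones(5), 0.95)

    def test_bad_content_rejected(self):
        with pytest.raises(ValueError, match="content"):
            hpd_interval(np.ones(50), 1.2)


class TestCountICTests:
    @pytest.mark.parametrize(
        "t,expected",
        [(14, (91, 4096, 372_736)), (2, (1, 1, 1)), (5, (10, 8, 80))],
    )
    def test_plan_sizes(self, t, expected):
        assert count_ic_tests(t) == expected

    def test_single_trait_rejected(self):
        with pytest.raises(ValueError, match="at least two"):
            count_ic_tests(1)


def _point_mass_pcp(sigma, traits):
    draws = CovarianceDraws(traits, np.repeat(np.asarray(sigma)[None], 40, axis=0))
    return posterior_partial_correlations(draws)


def _tight_pcp(sigma, traits, seed=0):
    """Posterior draws concentrated around sigma (width ~ n^-1/2, n = 5000).

    A degenerate point mass would declare even a numerically-nonzero
    (1e-16) partial correlation dependent, so decision tests use a tight
    but proper posterior.
    """
    from scipy import stats

    n = 5000
    sig = stats.invwishart.rvs(
        df=n, scale=np.asarray(sigma) * n, size=300,
        random_state=np.random.default_rng(seed),
    )
    return posterior_partial_correlations(CovarianceDraws(traits, sig))


def _chain_sigma(t=5, lam=0.9):
    L = np.zeros((t, t))
    for i in range(1, t):
        L[i, i - 1] = lam
    m = np.linalg.inv(np.eye(t) - L)
    return m @ m.T


class TestICSteps:
    def test_chain_covariance_yields_path_skeleton(self):
        traits = tuple("abcde")
        pdag, record = ic_skeleton(_tight_pcp(_chain_sigma(), traits), 0.95)
        assert pdag.undirected_edges() == [
            ("a", "b"), ("b", "c"), ("c", "d"), ("d", "e")
        ]
        # the separating sets of (a, c) all contain b
        assert record.in_any_separator(0, 2, 1)

    def test_independent_traits_yield_empty_graph(self):
        pdag, _ = ic_skeleton(_point_mass_pcp(np.eye(4), tuple("abcd")), 0.95)
        assert pdag.edges() == []

    def test_collider_detected_and_oriented(self):
        lam = np.zeros((3, 3))
        lam[1, 0] = lam[1, 2] = 0.8
        m = np.linalg.inv(np.eye(3) - lam)
        sigma = m @ m.T
        traits = ("y1", "y2", "y3")
        skel, record = ic_skeleton(_tight_pcp(sigma, traits), 0.95)
        assert skel.undirected_edges() == [("y1", "y2"), ("y2", "y3")]
        pdag = orient_colliders(skel, record)
        assert set(pdag.directed_edges()) == {("y1", "y2"), ("y3", "y2")}

    def test_chain_skeleton_stays_undirected(self):
        traits = tuple("abcde")
        skel, record = ic_skeleton(_tight_pcp(_chain_sigma(), traits), 0.95)
        pdag = propagate_orientations(orient_colliders(skel, record))
        assert pdag.directed_edges() == []

    def test_empty_skeleton_unchanged_by_orientation(self):
        pdag, record = ic_skeleton(_point_mass_pcp(np.eye(3), tuple("abc")), 0.95)
        assert orient_colliders(pdag, record).edges() == []

    def test_conflicting_collider_orientations_abort_with_report(self):
        pdag = PDAG(("a", "b", "c", "d"))
        for x, y in (("a", "b"), ("b", "c"), ("c", "d")):
            pdag.add_undirected(x, y)
        # separators claim neither b (for a,c) nor c (for b,d): both triples
        # demand a collider, pulling edge b-c in both directions
        record = SeparationRecord({(0, 2): [()], (1, 3): [()], (0, 3): [()]})
        with pytest.raises(OrientationConflictError, match="b-c"):
            orient_colliders(pdag, record)

    def test_meek_rule_one(self):
        pdag = PDAG(("a", "b", "c"))
        pdag.add_undirected("a", "b")
        pdag.add_undirected("b", "c")
        pdag.orient("a", "b")
        out = propagate_orientations(pdag)
        assert ("b", "c") in out.directed_edges()

    def test_meek_rule_two(self):
        pdag = PDAG(("a", "b", "c"))
        for x, y in (("a", "b"), ("b", "c"), ("a", "c")):
            pdag.add_undirected(x, y)
        pdag.orient("a", "b")
        pdag.orient("b", "c")
        out = propagate_orientations(pdag)
        assert ("a", "c") in out.directed_edges()

    def test_fully_undirected_graph_unchanged(self):
        pdag = PDAG(("a", "b", "c"))
        pdag.add_undirected("a", "b")
        pdag.add_undirected("b", "c")
        pdag.add_undirected("a", "c")
        assert propagate_orientations(pdag) == pdag

    def test_sample_order_permutation_invariance(self):
        rng = np.random.default_rng(3)
        sig = conjugate_covariance_posterior(
            simulate_dag_residuals(_zero_lam(4), np.ones(4), 2000, rng), 200, rng
        )
        traits = tuple("abcd")
        p1 = posterior_partial_correlations(CovarianceDraws(traits, sig))
        p2 = posterior_partial_correlations(CovarianceDraws(traits, sig[::-1].copy()))
        s1, _ = ic_skeleton(p1, 0.9)
        s2, _ = ic_skeleton(p2, 0.9)
        assert s1.edges() == s2.edges()


def _zero_lam(t):
    return np.zeros((t, t))


class TestPDAGSerialisation:
    def _pdag(self):
        pdag = PDAG(("a", "b", "c"), provenance=0.95)
        pdag.add_undirected("a", "b")
        pdag.add_undirected("b", "c")
        pdag.orient("b", "c")
        return pdag

    def test_tsv_round_trip(self, tmp_path):
        pdag = self._pdag()
        path = tmp_path / "g.tsv"
        pdag.to_tsv(path)
        back = PDAG.from_tsv(path, nodes=pdag.nodes)
        assert back == pdag
        assert back.provenance == 0.95

    def test_dot_marks_undirected_edges(self, tmp_path):
        text = self._pdag().to_dot(tmp_path / "g.dot")
        assert '"a" -> "b" [dir=none];' in text
        assert '"b" -> "c";' in text

    def test_self_edges_rejected(self):
        with pytest.raises(ValueError, match="self edge"):
            PDAG(("a",)).add_undirected("a", "a")
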