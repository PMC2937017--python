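import itertools

import numpy as np
import pytest
from scipy import stats

from cnakit import assoc
from cnakit.assoc import ContingencyCounts, PermutationPlan


def counts_from_margins(n11, nA, nB, n):
    return ContingencyCounts(n11=n11, n10=nA - n11, n01=nB - n11,
                             n00=n - nA - nB + n11)


class TestScoreTest:
    def test_worked_example_margins(self):
        # 35 doubly-aberrant of n=183 with margins 68 and 50
        counts = counts_from_margins(35, 68, 50, 183)
        z, p = assoc.score_test(counts)
        assert z > 0 and p < 0.0001

    def test_exact_independence(self):
        counts = counts_from_margins(25, 50, 50, 100)
        z, p = assoc.score_test(counts)
        assert z == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_frozen_example_table(self):
        # oracle: scipy Pearson chi-square, no continuity correction
        counts = ContingencyCounts(35, 33, 15, 100)
        table = np.array([[35, 33], [15, 100]])
        chi2 = stats.chi2_contingency(table, correction=False)[0]
        assert chi2 == pytest.approx(31.777, abs=1e-3)
        z, p = assoc.score_test(counts)
        assert z == pytest.approx(np.sqrt(chi2), rel=1e-12)
        assert z == pytest.approx(5.64, abs=0.01)
        assert p == pytest.approx(1.7e-8, rel=0.05)

    def test_degenerate_margin_raises(self):
        with pytest.raises(ValueError, match="untestable"):
            assoc.score_test(ContingencyCounts(0, 0, 10, 90))

    def test_z_squared_matches_chi2_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            table = rng.integers(1, 60, size=4)
            counts = ContingencyCounts(*map(int, table))
            z, _ = assoc.score_test(counts)
            chi2 = stats.chi2_contingency(
                np.array(table).reshape(2, 2), correction=False
            )[0]
            assert z * z == pytest.approx(chi2, rel=1e-10)

    def test_antisymmetry_in_roles(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n11, n10, n01, n00 = map(int, rng.integers(1, 40, size=4))
            z1, p1 = assoc.score_test(ContingencyCounts(n11, n10, n01, n00))
            # swap roles of A and B: transpose the table
            z2, p2 = assoc.score_test(ContingencyCounts(n11, n01, n10, n00))
            assert z1 == pytest.approx(z2, rel=1e-12)
            assert p1 == pytest.approx(p2, rel=1e-12)


class TestExpectedCooccurrence:
    def test_worked_example(self):
        assert assoc.expected_cooccurrence(0.37, 0.33) == pytest.approx(0.1221)
        assert round(assoc.expected_cooccurrence(0.37, 0.33) * 100) == 12

    def test_zero(self):
        assert assoc.expected_cooccurrence(0.0, 0.9) == 0.0

    def test_half_half(self):
        assert assoc.expected_cooccurrence(0.5, 0.5) == 0.25


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        assert assoc.bh_adjust([0.01, 0.02, 0.03]).tolist() \
            == pytest.approx([0.03, 0.03, 0.03])

    def test_single_p(self):
        assert assoc.bh_adjust([0.2]).tolist() == [0.2]

    def test_all_ones(self):
        assert assoc.bh_adjust([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]

    def test_q_at_least_p(self):
        rng = np.random.default_rng(2)
        p = rng.random(50)
        q = assoc.bh_adjust(p)
        assert (q >= p - 1e-12).all() and (q <= 1).all()

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(3)
        for _ in range(20):
            p = rng.random(rng.integers(1, 40))
            expected = multipletests(p, method="fdr_bh")[1]
            assert assoc.bh_adjust(p) == pytest.approx(expected, rel=1e-12)


class TestAllPairs:
    def test_identical_columns_dominate(self):
        rng = np.random.default_rng(4)
        X = (rng.random((100, 5)) < 0.4).astype(int)
        X[:, 1] = X[:, 0]
        results = assoc.all_pairs(X)
        top = max((r for r in results if r.testable), key=lambda r: abs(r.z))
        assert {top.i, top.j} == {0, 1}
        assert top.direction == "positive"

    def test_single_pair_q_equals_p(self):
        rng = np.random.default_rng(5)
        X = (rng.random((60, 2)) < 0.5).astype(int)
        (result,) = assoc.all_pairs(X)
        assert result.q == pytest.approx(result.p)

    def test_untestable_excluded_from_bh(self):
        rng = np.random.default_rng(6)
        X = (rng.random((50, 3)) < 0.5).astype(int)
        X[:, 2] = 0  # degenerate column
        results = {(r.i, r.j): r for r in assoc.all_pairs(X)}
        assert not results[(0, 2)].testable
        assert not results[(1, 2)].testable
        assert results[(0, 1)].q == pytest.approx(results[(0, 1)].p)

    def test_null_false_selection_rate(self):
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(50):
            X = (rng.random((200, 12)) < 0.3).astype(int)
            if assoc.select(assoc.all_pairs(X), fdr=0.05):
                hits += 1
        assert hits / 50 <= 0.12  # FDR 5% plus Monte Carlo slack

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(8)
        X = (rng.random((80, 6)) < 0.4).astype(int)
        base = assoc.all_pairs(X)
        shuffled = assoc.all_pairs(X[rng.permutation(80)])
        a = {(r.i, r.j): (r.z, r.p, r.q) for r in base if r.testable}
        b = {(r.i, r.j): (r.z, r.p, r.q) for r in shuffled if r.testable}
        assert a.keys() == b.keys()
        for key in a:
            assert a[key] == pytest.approx(b[key], rel=1e-12)


def exhaustive_permutation_p(X, i, j):
    """Oracle: enumerate every distinct independent column rearrangement."""
    n = X.shape[0]

    def arrangements(col):
        ones = int(col.sum())
        for pos in itertools.combinations(range(n), ones):
            v = np.zeros(n, dtype=int)
            v[list(pos)] = 1
            yield v

    counts = ContingencyCounts.from_columns(X[:, i], X[:, j])
    z_obs, _ = assoc.score_test(counts)
    total = 0
    exceed = 0
    for a in arrangements(X[:, i]):
        for b in arrangements(X[:, j]):
            c = ContingencyCounts.from_columns(a, b)
            z, _ = assoc.score_test(c)
            total += 1
            if abs(z) >= abs(z_obs) - 1e-12:
                exceed += 1
    return exceed / total


class TestPermutationTest:
    def test_identical_dense_columns_significant(self):
        rng = np.random.default_rng(9)
        col = (rng.random(50) < 0.5).astype(int)
        X = np.column_stack([col, col])
        results = assoc.permutation_test(X, plan=PermutationPlan(B=999, seed=0))
        (pair,) = results
        assert pair.perm_p <= 0.01

    def test_monte_carlo_matches_exhaustive_enumeration(self):
        X = np.array([[1, 1], [1, 1], [0, 0], [0, 1]])
        exact = exhaustive_permutation_p(X, 0, 1)
        results = assoc.permutation_test(
            X, plan=PermutationPlan(B=10_000, seed=1)
        )
        assert abs(results[0].perm_p - exact) < 0.02

    def test_null_perm_p_calibration(self):
        rng = np.random.default_rng(10)
        ps = []
        for rep in range(30):
            X = (rng.random((40, 4)) < 0.5).astype(int)
            results = assoc.permutation_test(
                X, plan=PermutationPlan(B=200, seed=rep)
            )
            ps.extend(r.perm_p for r in results if r.testable)
        ps = np.array(ps)
        assert 0.35 < ps.mean() < 0.65
        assert (ps <= 0.05).mean() <= 0.10

    def test_untestable_pairs_skipped(self):
        X = np.array([[1, 0], [1, 0], [1, 0], [1, 0]])
        results = assoc.permutation_test(X, plan=PermutationPlan(B=10, seed=0))
        assert not results[0].testable
        assert np.isnan(results[0].perm_p)

    def test_perm_fdr_monotone_in_z(self):
        rng = np.random.default_rng(11)
        X, _ = _planted_matrix(rng, n=150, k=10, n_pairs=2)
        results = assoc.permutation_test(X, plan=PermutationPlan(B=300, seed=3))
        testable = sorted(
            (r for r in results if r.testable), key=lambda r: -abs(r.z)
        )
        fdrs = [r.perm_fdr for r in testable]
        assert all(a <= b + 1e-12 for a, b in zip(fdrs, fdrs[1:]))


def _planted_matrix(rng, n, k, n_pairs, odds_ratio=5.0):
    from cnakit.simulate import simulate_planted_matrix

    freqs = rng.uniform(0.2, 0.4, k)
    pairs = [(2 * i, 2 * i + 1, odds_ratio) for i in range(n_pairs)]
    return simulate_planted_matrix(n, k, pairs, freqs,
                                   seed=int(rng.integers(2**31)))


class TestReplicate:
    def test_identical_result_sets(self):
        rng = np.random.default_rng(12)
        X, planted = _planted_matrix(rng, 300, 8, 2)
        results = assoc.all_pairs(X)
        common = assoc.replicate(results, results)
        selected = {(r.i, r.j) for r in assoc.select(results)}
        assert {(i, j) for i, j, _ in common} == selected

    def test_disjoint_selections_empty(self):
        rng = np.random.default_rng(13)
        X1, _ = _planted_matrix(rng, 300, 8, 1)
        X2 = X1.copy()
        X2[:, :2] = (rng.random((300, 2)) < 0.3).astype(int)  # kill the signal
        X2[:, 6:] = X1[:, :2]
        r1 = assoc.all_pairs(X1)
        r2 = assoc.all_pairs(X2)
        common = assoc.replicate(r1, r2)
        assert all((i, j) != (0, 1) or d != "positive" for i, j, d in common) \
            or common == []

    def test_mismatched_universe_error(self):
        rng = np.random.default_rng(14)
        X, _ = _planted_matrix(rng, 100, 6, 1)
        results = assoc.all_pairs(X)
        with pytest.raises(ValueError, match="universe"):
            assoc.replicate(results, results,
                            labels_test=["a", "b"], labels_validation=["a", "c"])

    def test_split_cohort_recovers_planted_pairs(self):
        rng = np.random.default_rng(15)
        X, planted = _planted_matrix(rng, 800, 10, 3, odds_ratio=6.0)
        half = 400
        r1 = assoc.all_pairs(X[:half])
        r2 = assoc.all_pairs(X[half:])
        common = {(i, j) for i, j, d in assoc.replicate(r1, r2)
                  if d == "positive"}
        assert set(planted) <= common


class TestMethodAgreement:
    def test_identical(self):
        assert assoc.method_agreement({(0, 1)}, {(0, 1)})["jaccard"] == 1.0

    def test_disjoint(self):
        assert assoc.method_agreement({(0, 1)}, {(2, 3)})["jaccard"] == 0.0

    def test_partial(self):
        out = assoc.method_agreement({1, 2, 3}, {2, 3, 4})
        assert out["jaccard"] == pytest.approx(0.5)
        assert out["frac_of_a"] == pytest.approx(2 / 3)

    def test_both_empty(self):
        assert assoc.method_agreement(set(), set())["jaccard"] == 1.0
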