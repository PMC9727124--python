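import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from immunoclass.io import ExpressionMatrix, GeneSignature, SignatureCollection
from immunoclass.stats import (
    benjamini_hochberg,
    differential_expression,
    fisher_exact_association,
    hypergeometric_ora,
    kruskal_wallis_by_class,
    logistic_lrt_comparison,
    preranked_gsea,
)


class TestBenjaminiHochberg:
    def test_hand_computed_stepup(self):
        assert np.allclose(benjamini_hochberg([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_all_ones_unchanged(self):
        assert np.allclose(benjamini_hochberg([1.0, 1.0, 1.0]), 1.0)

    def test_single_p_unchanged(self):
        assert benjamini_hochberg([0.2])[0] == 0.2

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.1, 1.5])
        with pytest.raises(ValueError):
            benjamini_hochberg([])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=20))
    def test_monotone_and_bounded(self, ps):
        adj = benjamini_hochberg(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-15)
        assert np.all(adj <= 1.0)
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-12)  # order-preserving on sorted p

    def test_fixed_points(self):
        # constant vectors are fixed points of the step-up adjustment
        for vec in ([1.0, 1.0, 1.0], [0.5, 0.5], [0.0]):
            assert np.allclose(benjamini_hochberg(vec), vec)


def _kw_h_bruteforce(groups):
    """Tie-corrected H from first principles (rank sums)."""
    flat = np.concatenate(groups)
    ranks = sps.rankdata(flat)
    n = len(flat)
    start, h = 0, 0.0
    for g in groups:
        r = ranks[start:start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(flat, return_counts=True)
    tie = 1 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / tie


class TestKruskalWallis:
    def test_matches_bruteforce_rank_computation(self):
        values = pd.Series(
            {"a1": 1.0, "a2": 2.0, "a3": 3.0, "b1": 10.0, "b2": 11.0, "b3": 12.0}
        )
        classes = {s: s[0] for s in values.index}
        (res,) = kruskal_wallis_by_class(values, classes)
        expected_h = _kw_h_bruteforce([np.array([1.0, 2, 3]), np.array([10.0, 11, 12])])
        assert res.statistic == pytest.approx(expected_h)
        assert res.group_medians == {"a": 2.0, "b": 11.0}

    def test_exact_permutation_agreement_two_groups(self, rng):
        """Chi-square p close to the exhaustive permutation p at n=8 per group."""
        x = rng.normal(size=8)
        y = rng.normal(0.8, 1, size=8)
        values = pd.Series(np.concatenate([x, y]), index=[f"s{i}" for i in range(16)])
        classes = {f"s{i}": ("a" if i < 8 else "b") for i in range(16)}
        (res,) = kruskal_wallis_by_class(values, classes)
        flat = values.to_numpy()
        count = 0
        total = 0
        for comb in itertools.combinations(range(16), 8):
            mask = np.zeros(16, dtype=bool)
            mask[list(comb)] = True
            h = _kw_h_bruteforce([flat[mask], flat[~mask]])
            total += 1
            if h >= res.statistic - 1e-12:
                count += 1
        exact_p = count / total
        assert abs(res.p - exact_p) < 0.03

    def test_identical_values_give_zero_statistic(self):
        values = pd.Series({"a": 1.0, "b": 1.0, "c": 1.0, "d": 1.0})
        classes = {"a": "x", "b": "x", "c": "y", "d": "y"}
        (res,) = kruskal_wallis_by_class(values, classes)
        assert res.statistic == 0.0 and res.p == 1.0

    def test_class_relabeling_invariance(self, rng):
        vals = pd.DataFrame(
            rng.normal(size=(3, 12)), index=list("fgh"),
            columns=[f"s{i}" for i in range(12)],
        )
        classes = {f"s{i}": f"c{i % 3}" for i in range(12)}
        renamed = {s: {"c0": "z2", "c1": "z0", "c2": "z1"}[c] for s, c in classes.items()}
        r1 = kruskal_wallis_by_class(vals, classes)
        r2 = kruskal_wallis_by_class(vals, renamed)
        assert [r.statistic for r in r1] == [r.statistic for r in r2]

    def test_empty_class_dropped_then_error_if_one_left(self):
        # class "y" has no matched sample: dropped with warning, then only one
        # class remains -> error
        values = pd.Series({"a": 1.0, "b": 2.0})
        with pytest.warns(UserWarning, match="y"):
            with pytest.raises(ValueError, match="2 non-empty"):
                kruskal_wallis_by_class(values, {"a": "x", "b": "x", "zz": "y"})


def log2_matrix(arr, prefix="g"):
    genes = [f"{prefix}{i}" for i in range(arr.shape[0])]
    cols = [f"s{i}" for i in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=cols), "log2norm")


class TestDifferentialExpression:
    def test_identical_gene_is_null(self, rng):
        arr = rng.normal(size=(3, 8))
        arr[0] = 1.0
        m = log2_matrix(arr)
        res = differential_expression(m, [f"s{i}" for i in range(4)], [f"s{i}" for i in range(4, 8)])
        assert res[0].log2fc == 0.0 and res[0].p == 1.0

    def test_label_swap_antisymmetry(self, rng):
        arr = rng.normal(size=(20, 10))
        m = log2_matrix(arr)
        a = [f"s{i}" for i in range(5)]
        b = [f"s{i}" for i in range(5, 10)]
        r1 = differential_expression(m, a, b)
        r2 = differential_expression(m, b, a)
        for x, y in zip(r1, r2):
            assert x.log2fc == pytest.approx(-y.log2fc)
            assert x.p == pytest.approx(y.p)

    def test_overlapping_groups_rejected(self, rng):
        m = log2_matrix(rng.normal(size=(3, 6)))
        with pytest.raises(ValueError, match="overlap"):
            differential_expression(m, ["s0", "s1"], ["s1", "s2"])

    def test_planted_shift_recovered(self, rng):
        n_genes, n_planted = 400, 40
        arr = rng.normal(5, 1, size=(n_genes, 30))
        arr[:n_planted, 15:] += 2.0
        m = log2_matrix(arr)
        a = [f"s{i}" for i in range(15)]
        b = [f"s{i}" for i in range(15, 30)]
        res = differential_expression(m, a, b)
        called = {r.gene for r in res if r.significant}
        planted = {f"g{i}" for i in range(n_planted)}
        sens = len(called & planted) / n_planted
        fdr = len(called - planted) / max(1, len(called))
        assert sens >= 0.95
        assert fdr <= 0.05


class TestHypergeometricORA:
    def test_closed_form_full_overlap(self):
        universe = {f"g{i}" for i in range(20)}
        hits = {f"g{i}" for i in range(5)}
        sets = SignatureCollection([GeneSignature("top5", "hallmark", frozenset(hits))])
        (res,) = hypergeometric_ora(hits, universe, sets)
        assert res.overlap_k == 5
        assert res.p == pytest.approx(1.0 / math.comb(20, 5))

    def test_zero_overlap_is_p_one(self):
        universe = {f"g{i}" for i in range(20)}
        hits = {"g0", "g1"}
        sets = SignatureCollection(
            [GeneSignature("other", "hallmark", frozenset({"g10", "g11"}))]
        )
        (res,) = hypergeometric_ora(hits, universe, sets)
        assert res.p == 1.0

    def test_disjoint_set_dropped(self):
        universe = {"g0", "g1"}
        sets = SignatureCollection(
            [
                GeneSignature("in", "hallmark", frozenset({"g0"})),
                GeneSignature("out", "hallmark", frozenset({"zz"})),
            ]
        )
        with pytest.warns(UserWarning, match="out"):
            res = hypergeometric_ora({"g0"}, universe, sets)
        assert [r.set_name for r in res] == ["in"]


def _unweighted_ks_bruteforce(order_hits):
    """Classic running-sum max deviation with uniform steps."""
    nh = sum(order_hits)
    nm = len(order_hits) - nh
    running, best = 0.0, 0.0
    for h in order_hits:
        running += 1.0 / nh if h else -1.0 / nm
        if abs(running) > abs(best):
            best = running
    return best


class TestPrerankedGsea:
    def _sets(self, names_genes):
        return SignatureCollection(
            [GeneSignature(n, "hallmark", frozenset(g)) for n, g in names_genes]
        )

    def test_top_block_scores_positive_and_extreme(self, rng):
        stats = pd.Series({f"g{i}": 50 - i + rng.normal(0, 1e-6) for i in range(50)})
        top = [f"g{i}" for i in range(5)]
        mid = [f"g{i}" for i in range(20, 25)]
        res = preranked_gsea(stats, self._sets([("top", top), ("mid", mid)]), n_perm=200, seed=1)
        by = {r.set_name: r for r in res}
        assert by["top"].es > 0
        assert by["top"].es > by["mid"].es

    def test_zero_metric_reduces_to_unweighted_ks(self):
        stats = pd.Series({f"g{i}": 0.0 for i in range(10)})
        genes = sorted(stats.index, key=str)  # tie order: by gene id
        hits = {"g1", "g4", "g7", "g8", "g9"}
        res = preranked_gsea(
            stats,
            self._sets([("s", hits)]),
            n_perm=100,
            seed=0,
            min_size=5,
        )
        expected = _unweighted_ks_bruteforce([g in hits for g in genes])
        assert res[0].es == pytest.approx(expected)

    def test_seeded_determinism(self, rng):
        stats = pd.Series(rng.normal(size=60), index=[f"g{i}" for i in range(60)])
        sets = self._sets([("a", [f"g{i}" for i in range(0, 12)]),
                           ("b", [f"g{i}" for i in range(30, 42)])])
        r1 = preranked_gsea(stats, sets, n_perm=150, seed=42)
        r2 = preranked_gsea(stats, sets, n_perm=150, seed=42)
        assert [(r.nes, r.fdr_q) for r in r1] == [(r.nes, r.fdr_q) for r in r2]

    def test_low_permutation_count_rejected(self, rng):
        stats = pd.Series(rng.normal(size=20), index=[f"g{i}" for i in range(20)])
        with pytest.raises(ValueError, match="n_perm"):
            preranked_gsea(stats, self._sets([("a", [f"g{i}" for i in range(6)])]), n_perm=50)


def _fisher_bruteforce(table):
    """Independent fixed-margin enumeration via itertools (probability-mass rule)."""
    t = np.asarray(table, dtype=int)
    cols = t.sum(axis=0)
    r1 = t.sum(axis=1)[0]
    n = t.sum()

    def prob(row1):
        num = sum(math.lgamma(c + 1) - math.lgamma(a + 1) - math.lgamma(c - a + 1)
                  for a, c in zip(row1, cols))
        den = math.lgamma(n + 1) - math.lgamma(r1 + 1) - math.lgamma(n - r1 + 1)
        return math.exp(num - den)

    p_obs = prob(t[0])
    total = 0.0
    for row1 in itertools.product(*[range(c + 1) for c in cols]):
        if sum(row1) != r1:
            continue
        p = prob(row1)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


class TestFisherExact:
    def test_balanced_table_is_p_one(self):
        assert fisher_exact_association([[1, 1], [1, 1]]) == pytest.approx(1.0)

    def test_2x2_matches_scipy(self, rng):
        for _ in range(25):
            t = rng.integers(1, 12, size=(2, 2))
            mine = fisher_exact_association(t)
            _, ref = sps.fisher_exact(t, alternative="two-sided")
            assert mine == pytest.approx(ref, rel=1e-9)

    def test_2x3_matches_bruteforce(self):
        table = [[3, 2, 1], [1, 2, 3]]
        assert fisher_exact_association(table) == pytest.approx(_fisher_bruteforce(table))

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        st.lists(st.integers(min_value=0, max_value=6), min_size=6, max_size=6).filter(
            lambda v: sum(v) <= 30
            and sum(v[:3]) > 0
            and sum(v[3:]) > 0
            and all(v[i] + v[i + 3] > 0 for i in range(3))
        )
    )
    def test_2xk_equals_enumeration_on_small_tables(self, flat):
        table = [flat[:3], flat[3:]]
        assert fisher_exact_association(table) == pytest.approx(_fisher_bruteforce(table))

    def test_external_cohort_style_table(self):
        # responders vs non-responders x IIH-FH vs other
        table = [[8, 4], [4, 29]]
        p = fisher_exact_association(table)
        assert p == pytest.approx(_fisher_bruteforce(table))
        assert p < 0.01  # strong association in this layout

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            fisher_exact_association([[0, 0], [1, 2]])


def _logistic_loglik(beta, X, y):
    eta = X @ beta
    return float(y @ eta - np.sum(np.log1p(np.exp(eta))))


class TestLogisticLRT:
    def test_hand_dataset_matches_independent_optimizer(self):
        samples = [f"s{i}" for i in range(8)]
        response = dict(zip(samples, [0, 1, 0, 0, 1, 1, 0, 1]))
        cps = dict(zip(samples, [1.0, 2.0, 0.0, 3.0, 1.0, 4.0, 2.0, 0.0]))
        cls = dict(zip(samples, ["A", "B", "A", "B", "A", "B", "A", "B"]))
        mc = logistic_lrt_comparison(response, cps, cls)

        from scipy.optimize import minimize

        n = len(samples)
        y = np.array([response[s] for s in samples], dtype=float)
        Xn = np.column_stack([np.ones(n), [cps[s] for s in samples]])
        Xf = np.column_stack([Xn, [1.0 if cls[s] == "B" else 0.0 for s in samples]])
        ll_n = -minimize(lambda b: -_logistic_loglik(b, Xn, y), np.zeros(2), method="BFGS").fun
        ll_f = -minimize(lambda b: -_logistic_loglik(b, Xf, y), np.zeros(3), method="BFGS").fun
        assert mc.loglik_null == pytest.approx(ll_n, abs=1e-6)
        assert mc.loglik_full == pytest.approx(ll_f, abs=1e-6)
        assert mc.lr_statistic == pytest.approx(2 * (ll_f - ll_n), abs=1e-5)
        assert mc.df == 1

    def test_single_class_level_gives_null_comparison(self):
        samples = [f"s{i}" for i in range(8)]
        response = {s: i % 2 for i, s in enumerate(samples)}
        cps = {s: float(i % 5) for i, s in enumerate(samples)}
        cls = {s: "only" for s in samples}
        mc = logistic_lrt_comparison(response, cps, cls)
        assert mc.lr_statistic == 0.0 and mc.p == 1.0 and mc.df == 0

    def test_all_same_response_rejected(self):
        samples = ["a", "b"]
        with pytest.raises(ValueError):
            logistic_lrt_comparison({s: 1 for s in samples}, {s: 0.0 for s in samples},
                                    {s: "x" for s in samples})
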