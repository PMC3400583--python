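"""Permutation enrichment, KS, Fisher, shared annotation and BH FDR."""

import itertools
import math
from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fflnet import (ContingencyTable2x2, ValidationError, bh_fdr,
                    fisher_exact, gen_annotations, ks_greater,
                    permutation_target_enrichment, shared_annotation_test)


class TestPermutationEnrichment:
    UNIVERSE = {f"g{i}" for i in range(8)}

    def test_universe_equals_candidates(self):
        results, _ = permutation_target_enrichment(
            {"m1": {"g0", "g1"}}, set(self.UNIVERSE), set(self.UNIVERSE),
            n_perm=50, seed=0)
        assert results[0].empirical_p == 1.0

    def test_no_targets(self):
        results, _ = permutation_target_enrichment(
            {"m1": set()}, {"g0", "g1"}, set(self.UNIVERSE),
            n_perm=50, seed=0)
        assert results[0].observed == 0
        assert results[0].empirical_p == 1.0

    def test_candidates_outside_universe_rejected(self):
        with pytest.raises(ValidationError):
            permutation_target_enrichment({"m1": set()}, {"zzz"},
                                          set(self.UNIVERSE), 10, 0)

    def test_within_mc_error_of_exhaustive_enumeration(self):
        """8-gene universe, 4 candidates: compare the sampled empirical p
        with the exact probability over all C(8,4)=70 draws."""
        targets = {"m1": {"g0", "g1", "g2"}, "m2": {"g0", "g5"}}
        candidates = {"g0", "g1", "g2", "g3"}
        n_perm = 4000
        results, _ = permutation_target_enrichment(
            targets, candidates, set(self.UNIVERSE), n_perm=n_perm, seed=3)
        for r in results:
            obs = len(targets[r.mirna] & candidates)
            hits = sum(
                1 for draw in itertools.combinations(sorted(self.UNIVERSE), 4)
                if len(targets[r.mirna] & set(draw)) >= obs)
            exact = hits / comb(8, 4)
            se = math.sqrt(exact * (1 - exact) / n_perm)
            assert abs(r.empirical_p - exact) <= 3 * se + 2 / n_perm

    def test_reproducible_and_order_invariant(self):
        targets = {"m1": {"g0"}, "m2": {"g1", "g2"}, "m3": {"g3"}}
        kw = dict(candidates={"g0", "g1"}, universe=set(self.UNIVERSE),
                  n_perm=200, seed=9)
        r1, _ = permutation_target_enrichment(targets, **kw)
        r2, _ = permutation_target_enrichment(
            dict(reversed(list(targets.items()))), **kw)
        assert r1 == r2

    def test_paired_t_summary_present(self):
        targets = {f"m{i}": {f"g{i % 8}", f"g{(i + 1) % 8}"}
                   for i in range(6)}
        _, summary = permutation_target_enrichment(
            targets, {"g0", "g1", "g2"}, set(self.UNIVERSE), 200, 1)
        assert summary["n_mirnas"] == 6
        assert 0 <= summary["paired_t_pvalue"] <= 1


def oracle_ks_greater(a, b):
    """Direct ECDF supremum scan over the pooled sample points."""
    a, b = sorted(a), sorted(b)
    d = 0.0
    for x in a + b:
        fa = sum(v <= x for v in a) / len(a)
        fb = sum(v <= x for v in b) / len(b)
        d = max(d, fb - fa)
    mn = len(a) * len(b) / (len(a) + len(b))
    return d, min(1.0, math.exp(-2 * mn * d * d))


class TestKSGreater:
    def test_identical_samples(self):
        a = [1.0, 2.0, 5.0, 5.0]
        assert ks_greater(a, a) == (0.0, 1.0)

    def test_complete_separation(self):
        d, p = ks_greater([10, 11, 12], [1, 2, 3])
        assert d == 1.0

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_ecdf_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = list(rng.normal(0.3, 1, 20))
        b = list(rng.normal(0.0, 1, 20))
        got = ks_greater(a, b)
        exp = oracle_ks_greater(a, b)
        assert got == pytest.approx(exp, abs=1e-12)

    def test_agrees_with_scipy_one_sided_statistic(self):
        from scipy.stats import ks_2samp
        rng = np.random.default_rng(5)
        a, b = rng.normal(0.5, 1, 30), rng.normal(0, 1, 25)
        d, _ = ks_greater(a, b)
        assert d == pytest.approx(ks_2samp(a, b, alternative="less").statistic,
                                  abs=1e-12)


def oracle_fisher_greater(a, b, c, d):
    """Exact conditional tail over all tables with the observed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    def prob(x):
        return Fraction(comb(r1, x) * comb(r2, c1 - x), comb(n, c1))
    lo, hi = max(0, c1 - r2), min(r1, c1)
    return float(sum(prob(x) for x in range(a, hi + 1)))


class TestFisherExact:
    def test_maximal_anti_association(self):
        _, p = fisher_exact(ContingencyTable2x2(0, 10, 10, 0), "greater")
        assert p == 1.0

    def test_matches_margin_enumeration_oracle(self):
        _, p = fisher_exact(ContingencyTable2x2(10, 90, 1, 99), "greater")
        assert p == pytest.approx(oracle_fisher_greater(10, 90, 1, 99),
                                  abs=1e-12)

    @pytest.mark.parametrize("seed", range(8))
    def test_oracle_small_margins(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c, d = (int(x) for x in rng.integers(0, 11, size=4))
        if a + b + c + d == 0:
            a = 1
        _, p = fisher_exact(ContingencyTable2x2(a, b, c, d), "greater")
        assert p == pytest.approx(oracle_fisher_greater(a, b, c, d),
                                  abs=1e-12)

    def test_transpose_symmetry(self):
        t1 = ContingencyTable2x2(3, 7, 2, 9)
        t2 = ContingencyTable2x2(3, 2, 7, 9)  # rows and columns swapped
        assert fisher_exact(t1, "greater")[1] == \
            pytest.approx(fisher_exact(t2, "greater")[1], abs=1e-12)


class TestSharedAnnotation:
    ANN = {"a": {"T1"}, "b": {"T1"}, "c": {"T2"}, "d": {"T3"}}

    def test_perfect_separation(self):
        table, _, p = shared_annotation_test(
            [("a", "b")] * 3, [("c", "d")] * 3, self.ANN)
        assert (table.a, table.b, table.c, table.d) == (3, 0, 0, 3)
        assert p == pytest.approx(oracle_fisher_greater(3, 0, 0, 3), abs=1e-12)

    def test_identical_lists_null_result(self):
        pairs = [("a", "b"), ("c", "d"), ("a", "c")]
        _, odds, p = shared_annotation_test(pairs, pairs, self.ANN)
        assert odds == pytest.approx(1.0)
        assert p >= 0.5

    def test_unannotated_pairs_dropped(self):
        table, _, _ = shared_annotation_test(
            [("a", "b"), ("a", "zz")], [("c", "d")], self.ANN)
        assert table.a + table.b == 1

    def test_all_unannotated_rejected(self):
        with pytest.raises(ValidationError):
            shared_annotation_test([("x", "y")], [("c", "d")], self.ANN)

    def test_null_calibration_rejection_rate(self):
        """With annotations shuffled independently of the pair lists, the
        test should reject at about its nominal 5% rate."""
        ids = [f"i{k}" for k in range(40)]
        rejections = 0
        n_runs = 200
        for seed in range(n_runs):
            rng = np.random.default_rng(seed)
            obs = [tuple(rng.choice(ids, 2, replace=False)) for _ in range(30)]
            nul = [tuple(rng.choice(ids, 2, replace=False)) for _ in range(30)]
            ann = gen_annotations(ids, n_terms=5, sharing_rate=0.0, seed=seed)
            # random shared structure: assign each id one of 6 common terms
            for i in ids:
                ann[i].add(f"C{rng.integers(0, 6)}")
            _, _, p = shared_annotation_test(obs, nul, ann)
            rejections += (p < 0.05)
        # binomial 3-sigma band around 0.05 (Fisher is conservative, so the
        # lower side is unbounded)
        assert rejections / n_runs <= 0.05 + 3 * math.sqrt(0.05 * 0.95 / n_runs)


class TestBHFDR:
    def test_single_p_identity(self):
        assert bh_fdr([0.03]) == [0.03]

    def test_hand_computed_step_up(self):
        assert bh_fdr([0.01, 0.02, 0.04]) == \
            pytest.approx([0.03, 0.03, 0.04])

    def test_all_equal_fixed_point(self):
        assert bh_fdr([0.2] * 5) == pytest.approx([0.2] * 5)

    def test_out_of_range_rejected(self):
        for bad in ([0.0], [1.5], [-0.1]):
            with pytest.raises(ValidationError):
                bh_fdr(bad)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(1e-8, 1.0, exclude_min=False), min_size=1,
                    max_size=30))
    def test_monotone_and_order_preserving(self, ps):
        qs = bh_fdr(ps)
        order = np.argsort(ps, kind="stable")
        sorted_qs = np.asarray(qs)[order]
        assert all(x <= y + 1e-15 for x, y in zip(sorted_qs, sorted_qs[1:]))
        assert all(q >= p - 1e-15 for p, q in zip(ps, qs))
        assert all(0 < q <= 1 for q in qs)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(2)
        ps = rng.uniform(1e-6, 1, 40)
        assert bh_fdr(ps) == pytest.approx(
            multipletests(ps, method="fdr_bh")[1], abs=1e-12)
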