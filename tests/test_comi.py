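import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from comimod.comi import (
    MiRnaGobpPair,
    build_profile,
    comi_score,
    enumerate_pairs,
    filter_profile,
    hypergeom_tail,
)
from comimod.data_io import GeneSetCollection
from comimod.errors import DataError


def brute_force_tail(x, M, K, N):
    denom = math.comb(M, N)
    return sum(math.comb(K, i) * math.comb(M - K, N - i)
               for i in range(x, min(K, N) + 1)) / denom


class TestHypergeomTail:
    def test_module_overlap_worked_example(self):
        # 33 shared modules between sets of 55 and 98 in a universe of 347
        p = hypergeom_tail(33, M=347, K=55, N=98)
        assert f"{p:.2e}" == "6.40e-08"

    def test_zero_overlap_is_certain(self):
        assert hypergeom_tail(0, M=10, K=5, N=4) == 1.0

    def test_small_exact_ratio(self):
        assert hypergeom_tail(3, M=10, K=5, N=4) == pytest.approx(55 / 210, rel=1e-14)

    def test_below_support_minimum_is_one(self):
        # with K + N > M some overlap is forced; a tail at or below it is 1
        assert hypergeom_tail(2, M=10, K=8, N=4) == 1.0

    @pytest.mark.parametrize("args", [(-1, 10, 5, 4), (5, 10, 5, 4), (3, 10, 11, 4),
                                      (3, 10, 5, 11), (1.5, 10, 5, 4)])
    def test_out_of_range_rejected(self, args):
        with pytest.raises(ValueError):
            hypergeom_tail(*args)

    @given(st.integers(1, 200), st.data())
    def test_matches_scipy_survival_function(self, M, data):
        K = data.draw(st.integers(0, M))
        N = data.draw(st.integers(0, M))
        x = data.draw(st.integers(0, min(K, N)))
        ours = hypergeom_tail(x, M, K, N)
        ref = stats.hypergeom.sf(x - 1, M, K, N)
        assert ours == pytest.approx(ref, rel=1e-9, abs=1e-300)

    def test_monotone_in_overlap(self):
        ps = [hypergeom_tail(x, M=100, K=30, N=20) for x in range(0, 21)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


def _toy_inputs():
    genes = [f"g{i}" for i in range(10)]
    expr = pd.DataFrame(np.arange(20.0).reshape(10, 2), index=genes, columns=["s1", "s2"])
    gobp = GeneSetCollection()
    gobp.add("GO:A", genes[:4], "")          # term of size 4
    gobp.add("GO:B", genes, "")              # covers the universe
    targets = GeneSetCollection()
    targets.add("mirX", genes[:3] + genes[4:6], "")  # K=5, overlap with GO:A = 3
    return targets, gobp, expr


class TestEnumeratePairs:
    def test_intersection_below_minimum_discarded(self):
        targets, gobp, expr = _toy_inputs()
        assert enumerate_pairs(targets, gobp, expr, min_intersection=10) == []

    def test_nonsignificant_overlap_discarded(self):
        # x=3, M=10, K=5, N=4 -> p = 55/210 > 0.05, so the pair is dropped
        targets, gobp, expr = _toy_inputs()
        pairs = enumerate_pairs(targets, gobp, expr, min_intersection=3, alpha=0.05,
                                min_nontargets=1)
        assert all(p.gobp_id != "GO:A" for p in pairs)
        relaxed = enumerate_pairs(targets, gobp, expr, min_intersection=3, alpha=0.3,
                                  min_nontargets=1)
        pair_a = [p for p in relaxed if p.gobp_id == "GO:A"]
        assert len(pair_a) == 1
        assert pair_a[0].p_overlap == pytest.approx(55 / 210, rel=1e-12)
        assert pair_a[0].x == 3 and pair_a[0].K == 5 and pair_a[0].N == 4 and pair_a[0].M == 10

    def test_partition_invariant(self):
        targets, gobp, expr = _toy_inputs()
        pairs = enumerate_pairs(targets, gobp, expr, min_intersection=3, alpha=0.3)
        for p in pairs:
            assert not (p.in_term_targets & p.in_term_nontargets)
            assert len(p.in_term_targets) + len(p.in_term_nontargets) == p.N

    def test_member_order_irrelevant(self):
        targets, gobp, expr = _toy_inputs()
        shuffled = GeneSetCollection()
        for sid in targets:
            shuffled.add(sid, list(reversed(targets.members(sid))), "")
        a = enumerate_pairs(targets, gobp, expr, min_intersection=3, alpha=0.3)
        b = enumerate_pairs(shuffled, gobp, expr, min_intersection=3, alpha=0.3)
        assert [(p.key, p.p_overlap) for p in a] == [(p.key, p.p_overlap) for p in b]

    def test_min_nontargets_guard(self):
        targets, gobp, expr = _toy_inputs()
        # GO:B (the whole universe) minus mirX targets leaves 5 genes; demanding
        # more non-targets than that kills the pair
        pairs = enumerate_pairs(targets, gobp, expr, min_intersection=3, alpha=1.0,
                                min_nontargets=6)
        assert all(p.gobp_id != "GO:B" for p in pairs)

    def test_empty_inputs_rejected(self):
        targets, gobp, expr = _toy_inputs()
        with pytest.raises(DataError):
            enumerate_pairs(GeneSetCollection(), gobp, expr)
        with pytest.raises(DataError):
            enumerate_pairs(targets, gobp, expr.iloc[:0])


def _pair(targets, nontargets):
    return MiRnaGobpPair(
        mirna_id="m", gobp_id="t",
        in_term_targets=frozenset(targets),
        in_term_nontargets=frozenset(nontargets),
        K=len(targets), N=len(targets) + len(nontargets), M=100, p_overlap=0.01,
    )


class TestComiScore:
    def _expr(self, values):
        genes = [f"g{i}" for i in range(len(values))]
        return pd.DataFrame({"s1": values}, index=genes), genes

    def test_hand_worked_value(self):
        expr, genes = self._expr([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        pair = _pair(genes[:3], genes[3:])
        assert comi_score(expr, pair, "s1") == pytest.approx(-3 / math.sqrt(2 / 3), rel=1e-12)

    def test_identical_groups_score_zero(self):
        expr, genes = self._expr([2.0, 5.0, 9.0, 2.0, 5.0, 9.0])
        pair = _pair(genes[:3], genes[3:])
        assert comi_score(expr, pair, "s1") == 0.0

    def test_swapping_groups_flips_sign(self):
        expr, genes = self._expr([1.0, 4.0, 2.0, 8.0, 3.0, 7.0])
        fwd = comi_score(expr, _pair(genes[:3], genes[3:]), "s1")
        rev = comi_score(expr, _pair(genes[3:], genes[:3]), "s1")
        assert fwd == -rev

    def test_matches_welch_t(self, rng):
        for _ in range(100):
            n, m = rng.integers(3, 30, size=2)
            a = rng.normal(size=n)
            b = rng.normal(size=m)
            expr = pd.DataFrame({"s1": np.concatenate([a, b])},
                                index=[f"g{i}" for i in range(n + m)])
            pair = _pair(list(expr.index[:n]), list(expr.index[n:]))
            ref = stats.ttest_ind(a, b, equal_var=False).statistic
            assert comi_score(expr, pair, "s1") == pytest.approx(ref, rel=1e-10)


class TestBuildProfile:
    def test_shape_and_orientation(self, rng):
        genes = [f"g{i}" for i in range(8)]
        expr = pd.DataFrame(rng.normal(size=(8, 3)), index=genes,
                            columns=["s1", "s2", "s3"])
        pairs = [_pair(genes[:3], genes[3:6]), _pair(genes[2:5], genes[5:])]
        prof = build_profile(expr, pairs)
        assert prof.shape == (2, 3)
        assert list(prof.columns) == ["s1", "s2", "s3"]

    def test_degenerate_pair_dropped(self, rng):
        genes = [f"g{i}" for i in range(8)]
        expr = pd.DataFrame(rng.normal(size=(8, 2)), index=genes, columns=["s1", "s2"])
        good = _pair(genes[:3], genes[3:6])
        degenerate = _pair(genes[:1], genes[3:6])  # single target: no variance
        prof = build_profile(expr, [good, degenerate])
        assert prof.shape[0] == 1

    def test_sample_permutation_permutes_columns(self, rng):
        genes = [f"g{i}" for i in range(8)]
        expr = pd.DataFrame(rng.normal(size=(8, 4)), index=genes,
                            columns=list("abcd"))
        pairs = [_pair(genes[:3], genes[3:])]
        prof = build_profile(expr, pairs)
        shuffled = build_profile(expr[["c", "a", "d", "b"]], pairs)
        assert np.array_equal(shuffled[list("abcd")].to_numpy(), prof.to_numpy())

    def test_all_degenerate_rejected(self, rng):
        genes = [f"g{i}" for i in range(4)]
        expr = pd.DataFrame(rng.normal(size=(4, 2)), index=genes, columns=["s1", "s2"])
        with pytest.raises(DataError):
            build_profile(expr, [_pair(genes[:1], genes[1:])])


def _profile(values):
    arr = np.asarray(values, float)
    idx = pd.MultiIndex.from_tuples([(f"m{i}", f"t{i}") for i in range(arr.shape[0])],
                                    names=["mirna_id", "gobp_id"])
    return pd.DataFrame(arr, index=idx, columns=[f"s{j}" for j in range(arr.shape[1])])


class TestFilterProfile:
    def test_drops_floor_fraction_lowest_variance(self, rng):
        rows = [np.full(4, 1.0), np.full(4, 2.0)]  # two zero-variance rows
        rows += [rng.normal(scale=s, size=4) for s in range(1, 19)]
        prof = _profile(rows)
        out = filter_profile(prof, drop_fraction=0.10)
        assert out.shape[0] == 18
        assert ("m0", "t0") not in out.index and ("m1", "t1") not in out.index

    def test_duplicate_rows_keep_first(self):
        base = [1.0, 5.0, 2.0, 8.0]
        prof = _profile([base, [0.0, 9.0, 1.0, 3.0], base])
        out = filter_profile(prof, drop_fraction=0.0)
        assert list(out.index) == [("m0", "t0"), ("m1", "t1")]

    def test_variance_tie_drops_later_row(self):
        same = [0.0, 1.0, 0.0, 1.0]
        prof = _profile([same, [v * 10 for v in same], [0.0, 5.0, 2.0, 7.0],
                         [1.0, 2.0, 1.0, 2.0]])
        # rows 0 and 3 tie on the smallest variance; only one is dropped and
        # the earlier row (0) survives
        out = filter_profile(prof, drop_fraction=0.25)
        assert ("m0", "t0") in out.index and ("m3", "t3") not in out.index

    def test_dedup_is_idempotent(self, rng):
        values = rng.normal(size=(10, 5))
        values[4] = values[1]
        prof = _profile(values)
        once = filter_profile(prof, drop_fraction=0.0)
        twice = filter_profile(once, drop_fraction=0.0)
        assert once.equals(twice)

    @given(st.integers(0, 9))
    def test_never_grows(self, n_extra):
        rng = np.random.default_rng(n_extra)
        prof = _profile(rng.normal(size=(5 + n_extra, 4)))
        assert filter_profile(prof, 0.10).shape[0] <= prof.shape[0]

    def test_bad_fraction_rejected(self):
        prof = _profile(np.ones((3, 3)))
        for bad in (-0.1, 1.0, 1.5):
            with pytest.raises(DataError):
                filter_profile(prof, bad)
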