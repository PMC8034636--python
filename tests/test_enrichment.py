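"""Enrichment statistics: exact tests, fold enrichment, feature profiles,
relative difference and contact-level similarity comparisons.

The exact tests are checked against independent oracles: the Fisher p-value
against an exhaustive rational-arithmetic hypergeometric enumeration, the
small-sample Mann-Whitney p against full enumeration of rank assignments.
"""

import math
from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest

from complexome.enrichment import (
    contact_similarity_comparison,
    feature_profile,
    fisher_exact_2x2,
    mannwhitney_two_sided,
    relative_difference,
    relative_difference_comparison,
    standard_enrichment,
)
from complexome.io import ComplexDataset, ComplexRecord, Member
from complexome.pairs import PairSet

from conftest import make_dataset


def fisher_oracle(a, b, c, d):
    """Exact two-sided Fisher p by rational hypergeometric enumeration."""
    N, r1, c1 = a + b + c + d, a + b, a + c
    r2 = N - r1
    lo, hi = max(0, c1 - r2), min(r1, c1)
    denom = comb(N, c1)
    pmf = {
        x: Fraction(comb(r1, x) * comb(r2, c1 - x), denom) for x in range(lo, hi + 1)
    }
    return float(sum(p for p in pmf.values() if p <= pmf[a]))


def mwu_oracle_p(a, b):
    """Two-sided Mann-Whitney p by enumeration of all group assignments."""
    pooled = sorted(a + b)
    assert len(set(pooled)) == len(pooled), "oracle assumes no ties"
    rank = {v: i + 1 for i, v in enumerate(pooled)}
    n = len(a)

    def u_of(sample):
        r = sum(rank[v] for v in sample)
        return r - n * (n + 1) / 2

    u_obs = u_of(a)
    mean_u = n * len(b) / 2
    dev_obs = abs(u_obs - mean_u)
    total = hits = 0
    for group in combinations(pooled, n):
        total += 1
        if abs(u_of(group) - mean_u) >= dev_obs - 1e-12:
            hits += 1
    return hits / total


class TestFisherExact:
    @pytest.mark.parametrize(
        "table, odds, p",
        [
            (((3, 1), (1, 3)), 9.0, 17 / 35),  # oracle: 34/70
            (((5, 0), (0, 5)), math.inf, 2 / 252),
            (((2, 2), (2, 2)), 1.0, 1.0),
        ],
    )
    def test_reference_tables(self, table, odds, p):
        (a, b), (c, d) = table
        assert fisher_oracle(a, b, c, d) == pytest.approx(p, abs=1e-12)
        got_odds, got_p = fisher_exact_2x2(table)
        assert got_odds == odds
        assert got_p == pytest.approx(p, abs=1e-10)

    def test_agrees_with_enumeration_on_random_tables(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 15, size=4)
            if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                continue
            _, p = fisher_exact_2x2(((a, b), (c, d)))
            assert p == pytest.approx(fisher_oracle(a, b, c, d), abs=1e-10)

    @pytest.mark.parametrize(
        "table", [((0, 0), (1, 2)), ((1, 0), (2, 0)), ((-1, 2), (3, 4))]
    )
    def test_degenerate_tables_raise(self, table):
        with pytest.raises(ValueError):
            fisher_exact_2x2(table)


class TestStandardEnrichment:
    def test_fold_arithmetic(self):
        co = PairSet("co", {(f"a{i}", f"b{i}") for i in range(10)})
        bg = PairSet("bg", {(f"c{i}", f"d{i}") for i in range(100)})
        std = PairSet("std", set(sorted(co.pairs)[:6]) | set(sorted(bg.pairs)[:6]))
        universe = co.pairs | bg.pairs
        res = standard_enrichment(co, bg, std, universe)
        assert res.fraction_cocomplex == pytest.approx(0.6)
        assert res.fraction_background == pytest.approx(0.06)
        assert res.fold == pytest.approx(10.0)
        assert res.contingency == ((6, 4), (6, 94))

    def test_standard_equal_universe_gives_fold_one(self):
        co = PairSet("co", {("a", "b")})
        bg = PairSet("bg", {("c", "d"), ("e", "f")})
        universe = co.pairs | bg.pairs
        res = standard_enrichment(co, bg, PairSet("std", set(universe)), universe)
        assert res.fraction_cocomplex == res.fraction_background == 1.0
        assert res.fold == 1.0

    def test_overlapping_groups_rejected(self):
        co = PairSet("co", {("a", "b")})
        bg = PairSet("bg", {("a", "b")})
        with pytest.raises(ValueError, match="overlap"):
            standard_enrichment(co, bg, PairSet("s", set()), co.pairs)

    def test_empty_restricted_group_raises(self):
        co = PairSet("co", {("a", "b")})
        bg = PairSet("bg", {("c", "d")})
        with pytest.raises(ValueError, match="co-complex"):
            standard_enrichment(co, bg, PairSet("s", set()), {("c", "d")})

    def test_fold_stable_under_universe_subsampling(self):
        # in expectation, uniform subsampling of the universe leaves fold unchanged
        rng = np.random.default_rng(11)
        co = PairSet("co", {(f"a{i:04d}", f"b{i:04d}") for i in range(2000)})
        bg = PairSet("bg", {(f"c{i:04d}", f"d{i:04d}") for i in range(8000)})
        std_pairs = {p for p in co.pairs if rng.random() < 0.4} | {
            p for p in bg.pairs if rng.random() < 0.1
        }
        std = PairSet("std", std_pairs)
        full = standard_enrichment(co, bg, std, co.pairs | bg.pairs)
        universe = sorted(co.pairs | bg.pairs)
        sub = {p for p in universe if rng.random() < 0.5}
        half = standard_enrichment(co, bg, std, sub)
        assert half.fold == pytest.approx(full.fold, rel=0.15)


class TestFeatureProfile:
    def test_member_at_background_median_has_zero_z(self):
        bg_vals = {f"b{i}": v for i, v in enumerate([1.0, 2.0, 3.0, 4.0, 5.0])}
        df = pd.DataFrame({"f": {**bg_vals, "m1": 3.0, "m2": 3.0}})
        prof = feature_profile(df, {"m1", "m2"}, set(bg_vals))
        assert prof.numeric["f"]["median_z"] == pytest.approx(0.0)

    def test_z_unit_when_one_sd_above_median(self):
        # background {1..5}: median 3, sample sd sqrt(2.5)
        bg = [1.0, 2.0, 3.0, 4.0, 5.0]
        sd = math.sqrt(sum((v - 3) ** 2 for v in bg) / 4)
        df = pd.DataFrame(
            {"f": {**{f"b{i}": v for i, v in enumerate(bg)}, "m": 3.0 + sd}}
        )
        prof = feature_profile(df, {"m"}, {f"b{i}" for i in range(5)})
        assert prof.numeric["f"]["median_z"] == pytest.approx(1.0)

    def test_binary_fold_enrichment(self):
        members = {f"m{i}": float(i < 4) for i in range(10)}  # 40% flagged
        bg = {f"b{i}": float(i < 4) for i in range(20)}  # 20% flagged
        df = pd.DataFrame({"flag": {**members, **bg}})
        prof = feature_profile(
            df, set(members), set(bg), kinds={"flag": "binary"}
        )
        assert prof.binary["flag"]["fold"] == pytest.approx(2.0)

    def test_zero_background_spread_skipped_with_warning(self):
        df = pd.DataFrame({"f": {"b1": 2.0, "b2": 2.0, "m": 5.0}})
        with pytest.warns(UserWarning, match="spread"):
            prof = feature_profile(df, {"m"}, {"b1", "b2"})
        assert "f" not in prof.numeric

    def test_z_scores_invariant_under_affine_transform(self):
        rng = np.random.default_rng(3)
        vals = {f"p{i}": float(v) for i, v in enumerate(rng.normal(5, 2, size=40))}
        members = {k for i, k in enumerate(vals) if i < 10}
        bg = set(vals) - members
        df1 = pd.DataFrame({"f": vals})
        df2 = pd.DataFrame({"f": {k: 3.0 * v + 7.0 for k, v in vals.items()}})
        p1 = feature_profile(df1, members, bg)
        p2 = feature_profile(df2, members, bg)
        assert p1.numeric["f"]["median_z"] == pytest.approx(
            p2.numeric["f"]["median_z"]
        )
        assert p1.numeric["f"]["p_value"] == pytest.approx(p2.numeric["f"]["p_value"])

    def test_overlapping_groups_rejected(self):
        df = pd.DataFrame({"f": {"x": 1.0, "y": 2.0}})
        with pytest.raises(ValueError):
            feature_profile(df, {"x"}, {"x", "y"})


class TestRelativeDifference:
    @pytest.mark.parametrize(
        "va, vb, expected", [(10.0, 5.0, 0.5), (7.0, 7.0, 0.0), (1.0, 0.0, 1.0)]
    )
    def test_values(self, va, vb, expected):
        scores = relative_difference(
            PairSet("x", {("a", "b")}), {"a": va, "b": vb}
        )
        assert scores[("a", "b")] == pytest.approx(expected)

    def test_zero_zero_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="zero"):
            scores = relative_difference(
                PairSet("x", {("a", "b")}), {"a": 0.0, "b": 0.0}
            )
        assert scores == {}

    def test_missing_values_excluded(self):
        scores = relative_difference(
            PairSet("x", {("a", "b"), ("a", "c")}), {"a": 1.0, "b": 2.0}
        )
        assert set(scores) == {("a", "b")}

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            relative_difference(PairSet("x", {("a", "b")}), {"a": -1.0, "b": 2.0})

    def test_scale_invariance(self):
        rng = np.random.default_rng(5)
        values = {f"p{i}": float(v) for i, v in enumerate(rng.uniform(0.1, 10, 20))}
        ps = PairSet(
            "x", set(combinations(sorted(values), 2))
        )
        s1 = relative_difference(ps, values)
        s2 = relative_difference(ps, {k: 13.7 * v for k, v in values.items()})
        for p in s1:
            assert s1[p] == pytest.approx(s2[p])

    def test_group_comparison_reports_rank_test(self):
        co = PairSet("co", {("a", "b"), ("c", "d")})
        bg = PairSet("bg", {("e", "f"), ("g", "h")})
        values = {"a": 10, "b": 9, "c": 8, "d": 7.5, "e": 10, "f": 1, "g": 8, "h": 2}
        res = relative_difference_comparison(co, bg, values)
        assert res["median_cocomplex"] < res["median_background"]
        assert 0 <= res["p_value"] <= 1


class TestMannWhitney:
    def test_identical_samples(self):
        u, p = mannwhitney_two_sided([1, 2, 3], [1, 2, 3])
        assert u == pytest.approx(4.5)  # n^2/2
        assert p == pytest.approx(1.0)

    def test_complete_separation_small_n(self):
        u, p = mannwhitney_two_sided([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)  # oracle: 2 / C(6,3)
        assert mwu_oracle_p([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_agrees_with_enumeration_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            a = list(rng.permutation(100)[:4].astype(float))
            b = list(rng.permutation(100)[4:9].astype(float) + 0.5)
            _, p = mannwhitney_two_sided(a, b)
            assert p == pytest.approx(mwu_oracle_p(a, b), abs=1e-12)

    def test_all_tied_warns_p_one(self):
        with pytest.warns(UserWarning, match="tied"):
            _, p = mannwhitney_two_sided([2.0, 2.0], [2.0])
        assert p == 1.0

    def test_single_element_equal_samples(self):
        with pytest.warns(UserWarning):
            _, p = mannwhitney_two_sided([1.0], [1.0])
        assert p == 1.0

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            mannwhitney_two_sided([], [1.0])


def contact_dataset(sims_by_class):
    """Two triangles with one annotated contact each, plus similarity map."""
    recs = []
    for cid, members in (("C1", "ABC"), ("C2", "DEF")):
        ms = [Member(m, "protein") for m in members]
        contacts = {frozenset((members[0], members[1]))}
        recs.append(ComplexRecord(cid, ms, contacts=contacts))
    ds = ComplexDataset("cd", recs)
    direct = [("A", "B"), ("D", "E")]
    indirect = [("A", "C"), ("B", "C"), ("D", "F"), ("E", "F")]
    background = [
        (a, b)
        for a in "ABC"
        for b in "DEF"
    ]
    sims = {}
    for cls, pairs in (("direct", direct), ("indirect", indirect), ("background", background)):
        for i, (a, b) in enumerate(pairs):
            sims[tuple(sorted((a, b)))] = sims_by_class[cls](i)
    return ds, sims


class TestContactSimilarity:
    def test_pair_classification(self):
        ds, sims = contact_dataset(
            {"direct": lambda i: 0.5, "indirect": lambda i: 0.3, "background": lambda i: 0.1}
        )
        res = contact_similarity_comparison(ds, sims)
        assert res["n_complexes_selected"] == 2
        assert len(res["distributions"]["direct"]) == 2
        assert len(res["distributions"]["indirect"]) == 4
        assert len(res["distributions"]["background"]) == 9

    def test_identical_similarities_no_separation(self):
        ds, sims = contact_dataset(
            {"direct": lambda i: 0.2, "indirect": lambda i: 0.2, "background": lambda i: 0.2}
        )
        with pytest.warns(UserWarning):
            res = contact_similarity_comparison(ds, sims)
        assert all(p == 1.0 for p in res["p_values"].values())

    def test_planted_ordering_recovered(self):
        ds, sims = contact_dataset(
            {
                "direct": lambda i: 0.5 + 0.01 * i,
                "indirect": lambda i: 0.3 + 0.01 * i,
                "background": lambda i: 0.1 + 0.01 * i,
            }
        )
        res = contact_similarity_comparison(ds, sims)
        m = res["medians"]
        assert m["direct"] > m["indirect"] > m["background"]

    def test_no_eligible_complex_raises(self):
        ds = ComplexDataset(
            "x", [ComplexRecord("C1", [Member("A"), Member("B")])]
        )
        with pytest.raises(ValueError, match="size"):
            contact_similarity_comparison(ds, {})
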