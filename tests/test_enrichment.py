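from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from declust.enrichment import (
    bh_adjust,
    compare_regulons,
    contingency,
    enrich_gene_sets,
    fisher_exact,
)
from declust.model import ContingencyTable, DEStatus, GeneSet, ThresholdConfig
from oracles import bh_formula, fisher_enumeration

UP, DOWN, NS = DEStatus.UP, DEStatus.DOWN, DEStatus.NOT_SIGNIFICANT


class TestFisher:
    def test_closed_form_one_sided(self):
        # all 3 DE genes inside a 3-gene set over a universe of 6:
        # C(3,3)*C(3,0)/C(6,3) = 1/20
        p = fisher_exact(ContingencyTable(3, 0, 0, 3), "greater")
        assert p == pytest.approx(0.05, abs=1e-12)

    def test_no_de_in_set_one_sided(self):
        assert fisher_exact(ContingencyTable(0, 5, 4, 6), "greater") == 1.0

    def test_all_zero_table_warns_p1(self):
        with pytest.warns(UserWarning, match="all-zero"):
            assert fisher_exact(ContingencyTable(0, 0, 0, 0)) == 1.0

    @pytest.mark.parametrize("alternative", ["two-sided", "greater"])
    def test_matches_enumeration_oracle(self, alternative):
        rng = np.random.default_rng(17)
        for _ in range(300):
            a, b, c, d = (int(x) for x in rng.integers(0, 7, size=4))
            if a + b + c + d == 0:
                continue
            got = fisher_exact(ContingencyTable(a, b, c, d), alternative)
            assert got == pytest.approx(
                fisher_enumeration(a, b, c, d, alternative), abs=1e-12
            )

    def test_greater_monotone_in_enrichment(self):
        # move one DE gene into the set while holding all margins fixed
        previous = 1.1
        for a in range(0, 6):
            p = fisher_exact(ContingencyTable(a, 5 - a, 5 - a, 5 + a), "greater")
            assert p <= previous + 1e-15
            previous = p

    def test_unknown_alternative_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact(ContingencyTable(1, 1, 1, 1), "less")


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_textbook_example(self):
        # p_i * 4 / i = 0.04 at every rank
        got = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert got == pytest.approx([0.04, 0.04, 0.04, 0.04], abs=1e-12)

    def test_matches_direct_formula_on_random_vectors(self):
        rng = np.random.default_rng(23)
        for _ in range(100):
            p = rng.uniform(0, 1, size=int(rng.integers(1, 40)))
            assert bh_adjust(p) == pytest.approx(bh_formula(p), abs=1e-12)

    def test_adjusted_dominates_raw_and_is_capped(self):
        rng = np.random.default_rng(29)
        p = rng.uniform(0, 1, size=200)
        q = bh_adjust(p)
        assert np.all(q >= p) and np.all(q <= 1.0)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(31)
        p = rng.uniform(0, 1, size=50)
        perm = rng.permutation(50)
        assert bh_adjust(p[perm]) == pytest.approx(bh_adjust(p)[perm])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.5])


def build_statuses(n_up, n_down, n_ns, prefix=""):
    statuses = {}
    for i in range(n_up):
        statuses[f"{prefix}u{i}"] = UP
    for i in range(n_down):
        statuses[f"{prefix}d{i}"] = DOWN
    for i in range(n_ns):
        statuses[f"{prefix}n{i}"] = NS
    return statuses


class TestEnrichGeneSets:
    def worked_example(self, set_size, n_down, n_up, universe_size=500, de_total=150):
        """A universe where one set holds the stated up/down DE members."""
        statuses = {}
        members = set()
        for i in range(n_down):
            statuses[f"m_d{i}"] = DOWN
            members.add(f"m_d{i}")
        for i in range(n_up):
            statuses[f"m_u{i}"] = UP
            members.add(f"m_u{i}")
        for i in range(set_size - n_down - n_up):
            statuses[f"m_n{i}"] = NS
            members.add(f"m_n{i}")
        remaining_de = de_total - n_down - n_up
        for i in range(remaining_de):
            statuses[f"x_d{i}"] = DOWN
        for i in range(universe_size - len(statuses)):
            statuses[f"x_n{i}"] = NS
        gs = GeneSet(name="S", members=members, source="test")
        (res,) = enrich_gene_sets([gs], statuses, set(statuses), ThresholdConfig())
        return res

    def test_algr_style_regulon_counts(self):
        # 20 genes, 12 down + 1 up -> 13 dysregulated, 65%
        res = self.worked_example(20, n_down=12, n_up=1)
        assert (res.n_de_in_set, res.n_down, res.n_up) == (13, 12, 1)
        assert res.fraction_dysregulated == pytest.approx(0.65)

    def test_lasr_style_regulon_counts(self):
        # 83 genes, 36 down + 15 up -> 51 dysregulated, ~61.4%
        res = self.worked_example(83, n_down=36, n_up=15)
        assert res.n_de_in_set == 51
        assert res.fraction_dysregulated == pytest.approx(51 / 83)
        assert round(100 * res.fraction_dysregulated) == 61

    def test_most_extreme_enrichment(self):
        # the set IS the DE list; universe twice its size
        statuses = build_statuses(10, 10, 20)
        de = {g for g, s in statuses.items() if s is not NS}
        gs = GeneSet(name="DE", members=de, source="test")
        (res,) = enrich_gene_sets([gs], statuses, set(statuses), ThresholdConfig())
        assert res.fraction_dysregulated == 1.0
        assert res.p_value == pytest.approx(
            fisher_enumeration(20, 0, 0, 20, "two-sided"), abs=1e-12
        )
        assert res.significant

    def test_set_outside_universe_flagged_untestable(self):
        statuses = build_statuses(5, 5, 40)
        inside = GeneSet(name="in", members={"u0", "u1", "n0"}, source="t")
        outside = GeneSet(name="out", members={"zz1", "zz2"}, source="t")
        with pytest.warns(UserWarning, match="outside universe"):
            res = enrich_gene_sets(
                [inside, outside], statuses, set(statuses), ThresholdConfig()
            )
        by_name = {r.set_name: r for r in res}
        assert not by_name["out"].testable
        assert math.isnan(by_name["out"].p_value)
        # BH family contains only the testable set: its padj equals its p
        assert by_name["in"].p_adjusted == pytest.approx(by_name["in"].p_value)

    def test_status_genes_must_lie_in_universe(self):
        statuses = build_statuses(1, 1, 1)
        gs = GeneSet(name="S", members={"u0"}, source="t")
        with pytest.raises(ValueError, match="outside the universe"):
            enrich_gene_sets([gs], statuses, {"u0"}, ThresholdConfig())

    def test_null_type_i_error_controlled(self):
        """Random sets with no planted signal are rarely called significant."""
        rng = np.random.default_rng(101)
        universe = [f"g{i}" for i in range(800)]
        n_sig = 0
        n_sets_total = 0
        for _ in range(25):
            de = set(rng.choice(universe, size=80, replace=False))
            statuses = {g: (UP if g in de else NS) for g in universe}
            sets = [
                GeneSet(
                    name=f"S{k}",
                    members=set(rng.choice(universe, size=25, replace=False)),
                    source="null",
                )
                for k in range(40)
            ]
            res = enrich_gene_sets(sets, statuses, set(universe), ThresholdConfig())
            n_sig += sum(r.significant for r in res)
            n_sets_total += len(res)
        rate = n_sig / n_sets_total
        # BH controls FDR at 0.05; allow two binomial standard errors
        assert rate <= 0.05 + 2 * math.sqrt(0.05 * 0.95 / n_sets_total)

    def test_planted_regulon_power(self):
        """Members DE at 5x background (0.5 vs 0.1) are almost always flagged."""
        hits = 0
        n_rep = 100
        for seed in range(n_rep):
            rng = np.random.default_rng(1000 + seed)
            universe = [f"g{i}" for i in range(1000)]
            members = set(rng.choice(universe, size=30, replace=False))
            statuses = {}
            for g in universe:
                rate = 0.5 if g in members else 0.1
                statuses[g] = UP if rng.random() < rate else NS
            gs = GeneSet(name="planted", members=members, source="sim")
            (res,) = enrich_gene_sets(
                [gs], statuses, set(universe), ThresholdConfig()
            )
            hits += res.significant
        assert hits >= 95


class TestCompareRegulons:
    def test_identical_sets(self):
        statuses = build_statuses(2, 2, 6)
        gs = GeneSet(name="A", members={"u0", "d0", "n0", "n1"}, source="t")
        rep = compare_regulons(gs, gs, statuses)
        assert rep.n_common_members == 4
        assert rep.fraction_dysregulated_a == rep.fraction_dysregulated_b == 0.5

    def test_disjoint_sets(self):
        statuses = build_statuses(2, 2, 6)
        a = GeneSet(name="A", members={"u0", "n0"}, source="t")
        b = GeneSet(name="B", members={"d0", "n1"}, source="t")
        assert compare_regulons(a, b, statuses).n_common_members == 0

    def test_hand_counted_intersection(self):
        statuses = build_statuses(5, 5, 20)
        a = GeneSet(name="A", members={f"u{i}" for i in range(5)}
                    | {f"n{i}" for i in range(5)}, source="t")
        b = GeneSet(name="B", members={f"u{i}" for i in range(3)}
                    | {f"n{i}" for i in range(3, 7)}, source="t")
        # by hand: common members are u0,u1,u2 and n3,n4 -> 5
        rep = compare_regulons(a, b, statuses)
        assert rep.n_common_members == 5
        assert rep.fraction_dysregulated_a == pytest.approx(0.5)
        assert rep.fraction_dysregulated_b == pytest.approx(3 / 7)


def test_contingency_margins():
    universe = {f"g{i}" for i in range(30)}
    members = {f"g{i}" for i in range(8)}
    de = {f"g{i}" for i in range(4, 16)}
    t = contingency(members, de, universe)
    assert t.a + t.c == len(members)
    assert t.a + t.b == len(de)
    assert t.n == len(universe)
    assert t.a == 4


def test_exhaustive_small_margin_tables_both_alternatives():
    """Fisher P equals full enumeration on every table with margins <= 5."""
    for a, b, c, d in itertools.product(range(4), repeat=4):
        if a + b + c + d == 0:
            continue
        for alt in ("two-sided", "greater"):
            assert fisher_exact(ContingencyTable(a, b, c, d), alt) == pytest.approx(
                fisher_enumeration(a, b, c, d, alt), abs=1e-12
            )
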