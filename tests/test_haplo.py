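"""Haplotype association: GRM, window scan invariants, selection rules,
Duncan grouping and allele classification."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from senespop import simulate as sim
from senespop.haplo import (
    JointHaplotypeWindow,
    duncan_groups,
    effective_genotype_means,
    posthoc_allele_effects,
    scan_joint_haplotypes,
    select_best_window,
    vanraden_grm,
)


class TestVanRaden:
    def test_hand_computed_two_individuals(self):
        G = vanraden_grm(np.array([[0.0], [2.0]]))
        np.testing.assert_allclose(G.to_numpy(), [[2, -2], [-2, 2]], atol=1e-12)

    def test_duplicated_individual_rows_identical(self):
        rng = np.random.default_rng(0)
        M = rng.integers(0, 3, size=(5, 40)).astype(float)
        M = np.vstack([M, M[2]])
        G = vanraden_grm(M).to_numpy()
        np.testing.assert_allclose(G[2], G[5], atol=1e-12)
        np.testing.assert_allclose(G, G.T, atol=1e-12)

    def test_identical_panel_is_rank_one(self):
        M = np.tile(np.array([[0.0, 1.0, 2.0, 1.0]]), (6, 1))
        G = vanraden_grm(M).to_numpy()
        assert np.linalg.matrix_rank(G, tol=1e-8) <= 1

    def test_monomorphic_panel_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            vanraden_grm(np.zeros((4, 10)))


def _mini_window(p, prop, **kw):
    base = dict(chrom="17", start=0, n_hbs=2, cm_span=(0.0, 3.0),
                haplotype_freqs={}, prop_retained=prop, n_retained=10,
                p_haplotype=p, p_index=prop * (-np.log10(p)))
    base.update(kw)
    return JointHaplotypeWindow(**base)


@pytest.fixture(scope="module")
def germ():
    g = sim.simulate_germplasm(sim.GermplasmConfig(seed=11, n_individuals=60,
                                                   n_haploblocks=8,
                                                   causal_start=2,
                                                   causal_size=3))
    return g, vanraden_grm(g.dosages)


@pytest.fixture(scope="module")
def best_window_analysis():
    g = sim.simulate_germplasm(sim.GermplasmConfig(seed=11))
    grm = vanraden_grm(g.dosages)
    ws = scan_joint_haplotypes(g.matrix, g.blues, grm, "17", sizes=range(2, 7))
    s, k = g.causal_window
    inner = (s * 3.0, (s + k - 1) * 3.0)
    return g, select_best_window(ws, inner, (0.0, 57.0))


class TestScan:
    def test_pindex_definition(self):
        w = _mini_window(1e-4, 0.5)
        assert w.p_index == pytest.approx(2.0)

    def test_window_enumeration_count(self, germ):
        g, grm = germ
        sizes = [2, 3, 4]
        ws = scan_joint_haplotypes(g.matrix, g.blues, grm, "17", sizes=sizes,
                                   maf=0.0)
        n_hb = 8
        assert len(ws) <= sum(n_hb - s + 1 for s in sizes)
        # with maf=0 no individual is filtered, so every window that has >= 2
        # haplotype levels appears exactly once
        starts = {(w.n_hbs, w.start) for w in ws}
        assert len(starts) == len(ws)

    def test_invariance_to_individual_order_and_labels(self, germ):
        g, grm = germ
        ws1 = scan_joint_haplotypes(g.matrix, g.blues, grm, "17", sizes=[3])
        order = list(reversed(g.matrix.individuals))
        m2 = g.matrix.subset_individuals(order)
        grm2 = grm.loc[order, order]
        ws2 = scan_joint_haplotypes(m2, g.blues, grm2, "17", sizes=[3])
        p1 = {w.start: w.p_index for w in ws1}
        p2 = {w.start: w.p_index for w in ws2}
        assert set(p1) == set(p2)
        for s in p1:
            assert p1[s] == pytest.approx(p2[s], rel=1e-5, abs=1e-8)

    def test_phenotype_coverage_precondition(self, germ):
        g, grm = germ
        with pytest.raises(ValueError, match="at least 20"):
            scan_joint_haplotypes(g.matrix, g.blues.iloc[:5], grm, "17", sizes=[2])

    def test_homozygous_panel_dosage_and_indicator_agree(self):
        """On an all-homozygous panel the allele-dosage design spans the same
        space as a plain per-genotype indicator design, so the haplotype-term
        test must coincide with an independently computed one-way F-test
        (the GRM is the identity, so GLS reduces to OLS)."""
        from senespop.haplo import _haplotype_lrt

        rng = np.random.default_rng(3)
        ids = [f"i{k}" for k in range(40)]
        hap = rng.integers(0, 2, 40)
        haps = {i: ((hap[k],), (hap[k],)) for k, i in enumerate(ids)}
        y = pd.Series(rng.normal(0, 1, 40) + 0.8 * hap, index=ids)
        grm = pd.DataFrame(np.eye(40), index=ids, columns=ids)
        p_dosage = _haplotype_lrt(haps, y, grm, [(0,), (1,)])
        # independent oracle: classic one-way ANOVA F between the two groups
        g0 = y[hap == 0].to_numpy()
        g1 = y[hap == 1].to_numpy()
        f_oracle, p_oracle = stats.f_oneway(g0, g1)
        assert p_dosage == pytest.approx(p_oracle, rel=1e-6)


class TestSelectBestWindow:
    def test_single_qualifying_window(self):
        w = _mini_window(1e-3, 1.0, cm_span=(10.0, 20.0))
        assert select_best_window([w], (12.0, 15.0), (0.0, 30.0)) is w

    def test_tie_broken_by_fewer_blocks(self):
        w4 = _mini_window(1e-3, 1.0, n_hbs=4, cm_span=(10.0, 20.0))
        w6 = _mini_window(1e-3, 1.0, n_hbs=6, cm_span=(10.0, 20.0))
        assert select_best_window([w6, w4], (12.0, 15.0), (0.0, 30.0)) is w4

    def test_no_overlap_gives_empty_result(self):
        w = _mini_window(1e-3, 1.0, cm_span=(40.0, 50.0))
        assert select_best_window([w], (10.0, 20.0), (0.0, 30.0)) is None

    def test_window_longer_than_outer_excluded(self):
        w = _mini_window(1e-3, 1.0, cm_span=(0.0, 30.0))
        assert select_best_window([w], (10.0, 20.0), (12.0, 18.0)) is None

    def test_empty_candidates_raise(self):
        with pytest.raises(ValueError):
            select_best_window([], (0, 1), (0, 1))


class TestDuncan:
    def test_two_separated_groups_get_distinct_letters(self):
        means = pd.Series({"A": 60.0, "B": 70.0})
        letters = duncan_groups(means, mse=1.0, df_resid=38,
                                n_sizes=pd.Series({"A": 20, "B": 20}))
        assert letters["A"] != letters["B"]

    def test_identical_means_share_one_letter(self):
        means = pd.Series({"A": 60.0, "B": 60.0, "C": 60.0})
        letters = duncan_groups(means, mse=4.0, df_resid=30,
                                n_sizes=pd.Series({"A": 10, "B": 10, "C": 10}))
        assert set(letters.index) == {"A", "B", "C"}
        assert len(set(letters.values)) == 1

    def test_separation_rate_against_range_oracle(self):
        """Five groups with means (+8.4, 0, 0, +4, +4), sd 3: the +8.4 group
        is separated from the 0 groups in >= 80% of 25 replicates, matching
        the literal least-significant-range computation."""
        rng = np.random.default_rng(42)
        shifts = {"late": 8.4, "z1": 0.0, "z2": 0.0, "m1": 4.0, "m2": 4.0}
        n_per = 14
        hits = 0
        oracle_hits = 0
        for _ in range(25):
            data = {g: 60 + s + rng.normal(0, 3, n_per) for g, s in shifts.items()}
            means = pd.Series({g: v.mean() for g, v in data.items()})
            mse = float(np.mean([v.var(ddof=1) for v in data.values()]))
            df = 5 * (n_per - 1)
            letters = duncan_groups(means, mse, df, pd.Series({g: n_per for g in data}))
            sep = (not set(letters["late"]) & set(letters["z1"])
                   and not set(letters["late"]) & set(letters["z2"]))
            hits += sep
            # independent oracle: literal Duncan least significant range for
            # the full span of 5 ordered means
            order = means.sort_values(ascending=False)
            span = list(order.index).index("z1") - list(order.index).index("late") + 1
            q = stats.studentized_range.ppf((1 - 0.1) ** (span - 1), span, df)
            oracle_hits += (means["late"] - means["z1"]) > q * np.sqrt(mse / n_per)
        assert hits >= 0.8 * 25
        assert abs(hits - oracle_hits) <= 3


class TestPosthoc:
    def test_forced_separation_two_haplotypes(self):
        ids = [f"i{k}" for k in range(30)]
        haps = {i: (("A",), ("A",)) if k < 15 else (("B",), ("B",))
                for k, i in enumerate(ids)}
        w = _mini_window(1e-3, 1.0, retained_ids=ids, haplotypes=haps)
        blues = pd.Series([60.0] * 15 + [70.0] * 15, index=ids)
        res = posthoc_allele_effects(w, blues)
        by = {c.haplotype: c for c in res.classifications}
        assert by["('A',)"].duncan_letters != by["('B',)"].duncan_letters
        assert abs(abs(by["('B',)"].effect_days) - 10.0) < 1e-8

    def test_all_equal_phenotypes_single_class(self):
        ids = [f"i{k}" for k in range(30)]
        haps = {i: (("A",), ("A",)) if k < 15 else (("B",), ("B",))
                for k, i in enumerate(ids)}
        w = _mini_window(1e-3, 1.0, retained_ids=ids, haplotypes=haps)
        blues = pd.Series(65.0, index=ids)
        res = posthoc_allele_effects(w, blues)
        assert {c.cls for c in res.classifications} == {"Ambiguous"}

    def test_causal_haplotype_classified_late(self, best_window_analysis):
        g, w = best_window_analysis
        res = posthoc_allele_effects(w, g.blues)
        late = [c for c in res.classifications if c.cls == "Late"]
        assert late, "no Late haplotype found"
        assert max(c.mean_blue for c in res.classifications) == pytest.approx(
            late[0].mean_blue)

    def test_effective_genotype_delay(self, best_window_analysis):
        g, w = best_window_analysis
        res = posthoc_allele_effects(w, g.blues)
        eg = effective_genotype_means(w, res, g.blues)
        assert set(eg.counts.index) <= {"Early/Early", "Early/Late", "Late/Late"}
        if eg.delay_het_vs_early is not None:
            assert eg.delay_het_vs_early > 0
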