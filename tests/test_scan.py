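"""Windowed popgen statistics against independent literal-formula oracles."""

import numpy as np
import pandas as pd
import pytest

from senespop import simulate as sim
from senespop.scan import (
    outlier_thresholds,
    read_vcf_panel,
    report_candidates,
    window_fst,
    window_pi,
    window_table,
    window_tajima_d,
)


def _panel(gt, positions, groups, length=10_000):
    samples = [f"s{i}" for i in range(gt.shape[1])]
    return sim.VariantPanel("c", np.asarray(positions, int), np.asarray(gt, int),
                            samples, pd.Series(groups, index=samples), length)


def _random_panel(rng, n_sites=30, n1=8, n2=7, missing=0.05, length=10_000):
    n = n1 + n2
    gt = rng.integers(0, 2, size=(n_sites, n, 2))
    if missing:
        mask = rng.random((n_sites, n)) < missing
        gt[mask] = -1
    pos = np.sort(rng.choice(np.arange(1, length + 1), n_sites, replace=False))
    return _panel(gt, pos, ["hardy"] * n1 + ["not_hardy"] * n2, length)


# ---------------------------------------------------------------------------
# literal-formula oracles (site-by-site transcriptions, no vectorisation)


def oracle_pi(gt_group, length):
    total = 0.0
    for s in range(gt_group.shape[0]):
        alleles = [a for pair in gt_group[s] for a in pair if a >= 0]
        n = len(alleles)
        if n < 2:
            continue
        p = sum(alleles) / n
        total += (n / (n - 1)) * 2 * p * (1 - p)
    return total / length


def oracle_tajima_d(gt_group):
    sites = []
    for s in range(gt_group.shape[0]):
        alleles = [a for pair in gt_group[s] for a in pair if a >= 0]
        if len(alleles) >= 4 and 0 < sum(alleles) < len(alleles):
            sites.append(alleles)
    S = len(sites)
    if S < 3:
        return None
    ns = [len(a) for a in sites]
    n = max(set(ns), key=ns.count)
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    pi_sum = 0.0
    for alleles in sites:
        m = len(alleles)
        p = sum(alleles) / m
        pi_sum += (m / (m - 1)) * 2 * p * (1 - p)
    var = e1 * S + e2 * S * (S - 1)
    return (pi_sum - S / a1) / np.sqrt(var)


def oracle_fst(gt1, gt2):
    num = den = 0.0
    used = False
    for s in range(gt1.shape[0]):
        stats_ = []
        skip = False
        for gt in (gt1, gt2):
            pairs = [pair for pair in gt[s] if pair[0] >= 0 and pair[1] >= 0]
            if len(pairs) < 2:
                skip = True
                break
            ni = len(pairs)
            p = sum(a for pair in pairs for a in pair) / (2 * ni)
            h = sum(1 for pair in pairs if pair[0] != pair[1]) / ni
            stats_.append((ni, p, h))
        if skip:
            continue
        (n1, p1, h1), (n2, p2, h2) = stats_
        r = 2
        nbar = (n1 + n2) / 2
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        if pbar <= 0 or pbar >= 1:
            continue
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4)
                           / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r
                                   - hbar * (2 * nbar - 1) / (4 * nbar))
        c = hbar / 2
        num += a
        den += a + b + c
        used = True
    if not used or den == 0:
        return None
    return num / den


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(8))
    def test_all_three_statistics(self, seed):
        """pi, Tajima's D and FST agree with literal-formula transcriptions
        on random <= 50-site windows with missing data, to 1e-10."""
        rng = np.random.default_rng(seed)
        p = _random_panel(rng, n_sites=int(rng.integers(5, 50)))
        cols1 = p.group_columns("hardy")
        cols2 = p.group_columns("not_hardy")
        pi = window_pi(p, "hardy", 0, 10_000)
        assert pi == pytest.approx(oracle_pi(p.genotypes[:, cols1], 10_000),
                                   abs=1e-10)
        d = window_tajima_d(p, "hardy", 0, 10_000)
        od = oracle_tajima_d(p.genotypes[:, cols1])
        if od is None:
            assert d is None
        else:
            assert d == pytest.approx(od, abs=1e-10)
        f = window_fst(p, 0, 10_000)
        of = oracle_fst(p.genotypes[:, cols1], p.genotypes[:, cols2])
        if of is None:
            assert f is None
        else:
            assert f == pytest.approx(of, abs=1e-10)

    def test_site_and_sample_order_invariance(self):
        rng = np.random.default_rng(99)
        p = _random_panel(rng, n_sites=25)
        perm_sites = rng.permutation(25)
        # positions must stay sorted for windowing; permute genotype rows and
        # their positions together, then re-sort
        order = np.argsort(p.positions[perm_sites])
        p2 = _panel(p.genotypes[perm_sites][order], p.positions[perm_sites][order],
                    p.groups.values, 10_000)
        perm_samples = rng.permutation(15)
        p3 = sim.VariantPanel("c", p.positions, p.genotypes[:, perm_samples],
                              [p.samples[i] for i in perm_samples],
                              p.groups, 10_000)
        for q in (p2, p3):
            assert window_pi(q, "hardy", 0, 10_000) == pytest.approx(
                window_pi(p, "hardy", 0, 10_000), abs=1e-12)
            assert window_fst(q, 0, 10_000) == pytest.approx(
                window_fst(p, 0, 10_000), abs=1e-12)


class TestPi:
    def test_monomorphic_window_is_zero(self):
        gt = np.zeros((4, 6, 2), int)
        p = _panel(gt, [10, 20, 30, 40], ["hardy"] * 3 + ["not_hardy"] * 3)
        assert window_pi(p, "hardy", 0, 10_000) == 0.0

    def test_single_site_hand_value(self):
        gt = np.array([[[0, 1], [0, 1], [-1, -1], [-1, -1]]])
        p = _panel(gt, [5], ["hardy", "hardy", "not_hardy", "not_hardy"])
        assert window_pi(p, "hardy", 0, 10_000) == pytest.approx((4 / 3 * 0.5) / 10_000)

    def test_doubling_window_halves_pi(self):
        rng = np.random.default_rng(1)
        p = _random_panel(rng, n_sites=20, missing=0.0, length=20_000)
        p.positions = np.sort(rng.choice(np.arange(1, 10_000), 20, replace=False))
        pi1 = window_pi(p, "hardy", 0, 10_000)
        pi2 = window_pi(p, "hardy", 0, 20_000)
        assert pi2 == pytest.approx(pi1 / 2)


class TestTajimaD:
    def test_sign_tracks_numerator(self):
        """D is negative for an excess of rare variants, positive for an
        excess of intermediate-frequency variants, and crosses zero exactly
        when pi_sum equals S/a1 (checked through the literal oracle)."""
        gt_rare = np.zeros((6, 5, 2), int)
        gt_rare[:, 0, 0] = 1      # six singletons: excess of rare variants
        p_rare = _panel(gt_rare, np.arange(1, 7) * 10, ["hardy"] * 5)
        assert window_tajima_d(p_rare, "hardy", 0, 10_000) < 0
        gt_mid = np.zeros((6, 5, 2), int)
        gt_mid[:, :2, :] = 1      # intermediate frequency: positive D
        p_mid = _panel(gt_mid, np.arange(1, 7) * 10, ["hardy"] * 5)
        assert window_tajima_d(p_mid, "hardy", 0, 10_000) > 0

    def test_too_few_segregating_sites_undefined(self):
        gt = np.zeros((2, 5, 2), int)
        gt[:, 0, 0] = 1
        p = _panel(gt, [10, 20], ["hardy"] * 5)
        assert window_tajima_d(p, "hardy", 0, 10_000) is None


class TestFst:
    def test_fixed_difference_is_one(self):
        gt = np.zeros((5, 10, 2), int)
        gt[:, 5:, :] = 1
        p = _panel(gt, np.arange(1, 6) * 100, ["hardy"] * 5 + ["not_hardy"] * 5)
        assert window_fst(p, 0, 10_000) == pytest.approx(1.0)

    def test_identical_groups_not_positive(self):
        rng = np.random.default_rng(2)
        col = rng.integers(0, 2, (30, 1, 2))
        gt = np.tile(col, (1, 10, 1))
        p = _panel(gt, np.arange(1, 31) * 10, ["hardy"] * 5 + ["not_hardy"] * 5)
        f = window_fst(p, 0, 10_000)
        assert -0.2 <= f <= 0.05


class TestOutliers:
    def _table(self, values):
        return pd.DataFrame({"chrom": "c", "start": np.arange(len(values)) * 10_000,
                             "end": (np.arange(len(values)) + 1) * 10_000,
                             "stat": values})

    def test_type7_quantile_and_strict_flags(self):
        tab = self._table(np.arange(1.0, 1001.0))
        res = outlier_thresholds(tab, "stat")
        assert res.threshold == pytest.approx(990.01)
        assert len(res.flagged) == 10

    def test_constant_windows_flag_nothing(self):
        tab = self._table(np.full(200, 3.3))
        res = outlier_thresholds(tab, "stat")
        assert res.threshold == pytest.approx(3.3)
        assert len(res.flagged) == 0

    def test_undefined_windows_do_not_move_threshold(self):
        tab = self._table(np.arange(1.0, 1001.0))
        with_nan = self._table(np.concatenate([np.arange(1.0, 1001.0), [np.nan]]))
        assert outlier_thresholds(with_nan, "stat").threshold == pytest.approx(
            outlier_thresholds(tab, "stat").threshold)

    def test_too_few_windows(self):
        with pytest.raises(ValueError):
            outlier_thresholds(self._table(np.arange(10.0)), "stat")


class TestCandidates:
    def test_empty_flags_empty_report(self):
        flagged = pd.DataFrame(columns=["chrom", "start", "end", "fst"])
        assert report_candidates(flagged, "fst", [("c", 0, 1000)]) == []

    def test_two_runs_inside_interval(self):
        flagged = pd.DataFrame({
            "chrom": "c",
            "start": [10_000, 20_000, 50_000],
            "end": [20_000, 30_000, 60_000],
            "fst": [0.5, 0.7, 0.6],
        })
        cands = report_candidates(flagged, "fst", [("c", 0, 100_000)])
        assert len(cands) == 2
        assert cands[0].n_windows == 2
        assert cands[0].peak_start == 20_000


class TestVcfReader:
    def test_multiallelic_skipped_and_counted(self, tmp_path):
        vcf = tmp_path / "x.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts0\ts1\n"
            "c\t10\t.\tA\tT\t.\tPASS\t.\tGT\t0/1\t0/0\n"
            "c\t20\t.\tA\tT,G\t.\tPASS\t.\tGT\t0/1\t0/2\n")
        groups = pd.Series(["hardy", "not_hardy"], index=["s0", "s1"], name="group")
        p = read_vcf_panel(vcf, groups)
        assert len(p.positions) == 1
        assert p.n_skipped == 1

    def test_unknown_sample_raises(self, tmp_path):
        vcf = tmp_path / "x.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts0\n"
            "c\t10\t.\tA\tT\t.\tPASS\t.\tGT\t0/1\n")
        groups = pd.Series(["hardy"], index=["nope"], name="group")
        with pytest.raises(ValueError, match="absent"):
            read_vcf_panel(vcf, groups)

    def test_empty_vcf_body_warns(self, tmp_path):
        vcf = tmp_path / "x.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts0\n")
        groups = pd.Series(["hardy"], index=["s0"], name="group")
        with pytest.warns(UserWarning):
            p = read_vcf_panel(vcf, groups)
        assert len(p.positions) == 0
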