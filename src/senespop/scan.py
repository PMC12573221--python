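"""Windowed population-genetic statistics for two-group diploid panels.

Nucleotide diversity (pi), Tajima's D and pairwise Weir-Cockerham FST are
computed in non-overlapping 10 kb windows (half-open, anchored at coordinate
0) between a 'hardy' and a 'not_hardy' cultivar group, with genome-wide 1%
empirical outlier thresholds and intersection reports against QTL intervals.

Conventions: VCF coordinates are 1-based and converted internally to 0-based
half-open; per-site pi uses the unbiased estimator (n/(n-1)) 2 p (1-p) over
the non-missing alleles; Tajima's constants use the modal non-missing allele
count of the window (sites with a deviating count still contribute pi and S);
the window FST is the ratio of summed variance components, reported as
computed (negative estimates are not clamped).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class GenotypePanel:
    chrom: str
    positions: np.ndarray          # 1-based bp
    genotypes: np.ndarray          # (n_sites, n_samples, 2) in {0,1,-1}
    samples: list
    groups: pd.Series              # sample -> 'hardy' / 'not_hardy'
    n_skipped: int = 0
    chrom_length: int = 0

    def group_columns(self, group) -> np.ndarray:
        return np.flatnonzero(self.groups.loc[self.samples].to_numpy() == group)


def read_vcf_panel(path, groups: pd.DataFrame | pd.Series) -> GenotypePanel:
    """Read biallelic SNPs from a VCF with cyvcf2; non-biallelic records are
    skipped and counted.  `groups` maps sample -> group label."""
    from cyvcf2 import VCF

    if isinstance(groups, pd.DataFrame):
        groups = groups.set_index("sample")["group"]
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    missing = [s for s in groups.index if s not in samples]
    if missing:
        raise ValueError(f"samples in group table absent from VCF: {missing}")
    positions, gts = [], []
    n_skipped = 0
    chrom = None
    chrom_length = 0
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            n_skipped += 1
            continue
        chrom = var.CHROM
        positions.append(var.POS)
        g = np.array(var.genotypes, dtype=int)[:, :2]
        gts.append(g)
    try:
        if chrom is not None and vcf.seqlens:
            chrom_length = int(dict(zip(vcf.seqnames, vcf.seqlens)).get(chrom, 0))
    except Exception:
        chrom_length = 0
    if not positions:
        import warnings
        warnings.warn("VCF contained no biallelic SNPs")
        return GenotypePanel(chrom or "", np.empty(0, dtype=int),
                             np.empty((0, len(samples), 2), dtype=int),
                             samples, groups, n_skipped, chrom_length)
    return GenotypePanel(chrom, np.asarray(positions, dtype=int),
                         np.stack(gts), samples, groups, n_skipped, chrom_length)


# ---------------------------------------------------------------------------
# per-window statistics


def _site_counts(gt: np.ndarray):
    """Derived-allele count and non-missing allele count per site."""
    ok = gt >= 0
    n = ok.sum(axis=(1, 2))
    der = np.where(ok, gt, 0).sum(axis=(1, 2))
    return der, n


def window_pi(panel: GenotypePanel, group: str, start: int, end: int) -> float | None:
    """Per-bp nucleotide diversity of `group` in the 0-based half-open window
    [start, end): sum over sites of (n/(n-1)) 2 p (1-p), divided by the
    window length in bp."""
    cols = panel.group_columns(group)
    sel = (panel.positions - 1 >= start) & (panel.positions - 1 < end)
    gt = panel.genotypes[np.ix_(np.flatnonzero(sel), cols)]
    if gt.size == 0:
        return 0.0
    der, n = _site_counts(gt)
    if np.all(n == 0):
        return None
    keep = n >= 2
    if not keep.any():
        return None
    p = der[keep] / n[keep]
    site_pi = (n[keep] / (n[keep] - 1.0)) * 2.0 * p * (1.0 - p)
    return float(site_pi.sum() / (end - start))


def _tajima_constants(n: int):
    i = np.arange(1, n)
    a1 = np.sum(1.0 / i)
    a2 = np.sum(1.0 / i**2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return a1, e1, e2


def window_tajima_d(panel: GenotypePanel, group: str, start: int, end: int,
                    min_sites: int = 3) -> float | None:
    """Tajima's D for `group` in [start, end).

    D = (pi_sum - S/a1) / sqrt(e1 S + e2 S (S-1)) with constants computed
    from the modal non-missing allele count of the window; sites with fewer
    than 4 non-missing alleles are excluded."""
    cols = panel.group_columns(group)
    sel = (panel.positions - 1 >= start) & (panel.positions - 1 < end)
    gt = panel.genotypes[np.ix_(np.flatnonzero(sel), cols)]
    if gt.size == 0:
        return None
    der, n = _site_counts(gt)
    keep = n >= 4
    der, n = der[keep], n[keep]
    seg = (der > 0) & (der < n)
    der, n = der[seg], n[seg]
    S = len(der)
    if S < min_sites:
        return None
    n_vals, n_counts = np.unique(n, return_counts=True)
    n_modal = int(n_vals[np.argmax(n_counts)])
    a1, e1, e2 = _tajima_constants(n_modal)
    p = der / n
    pi_sum = float(np.sum((n / (n - 1.0)) * 2.0 * p * (1.0 - p)))
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return None
    return float((pi_sum - S / a1) / np.sqrt(var))


def _wc_components(gt1: np.ndarray, gt2: np.ndarray):
    """Weir-Cockerham (1984) per-site variance components a, b, c for two
    populations of diploids; sites with < 2 genotyped diploids in either
    group, or monomorphic overall, contribute nothing."""
    r = 2
    comps = []
    for s in range(gt1.shape[0]):
        parts = []
        for gt in (gt1, gt2):
            g = gt[s]
            ok = np.all(g >= 0, axis=1)
            ni = int(ok.sum())
            if ni < 2:
                parts = None
                break
            alleles = g[ok]
            p_i = alleles.sum() / (2.0 * ni)
            h_i = float(np.mean(alleles[:, 0] != alleles[:, 1]))
            parts.append((ni, p_i, h_i))
        if parts is None:
            comps.append((0.0, 0.0, 0.0, False))
            continue
        (n1, p1, h1), (n2, p2, h2) = parts
        n_bar = (n1 + n2) / 2.0
        n_c = (r * n_bar - (n1**2 + n2**2) / (r * n_bar)) / (r - 1)
        p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
        if p_bar <= 0.0 or p_bar >= 1.0:
            comps.append((0.0, 0.0, 0.0, False))
            continue
        s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
        h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
        a = (n_bar / n_c) * (s2 - (p_bar * (1 - p_bar) - s2 * (r - 1) / r
                                   - h_bar / 4.0) / (n_bar - 1))
        b = (n_bar / (n_bar - 1)) * (p_bar * (1 - p_bar) - s2 * (r - 1) / r
                                     - h_bar * (2 * n_bar - 1) / (4 * n_bar))
        c = h_bar / 2.0
        comps.append((a, b, c, True))
    return comps


def window_fst(panel: GenotypePanel, start: int, end: int,
               groups=("hardy", "not_hardy")) -> float | None:
    """Weighted Weir-Cockerham FST between the two groups in [start, end):
    sum(a) / sum(a + b + c) over polymorphic sites."""
    sel = np.flatnonzero((panel.positions - 1 >= start) & (panel.positions - 1 < end))
    if sel.size == 0:
        return None
    gt1 = panel.genotypes[np.ix_(sel, panel.group_columns(groups[0]))]
    gt2 = panel.genotypes[np.ix_(sel, panel.group_columns(groups[1]))]
    comps = _wc_components(gt1, gt2)
    num = sum(a for a, b, c, ok in comps if ok)
    den = sum(a + b + c for a, b, c, ok in comps if ok)
    if den == 0 or not any(ok for *_, ok in comps):
        return None
    return float(num / den)


# ---------------------------------------------------------------------------
# genome-wide windowing, thresholds, reporting


def window_table(panel: GenotypePanel, window_size: int = 10_000,
                 pi_group: str = "hardy", d_group: str = "hardy") -> pd.DataFrame:
    """All-windows table of n_sites, pi, Tajima's D and pairwise FST."""
    if panel.positions.size == 0:
        return pd.DataFrame(columns=["chrom", "start", "end", "n_sites",
                                     "pi", "tajima_d", "fst"])
    length = panel.chrom_length or int(panel.positions.max())
    rows = []
    for start in range(0, length, window_size):
        end = start + window_size
        sel = (panel.positions - 1 >= start) & (panel.positions - 1 < end)
        rows.append({
            "chrom": panel.chrom, "start": start, "end": end,
            "n_sites": int(sel.sum()),
            "pi": window_pi(panel, pi_group, start, end),
            "tajima_d": window_tajima_d(panel, d_group, start, end),
            "fst": window_fst(panel, start, end),
        })
    df = pd.DataFrame(rows)
    return df.astype({"pi": float, "tajima_d": float, "fst": float})


@dataclass
class OutlierResult:
    statistic: str
    threshold: float
    tail: str
    flagged: pd.DataFrame


def outlier_thresholds(windows: pd.DataFrame, statistic: str,
                       tail: str = "upper", q: float = 0.99,
                       min_windows: int = 100) -> OutlierResult:
    """Empirical genome-wide quantile threshold (numpy 'linear', i.e. type-7)
    over defined windows; flags are strict inequalities."""
    vals = windows[statistic].to_numpy(dtype=float)
    defined = np.isfinite(vals)
    if defined.sum() < min_windows:
        raise ValueError(f"only {int(defined.sum())} defined windows; "
                         f"need at least {min_windows}")
    if tail == "upper":
        thr = float(np.quantile(vals[defined], q))
        mask = defined & (vals > thr)
    elif tail == "lower":
        thr = float(np.quantile(vals[defined], 1.0 - q))
        mask = defined & (vals < thr)
    else:
        raise ValueError(f"unknown tail {tail}")
    return OutlierResult(statistic, thr, tail, windows[mask].copy())


@dataclass
class CandidateLocus:
    chrom: str
    start: int
    end: int
    n_windows: int
    peak_start: int
    peak_value: float
    statistic: str


def report_candidates(flagged: pd.DataFrame, statistic: str,
                      intervals: list) -> list[CandidateLocus]:
    """Group flagged windows into contiguous runs and intersect them with QTL
    genomic intervals [(chrom, start bp, end bp), ...]."""
    out = []
    if flagged.empty:
        return out
    flagged = flagged.sort_values(["chrom", "start"])
    runs = []
    cur = None
    for row in flagged.itertuples(index=False):
        if cur is not None and row.chrom == cur["chrom"] and row.start == cur["end"]:
            cur["end"] = row.end
            cur["rows"].append(row)
        else:
            if cur is not None:
                runs.append(cur)
            cur = {"chrom": row.chrom, "start": row.start, "end": row.end,
                   "rows": [row]}
    runs.append(cur)
    for chrom, lo, hi in intervals:
        for run in runs:
            if str(run["chrom"]) != str(chrom):
                continue
            if run["start"] < hi and run["end"] > lo:
                peak = max(run["rows"], key=lambda r: getattr(r, statistic))
                out.append(CandidateLocus(str(chrom), run["start"], run["end"],
                                          len(run["rows"]), int(peak.start),
                                          float(getattr(peak, statistic)),
                                          statistic))
    return out
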