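"""Two-locus QTL dissection in full-sib families.

Builds compound genotypes (Q/q diplotypes at the two QTL regions, maternal
allele written first) from phased haploblock data, contrasts phenotypic
distributions with empirical CDFs and two-sample Kolmogorov-Smirnov tests,
classifies gene action (dominance and masking epistasis), profiles
S-locus-driven segregation distortion, and provides a simple within-family
haplotype-contrast scan used to localise simulated QTL.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .hb import MISSING, HaploblockMatrix


# ---------------------------------------------------------------------------
# ECDF and Kolmogorov-Smirnov


def ecdf(sample):
    """Right-continuous empirical CDF reaching 1; returns a callable."""
    x = np.sort(np.asarray(sample, dtype=float))
    n = len(x)
    if n == 0:
        raise ValueError("empty sample")

    def F(q):
        return np.searchsorted(x, np.asarray(q, dtype=float), side="right") / n

    F.x = x
    return F


@dataclass
class KsResult:
    d: float
    p: float
    n1: int
    n2: int
    low_power: bool = False


def ks_two_sample(a, b) -> KsResult:
    """Exact D by a merged-sort sweep; asymptotic two-sample p-value from the
    Kolmogorov distribution with effective size n1*n2/(n1+n2).  Small groups
    (n < 4) are flagged low power but still computed."""
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    cdf1 = np.searchsorted(a, pooled, side="right") / n1
    cdf2 = np.searchsorted(b, pooled, side="right") / n2
    d = float(np.max(np.abs(cdf1 - cdf2)))
    en = n1 * n2 / (n1 + n2)
    p = float(np.clip(stats.kstwobign.sf(np.sqrt(en) * d), 0.0, 1.0))
    return KsResult(d, p, n1, n2, low_power=(min(n1, n2) < 4))


# ---------------------------------------------------------------------------
# compound genotypes


@dataclass
class CompoundGenotype:
    individual: str
    family: str
    diplotypes: dict            # locus name -> 'qQ' etc. (maternal first)
    effective: str | None       # e.g. 'qQ/--', 'QQ/q-', 'QQ/QQ'
    excluded: bool = False
    reason: str | None = None


def _haplotype_origin(offspring_hap, parent_h0, parent_h1):
    """Match an inherited haplotype segment to a parental homolog.

    Returns 0/1, 'recombinant' when the segment matches neither homolog
    contiguously, or 'missing' when calls are absent."""
    if np.any(offspring_hap == MISSING) or np.any(parent_h0 == MISSING) \
            or np.any(parent_h1 == MISSING):
        return "missing"
    if np.array_equal(offspring_hap, parent_h0):
        return 0
    if np.array_equal(offspring_hap, parent_h1):
        return 1
    mendelian = np.all((offspring_hap == parent_h0) | (offspring_hap == parent_h1))
    return "recombinant" if mendelian else "unmatched"


def build_compound_genotypes(matrix: HaploblockMatrix, pedigree: pd.DataFrame,
                             outer_intervals: dict, parental_alleles: dict,
                             qtl_spec: list | None = None) -> list[CompoundGenotype]:
    """Q/q compound genotypes for every offspring in the pedigree.

    Parameters
    ----------
    outer_intervals : locus name -> (chrom, cM lo, cM hi): the outer QTL
        interval within which the inherited haplotype must be non-recombinant
        and fully called.
    parental_alleles : locus name -> {parent id: (label homolog 0, label
        homolog 1)} with labels in {'Q', 'q'}.

    Offspring with a recombination event, a missing call, or a haplotype
    matching neither parental homolog inside any outer interval are excluded
    with the reason recorded.
    """
    from .simulate import effective_class

    out = []
    blocks = matrix.blocks
    for row in pedigree.itertuples(index=False):
        if not row.mother or not row.father:
            continue
        i = matrix.index_of(row.id)
        im = matrix.index_of(row.mother)
        ip = matrix.index_of(row.father)
        diplo = {}
        excluded, reason = False, None
        for locus, (chrom, lo, hi) in outer_intervals.items():
            cidx = matrix.chrom_block_indices(chrom)
            cms = blocks["cm"].to_numpy()[cidx]
            sel = cidx[(cms >= lo) & (cms <= hi)]
            labels = []
            for parent_idx, parent_id, slot in ((im, row.mother, 0), (ip, row.father, 1)):
                origin = _haplotype_origin(matrix.calls[i, sel, slot],
                                           matrix.calls[parent_idx, sel, 0],
                                           matrix.calls[parent_idx, sel, 1])
                if origin == "missing":
                    excluded, reason = True, "missing"
                    break
                if origin == "recombinant":
                    excluded, reason = True, "recombinant"
                    break
                if origin == "unmatched":
                    excluded, reason = True, "pedigree inconsistency"
                    break
                labels.append(parental_alleles[locus][parent_id][origin])
            if excluded:
                break
            diplo[locus] = labels[0] + labels[1]
        if excluded:
            out.append(CompoundGenotype(row.id, row.family, {}, None, True, reason))
        else:
            eff = effective_class(diplo, qtl_spec) if qtl_spec else None
            out.append(CompoundGenotype(row.id, row.family, diplo, eff))
    return out


# ---------------------------------------------------------------------------
# gene action classification


@dataclass
class GeneActionResult:
    locus: str
    stratum_locus: str | None
    action: str                       # dominant_q | dominant_Q | additive | inconclusive
    epistasis: bool
    min_group_size: int
    pvalues: dict                     # stratum -> {(class a, class b): p}
    skipped: list = field(default_factory=list)


def _pairwise_ks(groups: dict) -> dict:
    p = {}
    for a in groups:
        for b in groups:
            if a < b and len(groups[a]) and len(groups[b]):
                p[(a, b)] = ks_two_sample(groups[a], groups[b]).p
    return p


def _dominance_label(groups: dict, pvals: dict, alpha: float) -> str:
    """Dominance: the two heterozygote groups are mutually non-different,
    non-different from one homozygote, and different from the other."""
    def get(a, b):
        key = (a, b) if (a, b) in pvals else (b, a)
        return pvals.get(key)

    hets = [g for g in groups if set(g) == {"q", "Q"}]
    if "QQ" not in groups or "qq" not in groups or not hets:
        return "inconclusive"
    if len(hets) == 2:
        p_hh = get(hets[0], hets[1])
        if p_hh is None or p_hh < alpha:
            return "inconclusive"
    like_qq = all((get(h, "qq") or 0.0) >= alpha for h in hets)
    diff_QQ = all((get(h, "QQ") or 1.0) < alpha for h in hets)
    like_QQ = all((get(h, "QQ") or 0.0) >= alpha for h in hets)
    diff_qq = all((get(h, "qq") or 1.0) < alpha for h in hets)
    if like_qq and diff_QQ:
        return "dominant_q"
    if like_QQ and diff_qq:
        return "dominant_Q"
    if diff_QQ and diff_qq:
        return "additive"
    return "inconclusive"


def classify_gene_action(samples: dict, locus: str = "locus2",
                         stratum_locus: str = "locus1",
                         alpha: float = 0.05) -> GeneActionResult:
    """Dominance/epistasis classification for the focal locus.

    `samples` maps (stratum diplotype, focal diplotype) -> phenotype array.
    Dominance is read within the stratum homozygous QQ at the other locus.
    Masking epistasis is flagged when the contrasts significant in the QQ
    stratum are all non-significant in the heterozygous stratum.
    Classification is invariant to the written orientation of heterozygotes.
    """
    strata = {}
    for (s, f), vals in samples.items():
        strata.setdefault(s, {})[f] = np.asarray(vals, dtype=float)
    skipped = [f"{s}:{f}" for s, d in strata.items() for f, v in d.items() if len(v) == 0]

    def stratum_groups(keys):
        merged = {}
        for s in keys:
            for f, v in strata.get(s, {}).items():
                if len(v):
                    merged[f] = np.concatenate([merged.get(f, np.empty(0)), v])
        return merged

    qq_groups = stratum_groups([s for s in strata if set(s) == {"Q"}])
    het_groups = stratum_groups([s for s in strata if set(s) == {"q", "Q"}])
    p_qq = _pairwise_ks(qq_groups)
    p_het = _pairwise_ks(het_groups)
    action = _dominance_label(qq_groups, p_qq, alpha) if qq_groups else "inconclusive"

    sig_qq = {pair for pair, p in p_qq.items() if p < alpha}
    epistasis = False
    if sig_qq and het_groups:
        def norm(pair):
            return tuple(sorted("".join(sorted(x)) for x in pair))
        het_norm = {norm(pair): p for pair, p in p_het.items()}
        matched = [het_norm[norm(pair)] for pair in sig_qq if norm(pair) in het_norm]
        epistasis = bool(matched) and all(p >= alpha for p in matched)

    sizes = [len(v) for d in (qq_groups, het_groups) for v in d.values() if len(v)]
    return GeneActionResult(locus, stratum_locus, action, epistasis,
                            int(min(sizes)) if sizes else 0,
                            {"QQ": p_qq, "het": p_het}, skipped)


def consensus_gene_action(results: list[GeneActionResult]) -> GeneActionResult:
    """Combine per-family classifications: the dominance label must be
    supported by at least one family and contradicted by none; epistasis is
    flagged when any family with both strata populated flags it."""
    labels = {r.action for r in results if r.action != "inconclusive"}
    action = labels.pop() if len(labels) == 1 else "inconclusive"
    epistasis = any(r.epistasis for r in results)
    sizes = [r.min_group_size for r in results if r.min_group_size]
    return GeneActionResult("consensus", None, action, epistasis,
                            min(sizes) if sizes else 0,
                            {i: r.pvalues for i, r in enumerate(results)})


# ---------------------------------------------------------------------------
# segregation distortion


@dataclass
class DistortionProfile:
    table: pd.DataFrame        # cm, dist_cm, freq (paternal coupling allele)
    slope: float | None
    intercept: float | None
    p: float | None


def distortion_profile(matrix: HaploblockMatrix, offspring_ids, father,
                       chrom, s_cm: float, coupling_homolog: int = 0,
                       n_boot: int = 500, seed: int = 0) -> DistortionProfile:
    """Frequency, among surviving offspring, of the paternal allele in
    coupling with the rejected S-allele, per marker, regressed on cM distance
    from the S-locus.

    `coupling_homolog` names the father's homolog carrying the shared
    S-allele.  Only markers where the father is heterozygous (paternal
    monohybrid segregation) are informative.  Because linked markers share
    the same transmissions, per-marker frequencies are strongly
    autocorrelated and a marker-level regression p-value would be grossly
    anti-conservative; the slope's p is therefore computed by bootstrapping
    offspring (the true sampling unit).
    """
    cidx = matrix.chrom_block_indices(chrom)
    if cidx.size == 0:
        return DistortionProfile(pd.DataFrame(), None, None, None)
    fi = matrix.index_of(father)
    cms = matrix.blocks["cm"].to_numpy()[cidx]
    off_idx = [matrix.index_of(i) for i in offspring_ids]
    cols, dists, marker_cms = [], [], []
    for j, cm in zip(cidx, cms):
        coup = matrix.calls[fi, j, coupling_homolog]
        other = matrix.calls[fi, j, 1 - coupling_homolog]
        if coup == MISSING or coup == other:
            continue
        pat = matrix.calls[off_idx, j, 1]
        col = np.where(pat == MISSING, np.nan, (pat == coup).astype(float))
        if np.all(np.isnan(col)):
            continue
        cols.append(col)
        dists.append(abs(float(cm) - s_cm))
        marker_cms.append(float(cm))
    if not cols:
        return DistortionProfile(pd.DataFrame(), None, None, None)
    ind = np.column_stack(cols)          # offspring x markers, coupling indicator
    freqs = np.nanmean(ind, axis=0)
    table = pd.DataFrame({"cm": marker_cms, "dist_cm": dists, "freq": freqs})
    if len(table) < 3 or table["dist_cm"].nunique() < 2:
        import warnings
        if len(table) and table["dist_cm"].nunique() < 2:
            warnings.warn("degenerate distance range; distortion regression skipped")
        return DistortionProfile(table, None, None, None)

    d = np.asarray(dists)
    d_c = d - d.mean()

    def slope_of(mat):
        f = np.nanmean(mat, axis=0)
        return float(d_c @ (f - f.mean()) / (d_c @ d_c))

    slope = slope_of(ind)
    intercept = float(freqs.mean() - slope * d.mean())
    rng = np.random.default_rng(seed)
    n = ind.shape[0]
    boots = np.array([slope_of(ind[rng.integers(0, n, n)]) for _ in range(n_boot)])
    se = boots.std(ddof=1)
    if se == 0:
        p = 0.0 if slope != 0 else 1.0
    else:
        p = float(2.0 * stats.norm.sf(abs(slope) / se))
    return DistortionProfile(table, slope, intercept, p)


# ---------------------------------------------------------------------------
# within-family haplotype-contrast scan


def family_haplotype_scan(matrix: HaploblockMatrix, pedigree: pd.DataFrame,
                          phenotypes: pd.Series, family: str) -> pd.DataFrame:
    """Welch-t contrast profile along the genome for one full-sib family.

    At each haploblock, offspring are split by which parental homolog they
    inherited (separately for each parent, where that parent is
    heterozygous); returns per-HB t, p and -log10 p for the stronger parent.
    This is localisation plumbing, not an estimate of QTL effects.
    """
    fam = pedigree[pedigree["family"] == family]
    if fam.empty:
        raise ValueError(f"unknown family {family}")
    mother, father = fam["mother"].iloc[0], fam["father"].iloc[0]
    off = [i for i in fam["id"] if i in phenotypes.index
           and np.isfinite(phenotypes[i])]
    if len(off) < 20:
        raise ValueError("need at least 20 phenotyped offspring")
    y = phenotypes.loc[off].to_numpy(dtype=float)
    off_idx = [matrix.index_of(i) for i in off]
    rows = []
    for j in range(matrix.n_blocks):
        rec = {"chrom": matrix.blocks["chrom"].iloc[j],
               "hb_index": int(matrix.blocks["index"].iloc[j]),
               "cm": float(matrix.blocks["cm"].iloc[j])}
        best = None
        for parent, slot in ((mother, 0), (father, 1)):
            pi = matrix.index_of(parent)
            h0, h1 = matrix.calls[pi, j]
            if h0 == MISSING or h1 == MISSING or h0 == h1:
                continue
            trans = matrix.calls[off_idx, j, slot]
            g0 = y[trans == h0]
            g1 = y[trans == h1]
            if len(g0) < 2 or len(g1) < 2:
                continue
            t, p = stats.ttest_ind(g0, g1, equal_var=False)
            if best is None or p < best[1]:
                best = (float(t), float(p), parent)
        if best is None:
            continue
        rec.update({"t": best[0], "p": best[1],
                    "neglog10p": float(-np.log10(max(best[1], 1e-300))),
                    "parent": best[2]})
        rows.append(rec)
    return pd.DataFrame(rows)
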