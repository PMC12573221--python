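"""Joint-haploblock haplotype association in diversity germplasm.

Two-stage analysis: a sliding scan over windows of 2-30 consecutive
haploblocks fits, per window, the kinship mixed model

    BLUE_ij = mu + H_i + G_j + e_ij

with the joint identical-by-state haplotype H as a fixed allele-dosage
effect (additive over the two homologs of each genotype) and the genotype G
as a random effect with a VanRaden G-matrix as covariance.  Windows are
scored by

    pIndex = (proportion of individuals retained after MAF filtering)
             * (-log10 p_haplotype)

where p_haplotype tests the haplotype term against the kinship-only null.
The best window under the QTL-interval constraints is then dissected
with an ordinary linear model, residual diagnostics, and Duncan's new
multiple range test (alpha 0.1) to classify haplotypes as Late / Early /
Ambiguous.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._lmm import RandomTerm, fit_lmm
from .hb import MISSING, HaploblockMatrix


def vanraden_grm(dosages, freqs=None) -> pd.DataFrame:
    """VanRaden genomic relationship matrix G = W W' / (2 sum p(1-p)),
    W = M - 2p, from a (individuals x markers) dosage matrix in {0,1,2}."""
    if isinstance(dosages, pd.DataFrame):
        ids = list(dosages.index)
        M = dosages.to_numpy(dtype=float)
    else:
        M = np.asarray(dosages, dtype=float)
        ids = list(range(M.shape[0]))
    if np.any((M < 0) | (M > 2)):
        raise ValueError("dosages must lie in {0, 1, 2}")
    p = M.mean(axis=0) / 2.0 if freqs is None else np.asarray(freqs, dtype=float)
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom == 0:
        raise ValueError("all markers monomorphic: zero VanRaden denominator")
    W = M - 2.0 * p
    G = (W @ W.T) / denom
    return pd.DataFrame(G, index=ids, columns=ids)


@dataclass
class JointHaplotypeWindow:
    chrom: str
    start: int                 # HB index of the first block
    n_hbs: int
    cm_span: tuple             # (cM of first HB, cM of last HB)
    haplotype_freqs: dict      # joint allele string -> frequency (all homologs)
    prop_retained: float
    n_retained: int
    p_haplotype: float
    p_index: float
    retained_ids: list = field(default_factory=list, repr=False)
    haplotypes: dict = field(default_factory=dict, repr=False)  # id -> (h0, h1)

    @property
    def length_cm(self) -> float:
        return self.cm_span[1] - self.cm_span[0]


def _window_haplotypes(matrix: HaploblockMatrix, block_idx):
    """Joint allele strings per homolog; individuals with any missing call in
    the window are excluded."""
    out = {}
    for i, ind in enumerate(matrix.individuals):
        sub = matrix.calls[i, block_idx, :]
        if np.any(sub == MISSING):
            continue
        out[ind] = (tuple(sub[:, 0].tolist()), tuple(sub[:, 1].tolist()))
    return out


def scan_joint_haplotypes(matrix: HaploblockMatrix, blues: pd.Series,
                          grm: pd.DataFrame, chrom, maf: float = 0.05,
                          sizes=range(2, 31), log=None) -> list[JointHaplotypeWindow]:
    """Score every window of consecutive haploblocks on one chromosome.

    Individuals are retained when both of their joint haplotypes in the
    window have frequency > `maf` (frequencies over all homologs entering the
    scan).  Windows with fewer than two haplotype levels after filtering are
    skipped.
    """
    phenotyped = [i for i in matrix.individuals if i in blues.index
                  and np.isfinite(blues[i])]
    if len(phenotyped) < 20:
        raise ValueError("need phenotype BLUEs for at least 20 individuals")
    cidx = matrix.chrom_block_indices(chrom)
    if cidx.size == 0:
        raise ValueError(f"no haploblocks on chromosome {chrom}")
    cms = matrix.blocks["cm"].to_numpy()[cidx]
    windows = []
    for size in sizes:
        for s in range(len(cidx) - size + 1):
            block_idx = cidx[s:s + size]
            haps = _window_haplotypes(matrix, block_idx)
            haps = {i: h for i, h in haps.items() if i in phenotyped}
            n_enter = len(haps)
            if n_enter == 0:
                continue
            counts = pd.Series([h for pair in haps.values() for h in pair]).value_counts()
            freqs = counts / counts.sum()
            keep = {i: pair for i, pair in haps.items()
                    if freqs[pair[0]] > maf and freqs[pair[1]] > maf}
            levels = sorted({h for pair in keep.values() for h in pair})
            prop = len(keep) / n_enter
            if len(levels) < 2:
                if log is not None:
                    log.append((chrom, s, size, "fewer than 2 haplotype levels"))
                continue
            p = _haplotype_lrt(keep, blues, grm, levels)
            pindex = prop * (-np.log10(max(p, 1e-300)))
            windows.append(JointHaplotypeWindow(
                chrom=str(chrom), start=s, n_hbs=size,
                cm_span=(float(cms[s]), float(cms[s + size - 1])),
                haplotype_freqs=freqs.to_dict(), prop_retained=prop,
                n_retained=len(keep), p_haplotype=p, p_index=float(pindex),
                retained_ids=sorted(keep), haplotypes=keep))
    return windows


def _haplotype_lrt(haps: dict, blues: pd.Series, grm: pd.DataFrame, levels) -> float:
    """p-value for the joint-haplotype term in the kinship mixed model.

    Allele effects are additive over the two homologs, so the model is fitted
    with one row per genotype and the haplotype term coded as dosages (copies
    of each haplotype, reference level dropped); the genotype random effect
    carries the G-matrix as covariance.  Fitting a literal duplicated-row
    layout (each homolog a row with the genotype's phenotype repeated) is
    degenerate under maximum likelihood — the within-pair contrasts carry no
    data — whereas the dosage layout estimates the identical allele effects
    on a sound likelihood.  The haplotype term is tested with a GLS F-test at
    the variance ratio estimated under the null model; the chi-square
    likelihood-ratio reference is anti-conservative at germplasm sample
    sizes (null rejection near 9% at the 5% level), while the F reference
    keeps the permutation null uniform."""
    from scipy import linalg

    from ._lmm import drop_aliased

    ids = sorted(haps)
    n = len(ids)
    y = blues.loc[ids].to_numpy(dtype=float)
    lut = {h: j for j, h in enumerate(levels)}
    D = np.zeros((n, len(levels)))
    for r, i in enumerate(ids):
        for k in range(2):
            D[r, lut[haps[i][k]]] += 1.0
    X_full = np.column_stack([np.ones(n), D[:, 1:]])
    X_null = np.ones((n, 1))
    K = grm.loc[ids, ids].to_numpy(dtype=float)
    terms = [RandomTerm("genotype", np.eye(n), K=K, levels=ids)]
    null = fit_lmm(y, X_null, terms, method="ml")
    # GLS F-test at the null's variance ratio: the chi-square LRT is
    # anti-conservative at these sample sizes, the F reference is not
    gamma = (null.varcomp["genotype"] / null.sigma2_resid
             if null.sigma2_resid > 0 else 0.0)
    V0 = np.eye(n) + gamma * K
    L = linalg.cholesky(V0 + 1e-10 * np.eye(n), lower=True)
    yw = linalg.solve_triangular(L, y, lower=True)
    Xf, _, _ = drop_aliased(linalg.solve_triangular(L, X_full, lower=True),
                            list(range(X_full.shape[1])))
    Xn = linalg.solve_triangular(L, X_null, lower=True)
    rss_full = float(np.sum((yw - Xf @ np.linalg.lstsq(Xf, yw, rcond=None)[0]) ** 2))
    rss_null = float(np.sum((yw - Xn @ np.linalg.lstsq(Xn, yw, rcond=None)[0]) ** 2))
    df1 = Xf.shape[1] - 1
    df2 = n - Xf.shape[1]
    if df1 <= 0 or df2 <= 0 or rss_full <= 0:
        return 1.0
    F = ((rss_null - rss_full) / df1) / (rss_full / df2)
    return float(stats.f.sf(max(F, 0.0), df1, df2))


def select_best_window(windows, inner_cm: tuple, outer_cm: tuple):
    """Maximal-pIndex window overlapping the inner QTL interval with a cM
    length not exceeding the outer interval's; ties broken by fewer HBs, then
    smaller start index.  Returns None when no window qualifies."""
    if not windows:
        raise ValueError("empty candidate list")
    outer_len = outer_cm[1] - outer_cm[0]
    ok = [w for w in windows
          if w.cm_span[0] <= inner_cm[1] and w.cm_span[1] >= inner_cm[0]
          and w.length_cm <= outer_len]
    if not ok:
        return None
    return min(ok, key=lambda w: (-w.p_index, w.n_hbs, w.start))


# ---------------------------------------------------------------------------
# Duncan's new multiple range test


def duncan_groups(means: pd.Series, mse: float, df_resid: int, n_sizes: pd.Series,
                  alpha: float = 0.1) -> pd.Series:
    """Letter groups from Duncan's new multiple range test.

    The least significant range for p ordered means is
    R_p = q(1 - (1-alpha)^(p-1); p, df) * sqrt(MSE / n_h) with n_h the
    harmonic mean of group sizes (agricolae convention for unequal n).
    Ranges contained in a non-significant range are declared non-significant.
    """
    order = means.sort_values(ascending=False)
    k = len(order)
    if k == 1:
        return pd.Series({order.index[0]: "a"})
    n_h = k / float((1.0 / n_sizes.loc[order.index]).sum())
    crit = {p: float(stats.studentized_range.ppf((1 - alpha) ** (p - 1), p, df_resid))
            * np.sqrt(mse / n_h) for p in range(2, k + 1)}
    m = order.to_numpy()
    nonsig = np.zeros((k, k), dtype=bool)   # i < j over the ordered means
    for span in range(k, 1, -1):
        for i in range(0, k - span + 1):
            j = i + span - 1
            if m[i] - m[j] <= crit[span]:
                nonsig[i, i:j + 1] = True
                for a in range(i, j + 1):
                    for b in range(a, j + 1):
                        nonsig[a, b] = True
    for i in range(k):
        nonsig[i, i] = True
    # maximal non-significant intervals -> letters
    letters = [set() for _ in range(k)]
    intervals = []
    for i in range(k):
        j = i
        while j + 1 < k and nonsig[i, j + 1]:
            j += 1
        intervals.append((i, j))
    # drop intervals contained in earlier ones
    maximal = []
    for iv in intervals:
        if not any(o[0] <= iv[0] and iv[1] <= o[1] for o in maximal):
            maximal.append(iv)
    for (a, b), letter in zip(maximal, string.ascii_lowercase):
        for idx in range(a, b + 1):
            letters[idx].add(letter)
    return pd.Series({h: "".join(sorted(ls)) for h, ls in zip(order.index, letters)})


@dataclass
class AlleleClassification:
    haplotype: str
    cls: str                   # Late | Early | Ambiguous
    effect_days: float         # vs model intercept (reference haplotype)
    mean_blue: float
    n_homologs: int
    duncan_letters: str


@dataclass
class PosthocResult:
    classifications: list
    bp_p: float                # studentized Breusch-Pagan on residuals
    shapiro_p: float
    mse: float
    df_resid: int
    reference: str
    model_p: pd.Series         # per-haplotype Wald p vs intercept


def posthoc_allele_effects(window: JointHaplotypeWindow, blues: pd.Series,
                           alpha: float = 0.1) -> PosthocResult:
    """Ordinary linear model of the BLUE on the joint haplotype (two rows per
    genotype), residual diagnostics, Duncan letters and Late/Early/Ambiguous
    classes.

    The most frequent haplotype is the intercept reference.  Haplotypes whose
    letters are confined to the highest-mean letter group are Late, to the
    lowest Early; haplotypes spanning both sides are Ambiguous.
    """
    import statsmodels.api as sm
    from statsmodels.stats.diagnostic import het_breuschpagan

    ids = window.retained_ids
    rows = [(str(window.haplotypes[i][k]), float(blues[i]))
            for i in ids for k in range(2)]
    df = pd.DataFrame(rows, columns=["hap", "blue"])
    levels = df["hap"].value_counts().index.tolist()   # most frequent first
    if len(levels) < 2:
        raise ValueError("need at least two haplotype levels")
    dummies = pd.get_dummies(pd.Categorical(df["hap"], categories=levels),
                             drop_first=True, dtype=float)
    X = sm.add_constant(dummies)
    ols = sm.OLS(df["blue"], X).fit()
    resid = ols.resid.to_numpy()
    if np.ptp(resid) == 0:
        bp_p, sw_p = 1.0, 1.0
    else:
        bp_p = float(het_breuschpagan(resid, X.to_numpy())[3])
        sw_p = float(stats.shapiro(resid)[1])
    means = df.groupby("hap")["blue"].mean()
    sizes = df.groupby("hap")["blue"].size()
    mse = float(ols.mse_resid)
    letters = duncan_groups(means, mse, int(ols.df_resid), sizes, alpha=alpha)
    order = means.sort_values(ascending=False)
    top_letters = set(letters[order.index[0]])
    bot_letters = set(letters[order.index[-1]])
    effects = {levels[0]: 0.0}
    pvals = {levels[0]: np.nan}
    for name in dummies.columns:
        effects[name] = float(ols.params[name])
        pvals[name] = float(ols.pvalues[name])
    classifications = []
    for hap in order.index:
        ls = set(letters[hap])
        in_top = bool(ls & top_letters)
        in_bot = bool(ls & bot_letters)
        if top_letters == bot_letters:
            cls = "Ambiguous"
        elif in_top and not in_bot:
            cls = "Late"
        elif in_bot and not in_top:
            cls = "Early"
        else:
            cls = "Ambiguous"
        classifications.append(AlleleClassification(
            haplotype=hap, cls=cls, effect_days=effects.get(hap, np.nan),
            mean_blue=float(means[hap]), n_homologs=int(sizes[hap]),
            duncan_letters=letters[hap]))
    return PosthocResult(classifications, bp_p, sw_p, mse, int(ols.df_resid),
                         levels[0], pd.Series(pvals))


@dataclass
class EffectiveGenotypes:
    means: pd.Series           # class -> mean BLUE
    counts: pd.Series
    n_excluded: int
    delay_het_vs_early: float | None   # Early/Late minus Early/Early


def effective_genotype_means(window: JointHaplotypeWindow,
                             posthoc: PosthocResult,
                             blues: pd.Series) -> EffectiveGenotypes:
    """Group fully inferred individuals (both homologs non-Ambiguous) into
    Early/Early, Early/Late and Late/Late diplotype classes."""
    cls_of = {c.haplotype: c.cls for c in posthoc.classifications}
    rows = []
    n_excluded = 0
    for i in window.retained_ids:
        c0 = cls_of.get(str(window.haplotypes[i][0]), "Ambiguous")
        c1 = cls_of.get(str(window.haplotypes[i][1]), "Ambiguous")
        if "Ambiguous" in (c0, c1):
            n_excluded += 1
            continue
        label = "/".join(sorted([c0, c1]))    # Early/Early, Early/Late, Late/Late
        rows.append((label, float(blues[i])))
    if not rows:
        return EffectiveGenotypes(pd.Series(dtype=float), pd.Series(dtype=int),
                                  n_excluded, None)
    df = pd.DataFrame(rows, columns=["cls", "blue"])
    means = df.groupby("cls")["blue"].mean()
    counts = df.groupby("cls")["blue"].size()
    delay = None
    if "Early/Late" in means.index and "Early/Early" in means.index:
        delay = float(means["Early/Late"] - means["Early/Early"])
    return EffectiveGenotypes(means, counts, n_excluded, delay)
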