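"""Phenotypic analysis of the germplasm collection.

Wraps the mixed-model engine with the trial's model structures:

* per-year genotype BLUEs (genotype fixed, planting year random);
* across-year genotype BLUEs (genotype fixed; year, planting-year-in-year and
  accession-replicate random) and BLUPs (the same with genotype random);
* fixed year effects (genotype and planting-year-in-genotype random);
* broad-sense heritability as the slope of BLUP regressed on BLUE;
* cooling-degree-day (CDD) models of the year effects;
* Pearson and Stuart's tau-c correlations and the variance-ratio F-test used
  for the climate-zone contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._lmm import MixedModelFit, RandomTerm, fit_lmm, indicator

REQUIRED_COLUMNS = ("genotype_id", "year", "year_planted", "tree_id")


@dataclass
class HeritabilityEstimate:
    h2: float
    n_genotypes: int
    intercept: float
    r_squared: float


@dataclass
class CddModel:
    base: float
    cdd_by_year: pd.Series     # accumulated to intercept + year effect
    r: float | None
    p: float | None


def _check(pheno: pd.DataFrame, response: str) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in pheno.columns]
    if missing:
        raise ValueError(f"phenotype table lacks columns {missing}")
    df = pheno.dropna(subset=[response]).copy()
    dup = df.duplicated(subset=["tree_id", "year"])
    if dup.any():
        raise ValueError("each tree-year may contribute at most one row")
    for c in ("genotype_id", "tree_id"):
        df[c] = df[c].astype(str)
    return df


def _genotype_design(df: pd.DataFrame):
    """Treatment-coded fixed genotype design (intercept + effects vs first level)."""
    levels = sorted(df["genotype_id"].unique())
    Z, _ = indicator(df["genotype_id"], levels)
    X = np.column_stack([np.ones(len(df)), Z[:, 1:]])
    names = ["(Intercept)"] + [f"G[{g}]" for g in levels[1:]]
    return X, names, levels


def _blues_from_fit(fit: MixedModelFit, levels) -> pd.Series:
    """Genotype BLUEs on the response scale: intercept + genotype effect."""
    mu = fit.beta[0]
    eff = {lv: 0.0 for lv in levels}
    for name, b in zip(fit.fe_names[1:], fit.beta[1:]):
        eff[name[2:-1]] = b
    return pd.Series({lv: mu + eff[lv] for lv in levels}, name="blue")


def blues_per_year(pheno: pd.DataFrame, year, response: str = "JD50"):
    """Single-year genotype BLUEs: response = mu + genotype (fixed)
    + planting-year (random) + residual."""
    df = _check(pheno, response)
    df = df[df["year"] == year]
    if df.empty:
        raise ValueError(f"no rows for year {year}")
    X, names, levels = _genotype_design(df)
    Zyp, yp_levels = indicator(df["year_planted"])
    terms = []
    if len(yp_levels) > 1:
        terms.append(RandomTerm("year_planted", Zyp, levels=yp_levels))
    fit = fit_lmm(df[response].to_numpy(), X, terms, fe_names=names)
    return _blues_from_fit(fit, levels), fit


def _across_year_terms(df: pd.DataFrame, include_genotype_random: bool):
    terms = []
    if include_genotype_random:
        Zg, g_levels = indicator(df["genotype_id"])
        terms.append(RandomTerm("genotype", Zg, levels=g_levels))
    Zy, y_levels = indicator(df["year"])
    terms.append(RandomTerm("year", Zy, levels=y_levels))
    yp_in_y = df["year"].astype(str) + ":" + df["year_planted"].astype(str)
    Zyp, yp_levels = indicator(yp_in_y)
    terms.append(RandomTerm("year_planted(year)", Zyp, levels=yp_levels))
    # accession replicate: a tree-level intercept (nested under planting year),
    # shared across assessment years
    acc = df["year_planted"].astype(str) + ":" + df["tree_id"].astype(str)
    Za, a_levels = indicator(acc)
    terms.append(RandomTerm("accession", Za, levels=a_levels))
    return terms


def blues_across_years(pheno: pd.DataFrame, response: str = "JD50"):
    """Across-year genotype BLUEs: genotype fixed; year, planting year nested
    in year and accession replicate random."""
    df = _check(pheno, response)
    X, names, levels = _genotype_design(df)
    terms = _across_year_terms(df, include_genotype_random=False)
    fit = fit_lmm(df[response].to_numpy(), X, terms, fe_names=names)
    return _blues_from_fit(fit, levels), fit


def blups_across_years(pheno: pd.DataFrame, response: str = "JD50"):
    """Across-year genotype BLUPs: as the BLUE model but with genotype random."""
    df = _check(pheno, response)
    X = np.ones((len(df), 1))
    terms = _across_year_terms(df, include_genotype_random=True)
    fit = fit_lmm(df[response].to_numpy(), X, terms, fe_names=["(Intercept)"])
    return fit.blups["genotype"].rename("blup"), fit


def year_effects(pheno: pd.DataFrame, response: str = "JD50"):
    """Fixed year-of-assessment effects (first year is the intercept
    reference); genotype and planting-year-in-genotype random.

    Returns (effects Series incl. reference year at 0, intercept, fit)."""
    df = _check(pheno, response)
    years = sorted(df["year"].unique())
    Zy, _ = indicator(df["year"], [str(y) for y in years])
    X = np.column_stack([np.ones(len(df)), Zy[:, 1:]])
    names = ["(Intercept)"] + [f"Y[{y}]" for y in years[1:]]
    Zg, g_levels = indicator(df["genotype_id"])
    yp_in_g = df["genotype_id"].astype(str) + ":" + df["year_planted"].astype(str)
    Zyp, yp_levels = indicator(yp_in_g)
    terms = [RandomTerm("genotype", Zg, levels=g_levels),
             RandomTerm("year_planted(genotype)", Zyp, levels=yp_levels)]
    fit = fit_lmm(df[response].to_numpy(), X, terms, fe_names=names)
    eff = {years[0]: 0.0}
    for name, b in zip(fit.fe_names[1:], fit.beta[1:]):
        eff[int(name[2:-1])] = float(b)
    return pd.Series(eff, name="year_effect"), float(fit.beta[0]), fit


def heritability_blup_on_blue(blups: pd.Series, blues: pd.Series) -> HeritabilityEstimate:
    """Broad-sense heritability approximated by the slope of the regression of
    genotype BLUPs on genotype BLUEs."""
    common = blups.index.intersection(blues.index)
    if len(common) < 3:
        raise ValueError("need at least 3 genotypes")
    x = blues.loc[common].to_numpy(dtype=float)
    y = blups.loc[common].to_numpy(dtype=float)
    x_c = x - x.mean()
    sxx = float(x_c @ x_c)
    if sxx == 0:
        raise ValueError("BLUEs have zero variance")
    slope = float(x_c @ (y - y.mean()) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / tss if tss > 0 else np.nan
    return HeritabilityEstimate(slope, len(common), intercept, r2)


# ---------------------------------------------------------------------------
# cooling degree days


def cdd(temps: pd.DataFrame, base: float, end_day: float, year=None) -> float:
    """CDD accumulated from Aug 1 (day 0) to `end_day`: sum over days of
    max(0, base - Tmean); a fractional final day contributes pro rata.

    `temps` has columns t (days since Aug 1) and tmean_c, optionally year."""
    df = temps if year is None else temps[temps["year"] == year]
    df = df.sort_values("t")
    t = df["t"].to_numpy(dtype=float)
    needed = np.arange(0, int(np.floor(end_day)) + 1)
    missing = np.setdiff1d(needed, t.astype(int))
    if missing.size:
        raise ValueError(f"temperature series has gaps at days {missing.tolist()[:10]}")
    by_day = df.set_index(df["t"].astype(int))["tmean_c"]
    full = int(np.floor(end_day))
    deficits = np.maximum(0.0, base - by_day.loc[np.arange(full)].to_numpy())
    total = float(deficits.sum())
    frac = end_day - full
    if frac > 0:
        total += frac * max(0.0, base - float(by_day.loc[full]))
    return total


DEFAULT_CDD_BASES = (5.0, 10.0, 15.0, 20.0, 25.0, 30.0)


def cdd_year_correlation(year_effects: pd.Series, intercept: float,
                         temps: pd.DataFrame,
                         bases=DEFAULT_CDD_BASES) -> list[CddModel]:
    """Per base: Pearson correlation between the yearly dates
    (intercept + year effect) and the CDD accumulated to those dates."""
    years = sorted(year_effects.index)
    if len(years) < 3:
        raise ValueError("need at least 3 years")
    dates = np.array([intercept + year_effects[y] for y in years])
    out = []
    for base in bases:
        vals = pd.Series({y: cdd(temps, base, d, year=y)
                          for y, d in zip(years, dates)})
        v = vals.to_numpy()
        if np.ptp(v) == 0 or np.ptp(dates) == 0:
            out.append(CddModel(base, vals, None, None))
            continue
        r, p = stats.pearsonr(dates, v)
        out.append(CddModel(base, vals, float(r), float(p)))
    return out


def best_cdd_base(models: list[CddModel]) -> float:
    defined = [m for m in models if m.r is not None]
    if not defined:
        raise ValueError("no CDD model has a defined correlation")
    return max(defined, key=lambda m: abs(m.r)).base


# ---------------------------------------------------------------------------
# correlation and variance tests


def pearson_cor(x, y) -> tuple[float, float]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need n >= 3")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class TauC:
    tau_c: float
    se: float
    ci: tuple
    level: float
    n: int


def stuart_tau_c(x, y, ci_level: float = 0.95) -> TauC:
    """Stuart's tau-c for ordinal variables:
    tau_c = 2 m (C - D) / (n^2 (m - 1)) with m = min(#rows, #cols) of the
    contingency table; the CI uses the consistent estimate of var(C - D)."""
    x = np.asarray(x)
    y = np.asarray(y)
    n = len(x)
    tab = pd.crosstab(pd.Series(x), pd.Series(y)).to_numpy(dtype=float)
    R, Cc = tab.shape
    m = min(R, Cc)
    if m < 2:
        import warnings
        warnings.warn("tau-c undefined direction: fewer than 2 levels; returning 0")
        return TauC(0.0, np.nan, (np.nan, np.nan), ci_level, n)
    # d[i,j] = (concordant count for cell ij) - (discordant count)
    A = np.zeros_like(tab)
    D = np.zeros_like(tab)
    for i in range(R):
        for j in range(Cc):
            A[i, j] = tab[:i, :j].sum() + tab[i + 1:, j + 1:].sum()
            D[i, j] = tab[:i, j + 1:].sum() + tab[i + 1:, :j].sum()
    PQ = float((tab * (A - D)).sum())     # 2(C - D), ordered pair count
    tau = m * PQ / (n**2 * (m - 1))
    d = A - D
    var = (4.0 * m**2 / ((m - 1) ** 2 * n**4)) * float((tab * d**2).sum() - PQ**2 / n)
    se = float(np.sqrt(max(var, 0.0)))
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    return TauC(float(tau), se, (tau - z * se, tau + z * se), ci_level, n)


def variance_ratio_test(a, b, alternative: str = "less") -> tuple[float, float]:
    """F-test of var(a)/var(b); one-sided by default (H1: var(a) < var(b))."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need n >= 3 per group")
    ratio = float(np.var(a, ddof=1) / np.var(b, ddof=1))
    dfa, dfb = len(a) - 1, len(b) - 1
    if alternative == "less":
        p = stats.f.cdf(ratio, dfa, dfb)
    elif alternative == "greater":
        p = stats.f.sf(ratio, dfa, dfb)
    elif alternative == "two-sided":
        p = 2 * min(stats.f.cdf(ratio, dfa, dfb), stats.f.sf(ratio, dfa, dfb))
        p = min(p, 1.0)
    else:
        raise ValueError(f"unknown alternative {alternative}")
    return ratio, float(p)
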