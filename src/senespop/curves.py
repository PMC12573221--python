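"""Logistic modelling of autumn canopy senescence.

Each tree-season series of visual percent-senescence scores is modelled with
the logistic function

    N(t) = K / (1 + ((K - N0) / N0) * exp(-r_sen * t))

where t counts days from August 1, K is the carrying capacity (maximum
percent canopy senescence in the model), N0 the modelled percentage at t = 0
and r_sen the maximal intrinsic rate of senescence.  Two anchor points are
added post hoc to every series before fitting: (t=0, 0%) for August 1 and
(t=152, 100%) for December 31.  The date at which the fitted curve crosses
50% (JD50) is the main phenotype; it is defined only when K > 50.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares
from scipy.special import expit, logit

ANCHOR_START_T = 0.0     # August 1
ANCHOR_END_T = 152.0     # December 31 (152 days after August 1)

K_BOUNDS = (1e-3, 120.0)
N0_MIN = 0.01
R_BOUNDS = (1e-6, 5.0)


@dataclass
class SenescenceSeries:
    """Dated percent-senescence observations for one tree in one season."""

    tree_id: str
    year: int
    t: np.ndarray
    values: np.ndarray
    anchors_included: bool = False

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.t.shape != self.values.shape:
            raise ValueError("t and values must have the same length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("observation times must be strictly increasing")
        if np.any((self.values < 0) | (self.values > 100)):
            raise ValueError("percent senescence must lie in [0, 100]")


@dataclass
class LogisticFit:
    tree_id: str
    year: int
    K: float
    N0: float
    r_sen: float
    rss: float
    converged: bool
    jd50: float | None = None
    n_obs: int = 0

    def predict(self, t):
        return logistic(np.asarray(t, dtype=float), self.K, self.N0, self.r_sen)


@dataclass
class SenScore:
    """Sparse-scoring summary: mean percent senescent canopy (%SEN)."""

    individual: str
    values: np.ndarray
    sen: float
    excluded: bool = False
    n_used: int = 0


def logistic(t, K, N0, r):
    return K / (1.0 + ((K - N0) / N0) * np.exp(-r * t))


def add_anchors(series: SenescenceSeries) -> SenescenceSeries:
    """Append the (Aug 1, 0%) and (Dec 31, 100%) anchor points.

    Raises if the anchors are already present or if an observation already
    occupies an anchor date (conflicting or not: the anchor convention owns
    those two dates).
    """
    if series.anchors_included:
        raise ValueError("anchors already included")
    if np.any(np.isin(series.t, [ANCHOR_START_T, ANCHOR_END_T])):
        raise ValueError("series already contains a point at an anchor date")
    t = np.concatenate([[ANCHOR_START_T], series.t, [ANCHOR_END_T]])
    v = np.concatenate([[0.0], series.values, [100.0]])
    order = np.argsort(t)
    return replace(series, t=t[order], values=v[order], anchors_included=True)


def _pack(K, N0, r):
    # free parametrisation keeping 0.01 < N0 < K inside box bounds
    u = logit(np.clip((N0 - N0_MIN) / (K - N0_MIN), 1e-9, 1 - 1e-9))
    return np.array([K, u, r])


def _unpack(theta):
    K, u, r = theta
    N0 = N0_MIN + (K - N0_MIN) * expit(u)
    return K, N0, r


def fit_logistic(series: SenescenceSeries, n_restarts: int = 5, seed: int = 0) -> LogisticFit:
    """Nonlinear least-squares fit of the anchored logistic model.

    Initial values: K = 100, N0 = max(first observation, 0.5), r_sen from a
    log-linear regression of logit(N/K) on t; up to `n_restarts` jittered
    restarts if the optimizer fails to converge.
    """
    if not series.anchors_included:
        raise ValueError("call add_anchors before fitting")
    t, v = series.t, series.values
    if len(t) < 4:
        raise ValueError("need at least 4 points (including anchors) to fit")

    def resid(theta):
        K, N0, r = _unpack(theta)
        return logistic(t, K, N0, r) - v

    obs = v[(t > ANCHOR_START_T) & (t < ANCHOR_END_T)]
    K0 = 100.0
    N0_0 = max(obs[0] if obs.size else 0.5, 0.5)
    frac = np.clip(v / K0, 1e-3, 1 - 1e-3)
    mask = (t > 0) & (t < ANCHOR_END_T)
    if mask.sum() >= 2:
        slope = np.polyfit(t[mask], logit(frac[mask]), 1)[0]
        r0 = float(np.clip(slope, 0.01, 1.0))
    else:
        r0 = 0.05

    rng = np.random.default_rng(seed)
    lo = np.array([K_BOUNDS[0], -30.0, R_BOUNDS[0]])
    hi = np.array([K_BOUNDS[1], 30.0, R_BOUNDS[1]])
    best = None
    for attempt in range(n_restarts + 1):
        if attempt == 0:
            K_i, N0_i, r_i = K0, N0_0, r0
        else:
            K_i = float(np.clip(K0 * rng.uniform(0.7, 1.1), *K_BOUNDS))
            N0_i = float(np.clip(N0_0 * rng.uniform(0.3, 3.0), N0_MIN * 1.1, K_i * 0.9))
            r_i = float(np.clip(r0 * rng.uniform(0.3, 3.0), *R_BOUNDS))
        theta0 = np.clip(_pack(K_i, N0_i, r_i), lo + 1e-9, hi - 1e-9)
        try:
            sol = least_squares(resid, theta0, bounds=(lo, hi), xtol=1e-12, ftol=1e-12, gtol=1e-12)
        except Exception:
            continue
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0] - 1e-12:
            best = (rss, sol)
        if sol.success and attempt == 0:
            break
    if best is None:
        return LogisticFit(series.tree_id, series.year, np.nan, np.nan, np.nan,
                           np.inf, False, None, len(t))
    rss, sol = best
    K, N0, r = _unpack(sol.x)
    fit = LogisticFit(series.tree_id, series.year, float(K), float(N0), float(r),
                      rss, bool(sol.success), None, len(t))
    fit.jd50 = jd50_from_fit(fit)
    return fit


def jd50_from_fit(fit: LogisticFit) -> float | None:
    """Closed-form day (since Aug 1) at which the fitted curve reaches 50%.

    t50 = (1/r) * ln( ((K - N0)/N0) / (K/50 - 1) ); undefined (None) when the
    carrying capacity never allows 50% senescence (K <= 50) or the fit failed.
    """
    if not fit.converged or not np.isfinite(fit.K):
        return None
    if fit.K <= 50.0:
        return None
    return float(np.log(((fit.K - fit.N0) / fit.N0) / (fit.K / 50.0 - 1.0)) / fit.r_sen)


def compute_sen_score(individual: str, values, n_expected: int = 6,
                      missing_policy: str = "strict", min_scores: int = 6) -> SenScore:
    """Mean percent senescent canopy across the sparse assessments (%SEN).

    missing_policy "strict" requires exactly `n_expected` scores;
    "mean-of-available" averages what is present, flagging the individual
    excluded when fewer than `min_scores` scores remain.
    """
    arr = np.asarray([v for v in values if v is not None and np.isfinite(v)], dtype=float)
    if np.any((arr < 0) | (arr > 100)):
        raise ValueError("scores must lie in [0, 100]")
    if missing_policy == "strict":
        if len(arr) != n_expected:
            raise ValueError(f"expected exactly {n_expected} scores, got {len(arr)}")
        return SenScore(individual, arr, float(arr.mean()), False, len(arr))
    if missing_policy == "mean-of-available":
        if len(arr) < min_scores:
            return SenScore(individual, arr, float("nan"), True, len(arr))
        return SenScore(individual, arr, float(arr.mean()), False, len(arr))
    raise ValueError(f"unknown missing policy: {missing_policy}")


def fit_observation_table(obs, seed: int = 0):
    """Fit every tree-season in an observation table.

    `obs` is a DataFrame with columns tree_id, genotype_id, year_planted,
    year, t, percent.  Returns a DataFrame of per-tree-season parameters.
    """
    import pandas as pd

    rows = []
    for (tree, year), g in obs.groupby(["tree_id", "year"], sort=True):
        g = g.sort_values("t")
        series = SenescenceSeries(str(tree), int(year), g["t"].to_numpy(),
                                  g["percent"].to_numpy())
        fit = fit_logistic(add_anchors(series), seed=seed)
        rows.append({
            "tree_id": str(tree),
            "genotype_id": g["genotype_id"].iloc[0],
            "year_planted": g["year_planted"].iloc[0],
            "year": int(year),
            "K": fit.K, "N0": fit.N0, "r_sen": fit.r_sen,
            "JD50": fit.jd50 if fit.jd50 is not None else np.nan,
            "rss": fit.rss, "converged": fit.converged,
        })
    return pd.DataFrame(rows)
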