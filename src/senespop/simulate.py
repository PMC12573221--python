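"""Synthetic data generators for every input the pipeline consumes.

The generators emulate the statistical structure of a Nordic apple
phenology-genetics experiment:

* pedigree-connected full-sib apple families with meioses following a
  Poisson/Haldane crossover model and fully phased haploblock (HB) output;
* gametophytic self-incompatibility (SI): pollen carrying an S-allele shared
  with the seed parent is rejected, producing transmission-ratio distortion
  that decays with recombination distance from the S-locus;
* logistic canopy-senescence trajectories with genotype, year and residual
  effects on the day of 50% senescence (JD50);
* autumn daily mean temperature series (seasonal cosine + year offsets +
  day-level noise) tied to the injected year effects through a
  cooling-degree-day (CDD) calibration;
* a germplasm panel of mosaic haplotypes carrying one late-senescence joint
  haplotype for the association scan;
* two-group diploid variant panels with a hard-sweep locus (local diversity
  loss) and a partial-sweep locus (intermediate-frequency haplotype).

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .hb import MISSING, HaploblockMatrix

# ---------------------------------------------------------------------------
# configuration types


@dataclass
class QtlSpec:
    """One biallelic QTL with Q (early senescence) and q (late) alleles.

    `effects` maps a diplotype class (maternal allele first: 'QQ', 'qQ',
    'Qq', 'qq') to the phenotype shift it confers.  `epistatic_mask` names
    another locus whose heterozygous or qq state nullifies this locus's
    effect (masking epistasis).
    """

    name: str
    chrom: str
    cm: float
    effects: dict
    gene_action: str = "additive"   # additive | dominant_q | dominant_Q
    epistatic_mask: str | None = None

    def __post_init__(self):
        for k, v in self.effects.items():
            if not np.isfinite(v):
                raise ValueError(f"non-finite effect for class {k}")
        if self.epistatic_mask == self.name:
            raise ValueError("a locus cannot mask itself")

    def effect_of(self, diplotype: str) -> float:
        return float(self.effects.get(diplotype, self.effects.get(diplotype[::-1], 0.0)))


@dataclass
class SimulationConfig:
    seed: int = 0
    founders: list = field(default_factory=list)
    families: list = field(default_factory=list)   # (mother, father, n_offspring)
    n_haploblocks_per_chrom: dict = field(default_factory=dict)
    genetic_map: dict = field(default_factory=dict)    # chrom -> array of cM
    physical_map: dict = field(default_factory=dict)   # chrom -> array of bp
    s_locus: tuple | None = None                       # (chrom, cM)
    founder_s_alleles: dict = field(default_factory=dict)
    founder_qtl_alleles: dict = field(default_factory=dict)  # qtl -> founder -> (h0, h1)
    qtl_spec: list = field(default_factory=list)
    missing_rate: float = 0.0
    # senescence collection
    n_genotypes: int = 150
    n_trees_per_genotype: int = 2
    planting_years: tuple = (2013, 2014, 2015, 2016, 2017)
    h2_target: float = 0.8
    mu_jd50: float = 66.0
    sigma_genotype: float = 8.0
    sigma_resid: float | None = None     # derived from h2_target when None
    r_sen: float = 0.12
    year_effects: dict = field(default_factory=lambda: {2019: 0.0, 2020: 18.8, 2021: 9.7})
    obs_dates: dict | None = None        # year -> days since Aug 1
    obs_noise_sd: float = 5.0
    rounding_step: float = 5.0
    # temperature
    temp_year_offsets: dict | None = None   # °C; calibrated when None
    temp_noise_sd: float = 1.0
    cdd_calibration_base: float | None = 15.0
    # MPP phenotype
    mpp_base_sen: float = 48.0
    mpp_noise_sd: float = 6.0

    @property
    def n_founders(self) -> int:
        return len(self.founders)

    def __post_init__(self):
        for chrom, cms in self.genetic_map.items():
            cms = np.asarray(cms, dtype=float)
            if np.any(np.diff(cms) <= 0):
                raise ValueError(f"cM positions not strictly increasing on {chrom}")
            bps = np.asarray(self.physical_map.get(chrom, []), dtype=float)
            if bps.size and np.any(np.diff(bps) <= 0):
                raise ValueError(f"bp positions not strictly increasing on {chrom}")
        if not (0.0 <= self.h2_target <= 1.0):
            raise ValueError("h2_target must lie in [0, 1]")
        for _, _, n in self.families:
            if n <= 0:
                raise ValueError("n_offspring must be positive")
        if self.obs_noise_sd < 0:
            raise ValueError("obs_noise_sd must be non-negative")
        if self.h2_target == 1.0 and (self.sigma_resid or 0.0) > 0:
            raise ValueError("h2_target = 1 is inconsistent with a nonzero residual sd")
        if self.obs_dates is None:
            self.obs_dates = {y: list(range(35, 120, 14)) for y in self.year_effects}

    def resid_sd(self) -> float:
        """Tree-year residual sd calibrated so the downstream BLUP-on-BLUE
        slope targets h2_target: slope ~ sg^2 / (sg^2 + sr^2/n_obs)."""
        if self.sigma_resid is not None:
            return float(self.sigma_resid)
        if self.h2_target >= 1.0:
            return 0.0
        n_obs = self.n_trees_per_genotype * len(self.year_effects)
        return float(self.sigma_genotype * np.sqrt(n_obs * (1.0 / self.h2_target - 1.0)))


def default_mpp_config(seed: int = 0) -> SimulationConfig:
    """Three pedigree-connected full-sib families segregating a two-locus
    dominant/epistatic system, with an S-locus shared between the parents of
    two of the crosses."""
    n11, n17 = 30, 30
    gmap = {"11": np.linspace(0.0, 58.0, n11), "17": np.linspace(0.0, 58.0, n17)}
    pmap = {"11": np.linspace(0.2e6, 28.0e6, n11), "17": np.linspace(0.3e6, 29.0e6, n17)}
    qtl11 = QtlSpec("qtl11", "11", 7.25, effects={}, gene_action="dominant_q")
    qtl17 = QtlSpec("qtl17", "17", 27.25,
                    effects={"QQ": 12.0}, gene_action="dominant_q",
                    epistatic_mask="qtl11")
    return SimulationConfig(
        seed=seed,
        founders=["Aroma", "Discovery", "Santana", "Katja"],
        families=[("Aroma", "Discovery", 150),
                  ("Santana", "Katja", 166),
                  ("Santana", "Aroma", 137)],
        n_haploblocks_per_chrom={"11": n11, "17": n17},
        genetic_map=gmap,
        physical_map=pmap,
        s_locus=("17", 48.0),
        founder_s_alleles={"Aroma": ("S2", "S5"), "Discovery": ("S10", "S24"),
                           "Santana": ("S3", "S5"), "Katja": ("S5", "S24")},
        founder_qtl_alleles={
            "qtl11": {"Aroma": ("Q", "q"), "Discovery": ("Q", "Q"),
                      "Santana": ("Q", "Q"), "Katja": ("Q", "Q")},
            "qtl17": {"Aroma": ("Q", "q"), "Discovery": ("Q", "q"),
                      "Santana": ("Q", "q"), "Katja": ("q", "Q")},
        },
        qtl_spec=[qtl11, qtl17],
    )


# ---------------------------------------------------------------------------
# meiosis and self-incompatibility


@dataclass
class Gamete:
    """One meiotic product: allele codes per chromosome plus bookkeeping."""

    alleles: dict                      # chrom -> array of allele codes
    homolog_of: dict                   # chrom -> array of source homolog (0/1)
    s_allele: str | None = None
    qtl_alleles: dict = field(default_factory=dict)   # qtl name -> 'Q'/'q'


def _chrom_mosaic(rng, cm_positions, length_cm):
    """Crossover mosaic: count ~ Poisson(L/100), breakpoints uniform in cM,
    no interference (Haldane-consistent).  Returns homolog index per query."""
    k = rng.poisson(length_cm / 100.0)
    breaks = np.sort(rng.uniform(0.0, length_cm, size=k))
    start = int(rng.integers(2))

    def homolog_at(pos):
        pos = np.asarray(pos, dtype=float)
        return (start + np.searchsorted(breaks, pos, side="right")) % 2

    return homolog_at


def _meiosis(rng, parent_calls, blocks_by_chrom, config,
             parent_id: str, s_homolog_source: dict | None) -> Gamete:
    alleles, hom_of, qtl_alleles = {}, {}, {}
    s_allele = None
    for chrom, (block_idx, cms) in blocks_by_chrom.items():
        length = max(cms[-1], config.s_locus[1] if (config.s_locus and
                     str(config.s_locus[0]) == chrom) else 0.0,
                     *[q.cm for q in config.qtl_spec if str(q.chrom) == chrom] or [0.0])
        hom_at = _chrom_mosaic(rng, cms, length)
        hom = hom_at(cms)
        alleles[chrom] = np.where(hom == 0, parent_calls[block_idx, 0],
                                  parent_calls[block_idx, 1])
        hom_of[chrom] = hom
        if config.s_locus and str(config.s_locus[0]) == chrom and s_homolog_source:
            h = int(hom_at(np.array([config.s_locus[1]]))[0])
            s_allele = s_homolog_source[parent_id][h]
        for q in config.qtl_spec:
            if str(q.chrom) == chrom and parent_id in config.founder_qtl_alleles.get(q.name, {}):
                h = int(hom_at(np.array([q.cm]))[0])
                qtl_alleles[q.name] = config.founder_qtl_alleles[q.name][parent_id][h]
    return Gamete(alleles, hom_of, s_allele, qtl_alleles)


def apply_si_selection(gametes, maternal_s_alleles, paternal_s_alleles,
                       s_locus=None) -> list:
    """Gametophytic SI acting on pollen only: male gametes whose S-allele
    matches either maternal S-allele are rejected."""
    maternal = set(maternal_s_alleles)
    paternal = set(paternal_s_alleles)
    out = []
    for g in gametes:
        if g.s_allele is not None and g.s_allele not in paternal:
            raise ValueError("gamete carries an S-allele absent from the father")
        if g.s_allele in maternal:
            continue
        out.append(g)
    return out


@dataclass
class PedigreeSim:
    matrix: HaploblockMatrix           # founders + offspring, fully phased
    pedigree: pd.DataFrame             # id, mother, father, family
    qtl_truth: pd.DataFrame            # individual, family, per-QTL diplotype
    s_alleles: dict                    # individual -> (maternal S, paternal S)
    config: SimulationConfig


def simulate_pedigree_haplotypes(config: SimulationConfig) -> PedigreeSim:
    """Drop gametes through the configured full-sib families.

    Founders receive unique allele labels per haploblock (code 2i + homolog
    for founder i), so offspring haplotype origin is always identifiable.
    Pollen is subjected to SI rejection when an S-locus is configured.
    """
    if not config.genetic_map:
        raise ValueError("empty genetic map")
    rng = np.random.default_rng(config.seed)
    chroms = list(config.genetic_map)
    blocks = pd.DataFrame([
        {"chrom": chrom, "index": j, "cm": float(cm),
         "bp_start": float(bp), "bp_end": float(bp) + 5000.0}
        for chrom in chroms
        for j, (cm, bp) in enumerate(zip(config.genetic_map[chrom],
                                         config.physical_map[chrom]))
    ])
    blocks_by_chrom = {
        chrom: (np.flatnonzero(blocks["chrom"] == chrom),
                np.asarray(config.genetic_map[chrom], dtype=float))
        for chrom in chroms
    }
    n_blocks = len(blocks)

    individuals, calls_list = [], []
    ped_rows, truth_rows = [], []
    s_alleles = {}
    founder_calls = {}
    for i, f in enumerate(config.founders):
        c = np.empty((n_blocks, 2), dtype=int)
        c[:, 0] = 2 * i
        c[:, 1] = 2 * i + 1
        founder_calls[f] = c
        individuals.append(f)
        calls_list.append(c)
        ped_rows.append({"id": f, "mother": "", "father": "", "family": ""})
        if f in config.founder_s_alleles:
            s_alleles[f] = tuple(config.founder_s_alleles[f])

    for mother, father, n_off in config.families:
        fam = f"{mother}x{father}"
        mother_s = config.founder_s_alleles.get(mother)
        father_s = config.founder_s_alleles.get(father)
        si_active = (config.s_locus is not None and mother_s is not None
                     and father_s is not None)
        if si_active and set(father_s) <= set(mother_s):
            raise ValueError(f"cross {fam} fully incompatible at the S-locus")
        for k in range(n_off):
            gm = _meiosis(rng, founder_calls[mother], blocks_by_chrom, config,
                          mother, config.founder_s_alleles or None)
            while True:
                gp = _meiosis(rng, founder_calls[father], blocks_by_chrom, config,
                              father, config.founder_s_alleles or None)
                if not si_active or apply_si_selection([gp], mother_s, father_s):
                    break
            oid = f"{fam}_{k + 1:03d}"
            c = np.empty((n_blocks, 2), dtype=int)
            for chrom in chroms:
                idx = blocks_by_chrom[chrom][0]
                c[idx, 0] = gm.alleles[chrom]
                c[idx, 1] = gp.alleles[chrom]
            individuals.append(oid)
            calls_list.append(c)
            ped_rows.append({"id": oid, "mother": mother, "father": father,
                             "family": fam})
            s_alleles[oid] = (gm.s_allele, gp.s_allele)
            row = {"individual": oid, "family": fam}
            for q in config.qtl_spec:
                row[q.name] = gm.qtl_alleles.get(q.name, "?") + gp.qtl_alleles.get(q.name, "?")
            truth_rows.append(row)

    calls = np.stack(calls_list)
    if config.missing_rate > 0:
        miss = rng.random(calls.shape[:2]) < config.missing_rate
        calls[miss] = MISSING
    matrix = HaploblockMatrix(individuals, blocks, calls)
    return PedigreeSim(matrix, pd.DataFrame(ped_rows), pd.DataFrame(truth_rows),
                       s_alleles, config)


def effective_class(diplotypes: dict, qtl_spec: list) -> str:
    """Collapse per-locus diplotypes into the effective compound genotype.

    A locus whose masking locus is heterozygous or qq is wildcarded to '--';
    a q-dominant locus that is not itself a mask source collapses any
    q-carrying diplotype to 'q-' (e.g. 'qQ/--', 'QQ/q-', 'QQ/QQ')."""
    mask_sources = {q.epistatic_mask for q in qtl_spec if q.epistatic_mask}
    parts = []
    for q in qtl_spec:
        d = diplotypes[q.name]
        masked = (q.epistatic_mask and q.epistatic_mask in diplotypes
                  and set(diplotypes[q.epistatic_mask]) != {"Q"})
        collapse_q = q.name not in mask_sources and q.gene_action == "dominant_q"
        if masked:
            parts.append("--")
        elif d == "QQ":
            parts.append("QQ")
        elif collapse_q:
            parts.append("q-")          # any q carrier at a dominant-q locus
        elif set(d) == {"q", "Q"}:
            parts.append("qQ")          # orientation-free heterozygote label
        else:
            parts.append(d)
    return "/".join(parts)


def simulate_mpp_phenotypes(sim: PedigreeSim, seed: int | None = None) -> pd.DataFrame:
    """%SEN phenotypes for the full-sib offspring from the true QTL diplotypes."""
    cfg = sim.config
    rng = np.random.default_rng(cfg.seed + 7919 if seed is None else seed)
    rows = []
    for _, r in sim.qtl_truth.iterrows():
        shift = 0.0
        diplo = {q.name: r[q.name] for q in cfg.qtl_spec}
        for q in cfg.qtl_spec:
            if q.epistatic_mask and q.epistatic_mask in diplo:
                if set(diplo[q.epistatic_mask]) != {"Q"}:
                    continue  # masked: heterozygous or qq at the masking locus
            shift += q.effect_of(diplo[q.name])
        sen = cfg.mpp_base_sen + shift + rng.normal(0.0, cfg.mpp_noise_sd)
        rows.append({"individual": r["individual"], "family": r["family"],
                     "sen": float(np.clip(sen, 0.0, 100.0))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# senescence collection


def simulate_true_jd50(config: SimulationConfig) -> pd.DataFrame:
    """True JD50 per tree-year: genotype + year + tree-year residual, additive
    on the day scale.  The residual sd is calibrated from h2_target."""
    rng = np.random.default_rng(config.seed)
    years = sorted(config.year_effects)
    sr = config.resid_sd()
    rows = []
    for g in range(config.n_genotypes):
        gid = f"G{g + 1:03d}"
        g_eff = rng.normal(0.0, config.sigma_genotype)
        for t in range(config.n_trees_per_genotype):
            tree = f"{gid}_T{t + 1}"
            yp = int(rng.choice(config.planting_years))
            for y in years:
                jd50 = (config.mu_jd50 + g_eff + config.year_effects[y]
                        + rng.normal(0.0, sr))
                rows.append({"tree_id": tree, "genotype_id": gid,
                             "year_planted": yp, "year": y,
                             "true_jd50": float(jd50), "genotype_effect": g_eff})
    return pd.DataFrame(rows)


def simulate_senescence_observations(config: SimulationConfig,
                                     true_jd50: pd.DataFrame) -> pd.DataFrame:
    """Visual scoring of each tree-year: logistic trajectory through 50% at
    the true JD50, Gaussian observation noise, rounding to the visual scoring
    step, clamped to [0, 100]."""
    rng = np.random.default_rng(config.seed + 104729)
    rows = []
    for r in true_jd50.itertuples(index=False):
        for t in config.obs_dates[int(r.year)]:
            val = 100.0 / (1.0 + np.exp(-config.r_sen * (t - r.true_jd50)))
            if config.obs_noise_sd > 0:
                val += rng.normal(0.0, config.obs_noise_sd)
            if config.rounding_step > 0:
                val = round(val / config.rounding_step) * config.rounding_step
            rows.append({"tree_id": r.tree_id, "genotype_id": r.genotype_id,
                         "year_planted": r.year_planted, "year": int(r.year),
                         "t": float(t), "percent": float(np.clip(val, 0.0, 100.0))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# temperature


def _seasonal_tmean(t):
    """Noise-free autumn daily mean (°C) at day t since Aug 1 (southern Sweden)."""
    doy = 213.0 + np.asarray(t, dtype=float)
    return 9.5 + 8.5 * np.cos(2.0 * np.pi * (doy - 197.0) / 365.0)


def _cdd_continuous(tmean_by_day, base, end_day):
    """CDD accumulated from day 0 to fractional end_day on a daily series."""
    full = int(np.floor(end_day))
    deficits = np.maximum(0.0, base - tmean_by_day[:full])
    total = float(deficits.sum())
    if full < len(tmean_by_day):
        total += (end_day - full) * max(0.0, base - tmean_by_day[full])
    return total


def simulate_temperature_series(config: SimulationConfig) -> pd.DataFrame:
    """Daily mean temperature for each assessment year, days 0..152 since
    Aug 1.  Year offsets are calibrated (unless supplied) so that the CDD
    model at `cdd_calibration_base` is exactly collinear with the injected
    year effects — the mechanism the year effects emulate."""
    rng = np.random.default_rng(config.seed + 15485863)
    years = sorted(config.year_effects)
    days = np.arange(0, 153)
    noise = {y: (rng.normal(0.0, config.temp_noise_sd, size=len(days))
                 if config.temp_noise_sd > 0 else np.zeros(len(days)))
             for y in years}
    offsets = dict(config.temp_year_offsets or {})
    if not offsets:
        offsets = _calibrate_temp_offsets(config, noise, days)
    rows = []
    for y in years:
        tm = _seasonal_tmean(days) + offsets.get(y, 0.0) + noise[y]
        for d, v in zip(days, tm):
            rows.append({"year": y, "t": int(d), "tmean_c": float(v)})
    return pd.DataFrame(rows)


def _calibrate_temp_offsets(config, noise, days):
    """Choose per-year temperature offsets so that points
    (date_j, CDD_base(date_j)) lie exactly on a line, where date_j is the
    JD50 intercept plus the injected year effect.

    The two extreme years anchor the line (coldest year offset 0, warmest
    +2 °C per 10 days of delay, capped); interior years are solved by root
    finding on their offset.
    """
    base = config.cdd_calibration_base or 15.0
    dates = {y: config.mu_jd50 + config.year_effects[y] for y in config.year_effects}
    order = sorted(dates, key=dates.get)
    first, last = order[0], order[-1]
    span = max(dates[last] - dates[first], 1e-9)
    # the warm offset stays small relative to the date delay, so the later
    # date still accumulates more cold (increasing line, as observed)
    offsets = {first: 0.0, last: min(0.05 * span, 1.0)}

    def cdd_for(year, off, end):
        tm = _seasonal_tmean(days) + off + noise[year]
        return _cdd_continuous(tm, base, end)

    c1 = cdd_for(first, offsets[first], dates[first])
    c2 = cdd_for(last, offsets[last], dates[last])
    for y in order[1:-1]:
        target = c1 + (c2 - c1) * (dates[y] - dates[first]) / span

        def g(off, _y=y):
            return cdd_for(_y, off, dates[_y]) - target

        lo, hi = -10.0, 12.0
        if g(lo) * g(hi) > 0:          # no crossing: fall back to proportional
            offsets[y] = offsets[last] * (dates[y] - dates[first]) / span
        else:
            offsets[y] = brentq(g, lo, hi, xtol=1e-10)
    return offsets


def simulate_zone_phenotypes(seed: int = 0, n: int = 126) -> pd.DataFrame:
    """Cultivar JD50 BLUEs with highest-recommended climate zones (1-6).

    Emulates the germplasm-zone relationship: a 3 d/zone negative trend (a
    15-day gap between zone-1 and zone-6 cultivars) against ~20 d within-zone
    scatter (hence a weak correlation near -0.2), with reduced JD50 variance
    among the hardiest (zone 6) cultivars reflecting directional selection
    for early senescence in the north (variance ratio near 0.3).
    """
    rng = np.random.default_rng(seed)
    counts = {1: 40, 2: 25, 3: 20, 4: 16, 5: 10, 6: 15}
    total = sum(counts.values())
    zones = np.repeat(list(counts), list(counts.values()))
    if total != n:
        zones = rng.choice(list(counts), size=n,
                           p=np.array(list(counts.values())) / total)
    sd = np.where(zones == 6, 11.0, 20.0)
    jd50 = 78.0 - 3.0 * zones + rng.normal(0.0, 1.0, len(zones)) * sd
    return pd.DataFrame({"genotype_id": [f"cv{i:03d}" for i in range(len(zones))],
                         "zone": zones.astype(int), "jd50": jd50})


# ---------------------------------------------------------------------------
# germplasm panel for the haplotype association scan


@dataclass
class GermplasmConfig:
    seed: int = 0
    chrom: str = "17"
    n_individuals: int = 75
    n_haploblocks: int = 20
    cm_spacing: float = 3.0
    bp_spacing: float = 1.2e6
    n_pool: int = 12
    n_alleles_per_hb: int = 4
    causal_start: int = 8           # HB index of the first causal block
    causal_size: int = 4            # number of consecutive causal HBs
    effect_days: float = 8.4        # JD50 shift per copy of the Late haplotype
    switch_prob_per_cm: float = 0.05
    causal_pool_freq: float = 0.25
    n_snp: int = 400
    poly_sd: float = 2.0
    resid_sd: float = 3.0
    mu: float = 66.0

    def __post_init__(self):
        if self.causal_start + self.causal_size > self.n_haploblocks:
            raise ValueError("causal window extends past the last haploblock")


@dataclass
class GermplasmSim:
    matrix: HaploblockMatrix
    blues: pd.Series                 # JD50 BLUE per individual
    dosages: pd.DataFrame            # genome-wide SNP dosages for the G-matrix
    causal_window: tuple             # (start HB index, n HBs)
    causal_haplotype: tuple          # joint allele string of the Late allele
    carriers: pd.Series              # copies of the Late haplotype per individual
    config: GermplasmConfig


def simulate_germplasm(cfg: GermplasmConfig) -> GermplasmSim:
    """Unrelated germplasm with mosaic haplotypes from a small ancestral pool.

    Homologs are Markov mosaics over pool haplotypes (switch probability
    proportional to cM distance), so linkage disequilibrium with the causal
    joint haplotype decays along the chromosome.  One pool haplotype carries
    a late-senescence (higher JD50) effect attached to its joint
    identical-by-state allele string over the causal window.
    """
    rng = np.random.default_rng(cfg.seed)
    nhb, npool = cfg.n_haploblocks, cfg.n_pool
    pool = rng.integers(0, cfg.n_alleles_per_hb, size=(npool, nhb))
    # make the causal string unique among pool haplotypes
    sl = slice(cfg.causal_start, cfg.causal_start + cfg.causal_size)
    for j in range(1, npool):
        if np.array_equal(pool[j, sl], pool[0, sl]):
            pool[j, cfg.causal_start] = (pool[j, cfg.causal_start] + 1) % cfg.n_alleles_per_hb
    freqs = np.concatenate([[cfg.causal_pool_freq],
                            rng.dirichlet(np.ones(npool - 1)) * (1 - cfg.causal_pool_freq)])
    switch = min(cfg.switch_prob_per_cm * cfg.cm_spacing, 0.5)

    def draw_homolog():
        src = np.empty(nhb, dtype=int)
        src[0] = rng.choice(npool, p=freqs)
        for j in range(1, nhb):
            src[j] = rng.choice(npool, p=freqs) if rng.random() < switch else src[j - 1]
        return pool[src, np.arange(nhb)]

    individuals = [f"cv{i + 1:03d}" for i in range(cfg.n_individuals)]
    calls = np.empty((cfg.n_individuals, nhb, 2), dtype=int)
    for i in range(cfg.n_individuals):
        calls[i, :, 0] = draw_homolog()
        calls[i, :, 1] = draw_homolog()
    causal_str = tuple(pool[0, sl])
    copies = np.array([
        sum(tuple(calls[i, sl, h]) == causal_str for h in range(2))
        for i in range(cfg.n_individuals)
    ])
    p_snp = rng.uniform(0.1, 0.9, size=cfg.n_snp)
    dosages = rng.binomial(2, p_snp, size=(cfg.n_individuals, cfg.n_snp)).astype(float)
    W = dosages - dosages.mean(axis=0)
    u = rng.normal(0.0, 1.0, size=cfg.n_snp)
    poly = W @ u
    sd = poly.std()
    poly = poly / sd * cfg.poly_sd if sd > 0 else poly
    blues = (cfg.mu + cfg.effect_days * copies + poly
             + rng.normal(0.0, cfg.resid_sd, size=cfg.n_individuals))
    blocks = pd.DataFrame({
        "chrom": cfg.chrom, "index": np.arange(nhb),
        "cm": np.arange(nhb) * cfg.cm_spacing,
        "bp_start": np.arange(nhb) * cfg.bp_spacing,
        "bp_end": np.arange(nhb) * cfg.bp_spacing + 5000.0,
    })
    matrix = HaploblockMatrix(individuals, blocks, calls)
    return GermplasmSim(matrix, pd.Series(blues, index=individuals, name="blue"),
                        pd.DataFrame(dosages, index=individuals),
                        (cfg.causal_start, cfg.causal_size), causal_str,
                        pd.Series(copies, index=individuals), cfg)


# ---------------------------------------------------------------------------
# two-group variant panel


@dataclass
class VariantPanelConfig:
    seed: int = 0
    n_individuals_per_group: tuple = (30, 29)     # (hardy, not_hardy)
    chrom: str = "chr17"
    chrom_length_bp: int = 1_000_000
    diversity: float = 0.003                      # baseline per-bp pi
    sweep_loci: list = field(default_factory=list)  # (bp, 'hard'|'partial', width)
    partial_freq: float = 0.5

    def __post_init__(self):
        if self.diversity < 0:
            raise ValueError("diversity must be non-negative")
        for pos, kind, width in self.sweep_loci:
            if width >= self.chrom_length_bp:
                raise ValueError("sweep width must be smaller than the chromosome")
            if kind not in ("hard", "partial"):
                raise ValueError(f"unknown sweep type {kind}")


@dataclass
class VariantPanel:
    chrom: str
    positions: np.ndarray              # 1-based bp
    genotypes: np.ndarray              # (n_sites, n_samples, 2) in {0,1,-1}
    samples: list
    groups: pd.Series                  # sample -> 'hardy' / 'not_hardy'
    chrom_length: int = 0

    def group_columns(self, group) -> np.ndarray:
        # same contract as the selection-scan reader's panel
        return np.flatnonzero(self.groups.loc[self.samples].to_numpy() == group)


def simulate_variant_panel(cfg: VariantPanelConfig) -> VariantPanel:
    """Neutral two-group panel with optional sweep loci in group 1 ('hardy').

    Neutral sites: total derived count drawn from the neutral frequency
    spectrum (P(i) ∝ 1/i) and scattered uniformly over haplotypes, so both
    groups share frequencies and the expected windowed pairwise diversity per
    bp equals `diversity`.  A hard sweep copies one 'hardy' haplotype across
    the whole group inside the sweep window (local loss of diversity,
    differentiation); a partial sweep copies it into a fraction
    `partial_freq` of the group (intermediate-frequency excess: positive
    Tajima's D and elevated FST).
    """
    rng = np.random.default_rng(cfg.seed)
    n1, n2 = cfg.n_individuals_per_group
    n = n1 + n2
    n_hap = 2 * n
    i_vals = np.arange(1, n_hap)
    a1 = np.sum(1.0 / i_vals)
    n_sites = int(round(cfg.diversity * cfg.chrom_length_bp * a1))
    positions = np.sort(rng.choice(np.arange(1, cfg.chrom_length_bp + 1),
                                   size=n_sites, replace=False))
    probs = (1.0 / i_vals) / a1
    counts = rng.choice(i_vals, size=n_sites, p=probs)
    haps = np.zeros((n_sites, n_hap), dtype=np.int8)
    for s in range(n_sites):
        carriers = rng.choice(n_hap, size=counts[s], replace=False)
        haps[s, carriers] = 1
    # group-1 haplotypes occupy columns 0 .. 2*n1-1
    for pos, kind, width in cfg.sweep_loci:
        in_win = (positions >= pos - width / 2) & (positions < pos + width / 2)
        if not in_win.any():
            continue
        if kind == "hard":
            # classic hard sweep: one extant haplotype fixed in the group
            sweep_col = int(rng.integers(0, 2 * n1))
            template = haps[np.ix_(in_win, [sweep_col])][:, 0]
            targets = np.arange(2 * n1)
        else:
            # partial sweep of a divergent haplotype at intermediate frequency:
            # the favoured lineage carries derived alleles at ~half the
            # segregating sites, creating the intermediate-frequency excess
            template = (rng.random(int(in_win.sum())) < 0.5).astype(np.int8)
            k = max(int(round(cfg.partial_freq * 2 * n1)), 1)
            targets = rng.choice(2 * n1, size=k, replace=False)
        for c in targets:
            haps[in_win, c] = template
    genotypes = haps.reshape(n_sites, n, 2).astype(np.int8)
    samples = [f"hardy_{i + 1:02d}" for i in range(n1)] + \
              [f"nothardy_{i + 1:02d}" for i in range(n2)]
    groups = pd.Series(["hardy"] * n1 + ["not_hardy"] * n2, index=samples, name="group")
    return VariantPanel(cfg.chrom, positions.astype(int), genotypes, samples,
                        groups, cfg.chrom_length_bp)


def write_vcf(panel: VariantPanel, path) -> int:
    """Write the panel as minimal VCF 4.2 (GT only). Returns the site count."""
    buf = _io.StringIO()
    buf.write("##fileformat=VCFv4.2\n")
    buf.write(f"##contig=<ID={panel.chrom},length={panel.chrom_length or int(panel.positions.max()) + 1}>\n")
    buf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    buf.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
              + "\t".join(panel.samples) + "\n")
    for s in range(len(panel.positions)):
        gts = []
        for i in range(len(panel.samples)):
            a, b = panel.genotypes[s, i]
            gts.append("./." if a < 0 or b < 0 else f"{a}/{b}")
        buf.write(f"{panel.chrom}\t{panel.positions[s]}\t.\tA\tT\t.\tPASS\t.\tGT\t"
                  + "\t".join(gts) + "\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())
    return len(panel.positions)


def write_groups(panel: VariantPanel, path) -> None:
    panel.groups.rename_axis("sample").reset_index().to_csv(path, index=False)
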