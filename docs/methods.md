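# Methods

`senespop` implements the quantitative-genetic analysis of autumn canopy
senescence in apple: logistic phenology modelling, mixed-model estimation of
genotype and year effects, haplotype association in diversity germplasm,
two-locus dissection in full-sib families, and windowed selection scans.
Synthetic-data generators reproduce the statistical structure of each input,
so the whole pipeline is testable without field or genotyping data.

## Senescence curves

Each tree-season series of visual percent-senescence scores is fitted with
the logistic

N(t) = K / (1 + ((K − N0)/N0) e^(−r_sen t)),

t in days from August 1.  K is the carrying capacity (maximum percent canopy
senescence in the model), N0 the modelled value at t = 0, and r_sen the
maximal intrinsic rate.  Two anchor points, (Aug 1, 0%) and (Dec 31, 100%),
are appended to every series before fitting; "last of December" is encoded
as t = 152 (Dec 31), and the 0% anchor is an ordinary data point, so N0
remains free.  Fitting is bounded nonlinear least squares (K ∈ (0, 120],
N0 ∈ (0.01, K) via a logistic reparameterisation, r_sen ∈ (0, 5]),
initialised at K = 100, N0 = max(first score, 0.5) and a rate from a
log-linear regression of logit(N/K) on t, with up to five jittered restarts.
The phenotype JD50 — the day the fitted curve crosses 50% — has the closed
form t50 = ln(((K − N0)/N0)/(K/50 − 1))/r_sen and is undefined when K ≤ 50.
Because the 100% anchor is generally not on a generating curve with K < 100,
exact-recovery tests sample all points, anchors included, from the curve
itself.

## Mixed models, heritability, cooling degree days

A single REML/ML engine fits y = Xβ + Σ Z_i u_i + e with u_i ~ N(0, σ_i² K_i)
(K_i identity or a supplied covariance such as a kinship matrix).  Variance
ratios γ_i = σ_i²/σ_e² are profiled; each likelihood evaluation uses the
Woodbury identity, so the cost is one Cholesky factorisation of a q × q
matrix (q = total random levels).  One ratio is optimised by bounded scalar
search, several by Nelder–Mead on log-ratios (function tolerance 1e-8).
Boundary estimates are reported as zero variances, not errors.  Fixed-effect
p-values are Wald t-tests without small-sample correction; fixed-effect
model comparisons use ML likelihood-ratio chi-square tests.

The model wrappers encode the trial design: per-year genotype BLUEs
(genotype fixed, planting year random); across-year BLUEs (genotype fixed;
assessment year, planting-year-within-year, and accession replicate random)
and BLUPs (the same with genotype random); and fixed assessment-year effects
with genotype and planting-year-within-genotype random.  The accession
replicate is a tree-level intercept shared across assessment years.  Year
effects use treatment coding with the first year as reference.  Genotypes
observed in a single year are retained.  Broad-sense heritability Ĥ² is the
slope of the ordinary regression of genotype BLUPs on genotype BLUEs.

Cooling degree days accumulate max(0, base − Tmean) from August 1 to a
(possibly fractional) end day, for bases 5–30 °C.  For each base, the
Pearson correlation between the per-year dates (intercept + year effect) and
the CDD accumulated to those dates is reported; zero-variance inputs are
flagged undefined rather than correlated.  Stuart's tau-c is
2m(C − D)/(n²(m − 1)) with a consistent-estimate variance for its CI
(99% for the climate-zone contrast, 95% otherwise, caller-specified);
variance ratios are compared by a one-sided F-test.

## Haplotype association in germplasm

The scan slides windows of 2–30 consecutive haploblocks along a chromosome.
Joint haplotypes are identical-by-state concatenated allele strings per
homolog; individuals with any missing call in a window are excluded, and an
individual is retained when both of its joint haplotypes exceed the minor
allele frequency threshold (0.05), frequencies being computed over all
homologs entering the scan.  Each window is scored by
pIndex = (proportion retained) × (−log10 p), and the best window must
overlap the inner QTL interval with a genetic length not exceeding the outer
interval's (ties: fewer blocks, then smaller start).

The haplotype term is tested in a mixed model with a genotype random effect
whose covariance is the VanRaden G-matrix G = WW′/(2Σp(1−p)), W = M − 2p.
The allele-effect model is additive over homologs and is fitted with one row
per genotype and haplotype *dosages* (0/1/2 copies) as fixed effects.  A
literal duplicated-row layout (each homolog a row carrying the genotype's
phenotype twice) is degenerate under maximum likelihood: the within-pair
contrasts contain no data, the genotype variance ratio diverges, and the
haplotype term is forced toward zero.  The dosage layout encodes the same
model on a well-posed likelihood; on all-homozygous panels it coincides with
a plain per-genotype design (verified in the suite).  The p-value is a GLS
F-test of the dosage columns at the variance ratio estimated under the null
model: the asymptotic chi-square likelihood-ratio reference rejected a
permutation null at 8–9% instead of 5%, while the F reference keeps null
p-values uniform (KS p ≈ 0.9) without measurable loss of window recovery.

Post-hoc allele effects use an ordinary linear model of the BLUE on the
haplotype with two rows per genotype (no random effect, so no degeneracy),
a studentized Breusch–Pagan test and a Shapiro–Wilk test on residuals, and
Duncan's new multiple range test at α = 0.1 with the harmonic mean of group
sizes for unequal n.  Haplotypes whose letters fall only in the
highest-mean letter group are Late, only in the lowest Early, spanning both
Ambiguous.  Individuals with both homologs non-Ambiguous are grouped into
Early/Early, Early/Late and Late/Late diplotype classes.

## Full-sib QTL dissection

Compound genotypes assign each inherited haplotype within an outer QTL
interval to a parental homolog by exact string match; offspring with a
recombination event, a missing call, or a haplotype matching neither
parental homolog are excluded with the reason recorded.  Heterozygotes are
written maternal-allele first; effective classes collapse q-carriers at a
dominant-q locus to "q-" and wildcard a locus masked by heterozygosity at
its epistatic partner (e.g. qQ/--, QQ/q-, QQ/QQ).

Phenotypic contrasts use the two-sample Kolmogorov–Smirnov test: exact D by
a merged-sort sweep, asymptotic p from the Kolmogorov distribution at
effective size n1·n2/(n1+n2) (the convention of R's stats::ks.test, which
serves as the frozen oracle); groups under four observations are flagged low
power.  Dominance at the focal locus (within the stratum homozygous QQ at
the other locus) requires the heterozygote groups to be mutually
non-different, non-different from one homozygote, and different from the
other; masking epistasis is flagged when the contrasts significant in the QQ
stratum are all non-significant in the heterozygous stratum.  A consensus
over families accepts a dominance label supported by at least one family and
contradicted by none.

The segregation-distortion profile tracks, per marker, the frequency among
offspring of the paternal allele in coupling with the shared S-allele and
regresses it on cM distance from the S-locus.  Because linked markers share
transmissions, marker-level regression p-values are grossly anti-conservative;
the slope's p-value is therefore obtained by bootstrapping offspring
(500 resamples), which preserves the between-marker correlation.  The
within-family haplotype-contrast scan (Welch t per haploblock on offspring
split by inherited parental homolog) is localisation plumbing for simulated
QTL, not an effect estimator.

## Selection scans

Windows are non-overlapping half-open 10 kb intervals anchored at coordinate
0; VCF positions are 1-based and converted internally.  Per-site diversity
is the unbiased (n/(n−1))·2p̂(1−p̂) over non-missing alleles; window π divides
the site sum by the window length.  Tajima's D uses the standard constants
computed from the modal non-missing allele count of the window (sites with
deviating counts still contribute π and S; sites with fewer than four
alleles are excluded) — an approximation close to common VCF tooling.
Pairwise FST is the Weir–Cockerham ratio of summed variance components
Σa/Σ(a+b+c); negative estimates are reported as computed.  Outlier
thresholds are empirical genome-wide type-7 quantiles (upper 1% for all
three statistics, with a lower tail available for π troughs), flags are
strict inequalities, and flagged windows are merged into contiguous runs
before intersection with QTL intervals.

## Synthetic-data generators

*Pedigrees.* Founders carry unique allele labels per haploblock.  Meioses
draw crossover counts Poisson(L/100) for map length L cM with breakpoints
uniform in cM and no interference (Haldane-consistent).  Gametophytic SI
acts on pollen only: male gametes carrying an S-allele present in the seed
parent are rejected and redrawn, producing coupling-allele frequencies near
zero at the S-locus that rise with recombination distance.  The default
full-sib design comprises three pedigree-connected families of
150/166/137 phenotyped offspring, a two-locus system with q dominant at the
second locus (+12 %SEN for QQ, phenotype noise sd 6 %SEN) masked by
heterozygosity at the first, and a shared parental S-allele in the two
distorted crosses with the suppressed paternal haplotype in coupling with q.

*Collection.* True JD50 per tree-year is genotype (sd 8 d) + injected year
offset (0, +18.8, +9.7 d) + tree-year residual, additive on the day scale.
The residual sd is calibrated so the expected BLUP-on-BLUE slope equals
`h2_target`: σ_res = σ_g √(n_obs(1/h² − 1)) with n_obs = trees × years.
Observations lie on a K = 100 logistic through 50% at the true JD50
(rate 0.12/d), with Gaussian noise (sd 5 percent points, an assumption — the
visual-scoring noise is not known) rounded to 5-point steps, the granularity
of visual scoring.

*Temperature.* A seasonal cosine (about 17.5 °C on Aug 1 falling to about
1 °C by late December) plus per-year offsets and day noise (sd 1 °C).  Year
temperature offsets are calibrated by root finding so that the points
(date_j, CDD15(date_j)) at date_j = intercept + year effect are exactly
collinear — the mechanism the injected year effects emulate; the generating
base is then identifiable as the base maximising |r| downstream.

*Germplasm.* Homologs are Markov mosaics over a pool of 12 ancestral
haplotypes (switch probability 0.05/cM), so linkage disequilibrium with the
causal window decays along the chromosome.  One pool haplotype (frequency
0.25) carries +8.4 d per copy attached to its IBS string over four
consecutive haploblocks; phenotypes add a polygenic term (sd 2 d) built from
the same 400 SNP dosages that feed the G-matrix, plus residual sd 3 d.

*Variant panels.* Neutral sites draw total derived counts from the neutral
frequency spectrum (P(i) ∝ 1/i) scattered uniformly over haplotypes, making
E[π] equal the configured per-bp diversity and E[D] ≈ 0; groups are random
partitions, so expected FST is 0.  A hard sweep copies one 'hardy' haplotype
across the group inside its window (π → 0, differentiation); a partial sweep
places a divergent haplotype (derived at ~half the segregating sites) at
frequency 0.5 (positive D, elevated FST).  These are direct constructions,
not coalescent simulations: they reproduce the window-statistic signatures,
not linkage structure within windows, recombination gradients, or
demography — so passing tests validate the estimators and outlier logic, not
inference about real sweep histories.

## Problem sizes and determinism

Default analysis sizes were chosen to keep any single check in the minutes
range on one core: heritability replicates run the full 150 × 2 × 3 chain;
the association scan uses 20 haploblocks with window sizes 2–8 (the full
2–30 range is supported and used when chromosomes are longer); selection
scans use 1–5 Mb panels of ~59 cultivars (100–500 windows) against the
standard 10 kb window convention.  All generators are deterministic under a
fixed seed; every stochastic test and the acceptance script derive their
streams from explicit seeds.

## Known limitations

The REML engine targets a handful of random terms on datasets of a few
thousand rows; it is not a sparse large-scale solver.  KS p-values are
asymptotic (flagged under n = 10, no exact small-n computation).  Duncan
letters use the containment convention for non-significant ranges.  The
within-family scan is not a QTL mapper — Bayesian mapping and IBD-probability
machinery are out of scope.  No field or array data are bundled; every analysis runs on synthetic
counterparts generated at representative effect sizes.
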