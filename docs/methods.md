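# Methods

`xdrive` implements the population-genetic machinery used to study a
selfish *Sex-Ratio* (SR) X chromosome segregating against the standard
(ST) arrangement in *Drosophila pseudoobscura*: pooled-sequencing
differentiation and diversity statistics, differentiation-based
divergence dating, a coalescent neutrality test for the inversion
polymorphism, haplotype-panel linkage disequilibrium, deterministic
drive–selection dynamics, and the classical statistics of mapping and
segregation experiments. This note records the models, the defaults and
their rationale, the numerical choices, and the known limitations.

## Pooled-sequencing statistics (`xdrive.pooled_popgen`)

**Data model.** Input is a sync-format table: per genomic position, one
`A:T:C:G:N:del` read-count column per pool. Each pool is a set of `n`
haploid X chromosomes sequenced together, so an observed read frequency
reflects two nested sampling layers: chromosomes into the pool
(binomial around the population frequency) and reads off the
chromosomes (binomial with replacement around the pool frequency).
Coordinates are 1-based, intervals closed.

**Callability.** A site is uncallable when any pool's nucleotide depth
is below that pool's haploid size or above the per-chromosome,
per-pool mean depth plus 3 SD; sites within ±5 bp of a supplied indel
position are masked; sites showing more than two alleles across pools
are dropped. Retained variant sites are biallelic.

**F_ST.** The estimator is a methods-of-moments ANOVA for pooled
reads. Writing `C` for depth, `n` for pool size, `p̂` for the read
frequency of one allele, and `a`/`b` for the between-/within-population
variance components, the sampling model gives per site

    E[p̂(1-p̂)] = b (C-1)(n-1)/(Cn)
    Var(p̂)    = a + b (C+n-1)/(Cn)

These two moment equations are solved for `(a, b)` via the within- and
between-pool sums of squares, and windows report the ratio of sums
`Σa / Σ(a+b)` (not the mean of per-site ratios, which is biased).
Window CIs bootstrap SNPs within the window. Negative estimates are
reported as computed and flagged; trailing short windows are flagged
`partial`. Two behaviors worth knowing: (i) under the model (two pools
drawn from one panmictic population) the estimator is centred on zero,
which the test suite verifies over >100 windows; (ii) conditioned on a
window whose read columns are *literally identical* between pools, the
estimate is ≈ −1/(n−1), because the between-pool mean square is exactly
zero while the expected within-pool sampling variance is subtracted —
this is a property of every estimator in the Weir–Cockerham family,
visible here because the pools hold only 8 chromosomes.

**Diversity.** Per-site heterozygosity is estimated as
`(1 − Σ p̂_a²) · C/(C−1) · n/(n−1)` — unbiased for the sample
heterozygosity of the `n` pooled chromosomes at adequate depth —
averaged over callable intergenic sites in physical windows (10 kb
default). Alleles with fewer than `min_count` (default 2) supporting
reads in a pool are treated as unobserved, so sub-threshold variants
contribute no diversity; windows with >40% uncallable sites are
skipped. Tajima's D contrasts the window's summed heterozygosity with
its segregating-site count using the classical constants at the pool
size. Unlike the full pooled-data estimator family, no analytic
correction is applied for the truncation the min-count filter induces;
at the depths simulated here (≈50×, pool of 8) the bias is within the
10% accuracy the truth-comparison test enforces, but at low depth or
large pools the estimates will be conservative.

**d_XY.** Per callable site each group's consensus base is drawn with
probability equal to its read frequency; d_XY is the fraction of
differing sites. Both the seeded draw-based value and its exact
expectation `Σ_s (1 − Σ_a p_a q_a)/L` are reported (the two agree in
expectation; the exact form is used for the bootstrap CI over sites).

**Site classification.** With an outgroup allele per site, callable
sites are assigned to: fixed-derived in either pool (the other pool
fixed for the outgroup allele), shared polymorphism, private
polymorphism, monomorphic, or unpolarizable (no outgroup base, or the
outgroup base matches neither allele). Removing the outgroup converts
exactly the fixed-derived categories to unpolarizable and touches
nothing else. Summaries include the fixed-derived:shared ratio and
per-window fixed-derived proportions.

## Divergence dating (`xdrive.dating`)

Differentiation is mapped to time with `T = −ln(1 − F_ST)` (natural
log; a base-10 log would not reproduce sub-million-year ages from
F_ST ≈ 0.7–0.8). Each window's focal `T` is scaled by the same
window's calibration `T` for a pair with a known split age (default
2 Myr), so locally varying mutation and drift rates cancel per window.
The region estimate is the unweighted mean of window ages
(SNP-weighted optional); its CI bootstraps windows. Windows with zero
calibration transform are excluded.

Limitations established by simulation: measured `T` is inflated at low
divergence by conditioning on observed SNPs, and saturates at high
divergence by the log; the time ratio of two comparisons is recovered
to within ~5–15% only in the intermediate regime (split time around
half the effective size). A single-founder inversion origin adds a
large time-independent offset to `T`, so absolute ages for an
inversion polymorphism inherit that upward bias; the parameter-recovery
test therefore uses ordinary splits (`founder_event=False`).

## Coalescent neutrality test (`xdrive.coalescent`)

Three lineages — outgroup species, ST, and SR — are simulated backward
in time on a single non-recombining locus (the conservative treatment
of an inverted region). Defaults follow the study system: total
effective size 1.8×10⁶ with the SR share at its observed population
frequency (1%, 13.5%, or 30%) and ST taking the remainder; outgroup
size 3.6×10⁵; inversion origin 2×10⁶ generations ago and species split
at 4×10⁶ (an 8×10⁶/4×10⁶ alternative is configurable); mutation rate
3.5×10⁻⁹ per bp per generation; samples of 1, 8, and 8 chromosomes.
All sizes are multiplied by 3/4 exactly once, at scenario
construction, for X hemizygosity. The locus length defaults to 10 kb to
mirror the diversity windows.

The single-founder origin is implemented literally: at the origin time
every surviving SR lineage coalesces instantaneously into one founder
lineage, which then joins the parental population (taken to be the
full-species size behind the origin, and also beyond the species
split). Mutations are Poisson on branches (infinite sites); π, S, and
Tajima's D per group follow from branch descendant counts.

The neutrality test is one-sided by default: the p-value is the
fraction of neutral replicates whose π_ST/π_SR ratio is at most the
observed ratio, i.e. whether the observed reduction in SR diversity is
too *small* for the drift-only model. Replicates with π_SR = 0 are
excluded from the denominator; a zero count is reported as `< 1/n`.
The internal simulator is the contract; its E[T₂], Watterson, and
msprime cross-checks live in the test suite.

## Haplotype-panel LD (`xdrive.ld`)

Aligned amplicon haplotypes labelled SR/ST are reduced to a 0/1
site-by-strain matrix: columns with gaps, more than two alleles, or
minor count below 2 (singletons) are removed, and the remaining
columns of all regions are concatenated with their provenance. Coding
is 1 = derived when an outgroup base is supplied, else 1 = minor
allele (ties to the lexicographically larger base); coding affects
display only, since for haploid data the correlation-based composite
LD reduces to the squared Pearson correlation of the indicators,
identical to `D²/(p(1−p)q(1−q))` from the 2×2 haplotype table and
invariant to recoding. Significance is `n·r²` against chi-square(1) or
a seeded permutation null; arrangement association per site is a
two-sided Fisher exact test. Both families of p-values are BH-adjusted
(step-up), and each Fisher test reports whether its margins allow
p < α at all — with 8+8 strains, low-frequency alleles cannot reach
significance regardless of association.

## Drive–selection dynamics (`xdrive.drive`)

Four X gamete types circulate: ST (`ab`), the full driver SR (`AB`),
and the single-unit recombinants BM (`Ab`, basal+medial block) and T
(`aB`, terminal inversion). Measured segregation proportions
(fraction of daughters per father type) are k = 0.969 (SR), 0.622
(BM), 0.426 (T); ST's measured 0.439 has a CI spanning 1/2 and is
treated as Mendelian by default (measured value available).

**Gametic layer.** `D_t = (1−c)^t D_0` with half-life
`ln(1/2)/ln(1−c)`; at the experimentally measured c = 0.0012 the
survey LD of 0.116 halves in 577 generations. The selection model adds
per-type haploid coefficients `s` and recombinant production from
SR/ST pairings at rate c/2 per pairing, with pairing probability the
product of the two type frequencies (and the reverse flux from BM/T
pairings). Production precedes selection within a generation; with SR
and ST pinned at their observed survey frequencies the recombinant
equilibrium is `x* = R(1−s)/s` with `R = (c/2)·P(SR)·P(ST)`, and
`fit_haploid_s` inverts this by bisection (tolerance 10⁻⁶). On the
pooled survey frequencies this yields s = 0.318 against the
terminal-only class and s = 0.636 against the basal+medial class,
against published values of 0.316 and 0.649; the fit is validated by
forward-model round trips to 10⁻⁵.

**Diploid layer.** Females carry two X's, recombine between the A and
B blocks at c only in double heterozygotes (AB/ab → Ab, aB at c/2
each; Ab/aB back-produces AB, ab), and undergo viability selection;
males are hemizygous and a type-g father sires a fraction k_g
daughters (who receive his X) per unit brood, with brood size
independent of genotype. Random mating with equal male mating success;
the census is the zygote stage; the pooled X pool weights females'
two copies and males' one by the current sex ratio.

Viability costs are recessive and independent per chromosome type. The
package expresses each cost in homozygous females *and* hemizygous
males by default: a single X is the full exposed dose in a male, so a
hemizygous male is "homozygous" in the relevant sense. This choice is
forced by the dynamics, not aesthetics — with strictly female-limited
recessive costs, drive at k = 0.969 cannot be balanced at the observed
13.5% SR frequency by *any* cost (even homozygous lethality leaves SR
near 30%), whereas with male expression a bisected cost of 42.05%
balances exactly, matching the published 43% requirement within a
point. A strictly female-limited mode remains available
(`cost_in_males=False`).

Solvers are all bisection with bracket checks: `find_balance_cost`
(two-type system, recombination off, equilibrium to 10⁻¹², cost
tolerance 10⁻⁶) and `min_cost_to_exclude` (four-type system started at
the two-type balance, recombination regenerating the focal recombinant
each generation, the non-focal recombinant's homozygote made lethal so
thresholds are measured one at a time; "replacement" operationalized as
the pooled SR frequency falling below 10⁻⁶ by a 10⁵-generation
horizon).

**Reproduction of the published diploid figures.** The published
drive–selection-balance cost (43%) and the haploid selection
coefficients are reproduced as above. Two further published figures
are not reproduced by this recursion, whose construction follows the
main-text ingredient list; the full derivation behind them was not
available to this implementation. (i) The LD half-life starting from
the survey frequencies at balance: published 47 generations, computed
80. Sensitivity: using all measured k values gives 60; dropping all
viability costs gives 18–21 (and reaches equilibrium within 200
generations); across census pools the value spans 54–96. The
qualitative conclusion — decay far faster than the neutral 577 — is
robust to every variant. (ii) The minimum recombinant costs that
protect the full driver: published 29% (BM) and 1% (T); computed 3.3%
and 0%. In this recursion a cost-free BM driver does replace SR (and
~3% stops it), while T, transmission-disadvantaged at its measured
k = 0.426, can never displace SR at any cost. The exhaustive
mating-table oracle (10⁻¹² agreement), stationarity at balance, and
monotone decay hold throughout, so the discrepancy reflects model
details (e.g. a different cost parameterization or replacement
criterion in the original derivation), not an implementation defect.

## Mapping and segregation statistics (`xdrive.mapstats`)

Exact binomial (Clopper–Pearson) intervals via beta-quantile
inversion, with the closed forms `1−(α/2)^{1/n}` at the boundaries;
the Kosambi map function `d = 25·ln((1+2r)/(1−2r))` cM (distances also
reported raw as 100r cM — the headline 0.12 cM figure is raw);
reciprocal-class chi-square against 1:1 without continuity correction
(the published χ² = 12 for a 12:0 split implies none; corrected value
by flag) plus the exact binomial p; survey LD `D = P(AB) − p_A q_B`
and `r² = D²/(p_A(1−p_A)q_B(1−q_B))` from four haplotype frequencies;
and the segregation proportion k with an exact CI and a distortion
flag when the CI excludes 1/2. The ten-survey haplotype-frequency
table (26,459 chromosomes; pooled D = 0.116, r² = 0.998) ships as a
package fixture.

## Synthetic data (`xdrive.simulate`)

Generators are deterministic given a seed and return truth records.
Pooled count tables reuse the internal coalescent — per window an
independent non-recombining genealogy yields 8+8+outgroup haplotypes,
pool frequencies are the sample frequencies, and reads are binomial at
the configured depth (50× default, matching the X-chromosome coverage
scale of the study design) — so the neutrality test and the data
generator share one stochastic model. Haplotype panels place known
numbers of arrangement-fixed, shared, singleton, and indel columns.
Testcross progeny are multinomial with parental classes at (1−c)/2 and
recombinants at c/2 (asymmetric recombinant viabilities optional);
segregation assays are binomial in k; surveys are multinomial over the
four haplotype classes.

What the generators do not emulate: read errors beyond binomial depth
sampling, mapping artifacts, indel/paralog contamination,
within-window linkage for the pooled tables beyond a single shared
genealogy, and recombination within loci. Passing truth-recovery tests
therefore demonstrates estimator correctness under clean sampling, not
robustness to alignment pathology.

## Problem sizes used in the shipped checks

The test suite and acceptance script scale published analyses to desk
size as the package's own verification conditions: coalescent checks
use 2,000–5,000 replicates (the neutrality scenario itself was
published at 10⁵; the mean-ratio criterion is stable at 2,000),
diversity truth-recovery uses 200 replicate 1-kb windows, the dating
recovery uses windows of 400 independent 2-kb loci, and the exclusion
solver uses a 10⁵-generation horizon with cost tolerance 10⁻³. All
stochastic steps take explicit seeds.
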