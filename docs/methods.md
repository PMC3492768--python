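# Methods

This note documents the statistical models implemented in `rainpop`, the
defaults and why they were chosen, the synthetic-data model and its limits,
and the numerical conventions that matter for reproducing results.

## Study design assumed throughout

The package targets a landscape-genetics design: *k* sites (default 6)
along a one-dimensional transect, each assigned to a rainfall category —
low (< 32 mm), moderate (32–44 mm), high (> 44 mm) mean monthly rainfall,
with the boundary values closed on the moderate side so every value maps to
exactly one category. Individuals carry a site label, a sex
(male/female/unknown; unknown-sex birds are excluded from all
sex-stratified analyses), multilocus codominant genotypes (Genepop text, 2-
or 3-digit allele codes, all-zero = missing), and a seven-trait morphology
panel: bill-head length, bill-nostril length, bill depth, bill width, wing
length, tarsus length (mm) and mass (g).

## Population-genetic statistics

**Diversity.** Per locus and site (and globally): allele count N_A,
observed heterozygosity H_O, unbiased gene diversity
H_E = 2n/(2n−1) · (1 − Σp̂²), and F_IS = 1 − H_O/H_E. F_IS is reported in
this simple (Nei) form because it sits alongside H_E/H_O as a descriptive
summary; the Weir–Cockerham small-f is a different estimator and is *not*
what this column contains. Monomorphic cells report F_IS as missing, never
as zero.

**Hardy–Weinberg tests.** Monte-Carlo exact test: the statistic is the
conditional probability of the genotype table given allele counts
(Levene's formula, n!·Πm_a!·2^H / ((2n)!·Πn_ab!)); the null re-pairs the 2n
allele copies at random. p = (1 + k)/(1 + N) (add-one estimator, so p > 0
always). Requires ≥ 5 typed individuals and a polymorphic locus; otherwise
the test is skipped with a reason.

**Linkage disequilibrium.** Genotypic contingency test: G statistic on the
genotype × genotype table, null built by permuting one locus's genotypes
across individuals within the site. Same p estimator and preconditions.

**F_ST.** Weir & Cockerham (1984) variance components a (among
populations), b (among individuals within populations), c (within
individuals), computed per allele and summed within locus; per-locus
θ = a/(a+b+c) and multi-locus θ = Σa/Σ(a+b+c) (ratio of sums, not mean of
ratios). Individuals missing at a locus are excluded from that locus only;
populations without data at a locus drop out of that locus's components.
Loci monomorphic across the selected sites contribute nothing and the
global θ is undefined (NaN) only if *all* loci are uninformative.

**Jackknife CI.** Delete-one-locus pseudovalues
L·θ − (L−1)·θ₍₋l₎ of the multi-locus θ; the 95% interval is the
pseudovalue mean ± 1.96 · SE. Requires ≥ 3 informative loci. With
identical per-locus components the interval collapses to the point
estimate, as it should.

**Multiple testing.** Sequential Bonferroni (Holm/Rice): p-values sorted
ascending, p₍k₎ compared with α/(m−k+1), stopping at the first failure.
The HWE/LD family is screened at the fixed printed threshold α = 0.01;
trait families (ANOVAs, regression coefficients, the selection scan) use
sequential Bonferroni at α = 0.05. Both are exposed in the pipeline
config.

## Dispersal and isolation by distance

**Assignment index.** AI = Σ_loci log₁₀ f(genotype | site allele
frequencies), f = p² (homozygote) or 2pq (heterozygote), over the
individual's typed loci. Frequencies are leave-one-out (the focal
individual's two copies removed); a post-removal frequency of zero is
floored at 1/(2n_site + 1) to keep the log finite. AIc centers AI within
site, so site means are 0 by construction. The floor and the leave-one-out
rule follow standard assignment-index practice; both are deliberate,
documented conventions rather than estimates.

**Sex-bias tests.** The philopatric sex is expected to show *higher*
per-sex θ and *lower* variance of AIc (its genotypes fit their sampling
site better). Because published analyses of this design differ on which
direction they report, the tested direction is a required argument, never
hard-coded. Statistics: vAIc compared as a male/female variance ratio,
mean AIc as a difference, per-sex multi-locus θ as a difference. The null
permutes sex labels within sites only (sites with one sex contribute
nothing), one-sided p with the add-one estimator.

**Isolation by distance.** Pairwise θ linearized as θ/(1−θ) (Rousset) and
correlated with log (natural) distance; the log base only rescales a
slope, not r or p. The Mantel test permutes rows and columns of one matrix
simultaneously; r is the Pearson correlation over the n(n−1)/2 upper
triangle. For n ≤ 6 sites all n! permutations are enumerated (p includes
the identity); otherwise Monte-Carlo with the add-one estimator. A pair
with θ = 1 linearizes to infinity and is excluded with a warning.

## P_ST versus F_ST

One-way ANOVA per trait/sex on the *pair* of sites (not pooled
within-variance across all sites — each pair stands alone):
σ²_W = MS_within, σ²_B = max(0, (MS_between − MS_within)/n₀),
n₀ = (N − Σnᵢ²/N)/(k−1). Then

    P_ST = (r σ²_B) / (r σ²_B + 2 σ²_W),  r = c/h²  (default 1).

The c/h² ratio expresses how much of the between-population phenotypic
variance is assumed additive-genetic relative to within; the default 1 is
the conventional neutral assumption, and the parameter exists for
sensitivity analysis. Negative method-of-moments σ²_B is truncated to 0
(P_ST is never negative); truncation is flagged per pair.

The interval on P_ST is the mean ± one SD of the pairwise estimates,
clamped to [0, 1]. This is deliberately a *descriptive spread*, not a
nominal confidence interval — with six populations a proper sampling
interval for P_ST is not estimable — and it is conservative for the
"exceeds" call: the verdict is "exceeds" only when the P_ST lower bound
clears the θ jackknife upper bound. Under neutral simulations this fires
in well under 10% of replicates; with a strong trait–rainfall slope it
fires in essentially all (see `tests/test_acceptance.py`).

## Condition index and the selection scan

Condition index (CI) = standardized residual of OLS mass ~ tarsus length,
fitted per sex (the sexes are size-dimorphic); per-stratum mean 0, SD 1 to
numerical precision. CI is a body-condition fitness proxy: the analysis
assumes relative mass at a given structural size tracks energetic state.

The condition–rainfall regression is one-sided (wetter → better
condition), fitted at the individual level by default (site-mean mode is
available); both r² and adjusted r² are always reported.

The selection scan bins each trait within sex × rainfall category on the
within-stratum z-score: |z| ≤ 1 "mean", 1 < |z| ≤ 2 "small"/"large",
|z| > 2 excluded (the three named ranges are exhaustive by definition;
exclusions are counted). The within-category SD (rather than a global SD)
makes bins comparable across categories. One-way ANOVA of CI across the
three bins, Holm across all scanned cells, and for significant cells:

* mean bin above both extremes (by > ε) → **stabilizing**
* both extremes above the mean bin (by > ε) → **disruptive**
* otherwise → **directional** toward the higher extreme; ε = 0.05 CI units
  absorbs "extreme tied with the mean" into the directional call.

Tarsus is never scanned (it defines CI); mass is excluded from the default
trait list for the same reason (it is the CI response) but can be passed
explicitly. The classifier is symmetric: negating a trait swaps
directional up/down and preserves stabilizing/disruptive.

## Synthetic-data model

**Genotypes.** Ancestral allele frequencies per locus are
symmetric-Dirichlet(1) over A alleles (default 12, giving H_E ≈ 0.75–0.9,
the diversity regime of highly polymorphic microsatellites). Sites form a
chain: site 1 is a Balding–Nichols-style Dirichlet draw around the
ancestor, each subsequent site around its left neighbour. The per-step
concentration uses F_eff = 2F_step/(1+F_step), calibrated so that the
*expected adjacent-site Weir–Cockerham θ equals F_step* (a one-directional
conditional draw with parameter F yields pairwise θ ≈ F/2, since both
sites deviate from their midpoint by half the drift; the calibration was
verified by simulation: θ̂ ≈ 0.0198 at F_step = 0.02 and 0.0493 at 0.05
over 50 replicates). Default F_step = 0.01 puts the 6-site global θ near
0.02 and the most-distant pairwise θ near 0.05 — a weakly structured,
high-gene-flow system. Genotypes are Hardy–Weinberg draws from the source
site; with per-sex probability m (defaults m_male = 0.05,
m_female = 0.25: female-biased dispersal) an individual is a
first-generation immigrant drawn entirely from a uniformly chosen adjacent
site. Entries are masked missing at rate 192/3300 ≈ 5.8%.

**Phenotypes.** Each trait is intercept + slope · rainfall(site) + N(0,
SD); the default intercepts/SDs are sized to an adult honeyeater-like
passerine and the slopes spread site means by about one within-site SD
across the 28–52 mm gradient. Mass = α + β·tarsus + condition effect +
N(0, 1 g), with the condition effect carrying a rainfall slope (0.03 g/mm)
and an optional selection term on the focal trait's within-stratum
z-score: −γz² (stabilizing), ±γz (directional), +γz² (disruptive); default
focal trait bill depth, γ = 0.5 g. The injected truth (mode, γ, slopes) is
returned for recovery tests.

**What the generator does not emulate.** No mutation model, overlapping
generations, pedigree, or multi-generation migration equilibrium
(immigrants are first-generation only, so the sex-bias signal is stronger
per migrant than in a system at migration–drift equilibrium); no
measurement error, no trait covariance beyond the mass–tarsus link, no
temporal variation. Passing recovery tests therefore demonstrates the
*estimators and decision rules* work when their assumptions hold, not that
real field data meet those assumptions.

## Test and acceptance problem sizes

The replicate-based checks use designs small enough to run routinely:
panmixia calibration at 2 × 50 individuals × 10 loci (100 replicates);
permutation-test calibration at 200–500 null replicates with 1000
permutations each; IBD recovery at 6 sites × 50 × 10 loci × 10 alleles,
F_step = 0.02 (100 replicates); sex-bias recovery at 6 sites × 90 (45 per
sex), F_step = 0.05, m = (0.1, 0.5) — the migration ratio is 5× with
absolute rates in the range field estimates suggest for this kind of
system, where per-sex-θ permutation power reaches ≥ 80%; selection
recovery at 200 individuals per rainfall category, γ = 0.5. The full suite
runs in a few minutes on one CPU.

## Known limitations

* F_IS is descriptive; no small-sample f estimator is provided.
* The HWE exact test uses Monte-Carlo only (no complete enumeration above
  trivial sizes); p-values are mildly conservative.
* The P_ST interval is a ±1 SD spread, not a nominal CI (see above), and
  the exceeds/overlaps verdict inherits that conservatism.
* P_ST assumes the c/h² ratio is known; no heritability is estimated.
* The pipeline consumes the geographic distance matrix as given (any
  overland/sea routing is the data provider's responsibility).
* R-statistics (allele-size-based R_ST) and Bayesian clustering are out of
  scope.
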