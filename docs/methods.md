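# Methods

This note documents the models behind each module, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical decisions a maintainer would want written
down. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Synthetic-data generator

### Genotypes

The genotype engine is a forward Wright–Fisher simulation on per-site
allele frequencies with free recombination (sites independent — a spec'd
simplification; there is no linkage, so no hitchhiking or background
selection). Per generation, deterministic selection and one-way mutation
(ancestral → derived, rate `mu = 2e-4` per site) update the expected
frequency, and binomial sampling over `2N` gene copies adds drift.
Fitnesses are `1, 1+hs, 1+s` with `s ≤ 0`.

Demography: a burn-in of `4 × ne_ancestral` generations from
monomorphic-ancestral initial conditions (this yields a derived-allele
frequency spectrum skewed toward rare variants, as polarized data
should be), a split into populations A and B `t_split = 300` generations
ago, a bottleneck in A only from generation 100 to 20 before sampling at
`ne_bottleneck = 12` (versus `ne_ancestral = 200`), then recovery. These
sizes and times put background differentiation at Fst ≈ 0.5 and the
bottleneck severity in the regime where drift overwhelms selection for
mildly deleterious alleles but not for severe ones — the
purging-versus-accumulation contrast the generator exists to produce.
Sample sizes (12 + 14 diploids) match the scale of small resequencing
panels for elusive mammals.

Mutation classes: synonymous (1500 sites), missense (1500), LOF (1200)
and intergenic (2500), with per-site selection coefficients drawn from
exponential distributions of fitness effects with class means
`s_missense = −0.015` and `s_lof = −0.9` (truncated at −1). Dominance is
additive (`h = 0.5`) except for the LOF class, which is fully recessive
(`dominance_lof = 0`): severe loss-of-function alleles are overwhelmingly
recessive, and recessivity is the mechanism that lets a bottleneck purge
them (homozygotes become visible to selection) while additive mildly
deleterious alleles drift upward. Both dominance values are parameters.

Observables: Grantham scores are uniform integers 5–215 on missense
sites (the "harmful missense" analysis class is the Grantham ≥ 150
subset); GERP-like scores are class-base values (intergenic −2,
synonymous −1, missense +2, LOF +5) plus `5·|s|` plus N(0, 1.5) noise,
so stronger selection means stochastically higher conservation; two
outgroup allele columns carry the true ancestral allele with error
`ε = 0.02` and missingness 0.01 each, so polarization exclusions are
exercised; genotypes are missing at rate 0.02; the VCF ALT allele is the
ancestral allele at 30% of sites, so polarization actually flips dosages.
Individuals are drawn from population frequencies under Hardy–Weinberg
proportions with an optional per-population inbreeding coefficient F
(used by the inbred-lineage experiments; the frequency-based engine has
no persistent individuals to self, so F is the faithful equivalent).
Monomorphic sites are dropped from the genotype matrix but kept in the
site ledger.

### Landscape, cline and niche

Climate variables live on a regular lon/lat grid (default 0.5°,
12° × 9° extent). The focal variable is a linear gradient along the
cline axis (latitude by default) spanning `cline_range = 10` units;
secondary variables get a diagonal gradient weighted 70/30 toward the
cline axis, plus smooth low-frequency noise (σ = 0.4). The diagonal
design is deliberate: a secondary variable aligned purely with the
between-population axis would make climate and population structure
unidentifiable, which no association method can resolve. Future
scenarios add a uniform per-variable shift (defaults emulate a mild and
a harsh scenario: +1.5 and +4.0 units on the focal variable).

Populations are placed in separate longitude bands, each split into five
sampling-site clusters spread along the cline, so the focal climate
variable varies *within* populations — the design that gives
genotype–environment association methods their power.

`embed_adaptive_cline` re-draws `n_causal = 25` intergenic loci with
derived-allele probability `1/(1+exp(−steepness·z))`, z the standardized
focal environment (default steepness 4 — near-fixed alternative alleles
at the cline ends). `embed_sweep` overwrites one 50-kb region (12 loci)
to near-fixation in A and near-loss in B, emulating the local
differentiation signature of a hard sweep (free recombination precludes
generating one dynamically). Occurrence records for the niche models are
drawn proportionally to a squared Gaussian suitability on the focal
variable (tolerance 1.0); this crisp unimodal niche yields member AUC
≈ 0.98 and TSS ≈ 0.9, the discrimination range published ensemble
habitat models for range-restricted species report.

### What passing tests do and do not show

The generator reproduces the statistical *structure* the analyses
assume: drift/selection balance by mutation class, excess homozygosity
after bottlenecks, clinal allele-frequency turnover, spatially smooth
climate. It does not emulate linkage, recombination maps, gene
conversion, sequencing error beyond missingness, reference bias, or
realistic geography. Tests passing here demonstrate the statistics are
computed correctly and behave as theory predicts under the model's
assumptions — not that any particular real dataset would show the same
effect sizes.

## Polarization and classification

Ancestral alleles are the majority across outgroup columns; missing
outgroup calls are ignored (a single observed allele decides — a
documented choice, since two informative outgroups cannot break a 1–1
tie); ties and all-missing sites are UNRESOLVED and excluded downstream
(their dosages are masked to missing so they cannot leak into any
statistic). Missense sites are deleterious ("radical") iff Grantham
≥ 150; sites are GERP-deleterious iff GERP ≥ 4. Both thresholds are
parameters.

## Load statistics

`L_A,B(C)` sums `f_iA(1−f_iB)` over class sites and divides by the same
sum over intergenic sites; `R_A/B = L_A,B / L_B,A`. Frequencies use
called alleles only. The jackknife deletes one of 100 contiguous
positional blocks (class and intergenic sites blocked jointly in genome
order, equal site counts per block); SD is the standard delete-one
jackknife estimate; fewer informative sites than blocks reduces the
block count with a warning. Monomorphic and UNRESOLVED sites are
excluded from C and I.

Masked load is the GERP sum over heterozygous deleterious-derived
genotypes, realized load over homozygous-derived ones; both divide by
the individual's count of called genotypes (the two denominators are
worded differently in parts of the literature; a `denominator="genome"`
switch divides by the total site count instead). Group differences are
assessed with Welch's t-test.

## Window scan

Weir–Cockerham (1984) variance components a, b, c are computed per SNP
for two populations (with missing-data-aware sample sizes) and summed
over 50-kb/25-kb sliding windows: Fst = Σa / Σ(a+b+c), the behavior of
the standard windowed VCF scan. A Hudson estimator sits behind a flag.
Per-window π divides the summed unbiased per-site heterozygosity
`d(n−d)/C(n,2)` by window length in bp (monomorphic positions count as
invariant). Windows are 0-based half-open (BED convention); scaffolds
shorter than one window are skipped; windows with fewer than 3 SNPs are
flagged low-support. Top-quantile outliers include ties at the
threshold. Candidate-set intersection reports per-combination Venn
counts and the at-least-k set.

## Genotype–environment association

Variables are pruned by iteratively removing the largest VIF until all
VIF ≤ 10, ties broken by name so the result is order-invariant.

**Ordination arm.** A redundancy analysis of mean-imputed, centered
dosages on the standardized climate matrix. Because genome-wide
structure dwarfs any climate signal in strongly diverged pairs, both
dosages and climate are first residualized on `k_condition = 2`
structure axes (partial RDA, standard practice for structure-confounded
landscapes; `k_condition=0` restores the plain version). Axis
significance uses permutation of sample rows — restricted to strata
obtained by clustering the structure-axis scores, because individuals
are exchangeable within, not across, genetic groups — with sequential
gatekeeping (a later axis counts only if every earlier one is
significant; marginal tests of later ordered eigenvalues are
anticonservative on their own). A SNP is an outlier when its loading on
any significant axis is more than 2 SDs from the mean loading (per-axis
SDs).

**Latent-factor arm.** Factors are the top-K axes of the
column-standardized (EIGENSTRAT-scaled) dosage matrix. Standardization
matters: on the raw covariance a compact block of high-variance adaptive
loci can become the second principal axis and absorb exactly the signal
being tested, while after per-SNP scaling genome-wide structure still
dominates the spectrum but a sparse causal block cannot. Each SNP is
regressed on the climate block plus the factors; the climate block is
tested jointly (F-type statistic; univariate mode behind a flag).
Parametric F p-values are not calibrated here — post-bottleneck dosage
matrices are heavily discrete (many sites monomorphic within one
population) and per-individual noise levels differ between populations —
so p-values come from a Freedman–Lane residual-permutation null
(restricted to factor-score strata, factors re-estimated per permuted
dataset) pooled across SNPs for tail resolution; 250 permutations give a
minimum attainable p of ~1/(250·n_snps). Benjamini–Hochberg FDR < 0.05
calls candidates; the final candidate set is the intersection of the two
arms. Genomic inflation λ is the median association χ² over its null
median.

## Genomic offset

**Gradient-forest turnover.** Per candidate SNP, a random forest
regresses population allele frequency at the sampling sites on the site
climates (all features considered at every split, minimum leaf 2 — with
a handful of predictors, random feature subsetting only injects spurious
splits on uninformative variables). Every split's impurity decrease is
credited to its variable at its threshold; per-SNP totals are rescaled
to the SNP's out-of-bag R² (SNPs with non-positive fit are dropped);
accumulating splits along each variable's axis yields a monotone
piecewise-constant cumulative-importance transform. Transforms are
constant outside the training range (clamping).

**Dissimilarity-spline turnover.** Pairwise Fst between sampling sites
is rescaled to [0, 1] and regressed on per-variable absolute I-spline
basis differences (3 basis functions, quadratic; I-splines evaluated by
numerically integrating the normalized B-spline basis on a 1025-point
grid) with non-negative coefficients via NNLS (the intercept is left
free through a ±column pair), so each per-variable transform is monotone
non-decreasing. Variable importance is the fitted transform's total
height. Offsets from both models use the same Euclidean-in-transformed-
space formulation, so the operators are model-agnostic.

**Operators.** Local offset is the per-cell distance between
transformed present and future climate. Forward offset is the minimum
distance from a cell's present vector to the future vector of any cell
within a great-circle cap (haversine on a 6371-km sphere; caps 100, 250,
500, 1000, ∞ km); the focal cell is always in its own pool, so forward
≤ local and forward is non-increasing in the cap. Reverse offset is the
minimum distance from a future cell's vector to any current cell's
present vector, uncapped. The RGB composite min–max scales
local/forward/reverse into red/green/blue; constant bands scale to 0
with a warning and nodata propagates.

## Ensemble habitat models and vulnerability

Presences are greedily thinned at 5 arc-min great-circle spacing;
background points are uniform over data cells not occupied by a retained
presence. Five member families — random forest, gradient boosting,
RBF-SVM (probability-calibrated), a spline-additive logistic model and a
plain logistic model — are each evaluated over 10 stratified 70/30
splits; members pass only if mean validation TSS > 0.8 and AUC > 0.9.
Accepted members are refitted on all data and weighted by mean TSS
(normalized; equal weighting behind a flag — the weighting scheme for
"weighted average" ensembles is rarely stated precisely, and TSS
weighting is the common choice in the ensemble-SDM literature).
`threshold_` is the ensemble's TSS-maximizing cutoff on the training
data. V_E = S_future − S_present per cell; habitat area change weights
cells by latitude-dependent spherical area.

## Problem sizes

Defaults are desk-scale by design: ~6200 simulated sites (~2800
segregating), 26 diploids, 4 × 5-Mb chromosomes (800 windows), a
24 × 18 climate grid, 300 occurrence records and 800 background points.
Multi-seed experiments use 10 replicate simulations (5 for the
association screen). A full pipeline run completes in well under a
minute on one core; the acceptance script in a few minutes.

## Known limitations

Free recombination means no linked selection, so the sweep fixture is an
engineered pattern, not an emergent one. Two populations give a single
real structure dimension; K = 2 therefore carries one noise factor,
which the permutation calibration absorbs. The latent-factor scan's
pooled permutation null calibrates the p-value *distribution*; per-SNP
exactness is traded for speed. The ordination's partial-RDA conditioning
means its outliers are defined relative to structure-free variation —
loci perfectly confounded with the population split are undetectable by
design (by either method; that information simply is not in the data).
I-spline integration is numerical (1025-point grid), accurate to well
below the fitted coefficients' uncertainty. The GDM-style model fits
rescaled Fst directly with an identity link rather than the classical
negative-exponential GLM; at desk-scale dissimilarities (far from
saturation) the two agree closely and the identity link keeps the fit a
convex NNLS problem.
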