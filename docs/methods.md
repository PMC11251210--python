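# Methods

## Model

The estimator rests on the drift–recombination equilibrium of an idealized
Wright–Fisher population: for two biallelic loci a genetic distance *c*
(Morgans) apart, the expected squared correlation of allele dosages is

    E(r²) = 1 / (1 + 4·Ne·c),

so a decaying LD profile, binned by distance, carries Ne in its shape. The
assumptions that matter: a closed population of constant size, no selection,
mutation or migration at the sampled loci, and enough generations at that
size for LD to have equilibrated (the relation reflects *recent* effective
size, on the order of 1/(2c) generations back for each distance bin). Real
breeding populations violate several of these; the estimate is then a
drift-equivalent summary, not a census.

## Pipeline

**Dosage matrix.** Genotypes are alt-allele counts 0/1/2 with an explicit
missing code. Phase is ignored throughout: r² is the squared Pearson
correlation of dosage vectors (genotypic r²), computed per pair over the
samples non-missing at both sites (pairwise-complete deletion). In highly
selfed material genotypic and haplotype-frequency r² converge; the genotypic
form is deterministic and needs no EM. Pairs where either site is
monomorphic among the shared samples carry no information and are skipped
and counted, never recorded as r² = 0.

**QC filters.** Markers are dropped when MAF < 0.05, missingness > 0.20 or
heterozygosity > 0.20 (rare alleles bias r² upward; high missingness makes
pairwise r² unstable; in a selfer, excess heterozygosity flags genotyping
artifacts or outcrossing contamination). Boundaries are literal: a marker at
exactly 5% MAF or exactly 20% missing/het is retained. The three filters are
applied jointly on stats computed once from the input — order-independent
and idempotent. Markers with every call missing have undefined (not zero)
MAF and het and are removed separately.

**Window and scores.** Pairwise r² is restricted to intra-chromosomal pairs
within 750 kb. No r² reporting floor is applied anywhere: a nonzero floor
would inflate mean r² and bias Ne downward. LD scores are the per-variant
*mean* (not sum) of neighbor r² within ±1000 kb at cutoff 0, self excluded;
a variant with no qualifying neighbor is reported missing rather than 0.

**Genetic distance.** Physical distances convert to Morgans through a
constant per-chromosome cM/Mb ratio (plain-text config, `default` plus
per-chromosome overrides): c = bp/1e6 × ratio/100. A piecewise (Marey-map)
conversion is an extension point, not implemented. A chromosome absent from
the config with no default raises at lookup time — completeness cannot be
judged at load time because the chromosome universe arrives with the data.

## The two-stage estimator

Pairs are grouped by c rounded to `c_round_digits` decimals of a Morgan
(rounding makes "group by" on floating distances well defined); each group
contributes one observation (c, mean r², n pairs). Groups at c = 0 are
dropped and counted. Then:

- **paper mode (default).** Stage 1 fits mean r² = β₀ + β₁·c by OLS via the
  normal equations; the fitted values μ̂ — not the raw means — feed the
  transform Y = 1/μ̂ − 1, X = 4c, and Ne is the no-intercept slope
  β₁ = ΣXY/ΣX². Fitting a line to a hyperbola is an approximation, but it
  smooths bin noise and reproduces the two-stage scheme exactly.
- **direct mode.** The binned means themselves are μ̂. On a noiseless
  equilibrium curve this inverts the relation exactly (Y = 4·Ne·c is
  proportional to X), which makes it the validation mode.

Rows with μ̂ ≤ 0 (possible at large c under a negative stage-1 slope) are
dropped and counted, never clamped: 1/μ̂ is undefined and clamping would
bias the slope. If every row is dropped the estimator raises; a non-positive
Ne (non-decaying profile) is returned with a degenerate flag and a warning.

**Binning resolution matters in direct mode.** At the default 6 decimals
(10⁻⁶ Morgan) nearly every pair is its own bin, and the reciprocal of a
single noisy r² is enormously right-skewed — E[1/r²] is effectively
unbounded when r² can approach 0 — so direct-mode estimates explode. The
recovery analyses therefore bin at 4 decimals (10⁻⁴ Morgan = 0.1 cM,
pooling on the order of a hundred pairs per bin), where each bin mean is a
stable estimate of E(r²). Paper mode is insensitive to the resolution
because stage 1 smooths across bins; the default stays at 6.

**Finite-sample correction (off by default).** Sample r² is inflated by
roughly 1/n for n sampled individuals. `estimate_ne(..., n_samples=n)`
subtracts 1/n from μ̂ before the transform. The plain relation carries no
correction term, so the default applies none; the uncorrected estimate is
accordingly biased slightly downward (≈10% at n = 50 in the recovery
experiment's regime, visible in the direct-mode medians only as a few
percent because the short-distance bins dominate).

## The simulator

Forward-time Wright–Fisher with standing variation: generation 0 draws each
haplotype's alleles independently at frequencies uniform on [0.1, 0.9] (so
LD starts at zero and all LD at sampling is drift-generated); each offspring
draws two gametes — with probability `selfing_rate` both from one uniform
parent — and each gamete recombines its parent's haplotypes with
Poisson(map-length) crossovers at uniform positions, chromosomes assorting
independently on a shared pedigree. No mutation, selection, migration or
structure. After burn-in (default 2N generations, enough for the 1/(1+4Nc)
quasi-equilibrium to form at the distances the window sees) a sample is
drawn, monomorphic sites are dropped (as a SNP panel would), and optional
per-genotype corruption — missingness and spurious heterozygote calls —
exercises the QC filters without touching the underlying LD.

What it emulates: equilibrium LD decay, fixation-induced marker loss,
selfing-elevated homozygosity, GBS-like missingness. What it does not:
mutation–drift balance (allele-frequency spectra are not realistic),
population structure and admixture, variable recombination along the
chromosome, linked selection. Passing recovery tests therefore show the
estimator chain is correct under its own assumptions — not that those
assumptions hold in any particular germplasm.

**Selfing and the recovery target.** At selfing rate s the equilibrium
inbreeding coefficient is F = s/(2−s); the nominal effective size N/(1+F)
is recorded in the simulation truth. It is deliberately *not* asserted as an
exact LD-recovery target: selfing also suppresses effective recombination by
a factor ≈ (1−F), which an LD-based estimator cannot distinguish from extra
drift, so recovered values under high selfing sit near N/(1+F)·(1−F). The
reference panels (selfing 0.9, F ≈ 0.82) show exactly this compression.
Exact recovery is asserted only under random mating.

## Problem sizes and numerics

The recovery experiment uses 20 replicates of census 100 with two 10-Mb
chromosomes at 1 cM/Mb, 300 initial loci each, 200 burn-in generations and
50 sampled individuals — large enough that the median direct-mode estimate
is well inside ±35% of truth, small enough that the whole suite runs in
seconds. The acceptance band reflects the stochastic spread of single-panel
LD estimates at these sizes (per-seed estimates range roughly 65–175).

Least squares is solved by the normal equations (the designs are 1–2
columns; conditioning is not a concern at these scales). r² is clipped at 1
to absorb float fuzz on exactly collinear dosage columns. A single distinct
c value makes stage 1 rank-deficient and raises. Duplicate VCF positions
are dropped (first record wins) to keep per-chromosome positions strictly
increasing; variant order is always (chrom, pos) lexicographic, which makes
every pipeline output byte-reproducible.

## Limitations

- The headline estimator assumes equilibrium; recent bottlenecks or
  expansions bend the LD-vs-c profile and the single-number summary hides
  that.
- Genotypic r² on unphased heterozygote-rich (outcrossing) data
  underestimates haplotype r²; the package targets selfers.
- No confidence intervals; a pair-block jackknife is the natural extension.
- Constant cM/Mb per chromosome ignores recombination heterogeneity
  (pericentromeric suppression), which shifts c for pairs in those regions.
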