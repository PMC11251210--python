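# svedne — LD-based effective population size for crop SNP panels

Effective population size (Ne) tells a plant breeder how fast a germplasm
pool is inbreeding and how much standing diversity it can sustain. For a
single contemporary sample of genotypes, Ne can be read off the extent of
linkage disequilibrium: at drift–recombination equilibrium the expected
squared allele-dosage correlation between two loci a genetic distance *c*
(Morgans) apart is

    E(r²) = 1 / (1 + 4·Ne·c)        so        Ne = (1/4c) · (1/E(r²) − 1).

`svedne` implements this estimator as a tested pipeline for biallelic SNP
panels of predominantly selfing crops (it was built around dry pea GBS data):

1. **genotype_io** — VCF → samples × variants dosage matrix (0/1/2, missing).
2. **qc_filters** — remove markers with MAF < 5%, missingness > 20% or
   heterozygosity > 20%, with a per-filter attrition report.
3. **ld_engine** — pairwise genotypic r² within a 750-kb physical window,
   distance-binned LD-decay curves, and per-SNP mean LD scores in 1000-kb
   windows (r² cutoff 0).
4. **genetic_map** — physical → genetic distance via configurable per-
   chromosome cM/Mb ratios.
5. **ne_estimator** — distance-binned mean r², then two least-squares stages:
   an intercept OLS fit of mean r² on *c* giving fitted values μ̂, and a
   no-intercept regression of Y = 1/μ̂ − 1 on X = 4c whose slope β₁ is Ne
   (`paper` mode). A `direct` mode transforms the binned means themselves and
   is exact on a noiseless equilibrium curve.
6. **synthetic_data** — a forward-time Wright–Fisher simulator with selfing
   and recombination that generates VCF panels with known ground truth, used
   to validate the whole chain by parameter recovery.

## Worked example

Simulate a small breeding panel and estimate its Ne:

```bash
svedne simulate --n-diploid 100 --seed 7 --out panel.vcf
svedne run panel.vcf --out-dir out/ --cm-per-mb 1.0 --het-max 0.5
```

Library use, end to end (the `analysis/` scripts are fuller versions of this):

```python
from svedne import (SimConfig, simulate, pairwise_r2, fill_genetic_distance,
                    GeneticMap, bin_mean_r2, estimate_ne)

G, truth = simulate(SimConfig(n_diploid=100, seed=0))      # random mating
pairs = fill_genetic_distance(pairwise_r2(G, max_bp=750_000),
                              GeneticMap(default_ratio=1.0))
est = estimate_ne(bin_mean_r2(pairs, c_round_digits=4), mode="direct")
print(round(est.ne, 2))   # -> 101.26  (true census size 100)
```

Running `python analysis/03_parameter_recovery.py` repeats this over 20 seeds
and prints:

```
true census size: 100 (random mating, so Ne ~ N)
median Ne over 20 seeds: paper mode 99.7, direct mode 100.2
```

`analysis/01_simulate_panels.py` + `analysis/02_ld_and_ne.py` contrast two
selfing germplasm types (census 60 closed program vs census 200 diversity
collection). From a run of those scripts:

```
elite:   short-range mean r2 0.923, Ne(paper)  4.9
diverse: short-range mean r2 0.849, Ne(paper) 27.2
```

The smaller, more inbred panel shows higher short-range LD and a smaller Ne —
the qualitative contrast the estimator exists to expose. Under selfing rate
*s* the estimates sit well below census size: the nominal effective size is
N/(1+F) with F = s/(2−s), and selfing further suppresses *effective*
recombination, which an LD-based estimator reads as extra drift (see
`docs/methods.md`).

## Command line

`svedne` exposes subcommands `qc`, `ld`, `ldscore`, `ne`, `simulate` and
`run` (full pipeline: QC report, LD pair table, genome-wide and per-chromosome
decay curves, LD-score TSV/BED, Ne JSON, run log). Defaults reproduce the
pipeline's reference settings: MAF ≥ 5%, missingness ≤ 20%, het ≤ 20%,
LD within 750 kb, LD scores in 1000-kb windows with r² cutoff 0.

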