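# Methods

## The estimation problem

Inbreeding depression (ID) is the decline of fitness with the inbreeding
coefficient F, quantified as the slope of an ordinary least-squares
regression of log phenotype on F. When pedigrees are unavailable, F is
estimated from SNPs. This package implements that workflow for a
deliberately unfavourable design: all individuals come from one generation
of a large panmictic population (so F varies little), samples are small
(tens of individuals), and the traits — pupae productivity P of a breeding
pair, and competitive fitness W = Wild/(Curly+1) pooled over four pairs —
depend on several parents of whom only one male is genotyped.

## Molecular inbreeding coefficients

**SNP-by-SNP (`YangInbreeding` / `f_yan`).** The
correlation-of-uniting-gametes estimator averages, over S markers, the
quadratic form `[x² − (1+2p)x + 2p²] / [2p(1−p)]` in the minor-allele
dosage x and minor-allele frequency p. Frequencies are always the *current*
frequencies of the analysis group itself, recomputed per group; SNPs
monomorphic within a group are dropped (undefined denominator), and missing
genotypes are excluded from both the frequency and that individual's
average (reducing its effective S). Under Hardy–Weinberg proportions at
known p the expectation is exactly zero; a heterozygote always contributes
−1. Two O(1/n) effects make the group mean slightly negative in practice:
the heterozygote excess of a finite random-mating cohort and the bias from
estimating p on the same n individuals — each contributes about −1/(2n).

**Runs of homozygosity (`ROHInbreeding` / `detect_roh`).** A window of 50
SNPs slides one SNP at a time along each chromosome; a window is homozygous
if it holds ≤ 1 heterozygote and ≤ 5 missing calls. Each SNP's hit rate is
the fraction of overlapping windows that are homozygous; SNPs at ≥ 5% are
ROH-eligible, and maximal runs of eligible SNPs — split at gaps > 1 Mb —
are reported if they hold ≥ 100 SNPs, span the minimum length and keep at
least 1 SNP per 50 kb. F_ROH = ΣL_ROH / L_auto with L_auto the marker-covered
autosomal length (119 Mb for the Drosophila emulation — a stated constant,
not inferred from data). Two edge conventions are deliberate choices where
the common tooling's behaviour is undocumented: windows truncated at
chromosome ends are judged with the same absolute het/missing bounds, and
segments inherit no per-segment heterozygote cap beyond window eligibility
(the count is reported). Coordinates are 1-based inclusive;
length = end − start + 1. Both minimum lengths (0.1 and 1 Mb) filter one
candidate-segment set, so F_ROH-1 ≤ F_ROH-0.1 by construction.

**Filters.** LD pruning follows indep-pairwise semantics (window 50, step
5, r² > 0.9); within a window the lower-MAF member of an offending pair is
dropped (tie: later position), which makes the pass deterministic. MAF
filtering (default 0.05) and uniform random SNP subsampling operate on the
analysis group's own frequencies.

## Depression inference

`InbreedingDepressionRegression.fit(F, log y)` returns the OLS slope (the
ID rate), its SE and the two-sided t-test p, plus two resampling measures:
a bootstrap over individuals (percentile 95% CI; one-sided significance as
the fraction of resampled slopes ≥ 0, a choice made here because the method
is usually named without its decision rule; the doubled two-sided version
is also reported) and a randomization test (phenotypes permuted among
individuals, one-sided p = (N_more_depression + 1)/(n_perm + 1), where
"more depression" means a more negative slope). Individuals with zero
phenotype are excluded from log analyses. With exactly two F groups the
slope equals the difference of group log-means over ΔF, which ties the
regression to the ratio estimator `ID = log(mean_0/mean_1)/ΔF` evaluated at
geometric means. Natural logarithms throughout. Pooled analyses concatenate
the groups' F values, each computed with its own group frequencies.

## Pedigree expectations

Kinship uses the recursive tabular method with exact rational arithmetic;
F(child) = f(sire, dam) identically. Genome sharing is defined as 2f
clipped to [0, 1] — deliberately without the inbreeding correction, since
the design calculus treats the 0.375 coancestry of generation-2 full-sib
mates as 75% genome sharing. The capture fraction of a partially genotyped
design is the mean sharing over contributing parents, assuming equal trait
contribution: 1/2 and 7/8 for productivity (non-inbred, inbred), 1/8 and
9/32 for fitness — the inbred fitness design counts eight contributors of
whom one wild-type female is a cousin of the genotyped male (f = 0.25,
r = 0.5); this accounting reproduces the printed 9/32 but the averaging
over vials with and without a cousin admits other readings. The effective
F attached to a trait that depends on both the parents' inbreeding (0.25)
and their progeny's (0.375) is the weighted mean, 0.3125 at equal weights.

A refinement the simulator makes visible: the capture-fraction calculus is
exact for unrelated mates (measured trait-level fraction 0.508 ± 0.024 vs
1/2), but for inbred full-sib mates the generative fraction is ~0.75 rather
than 7/8, because regressing a relative's deviation on an *inbred* proband
carries a 2f/(1+F) coefficient (0.6, not 0.75), and the realized-IBD
correlation between full-sib mates (~0.21) is weaker still than their
allele sharing. The 7/8 and 9/32 fractions are therefore upper-end
heuristics; the package reports them as the design calculus and tests the
exact non-inbred link plus the qualitative elevation for inbred mates.

## The simulator

Life cycle: adults mate uniformly at random; zygotes survive with
probability Π(1−hs)^het · Π(1−s)^hom over deleterious loci (multiplicative
fitness, matching the lethal-equivalents framework); survivors form N
adults (N/2 per sex). New deleterious mutations arise at a haploid genomic
rate U per gamete with s ~ exponential truncated to (0,1) and a dominance
rule h(s) = 0.5·e^(−13s) (h ≈ 0.25 for mild effects, near-recessive severe
ones); recessive lethals (s = 1, h = 0.02) arise at their own rate.
Defaults follow Drosophila mutation-accumulation consensus: U = 0.061,
median-scale s = 0.11, lethals at 0.015. Crossovers are Poisson per
chromosome on the genetic map (Haldane, no interference); with the
Drosophila flag set, male meiosis is achiasmate (whole-chromosome
transmission with independent assortment). Neutral markers are seeded
before burn-in in linkage equilibrium with 1/x-spectrum frequencies;
burn-in random mating then builds map-dependent LD.

The breeding schemes reproduce the experimental design with one
strengthening: the circular non-inbred scheme uses four founder families
per generation-2 pair (female from vial 4i, male from vial 4i+2), so all
generation-2 adults are exactly mutually unrelated, not just within pairs
(the physical experiment reuses vials and creates cross-pair sibships).
Scheme generations apply no viability selection beyond discarding lethal
homozygotes, so the built-in load maps exactly onto pedigree F: the
expected log P declines in F with slope −B,
B = Σ p q [2·log(1−hs) − log(1−s)], computable in closed form from the
base-population frequencies (`inbreeding_load`) and used as the
parameter-recovery oracle. The real experiment's viability selection
(purging) is deliberately absent, a known difference from the wet design.

Phenotypes: P ~ Poisson(κ · exp(mean parental log viability + ε)) with
lognormal environmental noise ε (σ = 0.35 by default, matching the ~0.4
coefficient of variation of observed productivities; κ = 100 puts the
non-inbred mean near the observed ~86). W divides a wild count driven by
the mean viability of the eight parents of a four-pair group by an
independent Poisson Curly count plus one (competitors come from an external
stock and carry no focal genetics; defaults 90 and 44 give W ≈ 2). One pair
per group is the sequenced designate, and only designate males with P > 0
are eligible for export — mirroring the 34-male design (17 + 17).

What the generator does not emulate: sequencing or genotyping error,
missingness beyond an optional uniform rate, purging during the schemes,
maternal effects, and linked selection on the markers during burn-in.
Passing tests therefore validate the estimators and the design arithmetic,
not robustness to genotyping artefacts.

## The variance study

Dispersion of realized F among individuals of identical pedigree is
governed by genetic map length (few independently segregating blocks →
wide spread). The study simulates a neutral base population per
architecture — two 0.5-Morgan chromosomes (Drosophila-like) vs twenty
1-Morgan chromosomes (mammal-like), maps taken as sex-averaged so both
sexes recombine — then forms replicate full-sib families (one offspring of
a full-sib mating each, pedigree F = 0.25) and an equal number of unrelated
non-inbred individuals (offspring of independent base pairs), and reports
the SD of `f_yan` within each group against its own sample frequencies.

Problem sizes: base N = 1000 with 100 burn-in generations, 10,000
segregating SNPs (seeded with a 2× excess to cover drift loss; a shortfall
falls back to all segregating sites with a warning), 500 replicate
families. The base size matters for the unrelated group: its SD is driven
by standing LD, which scales inversely with N, so a small desk-scale base
(N ≈ 100) would inflate that SD several-fold relative to a large panmictic
population; N = 1000 is the largest size that keeps the study to ~1–2
minutes per architecture on one CPU. The full-sib-offspring SD, by
contrast, is dominated by Mendelian segment sampling and is insensitive to
N. Typical outputs: SD ≈ 0.22 (full-sib offspring) and ≈ 0.03 (unrelated)
for the short genome, ≈ 0.06 and ≈ 0.015 for the long genome.

## Numerical and interface choices

- Seeding is hierarchical: one integer seed per operation spawns child
  generators, so every stage reproduces in isolation; the CLI logs the
  seed and parameter echo per stage.
- Dosage matrices are float arrays with NaN missing; estimators are
  scikit-learn compatible (`fit`/`transform`/`predict`, `get_params`,
  fitted attributes with trailing underscores) and the selectors
  (`LDPruner`, `MAFFilter`) implement `SelectorMixin`.
- Exact rational arithmetic (`fractions.Fraction`) for pedigree and design
  quantities; frequencies at exactly 0.5 break the minor-allele tie by
  lexicographic allele label, which leaves the estimator unchanged.
- VCF 4.2 (GT-only, `chr2`/`chr3`-style contigs with lengths) is the
  genotype interchange; PED/MAP writers exist for cross-checks against the
  standard tooling. Degenerate bootstrap resamples (constant F) are skipped
  and counted.

## Limitations

Single-locus recursion oracles ignore linkage (Hill–Robertson) effects, so
simulator/oracle agreement is asserted at 2-SD replicate tolerance, not
exactly. The ROH edge conventions above are choices, not reverse-engineered
behaviour of any particular tool, and toy-scale window oracles enforce them
exactly. No genotype-likelihood/low-coverage estimation, no IBD-HMM
methods, no X chromosome, no pedigree reconstruction from markers.
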