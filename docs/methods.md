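# Methods

This note documents the models and procedures implemented in `namgwas`,
the parameters that matter, what the synthetic data does and does not
emulate, and the numerical choices made where the design was open.

## The population model

The simulator emulates a nested association mapping (NAM) design: one
common parent crossed to F diverse founders, each cross selfed to a set
of fully inbred recombinant inbred lines (RILs).

**Founders.** Biallelic sites are placed uniformly over the genetic
map's bp range. Each site draws a minor allele frequency from a
configurable spectrum — `("beta", 0.5, 3)` scaled to (0, 0.5] by
default, rare-skewed like resequencing SFS — and founder alleles are
Bernoulli draws, redrawn while monomorphic so every emitted site
segregates. Founder alleles are independent across sites: there is no
ancestral LD among founders, so all linkage disequilibrium in the RILs
comes from co-inheritance. When a reference sequence is supplied, ref
alleles are the reference base so sites classify cleanly.

**RIL mosaics.** A RIL is one homozygous mosaic produced by a single
effective meiosis on a 2x-expanded map — the standard selfed-RIL map
expansion; crossover counts per chromosome are Poisson with mean
2 x (length in Morgans), positions uniform in cM and mapped to bp by
piecewise-linear interpolation. No crossover interference, no residual
heterozygosity, no genotyping error on anchors. Consequences: the
simulated data are cleaner than real data in exactly the ways the
projection module assumes, so passing projection tests bound the
method's error under ideal observation, not under GBS noise.

**Allele-frequency structure.** Because the common parent contributes
half of every family, an allele it carries has population frequency
0.5 + 0.5k/F' where k of the F' family founders also carry it. Rare
alleles private to the common parent therefore pile up at frequency
~0.5 — the mechanism behind the bimodal hit-MAF spectrum in NAM-style
data — and the generator reproduces it by construction.

**Gene models.** Genes are single-transcript, non-overlapping, with
UTRs, lognormal intron lengths around a 150 bp median (maize-like),
valid ATG...stop ORFs free of internal stops, and canonical GT..AG
intron dinucleotides in coding orientation. GFF3 (1-based) and FASTA
are written and read back with gffutils/Biopython; internally all
coordinates are 0-based half-open.

**Traits.** A trait is family effect + sum of beta x dosage + noise.
QTL sites are sampled from requested consequence classes or zones;
|beta| is lognormal, rank-coupled to founder MAF through a Gaussian
copula (Pearson rho = 2 sin(pi rho_s / 6)) so the expected Spearman
correlation of |beta| with MAF equals minus the requested coupling.
Heritability is defined conditional on family: h2 = var(genetic score)
/ (var(genetic score) + var(noise)). The noise vector is drawn, made
exactly orthogonal to the genetic score and the family dummies, and
scaled so realized h2 equals the request exactly. Family effects are
excluded from both sides of the definition — they are the design
nuisance every downstream model absorbs with a family covariate, and
with a handful of families their realized variance is too erratic to
budget against. `family_sd` is expressed as a multiple of the genetic
sd (default 0.3 in the pipeline).

## Projection

Parental origin along each RIL is known exactly at informative anchors
(anchors where the two parents differ) and interpolated linearly in cM
between them — the expected identity-by-descent probability for a
single effective meiosis; beyond terminal informative anchors the
nearest origin extends as a constant. Dosage at a site is
p x allele_founder + (1-p) x allele_common, so where the parents share
an allele the origin drops out. At ~1 anchor per cM the mean absolute
dosage error on simulated truth is below 0.01 and ~97% of entries are
exact (no breakpoint between informative flanking anchors).

## Joint linkage and chromosome-specific residuals

The joint-linkage model is forward stepwise OLS over anchor markers on
top of fixed family means (no random effects), with a configurable
entry p-value threshold (default 1e-4). Chromosome-specific residuals
refit the family term plus all selected anchors *not* on the focal
chromosome and subtract the fit: off-chromosome QTL and family
structure are removed while focal-chromosome signal survives. Marker
effects are re-estimated jointly in each leave-one-chromosome-out
refit rather than reusing full-model coefficients; the alternative
(fixing full-model coefficients) differs only at second order when the
selected anchors are near-orthogonal across chromosomes.

## The GWAS engine

**Forward selection.** At each step every candidate is scored by its
partial t-test p-value when added to the current OLS model; the
smallest-p candidate enters iff p < cutoff. The implementation keeps
an orthonormal basis of the current model and residualizes candidates
incrementally — algebraically identical to refitting every candidate
model (verified against a from-scratch statsmodels oracle to 1e-8 on
entry order, p-values and coefficients). Ties go to the lowest column
index (callers order columns by chromosome, position); candidates
collinear with the current model (residual norm below 1e-8 of the
column scale) are skipped and logged. p-values are computed through
the F(1, df) survival function, which equals the two-sided t-test but
is numerically stable at very small p.

**Permutation threshold.** Residuals are shuffled across lines; each
permutation records the genome-wide minimum single-marker p, and the
alpha-quantile of that distribution is the entry cutoff. The
literature value 9.50e-8 is kept as the config default but is specific
to the original dataset; every synthetic analysis derives its own
cutoff (alpha = 0.01). Calibration: with 500 lines x 2000 markers and
500 permutations, the realized genome-wide false-positive rate over
200 null traits sits inside the central 99% binomial band around 0.01.

**RMIP.** Each trait x chromosome is scanned with `n_iterations`
forward regressions (default 100), each on a uniform random 80%
subsample of lines (without replacement, seeded per trait, chromosome
and iteration). RMIP(marker) = fraction of iterations selecting it;
markers below 0.05 — fewer than 5 of 100 iterations — are dropped.
Reported effects are final joint-model coefficients of each iteration,
averaged over the iterations that selected the marker.

**Family term in the scan.** The subsampled forward models include the
family-mean term as base covariates. The residual response is already
family-centered; regressing it on *uncentered* dosages attenuates
effect estimates by the within-family variance fraction and lets
between-family allele patterns alias distant markers. With the family
term the effect estimates are unbiased for the within-family effect
and inclusion mass concentrates on causal sites. `forward_select`
itself defaults to intercept-only, so the single-marker engine is
unchanged; the base is supplied by `gwas_scan`/`rmip_scan`.

**Variance explained.** Per trait, one OLS fit of family term + all
retained hit dosages on the original line values; adjusted R^2 is
reported (family dummies span the constant, so the model is flagged as
containing one).

## Variant classification

A SNP-only, single-transcript consequence classifier with a fixed
severity order: stop_gained > stop_lost > start_lost > missense >
splice_site > synonymous > utr5 > utr3 > intron > upstream_proximal >
downstream_proximal > intergenic. Codons are assembled in coding
orientation (ref/alt arrive on the forward strand and are complemented
during assembly only); stop-retained changes count as synonymous; a
first-codon change away from ATG is start_lost unless it creates a
stop (stop_gained wins by severity). The splice window is the first
and last 2 bp of each intron. "Genic" means within the transcription
start-stop span; gene-proximal means within 5 kb of a span (both
configurable); distance ties between genes resolve to the lower
-coordinate gene. The classifier is checked against a full-CDS
retranslation oracle on 1000 random coding SNPs and is invariant under
reverse-complementing the genome and flipping all annotations. Indel
consequences, multiple transcripts, ncRNA classes and regulatory
builds are out of scope.

## Enrichment statistics

Class enrichment uses the input-site class proportions as the null:
classes with expected hit counts below 5 are dropped, the survivors
tested by Pearson chi-square; individual classes by a two-sided exact
binomial test in the minlike (point-probability) convention — the
convention R's `binom.test` uses and the one that reproduces the
published paralogy p-values. The circular-permutation null rotates all
hit positions on a chromosome by one shared uniform offset (modulo
chromosome length), preserving their number and spacing exactly;
p-values are extrapolated from a normal fit to the null counts (the
approach used when permutation counts exceed enumeration), with the
empirical rank p reported alongside and a degenerate flag when the
null is constant. Exhaustive enumeration over all offsets is available
for small layouts and agrees with sampling within Monte-Carlo error.

Gene-set tests report both the binomial p (p0 = K/N) and the two-sided
Fisher exact p. The Fisher table contrasts hit genes with the rest of
the background; whether the published table kept hit genes inside the
background column is not stated, so both constructions are computed —
the disjoint one (background minus hit genes) reproduces the printed
Fisher p and is the default. Gene-set scans adjust Fisher p-values
across sets with Benjamini-Yekutieli FDR (valid under arbitrary
dependence); BY >= BH >= raw holds by construction. Two-sample
distribution comparisons use two-sided Mann-Whitney and two-sample KS.

## Effect standardization and variance partitioning

Per trait, an empirical CDF is fit on the absolute values of *all*
effects the model identified across iterations, before RMIP filtering;
each retained polymorphism scores the ECDF value at its per-iteration
|effect| and carries the mean over its trait iterations (and over
traits for per-site summaries). Absolute values are used because
effect sign is arbitrary under allele recoding; scores depend only on
ranks. Marginal variance by class is delta adjusted R^2 between the
full hit model and the model dropping one class's hits, per trait; an
empty class scores exactly 0 and dropping everything leaves the valid
family-only model. MAF spectra fold dosage frequencies (rounded to the
nearest allele) to [0, 0.5], keeping monomorphic sites flagged at 0.
LD decay samples random same-chromosome site pairs within a distance
cap and reports percentile curves of squared Pearson correlation of
dosage columns per log-spaced distance bin; pairs with a zero-variance
member are skipped.

## Validation experiments

`experiments.null_calibration` and `experiments.qtl_recovery` are the
package's self-validation studies; `scripts/acceptance.py` runs them
from a single seed. Their fixed study design, chosen for
identifiability (the reasons follow), is: ten chromosomes of 100 cM
(4 Mb at 25 cM/Mb — compressed in bp, genetically maize-like), ~1
marker and ~1 anchor per cM, founder MAF uniform on (0.2, 0.5), 5
families x 200 RILs. The recovery trait has 10 QTL spread across
chromosomes with equal per-QTL variance shares (beta proportional to
1/sd(dosage), itself a strong negative MAF-effect coupling), h2 = 0.5,
family_sd = 0.3.

Design rationale, learned from structurally failing configurations and
verified on true genotypes (so they are identifiability limits, not
engine artifacts):

- *Rare causal variants are unlocalizable with few families.* A
  variant informative in one family projects onto the same dosage
  pattern as every other single-family variant on that chromosome up
  to the slowly-decaying origin correlation; forward selection then
  splits inclusion mass over dozens of interchangeable markers.
- *Clustered QTL create ghosts.* Several QTL on one chromosome let an
  intermediate marker correlate with their sum better than any causal
  site; chromosome-specific residuals remove this across chromosomes
  but not within one.
- *Tiny variance shares are unrecoverable.* A QTL holding ~1% of the
  variance cannot reach RMIP 0.95 at n = 1000 under any engine, so
  skewed lognormal shares test the architecture draw, not the scan.

Recovery counts a QTL when the summed RMIP of markers within 1 cM
reaches 0.95 — tightly linked markers share inclusion mass that
belongs to one signal — and nearly always the top marker is the causal
site itself. Under this design the scan recovers 9-10 of 10 QTL with
median effect error under 15% across seeds.

## Problem sizes and determinism

Default analysis sizes (pipeline config): 5 x 200 RILs, 2000 sites, 60
genes on two 2 Mb chromosomes; permutation thresholds from 200-500
permutations; 5000-10000 circular permutations. These sizes make every
stage's statistical behaviour measurable while keeping a full run in
minutes on one core. All randomness flows from one master seed through
per-purpose SHA-256-derived streams (founders / mosaics / phenotypes /
threshold / scan iterations ...), so rerunning or disabling one stage
never perturbs another and identical configs produce byte-identical
outputs.

## Known limitations

- Founders carry no ancestral LD, so input-set LD is purely
  co-inheritance; real founder haplotypes would raise input LD and
  slow its decay.
- No genotyping error, missing data, heterozygosity, segregation
  distortion, epistasis or G x E; CNVs enter only as pre-called binary
  markers.
- The classifier handles one transcript per gene and SNPs only; the
  severity order approximates the published predictor's without its
  regulatory and ncRNA classes.
- The joint-linkage and GWAS models are fixed-effects OLS throughout;
  no kinship/mixed-model control beyond the family term.
- With 5 families, mapping resolution is pattern-limited; the
  validation design documents (rather than hides) this by using
  common variants and spread QTL.
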